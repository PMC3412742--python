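"""Side-chain-augmented anisotropic network model (ANM).

Each residue contributes a backbone node at its C-alpha and, except for
glycine, one side-chain node at the centre of mass of its side-chain heavy
atoms.  Six residues whose interaction centre sits at the tip of the side
chain (ASP, ASN, ARG, LYS, GLN, GLU) use a named terminal atom instead of
the centre of mass.  Springs follow four rules, applied first-match-wins:

1. intra-residue C-alpha/side-chain tether, 10 kcal mol^-1 A^-2;
2. disulfide side-chain/side-chain bridge, 10 kcal mol^-1 A^-2;
3. sequential C-alpha pairs inside one helix or strand, 6 kcal mol^-1 A^-2
   (optionally all intra-element pairs);
4. distance shells: 3 / 2 / 1 kcal mol^-1 A^-2 for separations up to 0.4,
   0.8 and 1.2 nm; pairs beyond 1.2 nm get no spring.

Force constants are quoted in kcal mol^-1 A^-2 (the conventional ENM unit)
and converted to kJ mol^-1 nm^-2 when the Hessian is assembled, so
eigenvalues carry kJ mol^-1 nm^-2; all shape-level outputs (fluctuation
profiles, overlaps, correlations) are scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from enmpbsa.structures import Structure

#: kcal mol^-1 A^-2 -> kJ mol^-1 nm^-2
KCAL_A2_TO_KJ_NM2 = 418.4

#: Residues whose side-chain node is a named terminal atom, not the
#: side-chain centre of mass.
TERMINAL_SIDECHAIN_ATOM = {
    "ASP": "CG",
    "ASN": "CG",
    "ARG": "CZ",
    "LYS": "NZ",
    "GLN": "CD",
    "GLU": "CD",
}


@dataclass
class ENMParams:
    """Force-constant scheme of the extended ANM (kcal mol^-1 A^-2, nm)."""

    k_bonded: float = 10.0
    k_bridge: float = 10.0
    k_ss_backbone: float = 6.0
    shell_constants: tuple[float, float, float] = (3.0, 2.0, 1.0)
    shell_boundaries: tuple[float, float, float] = (0.4, 0.8, 1.2)
    #: apply the secondary-structure constant to every C-alpha pair within a
    #: contiguous helix/strand element instead of sequential pairs only
    ss_all_pairs_in_element: bool = False

    def __post_init__(self) -> None:
        consts = (self.k_bonded, self.k_bridge, self.k_ss_backbone, *self.shell_constants)
        if any(k <= 0 for k in consts):
            raise ValueError("all force constants must be positive")
        b = self.shell_boundaries
        if not (0 < b[0] < b[1] < b[2]):
            raise ValueError("shell boundaries must be strictly increasing and positive")

    @property
    def cutoff(self) -> float:
        return self.shell_boundaries[-1]

    def shell_constant(self, distance: float) -> float | None:
        for bound, k in zip(self.shell_boundaries, self.shell_constants):
            if distance <= bound:
                return k
        return None


@dataclass
class Node:
    id: int
    chain: str
    resnum: int
    resname: str
    kind: str  # "backbone" | "sidechain"
    coords: np.ndarray


@dataclass
class SpringNetwork:
    """Coarse-grained nodes plus springs (i, j, k, rest length).

    Force constants are stored in kcal mol^-1 A^-2; rest lengths equal the
    build-time node separations in nm.
    """

    nodes: list[Node]
    springs: list[tuple[int, int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for i, j, k, d in self.springs:
            if i == j:
                raise ValueError(f"spring {i}-{j} connects a node to itself")
            pair = frozenset((i, j))
            if pair in seen:
                raise ValueError(f"duplicate spring on pair {sorted(pair)}")
            seen.add(pair)

    def coords(self) -> np.ndarray:
        return np.array([n.coords for n in self.nodes], dtype=float)

    def components(self) -> np.ndarray:
        """Connected-component label per node."""
        n = len(self.nodes)
        if not self.springs:
            return np.arange(n)
        rows = [s[0] for s in self.springs] + [s[1] for s in self.springs]
        cols = [s[1] for s in self.springs] + [s[0] for s in self.springs]
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return connected_components(adj, directed=False)[1]

    def is_connected(self) -> bool:
        return len(self.nodes) > 0 and int(self.components().max(initial=0)) == 0

    def energy(self, coords: np.ndarray) -> float:
        """Total spring energy at the given node coordinates (kJ/mol).

        This is the function whose second derivatives define the Hessian;
        it exists chiefly so the assembled matrix can be cross-checked by
        finite differences.
        """
        e = 0.0
        for i, j, k, d0 in self.springs:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            e += 0.5 * k * KCAL_A2_TO_KJ_NM2 * (d - d0) ** 2
        return e


@dataclass
class ModeSet:
    """Eigenpairs of the ANM Hessian, ascending, with rigid modes counted.

    ``eigenvalues`` are in kJ mol^-1 nm^-2; ``eigenvectors`` has one
    orthonormal 3N-component mode per column.  The first ``n_rigid`` modes
    are rigid-body translations/rotations (near-zero eigenvalue).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_rigid: int
    coords: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def n_nonrigid(self) -> int:
        return self.eigenvectors.shape[1] - self.n_rigid

    def nonrigid_values(self, n_modes: int | None = None) -> np.ndarray:
        vals = self.eigenvalues[self.n_rigid:]
        return vals if n_modes is None else vals[:n_modes]

    def nonrigid_vectors(self, n_modes: int | None = None) -> np.ndarray:
        vecs = self.eigenvectors[:, self.n_rigid:]
        return vecs if n_modes is None else vecs[:, :n_modes]


def build_nodes(structure: Structure) -> list[Node]:
    """Place the ANM nodes on a structure.

    Backbone node at the C-alpha; side-chain node at the side-chain
    heavy-atom centre of mass (unit masses) or, for the six terminal-atom
    residues, at that named atom — falling back to the centre of mass with a
    warning if the atom is absent.  Glycine contributes no side-chain node.
    """
    nodes: list[Node] = []
    for res in structure.residues:
        ca = res.atom("CA")
        if ca is None:
            raise ValueError(f"residue {res.key} has no CA atom; cannot build ANM nodes")
        nodes.append(Node(len(nodes), res.chain, res.number, res.name, "backbone", np.array(ca.coords)))
        if res.name == "GLY":
            continue
        side = res.sidechain_heavy_atoms()
        if not side:
            continue
        terminal = TERMINAL_SIDECHAIN_ATOM.get(res.name)
        pos = None
        if terminal is not None:
            atom = res.atom(terminal)
            if atom is not None:
                pos = np.array(atom.coords)
            else:
                warnings.warn(f"{res.name} {res.key}: terminal atom {terminal} missing, using side-chain centre of mass")
        if pos is None:
            pos = np.mean([a.coords for a in side], axis=0)
        nodes.append(Node(len(nodes), res.chain, res.number, res.name, "sidechain", pos))
    return nodes


def _ss_elements(ss_labels) -> dict[tuple[str, int], tuple[str, int]]:
    """Assign each (chain, resnum) -> (label, element id).

    An element is a maximal run of consecutively numbered residues on one
    chain sharing the same H or E label; ``ss_labels`` must iterate in
    sequence order (dicts built from an ordered residue list do).
    """
    out: dict[tuple[str, int], tuple[str, int]] = {}
    element = -1
    prev = None
    for (chain, num), label in ss_labels.items():
        if label in ("H", "E"):
            if not (prev is not None and prev[0] == chain and prev[1] == num - 1 and prev[2] == label):
                element += 1
            out[(chain, num)] = (label, element)
        prev = (chain, num, label)
    return out


def build_springs(
    nodes: list[Node],
    params: ENMParams | None = None,
    disulfides=(),
    ss_labels=None,
) -> SpringNetwork:
    """Connect ANM nodes according to the four-rule force-constant scheme.

    ``disulfides`` is a list of ``((chain, num), (chain, num))`` CYS pairs;
    ``ss_labels`` maps ``(chain, num) -> {H,E,C}`` in sequence order.  Rules
    are applied with the precedence tether > disulfide > secondary structure
    > distance shell; bonded rules (1-2) apply regardless of the 1.2 nm
    nonbonded cutoff.  A node left without any spring is a disconnection:
    it is recorded as a warning and flagged on the returned network's modes.
    """
    params = params or ENMParams()
    ss_labels = ss_labels or {}
    elements = _ss_elements(ss_labels)
    ss_pairs = {frozenset(map(tuple, p)) for p in disulfides}

    coords = np.array([n.coords for n in nodes], dtype=float)
    pairs: set[tuple[int, int]] = set()
    # bonded pairs first (no cutoff)
    by_residue: dict[tuple[str, int], dict[str, int]] = {}
    for n in nodes:
        by_residue.setdefault((n.chain, n.resnum), {})[n.kind] = n.id
    for kinds in by_residue.values():
        if "backbone" in kinds and "sidechain" in kinds:
            pairs.add((min(kinds.values()), max(kinds.values())))
    sidechain_of = {
        (n.chain, n.resnum): n.id for n in nodes if n.kind == "sidechain"
    }
    for pair in ss_pairs:
        a, b = sorted(pair)
        ia, ib = sidechain_of.get(tuple(a)), sidechain_of.get(tuple(b))
        if ia is not None and ib is not None:
            pairs.add((min(ia, ib), max(ia, ib)))
    # nonbonded pairs within the cutoff
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(r=params.cutoff):
        pairs.add((min(i, j), max(i, j)))

    springs = []
    for i, j in sorted(pairs):
        a, b = nodes[i], nodes[j]
        d = float(np.linalg.norm(coords[i] - coords[j]))
        k = _spring_constant(a, b, d, params, ss_pairs, elements)
        if k is not None:
            springs.append((i, j, k, d))

    net = SpringNetwork(nodes=list(nodes), springs=springs)
    touched = {s[0] for s in springs} | {s[1] for s in springs}
    isolated = [n.id for n in nodes if n.id not in touched]
    if isolated:
        warnings.warn(f"{len(isolated)} node(s) have no spring: network disconnected")
    return net


def _spring_constant(a: Node, b: Node, d: float, params: ENMParams, ss_pairs, elements) -> float | None:
    if a.chain == b.chain and a.resnum == b.resnum and {a.kind, b.kind} == {"backbone", "sidechain"}:
        return params.k_bonded
    if a.kind == b.kind == "sidechain" and a.resname == b.resname == "CYS":
        if frozenset(((a.chain, a.resnum), (b.chain, b.resnum))) in ss_pairs:
            return params.k_bridge
    if a.kind == b.kind == "backbone":
        ea = elements.get((a.chain, a.resnum))
        eb = elements.get((b.chain, b.resnum))
        if ea is not None and ea == eb:
            sequential = a.chain == b.chain and abs(a.resnum - b.resnum) == 1
            if sequential or params.ss_all_pairs_in_element:
                return params.k_ss_backbone
    if d <= params.cutoff:
        return params.shell_constant(d)
    return None


def build_network(structure: Structure, params: ENMParams | None = None) -> SpringNetwork:
    """Convenience: nodes + springs straight from an annotated structure."""
    nodes = build_nodes(structure)
    return build_springs(nodes, params, structure.disulfides, structure.ss_labels())


def build_hessian(net: SpringNetwork) -> np.ndarray:
    """Assemble the 3N x 3N ANM Hessian (kJ mol^-1 nm^-2).

    For a spring (i, j) with constant k and rest vector r_ij the
    off-diagonal 3x3 super-element is -(k/d^2) r_ij r_ij^T; each diagonal
    super-element is minus the sum of its row's off-diagonals, which makes
    every uniform translation an exact null vector.
    """
    n = len(net.nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    coords = net.coords()
    h = np.zeros((3 * n, 3 * n))
    for i, j, k, _d0 in net.springs:
        rij = coords[j] - coords[i]
        d2 = float(rij @ rij)
        block = -(k * KCAL_A2_TO_KJ_NM2 / d2) * np.outer(rij, rij)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[sl_i, sl_j] += block
        h[sl_j, sl_i] += block
        h[sl_i, sl_i] -= block
        h[sl_j, sl_j] -= block
    return h


def eigenmodes(
    hessian: np.ndarray,
    n_modes: int | None = None,
    rigid_tol: float = 1e-8,
    network: SpringNetwork | None = None,
) -> ModeSet:
    """Diagonalize the Hessian and classify rigid-body modes.

    Modes with ``|lambda| <= rigid_tol * lambda_max`` are rigid.  A connected,
    externally unconstrained network has exactly six; more indicate
    disconnected bodies and raise an error naming the components when the
    network is supplied.
    """
    hessian = np.asarray(hessian, dtype=float)
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ValueError("Hessian must be symmetric")
    vals, vecs = eigh(hessian)
    lam_max = float(np.abs(vals).max())
    n_rigid = int(np.sum(np.abs(vals) <= rigid_tol * lam_max)) if lam_max > 0 else len(vals)
    if n_rigid > 6:
        detail = ""
        if network is not None:
            labels = network.components()
            groups = [np.flatnonzero(labels == c).tolist() for c in range(labels.max() + 1)]
            detail = f": disconnected components {groups}"
        raise ValueError(f"{n_rigid} near-zero modes (expected 6){detail}")
    coords = network.coords() if network is not None else None
    flags = []
    if network is not None and not network.is_connected():
        flags.append("disconnected")
    if n_modes is not None:
        keep = n_rigid + n_modes
        vals, vecs = vals[:keep], vecs[:, :keep]
    # sign convention: largest-magnitude component positive
    for m in range(vecs.shape[1]):
        peak = np.argmax(np.abs(vecs[:, m]))
        if vecs[peak, m] < 0:
            vecs[:, m] *= -1
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, n_rigid=n_rigid, coords=coords, flags=flags)


def compute_modes(structure: Structure, params: ENMParams | None = None, n_modes: int | None = None) -> ModeSet:
    """Structure -> network -> Hessian -> modes in one call."""
    net = build_network(structure, params)
    return eigenmodes(build_hessian(net), n_modes=n_modes, network=net)


def predicted_fluctuations(modes: ModeSet, n_modes: int | None = None):
    """Per-node mean-square fluctuation and B-factor profile.

    MSF_i is proportional to sum_m |v_i^m|^2 / lambda_m over the selected
    non-rigid modes (all by default) — the diagonal 3x3-trace of the
    Hessian pseudo-inverse.  B = (8 pi^2 / 3) MSF.  Both are reported up to
    a global scale (no k_B T factor); profiles, not absolute values, are
    the comparable quantity.
    """
    if modes.n_nonrigid == 0:
        raise ValueError("no non-rigid modes available")
    if n_modes is not None and n_modes > modes.n_nonrigid:
        raise ValueError(f"requested {n_modes} modes, only {modes.n_nonrigid} available")
    vals = modes.nonrigid_values(n_modes)
    vecs = modes.nonrigid_vectors(n_modes)
    per_node = vecs.reshape(modes.n_nodes, 3, -1)
    msf = np.einsum("nxm,nxm,m->n", per_node, per_node, 1.0 / vals)
    return msf, (8.0 * np.pi**2 / 3.0) * msf


def mode_overlap(a: ModeSet, b: ModeSet, node_map=None, n: int = 10) -> np.ndarray:
    """Absolute dot products between the first ``n`` non-rigid modes.

    ``node_map`` lists ``(node_in_a, node_in_b)`` index pairs spanning the
    common region (e.g. the receptor residues shared by two complexes);
    identity is assumed when omitted and the models are the same size.
    Sub-vectors over the mapped nodes are renormalized before the dot
    product, so values fall in [0, 1].
    """
    if node_map is None:
        if a.n_nodes != b.n_nodes:
            raise ValueError("node_map required when mode sets differ in size")
        node_map = [(i, i) for i in range(a.n_nodes)]
    node_map = list(node_map)
    if not node_map:
        raise ValueError("node_map is empty")
    ia = np.array([p[0] for p in node_map])
    ib = np.array([p[1] for p in node_map])
    n_a = min(n, a.n_nonrigid)
    n_b = min(n, b.n_nonrigid)
    va = a.nonrigid_vectors(n_a).reshape(a.n_nodes, 3, -1)[ia].reshape(3 * len(ia), -1)
    vb = b.nonrigid_vectors(n_b).reshape(b.n_nodes, 3, -1)[ib].reshape(3 * len(ib), -1)
    va = va / np.linalg.norm(va, axis=0, keepdims=True)
    vb = vb / np.linalg.norm(vb, axis=0, keepdims=True)
    return np.abs(va.T @ vb)


def nma_correlation(modes: ModeSet, n_modes: int = 25) -> np.ndarray:
    """Node-node cross-correlation map from the lowest-frequency modes.

    cov(i, j) is the trace of the 3x3 (i, j) block of the n-mode Hessian
    pseudo-inverse; the returned matrix is cov normalized to unit diagonal,
    hence in [-1, 1].
    """
    if modes.n_nonrigid < n_modes:
        raise ValueError(f"need {n_modes} non-rigid modes, have {modes.n_nonrigid}")
    vals = modes.nonrigid_values(n_modes)
    vecs = modes.nonrigid_vectors(n_modes).reshape(modes.n_nodes, 3, -1)
    cov = np.einsum("ixm,jxm,m->ij", vecs, vecs, 1.0 / vals)
    var = np.diag(cov)
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0).tolist()
        raise ValueError(f"nodes with zero variance: {bad}")
    return cov / np.sqrt(np.outer(var, var))


def mode_displacement_vectors(modes: ModeSet, mode_index: int = 0, target_rmsd: float = 0.2) -> np.ndarray:
    """Per-node displacement arrows for one non-rigid mode.

    The unit eigenvector is scaled so that the RMSD between the structures
    elongated along +v and -v equals ``target_rmsd`` (nm; the conventional
    display choice is 2 A = 0.2 nm).  Returns an (N, 3) array; the two
    elongations are ``coords +/- arrows``.
    """
    if not 0 <= mode_index < modes.n_nonrigid:
        raise ValueError(f"mode_index {mode_index} out of range (0..{modes.n_nonrigid - 1})")
    v = modes.nonrigid_vectors()[:, mode_index]
    v = v / np.linalg.norm(v)
    n = modes.n_nodes
    # RMSD(+s, -s) = 2 s / sqrt(N) for a unit mode
    s = target_rmsd * np.sqrt(n) / 2.0
    return (s * v).reshape(n, 3)


def write_nmd(modes: ModeSet, path, n_modes: int | None = None, names=None) -> None:
    """Write modes as NMD-style plain text (coordinates, then one line per
    mode: index, eigenvalue, 3N vector).  Rigid modes are flagged."""
    vals = modes.eigenvalues if n_modes is None else modes.eigenvalues[: modes.n_rigid + n_modes]
    vecs = modes.eigenvectors[:, : len(vals)]
    with open(path, "w") as out:
        if names is not None:
            out.write("names " + " ".join(map(str, names)) + "\n")
        if modes.coords is not None:
            out.write("coordinates " + " ".join(f"{x:.4f}" for x in np.ravel(modes.coords)) + "\n")
        for m, lam in enumerate(vals):
            tag = "rigid" if m < modes.n_rigid else "mode"
            comps = " ".join(f"{x:.6f}" for x in vecs[:, m])
            out.write(f"{tag} {m + 1} {lam:.6e} {comps}\n")
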