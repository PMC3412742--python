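"""Seeded generators for every input the analysis stages consume.

Nothing here runs dynamics.  Toy structures are idealized C-alpha traces
with pseudo side chains; ensembles are drawn directly from the Gaussian
distribution an elastic network model defines (covariance proportional to
the Hessian pseudo-inverse with rigid modes excluded), which gives the
fluctuation and correlation stages a closed-form ground truth; hydrogen-
bond interfaces are planted geometrically; energy tables are i.i.d.
Gaussian around known means so ledger aggregation is a parameter-recovery
exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from enmpbsa.enm import SpringNetwork, build_hessian, eigenmodes
from enmpbsa.structures import Atom, Residue, Structure
from enmpbsa.trajectory import Trajectory

_HELIX = {"radius": 0.23, "rise": 0.15, "twist_deg": 100.0}
_EXTENDED = {"radius": 0.20, "rise": 0.32, "twist_deg": 60.0}


@dataclass
class ToySpec:
    """Recipe for a deterministic toy protein.

    ``ss_pattern`` is a string over H/E/C of length ``n_residues``;
    ``disulfides`` lists 1-based residue-number pairs on the first chain
    (those residues become CYS with SG atoms placed ~0.203 nm apart);
    ``layout`` is one of single / dimer / trimer / trimer+receptors.
    """

    n_residues: int
    ss_pattern: str | None = None
    disulfides: list = field(default_factory=list)
    layout: str = "single"
    seed: int = 0
    residue_names: list | None = None

    def __post_init__(self) -> None:
        if self.ss_pattern is None:
            self.ss_pattern = "C" * self.n_residues
        if len(self.ss_pattern) != self.n_residues:
            raise ValueError("ss_pattern length must equal n_residues")
        if set(self.ss_pattern) - set("HEC"):
            raise ValueError("ss_pattern must use only H, E, C")
        if self.residue_names is not None and len(self.residue_names) != self.n_residues:
            raise ValueError("residue_names length must equal n_residues")


def _ca_trace(spec: ToySpec, rng: np.random.Generator) -> np.ndarray:
    """Idealized C-alpha trace: helical geometry for H runs, a wider
    extended spiral for E/C, with a tiny seeded jitter on coil so the trace
    is never exactly degenerate."""
    coords = np.zeros((spec.n_residues, 3))
    z = 0.0
    angle = 0.0
    for i, label in enumerate(spec.ss_pattern):
        geom = _HELIX if label == "H" else _EXTENDED
        if i > 0:
            angle += np.radians(geom["twist_deg"])
            z += geom["rise"]
        jitter = rng.normal(0.0, 0.01, size=3) if label == "C" else 0.0
        coords[i] = (
            np.array([geom["radius"] * np.cos(angle), geom["radius"] * np.sin(angle), z]) + jitter
        )
    return coords


def make_toy_structure(spec: ToySpec) -> Structure:
    """Build a toy structure satisfying the package's preconditions.

    Every residue gets N/CA/C/O backbone atoms and (except GLY) a CB
    pseudo side chain; CYS residues named in ``disulfides`` get SG atoms
    positioned to give an SG-SG separation of ~0.203 nm.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    ca = _ca_trace(spec, rng)

    names = list(spec.residue_names) if spec.residue_names else ["ALA"] * spec.n_residues
    ss_members = set()
    for i, j in spec.disulfides:
        for r in (i, j):
            if not 1 <= r <= spec.n_residues:
                raise ValueError(f"disulfide residue {r} out of range")
            names[r - 1] = "CYS"
            ss_members.add(r)

    def chain_residues(chain: str, offset: np.ndarray, rotation: np.ndarray | None = None) -> list[Residue]:
        xyz = ca @ rotation.T if rotation is not None else ca.copy()
        xyz = xyz + offset
        residues = []
        for i in range(spec.n_residues):
            pos = xyz[i]
            # local frame: radial direction (away from the z axis of this copy)
            radial = pos - offset
            radial[2] = 0.0
            nrm = np.linalg.norm(radial)
            radial = radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            atoms = [
                Atom("N", "N", pos + np.array([-0.10, 0.0, -0.06])),
                Atom("CA", "C", pos),
                Atom("C", "C", pos + np.array([0.10, 0.0, 0.06])),
                Atom("O", "O", pos + np.array([0.16, 0.0, 0.12])),
            ]
            if names[i] != "GLY":
                cb = pos + 0.153 * radial
                atoms.append(Atom("CB", "C", cb))
                if names[i] == "CYS" and (i + 1) not in ss_members:
                    atoms.append(Atom("SG", "S", cb + 0.18 * radial))
            residues.append(Residue(name=names[i], number=i + 1, chain=chain, atoms=atoms, ss_label=spec.ss_pattern[i]))
        return residues

    layouts = {
        "single": [("A", np.zeros(3))],
        "dimer": [("A", np.zeros(3)), ("B", np.array([2.5, 0.0, 0.0]))],
        "trimer": [
            ("A", np.zeros(3)),
            ("B", np.array([2.5, 0.0, 0.0])),
            ("C", np.array([0.0, 2.5, 0.0])),
        ],
        "trimer+receptors": [
            ("A", np.zeros(3)),
            ("B", np.array([2.5, 0.0, 0.0])),
            ("C", np.array([0.0, 2.5, 0.0])),
            ("R", np.array([-2.5, 0.0, 0.0])),
            ("S", np.array([0.0, -2.5, 0.0])),
            ("T", np.array([-2.5, -2.5, 0.0])),
        ],
    }
    if spec.layout not in layouts:
        raise ValueError(f"unknown layout {spec.layout!r}")
    residues = []
    first_chain = layouts[spec.layout][0][0]
    for chain, offset in layouts[spec.layout]:
        residues.extend(chain_residues(chain, offset))

    structure = Structure(residues=residues)
    # place disulfide SG pairs on the first chain, straddling the midpoint
    pairs = []
    for i, j in spec.disulfides:
        ri = structure.residue(first_chain, i)
        rj = structure.residue(first_chain, j)
        pi, pj = ri.atom("CA").coords, rj.atom("CA").coords
        gap = np.linalg.norm(pj - pi)
        if gap > 1.3:
            raise ValueError(f"disulfide {i}-{j} infeasible: CA separation {gap:.2f} nm")
        mid = 0.5 * (pi + pj)
        axis = (pj - pi) / gap
        ri.atoms.append(Atom("SG", "S", mid - 0.1015 * axis))
        rj.atoms.append(Atom("SG", "S", mid + 0.1015 * axis))
        pairs.append(((first_chain, i), (first_chain, j)))
    structure.disulfides = pairs
    return structure


@dataclass
class EnsembleSpec:
    """Gaussian ensemble drawn from a spring network's own normal modes.

    ``temperature`` is a global variance scale (nm^2 per inverse
    eigenvalue unit); all downstream comparisons are shape-based, so only
    relative fluctuations matter.
    """

    network: SpringNetwork
    n_frames: int = 100
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def sample_node_displacements(spec: EnsembleSpec):
    """Draw node displacements from the ENM Gaussian.

    Each frame is sum_m (z_m sqrt(T / lambda_m)) v_m with z_m standard
    normal, so projections onto rigid modes are identically zero and the
    variance along mode m is T / lambda_m.  Returns ``(displacements
    (n_frames, n_nodes, 3), modes)``.
    """
    net = spec.network
    if not net.is_connected():
        raise ValueError("network is disconnected; ensemble undefined")
    modes = eigenmodes(build_hessian(net), network=net)
    vals = modes.nonrigid_values()
    vecs = modes.nonrigid_vectors()
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, len(vals)))
    amp = np.sqrt(spec.temperature / vals)
    disp = (z * amp) @ vecs.T
    return disp.reshape(spec.n_frames, len(net.nodes), 3), modes


def sample_enm_ensemble(spec: EnsembleSpec, structure: Structure) -> Trajectory:
    """Turn ENM node displacements into an atom-level trajectory.

    Each atom inherits the displacement of its residue's node — backbone
    atoms follow the backbone node, side-chain atoms the side-chain node
    (falling back to backbone when a residue has none) — so the C-alpha
    statistics of the trajectory are exactly the backbone-node model.  The
    network must have been built from ``structure``.
    """
    from enmpbsa.structures import BACKBONE_ATOMS

    disp, _modes = sample_node_displacements(spec)
    node_of: dict[tuple[str, int, str], int] = {}
    for n in spec.network.nodes:
        node_of[(n.chain, n.resnum, n.kind)] = n.id
    records = structure.atom_records()
    atom_node = []
    for res, atom in records:
        kind = "backbone" if (atom.name in BACKBONE_ATOMS or atom.is_hydrogen) else "sidechain"
        idx = node_of.get((res.chain, res.number, kind))
        if idx is None:
            idx = node_of.get((res.chain, res.number, "backbone"))
        if idx is None:
            raise ValueError(f"no node for residue {res.key}; network/structure mismatch")
        atom_node.append(idx)
    base = np.array([a.coords for _, a in records])
    frames = base[None, :, :] + disp[:, atom_node, :]
    return Trajectory(topology=structure, frames=frames)


def make_planted_interface(n_bonds: int, n_decoys: int, seed: int = 0, n_frames: int = 1, occupancy: dict | None = None):
    """Plant an interface with known hydrogen-bond content.

    ``n_bonds`` donor-acceptor pairs satisfy the default geometric criteria
    (collinear N-H...O, d = 0.30 nm); ``n_decoys`` pairs each violate
    exactly one criterion (alternating distance > 0.35 nm and a 90-degree
    D-H...A kink).  Pairs are spaced 2 nm apart so they cannot interact.
    ``occupancy`` maps planted-bond index -> per-frame presence flags; an
    absent bond has its acceptor retracted to 0.50 nm.  Returns
    ``(structure, trajectory)``.
    """
    if n_bonds < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    occupancy = occupancy or {}
    residues = []
    total = n_bonds + n_decoys
    for k in range(total):
        z = 2.0 * k
        decoy = k >= n_bonds
        donor_atoms = [
            Atom("N", "N", np.array([0.0, 0.0, z])),
            Atom("H", "H", np.array([0.10, 0.0, z]), is_hydrogen=True),
        ]
        if decoy and (k - n_bonds) % 2 == 0:
            acceptor_pos = np.array([0.40, 0.0, z])  # distance violation
        elif decoy:
            acceptor_pos = np.array([0.10, 0.25, z])  # angle violation (90 deg at H)
        else:
            acceptor_pos = np.array([0.30, 0.0, z])
        residues.append(Residue(name="ASN", number=k + 1, chain="A", atoms=donor_atoms))
        residues.append(Residue(name="SER", number=k + 1, chain="B", atoms=[Atom("O", "O", acceptor_pos)]))
    structure = Structure(residues=residues)

    base = structure.coords()
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    records = structure.atom_records()
    for bond_idx, schedule in occupancy.items():
        if not 0 <= bond_idx < n_bonds:
            raise ValueError(f"occupancy for non-planted bond {bond_idx}")
        acceptor_flat = next(
            i for i, (res, atom) in enumerate(records)
            if res.chain == "B" and res.number == bond_idx + 1 and atom.name == "O"
        )
        schedule = list(schedule)
        if len(schedule) != n_frames:
            raise ValueError("occupancy schedule length must equal n_frames")
        z = 2.0 * bond_idx
        for f, present in enumerate(schedule):
            frames[f, acceptor_flat] = [0.30 if present else 0.50, 0.0, z]
    return structure, Trajectory(topology=structure, frames=frames)


def make_energy_table(true_means: dict, noise_sigma, n: int, seed: int = 0) -> pd.DataFrame:
    """Per-snapshot energy-component table with known truth.

    Columns are the keys of ``true_means``; each is i.i.d. Gaussian around
    its mean with ``noise_sigma`` (a scalar or per-column mapping).
    """
    if n < 2:
        raise ValueError("need at least 2 snapshots")
    rng = np.random.default_rng(seed)
    data = {}
    for col, mu in true_means.items():
        sigma = noise_sigma.get(col) if isinstance(noise_sigma, dict) else noise_sigma
        data[col] = mu + float(sigma) * rng.standard_normal(n)
    return pd.DataFrame(data)
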