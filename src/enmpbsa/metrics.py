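"""Trajectory- and structure-level observables.

Superposition RMSD, per-residue RMSF, dynamic cross-correlation maps,
geometric hydrogen bonds, Shrake-Rupley solvent-accessible surface area,
buried interface area and centre-of-group distance monitors.  All
coordinate arithmetic happens in the package's native nanometres; SASA is
reported in A^2 because the apolar solvation model's surface-tension
coefficient is conventionally quoted per A^2.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from enmpbsa.structures import Structure
from enmpbsa.trajectory import Trajectory, selection_keys

NM2_TO_A2 = 100.0

#: Bondi-style van der Waals radii, nm.
DEFAULT_VDW_RADII = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    A donor-acceptor contact counts when the donor-acceptor distance is at
    most ``d_cut`` (nm) and the donor-hydrogen-acceptor geometry deviates
    from linearity by at most ``angle_cut`` degrees (i.e. the D-H...A angle
    is >= 180 - angle_cut).  Setting ``angle_is_deviation_from_linear`` to
    False instead requires the raw D-H...A angle itself to be <= angle_cut,
    for tools that quote the criterion that way.
    """

    d_cut: float = 0.35
    angle_cut: float = 60.0
    angle_is_deviation_from_linear: bool = True
    #: maximum distance at which a hydrogen counts as bonded to its donor
    dh_bond_cut: float = 0.12

    def __post_init__(self) -> None:
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")
        if not 0 < self.angle_cut < 180:
            raise ValueError("angle_cut must be in (0, 180)")

    def angle_ok(self, dha_deg: float) -> bool:
        if self.angle_is_deviation_from_linear:
            return (180.0 - dha_deg) <= self.angle_cut
        return dha_deg <= self.angle_cut


@dataclass
class SASAConfig:
    probe_radius: float = 0.14  # nm, water probe
    n_points: int = 960
    radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    default_radius: float | None = None
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")
        if self.n_points < 32:
            raise ValueError("need at least 32 sphere points")

    def radius_of(self, element: str) -> float:
        r = self.radii.get(element, self.default_radius)
        if r is None:
            raise KeyError(f"no van der Waals radius for element {element!r}")
        return r


# ---------------------------------------------------------------------------
# superposition / RMSD / RMSF / DCCM


def kabsch_superpose(ref: np.ndarray, mob: np.ndarray):
    """Least-squares rigid-body fit of ``mob`` onto ``ref``.

    Returns ``(rotation 3x3, translation 3-vector, rmsd)`` such that
    ``mob @ rotation.T + translation`` best matches ``ref``; the RMSD is in
    the units of the input coordinates.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError(f"coordinate sets differ in shape: {ref.shape} vs {mob.shape}")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    rmat = rot.as_matrix()
    translation = ref_c - rmat @ mob_c
    fitted = mob @ rmat.T + translation
    rmsd = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
    return rmat, translation, float(rmsd)


def apply_fit(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def rmsd_series(
    traj: Trajectory,
    ref: Structure | None = None,
    selection=None,
    exclusions=(),
) -> pd.Series:
    """Per-frame C-alpha RMSD to a reference after Kabsch fitting.

    ``selection``/``exclusions`` are residue-key lists or ``chain:start-end``
    strings; each frame is superposed on the reference over the effective
    selection (selection minus exclusions) and the RMSD reported over the
    same atoms.  Excluding floppy regions (e.g. the receptor tail 134-153)
    keeps the fit from being dragged around by them.
    """
    ref = ref or traj.topology
    keys = _resolve_keys(traj.topology, selection)
    excluded = set(map(tuple, _resolve_keys(traj.topology, exclusions, default=[])))
    effective = [k for k in keys if tuple(k) not in excluded]
    if not effective:
        raise ValueError("effective selection is empty after exclusions")
    idx = traj.ca_indices(effective)
    ref_xyz = ref.ca_coords(effective)
    out = np.empty(len(traj))
    for f, frame in enumerate(traj.frames):
        _, _, out[f] = kabsch_superpose(ref_xyz, frame[idx])
    return pd.Series(out, index=pd.Index(traj.times, name="time_ps"), name="rmsd_nm")


def _resolve_keys(structure: Structure, selection, default=None):
    if selection is None:
        return default if default is not None else [r.key for r in structure.residues]
    if isinstance(selection, str):
        return selection_keys(structure, selection)
    return [tuple(k) for k in selection]


def _superposed_ca(traj: Trajectory, selection) -> tuple[np.ndarray, list]:
    """Frames' C-alpha coordinates superposed on the ensemble average
    (align to first frame, average, re-align to the average once)."""
    keys = _resolve_keys(traj.topology, selection)
    idx = traj.ca_indices(keys)
    xyz = traj.frames[:, idx, :].copy()
    if len(xyz) < 2:
        raise ValueError("need at least 2 frames")
    for ref in (xyz[0], None):
        target = xyz.mean(axis=0) if ref is None else ref
        for f in range(len(xyz)):
            r, t, _ = kabsch_superpose(target, xyz[f])
            xyz[f] = apply_fit(xyz[f], r, t)
    return xyz, keys


def rmsf(traj: Trajectory, selection=None) -> pd.Series:
    """Per-residue C-alpha root-mean-square fluctuation about the mean
    structure (nm), after superposition on that mean."""
    xyz, keys = _superposed_ca(traj, selection)
    dev = xyz - xyz.mean(axis=0)
    values = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return pd.Series(values, index=_key_index(keys), name="rmsf_nm")


def dccm(traj: Trajectory, selection=None) -> pd.DataFrame:
    """Dynamic cross-correlation matrix of C-alpha displacements.

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) after superposition on the
    mean structure; unit diagonal, symmetric, values in [-1, 1].
    """
    xyz, keys = _superposed_ca(traj, selection)
    dev = xyz - xyz.mean(axis=0)
    cov = np.einsum("fix,fjx->ij", dev, dev) / len(dev)
    var = np.diag(cov)
    zero = np.flatnonzero(var <= 0)
    if zero.size:
        raise ValueError(f"zero-variance residues: {[tuple(keys[i]) for i in zero]}")
    c = cov / np.sqrt(np.outer(var, var))
    labels = _key_index(keys)
    return pd.DataFrame(np.clip(c, -1.0, 1.0), index=labels, columns=labels)


def _key_index(keys):
    return pd.Index([f"{c}:{n}" for c, n in keys], name="residue")


# ---------------------------------------------------------------------------
# hydrogen bonds


def _polar_atoms(structure: Structure):
    """(index, residue, atom) triples split into heavies (N/O) and hydrogens."""
    heavies, hydrogens = [], []
    for i, (res, atom) in enumerate(structure.atom_records()):
        if atom.is_hydrogen:
            hydrogens.append((i, res, atom))
        elif atom.element in ("N", "O"):
            heavies.append((i, res, atom))
    return heavies, hydrogens


def hydrogen_bonds(structure: Structure, criteria: HBondCriteria | None = None):
    """Count geometric hydrogen bonds in one frame.

    Donors are N/O atoms with at least one hydrogen within the donor-H bond
    cutoff; acceptors are all N/O atoms.  Same-residue donor-acceptor pairs
    are ignored.  Returns ``(count, pairs)`` where each pair is
    ``((donor_key, donor_name), (acceptor_key, acceptor_name))``.
    """
    criteria = criteria or HBondCriteria()
    heavies, hydrogens = _polar_atoms(structure)
    bonds = []
    seen = set()
    for di, dres, datom in heavies:
        attached = [
            (hi, hatom)
            for hi, hres, hatom in hydrogens
            if np.linalg.norm(hatom.coords - datom.coords) <= criteria.dh_bond_cut
        ]
        if not attached:
            continue
        for ai, ares, aatom in heavies:
            if ai == di or (ares.key == dres.key):
                continue
            d = float(np.linalg.norm(aatom.coords - datom.coords))
            if d > criteria.d_cut:
                continue
            for hi, hatom in attached:
                angle = _angle_deg(datom.coords, hatom.coords, aatom.coords)
                if criteria.angle_ok(angle):
                    tag = (di, ai)
                    if tag not in seen:
                        seen.add(tag)
                        bonds.append(((dres.key, datom.name), (ares.key, aatom.name)))
                    break
    return len(bonds), bonds


def _angle_deg(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.asarray(a) - np.asarray(b)
    v2 = np.asarray(c) - np.asarray(b)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_occupancy(traj: Trajectory, pair, criteria: HBondCriteria | None = None) -> float:
    """Fraction of frames in which a given donor-acceptor hydrogen bond is
    present.  ``pair`` is ``((chain, resnum, donor_atom), (chain, resnum,
    acceptor_atom))``."""
    criteria = criteria or HBondCriteria()
    (dc, dn, da), (ac, an, aa) = pair
    di = traj.atom_index(dc, dn, da)
    ai = traj.atom_index(ac, an, aa)
    donor_res = traj.topology.residue(dc, dn)
    h_names = [a.name for a in donor_res.atoms if a.is_hydrogen]
    h_idx = [traj.atom_index(dc, dn, name) for name in h_names]
    if not h_idx:
        warnings.warn(f"donor {dc}:{dn}:{da} has no hydrogens; occupancy is 0")
        return 0.0
    hits = 0
    for frame in traj.frames:
        if np.linalg.norm(frame[ai] - frame[di]) > criteria.d_cut:
            continue
        for hi in h_idx:
            if np.linalg.norm(frame[hi] - frame[di]) > criteria.dh_bond_cut:
                continue
            if criteria.angle_ok(_angle_deg(frame[di], frame[hi], frame[ai])):
                hits += 1
                break
    return hits / len(traj)


# ---------------------------------------------------------------------------
# SASA / buried area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(structure: Structure, cfg: SASAConfig | None = None):
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is inflated by the probe radius and sampled with a fixed
    golden-spiral point set; a point survives if it lies outside every other
    inflated atom.  Returns ``(per_residue: pd.Series, total: float)`` in
    A^2; deterministic for a fixed point count.
    """
    cfg = cfg or SASAConfig()
    records = [
        (res, atom)
        for res, atom in structure.atom_records()
        if cfg.include_hydrogens or not atom.is_hydrogen
    ]
    if not records:
        raise ValueError("no atoms to compute SASA for")
    centers = np.array([a.coords for _, a in records])
    radii = np.array([cfg.radius_of(a.element) + cfg.probe_radius for _, a in records])
    unit = _sphere_points(cfg.n_points)
    tree = cKDTree(centers)
    per_atom = np.zeros(len(records))
    max_r = radii.max()
    for i, (center, r) in enumerate(zip(centers, radii)):
        pts = center + r * unit
        neighbors = [j for j in tree.query_ball_point(center, r + max_r) if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - centers[j], axis=1)
            exposed &= d > radii[j]
        per_atom[i] = 4.0 * np.pi * r**2 * exposed.mean() * NM2_TO_A2
    keys = []
    per_res: dict = {}
    for (res, _), area in zip(records, per_atom):
        label = f"{res.chain}:{res.number}"
        if label not in per_res:
            per_res[label] = 0.0
            keys.append(label)
        per_res[label] += area
    series = pd.Series([per_res[k] for k in keys], index=pd.Index(keys, name="residue"), name="sasa_A2")
    return series, float(per_atom.sum())


def _substructure(structure: Structure, chains) -> Structure:
    chains = set(chains)
    picked = [copy.deepcopy(r) for r in structure.residues if r.chain in chains]
    keys = {r.key for r in picked}
    ss = [(a, b) for a, b in structure.disulfides if tuple(a) in keys and tuple(b) in keys]
    return Structure(residues=picked, disulfides=ss)


def buried_area(source, partition: dict, cfg: SASAConfig | None = None) -> pd.Series:
    """Per-residue buried surface area of a complex, averaged over frames.

    ``partition`` maps partner name -> list of chain ids; the partners must
    cover every chain of the complex exactly once.  For each frame the
    buried area of residue i is SASA_i(its partner alone) minus
    SASA_i(complex) — non-negative up to quadrature noise.  ``source`` is a
    Trajectory or a single Structure.
    """
    cfg = cfg or SASAConfig()
    if isinstance(source, Structure):
        topo, frames = source, [source.coords()]
    else:
        topo, frames = source.topology, list(source.frames)
    all_chains = topo.chains()
    claimed: list[str] = []
    for chains in partition.values():
        claimed.extend(chains)
    if sorted(claimed) != sorted(all_chains) or len(claimed) != len(set(claimed)):
        raise ValueError(
            f"partition {dict(partition)} does not cover chains {all_chains} exactly once"
        )
    work = copy.deepcopy(topo)
    partners = {name: _substructure(topo, chains) for name, chains in partition.items()}
    partner_records = {
        name: [i for i, (res, _) in enumerate(topo.atom_records()) if res.chain in set(chains)]
        for name, chains in partition.items()
    }
    total = None
    for frame in frames:
        work.set_coords(frame)
        complex_sasa, _ = sasa(work, cfg)
        buried = pd.Series(0.0, index=complex_sasa.index)
        for name, sub in partners.items():
            sub.set_coords(np.asarray(frame)[partner_records[name]])
            alone, _ = sasa(sub, cfg)
            buried.loc[alone.index] = alone - complex_sasa.loc[alone.index]
        total = buried if total is None else total + buried
    result = total / len(frames)
    result.name = "buried_A2"
    return result


# ---------------------------------------------------------------------------
# distance monitors


def _group_indices(traj: Trajectory, group) -> np.ndarray:
    """Resolve a group spec into flat atom indices: a ``chain:start-end``
    string (all atoms of those residues), an iterable of residue keys, or an
    iterable of integer atom indices."""
    if isinstance(group, str):
        keys = {tuple(k) for k in selection_keys(traj.topology, group)}
        idx = [i for i, (res, _) in enumerate(traj.topology.atom_records()) if res.key in keys]
    else:
        group = list(group)
        if group and isinstance(group[0], (int, np.integer)):
            idx = [int(i) for i in group]
        else:
            keys = {tuple(k) for k in group}
            idx = [i for i, (res, _) in enumerate(traj.topology.atom_records()) if res.key in keys]
    if not idx:
        raise ValueError(f"group {group!r} resolves to no atoms")
    return np.array(idx)


def group_distance(traj: Trajectory, group_a, group_b, mass_weighted: bool = False) -> pd.Series:
    """Per-frame distance between the geometric centres of two atom groups
    (nm).  Mass weighting uses rough integer element masses when enabled."""
    ia, ib = _group_indices(traj, group_a), _group_indices(traj, group_b)
    if mass_weighted:
        masses = {"H": 1.0, "C": 12.0, "N": 14.0, "O": 16.0, "S": 32.0, "P": 31.0}
        records = traj.topology.atom_records()
        wa = np.array([masses.get(records[i][1].element, 12.0) for i in ia])
        wb = np.array([masses.get(records[i][1].element, 12.0) for i in ib])
    else:
        wa = np.ones(len(ia))
        wb = np.ones(len(ib))
    ca = np.einsum("fix,i->fx", traj.frames[:, ia, :], wa / wa.sum())
    cb = np.einsum("fix,i->fx", traj.frames[:, ib, :], wb / wb.sum())
    d = np.linalg.norm(ca - cb, axis=1)
    return pd.Series(d, index=pd.Index(traj.times, name="time_ps"), name="distance_nm")


def atom_pair_distance(traj: Trajectory, atom_a, atom_b) -> pd.Series:
    """Per-frame distance between two atoms given as (chain, resnum, name)."""
    ia = traj.atom_index(*atom_a)
    ib = traj.atom_index(*atom_b)
    d = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
    return pd.Series(d, index=pd.Index(traj.times, name="time_ps"), name="distance_nm")
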