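"""MM/PBSA free-energy bookkeeping.

The binding free energy of a complex is estimated as

    dG_binding = dG_complex - dG_protein - dG_ligand
    G          = H_gas + G_solv - TS          (TS neglected throughout)
    H_gas      = H_int + H_vdW + H_elect
    G_solv     = G_polar + G_apolar
    G_apolar   = gamma * SASA + b

with all energies in kJ/mol and SASA in A^2.  Gas-phase Coulomb and
Lennard-Jones terms are full direct sums — no cutoff, no periodicity.  The
polar solvation term comes from an external Poisson-Boltzmann solve and
enters as a per-snapshot input column whose solver settings are recorded as
:class:`PolarInputSpec` metadata.  Two assembly modes are provided:

* SITA (single-trajectory): partner coordinates are taken from the complex
  trajectory, so bonded terms cancel exactly and the gas-phase differences
  reduce to cross-partner pair sums.
* SETA (separate-trajectory): each species brings its own snapshot set;
  per-species means are combined with the reaction's stoichiometric
  coefficients (the unbound receptor is supplied as half a dimer) and SEMs
  add in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from enmpbsa.metrics import SASAConfig, sasa
from enmpbsa.structures import Structure
from enmpbsa.trajectory import Trajectory

#: Coulomb constant 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458

GAS_COMPONENTS = ["H_int", "H_vdW", "H_elect"]
SOLV_COMPONENTS = ["G_polar", "G_apolar"]
ALL_COMPONENTS = GAS_COMPONENTS + SOLV_COMPONENTS


@dataclass
class ApolarModel:
    """Linear SASA model for the apolar solvation free energy,
    G_apolar = gamma * SASA + b (gamma in kJ mol^-1 A^-2, b in kJ mol^-1)."""

    gamma: float = 0.0227
    b: float = 3.85112

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gamma) and math.isfinite(self.b)):
            raise ValueError("gamma and b must be finite")


@dataclass
class PolarInputSpec:
    """Settings of the external Poisson-Boltzmann solve behind an imported
    G_polar column; recorded verbatim as provenance with every ledger."""

    solute_dielectric: float = 2.0
    solvent_dielectric: float = 78.54
    grid_points: int = 225
    grid_spacing_A: float = 0.5
    dielectric_boundary: str = "van der Waals surface"
    counterions: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FFParams:
    """Per-atom nonbonded parameters keyed by (chain, resnum, atom name).

    ``charges`` in elementary charges; ``lj`` maps to (sigma nm, epsilon
    kJ/mol) combined by the stated rule ("geometric", the Gromos choice, or
    "lorentz").  ``bonded`` optionally carries harmonic bond/angle and
    periodic dihedral terms for internal energies.
    """

    charges: dict = field(default_factory=dict)
    lj: dict = field(default_factory=dict)
    combination_rule: str = "geometric"
    bonded: "BondedTerms | None" = None

    def __post_init__(self) -> None:
        if self.combination_rule not in ("geometric", "lorentz"):
            raise ValueError(f"unknown combination rule {self.combination_rule!r}")

    @classmethod
    def from_table(cls, table, combination_rule: str = "geometric") -> "FFParams":
        """Build from a delimited per-atom table with columns
        chain, resnum, atom, charge, sigma, epsilon."""
        df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep=None, engine="python")
        charges, lj = {}, {}
        for row in df.itertuples(index=False):
            key = (str(row.chain), int(row.resnum), str(row.atom))
            charges[key] = float(row.charge)
            lj[key] = (float(row.sigma), float(row.epsilon))
        return cls(charges=charges, lj=lj, combination_rule=combination_rule)

    def _gather(self, structure: Structure, what: str):
        keys = [(res.chain, res.number, atom.name) for res, atom in structure.atom_records()]
        source = self.charges if what == "charge" else self.lj
        missing = [k for k in keys if k not in source]
        if missing:
            raise KeyError(f"missing {what} parameters for atoms: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        return [source[k] for k in keys]

    def charge_array(self, structure: Structure) -> np.ndarray:
        return np.array(self._gather(structure, "charge"), dtype=float)

    def lj_arrays(self, structure: Structure):
        pairs = self._gather(structure, "lj")
        sig = np.array([p[0] for p in pairs])
        eps = np.array([p[1] for p in pairs])
        return sig, eps


@dataclass
class BondedTerms:
    """Harmonic bonds/angles and periodic dihedrals for H_int.

    bonds: ((chain,res,atom), (chain,res,atom), b0 nm, kb kJ mol^-1 nm^-2)
    angles: (a, b, c, theta0 deg, ka kJ mol^-1 rad^-2)
    dihedrals: (a, b, c, d, phi_s deg, k kJ mol^-1, multiplicity)
    """

    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    dihedrals: list = field(default_factory=list)


@dataclass
class EnergyComponents:
    """One snapshot's energy components (kJ/mol); derived sums are
    properties so they satisfy their defining identities exactly."""

    H_int: float = 0.0
    H_vdW: float = 0.0
    H_elect: float = 0.0
    G_polar: float = 0.0
    G_apolar: float = 0.0

    @property
    def H_gas(self) -> float:
        return self.H_int + self.H_vdW + self.H_elect

    @property
    def G_solv(self) -> float:
        return self.G_polar + self.G_apolar

    @property
    def G(self) -> float:
        return self.H_gas + self.G_solv  # - TS, with TS neglected

    def as_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in ALL_COMPONENTS})


@dataclass
class StoichStep:
    """One association step, product formed from coefficient-weighted
    reactants; the unbound receptor enters as half a receptor dimer."""

    step_id: int
    product: str
    reactants: list  # [(coefficient, species), ...]

    @classmethod
    def ligand_trimerization(cls, step_id: int, ligand: str = "LT", receptor_dimer: str = "(TNFR1)2") -> "StoichStep":
        """The three sequential receptor-binding steps: LT-(TNFR1)_{n-1} +
        1/2 (TNFR1)_2 -> LT-(TNFR1)_n for n = 1, 2, 3."""
        if step_id not in (1, 2, 3):
            raise ValueError("step_id must be 1, 2 or 3")
        prev = ligand if step_id == 1 else f"{ligand}-(TNFR1){step_id - 1}"
        return cls(
            step_id=step_id,
            product=f"{ligand}-(TNFR1){step_id}",
            reactants=[(1.0, prev), (0.5, receptor_dimer)],
        )


@dataclass
class FreeEnergyLedger:
    """Aggregated mean +/- SEM energy components for one reaction step.

    ``table`` is indexed by component name (dH_int, dH_vdW, dH_elect,
    dG_polar, dG_apolar, dG_solv, dG_binding) with columns ``mean`` and
    ``sem``; ``mode`` is "SITA" or "SETA".  Entropy is identically zero and
    recorded as neglected in the metadata.
    """

    table: pd.DataFrame
    mode: str
    n_snapshots: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("entropy", "neglected (TS = 0)")
        self.validate()

    def value(self, component: str) -> float:
        return float(self.table.loc[component, "mean"])

    def validate(self, tol: float = 1e-9) -> None:
        t = self.table
        get = lambda c: float(t.loc[c, "mean"]) if c in t.index else 0.0
        if "dG_solv" in t.index:
            if abs(get("dG_solv") - (get("dG_polar") + get("dG_apolar"))) > tol:
                raise ValueError("ledger violates dG_solv = dG_polar + dG_apolar")
        if "dG_binding" in t.index:
            total = sum(get(c) for c in ("dH_int", "dH_vdW", "dH_elect", "dG_polar", "dG_apolar"))
            if abs(get("dG_binding") - total) > tol:
                raise ValueError("ledger violates dG_binding = sum of components")

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        """Table at the 0.1 kJ/mol precision the field's tables print."""
        return self.table.round(decimals)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "component"
        with open(path, "w") as fh:
            for key, val in sorted(self.metadata.items()):
                fh.write(f"# {key}: {val}\n")
            fh.write(f"# mode: {self.mode}; n_snapshots: {self.n_snapshots}\n")
            out.to_csv(fh)


# ---------------------------------------------------------------------------
# gas-phase direct sums


def coulomb_energy(structure: Structure, ff: FFParams, dielectric: float = 1.0) -> float:
    """Full pairwise Coulomb sum, kJ/mol: f/eps * sum_{i<j} q_i q_j / r_ij.

    Vacuum dielectric by default (the reduced solute dielectric of the PB
    stage does not apply to the gas-phase term).  No cutoff, no exclusions,
    no periodicity.
    """
    q = ff.charge_array(structure)
    coords = structure.coords()
    if len(coords) < 2:
        return 0.0
    r = pdist(coords)
    qq = np.array([q[i] * q[j] for i in range(len(q)) for j in range(i + 1, len(q))])
    coincident = (r < 1e-9) & (qq != 0)
    if np.any(coincident):
        raise ValueError("coincident charged atoms")
    mask = r >= 1e-9
    return float(COULOMB_CONSTANT / dielectric * np.sum(qq[mask] / r[mask]))


def lj_energy(structure: Structure, ff: FFParams) -> float:
    """Full pairwise 12-6 Lennard-Jones sum, kJ/mol, using the force
    field's combination rule."""
    sig, eps = ff.lj_arrays(structure)
    coords = structure.coords()
    n = len(coords)
    if n < 2:
        return 0.0
    e = 0.0
    for i in range(n):
        sij, eij = _combine(sig[i], sig[i + 1:], eps[i], eps[i + 1:], ff.combination_rule)
        r = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        sr6 = (sij / r) ** 6
        e += float(np.sum(4.0 * eij * (sr6**2 - sr6)))
    return e


def _combine(s1, s2, e1, e2, rule):
    eij = np.sqrt(e1 * e2)
    sij = np.sqrt(s1 * s2) if rule == "geometric" else 0.5 * (s1 + s2)
    return sij, eij


def interaction_energy(structure: Structure, group_a, group_b, ff: FFParams, dielectric: float = 1.0) -> dict:
    """Cross-partner Coulomb and Lennard-Jones sums between two chain
    groups of one structure (the SITA gas-phase difference).

    By bilinearity this equals E(A u B) - E(A) - E(B) for both terms.
    Returns ``{"H_vdW": ..., "H_elect": ...}`` in kJ/mol.
    """
    records = structure.atom_records()
    set_a, set_b = set(group_a), set(group_b)
    ia = [i for i, (res, _) in enumerate(records) if res.chain in set_a]
    ib = [i for i, (res, _) in enumerate(records) if res.chain in set_b]
    if not ia or not ib:
        raise ValueError("empty partner group")
    if set_a & set_b:
        raise ValueError("partner groups overlap")
    q = ff.charge_array(structure)
    sig, eps = ff.lj_arrays(structure)
    coords = structure.coords()
    r = cdist(coords[ia], coords[ib])
    if np.any(r < 1e-9):
        raise ValueError("coincident atoms across partners")
    qq = np.outer(q[ia], q[ib])
    elect = COULOMB_CONSTANT / dielectric * float(np.sum(qq / r))
    sij, eij = _combine(sig[ia][:, None], sig[ib][None, :], eps[ia][:, None], eps[ib][None, :], ff.combination_rule)
    sr6 = (sij / r) ** 6
    vdw = float(np.sum(4.0 * eij * (sr6**2 - sr6)))
    return {"H_vdW": vdw, "H_elect": elect}


def internal_energy(structure: Structure, bonded: BondedTerms) -> float:
    """H_int = H_bond + H_angle + H_dihedral from supplied bonded terms."""
    pos = {
        (res.chain, res.number, atom.name): atom.coords
        for res, atom in structure.atom_records()
    }
    e = 0.0
    for a, b, b0, kb in bonded.bonds:
        d = float(np.linalg.norm(pos[tuple(a)] - pos[tuple(b)]))
        e += 0.5 * kb * (d - b0) ** 2
    for a, b, c, theta0, ka in bonded.angles:
        v1 = pos[tuple(a)] - pos[tuple(b)]
        v2 = pos[tuple(c)] - pos[tuple(b)]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta = math.acos(max(-1.0, min(1.0, cosang)))
        e += 0.5 * ka * (theta - math.radians(theta0)) ** 2
    for a, b, c, d, phi_s, k, mult in bonded.dihedrals:
        phi = _dihedral(pos[tuple(a)], pos[tuple(b)], pos[tuple(c)], pos[tuple(d)])
        e += k * (1.0 + math.cos(mult * phi - math.radians(phi_s)))
    return e


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2)))


# ---------------------------------------------------------------------------
# ledger arithmetic


def apolar_solvation(sasa_A2: float, model: ApolarModel | None = None) -> float:
    """Apolar solvation free energy, kJ/mol: gamma * SASA + b."""
    if sasa_A2 < 0:
        raise ValueError("SASA must be non-negative")
    model = model or ApolarModel()
    return model.gamma * sasa_A2 + model.b


def snapshot_free_energy(components) -> float:
    """G for one snapshot: H_int + H_vdW + H_elect + G_polar + G_apolar
    (entropy neglected).  Accepts an EnergyComponents, mapping or Series."""
    if isinstance(components, EnergyComponents):
        return components.G
    missing = [c for c in ALL_COMPONENTS if c not in components]
    if missing:
        raise KeyError(f"missing components: {missing}")
    return float(sum(components[c] for c in ALL_COMPONENTS))


def binding_energy(complex_components, partners) -> pd.Series:
    """Componentwise dG_binding = complex - sum of coefficient-weighted
    partners.

    ``partners`` is a list of ``(coefficient, components)`` (e.g. the
    receptor supplied as half a dimer gets coefficient 0.5).  Components
    are EnergyComponents, mappings or Series over the five base terms;
    missing terms are treated as absent only if absent everywhere.
    Returns a Series with the component differences plus derived dG_solv
    and dG_binding.
    """
    def to_series(c):
        if isinstance(c, EnergyComponents):
            return c.as_series()
        return pd.Series({k: float(v) for k, v in dict(c).items()})

    cx = to_series(complex_components)
    delta = cx.copy()
    for coeff, comp in partners:
        s = to_series(comp)
        if set(s.index) != set(cx.index):
            raise ValueError(f"component mismatch: {sorted(cx.index)} vs {sorted(s.index)}")
        delta = delta - coeff * s
    out = pd.Series({f"d{c}": delta[c] for c in delta.index})
    polar = out.get("dG_polar", 0.0)
    apolar = out.get("dG_apolar", 0.0)
    out["dG_solv"] = polar + apolar
    out["dG_binding"] = float(sum(out[f"d{c}"] for c in delta.index))
    return out


def total_electrostatics(source) -> float:
    """dH_elect + dG_polar: the net electrostatic balance between direct
    interaction and desolvation penalty (positive = desolvation wins)."""
    if isinstance(source, FreeEnergyLedger):
        t = source.table
        elect = float(t.loc["dH_elect", "mean"]) if "dH_elect" in t.index else 0.0
        polar = float(t.loc["dG_polar", "mean"]) if "dG_polar" in t.index else 0.0
        return elect + polar
    src = dict(source)
    elect = float(src.get("dH_elect", src.get("H_elect", 0.0)))
    polar = float(src.get("dG_polar", src.get("G_polar", 0.0)))
    return elect + polar


def aggregate_stats(series) -> tuple[float, float]:
    """Mean and standard error of the mean (sigma / sqrt(n), ddof = 1)."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 snapshots")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def _ledger_from_snapshots(per_snapshot: pd.DataFrame, mode: str, metadata: dict) -> FreeEnergyLedger:
    """Aggregate a per-snapshot component table into a ledger; derived rows
    are computed per snapshot first so their SEMs honour correlations."""
    df = per_snapshot.copy()
    df["dG_solv"] = df.get("dG_polar", 0.0) + df.get("dG_apolar", 0.0)
    df["dG_binding"] = sum(
        df[c] for c in ("dH_int", "dH_vdW", "dH_elect", "dG_polar", "dG_apolar") if c in df
    )
    rows = {}
    for col in df.columns:
        mean, sem = aggregate_stats(df[col])
        rows[col] = {"mean": mean, "sem": sem}
    order = [c for c in ("dH_int", "dH_vdW", "dH_elect", "dG_polar", "dG_apolar", "dG_solv", "dG_binding") if c in rows]
    table = pd.DataFrame(rows).T.loc[order]
    return FreeEnergyLedger(table=table, mode=mode, n_snapshots=len(df), metadata=metadata)


def sita_ledger(
    traj: Trajectory,
    partition: dict,
    ff: FFParams,
    polar_table: pd.DataFrame | None = None,
    apolar: ApolarModel | None = None,
    sasa_cfg: SASAConfig | None = None,
    window=None,
    dielectric: float = 1.0,
    polar_spec: PolarInputSpec | None = None,
) -> FreeEnergyLedger:
    """Single-trajectory MM/PBSA ledger.

    Partner coordinates come from the complex trajectory itself, so bonded
    terms cancel (dH_int = 0) and the gas-phase differences are exact
    cross-partner pair sums.  ``partition`` maps the two partner names to
    chain-id lists; ``polar_table`` (optional) has one row per snapshot
    with columns named after the complex ("complex") and the two partners,
    holding each species' G_polar; ``window`` selects snapshot indices.
    """
    if len(partition) != 2:
        raise ValueError("SITA partition must name exactly two partners")
    apolar = apolar or ApolarModel()
    sasa_cfg = sasa_cfg or SASAConfig()
    frames = np.arange(len(traj)) if window is None else np.asarray(list(window))
    (name_a, chains_a), (name_b, chains_b) = partition.items()
    if polar_table is not None and len(polar_table) != len(frames):
        raise ValueError(
            f"polar table has {len(polar_table)} rows for {len(frames)} snapshots"
        )
    import copy as _copy

    from enmpbsa.metrics import _substructure

    work = _copy.deepcopy(traj.topology)
    sub_a = _substructure(traj.topology, chains_a)
    sub_b = _substructure(traj.topology, chains_b)
    records = traj.topology.atom_records()
    idx_a = [i for i, (res, _) in enumerate(records) if res.chain in set(chains_a)]
    idx_b = [i for i, (res, _) in enumerate(records) if res.chain in set(chains_b)]

    rows = []
    for row_i, f in enumerate(frames):
        frame = traj.frames[f]
        work.set_coords(frame)
        gas = interaction_energy(work, chains_a, chains_b, ff, dielectric=dielectric)
        sub_a.set_coords(frame[idx_a])
        sub_b.set_coords(frame[idx_b])
        _, s_complex = sasa(work, sasa_cfg)
        _, s_a = sasa(sub_a, sasa_cfg)
        _, s_b = sasa(sub_b, sasa_cfg)
        d_apolar = (
            apolar_solvation(s_complex, apolar)
            - apolar_solvation(s_a, apolar)
            - apolar_solvation(s_b, apolar)
        )
        row = {"dH_int": 0.0, "dH_vdW": gas["H_vdW"], "dH_elect": gas["H_elect"], "dG_apolar": d_apolar}
        if polar_table is not None:
            pt = polar_table.iloc[row_i]
            row["dG_polar"] = float(pt["complex"] - pt[name_a] - pt[name_b])
        else:
            row["dG_polar"] = 0.0
        rows.append(row)
    metadata = {
        "partners": {name_a: list(chains_a), name_b: list(chains_b)},
        "polar": (polar_spec or PolarInputSpec()).as_dict() if polar_table is not None else "absent",
    }
    per_snapshot = pd.DataFrame(rows)[["dH_int", "dH_vdW", "dH_elect", "dG_polar", "dG_apolar"]]
    return _ledger_from_snapshots(per_snapshot, "SITA", metadata)


def species_component_table(
    traj: Trajectory,
    ff: FFParams,
    polar: pd.Series | np.ndarray | None = None,
    apolar: ApolarModel | None = None,
    sasa_cfg: SASAConfig | None = None,
    bonded: BondedTerms | None = None,
    dielectric: float = 1.0,
) -> pd.DataFrame:
    """Per-snapshot energy components of one species for SETA: full
    intramolecular gas-phase sums, SASA-based G_apolar, imported G_polar
    and (when bonded terms are supplied) H_int."""
    apolar = apolar or ApolarModel()
    sasa_cfg = sasa_cfg or SASAConfig()
    import copy as _copy

    work = _copy.deepcopy(traj.topology)
    rows = []
    for f in range(len(traj)):
        work.set_coords(traj.frames[f])
        _, total_sasa = sasa(work, sasa_cfg)
        row = {
            "H_vdW": lj_energy(work, ff),
            "H_elect": coulomb_energy(work, ff, dielectric=dielectric),
            "G_apolar": apolar_solvation(total_sasa, apolar),
            "G_polar": float(np.asarray(polar)[f]) if polar is not None else 0.0,
        }
        if bonded is not None:
            row["H_int"] = internal_energy(work, bonded)
        rows.append(row)
    cols = [c for c in ALL_COMPONENTS if c in rows[0]]
    return pd.DataFrame(rows)[cols]


def seta_ledger(
    tables: dict,
    stoich: StoichStep,
    window=None,
    polar_spec: PolarInputSpec | None = None,
) -> FreeEnergyLedger:
    """Separate-trajectory MM/PBSA ledger.

    ``tables`` maps species name -> per-snapshot component DataFrame (from
    :func:`species_component_table` or an imported delimited table).  Each
    species is averaged independently; differences follow the reaction's
    coefficients and SEMs combine in quadrature.  H_int is reported only if
    every species supplies it; otherwise the ledger is flagged incomplete.
    """
    needed = [stoich.product] + [sp for _, sp in stoich.reactants]
    missing = [sp for sp in needed if sp not in tables]
    if missing:
        raise KeyError(f"missing component tables for species: {missing}")
    terms = [(1.0, stoich.product)] + [(-coeff, sp) for coeff, sp in stoich.reactants]

    have_hint = all("H_int" in tables[sp].columns for sp in needed)
    components = [c for c in ALL_COMPONENTS if c != "H_int" or have_hint]

    stats: dict[str, dict[str, tuple[float, float]]] = {}
    n_min = None
    for sp in needed:
        df = tables[sp]
        if window is not None:
            df = df.iloc[list(window)]
        n_min = len(df) if n_min is None else min(n_min, len(df))
        sp_stats = {}
        for c in components:
            sp_stats[c] = aggregate_stats(df[c])
        sp_stats["G_solv"] = aggregate_stats(df["G_polar"] + df["G_apolar"])
        sp_stats["G_total"] = aggregate_stats(df[components].sum(axis=1))
        stats[sp] = sp_stats

    rows = {}
    for c in components + ["G_solv", "G_total"]:
        mean = sum(sign * stats[sp][c][0] for sign, sp in terms)
        sem = math.sqrt(sum((sign * stats[sp][c][1]) ** 2 for sign, sp in terms))
        label = {"G_solv": "dG_solv", "G_total": "dG_binding"}.get(c, f"d{c}")
        rows[label] = {"mean": mean, "sem": sem}
    order = [c for c in ("dH_int", "dH_vdW", "dH_elect", "dG_polar", "dG_apolar", "dG_solv", "dG_binding") if c in rows]
    table = pd.DataFrame(rows).T.loc[order]
    metadata = {
        "reaction": f"{' + '.join(f'{c} {sp}' for c, sp in stoich.reactants)} -> {stoich.product}",
        "step": stoich.step_id,
        "polar": (polar_spec or PolarInputSpec()).as_dict(),
    }
    if not have_hint:
        metadata["incomplete"] = "H_int omitted: bonded terms not supplied for all species"
    return FreeEnergyLedger(table=table, mode="SETA", n_snapshots=int(n_min), metadata=metadata)


def ledger_from_deltas(deltas: dict, mode: str = "SITA", sems: dict | None = None, n_snapshots: int = 0) -> FreeEnergyLedger:
    """Assemble a ledger from already-differenced component values.

    ``deltas`` maps dH_int/dH_vdW/dH_elect/dG_polar/dG_apolar (any subset;
    missing terms count as zero, matching single-trajectory tables that
    carry no internal-energy row) to kJ/mol values; dG_solv and dG_binding
    are derived.  Useful for re-aggregating published component tables.
    """
    sems = sems or {}
    base = [c for c in ("dH_int", "dH_vdW", "dH_elect", "dG_polar", "dG_apolar") if c in deltas]
    if not base:
        raise ValueError("no components supplied")
    rows = {c: {"mean": float(deltas[c]), "sem": float(sems.get(c, 0.0))} for c in base}
    polar = rows.get("dG_polar", {"mean": 0.0})["mean"]
    apolar = rows.get("dG_apolar", {"mean": 0.0})["mean"]
    rows["dG_solv"] = {
        "mean": polar + apolar,
        "sem": math.sqrt(sems.get("dG_polar", 0.0) ** 2 + sems.get("dG_apolar", 0.0) ** 2),
    }
    rows["dG_binding"] = {
        "mean": sum(rows[c]["mean"] for c in base),
        "sem": math.sqrt(sum(sems.get(c, 0.0) ** 2 for c in base)),
    }
    order = [c for c in ("dH_int", "dH_vdW", "dH_elect", "dG_polar", "dG_apolar", "dG_solv", "dG_binding") if c in rows]
    table = pd.DataFrame(rows).T.loc[order]
    return FreeEnergyLedger(table=table, mode=mode, n_snapshots=n_snapshots)


def read_energy_table(path) -> pd.DataFrame:
    """Read a delimited per-snapshot energy-component table.  Columns are a
    subset of H_int, H_vdW, H_elect, G_polar, G_apolar plus an optional
    ``species`` tag; returns the frame (split it by species as needed)."""
    df = pd.read_csv(path, sep=None, engine="python")
    known = set(ALL_COMPONENTS) | {"species", "snapshot"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown columns in energy table: {unknown}")
    return df
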