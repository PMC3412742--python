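"""Protein structure container and I/O.

Coordinates are stored in nanometres throughout the package; PDB files
(which print angstroms) are converted on read and write.  Residues are
identified by their author-assigned ``(chain, number)`` pair and all residue
ranges are inclusive on both ends, matching how crystallographic papers
quote them (e.g. the TNFR1 ectodomain spans residues 15-153).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser

NM_PER_ANGSTROM = 0.1

#: Atom names treated as backbone (everything else heavy is side chain).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "SOL", "H2O"})


@dataclass
class Atom:
    """A single atom: name, element, position (nm)."""

    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")


@dataclass
class Residue:
    """One residue with author numbering and a secondary-structure label.

    ``ss_label`` is one of ``H`` (helix), ``E`` (strand) or ``C`` (coil, the
    default when no assignment has been ingested).
    """

    name: str
    number: int
    chain: str
    atoms: list[Atom] = field(default_factory=list)
    ss_label: str = "C"
    flags: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def sidechain_heavy_atoms(self) -> list[Atom]:
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOMS]


@dataclass
class Structure:
    """Ordered residues plus the disulfide pairs detected or declared on them.

    Disulfides are stored as pairs of ``(chain, number)`` keys; both members
    must be cysteines present in the structure.
    """

    residues: list[Residue] = field(default_factory=list)
    disulfides: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, number) residue keys")
        index = {r.key: r for r in self.residues}
        for a, b in self.disulfides:
            if a == b:
                raise ValueError(f"disulfide pairs residue {a} with itself")
            for key in (a, b):
                res = index.get(tuple(key))
                if res is None:
                    raise ValueError(f"disulfide references absent residue {key}")
                if res.name != "CYS":
                    raise ValueError(f"disulfide references non-CYS residue {key}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.number == number:
                return r
        raise KeyError(f"no residue {chain}:{number}")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def atom_records(self) -> list[tuple[Residue, Atom]]:
        """Flat (residue, atom) list in file order."""
        return [(r, a) for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3), nm."""
        return np.array([a.coords for _, a in self.atom_records()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        records = self.atom_records()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(records), 3):
            raise ValueError("coordinate array does not match atom count")
        for (_, atom), xyz in zip(records, coords):
            atom.coords = np.array(xyz, dtype=float)

    def ca_coords(self, keys: list[tuple[str, int]] | None = None) -> np.ndarray:
        """C-alpha coordinates for the given residue keys (default: all)."""
        residues = self.residues if keys is None else [self.residue(c, n) for c, n in keys]
        out = []
        for r in residues:
            ca = r.atom("CA")
            if ca is None:
                raise KeyError(f"residue {r.key} has no CA atom")
            out.append(ca.coords)
        return np.array(out, dtype=float)

    def ss_labels(self) -> dict[tuple[str, int], str]:
        return {r.key: r.ss_label for r in self.residues}


@dataclass
class DomainMap:
    """Named inclusive residue ranges, e.g. the four cysteine-rich domains
    CRD1 (15-53), CRD2 (54-97), CRD3 (98-138) and CRD4 (139-153) of TNFR1."""

    ranges: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_chain: dict[str, list[tuple[int, int, str]]] = {}
        for name, (chain, start, end) in self.ranges.items():
            if start > end:
                raise ValueError(f"domain {name}: start {start} > end {end}")
            by_chain.setdefault(chain, []).append((start, end, name))
        for chain, spans in by_chain.items():
            spans.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(f"domains {n1} and {n2} overlap on chain {chain}")

    def residues_in(self, name: str, structure: Structure) -> list[Residue]:
        chain, start, end = self.ranges[name]
        return [r for r in structure.residues if r.chain == chain and start <= r.number <= end]


def read_pdb(path, include_hetero: bool = False, model: int = 0) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Waters and (by default) other heteroatoms are excluded.  Alternate
    locations are resolved to the highest-occupancy copy.  A residue without
    a C-alpha atom is kept but flagged ``no_ca`` with a warning.
    """
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", str(path))
    except Exception as exc:  # unreadable file is fatal
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc
    models = list(bio.get_models())
    if not models:
        raise OSError(f"no models in PDB file {path}")
    return _convert_model(models[model], include_hetero=include_hetero)


def _convert_model(bio_model, include_hetero: bool = False) -> Structure:
    residues: list[Residue] = []
    for chain in bio_model:
        for res in chain:
            hetflag, resseq, _icode = res.get_id()
            resname = res.get_resname().strip()
            if resname in _WATER_NAMES or hetflag == "W":
                continue
            if hetflag.strip() and not include_hetero:
                continue
            atoms = []
            for atom in res:  # Biopython yields the highest-occupancy altloc
                name = atom.get_name().strip()
                element = (atom.element or name[:1]).strip().capitalize() or "X"
                atoms.append(
                    Atom(
                        name=name,
                        element=element,
                        coords=np.asarray(atom.get_coord(), dtype=float) * NM_PER_ANGSTROM,
                        is_hydrogen=element == "H",
                    )
                )
            residue = Residue(name=resname, number=int(resseq), chain=chain.id.strip() or "A", atoms=atoms)
            if residue.atom("CA") is None:
                warnings.warn(f"residue {residue.key} ({resname}) has no CA atom")
                residue.flags.append("no_ca")
            residues.append(residue)
    return Structure(residues=residues)


def write_pdb(structure: Structure, path, frames: list[np.ndarray] | None = None) -> None:
    """Write a structure (optionally as a multi-model file) in PDB format.

    ``frames`` is an optional list of ``(n_atoms, 3)`` nm coordinate arrays;
    when given, one MODEL/ENDMDL block is emitted per frame.
    """
    records = structure.atom_records()

    def _block(out, coords):
        serial = 1
        for (res, atom), xyz in zip(records, coords):
            name = atom.name if len(atom.name) >= 4 else f" {atom.name}"
            x, y, z = (np.asarray(xyz, dtype=float) / NM_PER_ANGSTROM).tolist()
            out.write(
                f"ATOM  {serial:5d} {name:<4s}{res.name:>4s} {res.chain[:1]}{res.number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}\n"
            )
            serial += 1

    with open(path, "w") as out:
        if frames is None:
            _block(out, [a.coords for _, a in records])
        else:
            for i, frame in enumerate(frames, start=1):
                out.write(f"MODEL     {i:4d}\n")
                _block(out, frame)
                out.write("ENDMDL\n")
        out.write("END\n")


def select(structure: Structure, chain: str, resrange: tuple[int, int]) -> Structure:
    """Extract residues ``start..end`` (inclusive) of one chain.

    Order, atoms and secondary-structure labels are preserved.  Disulfides
    with both partners inside the selection are kept; a pair crossing the
    boundary is dropped with a warning.
    """
    start, end = resrange
    if start > end:
        raise ValueError(f"invalid range {start}-{end}")
    picked = [
        replace(r, atoms=list(r.atoms), flags=list(r.flags))
        for r in structure.residues
        if r.chain == chain and start <= r.number <= end
    ]
    if not picked:
        raise ValueError(f"selection {chain}:{start}-{end} is empty")
    keys = {r.key for r in picked}
    kept_ss = []
    for a, b in structure.disulfides:
        a, b = tuple(a), tuple(b)
        if a in keys and b in keys:
            kept_ss.append((a, b))
        elif a in keys or b in keys:
            warnings.warn(f"selection {chain}:{start}-{end} drops disulfide {a}-{b}")
    return Structure(residues=picked, disulfides=kept_ss)


def detect_disulfides(structure: Structure, cutoff: float = 0.25) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Detect disulfide bridges geometrically.

    Every CYS pair whose SG-SG distance is at or below ``cutoff`` (nm) is a
    candidate; candidates are accepted closest-first so that each cysteine
    ends up in at most one bridge.  The default 0.25 nm comfortably covers
    the canonical ~0.205 nm S-S bond while excluding non-bonded contacts.
    """
    cys = []
    for r in structure.residues:
        if r.name != "CYS":
            continue
        sg = r.atom("SG")
        if sg is None:
            warnings.warn(f"CYS {r.key} has no SG atom; skipped in disulfide detection")
            continue
        cys.append((r.key, sg.coords))
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i][1] - cys[j][1]))
            if d <= cutoff:
                candidates.append((d, cys[i][0], cys[j][0]))
    candidates.sort(key=lambda t: t[0])
    used: set[tuple[str, int]] = set()
    pairs = []
    for d, a, b in candidates:
        if a in used or b in used:
            warnings.warn(f"CYS {a if a not in used else b} left unpaired (closer partner already bonded)")
            continue
        pairs.append((a, b))
        used.update((a, b))
    return pairs


def load_ss_labels(structure: Structure, table) -> Structure:
    """Attach secondary-structure labels from a 3-column table.

    ``table`` is a path to whitespace/comma-delimited text with columns
    ``chain resnum label`` (label in H/E/C), or an iterable of such triples.
    Residues not listed keep the coil default; a listed residue missing from
    the structure triggers a warning.  The structure is modified in place and
    returned.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "read") or hasattr(table, "__fspath__"):
        rows = []
        with open(table) as fh:
            for line in fh:
                line = line.strip().replace(",", " ")
                if not line or line.startswith("#"):
                    continue
                chain, resnum, label = line.split()[:3]
                rows.append((chain, int(resnum), label))
    else:
        rows = [(c, int(n), lab) for c, n, lab in table]
    index = {r.key: r for r in structure.residues}
    for chain, resnum, label in rows:
        label = label.upper()
        if label not in {"H", "E", "C"}:
            raise ValueError(f"unknown secondary-structure label {label!r}")
        res = index.get((chain, resnum))
        if res is None:
            warnings.warn(f"secondary-structure label for absent residue {chain}:{resnum}")
            continue
        res.ss_label = label
    return structure
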