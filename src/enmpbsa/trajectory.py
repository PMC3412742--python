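"""Multi-frame coordinate trajectories aligned to a Structure topology.

Two plain-text dialects are read: multi-model PDB (MODEL/ENDMDL blocks) and
a whitespace XYZ table (one ``x y z`` row per atom in nm, frames separated
by blank lines).  Frame times are in picoseconds and default to the frame
index when the input carries none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from enmpbsa.structures import NM_PER_ANGSTROM, Structure, _convert_model, write_pdb


@dataclass
class Trajectory:
    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), nm
    times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        n_atoms = len(self.topology.atom_records())
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n_atoms, 3):
            raise ValueError(
                f"frames shape {self.frames.shape} does not match topology ({n_atoms} atoms)"
            )
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.frames):
                raise ValueError("times and frames length mismatch")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def atom_index(self, chain: str, resnum: int, atom_name: str) -> int:
        for i, (res, atom) in enumerate(self.topology.atom_records()):
            if res.chain == chain and res.number == resnum and atom.name == atom_name:
                return i
        raise KeyError(f"no atom {chain}:{resnum}:{atom_name}")

    def ca_indices(self, keys=None) -> np.ndarray:
        """Flat atom indices of the C-alpha atoms of the given residue keys
        (default: every residue), in topology order."""
        wanted = None if keys is None else {tuple(k) for k in keys}
        idx = []
        for i, (res, atom) in enumerate(self.topology.atom_records()):
            if atom.name == "CA" and (wanted is None or res.key in wanted):
                idx.append(i)
        if not idx:
            raise KeyError("selection resolves to no CA atoms")
        return np.array(idx)

    def frame_structure(self, i: int) -> Structure:
        """A deep-enough copy of the topology carrying frame ``i`` coordinates."""
        import copy

        s = copy.deepcopy(self.topology)
        s.set_coords(self.frames[i])
        return s

    def write_pdb(self, path) -> None:
        write_pdb(self.topology, path, frames=list(self.frames))

    def write_xyz(self, path) -> None:
        with open(path, "w") as out:
            for frame in self.frames:
                for x, y, z in frame:
                    out.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
                out.write("\n")


def parse_selection(spec: str) -> tuple[str, int, int]:
    """Parse a ``chain:start-end`` selection string (inclusive)."""
    chain, _, rng = spec.partition(":")
    if not rng:
        raise ValueError(f"bad selection {spec!r}, expected 'chain:start-end'")
    start, _, end = rng.partition("-")
    return chain, int(start), int(end or start)


def selection_keys(structure: Structure, spec: str) -> list[tuple[str, int]]:
    chain, start, end = parse_selection(spec)
    keys = [r.key for r in structure.residues if r.chain == chain and start <= r.number <= end]
    if not keys:
        raise ValueError(f"selection {spec!r} matches no residues")
    return keys


def read_multimodel_pdb(path, times=None) -> Trajectory:
    """Read a MODEL/ENDMDL multi-frame PDB; the first model is the topology."""
    parser = PDBParser(QUIET=True)
    bio = parser.get_structure("t", str(path))
    models = list(bio.get_models())
    if not models:
        raise OSError(f"no models in {path}")
    topo = _convert_model(models[0])
    n_atoms = len(topo.atom_records())
    frames = []
    for model in models:
        coords = np.array([a.get_coord() for a in model.get_atoms()], dtype=float) * NM_PER_ANGSTROM
        if len(coords) != n_atoms:
            raise ValueError(f"model {model.id} has {len(coords)} atoms, expected {n_atoms}")
        frames.append(coords)
    return Trajectory(topology=topo, frames=np.array(frames), times=times)


def read_xyz_frames(path, topology: Structure, times=None) -> Trajectory:
    """Read a plain whitespace XYZ table (nm) against a known topology."""
    n_atoms = len(topology.atom_records())
    frames, current = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if current:
                    frames.append(current)
                    current = []
                continue
            current.append([float(v) for v in line.split()[:3]])
    if current:
        frames.append(current)
    arr = np.array(frames, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != n_atoms:
        raise ValueError(f"XYZ frames of {arr.shape[1] if arr.ndim == 3 else '?'} atoms, expected {n_atoms}")
    return Trajectory(topology=topology, frames=arr, times=times)
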