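"""Structures, trajectories, and per-residue scalar export.

Coordinates are in Angstrom throughout.  Residues are identified by
``(chain, resid)`` with resids kept 1-based exactly as printed in the
source PDB, so residue labels used in the sulfotransferase literature
(P87, V148, F247, K197, M260, the KTVE motif 265-274, ...) map directly
onto keys of this package.  Per-residue scalars (RMSF in Angstrom,
punctual stress in pN) travel as :class:`ResidueScalarProfile` objects
and can be written onto the B-factor column of a PDB file for 3D
colour-coded visualisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ResidueKey = tuple[str, int]  # (chain id, 1-based resid)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass
class Structure:
    """A molecular structure: parallel per-atom arrays plus coordinates.

    Attributes
    ----------
    atom_names : list of str
        PDB atom names, stripped (``"CA"``, ``"N"``, ...).
    elements : list of str
        Element symbols, upper-case (``"C"``, ``"N"``, ``"H"``, ...).
    chains, resids, resnames : per-atom residue metadata
        ``(chains[i], resids[i])`` is the residue key of atom ``i``.
    coords : (n_atoms, 3) float array, Angstrom.
    """

    atom_names: list[str]
    elements: list[str]
    chains: list[str]
    resids: list[int]
    resnames: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if n == 0:
            raise ValueError("empty structure")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        # resids strictly increasing within each chain (new residue = new id)
        last: dict[str, int] = {}
        for ch, rid in zip(self.chains, self.resids):
            if ch in last and rid < last[ch]:
                raise ValueError(
                    f"resids not non-decreasing in chain {ch!r}: "
                    f"{rid} after {last[ch]}"
                )
            last[ch] = rid

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_keys(self) -> list[ResidueKey]:
        """Ordered unique residue keys, in file order."""
        seen: dict[ResidueKey, None] = {}
        for ch, rid in zip(self.chains, self.resids):
            seen.setdefault((ch, rid), None)
        return list(seen)

    def residue_name(self, key: ResidueKey) -> str:
        for ch, rid, rn in zip(self.chains, self.resids, self.resnames):
            if (ch, rid) == key:
                return rn
        raise KeyError(key)

    def atom_indices(self, key: ResidueKey) -> np.ndarray:
        mask = [
            (ch, rid) == key for ch, rid in zip(self.chains, self.resids)
        ]
        return np.flatnonzero(mask)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ch in self.chains:
            seen.setdefault(ch, None)
        return list(seen)

    def chain_sequence(self, chain: str) -> list[str]:
        """Residue names of one chain, in residue order."""
        out = []
        prev = None
        for ch, rid, rn in zip(self.chains, self.resids, self.resnames):
            if ch == chain and rid != prev:
                out.append(rn)
                prev = rid
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            self.atom_names, self.elements, self.chains, self.resids,
            self.resnames, np.array(coords, dtype=float),
        )


@dataclass
class Trajectory:
    """An ordered stack of coordinate frames sharing one topology.

    ``frame_interval_ps`` is optional bookkeeping metadata (time between
    saved frames); no dynamics is implied by it.
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval_ps: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, atoms, 3) stack")
        if self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match "
                f"topology with {self.topology.n_atoms} atoms"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class ResidueScalarProfile:
    """Per-residue scalar values with declared units.

    A thin mapping ``(chain, resid) -> float``.  ``units`` is free text
    ("A" for RMSF, "pN" for punctual stress).
    """

    values: dict[ResidueKey, float]
    units: str = ""

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite value for residue {k}")

    def __getitem__(self, key: ResidueKey) -> float:
        return self.values[key]

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return self.values.items()

    def keys(self):
        return self.values.keys()

    def as_series(self, keys: Sequence[ResidueKey]) -> np.ndarray:
        return np.array([self.values.get(k, 0.0) for k in keys])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"chain\tresid\tvalue_{self.units or 'au'}\n")
            for (ch, rid), v in self.values.items():
                fh.write(f"{ch}\t{rid}\t{float(v)!r}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ResidueScalarProfile":
        values: dict[ResidueKey, float] = {}
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            units = header[2].removeprefix("value_") if len(header) == 3 else ""
            for line in fh:
                ch, rid, v = line.rstrip("\n").split("\t")
                values[(ch, int(rid))] = float(v)
        return cls(values, units=units)


# ---------------------------------------------------------------------------
# PDB reading

_PDB_COORD = slice(30, 54)


def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resid = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"malformed ATOM/HETATM record at line {lineno}: {exc}"
        ) from None
    if icode not in (" ", ""):
        raise PDBParseError(
            f"insertion code {icode!r} at line {lineno} is not supported; "
            "renumber the structure first"
        )
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        for c in name:
            if c.isalpha():
                element = c.upper()
                break
    return name, altloc, resname, chain, resid, (x, y, z), occupancy, element


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a structure from a PDB v3.3 file (ATOM/HETATM records).

    Only the first MODEL of a multi-model file is read.  Alternate
    locations are resolved by keeping the highest-occupancy conformer
    (first wins a tie).  Insertion codes are rejected.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    path = Path(path)
    rows: list[tuple] = []
    # altloc bookkeeping: (chain, resid, name) -> (occupancy, row index)
    best: dict[tuple, tuple[float, int]] = {}
    in_model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model += 1
                if in_model > 1:
                    break
            elif rec == "ENDMDL":
                break
            elif rec in ("ATOM  ", "HETATM"):
                (name, altloc, resname, chain, resid, xyz, occ,
                 element) = _parse_atom_line(line, lineno)
                key = (chain, resid, name)
                if key in best:
                    prev_occ, prev_row = best[key]
                    if altloc not in (" ", "") and occ > prev_occ:
                        rows[prev_row] = (name, resname, chain, resid, xyz,
                                          element)
                        best[key] = (occ, prev_row)
                    continue
                rows.append((name, resname, chain, resid, xyz, element))
                best[key] = (occ, len(rows) - 1)
    if not rows:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    return Structure(
        atom_names=[r[0] for r in rows],
        elements=[r[5] for r in rows],
        chains=[r[2] for r in rows],
        resids=[r[3] for r in rows],
        resnames=[r[1] for r in rows],
        coords=np.array([r[4] for r in rows]),
    )


def _format_atom_line(serial: int, name: str, resname: str, chain: str,
                      resid: int, xyz, bfactor: float, element: str,
                      hetatm: bool = False) -> str:
    rec = "HETATM" if hetatm else "ATOM  "
    # PDB atom-name alignment: names of <4 chars start in column 14
    if len(name) < 4:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    line = (
        f"{rec}{serial:5d} {name_f} {resname:<3s} {chain:1s}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{bfactor:6.2f}"
        f"          {element:>2s}"
    )
    return line.ljust(80)


def write_structure(structure: Structure, path: str | Path,
                    bfactors: np.ndarray | None = None) -> None:
    """Write a Structure as PDB ATOM records (one model, no CONECT)."""
    if bfactors is None:
        bfactors = np.zeros(structure.n_atoms)
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            fh.write(_format_atom_line(
                i + 1, structure.atom_names[i], structure.resnames[i],
                structure.chains[i], structure.resids[i],
                structure.coords[i], float(bfactors[i]),
                structure.elements[i],
                hetatm=structure.resnames[i] in ("LIG", "HOH"),
            ) + "\n")
        fh.write("END".ljust(80) + "\n")


# ---------------------------------------------------------------------------
# Trajectories


def read_trajectory(path: str | Path, topology: Structure,
                    format: str = "multi-model-pdb",
                    frame_interval_ps: float | None = None) -> Trajectory:
    """Read an ordered frame stack sharing ``topology``.

    Formats: ``multi-model-pdb`` (MODEL/ENDMDL blocks) and ``xyz-frames``
    (repeated blocks of: atom-count line, comment line, ``name x y z``
    lines).  Every frame must have the topology's atom count.
    """
    path = Path(path)
    if format == "multi-model-pdb":
        frames = _read_multimodel_pdb_frames(path)
    elif format == "xyz-frames":
        frames = _read_xyz_frames(path)
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")
    for idx, fr in enumerate(frames):
        if fr.shape[0] != topology.n_atoms:
            raise ValueError(
                f"frame {idx} has {fr.shape[0]} atoms, topology has "
                f"{topology.n_atoms}"
            )
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(topology, np.stack(frames),
                      frame_interval_ps=frame_interval_ps)


def _read_multimodel_pdb_frames(path: Path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                frames.append(np.array(current))
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                current.append(parsed[5])
    if current and not saw_model:
        frames.append(np.array(current))  # plain single-model file
    return frames


def _read_xyz_frames(path: Path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ValueError(
                f"expected atom-count line at line {i + 1} of xyz file"
            ) from None
        block = lines[i + 2: i + 2 + count]
        if len(block) < count:
            raise ValueError(
                f"truncated xyz frame starting at line {i + 1}"
            )
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        frames.append(coords)
        i += 2 + count
    return frames


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str = "xyz-frames") -> None:
    path = Path(path)
    top = traj.topology
    if format == "xyz-frames":
        with open(path, "w") as fh:
            for f_idx in range(traj.n_frames):
                fh.write(f"{top.n_atoms}\n")
                fh.write(f"frame {f_idx}\n")
                for a in range(top.n_atoms):
                    x, y, z = traj.frames[f_idx, a]
                    fh.write(
                        f"{top.atom_names[a]} {x:.6f} {y:.6f} {z:.6f}\n"
                    )
    elif format == "multi-model-pdb":
        with open(path, "w") as fh:
            for f_idx in range(traj.n_frames):
                fh.write(f"MODEL {f_idx + 1:8d}".ljust(80) + "\n")
                for a in range(top.n_atoms):
                    fh.write(_format_atom_line(
                        a + 1, top.atom_names[a], top.resnames[a],
                        top.chains[a], top.resids[a], traj.frames[f_idx, a],
                        0.0, top.elements[a],
                    ) + "\n")
                fh.write("ENDMDL".ljust(80) + "\n")
            fh.write("END".ljust(80) + "\n")
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")


# ---------------------------------------------------------------------------
# B-factor export


def write_bfactor_pdb(structure: Structure, profile: ResidueScalarProfile,
                      path: str | Path,
                      clip: tuple[float, float] | None = None) -> None:
    """Write ``structure`` with ``profile`` rescaled into the B-factor column.

    Values are linearly mapped from ``clip = (lo, hi)`` onto [0, 99.99]
    (and clipped to it); ``clip=None`` uses the profile's own min/max.
    Residues absent from the profile are written as 0.00.  The B-factor
    occupies columns 61-66 with 2 decimals, per PDB v3.3.
    """
    keys = set(structure.residue_keys())
    for k in profile.keys():
        if k not in keys:
            raise KeyError(f"profile residue {k} not in structure")
    vals = np.array(list(profile.values.values()), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite profile values")
    if clip is None:
        lo, hi = (float(vals.min()), float(vals.max())) if len(vals) else (0, 1)
    else:
        lo, hi = clip
    span = hi - lo if hi > lo else 1.0
    bfac = np.zeros(structure.n_atoms)
    for a, (ch, rid) in enumerate(zip(structure.chains, structure.resids)):
        v = profile.values.get((ch, rid))
        if v is not None:
            bfac[a] = np.clip((v - lo) / span, 0.0, 1.0) * 99.99
    write_structure(structure, path, bfactors=bfac)
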