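"""Residue-level pairwise forces, mean force matrices, and punctual stress.

The mechanical signal of a binding perturbation is read out in three
steps.  For each frame, every spring contributes a *signed scalar*
pairwise force along the interatomic axis, ``f = -k (|r_i - r_j| - r0)``
(positive = repulsive, negative = attractive).  Averaging each residue
pair's force over all frames gives the mean force matrix F of one
condition.  Two conditions A and B are compared through the entrywise
absolute difference dF = |F_A - F_B|, and the per-residue *punctual
stress* S_i = sum_j dF_ij — the total absolute force change a residue
senses — localises the residues that feel the perturbation.  Units are
pN throughout.

The signed-scalar convention averaged over frames, with |.| applied
only when differencing conditions, is the default; averaging
per-frame absolute forces instead is available via ``signed=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import ResidueKey, ResidueScalarProfile, Trajectory
from .synthetic import ElasticNetwork

MIN_SPRING_LENGTH = 1e-6  # A; below this the axis is undefined


@dataclass
class ForceMatrix:
    """Symmetric residue x residue matrix of mean pairwise forces (pN)."""

    index: list[ResidueKey]   # matrix row -> residue key
    values: np.ndarray        # (n, n) signed, symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match index length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite force entries")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("force matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("force matrix diagonal must be zero")

    @property
    def n_residues(self) -> int:
        return len(self.index)

    def write_tsv(self, path: str | Path) -> None:
        _write_matrix_tsv(self.index, self.values, path)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ForceMatrix":
        index, values = _read_matrix_tsv(path)
        return cls(index, values)


@dataclass
class DeltaForceMatrix:
    """Entrywise |F_A - F_B|: non-negative, symmetric, zero diagonal (pN)."""

    index: list[ResidueKey]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match index length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("difference matrix entries must be >= 0")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("difference matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n_residues(self) -> int:
        return len(self.index)

    def write_tsv(self, path: str | Path) -> None:
        _write_matrix_tsv(self.index, self.values, path)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DeltaForceMatrix":
        index, values = _read_matrix_tsv(path)
        return cls(index, values)


def _write_matrix_tsv(index: Sequence[ResidueKey], values: np.ndarray,
                      path: str | Path) -> None:
    """Long-format TSV: an index-map header, then 'i j value_pN' rows.

    Floats are written with repr (17 significant digits) so the
    round-trip is lossless.
    """
    with open(path, "w") as fh:
        fh.write("# residues\t"
                 + "\t".join(f"{c}:{r}" for c, r in index) + "\n")
        fh.write("i\tj\tvalue_pN\n")
        n = len(index)
        for i in range(n):
            for j in range(i + 1, n):
                if values[i, j] != 0.0:
                    fh.write(f"{i}\t{j}\t{float(values[i, j])!r}\n")


def _read_matrix_tsv(path: str | Path):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "# residues":
            raise ValueError("missing residue index header")
        index: list[ResidueKey] = []
        for tok in header[1:]:
            ch, rid = tok.rsplit(":", 1)
            index.append((ch, int(rid)))
        fh.readline()  # column header
        n = len(index)
        values = np.zeros((n, n))
        for line in fh:
            i, j, v = line.rstrip("\n").split("\t")
            values[int(i), int(j)] = values[int(j), int(i)] = float(v)
    return index, values


# ---------------------------------------------------------------------------
# Force evaluation


def _spring_scalar_forces(coords: np.ndarray, net: ElasticNetwork
                          ) -> np.ndarray:
    """Signed scalar force on every spring at one conformation (pN)."""
    d = coords[net.springs[:, 0]] - coords[net.springs[:, 1]]
    length = np.sqrt((d * d).sum(axis=1))
    if np.any(length < MIN_SPRING_LENGTH):
        bad = int(np.argmin(length))
        i, j = net.springs[bad]
        raise ValueError(
            f"degenerate geometry: nodes {net.node_keys[i]} and "
            f"{net.node_keys[j]} are {length[bad]:.2e} A apart"
        )
    return -net.k * (length - net.r0)


def pairwise_forces_frame(coords: np.ndarray, net: ElasticNetwork
                          ) -> list[tuple[ResidueKey, ResidueKey, float]]:
    """Sparse signed pairwise residue forces for one frame (pN).

    Positive = repulsive, negative = attractive.  Multiple springs
    joining the same residue pair (e.g. several ligand tethers mapped to
    the ligand pseudo-residue) are summed.
    """
    f = _spring_scalar_forces(np.asarray(coords, dtype=float), net)
    acc: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for (i, j), fij in zip(net.springs, f):
        a, b = net.node_keys[int(i)], net.node_keys[int(j)]
        key = (a, b) if a <= b else (b, a)
        acc[key] = acc.get(key, 0.0) + float(fij)
    return [(a, b, v) for (a, b), v in acc.items()]


def net_node_forces(coords: np.ndarray, net: ElasticNetwork) -> np.ndarray:
    """Per-node net force vectors (pN) from the pairwise decomposition.

    Equals minus the gradient of the network energy — the bookkeeping
    identity that makes the pairwise decomposition exact.
    """
    coords = np.asarray(coords, dtype=float)
    f = _spring_scalar_forces(coords, net)
    d = coords[net.springs[:, 0]] - coords[net.springs[:, 1]]
    length = np.sqrt((d * d).sum(axis=1))
    u = d / length[:, None]
    out = np.zeros_like(coords)
    np.add.at(out, net.springs[:, 0], f[:, None] * u)
    np.add.at(out, net.springs[:, 1], -f[:, None] * u)
    return out


def mean_force_matrix(traj: Trajectory, net: ElasticNetwork,
                      signed: bool = True) -> ForceMatrix:
    """Mean pairwise force matrix over all frames of a trajectory (pN).

    ``signed=True`` (default) averages the signed per-frame scalar
    forces; ``signed=False`` averages their absolute values.  Residue
    pairs never joined by a spring are 0.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    keys = net.node_keys
    n = len(keys)
    # vectorised over frames: (n_frames, n_springs) spring lengths
    d = (traj.frames[:, net.springs[:, 0], :]
         - traj.frames[:, net.springs[:, 1], :])
    length = np.sqrt((d * d).sum(axis=2))
    if np.any(length < MIN_SPRING_LENGTH):
        f_idx, s_idx = np.unravel_index(np.argmin(length), length.shape)
        i, j = net.springs[s_idx]
        raise ValueError(
            f"frame {f_idx}: degenerate geometry between nodes "
            f"{net.node_keys[int(i)]} and {net.node_keys[int(j)]}"
        )
    f = -net.k * (length - net.r0)
    mean_f = (np.abs(f) if not signed else f).mean(axis=0)

    values = np.zeros((n, n))
    for (i, j), v in zip(net.springs, mean_f):
        values[i, j] += v
        values[j, i] += v
    return ForceMatrix(index=list(keys), values=values)


# ---------------------------------------------------------------------------
# Differencing and stress


def align_force_matrices(fa: ForceMatrix, fb: ForceMatrix
                         ) -> tuple[ForceMatrix, ForceMatrix]:
    """Pad both matrices onto the union index map (missing entries 0).

    A ligand pseudo-residue exists only in the bound condition; padding
    the apo matrix with a zero row/column makes the two conditions
    directly differencable while preserving residue order (apo order
    first, then new residues in the bound order).
    """
    union = list(fa.index)
    seen = set(union)
    for k in fb.index:
        if k not in seen:
            union.append(k)
            seen.add(k)
    return _reindex(fa, union), _reindex(fb, union)


def _reindex(fm: ForceMatrix, index: list[ResidueKey]) -> ForceMatrix:
    pos = {k: i for i, k in enumerate(index)}
    n = len(index)
    values = np.zeros((n, n))
    src = [pos[k] for k in fm.index]
    for a, ia in enumerate(src):
        for b, ib in enumerate(src):
            values[ia, ib] = fm.values[a, b]
    return ForceMatrix(index=index, values=values)


def force_difference(fa: ForceMatrix, fb: ForceMatrix) -> DeltaForceMatrix:
    """Entrywise absolute difference |F_A - F_B| (pN).

    The index maps must be identical; use :func:`align_force_matrices`
    first when the conditions differ in their residue sets.
    """
    if fa.index != fb.index:
        for a, b in zip(fa.index, fb.index):
            if a != b:
                raise ValueError(
                    f"index maps differ: {a} vs {b}; align the matrices first"
                )
        raise ValueError(
            f"index maps differ in length ({len(fa.index)} vs "
            f"{len(fb.index)}); align the matrices first"
        )
    return DeltaForceMatrix(index=list(fa.index),
                            values=np.abs(fa.values - fb.values))


def punctual_stress(dF: DeltaForceMatrix) -> ResidueScalarProfile:
    """Per-residue punctual stress S_i = sum_j dF_ij (pN).

    Satisfies the conservation identity
    ``sum_i S_i == 2 * sum_{i<j} dF_ij`` (every pair is sensed by both
    of its residues).
    """
    sums = dF.values.sum(axis=1)
    return ResidueScalarProfile(
        {k: float(s) for k, s in zip(dF.index, sums)}, units="pN",
    )
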