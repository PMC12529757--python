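"""Structural observables: superposition, RMSD, RMSF, gate distances.

The observables here characterise the conformational behaviour of an
ensemble: per-frame RMSD after optimal rigid superposition, per-residue
RMSF about the (iteratively refined) mean structure, and distributions
of named "gate" distances — pairs of C-alpha atoms whose separation
measures the openness of a binding-site gate (for SULT1A1: L1-L2 =
P87CA...V148CA, L1-L3 = P87CA...F247CA, cL3 = K197CA...M260CA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import (
    ResidueKey,
    ResidueScalarProfile,
    Structure,
    Trajectory,
)

_BACKBONE = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class AtomSelection:
    """Predicate over atoms of a topology.

    ``atom_names=None`` matches any name; ``heavy_only`` drops hydrogens;
    ``chains`` / ``resid_range`` restrict by residue.
    """

    atom_names: frozenset[str] | None = None
    heavy_only: bool = True
    chains: frozenset[str] | None = None
    resid_range: tuple[int, int] | None = None

    @classmethod
    def calpha(cls, chains: Sequence[str] | None = None) -> "AtomSelection":
        return cls(atom_names=frozenset({"CA"}),
                   chains=frozenset(chains) if chains else None)

    @classmethod
    def backbone(cls, chains: Sequence[str] | None = None) -> "AtomSelection":
        """Backbone heavy atoms (N, CA, C, O)."""
        return cls(atom_names=_BACKBONE,
                   chains=frozenset(chains) if chains else None)

    def indices(self, structure: Structure) -> np.ndarray:
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.atom_names is not None:
            mask &= np.array(
                [n in self.atom_names for n in structure.atom_names]
            )
        if self.heavy_only:
            mask &= np.array([e != "H" for e in structure.elements])
        if self.chains is not None:
            mask &= np.array([c in self.chains for c in structure.chains])
        if self.resid_range is not None:
            lo, hi = self.resid_range
            mask &= np.array([lo <= r <= hi for r in structure.resids])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"selection {self} matches no atoms")
        return idx


@dataclass(frozen=True)
class GateDefinition:
    """A named distance between two single atoms."""

    name: str
    endpoint_a: tuple[str, int, str]  # (chain, resid, atom name)
    endpoint_b: tuple[str, int, str]

    def resolve(self, structure: Structure) -> tuple[int, int]:
        out = []
        for ep in (self.endpoint_a, self.endpoint_b):
            ch, rid, name = ep
            hits = [
                i for i in range(structure.n_atoms)
                if structure.chains[i] == ch and structure.resids[i] == rid
                and structure.atom_names[i] == name
            ]
            if len(hits) != 1:
                raise ValueError(
                    f"gate {self.name!r}: endpoint {ep} resolves to "
                    f"{len(hits)} atoms (need exactly 1)"
                )
            out.append(hits[0])
        return out[0], out[1]


@dataclass
class DistanceDistribution:
    """Per-gate distance samples plus histograms (and an optional 2D joint)."""

    gate_names: list[str]
    samples: dict[str, np.ndarray]  # gate -> per-frame distances (A)
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # (edges, counts)
    joint: tuple[str, str, np.ndarray, np.ndarray, np.ndarray] | None = None
    # joint = (name_x, name_y, edges_x, edges_y, counts 2D)

    def write_tsv(self, samples_path: str | Path,
                  hist_path: str | Path) -> None:
        with open(samples_path, "w") as fh:
            fh.write("gate\tframe\tdistance_A\n")
            for g in self.gate_names:
                for f, d in enumerate(self.samples[g]):
                    fh.write(f"{g}\t{f}\t{d:.6f}\n")
        with open(hist_path, "w") as fh:
            fh.write("gate\tbin_lo\tbin_hi\tcount\n")
            for g in self.gate_names:
                edges, counts = self.histograms[g]
                for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                    fh.write(f"{g}\t{lo:.4f}\t{hi:.4f}\t{int(c)}\n")


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Optimal proper-rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the (weighted)
    least-squares RMSD to ``reference``.  The rotation is always proper
    (det = +1).

    Raises
    ------
    ValueError
        For fewer than 3 points or degenerate (collinear) geometry, where
        the optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("mobile and reference must have identical (n,3) shape")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(0) / wsum
    ref_c = (w[:, None] * reference).sum(0) / wsum
    mob0 = mobile - mob_c
    ref0 = reference - ref_c
    # degenerate if either cloud is (numerically) collinear
    for pts in (mob0, ref0):
        s = np.linalg.svd(pts * np.sqrt(w)[:, None], compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(ref0, mob0, weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    rmsd = float(rssd / np.sqrt(wsum))
    return R, t, rmsd


def _superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    return kabsch_superpose(mobile, reference)[2]


# ---------------------------------------------------------------------------
# RMSD / RMSF


def rmsd_series(traj: Trajectory, reference: Structure,
                fit_sel: AtomSelection | None = None,
                report_sel: AtomSelection | None = None,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (A) to ``reference`` after superposition on ``fit_sel``.

    ``fit_sel`` picks the atoms used for the rigid fit (default: backbone
    heavy atoms); ``report_sel`` the atoms entering the reported RMSD
    (default: same as the fit selection).  The two are independent so a
    backbone fit can report an all-heavy-atom RMSD.
    """
    fit_sel = fit_sel or AtomSelection.backbone()
    fit_idx = fit_sel.indices(traj.topology)
    ref_fit_idx = fit_sel.indices(reference)
    if fit_idx.size != ref_fit_idx.size:
        raise ValueError(
            f"fit selection resolves to {fit_idx.size} atoms in trajectory "
            f"but {ref_fit_idx.size} in reference"
        )
    rep_idx = report_sel.indices(traj.topology) if report_sel else fit_idx
    ref_rep_idx = report_sel.indices(reference) if report_sel else ref_fit_idx
    if rep_idx.size != ref_rep_idx.size:
        raise ValueError("report selection resolves differently in "
                         "trajectory and reference")

    ref_fit = reference.coords[ref_fit_idx]
    ref_rep = reference.coords[ref_rep_idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        if superpose:
            R, t, _ = kabsch_superpose(frame[fit_idx], ref_fit)
            rep = frame[rep_idx] @ R.T + t
        else:
            rep = frame[rep_idx]
        diff = rep - ref_rep
        out[f] = np.sqrt((diff * diff).sum() / rep_idx.size)
    return out


def pooled_rmsd_stats(series_per_run: Sequence[np.ndarray]):
    """Mean +/- SD per run and pooled across runs.

    Returns ``(per_run, pooled)`` where ``per_run`` is a list of
    ``(mean, sd)`` and ``pooled`` the same over all frames concatenated.
    """
    per_run = [(float(s.mean()), float(s.std(ddof=0))) for s in series_per_run]
    pooled = np.concatenate(list(series_per_run))
    return per_run, (float(pooled.mean()), float(pooled.std(ddof=0)))


def rmsf_per_residue(traj: Trajectory,
                     sel: AtomSelection | None = None,
                     superpose: bool = True,
                     reference: Structure | None = None,
                     tol: float = 1e-6,
                     max_iter: int = 50) -> ResidueScalarProfile:
    """Per-residue RMSF (A) about the mean structure.

    With ``superpose=True`` and no explicit reference, frames are
    iteratively superposed (on ``sel``) onto the running mean structure
    until the mean shifts by less than ``tol`` A — the standard
    self-consistent RMSF reference.  With a ``reference`` given, frames
    are superposed onto it once.  RMSF of a residue pools the squared
    fluctuations of all its selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = sel or AtomSelection.calpha()
    idx = sel.indices(traj.topology)
    X = traj.frames[:, idx, :].copy()  # (n_frames, m, 3)

    if superpose:
        if reference is not None:
            ref = reference.coords[sel.indices(reference)]
            for f in range(X.shape[0]):
                R, t, _ = kabsch_superpose(X[f], ref)
                X[f] = X[f] @ R.T + t
        else:
            mean = X[0].copy()
            for _ in range(max_iter):
                for f in range(X.shape[0]):
                    R, t, _ = kabsch_superpose(X[f], mean)
                    X[f] = X[f] @ R.T + t
                new_mean = X.mean(axis=0)
                shift = np.sqrt(((new_mean - mean) ** 2).sum(1).mean())
                mean = new_mean
                if shift < tol:
                    break
    mean = X.mean(axis=0)
    sq = ((X - mean) ** 2).sum(axis=2)  # (n_frames, m) squared displacement
    msf_atom = sq.mean(axis=0)          # per selected atom

    top = traj.topology
    per_res: dict[ResidueKey, list[float]] = {}
    for col, a in enumerate(idx):
        key = (top.chains[a], top.resids[a])
        per_res.setdefault(key, []).append(msf_atom[col])
    values = {k: float(np.sqrt(np.mean(v))) for k, v in per_res.items()}
    return ResidueScalarProfile(values, units="A")


# ---------------------------------------------------------------------------
# Gate distances


def gate_distances(traj: Trajectory, gates: Sequence[GateDefinition],
                   bin_width: float = 0.5,
                   joint_pair: tuple[str, str] | None = None
                   ) -> DistanceDistribution:
    """Per-frame gate distances with 1D histograms and an optional 2D joint.

    Default binning is 0.5 A over each gate's data range; ``joint_pair``
    names two gates whose joint 2D histogram is also built (the L1-L2 vs
    L1-L3 style gate-gate correlation plot).
    """
    samples: dict[str, np.ndarray] = {}
    for gate in gates:
        ia, ib = gate.resolve(traj.topology)
        d = traj.frames[:, ia, :] - traj.frames[:, ib, :]
        samples[gate.name] = np.sqrt((d * d).sum(axis=1))

    histograms = {}
    for name, s in samples.items():
        edges = _edges(s, bin_width)
        counts, edges = np.histogram(s, bins=edges)
        histograms[name] = (edges, counts)

    joint = None
    if joint_pair is not None:
        nx_, ny_ = joint_pair
        if nx_ not in samples or ny_ not in samples:
            raise ValueError(f"joint pair {joint_pair} not among gate names")
        ex = _edges(samples[nx_], bin_width)
        ey = _edges(samples[ny_], bin_width)
        counts2d, ex, ey = np.histogram2d(samples[nx_], samples[ny_],
                                          bins=(ex, ey))
        joint = (nx_, ny_, ex, ey, counts2d)

    return DistanceDistribution(
        gate_names=[g.name for g in gates],
        samples=samples, histograms=histograms, joint=joint,
    )


def _edges(s: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(s.min() / width) * width
    hi = np.ceil(s.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


# Default gate set for SULT1A1 numbering: the ligand-binding-site gates
# L1-L2 (P87CA-V148CA), L1-L3 (P87CA-F247CA) and the PAPS-pocket cover
# cL3 (K197CA-M260CA), per chain.
def default_sult1a1_gates(chain: str = "A") -> list[GateDefinition]:
    return [
        GateDefinition("L1-L2", (chain, 87, "CA"), (chain, 148, "CA")),
        GateDefinition("L1-L3", (chain, 87, "CA"), (chain, 247, "CA")),
        GateDefinition("cL3", (chain, 197, "CA"), (chain, 260, "CA")),
    ]


def chain_pair_rmsd(a: Structure, b: Structure,
                    sel: AtomSelection | None = None
                    ) -> dict[tuple[str, str], float]:
    """Heavy-atom RMSD between every chain of ``a`` and every chain of ``b``.

    Chains are paired atom-by-atom in order after applying ``sel``
    (default: C-alpha); pairs with unequal atom counts are skipped.
    Reports per-chain-pair values so asymmetric subunits are visible.
    """
    sel = sel or AtomSelection.calpha()
    out: dict[tuple[str, str], float] = {}
    for ca in a.chain_ids():
        ia = AtomSelection(sel.atom_names, sel.heavy_only,
                           frozenset({ca}), sel.resid_range).indices(a)
        for cb in b.chain_ids():
            ib = AtomSelection(sel.atom_names, sel.heavy_only,
                               frozenset({cb}), sel.resid_range).indices(b)
            if ia.size != ib.size or ia.size < 3:
                continue
            out[(ca, cb)] = _superposed_rmsd(a.coords[ia], b.coords[ib])
    return out
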