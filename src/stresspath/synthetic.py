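"""Synthetic two-condition elastic-network ensembles with planted pathways.

This module generates the statistical situation the force-difference
analysis assumes, at desk scale: a coarse-grained "protein" (one C-alpha
node per residue, one or two chains) whose dynamics is a harmonic spring
network, sampled *exactly* from its equilibrium Gaussian — frames are
drawn from N(x0, kT * H+), where H is the 3N x 3N anisotropic-network
Hessian and H+ its pseudoinverse over the non-rigid-body modes.  Exact
sampling rather than Langevin integration means every statistical check
(RMSF, covariance, equipartition) has a closed form.

Ligand binding is emulated as a planted perturbation: a ligand
pseudo-node tethered by springs to "site" residues, plus a designated
chain of springs stiffened by a factor lambda.  The perturbed springs
are the ground-truth allosteric pathway that the downstream
punctual-stress and maximin-pathway analysis should recover.

Default parameters: k = 100 pN/A, ENM cutoff = 8 A, kT = 41.4 pN*A
(300 K), lambda = 4 — chosen so planted force differences are of order
10^2 pN, the scale reported for cofactor-binding perturbations in
sulfotransferase simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structure_io import ResidueKey, Structure, Trajectory

DEFAULT_K = 100.0        # pN/A
DEFAULT_CUTOFF = 8.0     # A
DEFAULT_KT = 41.4        # pN*A, ~300 K
DEFAULT_LAMBDA = 4.0
RIGID_EIGVAL_FRACTION = 1e-8  # eigenvalues below this x largest are rigid

LIGAND_CHAIN = "X"


@dataclass
class ElasticNetwork:
    """Harmonic spring network over residue nodes (+ optional ligand nodes).

    ``node_keys[i]`` is the residue key of node ``i``; ``coords0`` the
    equilibrium coordinates (the energy minimum, since every spring's
    rest length is its equilibrium distance).  Springs are stored as an
    (m, 2) int index array with per-spring stiffness ``k`` (pN/A) and
    rest length ``r0`` (A).
    """

    node_keys: list[ResidueKey]
    coords0: np.ndarray                 # (n, 3) A
    springs: np.ndarray                 # (m, 2) int node indices, i < j
    k: np.ndarray                       # (m,) pN/A
    r0: np.ndarray                      # (m,) A
    kT: float = DEFAULT_KT              # pN*A

    def __post_init__(self) -> None:
        self.coords0 = np.asarray(self.coords0, dtype=float)
        self.springs = np.asarray(self.springs, dtype=int)
        self.k = np.asarray(self.k, dtype=float)
        self.r0 = np.asarray(self.r0, dtype=float)
        if np.any(self.k <= 0):
            raise ValueError("spring constants must be positive")
        if np.any(self.r0 <= 0):
            raise ValueError("rest lengths must be positive")
        if self.springs.size and (
            self.springs.min() < 0 or self.springs.max() >= self.n_nodes
        ):
            raise ValueError("spring endpoint out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.node_keys)

    @property
    def n_springs(self) -> int:
        return int(self.springs.shape[0])

    def energy(self, coords: np.ndarray) -> float:
        """Network potential energy (pN*A) from the full spring law."""
        d = coords[self.springs[:, 0]] - coords[self.springs[:, 1]]
        length = np.sqrt((d * d).sum(axis=1))
        return float(0.5 * (self.k * (length - self.r0) ** 2).sum())

    def harmonic_energy(self, coords: np.ndarray) -> float:
        """Quadratic-form energy 0.5 d'Hd about the equilibrium (pN*A).

        This is the energy of the linearised model the Gaussian ensemble
        samples; equipartition (kT/2 per non-rigid mode) holds for it
        exactly.  The full spring-law :meth:`energy` exceeds it by the
        anharmonic correction, which is not small at room-temperature
        fluctuation amplitudes.
        """
        d = (np.asarray(coords, dtype=float) - self.coords0).ravel()
        return float(0.5 * d @ self.hessian() @ d)

    def hessian(self) -> np.ndarray:
        """3N x 3N anisotropic-network Hessian at the equilibrium structure."""
        n = self.n_nodes
        H = np.zeros((3 * n, 3 * n))
        for (i, j), k, r0 in zip(self.springs, self.k, self.r0):
            d = self.coords0[i] - self.coords0[j]
            u = d / np.linalg.norm(d)
            block = k * np.outer(u, u)
            H[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
            H[3 * j:3 * j + 3, 3 * j:3 * j + 3] += block
            H[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= block
            H[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= block
        return H

    def to_structure(self) -> Structure:
        """One pseudo C-alpha atom per node (ligand nodes as LIG residues)."""
        names, elements, chains, resids, resnames = [], [], [], [], []
        for ch, rid in self.node_keys:
            names.append("CA")
            elements.append("C")
            chains.append(ch)
            resids.append(rid)
            resnames.append("LIG" if ch == LIGAND_CHAIN else "GLY")
        return Structure(names, elements, chains, resids, resnames,
                         self.coords0.copy())

    def write_tsv(self, path) -> None:
        """Spring-list TSV with a node-key header; floats via repr."""
        with open(path, "w") as fh:
            fh.write("# nodes\t"
                     + "\t".join(f"{c}:{r}" for c, r in self.node_keys)
                     + "\n")
            fh.write("# kT_pN_A\t" + repr(float(self.kT)) + "\n")
            fh.write("# coords\t"
                     + "\t".join(
                         f"{float(x)!r},{float(y)!r},{float(z)!r}"
                         for x, y, z in self.coords0)
                     + "\n")
            fh.write("i\tj\tk_pN_per_A\tr0_A\n")
            for (i, j), k, r0 in zip(self.springs, self.k, self.r0):
                fh.write(f"{i}\t{j}\t{float(k)!r}\t{float(r0)!r}\n")

    @classmethod
    def read_tsv(cls, path) -> "ElasticNetwork":
        with open(path) as fh:
            nodes_line = fh.readline().rstrip("\n").split("\t")
            if nodes_line[0] != "# nodes":
                raise ValueError("missing node header in network TSV")
            node_keys = []
            for tok in nodes_line[1:]:
                ch, rid = tok.rsplit(":", 1)
                node_keys.append((ch, int(rid)))
            kT = float(fh.readline().rstrip("\n").split("\t")[1])
            coord_line = fh.readline().rstrip("\n").split("\t")[1:]
            coords0 = np.array(
                [[float(v) for v in tok.split(",")] for tok in coord_line]
            )
            fh.readline()  # column header
            springs, ks, r0s = [], [], []
            for line in fh:
                i, j, k, r0 = line.rstrip("\n").split("\t")
                springs.append((int(i), int(j)))
                ks.append(float(k))
                r0s.append(float(r0))
        return cls(node_keys=node_keys, coords0=coords0,
                   springs=np.array(springs, dtype=int),
                   k=np.array(ks), r0=np.array(r0s), kT=kT)


@dataclass(frozen=True)
class PlantSpec:
    """Ground-truth ligand-binding perturbation.

    ``site_residues`` get springs to a new ligand pseudo-node;
    consecutive pairs of ``pathway_residues`` (which must already be
    spring-connected) have their springs stiffened by ``stiffening``.
    """

    site_residues: tuple[ResidueKey, ...]
    pathway_residues: tuple[ResidueKey, ...]
    stiffening: float = DEFAULT_LAMBDA
    ligand_k: float = DEFAULT_K


# ---------------------------------------------------------------------------
# Toy structures


def make_toy_structure(n_residues: int, n_chains: int = 1,
                       seed: int = 0, bond_length: float = 3.8,
                       min_sep: float = 3.4,
                       interface_dist: float = 4.5,
                       max_retries: int = 200) -> Structure:
    """Compact self-avoiding C-alpha chain(s) with ~3.8 A consecutive spacing.

    ``n_residues`` is the per-chain residue count.  The two-chain version
    places chain B in contact with chain A across a designated interface
    residue pair — the *last* residue of each chain (mimicking a
    C-terminal dimerisation motif) — at ``interface_dist`` separation.
    """
    if n_chains not in (1, 2):
        raise ValueError("n_chains must be 1 or 2")
    if n_residues < 8:
        raise ValueError("need at least 8 residues per chain")
    rng = np.random.default_rng(seed)
    xyz = None
    for _ in range(max_retries):
        chain_a = _grow_chain(n_residues, rng, bond_length, min_sep,
                              max_retries)
        coords = [chain_a]
        if n_chains == 2:
            chain_b = _place_partner(chain_a, n_residues, rng, bond_length,
                                     min_sep, interface_dist, max_retries)
            coords.append(chain_b)
        cand = np.vstack(coords)
        if _rigid_geometry(cand, DEFAULT_CUTOFF):
            xyz = cand
            break
    if xyz is None:
        raise RuntimeError(
            "could not place a mechanically rigid structure; "
            "try a different seed"
        )
    chains = ["A"] * n_residues + (["B"] * n_residues if n_chains == 2
                                   else [])
    n_total = xyz.shape[0]
    return Structure(
        atom_names=["CA"] * n_total,
        elements=["C"] * n_total,
        chains=chains,
        resids=list(range(1, n_residues + 1)) * n_chains,
        resnames=["GLY"] * n_total,
        coords=xyz,
    )


def _rigid_geometry(xyz: np.ndarray, cutoff: float) -> bool:
    """True if the distance-cutoff ENM on xyz has exactly 6 zero modes."""
    n = xyz.shape[0]
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    H = np.zeros((3 * n, 3 * n))
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu[dist[iu, ju] <= cutoff], ju[dist[iu, ju] <= cutoff]):
        u = diff[i, j] / dist[i, j]
        block = np.outer(u, u)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[sl_i, sl_i] += block
        H[sl_j, sl_j] += block
        H[sl_i, sl_j] -= block
        H[sl_j, sl_i] -= block
    evals = np.linalg.eigvalsh(H)
    return int((evals < RIGID_EIGVAL_FRACTION * evals[-1]).sum()) == 6


def _grow_chain(n: int, rng: np.random.Generator, bond: float,
                min_sep: float, max_retries: int) -> np.ndarray:
    """Self-avoiding compact random walk with fixed step length."""
    for _ in range(max_retries):
        pts = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            placed = False
            for _attempt in range(60):
                step = rng.normal(size=3)
                # compactness bias: drift back toward the centroid
                centroid = np.mean(pts, axis=0)
                drift = centroid - pts[-1]
                nd = np.linalg.norm(drift)
                if nd > 1e-9:
                    step = step + 0.8 * drift / nd
                step *= bond / np.linalg.norm(step)
                cand = pts[-1] + step
                prev = np.array(pts[:-1]) if len(pts) > 1 else None
                if prev is None or np.min(
                    np.linalg.norm(prev - cand, axis=1)
                ) >= min_sep:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError(
        "self-avoiding chain placement failed; try a different seed"
    )


def _place_partner(chain_a: np.ndarray, n: int, rng: np.random.Generator,
                   bond: float, min_sep: float, interface_dist: float,
                   max_retries: int, contact_cutoff: float = 8.0,
                   min_contacts: int = 10) -> np.ndarray:
    """Grow chain B and dock its last residue near chain A's last residue.

    The docked pose must give a mechanically rigid interface: besides
    the designated bridge pair (last residue of each chain) at
    ``interface_dist``, at least ``min_contacts`` inter-chain residue
    pairs must fall within ``contact_cutoff``, so the assembled dimer
    has only the six rigid-body zero modes.
    """
    from scipy.spatial.transform import Rotation

    anchor = chain_a[-1]
    centroid_a = chain_a.mean(axis=0)
    outward = anchor - centroid_a
    outward /= max(np.linalg.norm(outward), 1e-9)
    target = anchor + outward * interface_dist
    for _ in range(max(max_retries // 10, 5)):
        grown = _grow_chain(n, rng, bond, min_sep, max_retries)
        for _ in range(300):
            R = Rotation.random(rng=rng).as_matrix()
            chain_b = grown @ R.T
            chain_b = chain_b - chain_b[-1] + target
            dmat = np.linalg.norm(
                chain_a[:, None, :] - chain_b[None, :, :], axis=2
            )
            dmat_no_iface = dmat.copy()
            dmat_no_iface[-1, -1] = np.inf
            contacts = int((dmat <= contact_cutoff).sum())
            if (dmat_no_iface.min() >= min_sep
                    and contacts >= min_contacts):
                return chain_b
    raise RuntimeError(
        "dimer interface placement failed; try a different seed"
    )


# ---------------------------------------------------------------------------
# Network construction and sampling


def build_enm(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
              k: float = DEFAULT_K, kT: float = DEFAULT_KT) -> ElasticNetwork:
    """Distance-cutoff elastic network over the structure's residues.

    A spring of stiffness ``k`` joins every residue pair within
    ``cutoff`` A (one node per residue, at its first atom — for C-alpha
    models, the C-alpha).  Rest lengths equal the input distances, so the
    input structure is the exact energy minimum.
    """
    keys = structure.residue_keys()
    node_xyz = np.array([
        structure.coords[structure.atom_indices(key)[0]] for key in keys
    ])
    n = len(keys)
    diff = node_xyz[:, None, :] - node_xyz[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    iu, ju = np.triu_indices(n, k=1)
    within = dist[iu, ju] <= cutoff
    springs = np.stack([iu[within], ju[within]], axis=1)
    r0 = dist[iu, ju][within]
    net = ElasticNetwork(
        node_keys=keys, coords0=node_xyz, springs=springs,
        k=np.full(springs.shape[0], float(k)), r0=r0, kT=kT,
    )
    if not _connected(n, springs):
        raise ValueError(
            f"elastic network disconnected at cutoff {cutoff} A; "
            "use a larger cutoff"
        )
    return net


def _connected(n: int, springs: np.ndarray) -> bool:
    from scipy.cluster.hierarchy import DisjointSet
    ds = DisjointSet(range(n))
    for i, j in springs:
        ds.merge(int(i), int(j))
    return ds.n_subsets == 1


def sample_ensemble(net: ElasticNetwork, n_frames: int,
                    seed: int) -> Trajectory:
    """Draw frames exactly from the network's equilibrium Gaussian.

    Displacements are sampled in the eigenbasis of the Hessian H with
    variance kT / eigenvalue per non-rigid mode; the (up to six)
    rigid-body modes are excluded, so the ensemble has no net drift or
    tumble and no superposition is needed downstream.  Bitwise
    reproducible from ``seed``.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    H = net.hessian()
    evals, evecs = np.linalg.eigh(H)
    thresh = RIGID_EIGVAL_FRACTION * evals[-1]
    rigid = evals < thresh
    n_rigid = int(rigid.sum())
    if n_rigid > 6:
        raise ValueError(
            f"network has {n_rigid} near-zero modes (floppy network); "
            "add springs or raise the cutoff"
        )
    soft = ~rigid
    V = evecs[:, soft]                      # (3n, n_modes)
    sigma = np.sqrt(net.kT / evals[soft])   # per-mode std (A)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, sigma.size))
    disp = (z * sigma) @ V.T                # (n_frames, 3n)
    frames = net.coords0[None, :, :] + disp.reshape(n_frames, net.n_nodes, 3)
    return Trajectory(net.to_structure(), frames)


def analytic_msf(net: ElasticNetwork) -> np.ndarray:
    """Per-node mean squared fluctuation kT * tr(H+_ii), A^2 (exact)."""
    H = net.hessian()
    evals, evecs = np.linalg.eigh(H)
    thresh = RIGID_EIGVAL_FRACTION * evals[-1]
    soft = evals >= thresh
    inv = (evecs[:, soft] ** 2 / evals[soft]).sum(axis=1) * net.kT
    return inv.reshape(net.n_nodes, 3).sum(axis=1)


def mean_harmonic_energy(net: ElasticNetwork, frames: np.ndarray) -> float:
    """Mean 0.5 d'Hd over a frame stack (pN*A), Hessian built once."""
    H = net.hessian()
    D = frames.reshape(frames.shape[0], -1) - net.coords0.ravel()
    return float(0.5 * np.einsum("fi,ij,fj->f", D, H, D).mean())


def n_soft_modes(net: ElasticNetwork) -> int:
    evals = np.linalg.eigvalsh(net.hessian())
    return int((evals >= RIGID_EIGVAL_FRACTION * evals[-1]).sum())


# ---------------------------------------------------------------------------
# Planted perturbation


def plant_perturbation(net: ElasticNetwork, spec: PlantSpec,
                       ligand_resid: int = 1) -> ElasticNetwork:
    """Return a new network with the ligand attached and the pathway stiffened.

    The ligand pseudo-node is placed at the centroid of the site
    residues, displaced outward so no tether has zero length, and tied to
    each site residue by a spring of stiffness ``spec.ligand_k`` at the
    resulting distance.  Each consecutive pair of ``pathway_residues``
    must already share a spring; its stiffness is multiplied by
    ``spec.stiffening``.  The input network is not modified.
    """
    key_to_idx = {k: i for i, k in enumerate(net.node_keys)}
    for key in spec.site_residues + spec.pathway_residues:
        if key not in key_to_idx:
            raise KeyError(f"residue {key} not in network")

    springs = net.springs.copy()
    k = net.k.copy()
    r0 = net.r0.copy()

    pair_to_spring = {
        (min(i, j), max(i, j)): s
        for s, (i, j) in enumerate(net.springs)
    }
    for a, b in zip(spec.pathway_residues[:-1], spec.pathway_residues[1:]):
        ia, ib = key_to_idx[a], key_to_idx[b]
        key = (min(ia, ib), max(ia, ib))
        if key not in pair_to_spring:
            raise ValueError(
                f"pathway residues {a} and {b} share no spring; the "
                "pathway chain must be connected in the network"
            )
        k[pair_to_spring[key]] *= spec.stiffening

    node_keys = list(net.node_keys)
    coords0 = net.coords0
    if spec.site_residues:
        site_idx = [key_to_idx[s] for s in spec.site_residues]
        site_xyz = net.coords0[site_idx]
        centroid_all = net.coords0.mean(axis=0)
        pos = site_xyz.mean(axis=0)
        outward = pos - centroid_all
        nrm = np.linalg.norm(outward)
        outward = outward / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        pos = pos + 2.5 * outward  # keep tethers clear of zero length
        lig = len(node_keys)
        node_keys.append((LIGAND_CHAIN, ligand_resid))
        coords0 = np.vstack([net.coords0, pos])
        new_springs = [[min(i, lig), max(i, lig)] for i in site_idx]
        new_r0 = [float(np.linalg.norm(coords0[i] - pos)) for i in site_idx]
        springs = np.vstack([springs, np.array(new_springs, dtype=int)])
        k = np.concatenate([k, np.full(len(site_idx), spec.ligand_k)])
        r0 = np.concatenate([r0, np.array(new_r0)])

    return ElasticNetwork(node_keys=node_keys, coords0=coords0,
                          springs=springs, k=k, r0=r0, kT=net.kT)


def default_plant_spec(n_residues_per_chain: int = 32) -> PlantSpec:
    """The default planted-pathway scenario for a two-chain toy dimer.

    The ligand site sits just upstream of chain A's C-terminal interface
    residue (three tether residues, so the ligand node is held rigidly);
    the stiffened pathway runs along chain A's C-terminal segment,
    across the designated interface bridge (A-terminus to B-terminus),
    and two residues into chain B.
    """
    n = n_residues_per_chain
    return PlantSpec(
        site_residues=(("A", n - 4), ("A", n - 3), ("A", n - 2)),
        pathway_residues=(
            ("A", n - 2), ("A", n - 1), ("A", n), ("B", n), ("B", n - 1),
        ),
    )


def interface_bridge(n_residues_per_chain: int = 32) -> tuple[ResidueKey,
                                                              ResidueKey]:
    """The designated dimer-interface residue pair of the toy dimer."""
    n = n_residues_per_chain
    return ("A", n), ("B", n)
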