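"""Superposition, RMSD/RMSF, and gate-distance behaviour."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import stresspath as sp
from stresspath.metrics import (
    AtomSelection,
    GateDefinition,
    default_sult1a1_gates,
    gate_distances,
    kabsch_superpose,
)


def _random_cloud(rng, n=10, scale=3.0):
    return rng.normal(scale=scale, size=(n, 3))


def _grid_oracle_rmsd(mobile, reference):
    """Brute-force minimum RMSD over a refined dense rotation grid.

    Independent of the Kabsch solver: scans Euler-angle space coarsely,
    then refines twice around the best grid point down to 1e-3 rad.
    """
    mob = mobile - mobile.mean(0)
    ref = reference - reference.mean(0)
    n = mob.shape[0]

    def rmsd_for(rots):
        rotated = np.einsum("kij,nj->kni", rots, mob)
        d = rotated - ref
        return np.sqrt((d * d).sum(axis=(1, 2)) / n)

    best_angles = np.zeros(3)
    spans = [(np.pi, 0.12), (0.24, 0.012), (0.024, 0.0012)]
    best = np.inf
    for span, step in spans:
        ax = np.arange(-span, span + step / 2, step)
        grids = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"),
                         axis=-1).reshape(-1, 3) + best_angles
        rots = Rotation.from_euler("zyx", grids).as_matrix()
        vals = rmsd_for(rots)
        k = int(np.argmin(vals))
        best = float(vals[k])
        best_angles = grids[k]
    return best


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        rng = np.random.default_rng(0)
        x = _random_cloud(rng)
        R, t, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-8)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        x = _random_cloud(rng)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ Rz.T + np.array([5.0, 5.0, 5.0])
        R, t, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(x @ R.T + t, y, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(2)
        a, b = _random_cloud(rng), _random_cloud(rng)
        r_ab = kabsch_superpose(a, b)[2]
        r_ba = kabsch_superpose(b, a)[2]
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        Q = Rotation.random(rng=rng).as_matrix()
        a_moved = a @ Q.T + rng.normal(size=3)
        assert kabsch_superpose(a_moved, b)[2] == pytest.approx(
            r_ab, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_cloud(rng), _random_cloud(rng)
        exact = kabsch_superpose(a, b)[2]
        grid = _grid_oracle_rmsd(a, b)
        assert exact <= grid + 1e-9  # Kabsch is the true minimum
        assert grid - exact < 1e-3

    def test_degenerate_inputs_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_copies_of_reference_give_zero(self, toy_monomer):
        structure, _ = toy_monomer
        traj = sp.Trajectory(structure, np.stack([structure.coords] * 4))
        out = sp.rmsd_series(traj, structure,
                             fit_sel=AtomSelection.calpha())
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_pure_translation_superposes_to_zero(self, toy_monomer):
        structure, _ = toy_monomer
        frames = structure.coords[None] + np.array([3.0, 0.0, 0.0])
        traj = sp.Trajectory(structure, frames)
        out = sp.rmsd_series(traj, structure,
                             fit_sel=AtomSelection.calpha())
        assert out[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_closed_form(self, toy_monomer):
        structure, _ = toy_monomer
        n = structure.n_atoms
        d = 2.0
        frame = structure.coords.copy()
        frame[0, 0] += d
        traj = sp.Trajectory(structure, frame[None])
        out = sp.rmsd_series(traj, structure,
                             fit_sel=AtomSelection.calpha(),
                             superpose=False)
        assert out[0] == pytest.approx(d / np.sqrt(n), abs=1e-12)


class TestRmsf:
    def test_static_trajectory_is_zero(self, toy_monomer):
        structure, _ = toy_monomer
        traj = sp.Trajectory(structure, np.stack([structure.coords] * 3))
        prof = sp.rmsf_per_residue(traj)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in prof.values.values())

    def test_single_frame_rejected(self, toy_monomer):
        structure, _ = toy_monomer
        traj = sp.Trajectory(structure, structure.coords[None])
        with pytest.raises(ValueError, match="2 frames"):
            sp.rmsf_per_residue(traj)

    def test_iid_gaussian_displacements_analytic(self, toy_monomer):
        # i.i.d. isotropic noise of std sigma per coordinate -> RMSF
        # = sigma * sqrt(3) in expectation
        structure, _ = toy_monomer
        rng = np.random.default_rng(6)
        sigma = 0.3
        frames = structure.coords[None] + rng.normal(
            scale=sigma, size=(10_000, structure.n_atoms, 3))
        traj = sp.Trajectory(structure, frames)
        prof = sp.rmsf_per_residue(traj, superpose=False)
        vals = np.array(list(prof.values.values()))
        np.testing.assert_allclose(vals, sigma * np.sqrt(3), rtol=0.03)

    def test_invariant_to_frame_order(self, toy_monomer):
        structure, net = toy_monomer
        traj = sp.sample_ensemble(net, 50, seed=8)
        prof = sp.rmsf_per_residue(traj)
        rng = np.random.default_rng(9)
        perm = rng.permutation(traj.n_frames)
        prof_perm = sp.rmsf_per_residue(
            sp.Trajectory(traj.topology, traj.frames[perm]))
        for k in prof.keys():
            assert prof[k] == pytest.approx(prof_perm[k], abs=1e-7)


class TestGateDistances:
    def _line_structure(self, coords, resids=None, chain="A"):
        n = len(coords)
        resids = resids or list(range(1, n + 1))
        return sp.Structure(["CA"] * n, ["C"] * n, [chain] * n, resids,
                            ["GLY"] * n, np.array(coords, dtype=float))

    def test_three_four_five(self):
        s = self._line_structure([[0, 0, 0], [3, 4, 0], [1, 1, 1]])
        traj = sp.Trajectory(s, np.stack([s.coords] * 3))
        gate = GateDefinition("g", ("A", 1, "CA"), ("A", 2, "CA"))
        dist = gate_distances(traj, [gate])
        np.testing.assert_allclose(dist.samples["g"], 5.0)

    def test_rigid_motion_leaves_distances_unchanged(self, toy_monomer):
        structure, net = toy_monomer
        traj = sp.sample_ensemble(net, 20, seed=10)
        gate = GateDefinition("g", ("A", 1, "CA"), ("A", 8, "CA"))
        d0 = gate_distances(traj, [gate]).samples["g"]
        rng = np.random.default_rng(11)
        Q = Rotation.random(rng=rng).as_matrix()
        moved = sp.Trajectory(
            structure, traj.frames @ Q.T + rng.normal(size=3))
        d1 = gate_distances(moved, [gate]).samples["g"]
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_histogram_counts_and_joint_marginals(self, toy_monomer):
        structure, net = toy_monomer
        traj = sp.sample_ensemble(net, 200, seed=12)
        gates = [GateDefinition("a", ("A", 1, "CA"), ("A", 10, "CA")),
                 GateDefinition("b", ("A", 2, "CA"), ("A", 12, "CA"))]
        dist = gate_distances(traj, gates, joint_pair=("a", "b"))
        for name in ("a", "b"):
            _, counts = dist.histograms[name]
            assert counts.sum() == traj.n_frames
        _, _, ex, ey, joint = dist.joint
        assert joint.sum() == traj.n_frames
        np.testing.assert_array_equal(
            joint.sum(axis=1), dist.histograms["a"][1])
        np.testing.assert_array_equal(
            joint.sum(axis=0), dist.histograms["b"][1])

    def test_unresolvable_endpoint_names_gate(self):
        s = self._line_structure([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        traj = sp.Trajectory(s, s.coords[None])
        gate = GateDefinition("cL3", ("A", 197, "CA"), ("A", 260, "CA"))
        with pytest.raises(ValueError, match="cL3"):
            gate_distances(traj, [gate])

    def test_default_sult1a1_gates_resolve(self):
        resids = [87, 148, 197, 247, 260]
        rng = np.random.default_rng(13)
        s = self._line_structure(rng.normal(size=(5, 3)), resids=resids)
        for gate in default_sult1a1_gates("A"):
            ia, ib = gate.resolve(s)
            assert s.resids[ia] == gate.endpoint_a[1]
            assert s.resids[ib] == gate.endpoint_b[1]
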