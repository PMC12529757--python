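"""Shared fixtures: tiny PDB texts and small elastic-network scenarios."""

import numpy as np
import pytest

import stresspath as sp
from stresspath.synthetic import default_plant_spec

TWO_ATOM_PDB = (
    "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00"
    "           N\n"
    "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00"
    "           C\n"
    "END\n"
)


@pytest.fixture
def two_atom_pdb(tmp_path):
    p = tmp_path / "two_atom.pdb"
    p.write_text(TWO_ATOM_PDB)
    return p


@pytest.fixture(scope="session")
def toy_monomer():
    structure = sp.make_toy_structure(16, 1, seed=3)
    return structure, sp.build_enm(structure)


@pytest.fixture(scope="session")
def toy_dimer():
    structure = sp.make_toy_structure(32, 2, seed=0)
    return structure, sp.build_enm(structure)


@pytest.fixture(scope="session")
def planted_dimer(toy_dimer):
    _, net = toy_dimer
    spec = default_plant_spec(32)
    return net, sp.plant_perturbation(net, spec), spec


@pytest.fixture(scope="session")
def apo_vs_planted(planted_dimer):
    """One apo/bound force-matrix pair at a fixed seed (2000 frames)."""
    net, net_planted, spec = planted_dimer
    traj_a = sp.sample_ensemble(net, 2000, seed=11)
    traj_b = sp.sample_ensemble(net_planted, 2000, seed=12)
    fa = sp.mean_force_matrix(traj_a, net)
    fb = sp.mean_force_matrix(traj_b, net_planted)
    fa, fb = sp.align_force_matrices(fa, fb)
    return sp.force_difference(fa, fb), spec


def random_delta_matrix(rng, n=8, density=1.0):
    """A valid random DeltaForceMatrix for property tests."""
    vals = np.abs(rng.normal(size=(n, n)))
    if density < 1.0:
        vals *= rng.random(size=(n, n)) < density
    vals = np.triu(vals, k=1)
    vals = vals + vals.T
    index = [("A", i + 1) for i in range(n)]
    return sp.DeltaForceMatrix(index=index, values=vals)
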