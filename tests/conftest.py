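"""Shared fixtures: small synthetic ensembles with known ground truth."""

import numpy as np
import pytest

import ensemblecmp as ec


@pytest.fixture(scope="session")
def chain_center():
    """A 20-atom self-avoiding chain used as the reference conformation."""
    return ec.make_chain_center(20, seed=10)


@pytest.fixture(scope="session")
def far_center(chain_center):
    """A second conformation 20 Å (minimized RMSD) from the first."""
    return ec.displaced_center(chain_center, 20.0, seed=11)


@pytest.fixture(scope="session")
def tight_ensemble(chain_center):
    """200 frames from one harmonic well, 0.5 Å isotropic fluctuation."""
    spec = ec.SyntheticSpec(20, [(chain_center, 0.5, 1.0)], 200, seed=1, label="A")
    return ec.make_harmonic_ensemble(spec)


@pytest.fixture(scope="session")
def far_ensemble(far_center):
    """200 frames from a well 20 Å away from ``tight_ensemble``'s."""
    spec = ec.SyntheticSpec(20, [(far_center, 0.5, 1.0)], 200, seed=2, label="B")
    return ec.make_harmonic_ensemble(spec)


@pytest.fixture(scope="session")
def lowrank_ensemble(chain_center):
    """A well whose fluctuations live in 3 collective modes (MD-like)."""
    spec = ec.SyntheticSpec(
        20, [(chain_center, 0.5, 1.0)], 200, seed=4, label="L", n_modes=3
    )
    return ec.make_harmonic_ensemble(spec)


@pytest.fixture(scope="session")
def two_cloud_matrix(chain_center, far_center):
    """RMSD matrix over two 20-frame clouds separated by 20 Å."""
    ea = ec.make_harmonic_ensemble(
        ec.SyntheticSpec(20, [(chain_center, 0.5, 1.0)], 20, seed=3, label="a")
    )
    eb = ec.make_harmonic_ensemble(
        ec.SyntheticSpec(20, [(far_center, 0.5, 1.0)], 20, seed=4, label="b")
    )
    return ec.rmsd_matrix([ea, eb])
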