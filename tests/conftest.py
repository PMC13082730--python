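import warnings

import numpy as np
import pytest

import tipwall.forward_simulator as fs
from tipwall import ensemble_analysis as ea

warnings.filterwarnings("ignore", message="min_dist=.*admits only")


@pytest.fixture(scope="session")
def caul_spec():
    return fs.caulonema()


@pytest.fixture(scope="session")
def chlo_spec():
    return fs.chloronema()


@pytest.fixture(scope="session")
def caul_solution(caul_spec):
    """Forward-solved caulonema cell, constant K_h = 5, nu = 0.5."""
    return fs.solve_turgid_outline(caul_spec, fs.ModulusProfile.constant(5.0))


@pytest.fixture(scope="session")
def chlo_solution(chlo_spec):
    return fs.solve_turgid_outline(chlo_spec, fs.ModulusProfile.constant(5.0))


@pytest.fixture(scope="session")
def caul_cell(caul_spec, caul_solution):
    """Noise-free synthetic caulonema cell pair (default marker class)."""
    return fs.generate_cell(caul_spec, fs.ModulusProfile.constant(5.0),
                            fs.NoiseSpec.preset("none"), seed=0,
                            solution=caul_solution)


@pytest.fixture(scope="session")
def caul_run(caul_cell):
    """Full-pipeline inference on the noise-free caulonema cell."""
    return ea.run_single_cell(caul_cell)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
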