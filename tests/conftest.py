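"""Shared fixtures: small simulated panels and the desk-scale calibration
reference table (session-scoped; it backs the calibration tests)."""

import numpy as np
import pytest

from splitabc import (
    GenomeConfig,
    SplitModelParams,
    panel_to_genotypes,
    simulate_panel,
)
from splitabc.synth import generate_reference

# desk-scale calibration study: 3000 simulations of a 2.5 Mb segment with
# 20+20 diploids under the default priors and the 0.001 genotype error rate
CALIB_GENOME = GenomeConfig(sequence_length=2.5e6, recombination=1e-8, samples_per_pop=20)
CALIB_N_SIM = 3000
CALIB_SEED = 20260101


@pytest.fixture(scope="session")
def calibration_reference():
    """Reference table of the desk-scale calibration study (several minutes)."""
    return generate_reference(n_sim=CALIB_N_SIM, genome=CALIB_GENOME, seed=CALIB_SEED)


@pytest.fixture(scope="session")
def small_panel():
    """A small two-population panel with an intermediate split."""
    params = SplitModelParams(20000, 5000, 8000, 3000, 118)
    return simulate_panel(
        params,
        genome=GenomeConfig(sequence_length=1e6, samples_per_pop=8),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genotypes(small_panel):
    return panel_to_genotypes(small_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
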