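"""Shared fixtures: default-condition gradient ensembles at study scale.

The heavyweight ensembles (1000 replicates at the default noise levels,
matching the study conditions) are session-scoped so that the precision
tests share them instead of re-simulating.
"""

import numpy as np
import pytest

from morphograd import (
    EnsembleConfig,
    default_kinetics,
    deterministic_reference,
    run_ensemble,
)

MU_DELTA = 5.0  # µm; mu_lambda / 4
N_REPLICATES = 1000
MASTER_SEED = 2023


@pytest.fixture(scope="session")
def reference_n1():
    """Noise-free gradient for linear decay at default parameters."""
    return deterministic_reference(default_kinetics())


@pytest.fixture(scope="session")
def ensembles_n1():
    """Default-noise ensembles for linear decay, read out at 2, 5 and
    75 cell diameters from the source."""
    cfg = EnsembleConfig(kinetics=default_kinetics())
    targets = [2 * MU_DELTA, 5 * MU_DELTA, 75 * MU_DELTA]
    return run_ensemble(cfg, targets, n_replicates=N_REPLICATES, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def ensembles_n4():
    """Default-noise ensembles for strongly non-linear decay (n = 4),
    read out at 2 cell diameters from the source."""
    cfg = EnsembleConfig(kinetics=default_kinetics(n=4.0))
    return run_ensemble(cfg, [2 * MU_DELTA], n_replicates=N_REPLICATES, seed=MASTER_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
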