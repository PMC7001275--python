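"""Shared fixtures. The expensive Monte Carlo runs (1000-replicate
integration experiments, the persistence-length ensemble) are session-scoped
so the statistical tests and the acceptance checks share one computation."""

import numpy as np
import pytest

import tepolymer as tp
from tepolymer.integration import AttemptSchedule, TESpec, run_experiment

N_BEADS = 200
SOFT = tp.default_soft_indices(N_BEADS)  # joints 19, 39, ..., 179
N_REPLICATES = 1000


@pytest.fixture(scope="session")
def uniform_spec():
    return tp.SubstrateSpec(n_beads=N_BEADS, soft_indices=SOFT, lf_bp=150.0)


@pytest.fixture(scope="session")
def soft60_spec():
    return tp.SubstrateSpec(n_beads=N_BEADS, soft_indices=SOFT, lf_bp=60.0)


@pytest.fixture(scope="session")
def uniform_result(uniform_spec):
    """1000 replicates on the uniformly stiff substrate (l_f = l_p)."""
    return run_experiment(uniform_spec, TESpec(), N_REPLICATES, master_seed=11)


@pytest.fixture(scope="session")
def soft60_result(soft60_spec):
    """1000 replicates with soft sites at l_f = 60 bp."""
    return run_experiment(soft60_spec, TESpec(), N_REPLICATES, master_seed=12)


@pytest.fixture(scope="session")
def stiff_ensemble():
    """500 decorrelated frames of the uniform l_p = 150 bp substrate,
    spread over 25 independent chains."""
    spec = tp.SubstrateSpec(n_beads=N_BEADS)
    return tp.sample_ensemble(spec, n_frames=500, stride=10,
                              equil_sweeps=150, seed=42, n_chains=25)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
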