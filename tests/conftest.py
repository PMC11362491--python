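import numpy as np
import pytest

import dualrec as dr
from dualrec.mcmc import McmcConfig
from dualrec.recovery import STUDY_MCMC, run_recovery_study


@pytest.fixture(scope="session")
def exp1_config():
    return dr.experiment1_preset(seed=11)


@pytest.fixture(scope="session")
def exp1_data(exp1_config):
    thetas, counts = dr.simulate_experiment(exp1_config)
    return thetas, counts


@pytest.fixture(scope="session")
def small_fit(exp1_config, exp1_data):
    """One quick hierarchical fit reused by several tests."""
    _, counts = exp1_data
    model = dr.DualRecollectionModel(counts, exp1_config.design)
    res = model.fit_bayes(
        mcmc=McmcConfig(chains=2, draws=400, burn=300), seed=17
    )
    return model, res


@pytest.fixture(scope="session")
def exp1_recovery_study(exp1_config):
    """The 20-replication recovery study at the realistic operating point:
    48 participants, published group means as truths; shared by the
    recovery, coverage and posterior-predictive-calibration checks."""
    return run_recovery_study(
        exp1_config, reps=20, seed=101, mcmc=STUDY_MCMC, ppc_reps=200
    )


def random_thetas(n, rng, margin=0.0):
    """Uniform parameter vectors in [margin, 1-margin]^9."""
    return margin + (1 - 2 * margin) * rng.random((n, len(dr.PARAM_NAMES)))
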