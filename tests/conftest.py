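import warnings

import numpy as np
import pytest

import ambiddm as am

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def clean_itc_pop():
    """Population for the best intertemporal model, no contaminants."""
    return am.default_population("itc_aw_amb_rxd",
                                 p_rt_outlier=0.0, p_switch_trial=0.0,
                                 catch_error_rate=0.0)


@pytest.fixture(scope="session")
def small_cohort(clean_itc_pop):
    """Two clean synthetic participants, 98-trial intertemporal sessions."""
    behavior, truth, _ = am.simulate_cohort(2, clean_itc_pop, seed=7,
                                            session="domain")
    return behavior, truth


@pytest.fixture(scope="session")
def reference_fit(small_cohort):
    """One converged scaled-down fit, shared across the suite."""
    behavior, _ = small_cohort
    spec = am.get_model("itc_aw_amb_rxd")
    cfg = am.MCMCConfig(n_chains=2, n_warmup=500, n_sampling=500, seed=42)
    return am.fit_participant(behavior[behavior.participant == 0], spec, cfg)
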