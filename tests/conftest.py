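import numpy as np
import pytest
from scipy.stats import qmc

from hepasens import circulation_model as cm
from hepasens import cohort_distributions as cd
from hepasens.params import INPUT_NAMES, ModelConfig, default_parameters


@pytest.fixture(scope="session")
def config():
    return ModelConfig()

@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def baseline_trace(base_params, config):
    return cm.simulate_to_periodic(base_params, config)


@pytest.fixture(scope="session")
def baseline_outputs(baseline_trace):
    return cm.cycle_averages(baseline_trace)


@pytest.fixture(scope="session")
def small_study(config):
    """A small shared model study: 300 quasi-random subjects with pre-
    and post-resection outputs (used by filter/population tests)."""
    import warnings

    spec = cd.default_cohort_spec()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        eng = qmc.Sobol(len(INPUT_NAMES), scramble=True, rng=np.random.default_rng(7))
        U = eng.random(300)
    X = np.column_stack([spec.marginals[n].ppf(U[:, j])
                         for j, n in enumerate(INPUT_NAMES)])
    pre, post, ok = cm.evaluate_many(X, config)
    assert ok.all()
    import pandas as pd

    from hepasens.params import OUTPUT_NAMES

    inputs = pd.DataFrame(X, columns=list(INPUT_NAMES))
    pre_df = pd.DataFrame(pre[:, :6], columns=list(OUTPUT_NAMES))
    post_df = pd.DataFrame(post[:, :6], columns=list(OUTPUT_NAMES))
    return inputs, pre_df, post_df
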