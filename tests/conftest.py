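import warnings

import numpy as np
import pytest

import trnkit as tk

# enrichment helpers warn when DEG sets extend beyond the stated universe;
# that is expected in pipeline-level tests
warnings.filterwarnings("ignore", message=".*extends beyond universe.*")


@pytest.fixture(scope="session")
def default_config():
    return tk.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_study(default_config):
    """The default allelic-series study (144 samples, 20 TFs, 200 genes)."""
    return tk.simulate_study(default_config)


@pytest.fixture(scope="session")
def fitted_network(default_study):
    """Penalty selection plus network fit on the default study."""
    study = default_study
    expr, expressed = tk.preprocess_expression(
        study.counts, study.design, tf_list=list(study.config.tf_ids)
    )
    penalty = tk.select_penalty(expr, study.prior, seed=1)
    model = tk.fit_network(expr, study.prior, penalty, seed=1)
    return expr, penalty, model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
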