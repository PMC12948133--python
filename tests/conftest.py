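import numpy as np
import pytest

from sleepddm import generate, model


@pytest.fixture(scope="session")
def small_study():
    """A small NP-like study with known generating truth, simulated once."""
    design = generate.make_design("NP_LIKE", n_subjects=10, mean_trials=60, seed=11)
    gen = generate.default_generating_parameters()
    params = generate.draw_subject_parameters(gen, design, seed=12)
    data = generate.simulate_dataset(design, params, seed=13)
    return {"design": design, "gen": gen, "params": params, "trials": data}


@pytest.fixture(scope="session")
def small_fit(small_study):
    """One hierarchical DDM fit on the small study, shared across tests."""
    spec = model.RegressionSpec.full()
    fit = model.fit_hddm(small_study["trials"], spec,
                         n_samples=1500, burn_in=400, n_chains=2, seed=21)
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
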