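import numpy as np
import pytest
from hypothesis import settings

from psfield import SimulationParams, SurfaceSpec, build_spats_model, fit_reml, simulate_trial

settings.register_profile("suite", deadline=None, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_trial():
    """10x6 trial with a mild smooth trend; shared across read-only tests."""
    params = SimulationParams(
        n_rows=10, n_cols=6, n_geno=40, p_rep=0.3, n_checks=2,
        sigma2_g=1.0, sigma2_e=0.5, missing_rate=0.05,
        surface=SurfaceSpec(kind="smooth", amplitude=1.5, shape_seed=9),
        seed=21,
    )
    trial, truth = simulate_trial(params)
    return trial, truth, params


@pytest.fixture(scope="session")
def small_fit(small_trial):
    trial, _, _ = small_trial
    return fit_reml(build_spats_model(trial))
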