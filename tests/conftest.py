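import numpy as np
import pytest

import weibullmeans as wm


@pytest.fixture(scope="session")
def wind_samples():
    return wm.load_surat_thani()


@pytest.fixture(scope="session")
def wind_fits(wind_samples):
    return [wm.fit_weibull_mle(s) for s in wind_samples]


@pytest.fixture(scope="session")
def wind_estimates(wind_samples, wind_fits):
    return [wm.mean_estimate(s, f) for s, f in zip(wind_samples, wind_fits)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20230622)
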