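import numpy as np
import pytest

from neobag import respiration as R
from neobag import synthetic as S


@pytest.fixture(scope="session")
def basis500():
    """NRF basis on a 500 Hz epoch grid (shared across tests)."""
    return S.make_nrf_basis(fs=500.0)


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the default synthetic cohort with its ground truth."""
    return S.simulate_cohort(S.CohortParams(seed=1))


@pytest.fixture(scope="session")
def apnoea_clf():
    """Apnoea screen trained on a modest labelled synthetic set."""
    feats, labels = S.make_apnoea_training_set(80, seed=0)
    return R.train_apnoea_classifier(feats, labels, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
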