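import numpy as np
import pytest

from timeuse import models, simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_compositions(rng):
    """1000 random strictly positive 4-part compositions closed to 1440."""
    from timeuse import coda
    raw = rng.lognormal(mean=3.0, sigma=1.0, size=(1000, 4))
    return coda.closure(raw)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (n=378) shared across model tests."""
    return simulate.generate_cohort(simulate.default_config(seed=7, n=378))


@pytest.fixture(scope="session")
def cohort_ilr(cohort):
    data = models.add_ilr_columns(cohort)
    data["frontal_std"] = cohort["truth_roi_std_frontal"]
    data["gm_std"] = cohort["truth_roi_std_total_gm"]
    return data
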