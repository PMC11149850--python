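import numpy as np
import pytest

from ppgsurv.cohort import SimParams, simulate_cohort
from ppgsurv.pipeline import RunConfig, run_pipeline

ALL_COX_SETS = ("metadata", "office_refit_who", "lab_refit_who",
                "metadata_morph", "dls", "dls_plus", "dls_plus_plus",
                "sbp140")


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort for unit tests."""
    return simulate_cohort(SimParams(n=800, seed=11))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full end-to-end run shared by the integration-level tests.

    Default study conditions (cohort size 12,000 at the default site
    weights gives ~6,000 train / ~2,600 tune / ~3,400 test), all in-scope
    survival models fitted.
    """
    cfg = RunConfig(seed=1, extractor={"max_epochs": 8},
                    feature_sets=ALL_COX_SETS,
                    comparisons=(("dls", "office_refit_who"),
                                 ("metadata", "office_refit_who"),
                                 ("dls", "metadata")))
    return run_pipeline(cfg)


def random_survival(rng, n, signal=1.0, cens_frac=0.4):
    """Simple exponential survival data generator for metric tests."""
    score = rng.normal(size=n)
    t = rng.exponential(np.exp(-signal * score))
    c = rng.uniform(0, np.quantile(t, 1 - cens_frac), n)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    return times, events, score
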