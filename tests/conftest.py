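import numpy as np
import pytest

from pni.config import CohortSpec, PreprocessConfig
from pni.synthetic_cohort import degrade_panel, generate_baseline, generate_trajectories


def small_spec(seed: int = 7, **kw) -> CohortSpec:
    defaults = dict(n_per_group=(10, 10, 10), n_timepoints=12, seed=seed,
                    missing_rate=0.08, outlier_rate=0.01)
    defaults.update(kw)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def spec():
    return small_spec()


@pytest.fixture(scope="session")
def clean_panel(spec):
    return generate_trajectories(generate_baseline(spec), spec)


@pytest.fixture(scope="session")
def degraded_panel(spec, clean_panel):
    return degrade_panel(clean_panel, spec)


@pytest.fixture(scope="session")
def default_panel():
    """Full-size cohort at the published conditions (no degradation)."""
    s = CohortSpec(seed=11, missing_rate=0.0, outlier_rate=0.0)
    return generate_trajectories(generate_baseline(s), s)


@pytest.fixture()
def preprocess_config():
    return PreprocessConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
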