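import numpy as np
import pandas as pd
import pytest

from breathdx import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with a strong planted effect: fast, clearly separable."""
    cfg = SyntheticConfig(n_malignant=40, n_benign=25, n_compounds=60,
                          n_planted=6, n_excluded=4, effect_size=0.8,
                          postop_fraction=0.5, seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Default-parameter cohort mirroring the emulated study's structure."""
    cfg = SyntheticConfig(seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_tiny_tables():
    """3 samples x 2 compounds toy with hand-checkable numbers."""
    from breathdx import PeakTable, SnrTable

    areas = pd.DataFrame([[100.0, 1000.0], [200.0, 500.0], [400.0, 2000.0]],
                         index=["s1", "s2", "s3"], columns=["c1", "c2"])
    snr = pd.DataFrame(50.0, index=areas.index, columns=areas.columns)
    return PeakTable(areas.copy()), SnrTable(snr)
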