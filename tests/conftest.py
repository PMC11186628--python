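import numpy as np
import pytest

from otmatch.io import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(p=10, n=30, seed=0, mz_spacing=1.0):
    """Small feature table with well-separated m/z and random intensities."""
    r = np.random.default_rng(seed)
    return FeatureTable(
        feature_ids=tuple(f"f{i}" for i in range(p)),
        mz=100.0 + mz_spacing * np.arange(p),
        rt=np.sort(r.uniform(0.5, 12.0, p)),
        intensities=r.normal(size=(p, n)),
        sample_ids=tuple(f"s{j}" for j in range(n)),
    )


@pytest.fixture
def toy_table():
    return make_table()
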