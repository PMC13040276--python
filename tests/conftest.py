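import numpy as np
import pandas as pd
import pytest

from embryoeval import uniform_profile
from embryoeval.stages import ALL_CODES


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_table():
    """Hand-built 8-frame table: reference plus two raters, one perfect."""
    ref = [1, 2, 3, 4, 5, 6, 7, 4]
    noisy = [1, 3, 3, 4, 5, 6, 7, 3]  # two adjacent-stage errors
    return pd.DataFrame(
        {
            "embryo_id": [f"e{i % 3}" for i in range(8)],
            "frame_id": [f"f{i}" for i in range(8)],
            "reference": ref,
            "perfect": ref,
            "noisy": noisy,
        }
    )


def random_rating_table(rng, n_frames, rater_names, k=7):
    """Uniformly random labels; for oracle-equivalence sweeps."""
    data = {
        "embryo_id": [f"e{i}" for i in range(n_frames)],
        "frame_id": [f"f{i}" for i in range(n_frames)],
        "reference": rng.integers(1, k + 1, n_frames),
    }
    for r in rater_names:
        data[r] = rng.integers(1, k + 1, n_frames)
    return pd.DataFrame(data)


@pytest.fixture
def profile_pair():
    return uniform_profile("a", 0.8, 0.25), uniform_profile("b", 0.7, 0.4)
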