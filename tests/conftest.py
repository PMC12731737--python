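import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from entroseg import FixtureSpec, GrayImage, Histogram, make_bimodal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bimodal_fixture():
    """The standard well-separated bimodal test image with ground truth."""
    return make_bimodal(FixtureSpec(seed=42))


@pytest.fixture
def narrow_bimodal_fixture():
    """Bimodal image with tight modes: class entropies stay inside the
    Masi domain even at r = 1.5, so the Masi-sum criterion is solvable."""
    return make_bimodal(FixtureSpec(seed=42, bg_std=1.5, fg_std=1.5))


def histogram_from_counts(counts) -> Histogram:
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    return Histogram(counts=counts, probs=counts / total, total_pixels=total,
                     max_level=len(counts) - 1)
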