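from datetime import datetime

import numpy as np
import pytest

from rhythmkit import EpochSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def make_series(values, epoch_length=3600, start=datetime(2024, 1, 1), mask=None):
    return EpochSeries(start, epoch_length, np.asarray(values, dtype=float), mask)


@pytest.fixture
def series_factory():
    return make_series
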