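from datetime import date, datetime, timezone

import numpy as np
import pytest

from disorient import DailyPolaritySeries, PostRecord


def make_record(post_id="p1", day=1, label="F", retweets=0, likes=0, hour=12):
    return PostRecord(
        post_id=post_id,
        timestamp=datetime(2018, 1, day, hour, tzinfo=timezone.utc),
        label=label,
        n_retweets=retweets,
        n_likes=likes,
    )


@pytest.fixture
def small_series():
    """Five consecutive days with simple hand-checkable counts."""
    counts = np.array([
        [7, 2, 1],
        [0, 0, 0],   # empty day carried as zeros
        [5, 3, 2],
        [6, 2, 2],
        [8, 1, 1],
    ])
    return DailyPolaritySeries.from_arrays(date(2018, 1, 1), counts)


@pytest.fixture
def constant_series():
    """High-volume series with identical proportions every day."""
    counts = np.tile(np.array([[140, 33, 27]]), (30, 1))
    return DailyPolaritySeries.from_arrays(date(2018, 1, 1), counts)


@pytest.fixture
def noisy_series():
    """Sixty days of pure multinomial noise around a fixed opinion split."""
    rng = np.random.default_rng(2018)
    counts = rng.multinomial(200, [0.70, 0.164, 0.136], size=60)
    return DailyPolaritySeries.from_arrays(date(2018, 1, 1), counts)
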