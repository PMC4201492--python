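import numpy as np
import pytest

import moodcourse as mc


@pytest.fixture(scope="session")
def low_risk():
    return mc.get_preset("low_risk")


@pytest.fixture(scope="session")
def high_risk():
    return mc.get_preset("high_risk")


@pytest.fixture(scope="session")
def single_population():
    return mc.get_preset("single_population")


def random_run_spec(rng: np.random.Generator):
    """Random alternating run-length sequence exercising the 14 d / 180 d rules."""
    n_runs = int(rng.integers(1, 25))
    lengths = []
    for _ in range(n_runs):
        kind = rng.random()
        if kind < 0.5:
            lengths.append(int(rng.integers(1, 30)))    # around the 14 d threshold
        elif kind < 0.8:
            lengths.append(int(rng.integers(30, 200)))  # around the 180 d span
        else:
            lengths.append(int(rng.integers(200, 401)))
    start_neg = bool(rng.integers(2))
    return [
        ("neg" if (i % 2 == 0) == start_neg else "pos", length)
        for i, length in enumerate(lengths)
    ]


def expand_labels(annotation):
    """Per-day label strings from an interval annotation."""
    labels = [""] * annotation.total_days
    for iv in annotation.intervals:
        for day in range(iv.start_day, iv.end_day):
            labels[day] = iv.label.value
    return labels
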