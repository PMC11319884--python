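import numpy as np
import pytest

from inrkit import DEFAULT_TARGET_RANGES, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def all_ranges():
    """The five built-in indication target ranges."""
    return list(DEFAULT_TARGET_RANGES.values())


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured two-arm cohort, shared across tests."""
    config = SimulationConfig(n_per_arm={"non_web": 60, "web": 60}, seed=20240901)
    return simulate_cohort(config)


def ttr_discretization_oracle(points, target, n_steps=10_000):
    """Independent TTR oracle: per-segment midpoint discretization.

    Each consecutive segment is cut into ``n_steps`` equal time slices; the
    midpoint INR of each slice is classified against the range and the slice
    durations accumulated.  Returns (below, in, above) in days.
    """
    below = inside = above = 0.0
    for (t1, i1), (t2, i2) in zip(points, points[1:]):
        duration = t2 - t1
        if duration == 0:
            continue
        mids = (np.arange(n_steps) + 0.5) / n_steps
        inr = i1 + (i2 - i1) * mids
        dt = duration / n_steps
        below += dt * np.count_nonzero(inr < target.lower)
        above += dt * np.count_nonzero(inr > target.upper)
        inside += dt * np.count_nonzero((inr >= target.lower) & (inr <= target.upper))
    return below, inside, above
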