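import numpy as np
import pytest

from vinephen.fitting import AnnealSchedule
from vinephen.thermal import DailyTemperatureSeries


def constant_series(mean, n_days=60, start=1, half_range=5.0, year=None):
    """A flat temperature series: every day at `mean` deg C."""
    days = np.arange(start, start + n_days)
    t = np.full(n_days, float(mean))
    return DailyTemperatureSeries(days, t - half_range, t, t + half_range, year=year)


def random_series(rng, n_days=240, start=-121, mean=12.0, spread=8.0):
    """A rough random-walk temperature series for oracle comparisons."""
    days = np.arange(start, start + n_days)
    t = mean + np.cumsum(rng.normal(0, 1.2, n_days)) * 0.3 + rng.normal(0, 2.0, n_days)
    return DailyTemperatureSeries(days, t - 4.0, t, t + 4.0)


@pytest.fixture
def make_constant_series():
    return constant_series


@pytest.fixture
def make_random_series():
    return random_series


@pytest.fixture
def quick_schedule():
    """Light annealing settings for structural tests."""
    return AnnealSchedule(steps_per_temp=60, n_temps=20, n_starts=3)


def profiled_grid_loss(dataset, t0, tb):
    """Independent profiled-SSres evaluation by plain Python loops.

    Mirrors the calibration objective (GDD rates, F* profiled over the
    minimum and mean event-day accumulations) without touching any of the
    library's vectorised code paths.
    """
    at_obs = []
    cums = []
    for vy in dataset:
        total, curve = 0.0, []
        for day, x in zip(vy.series.day_index, vy.series.t_mean):
            if day < t0:
                continue
            total += max(0.0, x - tb)
            curve.append((int(day), total))
        cums.append(curve)
        reached = [c for d, c in curve if d <= vy.observed_day]
        at_obs.append(reached[-1] if reached else 0.0)
    included = [a for a in at_obs if a > 0]
    if not included:
        return float("inf")
    best = float("inf")
    for f in (min(included), sum(included) / len(included)):
        loss = 0.0
        for vy, curve in zip(dataset, cums):
            pred = next((d for d, c in curve if c >= f), vy.series.end)
            loss += (pred - vy.observed_day) ** 2
        best = min(best, loss)
    return best
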