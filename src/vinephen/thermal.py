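"""Daily thermal-forcing models and the accumulation rule for phenophase timing.

Three daily rate-of-forcing functions are provided:

* growing degree-days (GDD): linear excess of the daily mean temperature
  over a base temperature ``Tb``;
* a triangular response bounded by cardinal temperatures
  (``Tmin_c < Topt < Tmax_c``), returning values in [0, 1];
* the UniFORC sigmoid, ``1 / (1 + exp(d * (x - e)))`` for ``x >= 0`` with
  sharpness ``d < 0`` and mid-response temperature ``e > 0``, in (0, 1).

Daily rates are summed from a start day ``t0`` (inclusive); the phenophase
is predicted on the first day on which the cumulative forcing reaches the
critical threshold ``F*``.

The day coordinate is an integer index with 1 = Jan 1 of the event year;
days of the previous calendar year take indices <= 0 (Sep 1 = -121, always,
since Sep 1 to Dec 31 spans 122 days regardless of leap years).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

__all__ = [
    "ParameterError",
    "CoverageError",
    "DailyTemperatureSeries",
    "GDDParams",
    "TriangularParams",
    "UniFORCParams",
    "PredictedEvent",
    "rf_gdd",
    "rf_triangular",
    "rf_uniforc",
    "accumulate_forcing",
    "predict_event",
    "day_index_to_date",
    "date_to_day_index",
]


class ParameterError(ValueError):
    """A model parameter violates its domain (e.g. unordered cardinals, d >= 0)."""


class CoverageError(ValueError):
    """The temperature series does not cover the requested day window."""


def day_index_to_date(year: int, day: int) -> _dt.date:
    """Calendar date for an integer day index (1 = Jan 1 of ``year``)."""
    return _dt.date(year, 1, 1) + _dt.timedelta(days=day - 1)


def date_to_day_index(year: int, date: _dt.date) -> int:
    """Integer day index of ``date`` on the axis anchored at Jan 1 of ``year``."""
    return (date - _dt.date(year, 1, 1)).days + 1


@dataclass(frozen=True)
class DailyTemperatureSeries:
    """Contiguous daily Tmin/Tmean/Tmax driving forcing accumulation.

    Parameters
    ----------
    day_index
        Strictly consecutive integer day coordinates (no gaps).
    t_min, t_mean, t_max
        Daily temperatures in deg C, with ``t_min <= t_mean <= t_max``.
    year
        Event (calendar) year anchoring day index 1, if known.
    """

    day_index: np.ndarray
    t_min: np.ndarray
    t_mean: np.ndarray
    t_max: np.ndarray
    year: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "day_index", np.asarray(self.day_index, dtype=np.int64))
        for name in ("t_min", "t_mean", "t_max"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.day_index.size
        if n == 0:
            raise ValueError("temperature series is empty")
        if any(getattr(self, a).shape != (n,) for a in ("t_min", "t_mean", "t_max")):
            raise ValueError("day_index and temperature arrays must share one length")
        if n > 1 and not np.all(np.diff(self.day_index) == 1):
            gaps = self.day_index[:-1][np.diff(self.day_index) != 1]
            raise ValueError(f"day indices must be strictly consecutive; gap after day {gaps[0]}")
        if np.any(self.t_min > self.t_mean) or np.any(self.t_mean > self.t_max):
            bad = self.day_index[(self.t_min > self.t_mean) | (self.t_mean > self.t_max)][0]
            raise ValueError(f"t_min <= t_mean <= t_max violated on day {bad}")

    @property
    def start(self) -> int:
        return int(self.day_index[0])

    @property
    def end(self) -> int:
        return int(self.day_index[-1])

    def covers(self, day: int) -> bool:
        return self.start <= day <= self.end

    def index_of(self, day: int) -> int:
        if not self.covers(day):
            raise CoverageError(f"day {day} outside series [{self.start}, {self.end}]")
        return int(day - self.start)

    def window(self, first: int, last: int) -> "DailyTemperatureSeries":
        """Sub-series covering [first, last] inclusive."""
        i, j = self.index_of(first), self.index_of(last)
        return DailyTemperatureSeries(
            self.day_index[i : j + 1],
            self.t_min[i : j + 1],
            self.t_mean[i : j + 1],
            self.t_max[i : j + 1],
            year=self.year,
        )


ArrayLike = Union[float, np.ndarray]


def rf_gdd(x_t: ArrayLike, tb: float) -> ArrayLike:
    """Growing degree-days rate: ``max(0, x_t - Tb)``."""
    return np.maximum(0.0, np.asarray(x_t, dtype=np.float64) - tb)[()]


def rf_triangular(x_t: ArrayLike, tmin_c: float, topt: float, tmax_c: float) -> ArrayLike:
    """Triangular forcing in [0, 1] over cardinal temperatures.

    Zero at or below ``Tmin_c`` and at or above ``Tmax_c``; rises linearly
    to 1 at ``Topt`` and falls linearly back to 0 at ``Tmax_c``.
    """
    if not (tmin_c < topt < tmax_c):
        raise ParameterError(
            f"cardinal temperatures must satisfy Tmin < Topt < Tmax, got "
            f"({tmin_c}, {topt}, {tmax_c})"
        )
    x = np.asarray(x_t, dtype=np.float64)
    rising = (x - tmin_c) / (topt - tmin_c)
    falling = (x - tmax_c) / (topt - tmax_c)
    out = np.where(x <= topt, rising, falling)
    out = np.where((x <= tmin_c) | (x >= tmax_c), 0.0, out)
    return out[()]


def rf_uniforc(x_t: ArrayLike, d: float, e: float) -> ArrayLike:
    """UniFORC sigmoid forcing ``1 / (1 + exp(d * (x - e)))`` for x >= 0, else 0.

    ``d < 0`` makes the response increase with temperature; ``e`` is the
    temperature of half-maximal response. Days colder than 0 deg C
    contribute nothing (a hard cutoff of the published form).
    """
    if d >= 0:
        raise ParameterError(f"sharpness d must be < 0, got {d}")
    if e <= 0:
        raise ParameterError(f"mid-response temperature e must be > 0, got {e}")
    from scipy.special import expit

    x = np.asarray(x_t, dtype=np.float64)
    out = expit(-d * (x - e))  # overflow-safe 1 / (1 + exp(d (x - e)))
    out = np.where(x < 0.0, 0.0, out)
    return out[()]


@dataclass(frozen=True)
class GDDParams:
    """GDD model: start day ``t0``, base temperature ``Tb``, threshold ``F*`` (degree-days)."""

    t0: int
    tb: float
    fstar: float

    model_type = "gdd"
    free_names = ("t0", "tb")

    def __post_init__(self) -> None:
        if self.fstar <= 0:
            raise ParameterError(f"Fstar must be > 0, got {self.fstar}")

    def rate(self, x_t: ArrayLike) -> ArrayLike:
        return rf_gdd(x_t, self.tb)


@dataclass(frozen=True)
class TriangularParams:
    """Triangular model: ``t0``, cardinal temperatures, threshold ``F*`` (forcing units)."""

    t0: int
    tmin_c: float
    topt: float
    tmax_c: float
    fstar: float

    model_type = "triangular"
    free_names = ("t0", "tmin_c", "topt", "tmax_c")

    def __post_init__(self) -> None:
        if not (self.tmin_c < self.topt < self.tmax_c):
            raise ParameterError(
                f"cardinal ordering Tmin < Topt < Tmax violated: "
                f"({self.tmin_c}, {self.topt}, {self.tmax_c})"
            )
        if self.fstar <= 0:
            raise ParameterError(f"Fstar must be > 0, got {self.fstar}")

    def rate(self, x_t: ArrayLike) -> ArrayLike:
        return rf_triangular(x_t, self.tmin_c, self.topt, self.tmax_c)


@dataclass(frozen=True)
class UniFORCParams:
    """UniFORC model: ``t0``, sharpness ``d`` (< 0), mid-response ``e`` (> 0), ``F*``."""

    t0: int
    d: float
    e: float
    fstar: float

    model_type = "uniforc"
    free_names = ("t0", "d", "e")

    def __post_init__(self) -> None:
        if self.d >= 0:
            raise ParameterError(f"d must be < 0, got {self.d}")
        if self.e <= 0:
            raise ParameterError(f"e must be > 0, got {self.e}")
        if self.fstar <= 0:
            raise ParameterError(f"Fstar must be > 0, got {self.fstar}")

    def rate(self, x_t: ArrayLike) -> ArrayLike:
        return rf_uniforc(x_t, self.d, self.e)


ModelParams = Union[GDDParams, TriangularParams, UniFORCParams]


@dataclass(frozen=True)
class PredictedEvent:
    """Predicted phenophase day and the forcing accumulated by that day."""

    day: int
    forcing: float


def accumulate_forcing(
    series: DailyTemperatureSeries,
    t0: int,
    rate: Callable[[np.ndarray], np.ndarray],
    until: int,
) -> np.ndarray:
    """Cumulative forcing from day ``t0`` (inclusive) through day ``until``.

    ``rate`` maps daily mean temperature to a nonnegative daily forcing;
    element ``k`` of the result is the forcing summed over days
    ``t0 .. t0 + k``.
    """
    if until < t0:
        raise ValueError(f"until={until} precedes t0={t0}")
    if not (series.covers(t0) and series.covers(until)):
        raise CoverageError(
            f"series [{series.start}, {series.end}] does not cover [{t0}, {until}]"
        )
    x = series.t_mean[series.index_of(t0) : series.index_of(until) + 1]
    return np.cumsum(rate(x))


def predict_event(
    series: DailyTemperatureSeries, params: ModelParams
) -> Optional[PredictedEvent]:
    """First day whose cumulative forcing from ``params.t0`` reaches ``F*``.

    Returns ``None`` if the threshold is never reached within the series
    (the explicit no-event signal, as opposed to an exception for
    malformed input).
    """
    if not series.covers(params.t0):
        raise CoverageError(
            f"t0={params.t0} outside series [{series.start}, {series.end}]"
        )
    cum = accumulate_forcing(series, params.t0, params.rate, series.end)
    hit = np.searchsorted(cum, params.fstar, side="left")
    # cumsum is nondecreasing (rates >= 0), so searchsorted finds the first
    # index with cum >= fstar; == size means the threshold was never reached.
    if hit == cum.size:
        return None
    return PredictedEvent(day=int(params.t0 + hit), forcing=float(cum[hit]))
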