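"""Goodness-of-fit metrics for predicted vs observed phenophase dates.

Model selection and validation use three metrics: modelling efficiency
(EFF, the Nash-Sutcliffe form ``1 - SSres/SStot``; 1 = perfect, <= 0 = no
better than the observed mean), the root mean square error (RMSE, days)
and the mean absolute deviation (MAD, days). Bias is summarised by a
linear regression through the origin of predicted on observed dates
(slope b0 near 1 = unbiased), and prediction quality by the frequency of
absolute day differences in the classes [0-3], (3-6] and > 6 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedEfficiencyError",
    "FitMetrics",
    "OriginRegression",
    "DifferenceClassTable",
    "efficiency",
    "rmse",
    "mad",
    "compute_metrics",
    "regression_through_origin",
    "difference_classes",
]


class UndefinedEfficiencyError(ValueError):
    """EFF is undefined: fewer than two observations or zero observed variance."""


@dataclass(frozen=True)
class FitMetrics:
    """EFF, RMSE (days), MAD (days) and the number of variety-years used."""

    eff: float
    rmse: float
    mad: float
    n: int


@dataclass(frozen=True)
class OriginRegression:
    """Zero-intercept slope of predicted on observed with its 95% CI."""

    b0: float
    ci95: Tuple[float, float]


@dataclass(frozen=True)
class DifferenceClassTable:
    """Percentages of cases with |pred - obs| in [0,3], (3,6] and (6, inf) days."""

    pct_0_3: float
    pct_3_6: float
    pct_over_6: float

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.pct_0_3, self.pct_3_6, self.pct_over_6)


def _paired(observed: Sequence[float], predicted: Sequence[float], min_n: int):
    obs = np.asarray(observed, dtype=np.float64)
    pred = np.asarray(predicted, dtype=np.float64)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    if obs.size < min_n:
        raise ValueError(f"need at least {min_n} paired values, got {obs.size}")
    return obs, pred


def efficiency(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Modelling efficiency EFF = (SStot - SSres) / SStot = 1 - SSres/SStot.

    SStot is the sum of squared deviations of the observations from their
    mean; SSres the sum of squared residuals. Negative values pass through
    unclamped (a bad model is worse than predicting the mean); zero
    observed variance raises :class:`UndefinedEfficiencyError`.
    """
    obs, pred = _paired(observed, predicted, min_n=2)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedEfficiencyError("all observed values identical: SStot = 0")
    ss_res = float(np.sum((obs - pred) ** 2))
    return (ss_tot - ss_res) / ss_tot


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error sqrt(SSres / n), in days."""
    obs, pred = _paired(observed, predicted, min_n=1)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mad(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute deviation of predictions from observations, in days."""
    obs, pred = _paired(observed, predicted, min_n=1)
    return float(np.mean(np.abs(obs - pred)))


def compute_metrics(observed: Sequence[float], predicted: Sequence[float]) -> FitMetrics:
    """EFF, RMSE and MAD on one set of paired dates."""
    obs, _ = _paired(observed, predicted, min_n=2)
    return FitMetrics(
        eff=efficiency(observed, predicted),
        rmse=rmse(observed, predicted),
        mad=mad(observed, predicted),
        n=int(obs.size),
    )


def regression_through_origin(
    observed: Sequence[float], predicted: Sequence[float]
) -> OriginRegression:
    """Slope of the zero-intercept regression of predicted on observed.

    b0 = sum(pred * obs) / sum(obs^2); the 95% CI uses the zero-intercept
    model's residual variance on n - 1 degrees of freedom.
    """
    obs, pred = _paired(observed, predicted, min_n=2)
    sxx = float(np.sum(obs**2))
    if sxx == 0.0:
        raise ValueError("all observed values are zero; slope undefined")
    b0 = float(np.sum(pred * obs)) / sxx
    n = obs.size
    resid = pred - b0 * obs
    s2 = float(np.sum(resid**2)) / (n - 1)
    se = np.sqrt(s2 / sxx)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    return OriginRegression(b0=b0, ci95=(b0 - tcrit * se, b0 + tcrit * se))


def difference_classes(
    observed: Sequence[float], predicted: Sequence[float]
) -> DifferenceClassTable:
    """Percentage of cases with |pred - obs| in [0,3], (3,6] and > 6 days.

    Boundaries are allocated closed-right: a 3-day difference falls in the
    first class and a 6-day difference in the second.
    """
    obs, pred = _paired(observed, predicted, min_n=1)
    diff = np.abs(pred - obs)
    n = diff.size
    c1 = int(np.sum(diff <= 3))
    c2 = int(np.sum((diff > 3) & (diff <= 6)))
    c3 = n - c1 - c2
    return DifferenceClassTable(
        pct_0_3=100.0 * c1 / n,
        pct_3_6=100.0 * c2 / n,
        pct_over_6=100.0 * c3 / n,
    )
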