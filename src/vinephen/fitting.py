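"""Parameter estimation and the multistep calibration / validation workflow.

Calibration minimises the residual sum of squares (SSres) between observed
and predicted phenophase days with a Metropolis simulated-annealing search
over the model's threshold parameters (start day ``t0`` plus ``Tb``, the
cardinal temperatures, or ``d``/``e``). The critical forcing ``F*`` is not
annealed jointly: for any candidate threshold set it is profiled out as the
mean accumulated forcing at the observed event days, which is exact for
noiseless data and reduces the search dimension by one.

The workflow mirrors a multistep parameterisation: compare accumulation
start windows (Sep 1 of the previous year vs Jan 1 of the event year),
calibrate each variety independently, externally validate each fitted model
on every other variety's data with frozen parameters, and finally fit a
single pooled (global) model across varieties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluation import FitMetrics, compute_metrics
from .thermal import (
    CoverageError,
    DailyTemperatureSeries,
    GDDParams,
    ModelParams,
    TriangularParams,
    UniFORCParams,
    predict_event,
)

__all__ = [
    "ConfigError",
    "VarietyYear",
    "ParamSpace",
    "AnnealSchedule",
    "FitResult",
    "StartWindowComparison",
    "ValidationMatrix",
    "MultistepReport",
    "make_params",
    "assemble_dataset",
    "predict_dataset",
    "objective",
    "estimate_fstar",
    "anneal",
    "compare_start_windows",
    "calibrate_per_variety",
    "external_validate",
    "build_validation_matrix",
    "fit_global",
    "select_model",
    "run_multistep",
]


class ConfigError(ValueError):
    """Invalid search-space or schedule configuration."""


@dataclass(frozen=True)
class VarietyYear:
    """One variety-year: its driving temperature series and observed event day."""

    variety: str
    year: int
    series: DailyTemperatureSeries
    observed_day: int


Dataset = Sequence[VarietyYear]

# free (annealed) parameter names per model family; F* is profiled out
_FREE_NAMES: Dict[str, Tuple[str, ...]] = {
    "gdd": ("t0", "tb"),
    "triangular": ("t0", "tmin_c", "topt", "tmax_c"),
    "uniforc": ("t0", "d", "e"),
}

# parameter count including F*, used by the simplicity rule
_COMPLEXITY = {"gdd": 3, "uniforc": 4, "triangular": 5}

_DEFAULT_BOUNDS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "gdd": {"t0": (-122, 150), "tb": (0.0, 30.0)},
    "triangular": {
        "t0": (-122, 150),
        "tmin_c": (0.0, 15.0),
        "topt": (5.0, 30.0),
        "tmax_c": (15.0, 50.0),
    },
    "uniforc": {"t0": (-122, 150), "d": (-40.0, -0.01), "e": (5.0, 25.0)},
}


def make_params(model_type: str, values: Mapping[str, float], fstar: float) -> ModelParams:
    """Build the parameter object for ``model_type`` from a name->value mapping."""
    if model_type == "gdd":
        return GDDParams(t0=int(values["t0"]), tb=float(values["tb"]), fstar=fstar)
    if model_type == "triangular":
        return TriangularParams(
            t0=int(values["t0"]),
            tmin_c=float(values["tmin_c"]),
            topt=float(values["topt"]),
            tmax_c=float(values["tmax_c"]),
            fstar=fstar,
        )
    if model_type == "uniforc":
        return UniFORCParams(
            t0=int(values["t0"]), d=float(values["d"]), e=float(values["e"]), fstar=fstar
        )
    raise ConfigError(f"unknown model type {model_type!r}")


@dataclass(frozen=True)
class ParamSpace:
    """Per-parameter bounds and optional step granularity for the search.

    ``steps[name]`` of ``None`` means a continuous parameter; a positive
    step snaps proposals to that grid (``t0`` always uses step 1).
    """

    model_type: str
    bounds: Mapping[str, Tuple[float, float]]
    steps: Mapping[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_type not in _FREE_NAMES:
            raise ConfigError(f"unknown model type {self.model_type!r}")
        names = _FREE_NAMES[self.model_type]
        missing = [n for n in names if n not in self.bounds]
        if missing:
            raise ConfigError(f"bounds missing for parameters {missing}")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ConfigError(f"empty range for {name}: lower {lo} > upper {hi}")

    @classmethod
    def default(cls, model_type: str, **overrides: Tuple[float, float]) -> "ParamSpace":
        if model_type not in _DEFAULT_BOUNDS:
            raise ConfigError(f"unknown model type {model_type!r}")
        bounds = dict(_DEFAULT_BOUNDS[model_type])
        bounds.update(overrides)
        return cls(model_type=model_type, bounds=bounds)

    @property
    def free_names(self) -> Tuple[str, ...]:
        return _FREE_NAMES[self.model_type]

    def step_of(self, name: str) -> Optional[float]:
        if name == "t0":
            return float(self.steps.get("t0", 1) or 1)
        return self.steps.get(name)


@dataclass(frozen=True)
class AnnealSchedule:
    """Metropolis annealing settings (all overridable from run configs).

    Geometric cooling ``T_{k+1} = cooling * T_k`` over ``n_temps`` levels
    with ``steps_per_temp`` single-parameter proposals per level. The
    initial temperature is set from a short warm-up so that the starting
    acceptance rate is roughly ``initial_acceptance``. ``n_starts``
    independent restarts are run; restarts whose loss lies within
    ``loss_band`` (fractional) of the best define the reported
    per-parameter (max; min) ranges.
    """

    cooling: float = 0.95
    steps_per_temp: int = 200
    n_temps: int = 30
    n_starts: int = 10
    initial_acceptance: float = 0.8
    t0_proposal_sd: float = 2.0
    continuous_proposal_sd: float = 1.0
    loss_band: float = 0.05


@dataclass(frozen=True)
class FitResult:
    """Fitted model with metrics, predictions and multi-start ranges.

    ``param_ranges`` maps each parameter (including ``fstar``) to its
    (max, min) over the restarts whose loss fell within the loss band of
    the best; ``metric_ranges`` does the same for EFF and RMSE. ``sum_heat``
    is the accumulated forcing at the fitted threshold, i.e. ``F*``.
    """

    model_type: str
    params: ModelParams
    loss: float
    metrics: FitMetrics
    predictions: pd.DataFrame
    param_ranges: Dict[str, Tuple[float, float]]
    metric_ranges: Dict[str, Tuple[float, float]]
    n_starts: int
    seed: int

    @property
    def sum_heat(self) -> float:
        return self.params.fstar


def assemble_dataset(
    observations: Iterable,
    meteorology: Mapping[int, DailyTemperatureSeries],
    phenophase: str,
) -> list:
    """Join phenology records (``bbch == phenophase``) with their year's series."""
    out = []
    for rec in observations:
        if rec.bbch != phenophase:
            continue
        if rec.year not in meteorology:
            raise CoverageError(f"no meteorology for year {rec.year} ({rec.variety})")
        out.append(
            VarietyYear(
                variety=rec.variety,
                year=rec.year,
                series=meteorology[rec.year],
                observed_day=int(rec.doy),
            )
        )
    return out


# ---------------------------------------------------------------------------
# objective and F* profiling


def predict_dataset(params: ModelParams, dataset: Dataset) -> pd.DataFrame:
    """Predicted event day per variety-year under frozen ``params``.

    A variety-year whose forcing never reaches ``F*`` is assigned the last
    day of its series (the documented finite no-event penalty).
    """
    rows = []
    for vy in dataset:
        ev = predict_event(vy.series, params)
        pred = ev.day if ev is not None else vy.series.end
        rows.append((vy.variety, vy.year, vy.observed_day, pred))
    return pd.DataFrame(rows, columns=["variety", "year", "observed", "predicted"])


def objective(params: ModelParams, dataset: Dataset) -> float:
    """SSres of predicted vs observed event days (lower is better).

    Minimising SSres simultaneously maximises EFF and minimises RMSE, so a
    single criterion drives all the selection metrics.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    df = predict_dataset(params, dataset)
    resid = df["predicted"].to_numpy(dtype=float) - df["observed"].to_numpy(dtype=float)
    return float(np.sum(resid**2))


def estimate_fstar(params: ModelParams, dataset: Dataset) -> float:
    """Profile ``F*``: mean accumulated forcing at the observed event days.

    ``params.fstar`` is ignored; only ``t0`` and the threshold parameters
    matter. A variety-year with zero forcing accumulated by its observed
    day is excluded with a warning; if every year is excluded this raises.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    sums = []
    for vy in dataset:
        s = vy.series
        if params.t0 > vy.observed_day or not s.covers(params.t0):
            cum = 0.0
        else:
            x = s.t_mean[s.index_of(params.t0) : s.index_of(vy.observed_day) + 1]
            cum = float(np.sum(params.rate(x)))
        if cum <= 0.0:
            warnings.warn(
                f"zero forcing by the observed day for {vy.variety} {vy.year}; "
                "excluded from the F* estimate",
                stacklevel=2,
            )
            continue
        sums.append(cum)
    if not sums:
        raise ValueError("no variety-year accumulates positive forcing; F* undefined")
    return float(np.mean(sums))


class _Stacked:
    """Dataset stacked onto a common day grid for fast repeated evaluation."""

    def __init__(self, dataset: Dataset):
        if len(dataset) < 2:
            raise ValueError("need at least 2 variety-years to fit")
        self.start = max(vy.series.start for vy in dataset)
        self.end = min(vy.series.end for vy in dataset)
        if self.end < self.start:
            raise CoverageError("variety-year series share no common day window")
        rows = []
        obs = []
        for vy in dataset:
            w = vy.series.window(self.start, self.end)
            rows.append(w.t_mean)
            if not (self.start <= vy.observed_day <= self.end):
                raise CoverageError(
                    f"observed day {vy.observed_day} of {vy.variety} {vy.year} "
                    f"outside the common window [{self.start}, {self.end}]"
                )
            obs.append(vy.observed_day)
        self.tmean = np.vstack(rows)
        self.obs = np.asarray(obs, dtype=np.int64)
        self.obs_col = self.obs - self.start
        # worst plausible loss: every prediction at the window edge
        self.penalty = float(np.sum((self.end - self.obs.astype(float)) ** 2))
        self._rates_key: Optional[tuple] = None
        self._rates: Optional[np.ndarray] = None

    def _rate_matrix(self, model_type: str, values: Mapping[str, float]) -> np.ndarray:
        key = (model_type,) + tuple(
            float(values[n]) for n in _FREE_NAMES[model_type] if n != "t0"
        )
        if key == self._rates_key:
            return self._rates
        if model_type == "gdd":
            rates = np.maximum(0.0, self.tmean - values["tb"])
        elif model_type == "triangular":
            tmin_c, topt, tmax_c = values["tmin_c"], values["topt"], values["tmax_c"]
            x = self.tmean
            rates = np.where(
                x <= topt, (x - tmin_c) / (topt - tmin_c), (x - tmax_c) / (topt - tmax_c)
            )
            rates = np.where((x <= tmin_c) | (x >= tmax_c), 0.0, rates)
        elif model_type == "uniforc":
            from scipy.special import expit

            x = self.tmean
            rates = np.where(x < 0.0, 0.0, expit(-values["d"] * (x - values["e"])))
        else:  # pragma: no cover - guarded upstream
            raise ConfigError(f"unknown model type {model_type!r}")
        self._rates_key, self._rates = key, rates
        return rates

    def loss(self, model_type: str, values: Mapping[str, float]) -> Tuple[float, float]:
        """(SSres, profiled F*) for one threshold-parameter candidate."""
        t0 = int(values["t0"])
        if t0 < self.start or t0 > self.end:
            return self.penalty, math.nan
        rates = self._rate_matrix(model_type, values)
        c0 = t0 - self.start
        # slice-then-cumsum keeps the floats bitwise identical to the
        # per-series public path (accumulate_forcing from t0)
        cum = np.cumsum(rates[:, c0:], axis=1)
        rel_obs = self.obs_col - c0
        at_obs = np.where(rel_obs >= 0, cum[np.arange(cum.shape[0]), np.maximum(rel_obs, 0)], 0.0)
        included = at_obs > 0.0
        if not included.any():
            return self.penalty, math.nan
        # profile F*: two candidate thresholds — the smallest accumulation
        # reached at an observed event day and the mean accumulation — and
        # keep the SSres minimiser. The minimum hits the zero-loss interval
        # whenever one exists (any threshold between the latest pre-event
        # and the earliest event-day accumulation predicts every year
        # exactly); the mean is the natural noisy-data estimate. A richer
        # candidate set would let the search chase observation noise.
        inc = at_obs[included]
        cand = np.array([float(np.min(inc)), float(np.mean(inc))])
        n, m = cum.shape
        # rows of cum are sorted, so counting entries < f gives the first
        # crossing index for every (year, candidate) pair at once
        idx = np.sum(cum[:, :, None] < cand[None, None, :], axis=1)
        pred = t0 + idx.astype(float)
        pred[idx == m] = self.end
        losses = np.sum((pred - self.obs[:, None].astype(float)) ** 2, axis=0)
        best = losses.min()
        fstar = float(cand[losses == best].min())
        return float(best), fstar


# ---------------------------------------------------------------------------
# Metropolis simulated annealing


def _reflect(v: float, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    span = hi - lo
    # fold the real line onto [lo, hi] (triangle wave)
    v = (v - lo) % (2.0 * span)
    return lo + (span - abs(v - span))


def _initial_values(space: ParamSpace, rng: np.random.Generator) -> Dict[str, float]:
    for _ in range(200):
        vals: Dict[str, float] = {}
        for name in space.free_names:
            lo, hi = space.bounds[name]
            v = rng.uniform(lo, hi)
            step = space.step_of(name)
            if step:
                v = lo + round((v - lo) / step) * step
                v = min(max(v, lo), hi)
            vals[name] = v
        if space.model_type != "triangular" or (
            vals["tmin_c"] < vals["topt"] < vals["tmax_c"]
        ):
            return vals
    raise ConfigError("could not draw an ordered initial point from the bounds")


def _propose(
    space: ParamSpace,
    values: Dict[str, float],
    name: str,
    rng: np.random.Generator,
    schedule: AnnealSchedule,
) -> Optional[Dict[str, float]]:
    lo, hi = space.bounds[name]
    step = space.step_of(name)
    if step:
        sd = schedule.t0_proposal_sd if name == "t0" else max(schedule.continuous_proposal_sd, step)
        delta = round(rng.normal(0.0, sd) / step) * step
        if delta == 0:
            delta = step if rng.random() < 0.5 else -step
        v = _reflect(values[name] + delta, lo, hi)
        v = lo + round((v - lo) / step) * step
        v = min(max(v, lo), hi)
    else:
        v = _reflect(values[name] + rng.normal(0.0, schedule.continuous_proposal_sd), lo, hi)
    new = dict(values)
    new[name] = v
    if space.model_type == "triangular" and not (
        new["tmin_c"] < new["topt"] < new["tmax_c"]
    ):
        return None
    return new


def _chain(
    space: ParamSpace,
    stacked: _Stacked,
    rng: np.random.Generator,
    schedule: AnnealSchedule,
) -> Tuple[Dict[str, float], float]:
    values = _initial_values(space, rng)
    loss, _ = stacked.loss(space.model_type, values)
    best_values, best_loss = dict(values), loss

    # warm-up: size the initial temperature for ~initial_acceptance of uphill moves
    deltas = []
    for _ in range(40):
        name = space.free_names[rng.integers(len(space.free_names))]
        cand = _propose(space, values, name, rng, schedule)
        if cand is None:
            continue
        cl, _ = stacked.loss(space.model_type, cand)
        if cl > loss:
            deltas.append(cl - loss)
    t_init = (
        float(np.median(deltas)) / -math.log(schedule.initial_acceptance) if deltas else 1.0
    )
    t_init = max(t_init, 1e-9)

    temp = t_init
    for _ in range(schedule.n_temps):
        for _ in range(schedule.steps_per_temp):
            name = space.free_names[rng.integers(len(space.free_names))]
            cand = _propose(space, values, name, rng, schedule)
            if cand is None:
                continue
            cand_loss, _ = stacked.loss(space.model_type, cand)
            delta = cand_loss - loss
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                values, loss = cand, cand_loss
                if loss < best_loss:
                    best_values, best_loss = dict(values), loss
        temp *= schedule.cooling
    return best_values, best_loss


def _tiebreak_key(values: Mapping[str, float]) -> Tuple[float, ...]:
    # deterministic preference among equal-loss candidates: smallest Tb-like
    # threshold first, then earliest t0, then the remaining values
    tb_like = values.get("tb", values.get("tmin_c", values.get("e", 0.0)))
    rest = tuple(v for k, v in sorted(values.items()) if k not in ("t0",))
    return (float(tb_like), float(values["t0"])) + rest


def anneal(
    space: ParamSpace,
    dataset: Dataset,
    seed: int = 0,
    schedule: Optional[AnnealSchedule] = None,
) -> FitResult:
    """Multi-start Metropolis simulated annealing over ``space``.

    Reproducible for a fixed ``seed``: each restart draws from
    ``default_rng([seed, start_index])``. The best restart's parameters are
    refined into a :class:`FitResult`; restarts within the schedule's loss
    band populate the per-parameter (max; min) ranges.
    """
    schedule = schedule or AnnealSchedule()
    stacked = _Stacked(dataset)
    # t0 can only range over days the data actually cover
    t0_lo, t0_hi = space.bounds["t0"]
    eff_lo, eff_hi = max(t0_lo, stacked.start), min(t0_hi, stacked.end)
    if eff_lo > eff_hi:
        raise CoverageError(
            f"t0 bounds [{t0_lo}, {t0_hi}] do not intersect data coverage "
            f"[{stacked.start}, {stacked.end}]"
        )
    bounds = dict(space.bounds)
    bounds["t0"] = (eff_lo, eff_hi)
    space = ParamSpace(model_type=space.model_type, bounds=bounds, steps=dict(space.steps))

    runs = []
    for s in range(schedule.n_starts):
        rng = np.random.default_rng([seed, s])
        values, loss = _chain(space, stacked, rng, schedule)
        runs.append((values, loss))

    best_values, best_loss = min(runs, key=lambda r: (r[1],) + _tiebreak_key(r[0]))
    band = best_loss * (1.0 + schedule.loss_band) + 1e-9
    in_band = [r for r in runs if r[1] <= band]

    # final fit through the public per-series path (identical floats, but
    # carries per-year predictions and the fitted F*)
    _, fstar = stacked.loss(space.model_type, best_values)
    if math.isnan(fstar):
        raise ValueError(
            "no candidate accumulates positive forcing by the observed days; "
            "check the bounds against the data"
        )
    params = make_params(space.model_type, best_values, fstar)
    preds = predict_dataset(params, dataset)
    metrics = compute_metrics(preds["observed"], preds["predicted"])
    loss = float(np.sum((preds["predicted"] - preds["observed"]) ** 2))

    param_ranges: Dict[str, Tuple[float, float]] = {}
    effs, rmses, fstars = [], [], []
    for values, _ in in_band:
        _, f = stacked.loss(space.model_type, values)
        if math.isnan(f):
            continue
        p = make_params(space.model_type, values, f)
        d = predict_dataset(p, dataset)
        m = compute_metrics(d["observed"], d["predicted"])
        effs.append(m.eff)
        rmses.append(m.rmse)
        fstars.append(f)
        for name in space.free_names:
            cur = param_ranges.get(name)
            v = float(values[name])
            param_ranges[name] = (
                (v, v) if cur is None else (max(cur[0], v), min(cur[1], v))
            )
    param_ranges["fstar"] = (max(fstars), min(fstars))
    metric_ranges = {
        "eff": (max(effs), min(effs)),
        "rmse": (max(rmses), min(rmses)),
    }
    return FitResult(
        model_type=space.model_type,
        params=params,
        loss=loss,
        metrics=metrics,
        predictions=preds,
        param_ranges=param_ranges,
        metric_ranges=metric_ranges,
        n_starts=schedule.n_starts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# the multistep workflow


@dataclass(frozen=True)
class StartWindowComparison:
    """Fits under the Sep-1 and Jan-1 accumulation windows, and the choice."""

    jan: FitResult
    sep: FitResult
    selected: str  # "jan" | "sep"

    @property
    def selected_fit(self) -> FitResult:
        return self.jan if self.selected == "jan" else self.sep


def compare_start_windows(
    dataset: Dataset,
    model_type: str,
    seed: int = 0,
    schedule: Optional[AnnealSchedule] = None,
) -> StartWindowComparison:
    """Fit with t0 allowed from Sep 1 of the previous year vs from Jan 1.

    The window with the higher EFF wins; on a tie the Jan-1 window is kept
    as the simpler frame.
    """
    stacked_start = max(vy.series.start for vy in dataset)
    if stacked_start > -121:
        raise CoverageError(
            f"meteorology starts at day {stacked_start}; Sep 1 window needs day -121"
        )
    jan = anneal(
        ParamSpace.default(model_type, t0=(1, 150)), dataset, seed=seed, schedule=schedule
    )
    sep = anneal(
        ParamSpace.default(model_type, t0=(-121, 150)), dataset, seed=seed, schedule=schedule
    )
    selected = "sep" if sep.metrics.eff > jan.metrics.eff else "jan"
    return StartWindowComparison(jan=jan, sep=sep, selected=selected)


def _group_by_variety(dataset: Dataset) -> Dict[str, list]:
    groups: Dict[str, list] = {}
    for vy in dataset:
        groups.setdefault(vy.variety, []).append(vy)
    return groups


def calibrate_per_variety(
    all_data: Dataset,
    model_type: str,
    seed: int = 0,
    schedule: Optional[AnnealSchedule] = None,
    space: Optional[ParamSpace] = None,
) -> Dict[str, FitResult]:
    """Independently calibrate each variety's model (free thresholds).

    Varieties with fewer than two years are skipped with a warning. The
    same seed is used for every variety so identical datasets yield
    identical fits.
    """
    space = space or ParamSpace.default(model_type, t0=(1, 150))
    fits: Dict[str, FitResult] = {}
    for variety, data in _group_by_variety(all_data).items():
        if len(data) < 2:
            warnings.warn(
                f"variety {variety!r} has {len(data)} year(s); skipped", stacklevel=2
            )
            continue
        fits[variety] = anneal(space, data, seed=seed, schedule=schedule)
    return fits


def external_validate(donor: FitResult, recipient_dataset: Dataset) -> FitMetrics:
    """Metrics of the donor's frozen parameters on another variety's data."""
    preds = predict_dataset(donor.params, recipient_dataset)
    return compute_metrics(preds["observed"], preds["predicted"])


@dataclass(frozen=True)
class ValidationMatrix:
    """Cross-variety EFF/RMSE grids (rows: recipient dataset, cols: donor model).

    Diagonal cells hold each donor's own estimation metrics.
    """

    eff: pd.DataFrame
    rmse: pd.DataFrame
    donor_params: Dict[str, ModelParams]

    def best_donor(self) -> str:
        """Donor whose model transfers best: highest mean off-diagonal EFF."""
        scores = {}
        for donor in self.eff.columns:
            off = self.eff.loc[self.eff.index != donor, donor]
            scores[donor] = float(off.mean())
        return max(sorted(scores), key=lambda d: scores[d])


def build_validation_matrix(
    fits: Mapping[str, FitResult], datasets: Mapping[str, Dataset]
) -> ValidationMatrix:
    """Assemble the donor x recipient grid; diagonal = estimation metrics."""
    varieties = list(fits)
    eff = pd.DataFrame(index=varieties, columns=varieties, dtype=float)
    rmse = pd.DataFrame(index=varieties, columns=varieties, dtype=float)
    for donor, fit in fits.items():
        for recipient in varieties:
            m = fit.metrics if recipient == donor else external_validate(
                fit, datasets[recipient]
            )
            eff.loc[recipient, donor] = m.eff
            rmse.loc[recipient, donor] = m.rmse
    return ValidationMatrix(
        eff=eff, rmse=rmse, donor_params={v: f.params for v, f in fits.items()}
    )


def fit_global(
    all_data: Dataset,
    model_type: str,
    seed: int = 0,
    schedule: Optional[AnnealSchedule] = None,
    space: Optional[ParamSpace] = None,
) -> FitResult:
    """One parameter set fitted on the pooled multi-variety dataset."""
    space = space or ParamSpace.default(model_type, t0=(1, 150))
    return anneal(space, list(all_data), seed=seed, schedule=schedule)


def select_model(results: Mapping[str, FitResult], tol: float = 0.01) -> str:
    """Pick the model family: best EFF, but prefer simpler within ``tol``.

    Any family whose EFF is within ``tol`` of the best is a candidate; the
    one with the fewest parameters wins (GDD < UniFORC < Triangular).
    """
    if not results:
        raise ValueError("no fit results to select from")
    best_eff = max(r.metrics.eff for r in results.values())
    eligible = [m for m, r in results.items() if r.metrics.eff >= best_eff - tol]
    return min(eligible, key=lambda m: (_COMPLEXITY[m], m))


@dataclass(frozen=True)
class MultistepReport:
    """Everything the multistep procedure produces for one phenophase."""

    phenophase: str
    window: Optional[StartWindowComparison]
    per_variety: Dict[str, Dict[str, FitResult]]  # model_type -> variety -> fit
    selected_by_variety: Dict[str, str]
    validation: ValidationMatrix
    global_fit: FitResult

    def per_variety_table(self) -> pd.DataFrame:
        """Flat estimation table: one row per variety x model family."""
        rows = []
        for model_type, fits in self.per_variety.items():
            for variety, fit in fits.items():
                row = {
                    "variety": variety,
                    "model_type": model_type,
                    "eff": fit.metrics.eff,
                    "rmse": fit.metrics.rmse,
                    "mad": fit.metrics.mad,
                    "sum_heat": fit.sum_heat,
                    "n": fit.metrics.n,
                }
                for name in fit.params.free_names:
                    row[name] = getattr(fit.params, name)
                    mx, mn = fit.param_ranges[name]
                    row[f"{name}_max"], row[f"{name}_min"] = mx, mn
                rows.append(row)
        return pd.DataFrame(rows)


def run_multistep(
    dataset: Dataset,
    phenophase: str = "09",
    model_types: Sequence[str] = ("gdd", "triangular", "uniforc"),
    validation_model: str = "gdd",
    seed: int = 0,
    schedule: Optional[AnnealSchedule] = None,
    compare_windows: bool = True,
) -> MultistepReport:
    """The full multistep procedure on one phenophase's pooled dataset.

    1. optional Sep-1 vs Jan-1 start-window comparison on the pooled data;
    2. per-variety calibration for every requested model family;
    3. per-variety family selection (simplicity rule);
    4. cross-variety validation matrix for ``validation_model``;
    5. pooled global fit for ``validation_model``.
    """
    if validation_model not in model_types:
        raise ConfigError(
            f"validation model {validation_model!r} not among fitted families {model_types}"
        )
    window = None
    if compare_windows:
        window = compare_start_windows(dataset, model_types[0], seed=seed, schedule=schedule)
    per_variety = {
        m: calibrate_per_variety(dataset, m, seed=seed, schedule=schedule)
        for m in model_types
    }
    varieties = list(per_variety[validation_model])
    selected = {
        v: select_model({m: per_variety[m][v] for m in model_types if v in per_variety[m]})
        for v in varieties
    }
    groups = _group_by_variety(dataset)
    validation = build_validation_matrix(
        per_variety[validation_model], {v: groups[v] for v in varieties}
    )
    global_fit = fit_global(dataset, validation_model, seed=seed, schedule=schedule)
    return MultistepReport(
        phenophase=phenophase,
        window=window,
        per_variety=per_variety,
        selected_by_variety=selected,
        validation=validation,
        global_fit=global_fit,
    )
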