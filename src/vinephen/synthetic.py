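"""Synthetic meteorology and phenology emulating a temperate NW-Iberian vineyard.

The generator reproduces the statistical structure the calibration pipeline
assumes: a dozen seasons of daily temperatures from a single site, and for
each of four varieties one budburst (BBCH 09) and one flowering (BBCH 61)
event per season, produced by running a known ("truth") thermal model
forward and perturbing the resulting date with field-visit noise.

Daily mean temperature follows a seasonal sinusoid plus AR(1) residuals
(multi-day warm and cold spells; set ``ar1=0`` for white noise), with a
per-season mean shift for inter-annual variability; Tmin/Tmax are the mean
-/+ a diurnal half-range. Autocorrelated spells matter beyond realism:
episodes that dip below a base temperature are what make a forcing
threshold identifiable from event dates. The default scenario places
budburst around DOY 90-100 and flowering around DOY 145-160 under the
default variety truths.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .io import PhenologyObservation
from .thermal import (
    DailyTemperatureSeries,
    GDDParams,
    ModelParams,
    date_to_day_index,
    predict_event,
)

__all__ = [
    "ClimateScenario",
    "VarietyTruth",
    "default_scenario",
    "default_truths",
    "generate_temperature_series",
    "generate_observations",
    "write_manifest",
]

SEASON_START_DAY = -121  # Sep 1 of the previous year


@dataclass(frozen=True)
class ClimateScenario:
    """Parameters of the synthetic daily-temperature process.

    ``t_mean(day) = annual_mean + season_shift + amplitude *
    sin(2*pi*(day - phase_days)/365.25) + noise`` with the season shift
    drawn once per season from ``N(0, interannual_sd)``. ``phase_days=105``
    puts the warmest day in mid-July. ``ar1`` of 0 gives white day-to-day
    noise; in (0, 1) it gives an AR(1) process with the same marginal sd.
    """

    annual_mean: float = 13.3
    amplitude: float = 7.5
    phase_days: float = 105.0
    noise_sd: float = 3.0
    diurnal_half_range: float = 5.0
    interannual_sd: float = 1.0
    ar1: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.diurnal_half_range <= 0:
            raise ValueError("diurnal half-range must be > 0")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass(frozen=True)
class VarietyTruth:
    """Generating model and observation process for one synthetic variety.

    ``visit_interval_*`` of 0 records the exact event day; 3-7 snaps the
    (noisy) date forward to the next scheduled field visit, emulating
    discrete scouting every few days.
    """

    name: str
    budburst: ModelParams
    flowering: ModelParams
    noise_sd_days: float = 2.0
    visit_interval_budburst: int = 7
    visit_interval_flowering: int = 4

    def __post_init__(self) -> None:
        if self.noise_sd_days < 0:
            raise ValueError("observation noise sd must be >= 0")
        for iv in (self.visit_interval_budburst, self.visit_interval_flowering):
            if iv != 0 and not 3 <= iv <= 7:
                raise ValueError(f"visit interval must be 0 or in [3, 7], got {iv}")

    def params_for(self, bbch: str) -> ModelParams:
        return self.budburst if bbch == "09" else self.flowering

    def visit_interval_for(self, bbch: str) -> int:
        return self.visit_interval_budburst if bbch == "09" else self.visit_interval_flowering


def default_scenario(seed: int = 0, **overrides) -> ClimateScenario:
    """Temperate, warm, sub-humid site with cold nights (NW-Iberian profile)."""
    return ClimateScenario(seed=seed, **overrides)


def default_truths(
    noise_sd_days: float = 2.0,
    visit_interval_budburst: int = 7,
    visit_interval_flowering: int = 4,
) -> List[VarietyTruth]:
    """Four GDD-truth varieties seeded from published per-variety estimates.

    Start days, base temperatures and heat sums follow reported per-variety
    GDD fits so that the synthetic design reads like the real one.
    """
    kw = dict(
        noise_sd_days=noise_sd_days,
        visit_interval_budburst=visit_interval_budburst,
        visit_interval_flowering=visit_interval_flowering,
    )
    return [
        VarietyTruth(
            "Albarino",
            budburst=GDDParams(t0=62, tb=8.0, fstar=75.141),
            flowering=GDDParams(t0=27, tb=7.0, fstar=533.0),
            **kw,
        ),
        VarietyTruth(
            "Godello",
            budburst=GDDParams(t0=49, tb=5.0, fstar=208.931),
            flowering=GDDParams(t0=52, tb=6.0, fstar=626.092),
            **kw,
        ),
        VarietyTruth(
            "Loureira",
            budburst=GDDParams(t0=79, tb=10.0, fstar=18.616),
            flowering=GDDParams(t0=72, tb=6.0, fstar=587.035),
            **kw,
        ),
        VarietyTruth(
            "Treixadura",
            budburst=GDDParams(t0=49, tb=5.0, fstar=228.503),
            flowering=GDDParams(t0=52, tb=7.0, fstar=575.441),
            **kw,
        ),
    ]


def generate_temperature_series(
    scenario: ClimateScenario, year: int
) -> DailyTemperatureSeries:
    """One season of daily temperatures: Sep 1 of ``year - 1`` to Aug 31 of ``year``.

    Reproducible: the stream is keyed by ``(scenario.seed, year)``, so the
    same scenario and year always give the same series.
    """
    rng = np.random.default_rng([scenario.seed, year])
    season_shift = rng.normal(0.0, scenario.interannual_sd) if scenario.interannual_sd else 0.0
    end = date_to_day_index(year, _dt.date(year, 8, 31))
    days = np.arange(SEASON_START_DAY, end + 1)
    clim = scenario.annual_mean + season_shift + scenario.amplitude * np.sin(
        2.0 * np.pi * (days - scenario.phase_days) / 365.25
    )
    if scenario.noise_sd > 0:
        z = rng.normal(0.0, scenario.noise_sd, size=days.size)
        if scenario.ar1 > 0:
            noise = np.empty_like(z)
            noise[0] = z[0]
            innov_scale = np.sqrt(1.0 - scenario.ar1**2)
            for i in range(1, z.size):
                noise[i] = scenario.ar1 * noise[i - 1] + innov_scale * z[i]
        else:
            noise = z
        t_mean = clim + noise
    else:
        t_mean = clim
    return DailyTemperatureSeries(
        day_index=days,
        t_min=t_mean - scenario.diurnal_half_range,
        t_mean=t_mean,
        t_max=t_mean + scenario.diurnal_half_range,
        year=year,
    )


def _observe(
    event_day: int,
    truth: VarietyTruth,
    bbch: str,
    rng: np.random.Generator,
    visit_offset: int,
) -> int:
    day = event_day
    if truth.noise_sd_days > 0:
        day += int(round(rng.normal(0.0, truth.noise_sd_days)))
    interval = truth.visit_interval_for(bbch)
    if interval:
        # next scheduled visit on or after the (noisy) event day
        day += (visit_offset - day) % interval
    return day


def generate_observations(
    scenario: ClimateScenario,
    truths: Sequence[VarietyTruth],
    years: Sequence[int],
) -> Tuple[List[PhenologyObservation], Dict[int, DailyTemperatureSeries]]:
    """Simulate the full observational design: all varieties, both phenophases.

    For every year one shared temperature series is generated (one site);
    each variety's truth model is run forward to its event day, which is
    then perturbed by date noise and optionally snapped to the variety's
    visit schedule. Raises if a truth model never reaches its threshold,
    naming the variety-year.
    """
    if not truths:
        raise ValueError("no variety truths given")
    if not years:
        raise ValueError("no years given")
    meteorology = {year: generate_temperature_series(scenario, year) for year in years}
    observations: List[PhenologyObservation] = []
    for year in years:
        series = meteorology[year]
        for stage_idx, bbch in enumerate(("09", "61")):
            visit_rng = np.random.default_rng([scenario.seed, year, 7919, stage_idx])
            for v_idx, truth in enumerate(truths):
                params = truth.params_for(bbch)
                ev = predict_event(series, params)
                if ev is None:
                    raise ValueError(
                        f"truth model for {truth.name} {year} (BBCH {bbch}) never "
                        f"reaches F*={params.fstar}; adjust the scenario or truth"
                    )
                interval = truth.visit_interval_for(bbch)
                offset = int(visit_rng.integers(interval)) if interval else 0
                obs_rng = np.random.default_rng([scenario.seed, year, stage_idx, v_idx])
                doy = _observe(ev.day, truth, bbch, obs_rng, offset)
                observations.append(
                    PhenologyObservation(truth.name, year, bbch, doy)
                )
    return observations, meteorology


def write_manifest(
    path: Union[str, Path],
    scenario: ClimateScenario,
    truths: Sequence[VarietyTruth],
    years: Sequence[int],
) -> None:
    """Record the generating scenario, truths and seeds as JSON."""
    doc = {
        "scenario": dataclasses.asdict(scenario),
        "years": list(years),
        "truths": [
            {
                "name": t.name,
                "noise_sd_days": t.noise_sd_days,
                "visit_interval_budburst": t.visit_interval_budburst,
                "visit_interval_flowering": t.visit_interval_flowering,
                "budburst": {
                    "model_type": t.budburst.model_type,
                    **dataclasses.asdict(t.budburst),
                },
                "flowering": {
                    "model_type": t.flowering.model_type,
                    **dataclasses.asdict(t.flowering),
                },
            }
            for t in truths
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
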