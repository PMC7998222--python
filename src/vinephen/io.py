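"""CSV readers/writers and run configuration.

Meteorology CSV: one row per calendar day with columns ``date`` (ISO 8601),
``tmin``, ``tmean``, ``tmax`` in deg C. Phenology CSV: columns ``variety``,
``year``, ``bbch`` (09 budburst, 61 flowering), ``doy`` (observed day of
year). Readers validate hard (gaps, unordered temperatures, unknown stage
codes, duplicate events) and name the offending line; a season's series is
built on the back-extended day axis covering Sep 1 of the previous year
(day -121) through Aug 31 of the event year.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .thermal import DailyTemperatureSeries, date_to_day_index, day_index_to_date

__all__ = [
    "DataValidationError",
    "PhenologyObservation",
    "RunConfig",
    "read_meteorology",
    "write_meteorology",
    "read_phenology",
    "write_phenology",
    "load_config",
]

VALID_STAGES = ("09", "61")

SEASON_START_DAY = -121  # Sep 1 of the previous year, on the event-year axis


class DataValidationError(ValueError):
    """An input file failed validation; the message names the offending line."""


@dataclass(frozen=True)
class PhenologyObservation:
    """One observed phenological event: variety, year, BBCH stage and day of year."""

    variety: str
    year: int
    bbch: str
    doy: int


def write_meteorology(
    meteorology: Mapping[int, DailyTemperatureSeries], path: Union[str, Path]
) -> None:
    """Write season series as one contiguous daily CSV (date, tmin, tmean, tmax).

    Seasons abut without overlap (each runs Sep 1 to Aug 31), so their
    concatenation is a plain station record.
    """
    frames = []
    for year in sorted(meteorology):
        s = meteorology[year]
        dates = [day_index_to_date(year, int(d)) for d in s.day_index]
        frames.append(
            pd.DataFrame(
                {"date": dates, "tmin": s.t_min, "tmean": s.t_mean, "tmax": s.t_max}
            )
        )
    df = pd.concat(frames, ignore_index=True).drop_duplicates(subset="date")
    df = df.sort_values("date")
    df.to_csv(path, index=False, float_format="%.4f")


def read_meteorology(
    path: Union[str, Path],
    interpolate_gaps: bool = False,
    max_gap: int = 3,
) -> Dict[int, DailyTemperatureSeries]:
    """Read a daily station CSV into per-season series.

    Returns one :class:`DailyTemperatureSeries` per event year whose full
    window (Sep 1 of the previous year through Aug 31) is covered. Missing
    days are a hard error unless ``interpolate_gaps`` is set, in which case
    gaps of at most ``max_gap`` days are filled linearly.
    """
    df = pd.read_csv(path)
    required = ("date", "tmin", "tmean", "tmax")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"{path}: unparseable date ({exc})") from exc
    df = df.assign(date=dates).sort_values("date").reset_index(drop=True)
    for col in ("tmin", "tmean", "tmax"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2  # header + 1-based
            raise DataValidationError(f"{path}: non-numeric {col} on line {line}")
        df[col] = vals
    bad = (df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise DataValidationError(
            f"{path}: tmin <= tmean <= tmax violated on line {line} ({df['date'][bad].iloc[0]})"
        )
    if df["date"].duplicated().any():
        dup = df["date"][df["date"].duplicated()].iloc[0]
        raise DataValidationError(f"{path}: duplicate date {dup}")

    df = _fill_gaps(df, path, interpolate_gaps, max_gap)

    first, last = df["date"].iloc[0], df["date"].iloc[-1]
    by_date = df.set_index("date")
    out: Dict[int, DailyTemperatureSeries] = {}
    for year in range(first.year, last.year + 2):
        start = _dt.date(year - 1, 9, 1)
        end = _dt.date(year, 8, 31)
        if start < first or end > last:
            continue
        window = by_date.loc[start:end]
        days = np.array([date_to_day_index(year, d) for d in window.index])
        out[year] = DailyTemperatureSeries(
            day_index=days,
            t_min=window["tmin"].to_numpy(),
            t_mean=window["tmean"].to_numpy(),
            t_max=window["tmax"].to_numpy(),
            year=year,
        )
    if not out:
        raise DataValidationError(
            f"{path}: no event year with full Sep 1 - Aug 31 coverage "
            f"(data span {first} to {last})"
        )
    return out


def _fill_gaps(df: pd.DataFrame, path, interpolate_gaps: bool, max_gap: int) -> pd.DataFrame:
    deltas = np.diff([d.toordinal() for d in df["date"]])
    if np.all(deltas == 1):
        return df
    gap_pos = int(np.argmax(deltas > 1))
    gap_len = int(deltas[gap_pos] - 1)
    gap_after = df["date"].iloc[gap_pos]
    if not interpolate_gaps:
        raise DataValidationError(
            f"{path}: missing day(s) after {gap_after} ({gap_len} day gap); "
            "pass interpolate_gaps=True to fill gaps of up to "
            f"{max_gap} days"
        )
    if int(np.max(deltas)) - 1 > max_gap:
        worst = int(np.argmax(deltas))
        raise DataValidationError(
            f"{path}: gap of {int(deltas[worst]) - 1} days after "
            f"{df['date'].iloc[worst]} exceeds max_gap={max_gap}"
        )
    full = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D").date
    df = df.set_index("date").reindex(full)
    df[["tmin", "tmean", "tmax"]] = df[["tmin", "tmean", "tmax"]].interpolate("linear")
    return df.rename_axis("date").reset_index()


def write_phenology(
    observations: Iterable[PhenologyObservation], path: Union[str, Path]
) -> None:
    rows = [(o.variety, o.year, o.bbch, o.doy) for o in observations]
    pd.DataFrame(rows, columns=["variety", "year", "bbch", "doy"]).to_csv(
        path, index=False
    )


def read_phenology(path: Union[str, Path]) -> List[PhenologyObservation]:
    """Read phenology records; one event per (variety, year, BBCH stage)."""
    df = pd.read_csv(path, dtype={"bbch": str})
    required = ("variety", "year", "bbch", "doy")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")
    out: List[PhenologyObservation] = []
    seen = set()
    for i, row in df.iterrows():
        line = int(i) + 2
        bbch = str(row["bbch"]).zfill(2)
        if bbch not in VALID_STAGES:
            raise DataValidationError(
                f"{path}: unknown BBCH stage {row['bbch']!r} on line {line} "
                f"(expected one of {VALID_STAGES})"
            )
        try:
            year, doy = int(row["year"]), int(row["doy"])
        except (TypeError, ValueError) as exc:
            raise DataValidationError(f"{path}: bad year/doy on line {line}") from exc
        if not 1 <= doy <= 200:
            raise DataValidationError(
                f"{path}: doy {doy} outside [1, 200] on line {line}"
            )
        key = (str(row["variety"]), year, bbch)
        if key in seen:
            raise DataValidationError(
                f"{path}: duplicate event {key} on line {line}"
            )
        seen.add(key)
        out.append(PhenologyObservation(str(row["variety"]), year, bbch, doy))
    return out


@dataclass
class RunConfig:
    """Pipeline run settings, loadable from TOML or YAML.

    Paths are resolved by the caller; ``bounds`` entries override the
    default parameter-space bounds per model family, and ``schedule``
    entries override :class:`~vinephen.fitting.AnnealSchedule` fields.
    """

    meteorology: Optional[str] = None
    phenology: Optional[str] = None
    phenophase: str = "09"
    models: Sequence[str] = ("gdd", "triangular", "uniforc")
    validation_model: str = "gdd"
    seed: int = 0
    out_dir: str = "vinephen_out"
    bounds: Mapping[str, Mapping[str, Tuple[float, float]]] = field(default_factory=dict)
    schedule: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phenophase not in VALID_STAGES:
            raise DataValidationError(
                f"phenophase must be one of {VALID_STAGES}, got {self.phenophase!r}"
            )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a :class:`RunConfig` from a ``.toml`` or ``.yaml``/``.yml`` file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raise DataValidationError(f"unsupported config format: {path.suffix!r}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise DataValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**raw)
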