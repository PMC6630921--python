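"""Environmental covariates from hourly weather and 4-hourly soil records.

For each trial environment the season is summarized by:

* ``Tmax``  — mean of daily maximum air temperature, sowing→harvest (°C);
* ``VPDmax`` — the day's vapor pressure deficit evaluated at the hour of
  the daily maximum temperature, averaged sowing→harvest (kPa);
* ``SWC``  — volumetric soil water content × profile depth (500 mm),
  averaged per day and then over anthesis→harvest (mm);
* total precipitation sowing→harvest (mm).

Saturation vapor pressure uses the Tetens form adopted by FAO-56,
``es(T) = 0.6108 · exp(17.27·T / (T + 237.3))`` kPa, the standard
agrometeorological choice; VPD = es·(1 − RH/100).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "CoverageError",
    "PhenologyCalendar",
    "SeasonalIndices",
    "EnvironmentSummary",
    "saturation_vapor_pressure",
    "vpd_hourly",
    "daily_vpdmax",
    "seasonal_means",
    "swc_window_mean",
    "summarize_environment",
    "load_weather",
    "load_soil",
    "load_phenology",
    "parse_trial_code",
]

#: Tetens / FAO-56 saturation vapor pressure constants (kPa, dimensionless, °C).
SVP_A = 0.6108
SVP_B = 17.27
SVP_C = 237.3

#: Soil profile depth used to convert volumetric content to mm of water.
DEFAULT_SOIL_DEPTH_MM = 500.0

#: Days with fewer hourly records than this are excluded from seasonal means.
MIN_HOURS_PER_DAY = 18


class CoverageError(ValueError):
    """The sensor series does not cover the requested phenology window."""


@dataclass(frozen=True)
class PhenologyCalendar:
    """Key dates of one trial: sowing < anthesis < grain filling < harvest."""

    trial_code: str
    sowing: date
    anthesis: date
    grain_filling: date
    harvest: date

    def __post_init__(self) -> None:
        seq = [self.sowing, self.anthesis, self.grain_filling, self.harvest]
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(
                f"{self.trial_code}: phenology dates must be strictly increasing "
                f"(sowing < anthesis < grain filling < harvest), got {seq}"
            )


@dataclass
class SeasonalIndices:
    """Sowing→harvest aggregates of one weather series."""

    tmax_mean: float  # °C
    vpdmax_mean: float  # kPa
    precip_total: float  # mm
    n_days_used: int
    n_days_excluded: int  # days with < MIN_HOURS_PER_DAY hourly records


@dataclass
class EnvironmentSummary:
    """One trial environment: the unit row of the multi-environment table."""

    trial_code: str
    water_regime: str  # "FI" | "WS"
    location: str  # "sr" | "c"
    season: int
    gy_mean: float  # t ha^-1
    d13c_mean: Optional[float]  # ‰, None when no kernel isotope data
    sdd_mean: float  # °C
    tmax_mean: float  # °C
    vpdmax_mean: float  # kPa
    swc_mean: float  # mm
    precip_total: Optional[float] = None  # mm

    def __post_init__(self) -> None:
        if self.gy_mean < 0:
            raise ValueError(f"{self.trial_code}: negative mean grain yield")
        if self.vpdmax_mean < 0 or self.swc_mean < 0:
            raise ValueError(f"{self.trial_code}: negative VPDmax or SWC")


def parse_trial_code(code: str) -> tuple[str, str, int]:
    """Split e.g. ``"WSc 2011"`` into (regime, location, season)."""
    name, season = code.split()
    regime, location = name[:2], name[2:]
    if regime not in {"FI", "WS"}:
        raise ValueError(f"trial code {code!r}: unknown water regime {regime!r}")
    return regime, location, int(season)


# ---------------------------------------------------------------------------
# vapor pressure deficit
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(ta):
    """Tetens saturation vapor pressure es(T) in kPa (T in °C)."""
    ta = np.asarray(ta, dtype=float)
    out = SVP_A * np.exp(SVP_B * ta / (ta + SVP_C))
    return float(out) if out.ndim == 0 else out


def vpd_hourly(ta, rh):
    """Vapor pressure deficit (kPa) from air temperature (°C) and RH (%)."""
    ta = np.asarray(ta, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    out = saturation_vapor_pressure(ta) * (1.0 - rh / 100.0)
    return float(out) if np.ndim(out) == 0 else out


def daily_vpdmax(day: pd.DataFrame) -> float:
    """VPD at the hour of the day's maximum air temperature.

    Note this is *not* the maximum of the hourly VPDs: the convention is
    to evaluate VPD at the hottest hour using that hour's humidity.
    Ties in temperature are broken by the earliest timestamp.
    """
    if len(day) == 0:
        raise CoverageError("empty day passed to daily_vpdmax")
    day = day.sort_values("timestamp", kind="stable")
    row = day.loc[day["ta_c"].idxmax()]  # idxmax returns the first maximum
    return float(vpd_hourly(row["ta_c"], row["rh_pct"]))


# ---------------------------------------------------------------------------
# seasonal aggregation
# ---------------------------------------------------------------------------

def _window(df: pd.DataFrame, start: date, end: date) -> pd.DataFrame:
    d = df["timestamp"].dt.date
    return df[(d >= start) & (d <= end)]


def seasonal_means(
    weather: pd.DataFrame,
    cal: PhenologyCalendar,
    min_hours: int = MIN_HOURS_PER_DAY,
) -> SeasonalIndices:
    """Tmax, VPDmax means and precipitation total, sowing→harvest inclusive.

    Days with fewer than ``min_hours`` hourly records are excluded from
    the Tmax/VPDmax means (no imputation); the precipitation total sums
    every record in the window.
    """
    win = _window(weather, cal.sowing, cal.harvest)
    if len(win) == 0:
        raise CoverageError(
            f"{cal.trial_code}: weather series does not cover "
            f"[{cal.sowing}, {cal.harvest}]"
        )
    tmaxes, vpdmaxes, n_excl = [], [], 0
    for _, day in win.groupby(win["timestamp"].dt.date, sort=True):
        if len(day) < min_hours:
            n_excl += 1
            continue
        tmaxes.append(float(day["ta_c"].max()))
        vpdmaxes.append(daily_vpdmax(day))
    if not tmaxes:
        raise CoverageError(
            f"{cal.trial_code}: no complete days (>= {min_hours} hourly records) "
            f"in [{cal.sowing}, {cal.harvest}]"
        )
    return SeasonalIndices(
        tmax_mean=float(np.mean(tmaxes)),
        vpdmax_mean=float(np.mean(vpdmaxes)),
        precip_total=float(win["precip_mm"].sum()),
        n_days_used=len(tmaxes),
        n_days_excluded=n_excl,
    )


def swc_window_mean(
    soil: pd.DataFrame,
    cal: PhenologyCalendar,
    depth_mm: float = DEFAULT_SOIL_DEPTH_MM,
    end: str = "harvest",
) -> float:
    """Soil water content (mm) averaged over the anthesis→maturity window.

    Volumetric content θ (m³ m⁻³) is converted to mm of stored water by
    multiplying by the profile depth (default 500 mm).  The up-to-six
    scans of each day are averaged with equal weight, then the daily
    values are averaged over [anthesis, ``end``] inclusive, where
    ``end`` is ``"harvest"`` (default; maturity date is rarely recorded
    separately) or ``"grain_filling"``.
    """
    if end not in {"harvest", "grain_filling"}:
        raise ValueError(f"end must be 'harvest' or 'grain_filling', got {end!r}")
    stop = cal.harvest if end == "harvest" else cal.grain_filling
    win = _window(soil, cal.anthesis, stop)
    if len(win) == 0:
        raise CoverageError(
            f"{cal.trial_code}: soil series does not cover [{cal.anthesis}, {stop}]"
        )
    daily = win.groupby(win["timestamp"].dt.date)["theta_m3m3"].mean() * depth_mm
    return float(daily.mean())


def summarize_environment(
    plots: pd.DataFrame,
    weather: pd.DataFrame,
    soil: pd.DataFrame,
    cal: PhenologyCalendar,
    depth_mm: float = DEFAULT_SOIL_DEPTH_MM,
    swc_end: str = "harvest",
) -> EnvironmentSummary:
    """Collapse a trial into one environment row.

    ``plots`` must carry one row per plot with columns ``gy_t_ha`` and
    ``sdd_c``; ``big_delta13c_pm`` is optional (kernel isotope data are
    not collected in every season).  Trait means are arithmetic means
    over plots; environmental fields come from the sensor series.
    """
    if len(plots) == 0:
        raise ValueError(f"{cal.trial_code}: no plot records to summarize")
    regime, location, season = parse_trial_code(cal.trial_code)
    season_idx = seasonal_means(weather, cal)
    swc = swc_window_mean(soil, cal, depth_mm=depth_mm, end=swc_end)
    d13c = None
    if "big_delta13c_pm" in plots.columns and plots["big_delta13c_pm"].notna().any():
        d13c = float(plots["big_delta13c_pm"].mean())
    return EnvironmentSummary(
        trial_code=cal.trial_code,
        water_regime=regime,
        location=location,
        season=season,
        gy_mean=float(plots["gy_t_ha"].mean()),
        d13c_mean=d13c,
        sdd_mean=float(plots["sdd_c"].mean()),
        tmax_mean=season_idx.tmax_mean,
        vpdmax_mean=season_idx.vpdmax_mean,
        swc_mean=swc,
        precip_total=season_idx.precip_total,
    )


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def load_weather(path) -> pd.DataFrame:
    """Hourly weather CSV: ``timestamp, ta_c, rh_pct, precip_mm``."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "ta_c", "rh_pct", "precip_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    if ((df["rh_pct"] < 0) | (df["rh_pct"] > 100)).any():
        raise ValueError("weather table: rh_pct outside [0, 100]")
    if (df["precip_mm"] < 0).any():
        raise ValueError("weather table: negative precipitation")
    return df


def load_soil(path) -> pd.DataFrame:
    """Soil moisture CSV: ``timestamp, theta_m3m3`` (4-hourly scans)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "theta_m3m3"} - set(df.columns)
    if missing:
        raise ValueError(f"soil table missing columns: {sorted(missing)}")
    if ((df["theta_m3m3"] < 0) | (df["theta_m3m3"] > 1)).any():
        raise ValueError("soil table: theta_m3m3 outside [0, 1]")
    return df


def load_phenology(path) -> dict[str, PhenologyCalendar]:
    """Phenology CSV: ``trial_code, sowing, anthesis, grain_filling, harvest``."""
    df = pd.read_csv(
        path, parse_dates=["sowing", "anthesis", "grain_filling", "harvest"]
    )
    out = {}
    for _, row in df.iterrows():
        out[row["trial_code"]] = PhenologyCalendar(
            trial_code=row["trial_code"],
            sowing=row["sowing"].date(),
            anthesis=row["anthesis"].date(),
            grain_filling=row["grain_filling"].date(),
            harvest=row["harvest"].date(),
        )
    return out
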