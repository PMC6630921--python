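"""Synthetic thermal scenes, weather, soil moisture, and trial tables.

No field data accompany the analysis, so every module is exercised on
generated inputs with known ground truth:

* **Scenes** — 120×120 rasters of a row crop seen from above: cool
  canopy rows (Ta + SDD) over hot, sunlit soil (Ta + ~12 °C), each class
  Gaussian around its mean, arranged with a row-crop period so a
  band-threshold segmenter has a realistic job to do.
* **Weather** — hourly Mediterranean-season records: a sinusoidal
  diurnal cycle peaking at 15:00, slow seasonal drift, AR(1) day-to-day
  variation, humidity anti-correlated with temperature, sparse rain.
* **Trials** — multi-environment genotype tables wired the way the
  analysis assumes: under water stress SDD rises linearly with VPDmax,
  environment-mean grain yield decays exponentially with SDD, and Δ13C
  declines linearly with SDD; under full irrigation SDD stays below
  ~2 °C and yield is flat.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .isotope import composition_from_delta13c
from .thermal import CanopyMask, ThermalImage

__all__ = [
    "SceneSpec",
    "SceneSample",
    "TrialSpec",
    "EnvironmentCondition",
    "TrialData",
    "simulate_scene",
    "simulate_weather",
    "simulate_soil_moisture",
    "simulate_trials",
    "simulate_genotype_cohort",
    "default_trial_spec",
]


class GeometryError(ValueError):
    """Row geometry cannot realize the requested canopy fraction."""


@dataclass(frozen=True)
class SceneSpec:
    """Row-crop thermal scene parameters.

    Canopy pixels ~ N(ta + sdd_true, noise_sd); soil pixels
    ~ N(ta + soil_offset, 2·noise_sd).  Canopy occupies vertical rows of
    ``row_width`` pixels every ``row_period`` pixels.
    """

    height: int = 120
    width: int = 120
    ta: float = 25.0  # °C, midday air temperature
    sdd_true: float = 5.0  # °C, canopy offset from air
    soil_offset: float = 12.0  # °C, sunlit soil offset from air
    canopy_fraction: float = 0.58
    row_period: int = 12
    row_width: int = 7
    noise_sd: float = 0.5  # °C
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.canopy_fraction < 1.0):
            raise ValueError("canopy_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (1 <= self.row_width <= self.row_period):
            raise ValueError("require 1 <= row_width <= row_period")


@dataclass
class SceneSample:
    """A simulated scene with its ground truth."""

    image: ThermalImage
    mask: CanopyMask  # ground-truth canopy labels
    canopy_mean_true: float  # programmed canopy mean, ta + sdd_true


def simulate_scene(spec: SceneSpec) -> SceneSample:
    """Deterministic (given seed) thermal scene with ground-truth mask."""
    geom_fraction = spec.row_width / spec.row_period
    if abs(geom_fraction - spec.canopy_fraction) > 0.1:
        raise GeometryError(
            f"row geometry yields canopy fraction {geom_fraction:.2f}, "
            f"requested {spec.canopy_fraction:.2f}"
        )
    rng = np.random.default_rng(spec.seed)
    cols = np.arange(spec.width)
    canopy = np.broadcast_to(
        (cols % spec.row_period) < spec.row_width, (spec.height, spec.width)
    ).copy()
    px = np.where(
        canopy,
        spec.ta + spec.sdd_true,
        spec.ta + spec.soil_offset,
    ) + rng.normal(0.0, 1.0, canopy.shape) * np.where(
        canopy, spec.noise_sd, 2.0 * spec.noise_sd
    )
    image = ThermalImage(px, plot_id=f"scene-{spec.seed}")
    return SceneSample(
        image=image,
        mask=CanopyMask(canopy),
        canopy_mean_true=spec.ta + spec.sdd_true,
    )


def simulate_weather(
    days: int = 135,
    peak_temp_mean: float = 23.4,
    peak_temp_amplitude: float = 3.0,
    rh_at_peak: float = 40.0,
    seed: int = 0,
    start: str = "2011-09-01",
    diurnal_range: float = 12.0,
    noise_sd: float = 1.5,
    rain_prob: float = 0.12,
    rain_mean_mm: float = 6.0,
) -> pd.DataFrame:
    """Hourly weather table (``timestamp, ta_c, rh_pct, precip_mm``).

    Each day's temperature follows a cosine diurnal cycle peaking at
    15:00 with amplitude ``diurnal_range``; daily peaks combine a mean
    of ``peak_temp_mean``, a full-cycle sinusoid of amplitude
    ``peak_temp_amplitude`` over the season (mean ≈ 0), and AR(1)
    day-to-day noise (φ=0.6, sd ``noise_sd``).  Humidity tracks
    ``rh_at_peak`` at the daily maximum and rises ~2.2 %/°C as the air
    cools, clamped to [5, 100].  Rain falls as sparse 06:00 events.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    ar = np.zeros(days)
    eps = rng.normal(0.0, noise_sd, days)
    for d in range(1, days):
        ar[d] = 0.6 * ar[d - 1] + eps[d]
    ar[0] = eps[0]
    d = np.arange(days)
    peaks = peak_temp_mean + peak_temp_amplitude * np.sin(2 * np.pi * d / days) + ar

    hours = np.arange(24)
    diel = 0.5 * (1.0 + np.cos(2 * np.pi * (hours - 15) / 24))  # 1 at 15:00, 0 at 03:00
    ta = peaks[:, None] - diurnal_range * (1.0 - diel)[None, :]
    rh = rh_at_peak + 2.2 * (peaks[:, None] - ta) + rng.normal(0, 3.0, ta.shape)
    rh = np.clip(rh, 5.0, 100.0)
    precip = np.zeros_like(ta)
    rain_days = rng.random(days) < rain_prob
    precip[rain_days, 6] = rng.exponential(rain_mean_mm, int(rain_days.sum()))

    ts = pd.date_range(start=start, periods=days * 24, freq="h")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "ta_c": ta.ravel(),
            "rh_pct": rh.ravel(),
            "precip_mm": precip.ravel(),
        }
    )


def simulate_soil_moisture(
    days: int = 135,
    theta_start: float = 0.32,
    theta_end: float = 0.20,
    seed: int = 0,
    start: str = "2011-09-01",
    noise_sd: float = 0.004,
) -> pd.DataFrame:
    """4-hourly volumetric soil moisture: linear seasonal dry-down + noise."""
    rng = np.random.default_rng(seed)
    n = days * 6
    t = np.linspace(0.0, 1.0, n)
    theta = theta_start + (theta_end - theta_start) * t + rng.normal(0, noise_sd, n)
    theta = np.clip(theta, 0.005, 0.6)
    ts = pd.date_range(start=start, periods=n, freq="4h")
    return pd.DataFrame({"timestamp": ts, "theta_m3m3": theta})


# ---------------------------------------------------------------------------
# multi-environment trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentCondition:
    """Programmed climate of one trial environment."""

    trial_code: str
    water_regime: str  # "FI" | "WS"
    vpdmax_mean: float  # kPa
    tmax_mean: float  # °C
    swc_mean: float  # mm


@dataclass(frozen=True)
class TrialSpec:
    """Ground-truth structure of a multi-environment genotype trial.

    Links (defaults calibrated to the published multi-environment
    ranges: WS grain yield ≈ 1.7–8.1 t ha⁻¹ over SDD ≈ 2–12 °C):

    * ``sdd_link``: WS environment SDD = intercept + slope·VPDmax (+ noise);
      FI environments sit at ``fi_sdd_mean`` (< 2 °C) regardless of VPD.
    * ``gy_link`` (a, b): WS environment-mean GY = a·exp(b·SDD); FI mean
      GY is flat at ``fi_gy_mean``.
    * ``d13c_link``: Δ13C = intercept + slope·SDD in both regimes.
    """

    n_genotypes: int = 16
    environments: tuple = ()
    gy_link: tuple = (11.0, -0.15)  # a (t/ha), b (per °C)
    fi_gy_mean: float = 9.1  # t/ha
    d13c_link: tuple = (17.5, -0.25)  # intercept (‰), slope (‰ per °C)
    sdd_link: tuple = (-11.0, 9.7)  # intercept (°C), slope (°C per kPa)
    fi_sdd_mean: float = 0.85  # °C
    env_sdd_sd: float = 0.4  # °C, environment-level deviation around the link
    plot_noise_sd: dict = field(
        default_factory=lambda: {"gy": 0.6, "d13c": 0.5, "sdd": 0.8}
    )

    def __post_init__(self) -> None:
        if self.gy_link[0] <= 0:
            raise ValueError("gy_link amplitude a must be positive")
        if any(v < 0 for v in self.plot_noise_sd.values()):
            raise ValueError("plot_noise_sd entries must be >= 0")


def default_trial_spec(
    n_ws: int = 5, n_fi: int = 5, n_genotypes: int = 16, **kwargs
) -> TrialSpec:
    """Ten-environment spec spanning the published VPDmax range.

    WS environments sweep VPDmax 1.45–2.39 kPa (SDD ≈ 3–12 °C through
    the link); FI environments span the same climate but stay cool.
    """
    envs = []
    for i, v in enumerate(np.linspace(1.45, 2.39, n_ws)):
        envs.append(
            EnvironmentCondition(
                trial_code=f"WSsim {2011 + i}",
                water_regime="WS",
                vpdmax_mean=float(v),
                tmax_mean=float(19.0 + 2.7 * v),
                swc_mean=float(280.0 - 40.0 * (v - 1.9)),
            )
        )
    for i, v in enumerate(np.linspace(1.35, 1.92, n_fi)):
        envs.append(
            EnvironmentCondition(
                trial_code=f"FIsim {2011 + i}",
                water_regime="FI",
                vpdmax_mean=float(v),
                tmax_mean=float(19.0 + 2.7 * v),
                swc_mean=float(320.0 + 60.0 * (1.6 - v)),
            )
        )
    return TrialSpec(n_genotypes=n_genotypes, environments=tuple(envs), **kwargs)


@dataclass
class TrialData:
    """Simulated plot tables plus the generating ground truth."""

    plots: pd.DataFrame  # plot-level rows across all environments
    environments: pd.DataFrame  # per-environment generating values
    spec: TrialSpec


def simulate_trials(spec: TrialSpec, seed: int = 0) -> TrialData:
    """Draw plot tables for every environment in the spec.

    Environment-level values follow the links exactly up to an
    SDD-level disturbance (``env_sdd_sd``); plot-level noise is additive
    around the environment mean, so environment means recover the link
    values as the number of plots grows.  δ13C is written on the
    composition scale (as a mass spectrometer would report it) via the
    exact algebraic inverse of the discrimination formula.
    """
    if not spec.environments:
        raise ValueError("TrialSpec.environments is empty")
    rng = np.random.default_rng(seed)
    a, b = spec.gy_link
    d0, d1 = spec.d13c_link
    s0, s1 = spec.sdd_link
    env_rows, plot_rows = [], []
    for env in spec.environments:
        if env.water_regime == "WS":
            sdd_env = s0 + s1 * env.vpdmax_mean + rng.normal(0, spec.env_sdd_sd)
            gy_env = a * np.exp(b * sdd_env)
        else:
            sdd_env = spec.fi_sdd_mean + rng.normal(0, spec.env_sdd_sd)
            gy_env = spec.fi_gy_mean
        d13c_env = d0 + d1 * sdd_env
        env_rows.append(
            {
                "trial_code": env.trial_code,
                "water_regime": env.water_regime,
                "vpdmax_mean": env.vpdmax_mean,
                "tmax_mean": env.tmax_mean,
                "swc_mean": env.swc_mean,
                "sdd_true": sdd_env,
                "gy_true": gy_env,
                "d13c_true": d13c_env,
            }
        )
        g = spec.n_genotypes
        gy = gy_env + rng.normal(0, spec.plot_noise_sd["gy"], g)
        sdd = sdd_env + rng.normal(0, spec.plot_noise_sd["sdd"], g)
        d13c = d13c_env + rng.normal(0, spec.plot_noise_sd["d13c"], g)
        for i in range(g):
            plot_rows.append(
                {
                    "trial_code": env.trial_code,
                    "genotype": f"G{i + 1:03d}",
                    "gy_t_ha": max(gy[i], 0.05),
                    "delta13c_pm": composition_from_delta13c(d13c[i]),
                    "big_delta13c_pm": d13c[i],
                    "sdd_c": sdd[i],
                }
            )
    return TrialData(
        plots=pd.DataFrame(plot_rows),
        environments=pd.DataFrame(env_rows),
        spec=spec,
    )


def simulate_genotype_cohort(
    n_genotypes: int = 384,
    r2_target: float = 0.6,
    slope: float = -0.55,
    sdd_mean: float = 6.0,
    sdd_sd: float = 2.0,
    intercept: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-level (SDD, GY) cohort with a programmed r².

    GY = intercept + slope·SDD + ε with ε scaled so the population
    coefficient of determination equals ``r2_target``; at n = 384 the
    sample r² concentrates near the target.
    """
    if not (0.0 < r2_target < 1.0):
        raise ValueError("r2_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    sdd = rng.normal(sdd_mean, sdd_sd, n_genotypes)
    signal_sd = abs(slope) * sdd_sd
    noise_sd = signal_sd * np.sqrt((1.0 - r2_target) / r2_target)
    gy = intercept + slope * (sdd - sdd_mean) + rng.normal(0, noise_sd, n_genotypes)
    return pd.DataFrame({"genotype": [f"G{i + 1:03d}" for i in range(n_genotypes)],
                         "sdd_c": sdd, "gy_t_ha": gy})
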