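"""End-to-end orchestration: environment table → correlations, fits, typing.

A run is described by a :class:`RunConfig` (YAML-friendly), executed by
:func:`run_pipeline`, and summarized by a manifest recording the config
hash, seeds, library versions, per-stage row counts and every output
file, so a run can be reproduced bit-for-bit.

The package ships a transcription of the published ten-environment
summary table (printed data, not a download) as
:func:`load_reference_environments`; it drives the offline reproduction
of the multi-environment correlation and typing results.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import fit_exponential, fit_linear, pearson_matrix
from .clustering import (
    build_feature_table,
    cut_groups,
    pca_projection,
    percent_change_contrast,
    ward_d2_linkage,
)
from .indices import PhenologyCalendar, parse_trial_code

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "run_pipeline",
    "load_reference_environments",
    "reference_phenology",
]

#: Default variable set for the correlation stage, in display order.
DEFAULT_VARIABLES = ["sdd", "gy", "d13c", "tmax", "vpdmax", "swc"]
DATE_COLUMNS = ["sowing", "anthesis", "grain_filling", "harvest"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input file."""

    def __init__(self, stage: str, detail: str, source: Optional[str] = None):
        self.stage = stage
        self.source = source
        src = f" (input: {source})" if source else ""
        super().__init__(f"stage {stage!r} failed{src}: {detail}")


def load_reference_environments() -> pd.DataFrame:
    """The published ten-environment summary table (transcribed).

    One row per (water regime × site × season) environment with
    phenology dates and mean GY (t ha⁻¹), Δ13C (‰; one season missing),
    SDD (°C), Tmax (°C), VPDmax (kPa) and SWC (mm).
    """
    with resources.files("thermotype.data").joinpath(
        "table1_environments.csv"
    ).open() as fh:
        df = pd.read_csv(fh, parse_dates=DATE_COLUMNS)
    return df


def reference_phenology() -> dict[str, PhenologyCalendar]:
    """Phenology calendars of the ten reference environments."""
    df = load_reference_environments()
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


@dataclass
class RunConfig:
    """Validated inputs and options of one pipeline run."""

    env_table: Optional[str] = None  # environment CSV; None → packaged reference
    plot_table: Optional[str] = None  # optional per-plot CSV to summarize
    outdir: str = "thermotype_run"
    variables: list = field(default_factory=lambda: list(DEFAULT_VARIABLES))
    k: list = field(default_factory=lambda: [2, 3])
    phenology_encoding: str = "durations"
    normalization: str = "minmax"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.env_table, self.plot_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if any(int(k) < 1 for k in self.k):
            raise ValueError("every k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "env_table": self.env_table,
            "plot_table": self.plot_table,
            "outdir": self.outdir,
            "variables": list(self.variables),
            "k": [int(k) for k in self.k],
            "phenology_encoding": self.phenology_encoding,
            "normalization": self.normalization,
            "seed": self.seed,
        }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute load → summarize → correlate → fit → cluster; return manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: list[str] = []

    # -- load -------------------------------------------------------------
    try:
        if config.env_table is None:
            env = load_reference_environments()
        else:
            env = pd.read_csv(config.env_table)
            present = [c for c in DATE_COLUMNS if c in env.columns]
            for c in present:
                env[c] = pd.to_datetime(env[c])
        if "trial_code" not in env.columns:
            raise ValueError("environment table needs a trial_code column")
    except Exception as exc:
        raise PipelineStageError("load", str(exc), config.env_table) from exc
    counts["environments"] = len(env)

    # -- summarize (optional plot table) ----------------------------------
    if config.plot_table is not None:
        try:
            plots = pd.read_csv(config.plot_table)
            if len(plots) == 0:
                raise ValueError("plot table is empty")
            means = plots.groupby("trial_code").agg(
                gy=("gy_t_ha", "mean"), sdd=("sdd_c", "mean")
            )
            if "big_delta13c_pm" in plots.columns:
                means["d13c"] = plots.groupby("trial_code")["big_delta13c_pm"].mean()
            env = env.set_index("trial_code")
            for c in means.columns:
                env.loc[means.index, c] = means[c]
            env = env.reset_index()
            counts["plots"] = len(plots)
        except Exception as exc:
            raise PipelineStageError("summarize", str(exc), config.plot_table) from exc

    env_path = outdir / "environments.csv"
    env.to_csv(env_path, index=False, float_format="%.10g")
    outputs.append(env_path.name)

    # -- correlate --------------------------------------------------------
    try:
        variables = [v for v in config.variables if v in env.columns]
        corr = pearson_matrix(env, variables)
    except Exception as exc:
        raise PipelineStageError("correlate", str(exc), config.env_table) from exc
    for name, frame in (("r", corr.r), ("p", corr.p), ("stars", corr.stars),
                        ("n_pairs", corr.n_pairs)):
        p = outdir / f"correlation_{name}.csv"
        frame.to_csv(p, float_format="%.6g")
        outputs.append(p.name)
    counts["correlation_cells"] = int(corr.r.size)

    # -- per-regime fits --------------------------------------------------
    fits: dict[str, dict] = {}
    if "water_regime" not in env.columns:
        env = env.assign(
            water_regime=[parse_trial_code(t)[0] for t in env["trial_code"]]
        )
    for regime, sub in env.groupby("water_regime"):
        fits[regime] = {}
        for model, x, y in (
            ("exponential", "sdd", "gy"),
            ("linear", "sdd", "gy"),
            ("linear", "sdd", "d13c"),
        ):
            pair = sub[[x, y]].dropna()
            key = f"{y}_vs_{x}_{model}"
            try:
                fitter = fit_exponential if model == "exponential" else fit_linear
                fits[regime][key] = fitter(pair[x], pair[y]).to_dict()
            except ValueError as exc:
                fits[regime][key] = {"error": str(exc)}
    fits_path = outdir / "fits.json"
    _dump_json(fits, fits_path)
    outputs.append(fits_path.name)
    counts["fits"] = sum(len(v) for v in fits.values())

    # -- cluster ----------------------------------------------------------
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ft = build_feature_table(
                env,
                phenology_encoding=config.phenology_encoding,
                normalization=config.normalization,
            )
        result = ward_d2_linkage(ft)
        pca = pca_projection(ft, n_components=2)
        cluster_out = result.to_dict()
        cluster_out["normalization"] = config.normalization
        cluster_out["phenology_encoding"] = config.phenology_encoding
        cluster_out["pca_explained_variance_ratio"] = pca.explained_variance_ratio
        cluster_out["assignments"] = {}
        cluster_out["percent_change_vs_most_stressed"] = {}
        for k in config.k:
            groups = cut_groups(result, int(k))
            cluster_out["assignments"][str(k)] = groups.to_dict()
            # reference: the group with the highest mean SDD (most stressed)
            sdd_by_group = ft.raw["sdd"].groupby(groups).mean()
            ref = int(sdd_by_group.idxmax())
            contrast = percent_change_contrast(ft, groups, ref)
            cluster_out["percent_change_vs_most_stressed"][str(k)] = {
                str(g): contrast[g].round(6).to_dict() for g in contrast.columns
            }
    except Exception as exc:
        raise PipelineStageError("cluster", str(exc), config.env_table) from exc
    cluster_path = outdir / "cluster.json"
    _dump_json(cluster_out, cluster_path)
    outputs.append(cluster_path.name)
    scores_path = outdir / "pca_scores.csv"
    pca.scores.to_csv(scores_path, float_format="%.10g")
    outputs.append(scores_path.name)
    counts["clustered_environments"] = len(ft.labels)

    # -- manifest ---------------------------------------------------------
    cfg = config.to_dict()
    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "package": {"name": "thermotype", "version": __version__},
        "libraries": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "row_counts": counts,
        "outputs": outputs,
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
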