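"""Environment typing: normalization, Ward.D2 clustering, PCA, contrasts.

Trial environments are described by phenology (inter-stage durations in
days), productivity (GY), physiology (Δ13C, SDD) and climate (Tmax,
VPDmax, SWC).  After per-feature normalization the environments are
agglomerated by the Ward minimum-variance criterion in its "D2"
variant — the Lance–Williams recurrence operates on squared Euclidean
distances while merge heights are reported on the distance scale — and
the tree is cut into k groups.  A principal-component projection of the
same table is attached for display, and group contrasts are expressed
as percent change of each feature mean against a reference group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .indices import EnvironmentSummary, PhenologyCalendar

__all__ = [
    "FeatureTable",
    "ClusterResult",
    "PCAResult",
    "environment_frame",
    "build_feature_table",
    "ward_d2_linkage",
    "cut_groups",
    "pca_projection",
    "percent_change_contrast",
]

#: Feature columns of the normalized environment table, in order.
PHENOLOGY_FEATURES = [
    "days_sowing_to_anthesis",
    "days_anthesis_to_grain_filling",
    "days_grain_filling_to_harvest",
]
TRAIT_FEATURES = ["gy", "d13c", "sdd", "tmax", "vpdmax", "swc"]


@dataclass
class FeatureTable:
    """Environment × feature matrix with its normalization audit trail.

    ``raw`` holds the original feature values (after imputation),
    ``values`` the normalized ones.  ``scaling`` records the per-column
    statistics used (center/scale for z-scores, min/range for min–max)
    so any normalized value can be mapped back.
    """

    raw: pd.DataFrame
    values: pd.DataFrame
    normalization: str  # "minmax" | "zscore"
    scaling: pd.DataFrame
    imputed: dict = field(default_factory=dict)  # column -> [row labels]
    dropped: list = field(default_factory=list)  # zero-variance columns
    phenology_encoding: str = "durations"

    @property
    def labels(self) -> list:
        return list(self.values.index)


def environment_frame(
    summaries: Sequence[EnvironmentSummary],
    calendars: dict[str, PhenologyCalendar],
) -> pd.DataFrame:
    """Assemble environment rows + phenology dates into one DataFrame."""
    rows = []
    for s in summaries:
        cal = calendars[s.trial_code]
        rows.append(
            {
                "trial_code": s.trial_code,
                "sowing": pd.Timestamp(cal.sowing),
                "anthesis": pd.Timestamp(cal.anthesis),
                "grain_filling": pd.Timestamp(cal.grain_filling),
                "harvest": pd.Timestamp(cal.harvest),
                "gy": s.gy_mean,
                "d13c": np.nan if s.d13c_mean is None else s.d13c_mean,
                "sdd": s.sdd_mean,
                "tmax": s.tmax_mean,
                "vpdmax": s.vpdmax_mean,
                "swc": s.swc_mean,
            }
        )
    return pd.DataFrame(rows)


def build_feature_table(
    env: pd.DataFrame,
    phenology_encoding: str = "durations",
    normalization: str = "minmax",
    impute: bool = True,
) -> FeatureTable:
    """Normalized feature table for environment clustering.

    Parameters
    ----------
    env
        One row per environment with columns ``trial_code``, the four
        phenology dates (``sowing``, ``anthesis``, ``grain_filling``,
        ``harvest``), and ``gy, d13c, sdd, tmax, vpdmax, swc``.
    phenology_encoding
        ``"durations"`` (default) encodes the three inter-stage spans in
        days — raw calendar dates are not comparable across seasons —
        while ``"day-of-year"`` keeps each date's position in its year.
    normalization
        ``"minmax"`` (default) rescales each feature to [0, 1];
        ``"zscore"`` centers to mean 0, sd 1 (ddof=1).
    impute
        Replace missing values (typically a season without kernel Δ13C)
        by the column mean, recording which rows were imputed.
    """
    if len(env) < 2:
        raise ValueError("need at least 2 environments to build a feature table")
    if phenology_encoding not in {"durations", "day-of-year"}:
        raise ValueError(f"unknown phenology encoding {phenology_encoding!r}")
    if normalization not in {"minmax", "zscore"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    env = env.reset_index(drop=True)
    dates = {c: pd.to_datetime(env[c]) for c in
             ("sowing", "anthesis", "grain_filling", "harvest")}
    feat = {}
    if phenology_encoding == "durations":
        feat["days_sowing_to_anthesis"] = (dates["anthesis"] - dates["sowing"]).dt.days
        feat["days_anthesis_to_grain_filling"] = (
            dates["grain_filling"] - dates["anthesis"]
        ).dt.days
        feat["days_grain_filling_to_harvest"] = (
            dates["harvest"] - dates["grain_filling"]
        ).dt.days
    else:
        for c, s in dates.items():
            feat[f"doy_{c}"] = s.dt.dayofyear
    for c in TRAIT_FEATURES:
        feat[c] = env[c]
    raw = pd.DataFrame(feat, dtype=float)
    raw.index = pd.Index(env["trial_code"], name="trial_code")

    imputed: dict = {}
    for c in raw.columns:
        na = raw[c].isna()
        if na.any():
            if not impute:
                raise ValueError(f"column {c!r} has missing values and impute=False")
            if na.all():
                raise ValueError(f"column {c!r} is entirely missing")
            raw.loc[na, c] = raw[c].mean()
            imputed[c] = list(raw.index[na])

    dropped = [c for c in raw.columns if raw[c].nunique() <= 1]
    if dropped:
        warnings.warn(
            f"dropping zero-variance feature(s) {dropped}: normalization undefined",
            stacklevel=2,
        )
    kept = raw.drop(columns=dropped)

    if normalization == "zscore":
        center, scale = kept.mean(), kept.std(ddof=1)
        values = (kept - center) / scale
        scaling = pd.DataFrame({"center": center, "scale": scale})
    else:
        lo, rng = kept.min(), kept.max() - kept.min()
        values = (kept - lo) / rng
        scaling = pd.DataFrame({"center": lo, "scale": rng})
    return FeatureTable(
        raw=raw,
        values=values,
        normalization=normalization,
        scaling=scaling,
        imputed=imputed,
        dropped=dropped,
        phenology_encoding=phenology_encoding,
    )


# ---------------------------------------------------------------------------
# Ward.D2 agglomeration
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal-component projection of the normalized table."""

    scores: pd.DataFrame  # rows × components
    loadings: pd.DataFrame  # features × components
    explained_variance_ratio: np.ndarray  # all min(n-1, p) components; sums to 1


@dataclass
class ClusterResult:
    """Ward.D2 merge tree over environments.

    ``linkage`` uses the scipy convention: row ``[i, j, height, size]``
    merges clusters ``i`` and ``j`` (ids < n are original rows, id
    ``n + step`` is the cluster created at ``step``).  Heights are the
    Ward.D2 merge costs on the (non-squared) Euclidean distance scale
    and are nondecreasing.
    """

    linkage: np.ndarray
    labels: list
    feature_table: Optional[FeatureTable] = None
    pca: Optional[PCAResult] = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def assignments(self, k: int) -> pd.Series:
        return cut_groups(self, k)

    def newick(self) -> str:
        """Ultrametric Newick string; leaf depth equals its merge height."""
        n = len(self.labels)
        node_h = {i: 0.0 for i in range(n)}

        def render(node: int) -> str:
            if node < n:
                return str(self.labels[node]).replace(" ", "_")
            i, j, h, _ = self.linkage[node - n]
            i, j = int(i), int(j)
            return (
                f"({render(i)}:{h - node_h[i]:.6g},"
                f"{render(j)}:{h - node_h[j]:.6g})"
            )

        for step, (i, j, h, _) in enumerate(self.linkage):
            node_h[n + step] = float(h)
        return render(2 * n - 2) + ";"

    def to_dict(self) -> dict:
        return {
            "labels": list(map(str, self.labels)),
            "merges": [
                {"a": int(i), "b": int(j), "height": float(h), "size": int(s)}
                for i, j, h, s in self.linkage
            ],
            "newick": self.newick(),
        }


def _as_matrix(table) -> tuple[np.ndarray, list]:
    if isinstance(table, FeatureTable):
        return table.values.to_numpy(dtype=float), list(table.values.index)
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.index)
    arr = np.asarray(table, dtype=float)
    return arr, list(range(arr.shape[0]))


def ward_d2_linkage(table) -> ClusterResult:
    """Agglomerate rows by the Ward minimum-variance criterion (D2 form).

    Starting from pairwise Euclidean distances, cluster distances are
    updated with the Lance–Williams recurrence on squared distances

        d²(k, i∪j) = [(nᵢ+nₖ)d²(k,i) + (nⱼ+nₖ)d²(k,j) − nₖ d²(i,j)]
                     / (nᵢ+nⱼ+nₖ),

    and at each step the pair at minimal distance is merged, ties broken
    by the lowest cluster-index pair (original rows first, in row
    order).  Heights are √d² of the merged pair, so the tree matches R's
    ``hclust(method="ward.D2")`` on Euclidean distances.
    """
    X, labels = _as_matrix(table)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError(
            "table contains missing values; run build_feature_table (with "
            "imputation) before clustering"
        )
    n = X.shape[0]
    # squared Euclidean distances, keyed by frozen cluster-id pairs
    diff = X[:, None, :] - X[None, :, :]
    d2_full = np.einsum("ijk,ijk->ij", diff, diff)
    d2 = {(i, j): d2_full[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                i, j = active[a_idx], active[b_idx]
                key = (d2[(i, j)], i, j)
                if best is None or key < best:
                    best = key
        dmin, i, j = best
        merges[step] = [i, j, np.sqrt(max(dmin, 0.0)), sizes[i] + sizes[j]]
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            sk = sizes[k]
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            d2[(k, next_id)] = ((si + sk) * dik + (sj + sk) * djk - sk * dmin) / (
                si + sj + sk
            )
        sizes[next_id] = si + sj
        active = [a for a in active if a not in (i, j)] + [next_id]
        next_id += 1
    ft = table if isinstance(table, FeatureTable) else None
    return ClusterResult(linkage=merges, labels=labels, feature_table=ft)


def cut_groups(result: ClusterResult, k: int) -> pd.Series:
    """Cut the merge tree into ``k`` groups.

    Because Ward heights are nondecreasing, removing the ``k−1`` tallest
    merges is the same as stopping after the first ``n−k``.  Groups are
    numbered 1..k in order of their first-occurring row.
    """
    n = len(result.labels)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        i, j = int(result.linkage[step, 0]), int(result.linkage[step, 1])
        node = n + step
        parent[find(i)] = node
        parent[find(j)] = node
    roots: dict[int, int] = {}
    out = []
    for row in range(n):
        r = find(row)
        if r not in roots:
            roots[r] = len(roots) + 1
        out.append(roots[r])
    return pd.Series(out, index=pd.Index(result.labels, name="trial_code"), name="group")


def pca_projection(table, n_components: int = 2) -> PCAResult:
    """Principal components of the normalized table (SVD of centered data).

    Variance fractions are reported over *all* components and sum to 1.
    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive.
    """
    X, labels = _as_matrix(table)
    if isinstance(table, FeatureTable):
        cols = list(table.values.columns)
    elif isinstance(table, pd.DataFrame):
        cols = list(table.columns)
    else:
        cols = [f"f{i}" for i in range(X.shape[1])]
    if X.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} rows for {n_components} components"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: dominant loading of each component positive
    for c in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[c]))
        if Vt[c, pivot] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    total = float(np.sum(s**2))
    ratio = (s**2 / total) if total > 0 else np.full_like(s, 1.0 / s.size)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * s[:n_components]), index=labels, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=cols, columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, explained_variance_ratio=ratio)


def percent_change_contrast(
    table: FeatureTable,
    groups: pd.Series,
    reference,
) -> pd.DataFrame:
    """Per-feature percent change of each group mean vs. a reference group.

    Computed on the original (unscaled) feature values:
    ``100 · (group mean − reference mean) / |reference mean|``.  A
    reference mean of exactly 0 yields NaN for that feature (flagged by
    the caller-facing NaN rather than a bogus ratio).
    """
    groups = groups.reindex(table.raw.index)
    if groups.isna().any():
        raise ValueError("group assignments do not cover every table row")
    if (groups == reference).sum() == 0:
        raise ValueError(f"reference group {reference!r} is empty")
    means = table.raw.groupby(groups).mean()
    ref = means.loc[reference]
    out = {}
    for g in means.index:
        denom = ref.abs()
        pct = 100.0 * (means.loc[g] - ref) / denom
        pct[denom == 0] = np.nan
        out[g] = pct
    return pd.DataFrame(out)
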