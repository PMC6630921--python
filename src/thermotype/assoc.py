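"""Regression and correlation layer for trait–environment associations.

Linear fits serve the genotype-level SDD–GY/Δ13C relationships; the
environment-level grain-yield response to stress indices is fitted as a
two-parameter exponential decay ``y = a·exp(b·x)`` on the original
scale, so its r² is comparable with the linear fits.  The
multi-environment correlation structure is summarized as a
pairwise-complete Pearson matrix with the conventional significance
stars (* p<0.05, ** p<0.01) and no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RegressionFit",
    "CorrelationMatrix",
    "fit_linear",
    "fit_exponential",
    "pearson_matrix",
]


@dataclass
class RegressionFit:
    """One fitted association: model family, parameters, r², p, n."""

    model: str  # "linear" | "exponential"
    params: dict  # slope/intercept or a/b
    r2: float
    p_value: float
    n: int
    param_se: dict = field(default_factory=dict)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            return self.params["intercept"] + self.params["slope"] * x
        return self.params["a"] * np.exp(self.params["b"] * x)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "r2": self.r2,
            "p_value": self.p_value,
            "n": self.n,
        }


def _validate_xy(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"x and y lengths differ ({x.size} vs {y.size})")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} complete observations, got {x.size}")
    return x, y


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares y = intercept + slope·x.

    r² = 1 − SSE/SST; the p-value is the two-sided significance of the
    slope from its t statistic with n−2 degrees of freedom.
    """
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; linear fit is degenerate")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return RegressionFit(
        model="linear",
        params={"intercept": float(res.intercept), "slope": float(res.slope)},
        r2=r2,
        p_value=float(res.pvalue),
        n=int(x.size),
        param_se={"slope": float(res.stderr), "intercept": float(res.intercept_stderr)},
    )


def fit_exponential(x, y) -> RegressionFit:
    """Nonlinear least squares y = a·exp(b·x) on the original scale.

    Initialized from the log-linear fit (hence all y must be positive);
    r² = 1 − SSE/SST is computed on the original scale and may be ~0
    when the response is flat (b ≈ 0 reduces the model to a constant).
    The p-value tests b = 0 from its asymptotic standard error.
    """
    x, y = _validate_xy(x, y)
    if np.any(y <= 0):
        raise ValueError(
            "exponential fit needs positive responses for log-linear "
            "initialization; use a linear model or review the data"
        )
    b0, loga0 = np.polyfit(x, np.log(y), 1)
    try:
        popt, pcov = optimize.curve_fit(
            lambda t, a, b: a * np.exp(b * t),
            x,
            y,
            p0=[float(np.exp(loga0)), float(b0)],
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise ValueError(f"exponential fit did not converge: {exc}") from exc
    a, b = (float(v) for v in popt)
    resid = y - a * np.exp(b * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    dof = max(x.size - 2, 1)
    if se[1] > 0 and np.isfinite(se[1]):
        tstat = b / se[1]
        p = float(2 * stats.t.sf(abs(tstat), dof))
    else:
        p = float("nan")
    return RegressionFit(
        model="exponential",
        params={"a": a, "b": b},
        r2=r2,
        p_value=p,
        n=int(x.size),
        param_se={"a": float(se[0]), "b": float(se[1])},
    )


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson matrix with significance stars.

    ``r``, ``p`` and ``n_pairs`` are square DataFrames over
    ``variables``; ``stars`` holds "" / "*" / "**" per cell ("" on the
    diagonal).  Cells with fewer than 3 complete pairs carry NaN r and
    no p-value (flagged in ``insufficient``).
    """

    variables: list
    r: pd.DataFrame
    n_pairs: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    insufficient: list = field(default_factory=list)

    def cell(self, a: str, b: str) -> tuple[float, float, str]:
        return float(self.r.loc[a, b]), float(self.p.loc[a, b]), str(self.stars.loc[a, b])


def _star(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_matrix(table: pd.DataFrame, variables: Sequence[str]) -> CorrelationMatrix:
    """Pearson correlations among ``variables`` with pairwise deletion.

    Missing values (e.g. an environment without kernel isotope data)
    are dropped pair by pair, so each cell uses every complete pair of
    that variable couple.  p-values come from the t transform of r with
    ``n_pairs − 2`` degrees of freedom.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    insufficient = []
    for i in range(k):
        n[i, i] = int(table[variables[i]].notna().sum())
        for j in range(i + 1, k):
            sub = table[[variables[i], variables[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                insufficient.append((variables[i], variables[j]))
                continue
            rr, pp = stats.pearsonr(sub[variables[i]], sub[variables[j]])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    rdf = pd.DataFrame(r, index=variables, columns=variables)
    pdf = pd.DataFrame(p, index=variables, columns=variables)
    ndf = pd.DataFrame(n, index=variables, columns=variables)
    stars = pdf.map(_star)
    np.fill_diagonal(stars.values, "")  # r = 1 on the diagonal is not a finding
    np.fill_diagonal(pdf.values, 0.0)
    return CorrelationMatrix(
        variables=variables, r=rdf, n_pairs=ndf, p=pdf, stars=stars,
        insufficient=insufficient,
    )
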