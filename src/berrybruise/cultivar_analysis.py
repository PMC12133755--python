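"""Cultivar-level susceptibility screen: aggregation, two-cluster split,
Welch's t-test, and the ratio-vs-firmness regression.

The screen mirrors how breeders triage germplasm: average per-sample
bruising ratios to one mean per cultivar-year, separate cultivars into
bruise-resistant and bruise-susceptible groups by two-cluster K-means on
those means, report the separating threshold, and validate the split with
Welch's t-test — both on the ratios and on an independent firmness
covariate (YM20_BrSt, the force-deformation slope up to 20% of burst
strain, in MPa/%). Firmer cultivars are expected to bruise less, so the
resistant cluster should show significantly higher firmness.

In one dimension, K=2 K-means has an exact solution: the optimal
two-cluster partition is contiguous in sorted order, so scanning the n-1
sorted split points for minimum within-cluster sum of squares finds the
global optimum deterministically — no initialization, no iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateClusteringError",
    "ClusterResult",
    "WelchResult",
    "LinearFit",
    "YearScreen",
    "aggregate",
    "two_means_cluster",
    "welch_t_test",
    "fit_linear",
    "screen_report",
]


class DegenerateClusteringError(ValueError):
    """Two-cluster split is undefined (all values identical)."""


def aggregate(samples: pd.DataFrame, ratio_col: str = "ratio") -> pd.DataFrame:
    """Collapse per-sample ratios to one record per (cultivar, year).

    Null ratios (failed berries) are excluded and counted; cultivar-years
    with no valid sample are dropped with a warning. Returns columns
    ``cultivar, year, mean_ratio, n_samples, n_null`` (+ ``firmness`` if
    present, taken as the per-group mean).
    """
    required = {"cultivar", "year", ratio_col}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table lacks columns {sorted(missing)}")
    rows = []
    for (cultivar, year), grp in samples.groupby(["cultivar", "year"], sort=True):
        vals = grp[ratio_col].dropna()
        n_null = len(grp) - len(vals)
        if len(vals) == 0:
            warnings.warn(f"cultivar {cultivar!r} year {year!r} has no valid ratio; dropped")
            continue
        row = {
            "cultivar": cultivar,
            "year": year,
            "mean_ratio": float(vals.mean()),
            "n_samples": int(len(vals)),
            "n_null": int(n_null),
        }
        if "firmness" in grp.columns:
            firm = grp["firmness"].dropna()
            row["firmness"] = float(firm.mean()) if len(firm) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClusterResult:
    """Two-group split of cultivar means.

    ``threshold`` is the midpoint of the two centroids; ``boundary_midpoint``
    is the midpoint between the closest cross-cluster members (the widest-gap
    reading of a separating value). Labels are in input order.
    """

    labels: np.ndarray  # "resistant" | "susceptible", input order
    centroids: tuple[float, float]  # (resistant, susceptible)
    threshold: float
    boundary_midpoint: float
    inertia: float


def two_means_cluster(means: Sequence[float]) -> ClusterResult:
    """Exact 1-D K=2 K-means via the sorted split-point scan.

    Scans all n-1 contiguous splits of the sorted values and keeps the one
    minimizing within-cluster sum of squares; this is the global K-means
    optimum in one dimension. Deterministic and order-invariant.
    """
    values = np.asarray(means, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least 2 values to cluster")
    if np.ptp(values) == 0:
        raise DegenerateClusteringError("all values identical; no two-cluster split")
    order = np.argsort(values, kind="stable")
    s = values[order]
    n = len(s)
    csum = np.cumsum(s)
    csum2 = np.cumsum(s**2)
    best_k, best_wcss = 1, np.inf
    for k in range(1, n):
        lo_sum, lo_sum2 = csum[k - 1], csum2[k - 1]
        hi_sum, hi_sum2 = csum[-1] - lo_sum, csum2[-1] - lo_sum2
        wcss = (lo_sum2 - lo_sum**2 / k) + (hi_sum2 - hi_sum**2 / (n - k))
        if wcss < best_wcss - 1e-15:
            best_k, best_wcss = k, wcss
    lo_mean = float(csum[best_k - 1] / best_k)
    hi_mean = float((csum[-1] - csum[best_k - 1]) / (n - best_k))
    labels = np.empty(n, dtype=object)
    labels[order[:best_k]] = "resistant"
    labels[order[best_k:]] = "susceptible"
    return ClusterResult(
        labels=labels,
        centroids=(lo_mean, hi_mean),
        threshold=0.5 * (lo_mean + hi_mean),
        boundary_midpoint=0.5 * (s[best_k - 1] + s[best_k]),
        inertia=float(best_wcss),
    )


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances, unbiased s²).

    t = (m_a - m_b) / sqrt(s²_a/n_a + s²_b/n_b); degrees of freedom by
    Welch–Satterthwaite; p from the Student-t two-sided tail. Requires
    n >= 2 in each sample and nonzero variance in at least one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance; t undefined")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    n: int


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y on x with R² and residual RMSE.

    R² = 1 - SS_res/SS_tot, defined as 0 when SS_tot = 0 (constant y);
    constant x is an error. RMSE is the root mean squared residual against
    the fitted line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    design = np.stack([x, np.ones_like(x)], axis=1)
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / len(x)))
    return LinearFit(float(slope), float(intercept), float(r2), rmse, len(x))


@dataclass
class YearScreen:
    """One year's screen: the cluster split plus firmness validation."""

    year: object
    table: pd.DataFrame  # cultivar, mean_ratio, n_samples, label (+ firmness)
    clusters: ClusterResult
    ratio_test: WelchResult | None
    firmness_test: WelchResult | None
    firmness_fit: LinearFit | None


def screen_report(
    samples: pd.DataFrame,
    ratio_col: str = "ratio",
    pooled: bool = False,
    min_cultivars: int = 4,
) -> dict[object, YearScreen]:
    """Run the per-year susceptibility screen on a per-sample ratio table.

    For each year with at least ``min_cultivars`` cultivars: cluster the
    cultivar mean ratios into resistant/susceptible, Welch-test the mean
    ratios between labels, and — when a ``firmness`` column is present —
    Welch-test firmness between labels and fit the mean-ratio-on-firmness
    regression. ``pooled = True`` treats all years as one stratum keyed
    ``"pooled"``. Years with too few cultivars are skipped with a warning.
    """
    agg = aggregate(samples, ratio_col=ratio_col)
    if pooled:
        agg = agg.assign(year="pooled")
    out: dict[object, YearScreen] = {}
    for year, grp in agg.groupby("year", sort=True):
        grp = grp.reset_index(drop=True)
        if len(grp) < min_cultivars:
            warnings.warn(f"year {year!r}: only {len(grp)} cultivars; screen skipped")
            continue
        clusters = two_means_cluster(grp["mean_ratio"].to_numpy())
        table = grp.assign(label=clusters.labels)
        res = table.loc[table["label"] == "resistant", "mean_ratio"]
        sus = table.loc[table["label"] == "susceptible", "mean_ratio"]
        ratio_test = (
            welch_t_test(res, sus) if len(res) >= 2 and len(sus) >= 2 else None
        )
        firmness_test = firmness_fit = None
        if "firmness" in table.columns and table["firmness"].notna().all():
            fr = table.loc[table["label"] == "resistant", "firmness"]
            fs = table.loc[table["label"] == "susceptible", "firmness"]
            if len(fr) >= 2 and len(fs) >= 2:
                firmness_test = welch_t_test(fr, fs)
            if table["firmness"].nunique() > 1 and len(table) >= 3:
                firmness_fit = fit_linear(table["firmness"], table["mean_ratio"])
        out[year] = YearScreen(year, table, clusters, ratio_test, firmness_test, firmness_fit)
    return out
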