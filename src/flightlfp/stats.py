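"""Group comparisons across flight states and acceleration-binned trends.

Group comparison follows the two-branch protocol: one-way ANOVA when every
group passes a Shapiro-Wilk normality test at alpha = 0.05, otherwise
Kruskal-Wallis. Trend analysis bins a per-window metric by tangential
acceleration over [-6, 6] m/s^2, fits a least-squares polynomial to the
bin means and reports t-based 95% confidence bands; the gamma-PSD trend
uses order 1 (optionally 2) and the clustering-coefficient trend order 2
(U-shape).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "bin_by_acceleration",
           "TrendFit", "polyfit_trend"]

ALPHA = 0.05


@dataclass
class GroupComparison:
    test: str              # "anova" | "kruskal"
    statistic: float
    pvalue: float
    stars: str             # "", "*", "**", "***"
    normal: list[bool]     # per-group Shapiro-Wilk outcome


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(*groups: np.ndarray) -> GroupComparison:
    """ANOVA if all groups pass Shapiro-Wilk normality, else Kruskal-Wallis.

    A zero-variance group forces the non-parametric branch with a warning;
    fully identical data across groups returns p = 1 (no evidence of any
    difference).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs at least 3 observations")

    degenerate = any(g.std() == 0 for g in groups)
    if degenerate:
        warnings.warn("zero-variance group: forcing non-parametric test")
        normal = [False] * len(groups)
    else:
        normal = [bool(sps.shapiro(g).pvalue >= ALPHA) for g in groups]

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupComparison("kruskal", 0.0, 1.0, "", normal)

    if all(normal):
        res = sps.f_oneway(*groups)
        name = "anova"
    else:
        res = sps.kruskal(*groups)
        name = "kruskal"
    p = float(res.pvalue)
    return GroupComparison(name, float(res.statistic), p,
                           significance_stars(p), normal)


def bin_by_acceleration(values: np.ndarray, accelerations: np.ndarray,
                        bin_range: tuple[float, float] = (-6.0, 6.0),
                        width: float = 0.5,
                        min_count: int = 5) -> pd.DataFrame:
    """Half-open acceleration bins [lo, lo + width) with per-bin means.

    Bins with fewer than ``min_count`` observations are dropped. Returns a
    frame with bin_center, mean, count.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    values = np.asarray(values, dtype=float)
    acc = np.asarray(accelerations, dtype=float)
    if values.size == 0:
        return pd.DataFrame(columns=["bin_center", "mean", "count"])
    lo, hi = bin_range
    edges = np.arange(lo, hi + width / 2, width)
    idx = np.floor((acc - lo) / width).astype(int)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n >= min_count:
            rows.append({"bin_center": lo + (b + 0.5) * width,
                         "mean": float(values[sel].mean()), "count": n})
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    """Polynomial trend over binned means with pointwise 95% CI."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    coefficients: np.ndarray       # ascending order: c0 + c1 x + c2 x^2 ...
    coeff_se: np.ndarray
    coeff_ci: np.ndarray           # (order+1, 2), 95%
    ci_band: np.ndarray            # (n_bins, 2) pointwise 95% CI of the mean
    fitted: np.ndarray
    r_squared: float

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients[::-1], np.asarray(x, dtype=float))


def polyfit_trend(binned: pd.DataFrame, order: int = 1) -> TrendFit:
    """Least-squares polynomial on bin means with t-based 95% intervals.

    Requires at least ``order + 2`` bins; a rank-deficient design raises.
    Coefficient sign tests are exposed through ``coeff_ci``.
    """
    import statsmodels.api as sm

    x = np.asarray(binned["bin_center"], dtype=float)
    y = np.asarray(binned["mean"], dtype=float)
    if x.size < order + 2:
        raise ValueError(f"need at least {order + 2} bins for order {order}")
    X = np.vander(x, order + 1, increasing=True)
    if np.linalg.matrix_rank(X) < order + 1:
        raise ValueError("rank-deficient design (duplicate bin centers?)")
    model = sm.OLS(y, X).fit()
    pred = model.get_prediction(X)
    band = pred.conf_int(alpha=ALPHA)
    return TrendFit(
        bin_centers=x,
        bin_means=y,
        coefficients=np.asarray(model.params, dtype=float),
        coeff_se=np.asarray(model.bse, dtype=float),
        coeff_ci=np.asarray(model.conf_int(alpha=ALPHA), dtype=float),
        ci_band=np.asarray(band, dtype=float),
        fitted=np.asarray(model.fittedvalues, dtype=float),
        r_squared=float(model.rsquared),
    )
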