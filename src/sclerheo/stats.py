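"""Cohort assembly and correlation statistics.

Per region and elastic parameter, the association between volume-mean
birefringence and the parameter is tested with the two-sided Pearson
product-moment correlation (t distribution with n-2 df); significance is
flagged with ``*``, ``**``, ``***`` at p < 0.05, 0.01, 0.001, and an
ordinary least-squares line is reported for plotting.  No multiple-testing
correction is applied by default; Holm adjustment is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "pearson_test",
    "linear_regression",
    "build_results_table",
    "ELASTIC_PARAMS",
    "REGIONS",
]

REGIONS = ("A", "B", "C", "D")
ELASTIC_PARAMS = ("tangent_modulus_0", "structural_stiffness", "power_b")

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    """Significance label: p strictly below 0.001/0.01/0.05."""
    for thr, label in _STAR_THRESHOLDS:
        if p < thr:
            return label
    return ""


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    stars: str
    slope: float
    intercept: float


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Two-sided Pearson correlation test with OLS line.

    ``t = r sqrt((n-2)/(1-r^2))`` against Student t with n-2 df.  Requires
    n >= 3 finite samples and nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    res = sps.pearsonr(x, y)
    slope, intercept = linear_regression(x, y)
    return CorrelationResult(
        r=float(res.statistic),
        p=float(res.pvalue),
        n=len(x),
        stars=stars_for_p(float(res.pvalue)),
        slope=slope,
        intercept=intercept,
    )


def linear_regression(x: Sequence[float], y: Sequence[float]):
    """Ordinary least-squares line ``y = slope * x + intercept``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.std(x) == 0:
        raise ValueError("need >= 2 samples with nonzero x variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept)


def build_results_table(
    cohort: pd.DataFrame,
    parameters: Sequence[str] = ELASTIC_PARAMS,
    regions: Sequence[str] = REGIONS,
    holm: bool = False,
) -> pd.DataFrame:
    """Region x parameter grid of birefringence correlations.

    ``cohort`` needs columns ``region``, ``mean_birefringence`` and the
    parameter columns.  Regions with fewer than 3 samples are flagged
    (NaN results) rather than fatal.  With ``holm=True``, p-values (and
    stars) are Holm-adjusted across the grid.
    """
    rows = []
    for region in regions:
        sub = cohort[cohort["region"] == region]
        for param in parameters:
            if len(sub) < 3:
                rows.append(
                    {
                        "region": region,
                        "parameter": param,
                        "r": np.nan,
                        "p": np.nan,
                        "n": len(sub),
                        "stars": "",
                        "slope": np.nan,
                        "intercept": np.nan,
                        "flag": "insufficient_n",
                    }
                )
                continue
            res = pearson_test(sub["mean_birefringence"], sub[param])
            rows.append(
                {
                    "region": region,
                    "parameter": param,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "stars": res.stars,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "flag": "",
                }
            )
    table = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        ok = table["p"].notna()
        if ok.any():
            adj = multipletests(table.loc[ok, "p"], method="holm")[1]
            table.loc[ok, "p_holm"] = adj
            table.loc[ok, "stars"] = [stars_for_p(p) for p in adj]
    return table
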