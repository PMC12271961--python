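"""Correlation and simple regression between daytime usage and the
nocturnal inactivity gap, per demographic subgroup.

The unit of analysis is the participant: each contributes their mean daily
usage (total and per app category) and their mean nightly longest gap.
Pearson correlation is the default (Spearman available for heavily skewed
subgroups); the regression is ordinary least squares of gap on usage, with
the t-based slope p value on n−2 df.  Raw p values are reported by default;
Benjamini–Hochberg adjustment across the subgroup × predictor grid is
optional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .taxonomy import CATEGORIES

logger = logging.getLogger(__name__)

#: Usage predictors reported per subgroup: total and categories A–E
#: (the unknown category is noise by construction and not reported).
PREDICTORS = ("total", "A", "B", "C", "D", "E")

_PREDICTOR_COLS = {
    "total": "mean_total_hours",
    **{c: f"mean_hours_{c}" for c in CATEGORIES if c != "unknown"},
}


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and p value between two vectors.

    Pearson uses the product-moment formula with t-reference p; Spearman is
    Pearson on mid-ranks.  Zero variance on either side is an error naming
    the degenerate side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float


def ols_fit(x, y) -> OLSResult:
    """Simple least-squares fit of y on x; R² = 1 − SSE/SST."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    if np.ptp(y) == 0:
        # Flat response: exact zero slope, define R² = 0 and p undefined -> 1.
        return OLSResult(0.0, float(y[0]), 0.0, 1.0)
    return OLSResult(
        float(res.slope), float(res.intercept),
        float(res.rvalue ** 2), float(res.pvalue))


def subgroup_associations(
    usage_summary: pd.DataFrame,
    night_summary: pd.DataFrame,
    profiles: pd.DataFrame,
    grouping: str,
    method: str = "pearson",
    adjust_bh: bool = False,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-subgroup association of usage predictors with the mean night gap.

    Joins the three participant-level tables, then for each non-excluded
    level of *grouping* and each predictor in :data:`PREDICTORS` reports
    n, r, p, slope, intercept and R².  Subgroups with fewer than *min_n*
    joinable participants are skipped with a warning.
    """
    from .events import GROUPING_LEVELS

    merged = usage_summary.merge(
        night_summary[["participant_id", "mean_gap_hours"]], on="participant_id"
    ).merge(profiles[["participant_id", grouping]], on="participant_id")
    if merged.empty:
        raise ValueError("no participants joinable across usage, nights and profiles")
    merged[grouping] = merged[grouping].astype(str)

    rows = []
    for level in GROUPING_LEVELS[grouping]:
        if level == "excluded":
            continue
        sub = merged[merged[grouping] == level]
        if len(sub) == 0:
            continue
        if len(sub) < min_n:
            logger.warning("subgroup %s=%s has n=%d < %d; skipped",
                           grouping, level, len(sub), min_n)
            continue
        y = sub["mean_gap_hours"].to_numpy(float)
        for predictor in PREDICTORS:
            x = sub[_PREDICTOR_COLS[predictor]].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("subgroup %s=%s predictor %s degenerate; skipped",
                               grouping, level, predictor)
                continue
            r, p = correlate(x, y, method=method)
            fit = ols_fit(x, y)
            rows.append({
                "grouping": grouping,
                "subgroup": level,
                "predictor": predictor,
                "n": len(sub),
                "r": r,
                "p": p,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_slope": fit.p_slope,
            })
    out = pd.DataFrame(rows)
    if adjust_bh and len(out):
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
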