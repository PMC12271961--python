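"""Group-comparison battery: medians/IQRs, distributional screening,
Kruskal–Wallis with tie correction, and Dunn post hoc pairwise tests.

The battery is deliberately nonparametric: usage durations and inactivity
gaps are skewed and often tied, so locations are summarized as medians with
first/third quartiles and compared with the tie-corrected Kruskal–Wallis
H statistic (chi-square reference, k−1 df).  Normality (Shapiro–Wilk) and
homogeneity of variance (Brown–Forsythe) checks are reported for screening
but never gate the rank test.

Dunn's z for groups i, j with pooled mid-ranks is

    z_ij = (rbar_i − rbar_j) / sqrt((N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j))

with T = t³ − t summed over tie groups; two-sided normal p values, Holm-
adjusted by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def median_iqr(values) -> tuple[float, float, float]:
    """Median and first/third quartiles (linear-interpolation convention)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median_iqr requires at least one value")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool
    degenerate: bool = False


def normality_check(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk screening for one group (3 ≤ n ≤ 5000)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality check requires n >= 3")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable beyond n = 5000")
    if np.ptp(x) == 0:
        return NormalityResult(np.nan, np.nan, False, degenerate=True)
    stat, p = stats.shapiro(x)
    return NormalityResult(float(stat), float(p), bool(p >= alpha))


def variance_homogeneity(groups) -> tuple[float, float]:
    """Brown–Forsythe (median-centered Levene) test across groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    w, p = stats.levene(*groups, center="median")
    return float(w), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    """Σ(t³ − t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float
    degenerate: bool = False


def kruskal_wallis(groups, method: str = "chi2", n_permutations: int = 10_000,
                   seed: int | None = None) -> KWResult:
    """Tie-corrected Kruskal–Wallis test across k ≥ 2 groups.

    H is computed on pooled mid-ranks and divided by the tie correction
    1 − ΣT/(N³−N).  ``method='chi2'`` uses the k−1-df chi-square reference;
    ``method='permutation'`` estimates p by label permutation (intended for
    small samples, n ≤ ~30).  A pooled sample with a single distinct value
    is degenerate: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return KWResult(0.0, k - 1, 1.0, degenerate=True)

    h = _h_statistic(pooled, sizes)
    if method == "chi2":
        p = float(stats.chi2.sf(h, k - 1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        work = pooled.copy()
        for _ in range(n_permutations):
            rng.shuffle(work)
            if _h_statistic(work, sizes) >= h - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KWResult(float(h), k - 1, p)


def _h_statistic(pooled: np.ndarray, sizes: np.ndarray) -> float:
    """Tie-corrected H on the pooled sample laid out group by group."""
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum(sizes)
    mean_ranks = [ranks[b - s:b].mean() for s, b in zip(sizes, bounds)]
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(
        sizes * (np.asarray(mean_ranks) - (n_total + 1) / 2.0) ** 2)
    correction = 1.0 - _tie_term(pooled) / (n_total ** 3 - n_total)
    return h / correction


def dunn_posthoc(groups, adjustment: str = "holm",
                 labels: list | None = None) -> pd.DataFrame:
    """Dunn's pairwise rank-mean z tests after a Kruskal–Wallis test.

    Returns one row per unordered pair with ``z``, two-sided ``p_raw`` and
    ``p_adjusted`` (``holm`` default; ``bonferroni`` and ``none``
    available).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = list(range(k))
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum(sizes)
    mean_ranks = np.array([ranks[b - s:b].mean() for s, b in zip(sizes, bounds)])

    if np.ptp(pooled) == 0:
        var_term = 0.0
    else:
        var_term = (n_total * (n_total + 1) / 12.0
                    - _tie_term(pooled) / (12.0 * (n_total - 1)))

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        denom = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p_raw = float(2 * stats.norm.sf(abs(z)))
        rows.append((labels[i], labels[j], float(z), p_raw))
    out = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p_raw"])

    if adjustment == "none":
        out["p_adjusted"] = out["p_raw"]
    elif adjustment in ("holm", "bonferroni"):
        out["p_adjusted"] = multipletests(out["p_raw"], method=adjustment)[1]
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return out


@dataclass
class GroupTestResult:
    """Comparison of one variable across the levels of one grouping."""

    variable: str
    grouping: str
    summary: pd.DataFrame        # level, n, median, q1, q3, shapiro_p
    H: float
    df: int
    p_value: float
    levene_W: float
    levene_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    degenerate: bool = False


def compare_groups(
    values: pd.DataFrame,
    profiles: pd.DataFrame,
    grouping: str,
    variable: str,
    adjustment: str = "holm",
) -> GroupTestResult:
    """Run the full battery for one variable across one demographic grouping.

    *values* has columns ``participant_id`` and *variable*.  Participants in
    the ``excluded`` level are dropped, as are levels left empty; fewer than
    two usable levels is an error.
    """
    merged = values.merge(
        profiles[["participant_id", grouping]], on="participant_id", how="inner")
    merged = merged.dropna(subset=[variable])
    merged[grouping] = merged[grouping].astype(str)
    merged = merged[merged[grouping] != "excluded"]

    from .events import GROUPING_LEVELS

    level_order = [lv for lv in GROUPING_LEVELS[grouping] if lv != "excluded"]
    present = [lv for lv in level_order if (merged[grouping] == lv).any()]
    dropped = [lv for lv in level_order if lv not in present]
    if dropped:
        logger.info("grouping %s: empty levels dropped: %s", grouping, dropped)
    if len(present) < 2:
        raise ValueError(
            f"grouping {grouping!r} has fewer than two usable levels with data")

    group_values = [
        merged.loc[merged[grouping] == lv, variable].to_numpy(float) for lv in present
    ]
    rows = []
    for lv, g in zip(present, group_values):
        med, q1, q3 = median_iqr(g)
        if 3 <= g.size <= 5000 and np.ptp(g) > 0:
            sh_p = normality_check(g).p_value
        else:
            sh_p = np.nan
        rows.append((lv, g.size, med, q1, q3, sh_p))
    summary = pd.DataFrame(
        rows, columns=["level", "n", "median", "q1", "q3", "shapiro_p"])

    if all(g.size >= 2 for g in group_values):
        lev_w, lev_p = variance_homogeneity(group_values)
    else:
        lev_w, lev_p = np.nan, np.nan

    kw = kruskal_wallis(group_values)
    pairwise = dunn_posthoc(group_values, adjustment=adjustment, labels=present)
    return GroupTestResult(
        variable=variable,
        grouping=grouping,
        summary=summary,
        H=kw.H,
        df=kw.df,
        p_value=kw.p_value,
        levene_W=lev_w,
        levene_p=lev_p,
        pairwise=pairwise,
        degenerate=kw.degenerate,
    )
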