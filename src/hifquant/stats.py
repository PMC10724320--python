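"""Group summaries and all-pairs comparison of specimen positivity.

Groups of per-specimen positivity percentages are compared with Tamhane's
T2 procedure: for every pair of groups a Welch-type t statistic

    t = (m_i - m_j) / sqrt(s_i^2/n_i + s_j^2/n_j)

with Welch–Satterthwaite degrees of freedom, two-sided p from the t
distribution, and a Šidák family adjustment p_adj = 1 - (1 - p)^m over the
m = k(k-1)/2 pairs.  The procedure is valid under unequal sample sizes and
unequal variances, which is exactly the situation here (e.g. 55 primary
pterygia vs 6 recurrences vs 20 controls).

Also provides the report-level arithmetic used alongside: integer positive-
specimen percentages and marker ratios at two significant figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "PairwiseComparison",
    "group_summary",
    "tamhane_t2",
    "positive_fraction",
    "mean_ratio",
    "round_sig",
    "correlate",
]


@dataclass
class GroupSample:
    """One group's positivity values with its summary statistics."""

    label: str
    values: np.ndarray
    n: int
    mean: float
    sd: float  # sample SD (n-1 denominator); 0.0 for n == 1


def group_summary(values, label: str = "") -> GroupSample:
    """Mean and sample standard deviation of one group.

    Raises on empty input; a single value has sd 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("group_summary requires at least one value")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSample(label=label, values=arr, n=int(arr.size), mean=float(arr.mean()), sd=sd)


@dataclass
class PairwiseComparison:
    """One Tamhane-T2 pairwise result."""

    pair: tuple[str, str]
    t_statistic: float
    welch_df: float
    p_raw: float
    p_adjusted: float
    significant: bool


_P_FLOOR = 1e-300  # keep p in (0, 1] even for overwhelming effects


def _welch_pair(a: GroupSample, b: GroupSample) -> tuple[float, float, float]:
    va = a.sd**2 / a.n
    vb = b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0.0:
        # zero variance in both groups: identical values give p = 1,
        # separated constants an (effectively) zero p
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        t = math.inf if a.mean > b.mean else -math.inf
        return t, float(a.n + b.n - 2), _P_FLOOR
    t = (a.mean - b.mean) / math.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, max(min(p, 1.0), _P_FLOOR)


def tamhane_t2(groups: list[GroupSample], alpha: float = 0.05) -> list[PairwiseComparison]:
    """All-pairs Tamhane T2 comparisons at family-wise level ``alpha``.

    Requires >= 2 groups, each with n >= 2.  Significance uses the strict
    inequality p_adj < alpha.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has n < 2; inference undefined")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for a, b in combinations(groups, 2):
        t, df, p = _welch_pair(a, b)
        p_adj = min(1.0, 1.0 - (1.0 - p) ** m)
        p_adj = max(p_adj, p)  # guard against rounding below p_raw for tiny p
        out.append(
            PairwiseComparison(
                pair=(a.label, b.label),
                t_statistic=t,
                welch_df=df,
                p_raw=p,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return out


def positive_fraction(n_positive: int, n_total: int) -> int:
    """Percentage of positive specimens, rounded half-up to an integer.

    e.g. 28 of 55 -> 51, 19 of 28 -> 68, 20 of 20 -> 100.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must be in [0, n_total]")
    return int(math.floor(100.0 * n_positive / n_total + 0.5))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half-up (decimal arithmetic)."""
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    shift = sig - 1 - int(math.floor(math.log10(abs(x))))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def mean_ratio(mean_numerator: float, mean_denominator: float) -> float:
    """Ratio of two group means at two significant figures (e.g. 38/11 -> 3.5)."""
    if mean_denominator <= 0:
        raise ValueError("denominator mean must be positive")
    return round_sig(mean_numerator / mean_denominator, 2)


def correlate(x, y) -> dict[str, float]:
    """Pearson and Spearman correlation between paired measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }
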