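"""Evaluation of ranked gene lists: cumulative precision/recall/F curves,
maximum F-measure, recall-at-rank curves, and a paired Wilcoxon signed-rank
comparison between two methods' curves.

At rank cutoff n, with T_n the number of top-n genes found in the validation
set, E_n the number extracted (E_n = n for the package's own lists) and C the
validation-set size:

    R(n) = T_n / C,    P(n) = T_n / E_n,    F(n) = 2 P(n) R(n) / (P(n) + R(n))
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .corpus import ValidationSet
from .exceptions import DegenerateDataError, ValidationError
from .scoring import RankedGeneList

#: nonzero-pair count at or below which the exact sign-flip null is used
EXACT_WILCOXON_LIMIT = 20

__all__ = [
    "PRPoint",
    "WilcoxonResult",
    "pr_curve",
    "pr_table",
    "max_f",
    "recall_curve",
    "wilcoxon_compare",
]


@dataclass(frozen=True)
class PRPoint:
    n: int
    t_n: int
    e_n: int
    precision: float
    recall: float
    f: float


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: rank sum of positive differences
    pvalue: float  # one-sided, alternative: first curve exceeds the second
    n_pairs: int  # nonzero differences retained
    method: str  # "exact" or "normal"


def pr_curve(
    ranked: RankedGeneList, validation: ValidationSet
) -> list[PRPoint]:
    """Cumulative precision/recall/F at every rank cutoff n = 1..len(ranked)."""
    if len(ranked) == 0:
        raise ValidationError("cannot evaluate an empty ranked list")
    c = len(validation)
    points: list[PRPoint] = []
    hits = 0
    for n, gene_id in enumerate(ranked.gene_ids, start=1):
        if gene_id in validation:
            hits += 1
        precision = hits / n
        recall = hits / c
        f = 2 * precision * recall / (precision + recall) if hits else 0.0
        points.append(PRPoint(n, hits, n, precision, recall, f))
    return points


def pr_table(curve: Sequence[PRPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n": [p.n for p in curve],
            "t_n": [p.t_n for p in curve],
            "e_n": [p.e_n for p in curve],
            "precision": [p.precision for p in curve],
            "recall": [p.recall for p in curve],
            "f": [p.f for p in curve],
        }
    )


def max_f(curve: Sequence[PRPoint]) -> tuple[float, int]:
    """Maximum F over the curve and the smallest rank attaining it."""
    if not curve:
        raise ValidationError("empty precision/recall curve")
    best = curve[0]
    for point in curve[1:]:
        if point.f > best.f:
            best = point
    return best.f, best.n


def recall_curve(
    ranked: RankedGeneList, validation: ValidationSet
) -> np.ndarray:
    """R(n) for n = 1..len(ranked); nondecreasing by construction."""
    c = len(validation)
    hits = np.fromiter(
        (1 if g in validation else 0 for g in ranked.gene_ids),
        dtype=float,
        count=len(ranked),
    )
    return np.cumsum(hits) / c


def _exact_upper_tail(double_ranks: np.ndarray, double_w: int) -> float:
    """P(W+ >= w) under uniform sign flips, by dynamic programming over the
    (possibly tied, hence half-integer) rank multiset, doubled to integers."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return float(counts[double_w:].sum() / 2 ** len(double_ranks))


def wilcoxon_compare(
    curve_a: Sequence[float], curve_b: Sequence[float]
) -> WilcoxonResult:
    """One-sided paired Wilcoxon signed-rank test that curve_a exceeds curve_b.

    Both curves are truncated to the shorter length and paired rank-by-rank.
    Zero differences are dropped.  With at most ``EXACT_WILCOXON_LIMIT``
    nonzero pairs the null distribution of W+ is computed exactly by sign
    enumeration (tie-aware); beyond that a normal approximation with tie
    correction is used.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    m = min(a.size, b.size)
    if m == 0:
        raise ValidationError("empty curve")
    diffs = a[:m] - b[:m]
    diffs = diffs[diffs != 0.0]
    if diffs.size == 0:
        raise DegenerateDataError(
            "all paired differences are zero; the comparison is degenerate"
        )
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    n = diffs.size

    if n <= EXACT_WILCOXON_LIMIT:
        double_ranks = np.rint(2 * ranks).astype(int)
        pvalue = _exact_upper_tail(double_ranks, int(round(2 * w_plus)))
        return WilcoxonResult(w_plus, pvalue, n, "exact")

    mean = n * (n + 1) / 4.0
    variance = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    variance -= (tie_counts**3 - tie_counts).sum() / 48.0
    if variance <= 0:
        raise DegenerateDataError("zero variance in signed-rank statistic")
    z = (w_plus - mean) / np.sqrt(variance)
    return WilcoxonResult(w_plus, float(norm.sf(z)), n, "normal")
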