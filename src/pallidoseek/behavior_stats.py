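"""Behavioral endpoint statistics.

Devaluation testing (exact two-sided Wilcoxon signed-rank on paired
valued/devalued response counts), nonparametric group comparisons
(Kruskal-Wallis omnibus with Dunn's pairwise posthoc z tests,
Bonferroni-adjusted), and two-bottle-choice evaporation normalization.

The signed-rank test drops zero differences (classic Wilcoxon
convention) and is exact — computed from the full null distribution of
the positive-rank sum — up to n = 25 informative pairs, switching to
the tie-corrected normal approximation above that.  Average ranks are
used for tied magnitudes; the distribution is evaluated on doubled
ranks so half-integer ranks stay on an integer lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

EXACT_MAX_N = 25


@dataclass
class DevaluationResult:
    """Paired valued/devalued counts with signed-rank test output.

    ``devaluation_index`` is devalued/(valued+devalued) per subject
    (0.5 = insensitive to devaluation, < 0.5 = goal-directed shift);
    NaN where a subject produced no responses at all.
    """

    valued: np.ndarray
    devalued: np.ndarray
    statistic: float          # W+ = sum of ranks of positive differences
    p_value: float
    devaluation_index: np.ndarray
    n_informative: int        # pairs remaining after dropping zeros
    all_tied: bool
    method: str               # "exact" | "normal_approx" | "degenerate"


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_adjusted: float


@dataclass
class GroupComparison:
    labels: list[str]
    statistic: float          # Kruskal-Wallis H (tie-corrected)
    p_value: float
    posthoc: list[PairwiseResult]
    all_tied: bool = False


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Null PMF of the positive-rank sum on the doubled-rank lattice.

    Under H0 each difference is independently positive with probability
    1/2, so the rank sum is a convolution of {0, r} point masses.
    """
    total = int(doubled_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def exact_signed_rank(diffs: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided signed-rank test; returns (W+, p, method).

    Zero differences are dropped.  All-zero input yields p = 1
    ("degenerate").  Exact for n <= 25 informative pairs, otherwise the
    tie-corrected normal approximation.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, "degenerate"
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        r2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        pmf = _signed_rank_distribution(r2)
        cdf = np.cumsum(pmf)
        p_le = float(cdf[w2])
        p_ge = float(1.0 - (cdf[w2 - 1] if w2 > 0 else 0.0))
        return w_plus, min(1.0, 2.0 * min(p_le, p_ge)), "exact"
    mean = n * (n + 1) / 4.0
    # tie correction on the rank-sum variance
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 1.0, "degenerate"
    z = (w_plus - mean) / math.sqrt(var)
    return w_plus, float(2.0 * stats.norm.sf(abs(z))), "normal_approx"


def devaluation_test(pairs: Sequence[tuple[float, float]] | np.ndarray
                     ) -> DevaluationResult:
    """Paired valued-vs-devalued comparison of response counts."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be an (n >= 1, 2) array of "
                         "(valued, devalued) counts")
    if np.any(arr < 0):
        raise ValueError("response counts must be >= 0")
    valued, devalued = arr[:, 0], arr[:, 1]
    diffs = valued - devalued
    w_plus, p, method = exact_signed_rank(diffs)
    totals = valued + devalued
    with np.errstate(invalid="ignore"):
        index = np.where(totals > 0, devalued / totals, np.nan)
    return DevaluationResult(
        valued=valued, devalued=devalued, statistic=w_plus, p_value=p,
        devaluation_index=index,
        n_informative=int(np.count_nonzero(diffs)),
        all_tied=bool(np.all(diffs == 0)), method=method)


def group_compare(groups: Sequence[Sequence[float]],
                  labels: Sequence[str] | None = None,
                  reference: str | None = None) -> GroupComparison:
    """Kruskal-Wallis omnibus with Dunn's posthoc pairwise z tests.

    Posthoc pairs are all unordered group pairs, or only pairs against
    ``reference`` if given.  Dunn z statistics use the pooled-rank
    variance with tie correction; p values are two-sided and
    Bonferroni-adjusted over the tested pairs.  Fully tied data return
    the degenerate convention (statistic 0, p = 1).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    labels = list(labels)
    if len(labels) != len(gs):
        raise ValueError("labels/groups length mismatch")

    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        pairs = _posthoc_pairs(labels, reference)
        posthoc = [PairwiseResult(a, b, 0.0, 1.0) for a, b in pairs]
        return GroupComparison(labels=labels, statistic=0.0, p_value=1.0,
                               posthoc=posthoc, all_tied=True)

    h, p = stats.kruskal(*gs)

    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = {labels[i]: ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(gs))}
    n_of = dict(zip(labels, sizes))
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12 * (n_total - 1))
    sigma2 = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = _posthoc_pairs(labels, reference)
    posthoc = []
    for a, b in pairs:
        se = math.sqrt(sigma2 * (1.0 / n_of[a] + 1.0 / n_of[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_adj = min(1.0, 2.0 * stats.norm.sf(abs(z)) * len(pairs))
        posthoc.append(PairwiseResult(a, b, float(z), float(p_adj)))
    return GroupComparison(labels=labels, statistic=float(h),
                           p_value=float(p), posthoc=posthoc)


def _posthoc_pairs(labels: Sequence[str],
                   reference: str | None) -> list[tuple[str, str]]:
    if reference is None:
        return list(combinations(labels, 2))
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among group labels")
    return [(reference, lb) for lb in labels if lb != reference]


def normalize_evaporation(raw_ml: float | np.ndarray,
                          control_cage_losses: Sequence[float]
                          ) -> tuple[np.ndarray | float, bool]:
    """Subtract mean evaporation of empty control cages from consumption.

    Returns (corrected volume, clamped flag); negative corrected values
    are floored at 0 and flagged.
    """
    losses = np.asarray(control_cage_losses, dtype=float)
    if losses.size < 1:
        raise ValueError("need at least one control measurement")
    raw = np.asarray(raw_ml, dtype=float)
    if np.any(raw < 0) or np.any(losses < 0):
        raise ValueError("volumes must be >= 0")
    corrected = raw - losses.mean()
    clamped = bool(np.any(corrected < 0))
    corrected = np.maximum(corrected, 0.0)
    if np.isscalar(raw_ml) or raw.ndim == 0:
        return float(corrected), clamped
    return corrected, clamped
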