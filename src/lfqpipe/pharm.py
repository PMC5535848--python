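"""Behavioural and infarct statistics.

Covers the pharmacology arm of the study design: five-point neurological
deficit (Longa) scores compared by a Wilcoxon-Mann-Whitney rank-sum test
(exact enumeration for small samples, tie-corrected normal approximation
otherwise), TTC infarct volume expressed as a percentage of the left
hemisphere, one-way ANOVA with a Newman-Keuls (studentized-range
step-down) post hoc, and exhaustive reconstruction of integer score
multisets from printed mean +/- SD summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

LONGA_SCALE = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class LongaScores:
    """Neurological deficit scores for one group (integers 0-4)."""

    group: str
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError(f"group {self.group!r} has no scores")
        bad = [s for s in self.scores if s not in LONGA_SCALE]
        if bad:
            raise ValueError(f"scores outside the 0-4 scale: {bad}")


def infarct_percent(infarct_areas, hemisphere_areas) -> float:
    """Infarct volume as a percentage of the left hemisphere.

    Both inputs are per-slice areas over the five coronal sections
    (constant slice thickness, so summed areas proxy volume):
    ``100 * sum(infarct) / sum(hemisphere)``.
    """
    inf = np.asarray(infarct_areas, dtype=float)
    hemi = np.asarray(hemisphere_areas, dtype=float)
    if inf.shape != (5,) or hemi.shape != (5,):
        raise ValueError("expected exactly 5 slice areas per measurement")
    if (inf < 0).any() or (hemi < 0).any():
        raise ValueError("areas must be non-negative")
    if (inf > hemi).any():
        raise ValueError("infarct area exceeds hemisphere area on some slice")
    total_hemi = hemi.sum()
    if total_hemi <= 0:
        raise ValueError("zero total hemisphere area")
    return float(100.0 * inf.sum() / total_hemi)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def rank_sum(a, b, method: str = "auto", alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test with mid-ranks for ties.

    Parameters
    ----------
    a, b : sequences of values (e.g. Longa scores).
    method : "exact" (full enumeration of rank assignments), "normal"
        (tie-corrected normal approximation), or "auto" (exact when both
        groups have <= 8 values).
    alternative : "two-sided", "less" or "greater" (on group a's ranks).

    Returns
    -------
    (W, p) where W is the rank sum of group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if method == "auto":
        method = "exact" if max(a.size, b.size) <= 8 else "normal"
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[: a.size].sum())
    n1, n2 = a.size, b.size
    n = n1 + n2
    if method == "exact":
        total = comb(n, n1)
        le = ge = 0
        tol = 1e-9
        for idx in itertools.combinations(range(n), n1):
            s = ranks[list(idx)].sum()
            if s <= w + tol:
                le += 1
            if s >= w - tol:
                ge += 1
        p_less, p_greater = le / total, ge / total
    elif method == "normal":
        mean_w = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / ((n) * (n - 1))
        var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:
            return w, 1.0
        sd_w = np.sqrt(var_w)
        # continuity-corrected tails
        p_less = float(stats.norm.cdf((w - mean_w + 0.5) / sd_w))
        p_greater = float(stats.norm.sf((w - mean_w - 0.5) / sd_w))
    else:
        raise ValueError(f"unknown method {method!r}")
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w, float(p)


def anova_snk(groups: dict[str, list[float]], alpha: float = 0.05) -> dict:
    """One-way ANOVA followed by the Newman-Keuls step-down post hoc.

    SNK: group means are sorted; each pair is tested with the
    studentized-range statistic at its span size r (number of means the
    comparison stretches over), stepping down from the widest span.  A
    non-significant span blocks every comparison nested inside it.

    Returns a dict with ``F``, ``p``, degrees of freedom, and a
    ``pairs`` list of (group_lo, group_hi, q, p_q, significant).
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(data) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(data)
    n_total = sum(len(d) for d in data)
    df_between, df_within = k - 1, n_total - k
    grand = np.concatenate(data).mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ss_between > 0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat, p = 0.0, 1.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))

    order = np.argsort([d.mean() for d in data], kind="stable")
    sorted_names = [names[i] for i in order]
    sorted_means = [data[i].mean() for i in order]
    sorted_ns = [len(data[i]) for i in order]

    blocked = set()
    pairs = []
    # widest spans first; a non-significant span blocks its sub-spans
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = sorted_means[j] - sorted_means[i]
            n_h = 2.0 / (1.0 / sorted_ns[i] + 1.0 / sorted_ns[j])
            if ms_within > 0:
                q = diff / np.sqrt(ms_within / n_h)
                p_q = float(stats.studentized_range.sf(q, span, df_within))
            else:
                q = float("inf") if diff > 0 else 0.0
                p_q = 0.0 if diff > 0 else 1.0
            significant = (p_q < alpha) and ((i, j) not in blocked)
            if not significant:
                # block all nested comparisons
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        blocked.add((ii, jj))
            pairs.append(
                {
                    "group_lo": sorted_names[i],
                    "group_hi": sorted_names[j],
                    "span": span,
                    "q": float(q),
                    "p_q": p_q,
                    "significant": bool(significant),
                }
            )
    return {
        "F": float(f_stat),
        "p": p,
        "df_between": df_between,
        "df_within": df_within,
        "ms_within": float(ms_within),
        "zero_variance": ms_within == 0,
        "pairs": pairs,
    }


def reconstruct_score_multiset(
    mean: float, sd: float, n: int, max_score: int = 4, decimals: int = 2
) -> list[tuple[int, ...]]:
    """All integer score multisets matching a printed mean +/- SD summary.

    Exhaustively searches multisets of size ``n`` over scores
    ``0..max_score`` whose mean and *population* SD (ddof=0, the
    convention matching the printed tables) round to the given values at
    ``decimals`` places.  Returns sorted tuples; an empty list means no
    multiset reproduces the summary.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tol = 0.5 * 10.0**-decimals + 1e-12
    matches = []
    for combo in itertools.combinations_with_replacement(range(max_score + 1), n):
        arr = np.array(combo, dtype=float)
        if abs(arr.mean() - mean) <= tol and abs(arr.std(ddof=0) - sd) <= tol:
            matches.append(combo)
    return matches
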