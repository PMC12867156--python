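"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately naive (all-pairs loops, integer-line unions,
pair counting) and shares no code with the package's implementations.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np


def brute_overlap_members(
    a: Sequence[Tuple[str, int, int]], b: Sequence[Tuple[str, int, int]]
) -> List[Tuple[str, int, int]]:
    """Members of `a` overlapping >=1 bp with any member of `b` (all pairs)."""
    out = []
    for ca, sa, ea in a:
        hit = False
        for cb, sb, eb in b:
            if ca == cb and sa < eb and sb < ea:
                hit = True
                break
        if hit:
            out.append((ca, sa, ea))
    return out


def brute_union_ranges(
    intervals: Sequence[Tuple[str, int, int]], size: int = 1 << 16
) -> List[Tuple[str, int, int]]:
    """Merged maximal intervals via an explicit covered-positions array."""
    by_chrom: Dict[str, np.ndarray] = {}
    for c, s, e in intervals:
        cov = by_chrom.setdefault(c, np.zeros(size, dtype=bool))
        cov[s:e] = True
    out: List[Tuple[str, int, int]] = []
    for c in sorted(by_chrom):
        cov = by_chrom[c]
        diff = np.diff(cov.astype(np.int8))
        starts = list(np.where(diff == 1)[0] + 1)
        ends = list(np.where(diff == -1)[0] + 1)
        if cov[0]:
            starts.insert(0, 0)
        if cov[-1]:
            ends.append(size)
        out.extend((c, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def naive_profile(
    sites: Sequence[Tuple[str, int, int]],
    midpoints: Dict[str, Sequence[int]],
    window: int,
    bin_width: int,
) -> np.ndarray:
    """Per-site loop aggregate profile (resize, then bin each midpoint)."""
    n_bins = window // bin_width
    counts = np.zeros(n_bins, dtype=int)
    for chrom, s, e in sites:
        center = (s + e) // 2
        rstart = max(0, center - window // 2)
        for pos in midpoints.get(chrom, ()):
            if rstart <= pos < rstart + window:
                counts[(pos - rstart) // bin_width] += 1
    return counts


def pair_auc(scores: Sequence[float], is_pos: Sequence[bool]) -> float:
    """AUC by explicit pair counting, ties worth one half."""
    pos = [s for s, y in zip(scores, is_pos) if y]
    neg = [s for s, y in zip(scores, is_pos) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_scan(scores: Sequence[float], is_pos: Sequence[bool]) -> float:
    """Max of TPR - FPR over all real thresholds for `score > thr`."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(is_pos, dtype=bool)
    u = np.unique(scores)
    candidates = np.concatenate([[u.min() - 1], u, (u[:-1] + u[1:]) / 2 if len(u) > 1 else []])
    best = -np.inf
    for thr in candidates:
        pred = scores > thr
        tpr = (pred & y).sum() / y.sum()
        fpr = (pred & ~y).sum() / (~y).sum()
        best = max(best, tpr - fpr)
    return float(best)


def exact_ranksum_p_separated(n: int, m: int) -> float:
    """Exact two-sided rank-sum p for complete separation of groups n, m."""
    from math import comb

    return 2.0 / comb(n + m, n)


def random_interval_set(
    rng: np.random.Generator,
    n: int,
    chrom: str = "chrT",
    size: int = 10_000,
    max_width: int = 300,
) -> List[Tuple[str, int, int]]:
    starts = rng.integers(0, size - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return [(chrom, int(s), int(s + w)) for s, w in zip(starts, widths)]
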