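"""Derivation of the cell-line-informed signature site sets.

Three site sets feed the integrated plasma score: promoter-mark (H3K4me3)
tumor-up peaks, enhancer-mark (H3K27ac) tumor-up peaks, and fusion-occupied
transcription-factor binding sites.  Tumor-up peaks come from a differential
analysis of cell-line count matrices; fusion-occupied TFBSs from intersecting
a catalogue of known binding sites with fusion ChIP peaks.  Before scoring,
TFBSs that overlap the H3K27ac tumor-up peaks are discarded so a region's
signal is never counted twice.

The differential test is deliberately lightweight and fully specified:
counts-per-million with a 0.5 pseudocount, log2 fold change of group mean
CPM, a per-peak test on log2-CPM, and Benjamini-Hochberg adjustment across
all peaks of the mark.  The default test is an empirical-Bayes *moderated*
pooled-variance t-test: per-peak variances are squeezed toward a prior
estimated from all peaks (method-of-moments on log variances), which shares
variance information across peaks exactly as negative-binomial GLM
pipelines share dispersion, and is what makes small designs (3-6 samples
per group) usable.  A plain Welch t-test and an exact rank-sum test are
available as options; groups with fewer than 3 samples automatically fall
back to the exact rank-sum test.  The selection logic of the upstream
pipeline (thresholded |log2FC| plus an FDR-q cut over the consensus peaks
of the mark) is preserved as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .intervals import (
    GenomicInterval,
    SiteSet,
    extend_and_merge,
    overlap_intersect,
    subtract_overlapping,
)

__all__ = [
    "CountMatrix",
    "DifferentialPeak",
    "SignatureBundle",
    "consensus_peaks",
    "differential_peaks",
    "fusion_occupied_tfbs",
    "assemble_bundle",
]


@dataclass
class CountMatrix:
    """Per-peak, per-sample read counts over a consensus peak set.

    ``counts`` has shape ``(n_peaks, n_samples)``; ``group`` labels each
    sample column (e.g. ``tRCC`` / ``ccRCC``).
    """

    peaks: SiteSet
    samples: List[str]
    counts: np.ndarray
    group: List[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.peaks)} peaks, {len(self.samples)} samples)"
            )
        if len(self.group) != len(self.samples):
            raise ValidationError("one group label per sample required")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
            }
        )
        for j, s in enumerate(self.samples):
            df[s] = self.counts[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, group: Sequence[str], mark: Optional[str] = None):
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"{path}: count matrix must start with columns {sorted(required)}"
            )
        samples = [c for c in df.columns if c not in required]
        peaks = SiteSet(
            (
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in df.itertuples()
            ),
            mark=mark,
        )
        return cls(peaks, samples, df[samples].to_numpy(), list(group))


@dataclass
class DifferentialPeak:
    interval: GenomicInterval
    log2fc: float
    p: float
    q: float


@dataclass
class SignatureBundle:
    """The three deduplicated signature site sets used for plasma scoring."""

    k4_up: SiteSet
    k27_up: SiteSet
    tfbs: SiteSet

    def __post_init__(self) -> None:
        shared = overlap_intersect(self.tfbs, self.k27_up)
        if len(shared) != 0:
            raise ValidationError(
                f"{len(shared)} TFBSs overlap the H3K27ac-up set; "
                "deduplicate with assemble_bundle first"
            )


def consensus_peaks(peak_sets: Sequence[SiteSet]) -> SiteSet:
    """Union of per-sample peak sets with overlapping (or book-ended) peaks
    merged into maximal disjoint intervals.  All inputs must share a mark."""
    if not peak_sets:
        raise ValidationError("need at least one peak set")
    marks = {s.mark for s in peak_sets}
    if len(marks) > 1:
        raise ValidationError(f"mixed marks in consensus: {sorted(map(str, marks))}")
    union = SiteSet(
        (iv for s in peak_sets for iv in s),
        mark=peak_sets[0].mark,
        label="consensus",
    )
    return extend_and_merge(union, flank=0)


def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _moderated_t_pvalues(
    la: np.ndarray, lb: np.ndarray, tau: float = 0.0
) -> np.ndarray:
    """Empirical-Bayes moderated pooled-variance t-test per row.

    Per-row pooled variances are squeezed toward a prior (s0^2, d0)
    estimated from all rows by method of moments on log variances; the t
    statistic then has d + d0 degrees of freedom.  Sharing variance
    information across peaks is what gives 3-6 samples/group usable power.

    ``tau`` > 0 tests against the interval null |difference| <= tau
    (a fold-change-threshold test in the style of TREAT), so a peak is
    significant only when its difference significantly *exceeds* the
    threshold rather than merely being nonzero with a point estimate past
    it.  ``tau = 0`` reduces to the ordinary two-sided test.
    """
    na, nb = la.shape[1], lb.shape[1]
    d = na + nb - 2
    ss = la.var(axis=1, ddof=1) * (na - 1) + lb.var(axis=1, ddof=1) * (nb - 1)
    s2 = np.maximum(ss / d, 1e-12)
    z = np.log(s2)
    e = z - float(digamma(d / 2.0)) + np.log(d / 2.0)
    excess = float(np.var(e, ddof=1)) - float(polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df = d + d0
    else:
        # no excess variability across rows: variances effectively common
        s2_post = np.full_like(s2, float(np.exp(np.mean(e))))
        df = 1e6
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    diff = la.mean(axis=1) - lb.mean(axis=1)
    if tau <= 0:
        return 2.0 * stats.t.sf(np.abs(diff) / se, df)
    t_near = (np.abs(diff) - tau) / se
    t_far = (np.abs(diff) + tau) / se
    return stats.t.sf(t_near, df) + stats.t.sf(t_far, df)


def differential_peaks(
    m: CountMatrix,
    lfc_min: float,
    q_max: float,
    group_a: str = "tRCC",
    group_b: str = "ccRCC",
    pseudocount: float = 0.5,
    method: str = "moderated",
    normalization: str = "median-ratio",
) -> Tuple[List[DifferentialPeak], List[DifferentialPeak]]:
    """Peaks differentially covered between ``group_a`` and ``group_b``.

    ``method`` is one of ``moderated`` (default; empirical-Bayes pooled
    variance), ``welch`` or ``ranksum``; groups with <3 samples always use
    the exact rank-sum test.  ``normalization`` selects the library-size
    estimate: ``median-ratio`` (default; median-of-ratios size factors,
    robust to a subset of strongly differential peaks dominating the
    library) or ``total-count``.  Returns ``(up, down)``: peaks with BH
    q < ``q_max`` and log2FC > ``lfc_min`` (up, enriched in ``group_a``) or
    < ``-lfc_min`` (down).  log2FC > 0 means enriched in ``group_a``.
    """
    if method not in ("moderated", "welch", "ranksum"):
        raise ValidationError(f"unknown method {method!r}")
    if normalization not in ("median-ratio", "total-count"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    ia = np.array([g == group_a for g in m.group])
    ib = np.array([g == group_b for g in m.group])
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValidationError("need >=2 samples per group")
    total = m.counts.sum(axis=0).astype(float)
    if total[ia].sum() <= 0 or total[ib].sum() <= 0:
        raise ValidationError("a group has zero total counts")
    if np.any(total <= 0):
        raise ValidationError("every sample needs a positive library size")

    if normalization == "median-ratio":
        logc = np.log(m.counts + pseudocount)
        geo = logc.mean(axis=1)
        sf = np.exp(np.median(logc - geo[:, None], axis=0))
        sf /= np.exp(np.mean(np.log(sf)))  # geometric mean 1
        libsize = sf * float(np.median(total))
    else:
        libsize = total

    cpm = (m.counts + pseudocount) / libsize[None, :] * 1e6
    log2cpm = np.log2(cpm)
    mean_a = cpm[:, ia].mean(axis=1)
    mean_b = cpm[:, ib].mean(axis=1)
    log2fc = np.log2(mean_a) - np.log2(mean_b)

    la, lb = log2cpm[:, ia], log2cpm[:, ib]
    if ia.sum() < 3 or ib.sum() < 3 or method == "ranksum":
        # exact two-sided rank-sum per peak for very small designs
        p = np.array(
            [
                stats.mannwhitneyu(
                    la[i], lb[i], alternative="two-sided", method="exact"
                ).pvalue
                if len(set(np.concatenate([la[i], lb[i]]))) > 1
                else 1.0
                for i in range(la.shape[0])
            ]
        )
    elif method == "welch":
        p = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
    else:
        # the moderated test is threshold-aware: significance requires the
        # difference to significantly exceed lfc_min, not merely be nonzero
        p = _moderated_t_pvalues(la, lb, tau=max(lfc_min, 0.0))
    p = np.where(np.isnan(p), 1.0, np.clip(p, 0.0, 1.0))
    q = multipletests(p, method="fdr_bh")[1]

    up: List[DifferentialPeak] = []
    down: List[DifferentialPeak] = []
    for i, peak in enumerate(m.peaks):
        if q[i] >= q_max:
            continue
        dp = DifferentialPeak(peak, float(log2fc[i]), float(p[i]), float(q[i]))
        if log2fc[i] > lfc_min:
            up.append(dp)
        elif log2fc[i] < -lfc_min:
            down.append(dp)
    return up, down


def fusion_occupied_tfbs(
    known_tfbs: SiteSet, fusion_peak_sets: Sequence[SiteSet]
) -> SiteSet:
    """Known TFBSs retained because a fusion ChIP peak (consensus over the
    provided peak sets) overlaps them by >=1 bp.  Output coordinates are the
    known-TFBS coordinates."""
    if len(known_tfbs) == 0:
        raise ValidationError("known_tfbs must be nonempty")
    if not fusion_peak_sets or all(len(s) == 0 for s in fusion_peak_sets):
        return known_tfbs.replace([])
    union = SiteSet(
        (iv for s in fusion_peak_sets for iv in s),
        mark=fusion_peak_sets[0].mark,
    )
    merged = extend_and_merge(union, flank=0)
    return overlap_intersect(known_tfbs, merged)


def assemble_bundle(
    k4_up: SiteSet, k27_up: SiteSet, tfbs_raw: SiteSet
) -> SignatureBundle:
    """Build the scoring bundle, discarding TFBSs shared (>=1-bp overlap)
    with the H3K27ac tumor-up peaks so their signal is not double counted."""
    tfbs = subtract_overlapping(tfbs_raw, k27_up)
    return SignatureBundle(k4_up=k4_up, k27_up=k27_up, tfbs=tfbs)
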