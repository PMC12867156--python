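"""The integrated epigenomic score (TIES) and ROC classification.

For each plasma sample three depth-normalised signals are measured:
H3K4me3 signal at promoter-mark tumor-up sites, H3K27ac signal at
enhancer-mark tumor-up sites, and H3K27ac signal at the deduplicated
fusion-occupied TFBSs.  The three are summed (unweighted by default) and a
logarithm taken; the log floor keeps fully background-subtracted samples
finite.  Because the log is a strictly increasing transform, AUC, Youden
thresholds and rank tests downstream do not depend on the chosen base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import PartialScoreError, ValidationError
from .intervals import SiteSet
from .quant import FragmentSet, Midpoints, QuantConfig, midpoints, site_signal
from .signatures import SignatureBundle

__all__ = [
    "MARK_K4",
    "MARK_K27",
    "TiesConfig",
    "TiesResult",
    "RocResult",
    "compute_ties",
    "score_sample",
    "roc_auc",
]

MARK_K4 = "H3K4me3"
MARK_K27 = "H3K27ac"

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass
class TiesConfig:
    """Parameters of the integrated score.

    log_base: "e", "2" or "10" (any base gives the same classifier ordering).
    eps: floor applied to the summed signal before the log.
    weights: per-component weights for (k4, k27, tfbs); default unweighted.
    """

    log_base: str = "e"
    eps: float = 1e-6
    weights: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if str(self.log_base) not in _LOG_BASES:
            raise ValidationError("log_base must be one of 'e', '2', '10'")
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")

    @property
    def base(self) -> float:
        return _LOG_BASES[str(self.log_base)]


@dataclass
class TiesResult:
    """Per-sample component signals and the integrated score."""

    sample_id: str
    s_k4: float
    s_k27: float
    s_tfbs: float
    ties: float
    label: Optional[str] = None
    tumor_fraction: Optional[float] = None
    components_used: Tuple[str, ...] = ("k4", "k27", "tfbs")


@dataclass
class RocResult:
    auc: float
    points: List[Tuple[float, float]]  # (FPR, TPR) over all thresholds


def compute_ties(
    s_k4: float,
    s_k27: float,
    s_tfbs: float,
    cfg: Optional[TiesConfig] = None,
) -> float:
    """log of the (floored) weighted sum of the three component signals."""
    cfg = cfg or TiesConfig()
    w = cfg.weights
    total = w[0] * s_k4 + w[1] * s_k27 + w[2] * s_tfbs
    return math.log(max(total, cfg.eps), cfg.base)


def score_sample(
    frags: Mapping[str, FragmentSet],
    bundle: SignatureBundle,
    dhs: SiteSet,
    quant_cfg: Optional[QuantConfig] = None,
    ties_cfg: Optional[TiesConfig] = None,
    sample_id: Optional[str] = None,
    allow_partial: bool = False,
) -> TiesResult:
    """Score one plasma sample from its per-mark fragment sets.

    H3K4me3 fragments are quantified at the promoter-mark tumor-up sites;
    H3K27ac fragments at the enhancer-mark tumor-up sites and at the
    deduplicated fusion-occupied TFBSs.  A missing assay raises
    :class:`PartialScoreError` naming it unless ``allow_partial`` is set, in
    which case the missing components contribute 0 and are dropped from
    ``components_used``.
    """
    quant_cfg = quant_cfg or QuantConfig()
    ties_cfg = ties_cfg or TiesConfig()
    missing = [m for m in (MARK_K4, MARK_K27) if m not in frags]
    if missing and not allow_partial:
        raise PartialScoreError(
            f"sample is missing assay(s): {', '.join(missing)}"
        )
    if sample_id is None:
        present = [frags[m] for m in (MARK_K4, MARK_K27) if m in frags]
        sample_id = present[0].sample_id if present else "sample"

    used: List[str] = []
    s_k4 = s_k27 = s_tfbs = 0.0
    if MARK_K4 in frags:
        pts4 = midpoints(frags[MARK_K4])
        s_k4 = site_signal(pts4, bundle.k4_up, dhs, quant_cfg)
        used.append("k4")
    if MARK_K27 in frags:
        pts27 = midpoints(frags[MARK_K27])
        s_k27 = site_signal(pts27, bundle.k27_up, dhs, quant_cfg)
        s_tfbs = site_signal(pts27, bundle.tfbs, dhs, quant_cfg)
        used.extend(["k27", "tfbs"])

    ties = compute_ties(s_k4, s_k27, s_tfbs, ties_cfg)
    return TiesResult(
        sample_id=sample_id,
        s_k4=s_k4,
        s_k27=s_k27,
        s_tfbs=s_tfbs,
        ties=ties,
        components_used=tuple(used),
    )


def _binary_labels(labels: Sequence, positive) -> np.ndarray:
    y = np.array([1 if l == positive else 0 for l in labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("need at least one positive and one negative")
    return y


def roc_auc(
    scores: Sequence[float],
    labels: Sequence,
    positive="pos",
) -> RocResult:
    """Rank-based ROC/AUC (ties counted one half), endpoints included."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(labels):
        raise ValidationError("scores and labels must have equal length")
    y = _binary_labels(labels, positive)
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    points = [(float(f), float(t)) for f, t in zip(fpr, tpr)]
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return RocResult(auc=auc, points=points)
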