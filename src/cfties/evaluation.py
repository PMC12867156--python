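"""Threshold selection, leave-one-out cross-validation, and longitudinal
monitoring statistics.

The operating threshold maximises Youden's J = TPR - FPR under the rule
``score > threshold -> positive``.  Candidate thresholds are the midpoints
between consecutive distinct sorted scores plus sentinels below the minimum
and above the maximum; among equal-J candidates the largest (most specific)
threshold wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ThresholdResult",
    "LoocvResult",
    "DrawPair",
    "youden_threshold",
    "loo_cv",
    "consecutive_deltas",
    "group_compare",
]

logger = logging.getLogger(__name__)


@dataclass
class ThresholdResult:
    threshold: float
    youden_j: float
    tpr: float
    fpr: float


@dataclass
class LoocvResult:
    predictions: List[bool]  # per-sample predicted positive
    precision: float
    recall: float
    specificity: float
    mean_threshold: float
    thresholds: List[float]


@dataclass
class DrawPair:
    """Change between two consecutive draws of one patient.  ``delta_ties``
    is the percent change 100*(t1 - t0)/|t0|; ``delta_tf`` the absolute
    change in tumor fraction.  ``status`` labels the clinical interval."""

    patient_id: str
    t0: object
    t1: object
    delta_ties: float
    delta_tf: float
    status: str


def _validate_binary(scores, labels, positive) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.array([l == positive for l in labels])
    if len(scores) != len(y):
        raise ValidationError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise ValidationError("need both classes present")
    return scores, y


def youden_threshold(
    scores: Sequence[float], labels: Sequence, positive="pos"
) -> ThresholdResult:
    """Threshold maximising J = TPR - FPR for ``score > threshold``.

    Ties in J break toward the largest threshold (maximal specificity)."""
    scores, y = _validate_binary(scores, labels, positive)
    u = np.unique(scores)
    candidates = np.concatenate(
        [[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]]
    )
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    best: Optional[ThresholdResult] = None
    for thr in candidates:
        pred = scores > thr
        tpr = float((pred & y).sum()) / n_pos
        fpr = float((pred & ~y).sum()) / n_neg
        j = tpr - fpr
        # >= so the largest threshold among equal-J candidates is kept
        if best is None or j >= best.youden_j:
            best = ThresholdResult(float(thr), j, tpr, fpr)
    assert best is not None
    return best


def loo_cv(
    scores: Sequence[float], labels: Sequence, positive="pos"
) -> LoocvResult:
    """Leave-one-out cross-validation of the Youden-threshold classifier.

    Each fold fits the threshold on n-1 samples and classifies the held-out
    sample by ``score > threshold``.  Precision, recall (sensitivity) and
    specificity are pooled over all held-out predictions; the reported
    threshold is the mean across folds.
    """
    scores, y = _validate_binary(scores, labels, positive)
    n = len(scores)
    if n < 3:
        raise ValidationError("LOO-CV needs n >= 3")
    preds: List[bool] = []
    thresholds: List[float] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if y[mask].all() or not y[mask].any():
            raise ValidationError(
                f"training fold {i} (holding out sample {i}) has a single class"
            )
        res = youden_threshold(scores[mask], y[mask], positive=True)
        thresholds.append(res.threshold)
        preds.append(bool(scores[i] > res.threshold))
    pred = np.array(preds)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    return LoocvResult(
        predictions=preds,
        precision=precision,
        recall=recall,
        specificity=specificity,
        mean_threshold=float(np.mean(thresholds)),
        thresholds=thresholds,
    )


def consecutive_deltas(
    records: Sequence[Dict],
    eps_floor: float = 1e-5,
) -> List[DrawPair]:
    """Per-patient consecutive-draw changes in score and tumor fraction.

    ``records`` are dicts with keys ``patient_id``, ``draw_date``, ``ties``,
    ``tumor_fraction`` and ``status`` (the clinical label of the interval
    ending at that draw).  Draws are ordered by date within patient; each
    adjacent pair yields one :class:`DrawPair` labelled by the later draw's
    status.  Pairs whose baseline score magnitude is below ``eps_floor``
    are excluded (percent change undefined near the log floor) and logged.
    """
    by_patient: Dict[str, List[Dict]] = {}
    for r in records:
        by_patient.setdefault(str(r["patient_id"]), []).append(r)
    pairs: List[DrawPair] = []
    for pid, rows in sorted(by_patient.items()):
        rows = sorted(rows, key=lambda r: r["draw_date"])
        for prev, cur in zip(rows[:-1], rows[1:]):
            t0 = float(prev["ties"])
            if abs(t0) < eps_floor:
                logger.warning(
                    "patient %s: pair %s -> %s excluded (baseline score %.3g "
                    "below floor)", pid, prev["draw_date"], cur["draw_date"], t0
                )
                continue
            delta_ties = 100.0 * (float(cur["ties"]) - t0) / abs(t0)
            delta_tf = float(cur.get("tumor_fraction") or 0.0) - float(
                prev.get("tumor_fraction") or 0.0
            )
            pairs.append(
                DrawPair(
                    patient_id=pid,
                    t0=prev["draw_date"],
                    t1=cur["draw_date"],
                    delta_ties=delta_ties,
                    delta_tf=delta_tf,
                    status=str(cur.get("status", "")),
                )
            )
    return pairs


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Exact for small untied samples, normal approximation with tie and
    continuity correction otherwise.  Returns ``(U statistic, p value)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and a.size <= 25 and b.size <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
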