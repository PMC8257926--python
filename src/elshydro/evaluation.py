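"""ROC analysis, paired AUC comparison (DeLong), continuous NRI, and
threshold-based diagnostic indices.

Conventions fixed here and used throughout:

* The positive-call rule at a threshold t is ``prob >= t``.
* AUC uses the Mann-Whitney form, ties half-credited, which equals the
  trapezoidal area under the empirical ROC.
* The operating threshold is the closest-top-left point of the ROC,
  minimising (1-sensitivity)^2 + (1-specificity)^2, ties broken toward the
  higher (more specific) threshold.
* Continuous NRI counts any probability increase (decrease) as upward
  (downward) reclassification; its variance is the independent sum of the
  event and non-event multinomial variances, no continuity correction.
* Two-sided p-values come from the standard normal (asymptotic); sample
  sizes in this design are ~100 per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RocResult",
    "IndexReport",
    "DelongResult",
    "NriResult",
    "roc",
    "delong_test",
    "closest_topleft",
    "indices_at",
    "continuous_nri",
    "reclassification_data",
]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.sum() in (0, len(labels)):
        raise ValueError("both classes must be present")
    return labels


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve: thresholds (descending, starting above the
    maximum probability so the curve begins at (0,0)), matching
    (1-specificity, sensitivity) points, and the AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(probs, labels) -> RocResult:
    """Empirical ROC with one point per distinct probability plus (0,0).

    AUC is computed in the Mann-Whitney form, P(case prob > control prob)
    plus half the tie probability, which coincides with the trapezoidal
    area under the returned points.
    """
    probs = np.asarray(probs, dtype=float)
    labels = _check_labels(labels)
    if not np.isfinite(probs).all():
        raise ValueError("probabilities must be finite")
    order = np.argsort(-probs, kind="stable")
    p_sorted = probs[order]
    y_sorted = labels[order]
    distinct = np.r_[True, np.diff(p_sorted) != 0]
    idx = np.flatnonzero(distinct)
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1.0 - y_sorted)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    # value at each distinct threshold = counts including all tied values
    ends = np.r_[idx[1:] - 1, len(probs) - 1]
    tpr = np.r_[0.0, tp_cum[ends] / n_pos]
    fpr = np.r_[0.0, fp_cum[ends] / n_neg]
    thresholds = np.r_[np.inf, p_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def closest_topleft(roc_result: RocResult) -> float:
    """Operating threshold: ROC point closest to the perfect corner (0, 1).

    Minimises squared Euclidean distance (1-tpr)^2 + fpr^2; among ties the
    higher threshold (the more specific rule) is returned.
    """
    d2 = (1.0 - roc_result.tpr) ** 2 + roc_result.fpr**2
    best = d2.min()
    tied = np.flatnonzero(d2 == best)
    thr = float(np.max(roc_result.thresholds[tied]))
    if not np.isfinite(thr):
        # the (0,0) sentinel point; any threshold above the max prob is
        # equivalent — report just above the largest finite threshold
        finite = roc_result.thresholds[np.isfinite(roc_result.thresholds)]
        thr = float(finite.max()) if finite.size else 1.0
    return thr


@dataclass(frozen=True)
class IndexReport:
    """Confusion counts and the four diagnostic indices at one threshold.

    An index whose denominator is empty (no predicted positives/negatives,
    or a missing class) is reported as NaN, not zero.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def indices_at(probs, labels, threshold: float) -> IndexReport:
    """Sensitivity, specificity, PPV and NPV with the ``prob >= t`` rule."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = probs >= threshold
    tp = int(np.sum(pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    fn = int(np.sum(~pos & (labels == 1)))
    tn = int(np.sum(~pos & (labels == 0)))

    def _frac(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return IndexReport(
        threshold=float(threshold),
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_frac(tp, tp + fn),
        specificity=_frac(tn, tn + fp),
        ppv=_frac(tp, tp + fp),
        npv=_frac(tn, tn + fn),
    )


# ---------------------------------------------------------------------------
# DeLong's test for paired AUCs


def _placements(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-case / per-control structural components (placement
    values), ties half-credited."""
    x = probs[labels == 1]  # cases
    y = probs[labels == 0]  # controls
    gt = (x[:, None] > y[None, :]).astype(float)
    eq = (x[:, None] == y[None, :]).astype(float)
    s = gt + 0.5 * eq
    v10 = s.mean(axis=1)  # one per case
    v01 = s.mean(axis=0)  # one per control
    return float(s.mean()), v10, v01


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(probs_a, probs_b, labels) -> DelongResult:
    """Paired comparison of two AUCs on the same subjects.

    The covariance of the two AUC estimates is built from DeLong's
    structural components; z = (auc_b - auc_a) / sd(diff) and the two-sided
    p-value is standard normal.  Identical predictions (zero variance of the
    difference) yield p = 1 with ``degenerate=True``.
    """
    probs_a = np.asarray(probs_a, dtype=float)
    probs_b = np.asarray(probs_b, dtype=float)
    labels = _check_labels(labels)
    if probs_a.shape != probs_b.shape or probs_a.shape != labels.shape:
        raise ValueError("probability vectors must be paired with the labels")
    auc_a, v10_a, v01_a = _placements(probs_a, labels)
    auc_b, v10_b, v01_b = _placements(probs_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_b - auc_a
    if var_diff <= 0:
        return DelongResult(auc_a, auc_b, max(var_diff, 0.0), 0.0, 1.0, degenerate=True)
    z = diff / np.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, var_diff, float(z), p)


# ---------------------------------------------------------------------------
# continuous net reclassification improvement


@dataclass(frozen=True)
class NriResult:
    nri: float
    z: float
    p_value: float
    p_up_case: float
    p_down_case: float
    p_up_control: float
    p_down_control: float
    degenerate: bool = False


def continuous_nri(probs_old, probs_new, labels) -> NriResult:
    """Continuous (category-free) net reclassification improvement.

    NRI = [P(up|case) - P(down|case)] + [P(down|control) - P(up|control)]
    where up/down mean the new model's probability moved up/down and ties
    count as no movement.  The variance is the sum of the event and
    non-event multinomial variances (independent groups); z and the
    two-sided p-value are asymptotic normal.
    """
    old = np.asarray(probs_old, dtype=float)
    new = np.asarray(probs_new, dtype=float)
    labels = _check_labels(labels)
    if old.shape != new.shape or old.shape != labels.shape:
        raise ValueError("probability vectors must be paired with the labels")
    up = new > old
    down = new < old
    case = labels == 1
    ctrl = labels == 0
    n1, n0 = int(case.sum()), int(ctrl.sum())
    pu1 = float(up[case].mean())
    pd1 = float(down[case].mean())
    pu0 = float(up[ctrl].mean())
    pd0 = float(down[ctrl].mean())
    nri = (pu1 - pd1) + (pd0 - pu0)
    var = (pu1 + pd1 - (pu1 - pd1) ** 2) / n1 + (pu0 + pd0 - (pd0 - pu0) ** 2) / n0
    if var <= 0:
        return NriResult(nri, 0.0, 1.0, pu1, pd1, pu0, pd0, degenerate=True)
    z = nri / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return NriResult(nri, float(z), p, pu1, pd1, pu0, pd0)


def reclassification_data(probs_old, probs_new, labels) -> pd.DataFrame:
    """Per-subject table behind the reclassification plot: old and new
    probability, label, and movement (up / down / tied)."""
    old = np.asarray(probs_old, dtype=float)
    new = np.asarray(probs_new, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if old.shape != new.shape or old.shape != labels.shape:
        raise ValueError("inputs must be paired")
    movement = np.where(new > old, "up", np.where(new < old, "down", "tied"))
    return pd.DataFrame(
        {"prob_old": old, "prob_new": new, "label": labels, "movement": movement}
    )
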