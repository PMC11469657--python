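"""Classification cutoffs and confusion-matrix metrics.

Cutoffs are midpoints between consecutive distinct risk values plus
sentinels at minus/plus infinity (predict-everyone / predict-no-one).
Prediction is "death iff oriented risk > cutoff", which yields the familiar
half-unit cutoffs for integer scores (e.g. ISS > 13.5).  Two cutoff rules
are provided: the Youden index (maximise Se + Sp - 1) and a sensitivity
floor (among cutoffs with Se >= floor, maximise Sp) used for screening
where missing a death is costlier than a false alarm.

For scores where lower is worse the oriented risk is the negated score, so
an oriented cutoff c reads back as "score < -c" in native units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .discrimination import UndefinedMetricError

__all__ = [
    "ThresholdReport",
    "candidate_cutoffs",
    "confusion_at",
    "youden_cutoff",
    "se_floor_cutoff",
]


@dataclass
class ThresholdReport:
    """One cutoff and its confusion-matrix metrics (percentages)."""

    score: str
    rule: str                      # "youden" | "se_floor"
    cutoff: float                  # oriented axis (larger = worse)
    direction: str                 # ">" on the oriented axis
    native_cutoff: float           # back in the score's own units
    native_direction: str          # ">" for higher-worse, "<" for lower-worse
    se: float
    sp: float
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float
    npv_defined: bool
    youden_j: Optional[float] = None

    def native_label(self) -> str:
        """Human-readable cutoff, e.g. '>13.5' or '<7.5' or 'Inf'."""
        if math.isinf(self.native_cutoff):
            return "Inf"
        return f"{self.native_direction}{self.native_cutoff:g}"


def candidate_cutoffs(risk) -> np.ndarray:
    """Midpoints between consecutive distinct sorted risks, with -inf and
    +inf sentinels (all-positive and all-negative rules)."""
    risk = np.asarray(risk, dtype=float)
    if risk.size == 0:
        raise ValueError("need at least one observation")
    distinct = np.unique(risk)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def confusion_at(risk, labels, cutoff: float):
    """(se, sp, ppv, npv, accuracy) in percent at 'predict death iff
    risk > cutoff'.  ppv/npv are None when no patient is predicted
    positive/negative."""
    risk = np.asarray(risk, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = risk > cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    n = len(labels)
    se = 100.0 * tp / (tp + fn) if (tp + fn) else None
    sp = 100.0 * tn / (tn + fp) if (tn + fp) else None
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) else None
    npv = 100.0 * tn / (tn + fn) if (tn + fn) else None
    accuracy = 100.0 * (tp + tn) / n
    return se, sp, ppv, npv, accuracy


def _report(score, rule, cutoff, risk, labels, orientation, youden_j=None):
    se, sp, ppv, npv, accuracy = confusion_at(risk, labels, cutoff)
    higher_worse = orientation == "higher_worse"
    return ThresholdReport(
        score=score, rule=rule, cutoff=float(cutoff), direction=">",
        native_cutoff=float(cutoff) if higher_worse else float(-cutoff),
        native_direction=">" if higher_worse else "<",
        se=se, sp=sp, ppv=ppv, npv=npv, accuracy=accuracy,
        npv_defined=npv is not None, youden_j=youden_j,
    )


def youden_cutoff(risk, labels, score: str = "score",
                  orientation: str = "higher_worse") -> ThresholdReport:
    """Cutoff maximising Youden's J = Se + Sp - 1; ties broken toward
    higher sensitivity (the lower cutoff)."""
    risk = np.asarray(risk, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("Youden cutoff needs both classes")
    best = None
    for c in candidate_cutoffs(risk):
        se, sp, _, _, _ = confusion_at(risk, labels, c)
        j = se / 100.0 + sp / 100.0 - 1.0
        # strictly-better J wins; on a J tie keep the higher-Se candidate
        if best is None or j > best[0] + 1e-12 or (
                abs(j - best[0]) <= 1e-12 and se > best[1] + 1e-12):
            best = (j, se, c)
    j, _, c = best
    return _report(score, "youden", c, risk, labels, orientation, youden_j=j)


def se_floor_cutoff(risk, labels, floor: float = 0.95, score: str = "score",
                    orientation: str = "higher_worse") -> ThresholdReport:
    """Among cutoffs with sensitivity >= floor, maximise specificity.

    The -inf sentinel (predict everyone a death, Se = 100%) always
    qualifies, so the rule is total: when nothing else reaches the floor the
    report shows Se 100, Sp 0, undefined NPV and accuracy = prevalence.
    """
    risk = np.asarray(risk, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("sensitivity-floor cutoff needs both classes")
    if not 0.0 <= floor <= 1.0:
        raise ValueError(f"floor must be in [0,1], got {floor}")
    best = None
    for c in candidate_cutoffs(risk):
        se, sp, _, _, _ = confusion_at(risk, labels, c)
        if se is None or se < 100.0 * floor - 1e-9:
            continue
        if best is None or sp > best[0] + 1e-12 or (
                abs(sp - best[0]) <= 1e-12 and se > best[1] + 1e-12):
            best = (sp, se, c)
    _, _, c = best
    return _report(score, "se_floor", c, risk, labels, orientation)
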