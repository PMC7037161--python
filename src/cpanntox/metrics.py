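"""Confusion-matrix statistics and the GA optimization criteria.

The positive class (label 1) is the hepatotoxic class throughout.  Model
search ranks chromosomes by one of three criteria, each damped by a
descriptor-count penalty ``f``:

    OC1 = min(sensitivity(TE1), specificity(TE1)) * f
    OC2 = MCC(TE1) * f
    OC3 = MCC(TR) * MCC(TE1) * f
    f   = 1 - p * (Nselected - 1) / Ndescriptors

where TE1 is the first test set, TR the training set, ``p >= 0`` a
user-chosen strength, ``Nselected`` the number of descriptors in the model
and ``Ndescriptors`` the size of the candidate pool.  ``f = 1`` when the
penalty is off (``p = 0``) or the model uses a single descriptor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "mcc",
    "sensitivity",
    "specificity",
    "descriptor_penalty",
    "optimization_criterion",
    "CRITERIA",
]

CRITERIA = ("OC1", "OC2", "OC3")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Standard 2x2 counts; positive class = 1 (hepatotoxic)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    If any marginal (TP+FP, TP+FN, TN+FP, TN+FN) is zero the coefficient is
    undefined; 0 is returned so that model ranking stays total.
    """
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); raises when no positives were evaluated."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive objects")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); raises when no negatives were evaluated."""
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative objects")
    return c.tn / (c.tn + c.fp)


def descriptor_penalty(p: float, n_selected: int, n_descriptors: int) -> float:
    """Penalty factor f = 1 - p * (Nselected - 1) / Ndescriptors."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if not 1 <= n_selected <= n_descriptors:
        raise ValueError("need 1 <= n_selected <= n_descriptors")
    return 1.0 - p * (n_selected - 1) / n_descriptors


def optimization_criterion(
    criterion: str,
    f: float,
    *,
    sens_te1: float | None = None,
    spec_te1: float | None = None,
    mcc_te1: float | None = None,
    mcc_train: float | None = None,
) -> float:
    """Evaluate one of the three criteria; higher is better."""
    if criterion == "OC1":
        if sens_te1 is None or spec_te1 is None:
            raise ValueError("OC1 needs sens_te1 and spec_te1")
        return min(sens_te1, spec_te1) * f
    if criterion == "OC2":
        if mcc_te1 is None:
            raise ValueError("OC2 needs mcc_te1")
        return mcc_te1 * f
    if criterion == "OC3":
        if mcc_te1 is None or mcc_train is None:
            raise ValueError("OC3 needs mcc_train and mcc_te1")
        return mcc_train * mcc_te1 * f
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
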