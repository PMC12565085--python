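"""Validation metrics for regression and (multi)class classification.

Regression: RMSE, MAE, MedAE, R² (1 − SS_res/SS_tot about the validation
mean), Q²F3 (external-validation determination coefficient whose denominator
is the per-chemical training variance about the training mean, making it
comparable across validation sets) and GMFE (geometric mean fold error,
10^mean|log10(ŷ/y)|, computed on the linear scale; 1 is perfect and values
around or below 2 are conventionally acceptable for PK endpoints).

Classification: sensitivity, specificity and balanced accuracy from confusion
counts; multiclass metrics are computed one-vs-rest per class and aggregated
macro (unweighted mean over classes) and micro (summed one-vs-rest counts).
All values are full precision; rounding belongs to the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    NonPositiveValueError,
    UndefinedClassError,
    ZeroTrainVarianceError,
)


@dataclass(frozen=True)
class RegressionEval:
    """Observed/predicted validation values plus the training observations."""

    y_out: np.ndarray
    y_hat: np.ndarray
    y_train: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "y_out", np.asarray(self.y_out, dtype=float))
        object.__setattr__(self, "y_hat", np.asarray(self.y_hat, dtype=float))
        if self.y_train is not None:
            object.__setattr__(
                self, "y_train", np.asarray(self.y_train, dtype=float)
            )
        if self.y_out.shape != self.y_hat.shape or self.y_out.size < 1:
            raise ValueError("y_out and y_hat must be equal-length, non-empty")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


def rmse(e: RegressionEval) -> float:
    return float(np.sqrt(np.mean((e.y_out - e.y_hat) ** 2)))


def mae(e: RegressionEval) -> float:
    return float(np.mean(np.abs(e.y_out - e.y_hat)))


def medae(e: RegressionEval) -> float:
    return float(np.median(np.abs(e.y_out - e.y_hat)))


def r2(e: RegressionEval) -> float:
    """Determination coefficient about the mean of the observed y_out."""
    ss_res = float(np.sum((e.y_out - e.y_hat) ** 2))
    ss_tot = float(np.sum((e.y_out - np.mean(e.y_out)) ** 2))
    if ss_tot == 0.0:
        raise ZeroTrainVarianceError("observed validation values are constant")
    return 1.0 - ss_res / ss_tot


def q2f3(e: RegressionEval) -> float:
    """External-validation Q²F3.

    1 − [Σ_out (yᵢ−ŷᵢ)²/n_out] / [Σ_train (yᵢ−ȳ_train)²/n_train]; the
    training-based denominator makes the statistic independent of how the
    validation chemicals happen to be distributed.
    """
    if e.y_train is None or e.y_train.size == 0:
        raise ValueError("q2f3 requires y_train")
    denom = float(np.mean((e.y_train - np.mean(e.y_train)) ** 2))
    if denom == 0.0:
        raise ZeroTrainVarianceError("training values are constant")
    num = float(np.mean((e.y_out - e.y_hat) ** 2))
    return 1.0 - num / denom


def gmfe(e: RegressionEval) -> float:
    """Geometric mean fold error on the linear scale.

    Requires strictly positive observed and predicted values (VDss predictions
    must be back-transformed from ln before calling).
    """
    if np.min(e.y_out) <= 0 or np.min(e.y_hat) <= 0:
        raise NonPositiveValueError("GMFE requires strictly positive values")
    return float(10.0 ** np.mean(np.abs(np.log10(e.y_hat / e.y_out))))


def se_sp_ba(c: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), BA = (SE+SP)/2."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedClassError("a confusion denominator is zero")
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    return se, sp, (se + sp) / 2.0


def confusion_one_vs_rest(labels_true: Sequence, labels_pred: Sequence,
                          positive) -> ConfusionCounts:
    lt = np.asarray(labels_true)
    lp = np.asarray(labels_pred)
    if lt.shape != lp.shape:
        raise ValueError("label vectors must align")
    t = lt == positive
    p = lp == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)),
    )


def multiclass_eval(labels_true: Sequence, labels_pred: Sequence,
                    classes: Sequence) -> dict:
    """Per-class one-vs-rest SE/SP/BA plus macro and micro aggregates.

    Macro metrics are unweighted means over classes; micro metrics come from
    the summed one-vs-rest confusion counts (micro-BA = (micro-SE+micro-SP)/2).
    A class with a zero denominator propagates ``UNDEFINED_CLASS``.
    """
    per_class: dict = {}
    tot = dict(tp=0, tn=0, fp=0, fn=0)
    for cls in classes:
        c = confusion_one_vs_rest(labels_true, labels_pred, cls)
        se, sp, ba = se_sp_ba(c)
        per_class[cls] = {"se": se, "sp": sp, "ba": ba, "counts": c}
        tot["tp"] += c.tp
        tot["tn"] += c.tn
        tot["fp"] += c.fp
        tot["fn"] += c.fn
    macro = {
        "se": float(np.mean([per_class[c]["se"] for c in classes])),
        "sp": float(np.mean([per_class[c]["sp"] for c in classes])),
        "ba": float(np.mean([per_class[c]["ba"] for c in classes])),
    }
    mse, msp, mba = se_sp_ba(ConfusionCounts(**tot))
    micro = {"se": mse, "sp": msp, "ba": mba}
    return {"per_class": per_class, "macro": macro, "micro": micro}


def regression_report(e: RegressionEval) -> dict[str, float]:
    """All regression metrics applicable to the evaluation object."""
    out = {"rmse": rmse(e), "mae": mae(e), "medae": medae(e), "r2": r2(e)}
    if e.y_train is not None and e.y_train.size:
        out["q2f3"] = q2f3(e)
    if np.min(e.y_out) > 0 and np.min(e.y_hat) > 0:
        out["gmfe"] = gmfe(e)
    return out
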