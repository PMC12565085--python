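"""Two-stage variable selection in the VSURF style.

Stage 1 ranks descriptors by random-forest permutation importance measured on
out-of-bag (OOB) samples: the importance of a descriptor is the mean decrease
in OOB performance (R² for regression, accuracy for classification) when that
descriptor's column is permuted. A noise floor is estimated from "shadow"
descriptors — shuffled copies of every real column appended to the design —
and only descriptors whose importance exceeds mean + 1 sd of the shadow
importances survive.

Stage 2 walks the surviving descriptors in rank order and keeps a candidate
only when adding it improves cross-validated error by more than one standard
deviation of the incumbent model's fold errors, stopping after ``patience``
consecutive non-improvements. The kept set is the "interpretation" descriptor
set used for modeling.

This is a re-specification of the two-stage idea, not a port of the R VSURF
package; numerical parity with VSURF is an explicit non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold

from .errors import DegenerateTargetError
from .features import DescriptorMatrix

DEFAULT_N_TREES = 500
DEFAULT_STEPWISE_TREES = 100
DEFAULT_N_REPEATS = 3
DEFAULT_PATIENCE = 3
DEFAULT_CV_FOLDS = 5


@dataclass
class SelectionResult:
    ranked: pd.DataFrame            # name, importance_mean, importance_sd
    threshold_set: list[str]        # stage-1 survivors, in rank order
    interpretation_set: list[str]   # stage-2 survivors, in rank order
    noise_floor: float
    seeds: dict = field(default_factory=dict)


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, DescriptorMatrix):
        return x.frame
    return pd.DataFrame(x)


def _is_classification(y: np.ndarray) -> bool:
    return y.dtype.kind in "OUSb"


def _oob_masks(model, n_samples: int) -> np.ndarray:
    """Boolean (n_trees, n_samples) matrix of out-of-bag membership."""
    masks = np.ones((len(model.estimators_), n_samples), dtype=bool)
    for t, sampled in enumerate(model.estimators_samples_):
        masks[t, sampled] = False
    return masks


def _oob_score(model, masks: np.ndarray, x32: np.ndarray, y: np.ndarray,
               classification: bool, classes: np.ndarray | None) -> float:
    """Forest OOB performance with per-tree predictions on ``x32``."""
    n = x32.shape[0]
    if classification:
        agg = np.zeros((n, len(classes)))
    else:
        agg = np.zeros(n)
    counts = np.zeros(n)
    for t, tree in enumerate(model.estimators_):
        oob = masks[t]
        if not oob.any():
            continue
        pred = tree.tree_.predict(x32[oob])
        if classification:
            # leaf class counts -> per-tree probabilities
            agg[oob] += pred / pred.sum(axis=1, keepdims=True)
        else:
            agg[oob] += pred[:, 0]
        counts[oob] += 1
    have = counts > 0
    if classification:
        pred_labels = classes[np.argmax(agg[have], axis=1)]
        return float(np.mean(pred_labels == y[have]))
    pred = agg[have] / counts[have]
    resid = y[have] - pred
    tot = y[have] - y[have].mean()
    return float(1.0 - (resid @ resid) / (tot @ tot))


def rank_by_permutation_importance(
    x, y, n_repeats: int = DEFAULT_N_REPEATS, seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> pd.DataFrame:
    """Rank descriptors by mean decrease in OOB performance under permutation.

    Returns a frame (name, importance_mean, importance_sd) sorted descending
    by mean importance, ties broken by name. Deterministic given the seed.

    Raises
    ------
    DegenerateTargetError
        If the response is constant.
    """
    frame = _as_frame(x)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateTargetError("response is constant")
    classification = _is_classification(y)
    cls = RandomForestClassifier if classification else RandomForestRegressor
    model = cls(n_estimators=n_trees, random_state=seed, bootstrap=True,
                oob_score=False, n_jobs=1)
    x32 = np.ascontiguousarray(frame.to_numpy(), dtype=np.float32)
    model.fit(x32, y)
    classes = model.classes_ if classification else None
    masks = _oob_masks(model, x32.shape[0])
    baseline = _oob_score(model, masks, x32, y, classification, classes)

    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(frame.columns):
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(x32.shape[0])
            xp = x32.copy()
            xp[:, j] = x32[perm, j]
            drops.append(baseline - _oob_score(model, masks, xp, y,
                                               classification, classes))
        rows.append({"name": name,
                     "importance_mean": float(np.mean(drops)),
                     "importance_sd": float(np.std(drops, ddof=1))
                     if n_repeats > 1 else 0.0})
    out = pd.DataFrame(rows).sort_values(
        ["importance_mean", "name"], ascending=[False, True]
    ).reset_index(drop=True)
    return out


def threshold_by_shadows(
    x, y, n_repeats: int = DEFAULT_N_REPEATS, seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[pd.DataFrame, list[str], float]:
    """Stage 1: rank with shadow descriptors and apply the noise floor.

    Shadows are seeded shuffled copies of every real column, appended to the
    design before ranking; the floor is mean + 1 sd of the shadow importances.
    Returns (ranking of real descriptors, surviving names in rank order,
    floor).
    """
    frame = _as_frame(x)
    rng = np.random.default_rng(seed)
    shadows = frame.apply(lambda col: rng.permutation(col.to_numpy()))
    shadows.columns = [f"__shadow__{c}" for c in frame.columns]
    augmented = pd.concat([frame, shadows], axis=1)
    ranked = rank_by_permutation_importance(
        augmented, y, n_repeats=n_repeats, seed=seed, n_trees=n_trees)
    is_shadow = ranked["name"].str.startswith("__shadow__")
    shadow_imp = ranked.loc[is_shadow, "importance_mean"].to_numpy()
    floor = float(shadow_imp.mean() + shadow_imp.std(ddof=1)) if len(
        shadow_imp) > 1 else float(shadow_imp.mean())
    real = ranked.loc[~is_shadow].reset_index(drop=True)
    survivors = real.loc[real["importance_mean"] > floor, "name"].tolist()
    return real, survivors, floor


def _cv_errors(frame: pd.DataFrame, y: np.ndarray, cols: list[str],
               classification: bool, seed: int, n_trees: int,
               n_folds: int) -> np.ndarray:
    """Per-fold CV errors (RMSE or misclassification rate) for a column set.

    An empty column set scores the trivial model (fold-train mean / majority
    class), which anchors the stepwise baseline.
    """
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = []
    for tr, va in kf.split(frame):
        y_tr, y_va = y[tr], y[va]
        if not cols:
            if classification:
                vals, counts = np.unique(y_tr, return_counts=True)
                pred = np.full(len(va), vals[np.argmax(counts)])
            else:
                pred = np.full(len(va), y_tr.mean())
        else:
            cls = (RandomForestClassifier if classification
                   else RandomForestRegressor)
            model = cls(n_estimators=n_trees, random_state=seed, n_jobs=1)
            model.fit(frame.iloc[tr][cols], y_tr)
            pred = model.predict(frame.iloc[va][cols])
        if classification:
            errors.append(float(np.mean(pred != y_va)))
        else:
            errors.append(float(np.sqrt(np.mean((pred - y_va) ** 2))))
    return np.asarray(errors)


def stepwise_forward_select(
    ranked: list[str], x, y, patience: int = DEFAULT_PATIENCE, seed: int = 0,
    n_trees: int = DEFAULT_STEPWISE_TREES, n_folds: int = DEFAULT_CV_FOLDS,
) -> list[str]:
    """Stage 2: greedy forward selection along the importance ranking.

    A candidate is kept when it lowers the mean CV error by more than one
    standard deviation of the incumbent model's fold errors; the walk stops
    after ``patience`` consecutive rejections (``patience=0`` keeps only a
    strictly monotone improvement chain).
    """
    frame = _as_frame(x)
    y = np.asarray(y)
    classification = _is_classification(y)
    kept: list[str] = []
    best = _cv_errors(frame, y, kept, classification, seed, n_trees, n_folds)
    rejections = 0
    for name in ranked:
        cand = _cv_errors(frame, y, kept + [name], classification, seed,
                          n_trees, n_folds)
        tol = float(best.std(ddof=1))
        if cand.mean() < best.mean() - tol:
            kept.append(name)
            best = cand
            rejections = 0
        else:
            rejections += 1
            if rejections > patience:
                break
    return kept


def select_descriptors(
    x, y, seed: int = 0, n_repeats: int = DEFAULT_N_REPEATS,
    n_trees: int = DEFAULT_N_TREES,
    stepwise_trees: int = DEFAULT_STEPWISE_TREES,
    patience: int = DEFAULT_PATIENCE, n_folds: int = DEFAULT_CV_FOLDS,
) -> SelectionResult:
    """Full two-stage selection; returns ranking, both sets and the seeds."""
    ranked, threshold_set, floor = threshold_by_shadows(
        x, y, n_repeats=n_repeats, seed=seed, n_trees=n_trees)
    interpretation = stepwise_forward_select(
        threshold_set, x, y, patience=patience, seed=seed,
        n_trees=stepwise_trees, n_folds=n_folds)
    return SelectionResult(
        ranked=ranked, threshold_set=threshold_set,
        interpretation_set=interpretation, noise_floor=floor,
        seeds={"seed": seed, "n_repeats": n_repeats, "n_trees": n_trees,
               "stepwise_trees": stepwise_trees, "patience": patience,
               "n_folds": n_folds},
    )
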