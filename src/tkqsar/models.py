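"""Learner harness: grid search, repeated cross-validation, final fit.

The harness is learner-agnostic: adapters expose a bare fit/predict contract
for random forests and two gradient-boosting flavors (XGBoost, LightGBM), and
any callable factory can be registered (e.g. an external message-passing
network). Model selection follows a fixed per-task criterion: highest mean
Q²F3 for F% regression, lowest mean GMFE for VDss regression, highest
balanced accuracy for binary, highest macro-BA for multiclass tasks.
Robustness is assessed with repeated k-fold cross-validation (50 iterations
of 5 folds by default), reporting each metric as mean ± sd over folds.
VDss regression is fit on the natural-log scale and predictions are
back-transformed before any thresholding or GMFE computation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold

from . import metrics as M
from .chemreg import Endpoint
from .datasets import ClassScheme, inverse_ln_transform, ln_transform
from .errors import UnknownLearnerError

REGRESSION = "regression"
BINARY = "binary"
MULTICLASS = "multiclass"

IDENTITY = "identity"
LN = "ln"


@dataclass(frozen=True)
class TaskSpec:
    task: str
    endpoint: Endpoint
    scheme: ClassScheme | None = None
    target_transform: str = IDENTITY

    def __post_init__(self):
        if self.task in (BINARY, MULTICLASS) and self.scheme is None:
            raise ValueError(f"{self.task} task requires a ClassScheme")
        if self.task not in (REGRESSION, BINARY, MULTICLASS):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass(frozen=True)
class CVProtocol:
    n_iterations: int = 50
    n_folds: int = 5
    seed: int = 0


@dataclass
class CVReport:
    per_fold: pd.DataFrame          # iteration, fold, one column per metric
    aggregate: pd.DataFrame         # metric, mean, sd

    @staticmethod
    def from_folds(per_fold: pd.DataFrame) -> "CVReport":
        metric_cols = [c for c in per_fold.columns
                       if c not in ("iteration", "fold")]
        agg = pd.DataFrame({
            "metric": metric_cols,
            "mean": [float(per_fold[c].mean()) for c in metric_cols],
            "sd": [float(per_fold[c].std(ddof=1)) for c in metric_cols],
        })
        return CVReport(per_fold=per_fold, aggregate=agg)


# --------------------------------------------------------------------------
# learner registry

LearnerFactory = Callable[[str, dict, int], object]
_LEARNERS: dict[str, LearnerFactory] = {}


def register_learner(name: str, factory: LearnerFactory) -> None:
    """Register ``factory(task, params, seed) -> estimator`` under ``name``."""
    _LEARNERS[name] = factory


def make_learner(name: str, task: str, params: dict | None = None,
                 seed: int = 0):
    if name not in _LEARNERS:
        raise UnknownLearnerError(f"no learner registered as {name!r}")
    return _LEARNERS[name](task, dict(params or {}), seed)


def _rf_factory(task: str, params: dict, seed: int):
    params.setdefault("n_estimators", 500)
    cls = RandomForestRegressor if task == REGRESSION else RandomForestClassifier
    return cls(random_state=seed, n_jobs=1, **params)


class _EncodedClassifier:
    """String-label wrapper for learners that need integer classes."""

    def __init__(self, inner):
        self.inner = inner
        self.classes_: np.ndarray | None = None

    def fit(self, x, y):
        self.classes_, codes = np.unique(np.asarray(y), return_inverse=True)
        self.inner.fit(x, codes)
        return self

    def predict(self, x):
        return self.classes_[np.asarray(self.inner.predict(x), dtype=int)]


def _xgboost_factory(task: str, params: dict, seed: int):
    try:
        import xgboost as xgb
    except ImportError as exc:  # pragma: no cover
        raise UnknownLearnerError("xgboost is not installed") from exc
    params.setdefault("n_estimators", 300)
    params.setdefault("verbosity", 0)
    if task == REGRESSION:
        return xgb.XGBRegressor(random_state=seed, **params)
    return _EncodedClassifier(xgb.XGBClassifier(random_state=seed, **params))


def _lightgbm_factory(task: str, params: dict, seed: int):
    try:
        import lightgbm as lgb
    except ImportError as exc:  # pragma: no cover
        raise UnknownLearnerError("lightgbm is not installed") from exc
    params.setdefault("n_estimators", 300)
    params.setdefault("verbose", -1)
    cls = lgb.LGBMRegressor if task == REGRESSION else lgb.LGBMClassifier
    return cls(random_state=seed, **params)


register_learner("rf", _rf_factory)
register_learner("xgboost", _xgboost_factory)
register_learner("lightgbm", _lightgbm_factory)


# --------------------------------------------------------------------------
# task plumbing

def regression_to_class(pred: float | np.ndarray, scheme: ClassScheme):
    """Threshold regression output (original endpoint scale) into classes.

    Shares the strict-greater "high" convention with the discretizer, so a
    prediction exactly at a cutpoint falls in the lower class.
    """
    if np.isscalar(pred):
        return scheme.label_of(float(pred))
    return np.asarray([scheme.label_of(float(p)) for p in np.asarray(pred)])


def _transform_y(y: np.ndarray, spec: TaskSpec) -> np.ndarray:
    if spec.task == REGRESSION and spec.target_transform == LN:
        return ln_transform(y)
    return y


def _back_transform(pred: np.ndarray, spec: TaskSpec) -> np.ndarray:
    if spec.task == REGRESSION and spec.target_transform == LN:
        return inverse_ln_transform(pred)
    return pred


def _fold_metrics(y_tr, y_va, pred, spec: TaskSpec) -> dict[str, float]:
    """Task-appropriate metrics for one evaluation fold.

    Regression values arrive on the original endpoint scale; ``y_tr`` anchors
    the Q²F3 denominator.
    """
    if spec.task == REGRESSION:
        e = M.RegressionEval(y_out=y_va, y_hat=pred, y_train=y_tr)
        out = {"rmse": M.rmse(e), "mae": M.mae(e), "medae": M.medae(e)}
        try:
            out["r2"] = M.r2(e)
            out["q2f3"] = M.q2f3(e)
        except Exception:
            pass
        if np.min(y_va) > 0 and np.min(pred) > 0:
            out["gmfe"] = M.gmfe(e)
        return out
    classes = list(spec.scheme.labels)
    present = [c for c in classes if c in set(y_va)]
    if spec.task == BINARY:
        try:
            c = M.confusion_one_vs_rest(y_va, pred, classes[-1])
            se, sp, ba = M.se_sp_ba(c)
            return {"se": se, "sp": sp, "ba": ba}
        except Exception:
            return {"se": np.nan, "sp": np.nan, "ba": np.nan}
    try:
        res = M.multiclass_eval(y_va, pred, present)
        return {"macro_se": res["macro"]["se"], "macro_sp": res["macro"]["sp"],
                "macro_ba": res["macro"]["ba"], "micro_se": res["micro"]["se"],
                "micro_sp": res["micro"]["sp"], "micro_ba": res["micro"]["ba"]}
    except Exception:
        return {k: np.nan for k in ("macro_se", "macro_sp", "macro_ba",
                                    "micro_se", "micro_sp", "micro_ba")}


def selection_metric(spec: TaskSpec) -> tuple[str, bool]:
    """(metric name, higher_is_better) used for model/grid selection."""
    if spec.task == REGRESSION:
        if spec.endpoint is Endpoint.VDSS_L_PER_KG:
            return "gmfe", False
        return "q2f3", True
    if spec.task == BINARY:
        return "ba", True
    return "macro_ba", True


def _fit_predict_fold(learner: str, params: dict, seed: int, spec: TaskSpec,
                      x_tr, y_tr, x_va):
    model = make_learner(learner, spec.task, params, seed)
    model.fit(x_tr, _transform_y(y_tr, spec))
    return _back_transform(np.asarray(model.predict(x_va)), spec)


# --------------------------------------------------------------------------
# grid search and repeated CV

def grid_search(learner: str, grid: dict[str, Sequence], x, y, spec: TaskSpec,
                n_folds: int = 5, seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid evaluation by k-fold CV on the training set.

    All grid points share the same seeded folds; the best point maximizes (or
    minimizes, for GMFE) the mean of the task's selection metric, with ties
    broken in favor of the first-listed point. A point whose fit fails is
    scored as worst possible. Returns (best_params, results table).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    frame = pd.DataFrame(x)
    y = np.asarray(y)
    keys = list(grid.keys())
    points = [dict(zip(keys, combo))
              for combo in itertools.product(*(grid[k] for k in keys))]
    metric, higher = selection_metric(spec)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(frame))

    rows = []
    for point in points:
        scores = []
        for tr, va in folds:
            try:
                pred = _fit_predict_fold(learner, point, seed, spec,
                                         frame.iloc[tr], y[tr], frame.iloc[va])
                scores.append(_fold_metrics(y[tr], y[va], pred, spec)[metric])
            except Exception:
                scores.append(np.nan)
        arr = np.asarray(scores, dtype=float)
        mean = float(np.nanmean(arr)) if np.isfinite(arr).any() else np.nan
        rows.append({**{f"param_{k}": v for k, v in point.items()},
                     "mean_score": mean})
    table = pd.DataFrame(rows)

    def sort_value(m):
        if np.isnan(m):
            return -np.inf
        return m if higher else -m

    best_idx = max(range(len(points)),
                   key=lambda i: (sort_value(table["mean_score"][i]), -i))
    return points[best_idx], table


def repeated_cv(learner: str, x, y, spec: TaskSpec,
                protocol: CVProtocol = CVProtocol(),
                params: dict | None = None) -> CVReport:
    """Repeated k-fold CV: a fresh seeded partition per iteration.

    Each iteration's folds exactly partition the training rows (asserted);
    per-fold metrics are aggregated to mean ± sd. Byte-identical given the
    same protocol seed.
    """
    frame = pd.DataFrame(x)
    y = np.asarray(y)
    rows = []
    for it in range(protocol.n_iterations):
        kf = KFold(n_splits=protocol.n_folds, shuffle=True,
                   random_state=protocol.seed + it)
        seen: list[np.ndarray] = []
        for fold, (tr, va) in enumerate(kf.split(frame)):
            seen.append(va)
            pred = _fit_predict_fold(learner, params or {}, protocol.seed,
                                     spec, frame.iloc[tr], y[tr],
                                     frame.iloc[va])
            rows.append({"iteration": it, "fold": fold,
                         **_fold_metrics(y[tr], y[va], pred, spec)})
        covered = np.sort(np.concatenate(seen))
        assert np.array_equal(covered, np.arange(len(frame))), \
            "CV folds must partition the training set"
    return CVReport.from_folds(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# final model

@dataclass
class FittedModel:
    learner: str
    params: dict
    spec: TaskSpec
    descriptor_names: list[str]
    seed: int
    model: object = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        """Predictions on the original endpoint scale (or class labels)."""
        frame = pd.DataFrame(x)[self.descriptor_names]
        return _back_transform(np.asarray(self.model.predict(frame)), self.spec)

    def predict_class(self, x) -> np.ndarray:
        """Classes: direct for classifiers, thresholded for regressors."""
        pred = self.predict(x)
        if self.spec.task == REGRESSION:
            if self.spec.scheme is None:
                raise ValueError("regression-to-class needs a scheme")
            return regression_to_class(pred, self.spec.scheme)
        return pred

    def manifest(self) -> dict:
        return {
            "learner": self.learner,
            "params": self.params,
            "task": self.spec.task,
            "endpoint": self.spec.endpoint.value,
            "scheme": None if self.spec.scheme is None else {
                "cutpoints": list(self.spec.scheme.cutpoints),
                "labels": list(self.spec.scheme.labels),
            },
            "target_transform": self.spec.target_transform,
            "descriptors": self.descriptor_names,
            "seed": self.seed,
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2,
                                         sort_keys=True) + "\n")


def fit_model(learner: str, x, y, spec: TaskSpec, params: dict | None = None,
              seed: int = 0) -> FittedModel:
    frame = pd.DataFrame(x)
    model = make_learner(learner, spec.task, params, seed)
    model.fit(frame, _transform_y(np.asarray(y), spec))
    return FittedModel(learner=learner, params=dict(params or {}), spec=spec,
                       descriptor_names=list(frame.columns), seed=seed,
                       model=model)
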