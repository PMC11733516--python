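"""Closed-form ridge regression with k-fold out-of-fold evaluation.

The screening score is predicted from stacked text embeddings by ridge
regression (L2 penalty λ, unpenalized intercept, optional per-fold feature
standardization).  Validity is measured on pooled out-of-fold predictions —
each respondent predicted by the model trained on the other k−1 folds — via
the Pearson correlation with the observed totals and the mean absolute
error.  Standardization parameters are learned on training folds only, so
no information leaks from a held-out fold into its own predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

__all__ = [
    "RidgeSpec",
    "CVSpec",
    "RidgeModel",
    "OOFResult",
    "EvalMetrics",
    "ridge_fit",
    "kfold_split",
    "oof_predict",
    "evaluate",
    "pearson_with_p",
    "select_lambda",
    "clamp_for_display",
]


@dataclass(frozen=True)
class RidgeSpec:
    """L2 penalty and preprocessing for the ridge fit.

    The default λ=1000 is sized for standardized text embeddings with
    hundreds-to-thousands of columns at a few hundred observations, where
    near-zero penalties let the stacked model overfit badly enough that a
    single-question model beats it out of fold.  Use :func:`select_lambda`
    for a data-driven choice.
    """

    lam: float = 1000.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("ridge penalty must be >= 0")


@dataclass(frozen=True)
class CVSpec:
    k: int = 10
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class RidgeModel:
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xs @ self.coef + self.intercept


@dataclass
class OOFResult:
    fold_assignment: np.ndarray
    predictions: np.ndarray


@dataclass
class EvalMetrics:
    label: str
    n: int
    pearson_r: float
    r_pvalue: float
    mae: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "r": self.pearson_r,
            "p": self.r_pvalue,
            "mae": self.mae,
        }


def ridge_fit(X, y, ridge_spec: RidgeSpec = RidgeSpec()) -> RidgeModel:
    """Solve (XᵀX + λI)β = Xᵀy on centered (optionally standardized) data.

    The intercept is never penalized: it reproduces the mean response at the
    mean feature vector.  When p > n the equivalent dual system
    β = Xᵀ(XXᵀ + λI)⁻¹y is solved instead (exact, O(n³) rather than O(p³)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D and row-aligned with y")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")

    n, p = X.shape
    x_mean = X.mean(axis=0)
    if ridge_spec.standardize:
        x_scale = X.std(axis=0, ddof=0)
        x_scale[x_scale == 0] = 1.0  # constant columns carry no signal
    else:
        x_scale = np.ones(p)
    Xc = (X - x_mean) / x_scale
    y_mean = y.mean()
    yc = y - y_mean

    lam = ridge_spec.lam
    if p <= n:
        A = Xc.T @ Xc + lam * np.eye(p)
        coef = np.linalg.solve(A, Xc.T @ yc) if lam > 0 else np.linalg.lstsq(Xc, yc, rcond=None)[0]
    else:
        G = Xc @ Xc.T + lam * np.eye(n)
        alpha = np.linalg.solve(G, yc) if lam > 0 else np.linalg.lstsq(Xc, yc, rcond=None)[0]
        coef = Xc.T @ alpha if lam > 0 else alpha
    return RidgeModel(coef=coef, intercept=float(y_mean), x_mean=x_mean / 1.0, x_scale=x_scale)


def kfold_split(n: int, cv_spec: CVSpec = CVSpec()) -> np.ndarray:
    """Assign each of n indices to one of k folds; sizes differ by at most 1."""
    if cv_spec.k > n:
        raise ValueError(f"k={cv_spec.k} exceeds n={n}")
    splitter = KFold(
        n_splits=cv_spec.k,
        shuffle=cv_spec.shuffle,
        random_state=cv_spec.seed if cv_spec.shuffle else None,
    )
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n))):
        assignment[test_idx] = fold
    return assignment


def oof_predict(
    features,
    y,
    ridge_spec: RidgeSpec = RidgeSpec(),
    cv_spec: CVSpec = CVSpec(),
    fold_assignment: np.ndarray | None = None,
) -> OOFResult:
    """Out-of-fold predictions: each row predicted by a model it never trained.

    ``features`` is an array or a FeatureMatrix; a precomputed
    ``fold_assignment`` may be passed to hold folds fixed across repeated
    evaluations (as the word-ablation scan requires).
    """
    X = getattr(features, "values", features)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features not row-aligned with y")
    n = X.shape[0]
    if fold_assignment is None:
        fold_assignment = kfold_split(n, cv_spec)
    preds = np.empty(n)
    for fold in np.unique(fold_assignment):
        test = fold_assignment == fold
        model = ridge_fit(X[~test], y[~test], ridge_spec)
        preds[test] = model.predict(X[test])
    return OOFResult(fold_assignment=fold_assignment, predictions=preds)


def pearson_with_p(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p-value via t = r·sqrt((n−2)/(1−r²))."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    n = len(pred)
    if n < 3 or np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(pred, obs)[0, 1])
    r_clip = min(max(r, -0.9999999999), 0.9999999999)
    t = r_clip * np.sqrt((n - 2) / (1 - r_clip**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def evaluate(
    oof_result: OOFResult,
    y,
    subgroups: Mapping[str, np.ndarray] | None = None,
) -> list[EvalMetrics]:
    """Pearson r (+p) and MAE overall and per subgroup mask."""
    y = np.asarray(y, dtype=float)
    preds = oof_result.predictions
    groups: dict[str, np.ndarray] = {"general": np.ones(len(y), dtype=bool)}
    if subgroups:
        groups.update({k: np.asarray(v, dtype=bool) for k, v in subgroups.items()})
    out = []
    for label, mask in groups.items():
        n = int(mask.sum())
        if n < 3:
            out.append(EvalMetrics(label, n, float("nan"), float("nan"), float("nan")))
            continue
        r, p = pearson_with_p(preds[mask], y[mask])
        mae = float(np.mean(np.abs(preds[mask] - y[mask])))
        out.append(EvalMetrics(label, n, r, p, mae))
    return out


def select_lambda(
    X,
    y,
    grid: Sequence[float] = (1.0, 10.0, 100.0, 1000.0, 10000.0),
    cv_spec: CVSpec = CVSpec(k=5),
    standardize: bool = True,
) -> float:
    """Pick the penalty minimizing inner-CV out-of-fold squared error."""
    best_lam, best_mse = None, np.inf
    for lam in grid:
        spec = RidgeSpec(lam=lam, standardize=standardize)
        oof = oof_predict(X, y, spec, cv_spec)
        mse = float(np.mean((oof.predictions - np.asarray(y, dtype=float)) ** 2))
        if mse < best_mse:
            best_lam, best_mse = lam, mse
    return float(best_lam)


def clamp_for_display(
    predictions, floor: float = 4.0, ceiling: float | None = None
) -> np.ndarray:
    """Clamp predictions to the attainable scale range, for plotting only.

    Model predictions below the scale minimum are raised to it; metrics are
    always computed on the raw predictions, never on clamped ones.
    """
    out = np.asarray(predictions, dtype=float).copy()
    out[out < floor] = floor
    if ceiling is not None:
        out[out > ceiling] = ceiling
    return out
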