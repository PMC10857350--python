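"""Spectral regression families behind one fit/predict contract.

Three model families are supported, mirroring common practice in soil
spectroscopy:

* ``plsr`` — partial least squares regression (PLS1), implemented here
  with the NIPALS algorithm. At full rank its predictions coincide with
  ordinary least squares, which serves as a cheap internal oracle.
* ``rule_tree`` — a Cubist-style rule/model-tree ensemble, backed by
  gradient-boosted regression trees.
* ``random_forest`` — bagged regression trees.

Evaluation uses the fraction-of-variance coefficient of determination
R² = 1 − SS_res/SS_tot, which can be negative when predictions are
worse than the mean — a legitimate outcome on external validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

__all__ = [
    "RegressorSpec",
    "FitResult",
    "EvalMetrics",
    "NipalsPLS",
    "fit",
    "predict",
    "r_squared",
]

FAMILIES = ("plsr", "rule_tree", "random_forest")


@dataclass
class RegressorSpec:
    """Model family plus its hyper-parameters and seed.

    Family defaults: plsr ``n_components = min(20, rank)``; rule_tree
    ``max_depth 8, min_leaf 5, n_committees 1`` (100 boosting rounds per
    committee); random_forest ``n_trees 500, min_leaf 1,
    features_per_split 0.33``.
    """

    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        hp = self.hyperparams
        if hp.get("n_components", 1) < 1:
            raise ValueError("n_components must be >= 1")
        if hp.get("n_trees", 1) < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class EvalMetrics:
    """R² (may be negative) and the number of evaluated samples."""

    r2: float
    n: int


@dataclass
class FitResult:
    """A fitted model handle plus training provenance."""

    model: object
    family: str
    target_name: str
    n_bands: int
    training_ids: np.ndarray
    calibration_r2: float
    n_dropped_missing: int = 0


class NipalsPLS:
    """PLS1 regression via NIPALS deflation.

    Components are extracted from the centred data; the final model is
    collapsed to a single coefficient vector ``B = W (PᵀW)⁻¹ q`` so
    prediction is a plain affine map. Extraction stops early if the
    residual covariance vanishes (e.g. constant targets), in which case
    predictions fall back to the training mean.
    """

    def __init__(self, n_components: Optional[int] = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NipalsPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        rank = int(np.linalg.matrix_rank(Xc))
        n_comp = self.n_components
        if n_comp is None:
            n_comp = min(20, max(rank, 1))
        elif n_comp > rank:
            raise ValueError(
                f"n_components={n_comp} exceeds achievable rank {rank}"
            )
        W, P, Q = [], [], []
        eps = np.finfo(float).eps
        for _ in range(n_comp):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw < 1e3 * eps * max(1.0, np.abs(yc).max(initial=0.0)):
                break  # nothing left to extract (constant/fully deflated y)
            w /= nw
            t = Xc @ w
            tt = float(t @ t)
            if tt < 1e3 * eps:
                break
            p = Xc.T @ t / tt
            q = float(yc @ t / tt)
            Xc = Xc - np.outer(t, p)
            yc = yc - q * t
            W.append(w)
            P.append(p)
            Q.append(q)
        if W:
            self.W_ = np.column_stack(W)
            self.P_ = np.column_stack(P)
            self.q_ = np.asarray(Q)
            self.coef_ = self.W_ @ np.linalg.solve(self.P_.T @ self.W_, self.q_)
        else:
            self.W_ = np.zeros((X.shape[1], 0))
            self.P_ = np.zeros((X.shape[1], 0))
            self.q_ = np.zeros(0)
            self.coef_ = np.zeros(X.shape[1])
        self.n_components_ = len(W)
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def _build_model(spec: RegressorSpec):
    hp = spec.hyperparams
    if spec.family == "plsr":
        return NipalsPLS(n_components=hp.get("n_components"))
    if spec.family == "rule_tree":
        return GradientBoostingRegressor(
            n_estimators=100 * hp.get("n_committees", 1),
            max_depth=hp.get("max_depth", 8),
            min_samples_leaf=hp.get("min_leaf", 5),
            learning_rate=hp.get("learning_rate", 0.1),
            max_features=hp.get("features_per_split", 0.25),
            random_state=spec.seed,
        )
    return RandomForestRegressor(
        n_estimators=hp.get("n_trees", 500),
        min_samples_leaf=hp.get("min_leaf", 1),
        max_features=hp.get("features_per_split", 0.33),
        random_state=spec.seed,
        n_jobs=1,
    )


def fit(
    spec: RegressorSpec,
    X: np.ndarray,
    y: np.ndarray,
    sample_ids=None,
    target_name: str = "",
) -> FitResult:
    """Fit one target on a spectra matrix; rows with missing y are
    dropped and counted in ``n_dropped_missing``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    if sample_ids is None:
        sample_ids = np.arange(X.shape[0])
    sample_ids = np.asarray(sample_ids)
    keep = np.isfinite(y)
    n_dropped = int((~keep).sum())
    X, y, sample_ids = X[keep], y[keep], sample_ids[keep]
    if y.size < 2:
        raise ValueError("need at least 2 non-missing training targets")
    model = _build_model(spec).fit(X, y)
    fitted = model.predict(X)
    if np.ptp(y) == 0:
        cal_r2 = float("nan")  # R^2 undefined for a constant target
    else:
        cal_r2 = r_squared(y, fitted).r2
    return FitResult(
        model=model,
        family=spec.family,
        target_name=target_name,
        n_bands=X.shape[1],
        training_ids=sample_ids,
        calibration_r2=cal_r2,
        n_dropped_missing=n_dropped,
    )


def predict(fit_result: FitResult, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != fit_result.n_bands:
        raise ValueError(
            f"band mismatch: model trained on {fit_result.n_bands} bands, "
            f"got {X.shape[1]}"
        )
    out = np.asarray(fit_result.model.predict(X), dtype=float)
    if not np.isfinite(out).all():
        raise ValueError("model produced non-finite predictions")
    return out


def r_squared(observed, predicted) -> EvalMetrics:
    """Coefficient of determination, 1 − SS_res/SS_tot (not squared
    correlation), so values below 0 are possible and meaningful."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant: R^2 undefined (SS_tot = 0)")
    ss_res = float(np.sum((obs - pred) ** 2))
    return EvalMetrics(r2=1.0 - ss_res / ss_tot, n=int(obs.size))
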