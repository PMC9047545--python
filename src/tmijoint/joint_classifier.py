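"""Elastic-net logistic regression for tumor/normal classification.

Minimizes the penalized negative log-likelihood

    (1/n) * sum_i [log(1 + exp(eta_i)) - y_i * eta_i]
        + mu * [(1 - alpha)/2 * ||beta||_2^2 + alpha * ||beta||_1]

with eta_i = beta0 + x_i . beta, an unpenalized intercept and internally
standardized features, via monotone proximal gradient descent (soft-threshold
prox for the L1 part, backtracking line search). Evaluation follows the
three-case design: bacteria-only, cell-only and joint feature blocks,
stratified 75/25 splits repeated over seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ElasticNetConfig:
    mu: float | None = None  # None -> picked by internal CV over a log grid
    alpha: float = 0.5
    max_iter: int = 2000
    tol: float = 1e-9
    seed: int = 0
    train_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.mu is not None and self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class LogisticModel:
    beta0: float
    beta: np.ndarray  # on the original (unstandardized) feature scale
    mu: float
    alpha: float
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    feature_names: list[str] | None = None


def _objective(X, y, b0, b, mu, alpha):
    eta = b0 + X @ b
    # log(1 + e^eta) - y*eta, numerically stable
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    pen = mu * ((1 - alpha) / 2.0 * float(b @ b) + alpha * float(np.abs(b).sum()))
    return nll + pen


def _soft_threshold(v: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)


def fit_logistic_en(
    features: pd.DataFrame | np.ndarray,
    labels,
    config: ElasticNetConfig | None = None,
) -> LogisticModel:
    """Fit the penalized logistic model by proximal gradient descent.

    The objective trace is monotone non-increasing (backtracking guarantees
    descent). Non-convergence within ``max_iter`` flags the result instead of
    raising. Coefficients are mapped back to the original feature scale.
    """
    config = config or ElasticNetConfig()
    names = list(features.columns) if isinstance(features, pd.DataFrame) else None
    X_raw = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X_raw.shape[0] != y.size:
        raise ValueError("features and labels disagree on sample count")
    if not np.all(np.isfinite(X_raw)):
        raise ValueError("features must be finite")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be 0/1")
    for cls in (0.0, 1.0):
        if (y == cls).sum() < 2:
            raise ValueError(f"need at least 2 samples of class {int(cls)}")

    mu = config.mu
    if mu is None:
        mu = _select_mu_by_cv(X_raw, y, config)

    means = X_raw.mean(axis=0)
    sds = X_raw.std(axis=0)
    sds[sds == 0] = 1.0
    X = (X_raw - means) / sds
    n, p = X.shape

    b = np.zeros(p)
    b0 = 0.0
    # Lipschitz bounds for the smooth part (logistic curvature <= 1/4); the
    # unpenalized intercept gets its own, larger step so a strong penalty on
    # beta does not stall it
    L_b = float(np.linalg.norm(X, 2) ** 2) / (4.0 * n) + mu * (1 - config.alpha) + 0.25
    L_b0 = 0.25
    trace = [_objective(X, y, b0, b, mu, config.alpha)]
    converged = False
    for _ in range(config.max_iter):
        eta = b0 + X @ b
        prob = 1.0 / (1.0 + np.exp(-eta))
        resid = prob - y
        grad_b = X.T @ resid / n + mu * (1 - config.alpha) * b
        grad_b0 = float(resid.mean())
        t = 1.0
        obj_old = trace[-1]
        for _bt in range(60):
            b_new = _soft_threshold(b - (t / L_b) * grad_b, (t / L_b) * mu * config.alpha)
            b0_new = b0 - (t / L_b0) * grad_b0
            obj_new = _objective(X, y, b0_new, b_new, mu, config.alpha)
            if obj_new <= obj_old + 1e-15:
                break
            t *= 0.5
        else:  # pragma: no cover - step underflow
            b_new, b0_new, obj_new = b, b0, obj_old
        gain = obj_old - obj_new
        b, b0 = b_new, b0_new
        trace.append(obj_new)
        if gain < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn("elastic-net solver hit max_iter without converging", stacklevel=2)

    beta = b / sds
    beta0 = b0 - float(means @ beta)
    return LogisticModel(
        beta0=beta0,
        beta=beta,
        mu=mu,
        alpha=config.alpha,
        converged=converged,
        objective_trace=trace,
        feature_names=names,
    )


def _select_mu_by_cv(X, y, config: ElasticNetConfig, grid=None, k: int = 5) -> float:
    """5-fold CV accuracy over a log grid of penalty weights."""
    grid = grid if grid is not None else np.logspace(-4, 1, 8)
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, k)
    best_mu, best_acc = float(grid[0]), -np.inf
    for mu in grid:
        accs = []
        for fold in folds:
            mask = np.ones(len(y), dtype=bool)
            mask[fold] = False
            if len(np.unique(y[mask])) < 2 or (y[mask] == 0).sum() < 2 or (y[mask] == 1).sum() < 2:
                continue
            sub = ElasticNetConfig(
                mu=float(mu),
                alpha=config.alpha,
                max_iter=min(config.max_iter, 500),
                tol=max(config.tol, 1e-7),
                seed=config.seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_logistic_en(X[mask], y[mask], sub)
            _, pred = predict(model, X[~mask])
            accs.append(float((pred == y[~mask]).mean()))
        acc = float(np.mean(accs)) if accs else -np.inf
        if acc > best_acc:
            best_acc, best_mu = acc, float(mu)
    return best_mu


def predict(model: LogisticModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities p = sigmoid(beta0 + x.beta) and hard labels at 0.5."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.beta.size:
        raise ValueError(
            f"feature-count mismatch: model has {model.beta.size}, input {X.shape[1]}"
        )
    eta = model.beta0 + X @ model.beta
    probs = 1.0 / (1.0 + np.exp(-eta))
    return probs, (probs >= 0.5).astype(int)


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test index split; guarantees both classes in
    both partitions (re-balances the smallest class if rounding empties it)."""
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def evaluate_three_cases(
    bacteria_features: pd.DataFrame,
    cell_features: pd.DataFrame,
    labels,
    config: ElasticNetConfig | None = None,
    repeats: int = 10,
    seed: int = 0,
) -> dict[str, dict]:
    """Held-out accuracy for bacteria-only, cells-only and joint features.

    Samples are aligned on the bacteria index; each repeat draws a fresh
    stratified 75/25 split, fits one model per feature case and scores the
    test fold. Returns per-case mean, sd and per-repeat accuracies.
    """
    config = config or ElasticNetConfig()
    if not bacteria_features.index.equals(cell_features.index):
        cell_features = cell_features.loc[bacteria_features.index]
    y = np.asarray(labels, dtype=float).ravel()
    if y.size != len(bacteria_features):
        raise ValueError("label count does not match sample count")
    cases = {
        "bacteria": bacteria_features.to_numpy(dtype=float),
        "cells": cell_features.to_numpy(dtype=float),
        "joint": np.hstack(
            [bacteria_features.to_numpy(dtype=float), cell_features.to_numpy(dtype=float)]
        ),
    }
    results = {name: [] for name in cases}
    seeds = [seed + r for r in range(repeats)]
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        train, test = stratified_split(y, config.train_fraction, rng)
        for name, X in cases.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_logistic_en(X[train], y[train], config)
            _, pred = predict(model, X[test])
            results[name].append(float((pred == y[test]).mean()))
    return {
        name: {
            "accuracy_mean": float(np.mean(acc)),
            "accuracy_sd": float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0,
            "accuracies": acc,
            "seeds": seeds,
        }
        for name, acc in results.items()
    }
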