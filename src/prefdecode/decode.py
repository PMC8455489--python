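"""Decoding real-life self-control failure probability from ROI patterns.

Each subject contributes a feature vector of LONG > SHORT contrast values
at the ROI voxels and an outcome y in (0, 1) (their EMA-derived failure
probability). An L1-regularized logistic regression with fractional
responses is trained under leave-one-subject-out cross-validation; the
penalty is chosen by a *nested* inner LOSO loop on each training set over
the grid {2^-8, 2^-8.5, ..., 2^-13.5}. Predictive power is the Pearson
correlation between cross-validated predictions and observed outcomes,
assessed by permuting the predictions and counting null correlations at
least as large as the observed one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._l1 import fit_l1_path, fit_l1_single

__all__ = [
    "DEFAULT_LAMBDA_GRID", "FeatureMatrix", "DecodingResult",
    "PermutationResult", "L1LogisticRegression", "PatternDecoder",
    "extract_features", "fit_l1_logistic", "select_lambda_nested",
    "loso_predict", "kfold_predict", "permutation_test",
    "univariate_baseline",
]

DEFAULT_LAMBDA_GRID = 2.0 ** -np.arange(8.0, 14.0, 0.5)  # 2^-8 .. 2^-13.5


@dataclass
class FeatureMatrix:
    values: np.ndarray            # (n_subjects, n_roi_voxels)
    subject_ids: list[str]
    voxel_coords: np.ndarray      # (n_roi_voxels, 3) lattice indices


@dataclass
class DecodingResult:
    subject_ids: list[str]
    y_obs: np.ndarray
    y_pred: np.ndarray
    chosen_lambda: np.ndarray     # per outer fold
    r: float
    rmse: float
    coefficients: np.ndarray      # (n_folds, n_features), sparse-ish
    intercepts: np.ndarray


@dataclass
class PermutationResult:
    n_perm: int
    observed_r: float
    null_exceed_count: int
    p: float
    p_str: str
    p_plus_one: float             # (b+1)/(m+1) estimator, reported alongside
    null_r: np.ndarray = field(repr=False, default=None)


def extract_features(
    maps: np.ndarray | list,
    roi_mask: np.ndarray,
    subject_ids: list[str] | None = None,
) -> FeatureMatrix:
    """One row per subject, columns in canonical (C-order) mask ordering.

    ``maps`` stacks per-subject contrast volumes (N, nx, ny, nz); rows are
    sorted by subject id so file discovery order cannot matter.
    """
    maps = np.asarray(maps, float)
    roi_mask = np.asarray(roi_mask, bool)
    if maps.shape[1:] != roi_mask.shape:
        raise ValueError("contrast maps and ROI mask are on different grids")
    n = maps.shape[0]
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:02d}" for i in range(n)]
    order = np.argsort(np.asarray(subject_ids, dtype=object))
    coords = np.argwhere(roi_mask)
    flat = maps.reshape(n, -1)[:, roi_mask.ravel()]
    return FeatureMatrix(flat[order], [subject_ids[i] for i in order], coords)


class L1LogisticRegression(BaseEstimator):
    """L1-penalized logistic regression with fractional responses.

    Minimises mean binomial deviance plus ``lam * sum(|coef|)`` with an
    unpenalised intercept (the estimator behind Matlab's ``lassoglm``).
    Accepts y anywhere in [0, 1], so a probability outcome can be
    regressed directly; predictions are inverse-logit scores in (0, 1).

    Attributes (after ``fit``): ``coef_``, ``intercept_``, ``n_iter_``.
    """

    def __init__(self, lam: float = 1e-3, tol: float = 1e-5,
                 max_outer: int = 25, max_inner: int = 60):
        self.lam = lam
        self.tol = tol
        self.max_outer = max_outer
        self.max_inner = max_inner

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        coef, b0 = fit_l1_single(X, y, self.lam, tol=self.tol,
                                 max_outer=self.max_outer,
                                 max_inner=self.max_inner)
        self.coef_ = coef
        self.intercept_ = b0
        return self

    def decision_function(self, X):
        return self.intercept_ + np.asarray(X, float) @ self.coef_

    def predict(self, X):
        """Predicted probability (inverse-logit of the linear score)."""
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))


def fit_l1_logistic(X, y, lam: float) -> tuple[np.ndarray, float]:
    """Functional wrapper: returns ``(coefficients, intercept)``."""
    m = L1LogisticRegression(lam=lam).fit(X, y)
    return m.coef_, m.intercept_


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _heldout_criterion(y_true: np.ndarray, p_hat: np.ndarray,
                       criterion: str) -> np.ndarray:
    eps = 1e-12
    p = np.clip(p_hat, eps, 1 - eps)
    if criterion == "deviance":
        return -2.0 * (y_true[:, None] * np.log(p)
                       + (1.0 - y_true[:, None]) * np.log(1.0 - p))
    if criterion == "mse":
        return (p - y_true[:, None]) ** 2
    raise ValueError(f"unknown inner criterion {criterion!r}")


def select_lambda_nested(
    X_train: np.ndarray,
    y_train: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    inner_criterion: str = "deviance",
    standardize: bool = True,
) -> float:
    """Penalty choice by inner leave-one-subject-out cross-validation.

    For every grid value the held-out criterion of the inner predictions
    is accumulated; the minimiser is returned, ties resolved toward the
    largest (sparsest) penalty. A length-1 grid short-circuits.
    """
    grid = np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be sorted descending")
    if grid.size == 1:
        return float(grid[0])
    n = X_train.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training subjects for the inner loop")
    # NOTE: inner-fold fits must start cold; warm-starting them from a fit
    # on all training rows leaks the held-out row into the selection and
    # biases it toward the smallest penalty.
    loss = np.zeros((n, grid.size))
    for i in range(n):
        tr = np.arange(n) != i
        Xt, yt = X_train[tr], y_train[tr]
        if standardize:
            Xt, mu, sd = _standardize_train(Xt)
            Xh = (X_train[i] - mu) / sd
        else:
            Xh = X_train[i]
        B, B0 = fit_l1_path(Xt, yt, grid, tol=1e-4)
        eta = B0 + B @ Xh
        p_hat = 1.0 / (1.0 + np.exp(-eta))
        loss[i] = _heldout_criterion(np.array([y_train[i]]), p_hat[None, :],
                                     inner_criterion)[0]
    total = loss.sum(axis=0)
    best = np.flatnonzero(total <= total.min() + 1e-12)[0]  # grid descends
    return float(grid[best])


class PatternDecoder(BaseEstimator):
    """Cross-validated ROI-pattern decoder of failure probability.

    ``fit(X, y)`` runs the outer cross-validation (leave-one-subject-out
    by default, k-fold when ``cv`` is an integer): per fold, features are
    standardized on training rows only, the penalty is selected by nested
    inner LOSO, the model refit, and the held-out subjects predicted.
    Fitted attributes hold the cross-validated predictions (``y_pred_``),
    Pearson ``r_``, ``rmse_``, per-fold penalties and coefficients, plus a
    final whole-sample model (``coef_``, ``intercept_``) used by
    ``predict`` on new data.
    """

    def __init__(self, lambda_grid=None, cv: str | int = "loso",
                 inner_criterion: str = "deviance", standardize: bool = True,
                 seed: int = 0):
        self.lambda_grid = lambda_grid
        self.cv = cv
        self.inner_criterion = inner_criterion
        self.standardize = standardize
        self.seed = seed

    # -- fold construction -------------------------------------------------
    def _folds(self, y: np.ndarray) -> list[np.ndarray]:
        n = len(y)
        if self.cv == "loso" or self.cv == n:
            return [np.array([i]) for i in range(n)]
        k = int(self.cv)
        if k < 2:
            raise ValueError("k must be >= 2")
        # stratify by outcome quantile: sort by y, deal blocks round-robin
        rng = np.random.default_rng(self.seed)
        order = np.argsort(y, kind="stable")
        folds: list[list[int]] = [[] for _ in range(k)]
        for start in range(0, n, k):
            block = order[start:start + k]
            for slot, idx in zip(rng.permutation(k)[:len(block)], block):
                folds[slot].append(int(idx))
        return [np.sort(np.array(f, int)) for f in folds if f]

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        if n < 4:
            raise ValueError("need at least 4 subjects")
        if np.all(y == y[0]):
            raise ValueError("constant outcome: correlation undefined")
        grid = (DEFAULT_LAMBDA_GRID if self.lambda_grid is None
                else np.asarray(self.lambda_grid, float))
        folds = self._folds(y)
        y_pred = np.empty(n)
        lambdas = np.empty(len(folds))
        coefs = np.zeros((len(folds), p))
        icepts = np.zeros(len(folds))
        for f, test_idx in enumerate(folds):
            tr = np.setdiff1d(np.arange(n), test_idx)
            Xtr, ytr = X[tr], y[tr]
            if self.standardize:
                Xs, mu, sd = _standardize_train(Xtr)
                Xte = (X[test_idx] - mu) / sd
            else:
                Xs, Xte = Xtr, X[test_idx]
            lam = (float(grid[0]) if grid.size == 1 else
                   select_lambda_nested(Xtr, ytr, grid,
                                        self.inner_criterion,
                                        self.standardize))
            coef, b0 = fit_l1_single(Xs, ytr, lam)
            eta = b0 + Xte @ coef
            y_pred[test_idx] = 1.0 / (1.0 + np.exp(-eta))
            lambdas[f] = lam
            coefs[f] = coef
            icepts[f] = b0
        self.y_obs_ = y
        self.y_pred_ = y_pred
        self.lambda_per_fold_ = lambdas
        self.fold_coefs_ = coefs
        self.fold_intercepts_ = icepts
        self.folds_ = folds
        self.r_ = float(stats.pearsonr(y_pred, y)[0]) if np.std(y_pred) > 0 \
            else float("nan")
        self.rmse_ = float(np.sqrt(np.mean((y_pred - y) ** 2)))
        # final whole-sample model for out-of-sample use
        if self.standardize:
            Xs, self.mu_, self.sd_ = _standardize_train(X)
        else:
            Xs, self.mu_, self.sd_ = X, np.zeros(p), np.ones(p)
        lam_all = (float(grid[0]) if grid.size == 1 else
                   select_lambda_nested(X, y, grid, self.inner_criterion,
                                        self.standardize))
        self.lambda_ = lam_all
        self.coef_, self.intercept_ = fit_l1_single(Xs, y, lam_all)
        return self

    def predict(self, X):
        Xs = (np.asarray(X, float) - self.mu_) / self.sd_
        return 1.0 / (1.0 + np.exp(-(self.intercept_ + Xs @ self.coef_)))

    def result(self, subject_ids: list[str] | None = None) -> DecodingResult:
        ids = subject_ids or [f"sub-{i + 1:02d}" for i in range(len(self.y_obs_))]
        return DecodingResult(ids, self.y_obs_, self.y_pred_,
                              self.lambda_per_fold_, self.r_, self.rmse_,
                              self.fold_coefs_, self.fold_intercepts_)


def loso_predict(X, y, lambda_grid=None, inner_criterion="deviance",
                 standardize=True, subject_ids=None) -> DecodingResult:
    """Leave-one-subject-out cross-validated decoding (functional wrapper)."""
    dec = PatternDecoder(lambda_grid=lambda_grid, cv="loso",
                         inner_criterion=inner_criterion,
                         standardize=standardize).fit(X, y)
    return dec.result(subject_ids)


def kfold_predict(X, y, k: int, lambda_grid=None, inner_criterion="deviance",
                  standardize=True, seed=0, subject_ids=None) -> DecodingResult:
    """Seeded k-fold variant (outcome-quantile stratified folds)."""
    dec = PatternDecoder(lambda_grid=lambda_grid, cv=k,
                         inner_criterion=inner_criterion,
                         standardize=standardize, seed=seed).fit(X, y)
    return dec.result(subject_ids)


def _pearson_nulls(y_obs: np.ndarray, y_pred: np.ndarray,
                   perms: np.ndarray) -> np.ndarray:
    zo = (y_obs - y_obs.mean()) / y_obs.std()
    zp = (y_pred - y_pred.mean()) / y_pred.std()
    return (zp[perms] * zo).mean(axis=1)


def permutation_test(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    n_perm: int = 1_000_000,
    seed: int = 0,
    exact: bool = False,
    keep_null: bool = False,
) -> PermutationResult:
    """Permutation inference on the prediction–outcome correlation.

    The predictions are randomly permuted ``n_perm`` times; the p-value is
    the fraction of null correlations greater than or equal to the
    observed one. With ``exact=True`` (n <= 9) all n! permutations are
    enumerated instead. When no null draw reaches the observed value the
    p-value is reported as "< 1/n_perm" alongside the raw 0.
    """
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    n = len(y_obs)
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        raise ValueError("constant vector: correlation undefined")
    r_obs = float(stats.pearsonr(y_pred, y_obs)[0])
    if exact:
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        perms = np.array(list(itertools.permutations(range(n))))
        m = perms.shape[0]
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        m = int(n_perm)
        nulls = np.empty(m)
        batch = max(1, min(m, 20_000_000 // max(n, 1)))
        done = 0
        while done < m:
            b = min(batch, m - done)
            perms_b = rng.permuted(
                np.broadcast_to(np.arange(n), (b, n)).copy(), axis=1)
            nulls[done:done + b] = _pearson_nulls(y_obs, y_pred, perms_b)
            done += b
        count = int(np.sum(nulls >= r_obs - 1e-15))
        return _perm_result(m, r_obs, count, nulls if keep_null else None)
    nulls = _pearson_nulls(y_obs, y_pred, perms)
    count = int(np.sum(nulls >= r_obs - 1e-15))
    return _perm_result(m, r_obs, count, nulls if keep_null else None)


def _perm_result(m, r_obs, count, nulls) -> PermutationResult:
    p = count / m
    p_str = f"< {1.0 / m:g}" if count == 0 else f"{p:g}"
    return PermutationResult(m, r_obs, count, p, p_str,
                             (count + 1) / (m + 1), nulls)


def univariate_baseline(
    maps: np.ndarray,
    roi_labels: np.ndarray,
    y: np.ndarray,
    lambda_grid=None,
    run_mvpa: bool = True,
) -> pd.DataFrame:
    """Per-ROI mean-signal correlation and (optionally) per-ROI decoding.

    ``roi_labels`` is an integer volume (0 background, 1..k per cluster).
    For each ROI: the subject-wise mean contrast value is correlated with
    the outcome; with ``run_mvpa`` a LOSO decoder restricted to that ROI's
    voxels is also fit.
    """
    maps = np.asarray(maps, float)
    y = np.asarray(y, float)
    ids = sorted(set(roi_labels.ravel()) - {0})
    if not ids:
        raise ValueError("no ROIs in label volume")
    rows = []
    for lab in ids:
        m = roi_labels == lab
        feats = maps.reshape(maps.shape[0], -1)[:, m.ravel()]
        mean_sig = feats.mean(axis=1)
        if np.std(mean_sig) > 0 and np.std(y) > 0:
            r, p = stats.pearsonr(mean_sig, y)
        else:
            r, p = float("nan"), float("nan")
        row = {"roi": int(lab), "n_voxels": int(m.sum()),
               "r_mean_signal": float(r), "p_mean_signal": float(p)}
        if run_mvpa:
            res = loso_predict(feats, y, lambda_grid=lambda_grid)
            row["r_mvpa"] = res.r
            row["rmse_mvpa"] = res.rmse
        rows.append(row)
    return pd.DataFrame(rows)
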