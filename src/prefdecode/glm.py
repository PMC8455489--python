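"""First-level GLM: design construction, per-voxel OLS, and the contrast.

The model has one boxcar-convolved regressor per nonempty decision
category, a missed-trial nuisance regressor, six motion parameters,
discrete-cosine drift columns implementing a 128-s high-pass filter, and a
constant. The contrast of interest is decisions in line with long-term
consequences minus decisions in line with short-term consequences, each
side averaged over its two collapsed categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import LONG_SET, SHORT_SET, TrialClass, TrialResponse
from .hrf import HrfParams, canonical_hrf

__all__ = [
    "DesignMatrix", "GlmFit", "ContrastMap",
    "build_design_matrix", "dct_drift_basis", "fit_glm",
    "contrast_tstats", "compute_contrast",
]

TASK_ORDER = [c for c in TrialClass]  # 8 decision categories then MISSED


@dataclass
class DesignMatrix:
    values: np.ndarray            # (n_scans, n_columns)
    column_labels: list[str]
    frame_times_s: np.ndarray
    tr_s: float
    dropped_conditions: list[str] = field(default_factory=list)

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.column_labels.index(label)]


def dct_drift_basis(n_scans: int, tr_s: float, hp_cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift columns with periods above ``hp_cutoff_s``.

    The k-th basis function has period 2T/k (T = scan duration); columns
    are emitted for k = 1 .. floor(2T / cutoff), excluding the constant
    (k = 0), which is a separate design column.
    """
    T = n_scans * tr_s
    if not np.isfinite(hp_cutoff_s):
        return np.empty((n_scans, 0))
    if hp_cutoff_s <= 0:
        raise ValueError("hp_cutoff_s must be positive")
    k_max = int(np.floor(2.0 * T / hp_cutoff_s))
    n = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
            for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def _condition_regressor(onsets: np.ndarray, duration_s: float, n_scans: int,
                         tr_s: float, hrf_params: HrfParams) -> np.ndarray:
    """Boxcar at microtime resolution, convolved with the HRF, resampled."""
    dt = tr_s / hrf_params.microtime_bins
    n_micro = int(np.ceil(n_scans * tr_s / dt)) + 1
    box = np.zeros(n_micro)
    for on in onsets:
        i0 = int(np.round(on / dt))
        i1 = max(i0 + 1, int(np.round((on + duration_s) / dt)))
        box[i0:min(i1, n_micro)] = 1.0
    kernel = canonical_hrf(hrf_params, dt)
    conv = np.convolve(box, kernel)[:n_micro] * dt
    frame_idx = np.round(np.arange(n_scans) * tr_s / dt).astype(int)
    return conv[frame_idx]


def build_design_matrix(
    trials: list[TrialResponse],
    classes: list[TrialClass],
    motion: np.ndarray | None,
    n_scans: int,
    tr_s: float,
    stim_dur_s: float = 3.5,
    hrf_params: HrfParams | None = None,
    hp_cutoff_s: float = 128.0,
) -> DesignMatrix:
    """Assemble the first-level design matrix.

    Task columns appear in canonical category order; empty categories are
    dropped and recorded in ``dropped_conditions``. Motion (6 columns),
    drift and constant columns follow the task block.
    """
    if hrf_params is None:
        hrf_params = HrfParams()
    onsets = np.array([t.onset_s for t in trials])
    if len(onsets) != len(classes):
        raise ValueError("trials and classes length mismatch")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing (identical or "
                         "overlapping event onsets)")
    if onsets.size and onsets[-1] >= n_scans * tr_s:
        raise ValueError("onsets extend beyond scan duration")

    cols, labels, dropped = [], [], []
    cls_arr = np.array([c.value for c in classes])
    for cond in TASK_ORDER:
        cond_onsets = onsets[cls_arr == cond.value]
        if cond_onsets.size == 0:
            dropped.append(cond.value)
            continue
        cols.append(_condition_regressor(cond_onsets, stim_dur_s, n_scans,
                                         tr_s, hrf_params))
        labels.append(cond.value)

    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape != (n_scans, 6):
            raise ValueError(f"motion must be (n_scans, 6), got {motion.shape}")
        for j in range(6):
            cols.append(motion[:, j])
            labels.append(f"motion_{j + 1}")

    drift = dct_drift_basis(n_scans, tr_s, hp_cutoff_s)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        labels.append(f"drift_{j + 1}")

    cols.append(np.ones(n_scans))
    labels.append("constant")

    return DesignMatrix(np.column_stack(cols), labels,
                        np.arange(n_scans) * tr_s, tr_s, dropped)


@dataclass
class GlmFit:
    betas: np.ndarray        # (n_columns, n_voxels)
    sigma2: np.ndarray       # (n_voxels,) residual variance
    df_resid: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    residuals: np.ndarray | None = None


def fit_glm(
    data: np.ndarray,
    design: DesignMatrix,
    keep_residuals: bool = False,
    ar1_prewhiten: bool = False,
) -> GlmFit:
    """Ordinary least squares per voxel on a (n_scans, n_voxels) array.

    With ``ar1_prewhiten`` a single Cochrane–Orcutt pass is applied: the
    lag-1 autocorrelation is pooled over voxels from OLS residuals, data
    and design are quasi-differenced, and the model refit.
    """
    X = design.values
    Y = np.asarray(data, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("scan count mismatch between data and design")
    if np.isnan(Y).any():
        raise ValueError("NaNs in data")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, design.column_labels)
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns involve {bad}")
    if ar1_prewhiten:
        fit0 = fit_glm(Y, design, keep_residuals=True)
        r = fit0.residuals
        rho = float(np.sum(r[1:] * r[:-1]) / np.sum(r[:-1] ** 2))
        rho = np.clip(rho, -0.99, 0.99)
        Yw = Y[1:] - rho * Y[:-1]
        Xw = X[1:] - rho * X[:-1]
        design = DesignMatrix(Xw, design.column_labels,
                              design.frame_times_s[1:], design.tr_s,
                              design.dropped_conditions)
        X, Y = Xw, Yw

    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    df = X.shape[0] - rank
    sigma2 = (resid ** 2).sum(axis=0) / df
    xtx_inv = pinv @ pinv.T
    return GlmFit(betas, sigma2, df, design, xtx_inv,
                  residuals=resid if keep_residuals else None)


def _collinear_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [labels[i] for i in np.where(diag < tol)[0]]


def contrast_weights(design: DesignMatrix) -> np.ndarray:
    """LONG-minus-SHORT weights, each side normalised to sum to 1.

    A collapsed side with only one surviving regressor (the other category
    was empty for this subject) gives that regressor full weight.
    """
    labels = design.column_labels
    long_idx = [labels.index(c.value) for c in LONG_SET if c.value in labels]
    short_idx = [labels.index(c.value) for c in SHORT_SET if c.value in labels]
    if not long_idx or not short_idx:
        raise ValueError("contrast undefined: one collapsed set is empty "
                         "(subject should have been excluded)")
    w = np.zeros(len(labels))
    for i in long_idx:
        w[i] = 1.0 / len(long_idx)
    for i in short_idx:
        w[i] = -1.0 / len(short_idx)
    return w


def contrast_tstats(fit: GlmFit, weights: np.ndarray) -> np.ndarray:
    """t statistic of ``weights @ betas`` per voxel."""
    est = weights @ fit.betas
    var = fit.sigma2 * float(weights @ fit.xtx_inv @ weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        return est / np.sqrt(var)


@dataclass
class ContrastMap:
    values: np.ndarray            # flat (n_voxels,) or 3-D volume
    subject_id: str
    df_resid: int
    weights: dict[str, float]
    dropped_conditions: list[str]


def compute_contrast(fit: GlmFit, subject_id: str = "") -> ContrastMap:
    """LONG > SHORT contrast estimate per voxel (collapsed at contrast level)."""
    w = contrast_weights(fit.design)
    values = w @ fit.betas
    weights = {lab: float(wi) for lab, wi in zip(fit.design.column_labels, w)
               if wi != 0.0}
    return ContrastMap(values, subject_id, fit.df_resid, weights,
                       list(fit.design.dropped_conditions))
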