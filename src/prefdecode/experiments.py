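"""Validation experiments: error-rate calibration and parameter recovery.

These are the package's own checks that its inferential machinery keeps
its promises on data generated by :mod:`prefdecode.simulate`:

* ``rft_fwe_calibration`` — empirical family-wise error of the
  random-field-theory voxel threshold on smooth Gaussian noise;
* ``permutation_null_calibration`` — false-positive rate (and p-value
  uniformity) of the decode + permutation stage when the brain-outcome
  coupling is absent;
* ``parameter_recovery`` — full-pipeline replicates measuring ROI
  recovery (Dice against the planted masks) and decoding significance.

Problem sizes are desk-scale (see the methods note); each function takes
an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage, stats

from . import ema, group
from ._seeds import child_rng
from .decode import loso_predict, permutation_test
from .pipeline import PipelineConfig, run_pipeline
from .simulate import (SimulationConfig, make_roi_labels, simulate_dataset,
                       simulate_ema)

__all__ = ["rft_fwe_calibration", "permutation_null_calibration",
           "parameter_recovery", "recovery_config"]

_F2S = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def rft_fwe_calibration(
    n_reps: int = 500,
    n_subjects: int = 30,
    dims: tuple[int, int, int] = (16, 16, 16),
    fwhm_vox: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical FWE of the voxel threshold on smooth null t-fields.

    Each replicate builds ``n_subjects`` Gaussian-noise maps smoothed with
    a known kernel, runs the full group stage (t-field, residual
    smoothness estimation, expected-EC threshold), and records whether any
    voxel exceeds t_FWE. The returned rate should sit near ``alpha``.
    """
    mask = np.ones(dims, bool)
    sig = fwhm_vox * _F2S
    hits = 0
    for rep in range(n_reps):
        rng = child_rng(seed, "rft", rep)
        maps = ndimage.gaussian_filter(
            rng.standard_normal((n_subjects,) + dims), (0, sig, sig, sig))
        stat = group.one_sample_t(maps, mask)
        sm = group.estimate_smoothness(maps - maps.mean(axis=0), mask, 1.0)
        _, t_fwe = group.rft_voxel_fwe(stat, sm, alpha)
        hits += bool(stat.t_volume.max() > t_fwe)
    return {"n_reps": n_reps, "fwe_rate": hits / n_reps, "alpha": alpha}


def _null_features(cfg: SimulationConfig, rep_seed: int):
    """Outcome and ROI feature matrix of one null-coupling cohort.

    The cohort is generated by the study simulator with ``coupling_b=0``;
    features are the subjects' measurement-resolution contrast patterns at
    the planted ROI voxels plus first-level estimation noise (the BOLD ->
    GLM steps reproduce exactly these patterns up to that noise, so the
    decode stage sees statistically equivalent input at a fraction of the
    cost).
    """
    cfg = replace(cfg, coupling_b=0.0, seed=rep_seed)
    study = simulate_dataset(cfg, keep_bold=False)
    roi = study.ground_truth.roi_mask
    sig = cfg.smooth_fwhm_mm * _F2S / cfg.voxel_size_mm
    rng = child_rng(rep_seed, "estnoise")
    feats, ys = [], []
    for i, s in enumerate(study.subjects):
        summ = ema.summarize_ema(s.ema)
        if not summ.p_scf_defined:
            continue
        vol = ndimage.gaussian_filter(study.ground_truth.true_beta_long[i], sig)
        feats.append(vol[roi] + rng.normal(0.0, 0.03, roi.sum()))
        ys.append(summ.p_scf)
    return np.array(feats), np.array(ys)


def _independent_null_outcomes(cfg: SimulationConfig, rep_seed: int,
                               n: int) -> np.ndarray:
    """Fresh outcome draws with no dependence on any feature matrix."""
    rng = child_rng(rep_seed, "nullout")
    ys = []
    while len(ys) < n:
        p = 1.0 / (1.0 + np.exp(-(cfg.coupling_intercept
                                  + cfg.logit_noise_sd * rng.normal())))
        summ = ema.summarize_ema(
            simulate_ema(float(np.clip(p, 1e-6, 1 - 1e-6)), cfg, rng))
        if summ.p_scf_defined:
            ys.append(summ.p_scf)
    return np.array(ys)


def permutation_null_calibration(
    n_reps: int = 500,
    n_subjects: int = 16,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Operating characteristics of the permutation test under its null.

    Each replicate decodes a null cohort (``coupling_b = 0``) to obtain a
    realistic prediction vector, then tests it against an *independent*
    EMA outcome draw for which the no-association null holds exactly.
    Returns the rejection rate at ``alpha`` (expected: ``alpha``) and the
    replicate p-values (expected: uniform). The stricter end-to-end null
    — testing the cross-validated predictions against the very outcomes
    they were trained alongside — is measured by
    :func:`parameter_recovery` (``null_reject_rate``) and is known to be
    only approximately calibrated at desk-scale n; see the methods note.
    """
    cfg = SimulationConfig(
        n_subjects=n_subjects, grid_dims=(12, 12, 12), n_items=12, n_reps=1,
        roi_specs=(((6, 6, 6), 4.5),), seed=0)
    pvals = []
    for rep in range(n_reps):
        rep_seed = int(child_rng(seed, "nullperm", rep).integers(2 ** 31))
        X, y = _null_features(cfg, rep_seed)
        if len(y) < 4 or np.std(y) == 0:
            continue
        res = loso_predict(X, y)
        if np.std(res.y_pred) == 0:
            pvals.append(1.0)
            continue
        y_indep = _independent_null_outcomes(cfg, rep_seed, len(y))
        if np.std(y_indep) == 0:
            pvals.append(1.0)
            continue
        perm = permutation_test(y_indep, res.y_pred, n_perm=n_perm,
                                seed=rep_seed ^ 0x5A5A)
        pvals.append(perm.p)
    pvals = np.array(pvals)
    return {
        "n_reps": int(len(pvals)),
        "rejection_rate": float(np.mean(pvals < alpha)),
        "alpha": alpha,
        "p_values": pvals,
    }


def recovery_config(seed: int, coupling_b: float = 2.0,
                    n_subjects: int = 40) -> PipelineConfig:
    """Desk-scale recovery configuration: 16^3 grid, three planted ROIs."""
    sim = SimulationConfig(
        n_subjects=n_subjects, grid_dims=(16, 16, 16),
        roi_specs=(((4, 5, 8), 6.0), ((11, 5, 8), 6.0), ((8, 11, 10), 6.0)),
        coupling_b=coupling_b, seed=seed)
    return PipelineConfig(sim=sim, n_perm=2000, seed=seed)


def _decode_arm(maps, roi_mask, study, task_idx, n_perm, perm_seed):
    """Decode + permutation p for one outcome arm on shared contrast maps."""
    summaries = [ema.summarize_ema(s.ema) for s in study.subjects]
    keep = [j for j, i in enumerate(task_idx)
            if summaries[i].p_scf_defined]
    if len(keep) < 4:
        return float("nan"), 1.0
    y = np.array([summaries[task_idx[j]].p_scf for j in keep])
    if np.std(y) == 0:
        return float("nan"), 1.0
    X = maps[keep].reshape(len(keep), -1)[:, roi_mask.ravel()]
    res = loso_predict(X, y)
    if np.std(res.y_pred) == 0:
        return res.r, 1.0
    perm = permutation_test(y, res.y_pred, n_perm=n_perm, seed=perm_seed)
    return res.r, perm.p


def parameter_recovery(
    n_reps: int = 20,
    coupling_b: float = 2.0,
    n_subjects: int = 40,
    n_perm: int = 2000,
    seed: int = 0,
) -> dict:
    """Paired full-pipeline replicates: ROI Dice, decoding power, null FPR.

    Each replicate simulates a cohort with the given coupling, runs first
    level GLMs, the group stage (Dice against the planted masks), and the
    decode + permutation stage; a matched null arm re-simulates the same
    cohort with ``coupling_b = 0`` — decisions, BOLD, and therefore maps
    and ROI are bit-identical, only the EMA outcomes decouple — and
    decodes the same features against the null outcomes. Replicates where
    no cluster survives count as recovery failures (dice 0, p = 1).
    """
    from . import behavior as _beh
    from .pipeline import _first_level_maps, _group_stage

    rows = []
    for rep in range(n_reps):
        rep_seed = int(child_rng(seed, "recovery", rep).integers(2 ** 31))
        cfg = recovery_config(rep_seed, coupling_b, n_subjects)
        study = simulate_dataset(cfg.sim, keep_bold=False)
        task_idx = [i for i, s in enumerate(study.subjects)
                    if _beh.apply_task_exclusions(s.classes)[0]]
        row = {"dice": 0.0, "r": float("nan"), "p": 1.0,
               "r_null": float("nan"), "p_null": 1.0, "halted": True}
        if len(task_idx) >= 4:
            maps, _ = _first_level_maps(study, cfg, task_idx)
            stat, smooth, table, roi_all = _group_stage(maps, cfg)
            try:
                roi = group.clusters_to_roi(table, roi_all, cfg.roi_mode)
            except ValueError:
                rows.append(row)
                continue
            row["halted"] = False
            row["dice"] = group.dice(roi.mask, study.ground_truth.roi_mask)
            row["peak_t"] = float(table["peak_t"].max())
            row["r"], row["p"] = _decode_arm(
                maps, roi.mask, study, task_idx, n_perm, rep_seed ^ 0xA5A5)
            null_study = simulate_dataset(replace(cfg.sim, coupling_b=0.0),
                                          keep_bold=False)
            row["r_null"], row["p_null"] = _decode_arm(
                maps, roi.mask, null_study, task_idx, n_perm,
                rep_seed ^ 0x3C3C)
        rows.append(row)
    dices = np.array([r["dice"] for r in rows])
    ps = np.array([r["p"] for r in rows])
    ps0 = np.array([r["p_null"] for r in rows])
    return {
        "n_reps": n_reps,
        "coupling_b": coupling_b,
        "dice_ge_05_rate": float(np.mean(dices >= 0.5)),
        "reject_rate": float(np.mean(ps < 0.05)),
        "null_reject_rate": float(np.mean(ps0 < 0.05)),
        "mean_dice": float(dices.mean()),
        "mean_r": float(np.nanmean([r["r"] for r in rows])),
        "replicates": rows,
    }
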