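"""End-to-end orchestration: simulate -> ema -> behavior -> glm -> group -> decode.

``run_pipeline`` executes every stage on a simulated cohort with one
master seed, applies the EMA and task exclusion rules, derives the
decoding ROI from the group analysis, and returns a machine-readable
report. Two ROI-selection modes are provided: ``paper`` derives the ROI
from the full analysed sample (feature selection sees the test subjects,
as in the original analysis, which can be optimistic), while ``honest``
re-derives the ROI inside each outer cross-validation fold from the
training subjects only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, behavior, ema, glm, group
from ._seeds import child_rng
from .decode import (DEFAULT_LAMBDA_GRID, extract_features, fit_l1_single,
                     loso_predict, permutation_test, select_lambda_nested,
                     _standardize_train)
from .simulate import SimulatedStudy, SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "RunReport"]


@dataclass
class PipelineConfig:
    """All stage options; thresholds default to the analysis' printed values."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    hp_cutoff_s: float = 128.0
    prewhiten: bool = False
    cluster_p: float = 0.001
    extent_mm3: float = 270.0
    fwe_alpha: float = 0.05
    connectivity: int = 18
    roi_mode: str = "all_clusters"
    lambda_grid: tuple[float, ...] = tuple(DEFAULT_LAMBDA_GRID)
    inner_criterion: str = "deviance"
    standardize: bool = True
    n_perm: int = 1_000_000
    mode: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "honest"):
            raise ValueError("mode must be 'paper' or 'honest'")
        # one master seed drives simulation and inference children
        self.sim.seed = self.seed


RunReport = dict


def _first_level_maps(study: SimulatedStudy, cfg: PipelineConfig,
                      subject_idx: list[int]) -> tuple[np.ndarray, list[str]]:
    maps, ids = [], []
    for i in subject_idx:
        s = study.subjects[i]
        bold, motion = study.subject_bold(i)
        design = glm.build_design_matrix(
            s.trials, s.classes, motion, bold.shape[0], cfg.sim.tr_s,
            stim_dur_s=cfg.sim.stim_dur_s, hrf_params=cfg.sim.hrf,
            hp_cutoff_s=cfg.hp_cutoff_s)
        fit = glm.fit_glm(bold.reshape(bold.shape[0], -1), design,
                          ar1_prewhiten=cfg.prewhiten)
        cmap = glm.compute_contrast(fit, s.subject_id)
        maps.append(cmap.values.reshape(cfg.sim.grid_dims))
        ids.append(s.subject_id)
    return np.stack(maps), ids


def _group_stage(maps: np.ndarray, cfg: PipelineConfig):
    mask = np.ones(maps.shape[1:], bool)
    stat = group.one_sample_t(maps, mask)
    resid = maps - maps.mean(axis=0)
    smooth = group.estimate_smoothness(resid, mask, cfg.sim.voxel_size_mm)
    table, roi_all = group.extract_clusters(
        stat, smooth, cfg.cluster_p, cfg.extent_mm3, cfg.fwe_alpha,
        cfg.connectivity)
    return stat, smooth, table, roi_all


def _honest_loso(maps: np.ndarray, y: np.ndarray, cfg: PipelineConfig):
    """LOSO decoding with the ROI re-derived per fold from training maps."""
    n = len(y)
    y_pred = np.empty(n)
    grid = np.asarray(cfg.lambda_grid, float)
    n_empty = 0
    for i in range(n):
        tr = np.arange(n) != i
        try:
            _, _, table_i, roi_i = _group_stage(maps[tr], cfg)
            roi_i = group.clusters_to_roi(table_i, roi_i, cfg.roi_mode)
            feats = maps.reshape(n, -1)[:, roi_i.mask.ravel()]
        except ValueError:
            n_empty += 1
            y_pred[i] = float(np.mean(y[tr]))
            continue
        Xtr, ytr = feats[tr], y[tr]
        Xs, mu, sd = _standardize_train(Xtr)
        lam = select_lambda_nested(Xtr, ytr, grid, cfg.inner_criterion,
                                   cfg.standardize)
        coef, b0 = fit_l1_single(Xs, ytr, lam)
        eta = b0 + (feats[i] - mu) / sd @ coef
        y_pred[i] = 1.0 / (1.0 + np.exp(-eta))
    return y_pred, n_empty


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run every stage and return the report dictionary.

    Halts with a clear error if any stage empties the cohort or no ROI
    survives cluster extraction.
    """
    study = simulate_dataset(cfg.sim, keep_bold=False)
    n = cfg.sim.n_subjects

    # --- EMA stage -------------------------------------------------------
    summaries = [ema.summarize_ema(s.ema) for s in study.subjects]
    ema_included, ema_log = ema.apply_ema_exclusions(summaries)
    p_scf = {s.subject_id: s.p_scf for s in summaries}

    # --- behavior stage --------------------------------------------------
    task_log = []
    task_included = []
    for i, s in enumerate(study.subjects):
        ok, reasons = behavior.apply_task_exclusions(s.classes)
        if ok:
            task_included.append(i)
        else:
            task_log += [{"subject_id": s.subject_id, "reason": r}
                         for r in reasons]
    if not task_included:
        raise RuntimeError("behavior stage: task exclusions emptied the cohort")

    # --- first-level GLM -------------------------------------------------
    maps, map_ids = _first_level_maps(study, cfg, task_included)

    # --- group stage -----------------------------------------------------
    stat, smooth, table, roi_all = _group_stage(maps, cfg)
    try:
        roi = group.clusters_to_roi(table, roi_all, cfg.roi_mode)
    except ValueError as e:
        raise RuntimeError(f"group stage: {e}") from None

    gt_mask = study.ground_truth.roi_mask
    dice = group.dice(roi.mask, gt_mask)

    # --- decode stage ----------------------------------------------------
    decode_idx = [i for i in task_included
                  if study.subjects[i].subject_id in ema_included]
    if len(decode_idx) < 4:
        raise RuntimeError("decode stage: fewer than 4 subjects remain")
    sel = np.array([map_ids.index(study.subjects[i].subject_id)
                    for i in decode_idx])
    dmaps = maps[sel]
    ids = [study.subjects[i].subject_id for i in decode_idx]
    y = np.array([p_scf[s] for s in ids])
    grid = np.asarray(cfg.lambda_grid, float)

    honest_empty = 0
    if cfg.mode == "paper":
        feats = extract_features(dmaps, roi.mask, ids)
        res = loso_predict(feats.values, y[np.argsort(np.asarray(ids, object))],
                           lambda_grid=grid,
                           inner_criterion=cfg.inner_criterion,
                           standardize=cfg.standardize,
                           subject_ids=feats.subject_ids)
        y_obs, y_pred = res.y_obs, res.y_pred
        chosen = res.chosen_lambda.tolist()
        out_ids = feats.subject_ids
    else:
        y_pred, honest_empty = _honest_loso(dmaps, y, cfg)
        y_obs, chosen, out_ids = y, [], ids

    from scipy import stats as _st
    r = float(_st.pearsonr(y_pred, y_obs)[0]) if np.std(y_pred) > 0 else float("nan")
    rmse = float(np.sqrt(np.mean((y_pred - y_obs) ** 2)))
    perm_seed = int(child_rng(cfg.seed, "permutation").integers(2 ** 31))
    perm = permutation_test(y_obs, y_pred, n_perm=cfg.n_perm, seed=perm_seed)

    report: RunReport = {
        "software_version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "config": _jsonable(cfg),
        "stages": {
            "ema": {"n_subjects": n, "included": ema_included,
                    "exclusions": ema_log},
            "behavior": {"n_included": len(task_included),
                         "exclusions": task_log},
            "glm": {"n_maps": int(maps.shape[0])},
            "group": {
                "df": stat.df,
                "fwhm_mm": smooth.fwhm_mm.tolist(),
                "resels": smooth.resels.tolist(),
                "t_fwe": roi.provenance.get("t_fwe"),
                "n_clusters": int(len(table)),
                "cluster_table": table.to_dict(orient="records"),
                "roi_voxels": int(roi.mask.sum()),
                "dice_vs_ground_truth": dice,
            },
            "decode": {
                "n_subjects": len(y_obs),
                "r": r, "rmse": rmse,
                "chosen_lambda": chosen,
                "honest_folds_without_roi": honest_empty,
                "subject_ids": out_ids,
                "y_obs": np.asarray(y_obs).tolist(),
                "y_pred": np.asarray(y_pred).tolist(),
            },
            "permutation": {
                "n_perm": perm.n_perm, "observed_r": perm.observed_r,
                "null_exceed_count": perm.null_exceed_count,
                "p": perm.p, "p_str": perm.p_str,
                "p_plus_one": perm.p_plus_one,
            },
        },
    }
    return report


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k))
                for k in obj.__dataclass_fields__}
    if isinstance(obj, (np.ndarray, tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report: RunReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
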