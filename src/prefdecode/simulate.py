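"""Synthetic multi-subject study generator with known ground truth.

The generator emulates the study design end to end: six-point consequence
ratings with a configurable fraction of divergent items, 40 items x 3
repetitions of 3.5-s decision events with jittered 5/6/7-s ISIs at TR 2 s,
one week of EMA alarms (desire -> conflict -> enactment), and 4-D BOLD
volumes built from exactly the forward model the analysis GLM assumes
(boxcar (*) canonical HRF per decision category, discrete-cosine drift,
motion nuisance loadings, AR(1) Gaussian noise, Gaussian smoothing), so
noise-free parameter recovery is exact by construction.

Between-subject coupling: each subject's true LONG > SHORT pattern in the
planted ROIs is the common effect plus a smooth subject-specific deviation
field; a fixed random weight vector over ROI voxels maps that pattern to a
scalar "pattern expression", whose standardised value enters the logit of
the subject's true real-life failure probability with slope ``coupling_b``
(plus independent subject heterogeneity) and, with opposite sign, the
latent self-control that drives in-task decisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from ._seeds import child_rng
from .behavior import (ItemRating, TrialClass, TrialResponse, classify_item,
                       classify_subject, ItemKind)
from .ema import EmaRecord, write_ema_tsv
from .glm import _condition_regressor, dct_drift_basis
from .hrf import HrfParams

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedStudy",
           "simulate_ratings", "simulate_decisions", "simulate_ema",
           "simulate_bold", "simulate_dataset", "make_roi_labels"]

_FWHM2SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Timing, trial counts, and EMA response/desire/conflict/failure rates
    default to the observed study values; voxel grid and effect scales are
    desk-scale choices documented in the methods note.
    """

    n_subjects: int = 24
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_items: int = 40
    n_reps: int = 3
    stim_dur_s: float = 3.5
    isi_choices_s: tuple[float, ...] = (5.0, 6.0, 7.0)
    roi_specs: tuple[tuple[tuple[int, int, int], float], ...] = (
        ((6, 15, 14), 6.0), ((17, 15, 14), 6.0), ((11, 9, 16), 6.0))
    effect_size: float = 0.15          # LONG-SHORT amplitude in ROI (signal units)
    pattern_sd: float = 0.15           # between-subject pattern deviation sd (ROI)
    between_sd: float = 0.1            # mean-zero contrast variability everywhere
    coupling_b: float = 2.0            # logit slope: pattern expression -> p_fail
    coupling_intercept: float = 0.124  # logit of the mean failure rate 0.531
    logit_noise_sd: float = 0.5        # subject heterogeneity beyond the brain
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amp: float = 1.0
    smooth_fwhm_mm: float = 8.0
    motion_load_sd: float = 0.1
    divergence_frac: float = 0.5
    miss_prob: float = 0.02
    decision_slope: float = 1.0
    decision_bias: float = -0.24       # logit of 27.26/61.83 long-consistent
    congruent_accept_prob: float = 0.9
    n_alarms: int = 56
    p_respond: float = 0.785
    p_desire: float = 0.724
    p_conflict: float = 0.365
    p_resist: float = 0.5
    hrf: HrfParams = field(default_factory=HrfParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 8 for d in self.grid_dims):
            raise ValueError("grid_dims must each be >= 8")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        for name in ("p_respond", "p_desire", "p_conflict", "p_resist",
                     "divergence_frac", "miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for (c, r_mm) in self.roi_specs:
            r_vox = r_mm / self.voxel_size_mm
            for ax in range(3):
                if c[ax] - r_vox < 0 or c[ax] + r_vox >= self.grid_dims[ax]:
                    raise ValueError(f"ROI at {c} (radius {r_mm} mm) leaves "
                                     f"the grid {self.grid_dims}")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0 or self.stim_dur_s <= 0:
            raise ValueError("voxel_size_mm, tr_s, stim_dur_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    roi_mask: np.ndarray               # 3-D bool, union of planted ROIs
    roi_labels: np.ndarray             # 3-D int, 1..k per planted ROI
    weight_vector: np.ndarray          # fixed w over ROI voxels
    latent_self_control: np.ndarray    # per subject
    pattern_expression: np.ndarray     # standardised, per subject
    true_p_fail: np.ndarray            # per subject
    true_beta_long: np.ndarray         # (n_subjects, nx, ny, nz)
    true_beta_short: np.ndarray        # (n_subjects, nx, ny, nz)


def make_roi_labels(cfg: SimulationConfig) -> np.ndarray:
    """Integer volume of the planted spherical ROIs (1..k, 0 background)."""
    labels = np.zeros(cfg.grid_dims, int)
    idx = np.indices(cfg.grid_dims)
    for k, (center, r_mm) in enumerate(cfg.roi_specs, start=1):
        d2 = sum((idx[ax] - center[ax]) ** 2 for ax in range(3))
        labels[d2 * cfg.voxel_size_mm ** 2 <= r_mm ** 2] = k
    return labels


def simulate_ratings(cfg: SimulationConfig,
                     rng: np.random.Generator) -> list[ItemRating]:
    """Six-point short/long consequence ratings for all items.

    Each item is divergent (opposite rating signs) with probability
    ``divergence_frac``; magnitudes are uniform on {1, 2, 3} and zero
    never occurs (the six-point scale has no neutral point).
    """
    if cfg.n_items < 2:
        raise ValueError("need at least 2 items")
    ratings = []
    for i in range(cfg.n_items):
        mag_s, mag_l = rng.integers(1, 4, size=2)
        if rng.random() < cfg.divergence_frac:
            s_pos = rng.random() < 0.5
            short, long_ = (mag_s, -mag_l) if s_pos else (-mag_s, mag_l)
        else:
            pos = rng.random() < 0.5
            short, long_ = (mag_s, mag_l) if pos else (-mag_s, -mag_l)
        ratings.append(ItemRating(f"item{i + 1:03d}", int(short), int(long_)))
    return ratings


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_decisions(
    ratings: list[ItemRating],
    latent_self_control: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[TrialResponse]:
    """Trial sequence with onsets and four-point decisions.

    Items are shuffled within each repetition block. On divergent items
    the probability of a long-term-consistent decision is a logistic
    function of the subject's latent self-control; congruent items are
    accepted (all-positive) or declined (all-negative) with probability
    ``congruent_accept_prob``. Each trial is missed with ``miss_prob``.
    """
    if not ratings:
        raise ValueError("ratings must be nonempty")
    p_long = _sigmoid(cfg.decision_slope * latent_self_control
                      + cfg.decision_bias)
    trials = []
    onset = 0.0
    k = 0
    for _ in range(cfg.n_reps):
        for idx in rng.permutation(len(ratings)):
            r = ratings[idx]
            if rng.random() < cfg.miss_prob:
                decision = None
            else:
                strength = int(rng.integers(1, 3))  # 1 or 2
                kind = classify_item(r)
                if kind is ItemKind.DIVERGENT:
                    go_long = rng.random() < p_long
                    # long-term-consistent: decline if long-term is negative
                    accept = (r.long_term > 0) if go_long else (r.long_term < 0)
                else:
                    wants = rng.random() < cfg.congruent_accept_prob
                    accept = wants if kind is ItemKind.CONGRUENT_POS else not wants
                decision = strength if accept else -strength
            trials.append(TrialResponse(k, r.item_id, onset, decision))
            onset += cfg.stim_dur_s + float(rng.choice(cfg.isi_choices_s))
            k += 1
    return trials


def simulate_ema(
    true_p_fail: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "sub-01",
) -> list[EmaRecord]:
    """One week of alarm records with the desire->conflict->enactment chain."""
    if not 0.0 < true_p_fail < 1.0:
        raise ValueError("true_p_fail must be in (0, 1)")
    records = []
    for a in range(1, cfg.n_alarms + 1):
        if rng.random() >= cfg.p_respond:
            records.append(EmaRecord(subject_id, a, answered=False))
            continue
        desire = rng.random() < cfg.p_desire
        if not desire:
            records.append(EmaRecord(subject_id, a, True, desire=False))
            continue
        ds = int(rng.integers(1, 7))
        dt = int(rng.integers(1, 20))
        conflict = rng.random() < cfg.p_conflict
        if not conflict:
            records.append(EmaRecord(subject_id, a, True, True, ds, dt, False))
            continue
        records.append(EmaRecord(
            subject_id, a, True, True, ds, dt, True,
            conflict_strength=int(rng.integers(1, 7)),
            resisted=bool(rng.random() < cfg.p_resist),
            enacted=bool(rng.random() < true_p_fail)))
    return records


def n_scans_for(trials: list[TrialResponse], cfg: SimulationConfig) -> int:
    last = trials[-1].onset_s + cfg.stim_dur_s
    return int(np.ceil((last + 32.0) / cfg.tr_s))


def simulate_bold(
    trials: list[TrialResponse],
    classes: list[TrialClass],
    beta_long: np.ndarray,
    beta_short: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_scans: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-model BOLD: (n_scans, nx, ny, nz) data plus 6 motion series.

    Signal per voxel is the sum over decision categories of the
    boxcar-convolved HRF regressor times the category's true beta (LONG
    categories carry ``beta_long``, SHORT ones ``beta_short``, all others
    zero), plus low-frequency cosine drift, motion loadings, and AR(1)
    noise; the whole run is then spatially smoothed.
    """
    if n_scans is None:
        n_scans = n_scans_for(trials, cfg)
    last = trials[-1].onset_s + cfg.stim_dur_s
    if n_scans * cfg.tr_s < last + 32.0:
        raise ValueError("scan length does not cover the paradigm + 32 s")
    dims = beta_long.shape
    nvox = int(np.prod(dims))
    onsets = np.array([t.onset_s for t in trials])
    cls = np.array([c.value for c in classes])
    data = np.zeros((n_scans, nvox))

    cond_betas = {
        TrialClass.LT_A: beta_long, TrialClass.LT_B: beta_long,
        TrialClass.ST_A: beta_short, TrialClass.ST_B: beta_short,
    }
    for cond in TrialClass:
        cond_onsets = onsets[cls == cond.value]
        if cond_onsets.size == 0:
            continue
        beta = cond_betas.get(cond)
        if beta is None or not np.any(beta):
            continue
        reg = _condition_regressor(cond_onsets, cfg.stim_dur_s, n_scans,
                                   cfg.tr_s, cfg.hrf)
        data += np.outer(reg, beta.ravel())

    if cfg.drift_amp > 0:
        dct = dct_drift_basis(n_scans, cfg.tr_s, 128.0)
        if dct.shape[1]:
            coefs = rng.normal(0.0, cfg.drift_amp, size=(dct.shape[1], nvox))
            data += dct @ coefs

    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_scans, 6)), axis=0)
    if cfg.motion_load_sd > 0:
        loads = rng.normal(0.0, cfg.motion_load_sd, size=(6, nvox))
        data += motion @ loads

    if cfg.noise_sd > 0:
        innov_sd = cfg.noise_sd * np.sqrt(1.0 - cfg.ar1_rho ** 2)
        white = rng.normal(0.0, innov_sd, size=(n_scans, nvox))
        if cfg.ar1_rho > 0:
            white[0] /= np.sqrt(1.0 - cfg.ar1_rho ** 2)
            data += signal.lfilter([1.0], [1.0, -cfg.ar1_rho], white, axis=0)
        else:
            data += white

    vol = data.reshape((n_scans,) + dims)
    if cfg.smooth_fwhm_mm > 0:
        sig = cfg.smooth_fwhm_mm * _FWHM2SIGMA / cfg.voxel_size_mm
        vol = ndimage.gaussian_filter(vol, sigma=(0.0, sig, sig, sig))
    return vol, motion


@dataclass
class SubjectData:
    subject_id: str
    ratings: list[ItemRating]
    trials: list[TrialResponse]
    classes: list[TrialClass]
    ema: list[EmaRecord]
    bold: np.ndarray | None
    motion: np.ndarray | None
    n_scans: int


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    subjects: list[SubjectData]
    ground_truth: GroundTruth

    def subject_bold(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(Re)generate subject ``i``'s BOLD and motion deterministically.

        Uses the same child seed as :func:`simulate_dataset`, so the result
        is identical whether volumes were kept in memory or regenerated —
        lets the pipeline stream subjects instead of holding every 4-D run.
        """
        s = self.subjects[i]
        if s.bold is not None:
            return s.bold, s.motion
        return simulate_bold(
            s.trials, s.classes, self.ground_truth.true_beta_long[i],
            self.ground_truth.true_beta_short[i], self.config,
            child_rng(self.config.seed, "bold", i))

    def write(self, root: str | Path, write_bold: bool = True) -> Path:
        """Write the BIDS-like tree (sub-XX/{func,beh,ema}) plus ground truth."""
        import nibabel as nib

        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        affine = np.diag([self.config.voxel_size_mm] * 3 + [1.0])
        for s in self.subjects:
            for sub in ("func", "beh", "ema"):
                (root / s.subject_id / sub).mkdir(parents=True, exist_ok=True)
            beh = root / s.subject_id / "beh"
            pd.DataFrame(
                [{"item_id": r.item_id, "short_term": r.short_term,
                  "long_term": r.long_term} for r in s.ratings]
            ).to_csv(beh / f"{s.subject_id}_ratings.tsv", sep="\t", index=False)
            pd.DataFrame(
                [{"onset": t.onset_s, "duration": self.config.stim_dur_s,
                  "item_id": t.item_id,
                  "decision": "n/a" if t.decision is None else t.decision,
                  "missed": int(t.decision is None)} for t in s.trials]
            ).to_csv(beh / f"{s.subject_id}_events.tsv", sep="\t", index=False)
            write_ema_tsv(s.ema, root / s.subject_id / "ema"
                          / f"{s.subject_id}_ema.tsv")
            if write_bold and s.bold is not None:
                func = root / s.subject_id / "func"
                img = nib.Nifti1Image(
                    np.moveaxis(s.bold, 0, -1).astype(np.float32), affine)
                nib.save(img, func / f"{s.subject_id}_bold.nii.gz")
                pd.DataFrame(
                    s.motion, columns=[f"motion_{j + 1}" for j in range(6)]
                ).to_csv(func / f"{s.subject_id}_motion.tsv", sep="\t",
                         index=False)
        gt = self.ground_truth
        nib.save(nib.Nifti1Image(gt.roi_labels.astype(np.int16), affine),
                 root / "ground_truth_roi.nii.gz")
        payload = {
            "subjects": [s.subject_id for s in self.subjects],
            "latent_self_control": gt.latent_self_control.tolist(),
            "pattern_expression": gt.pattern_expression.tolist(),
            "true_p_fail": gt.true_p_fail.tolist(),
            "config": _config_dict(self.config),
        }
        (root / "ground_truth.json").write_text(json.dumps(payload, indent=2))
        return root


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["hrf"] = asdict(cfg.hrf)
    return d


def simulate_dataset(cfg: SimulationConfig,
                     keep_bold: bool = True) -> SimulatedStudy:
    """Generate the full multi-subject study, reproducible from ``cfg.seed``.

    Every stochastic step draws from a child generator keyed by
    (master seed, stage, subject), so identical configurations produce
    identical studies and individual stages can be replayed in isolation.
    """
    roi_labels = make_roi_labels(cfg)
    roi_mask = roi_labels > 0
    roi_flat = np.flatnonzero(roi_mask.ravel())
    n_roivox = roi_flat.size
    n = cfg.n_subjects

    w = child_rng(cfg.seed, "weights").normal(size=n_roivox)
    w /= np.linalg.norm(w)

    sig = cfg.smooth_fwhm_mm * _FWHM2SIGMA / cfg.voxel_size_mm
    beta_long = np.zeros((n,) + tuple(cfg.grid_dims))
    for i in range(n):
        rng_i = child_rng(cfg.seed, "pattern", i)
        dev = rng_i.normal(size=cfg.grid_dims)
        if sig > 0:
            dev = ndimage.gaussian_filter(dev, sig)
        dev_roi = dev[roi_mask]
        sd = dev_roi.std()
        dev_roi = dev_roi / sd if sd > 0 else dev_roi
        vol = np.zeros(cfg.grid_dims)
        vol[roi_mask] = cfg.effect_size + cfg.pattern_sd * dev_roi
        if cfg.between_sd > 0:
            # idiosyncratic mean-zero contrast variability over the whole
            # grid (individual differences unrelated to the planted effect)
            idio = rng_i.normal(size=cfg.grid_dims)
            if sig > 0:
                idio = ndimage.gaussian_filter(idio, sig)
            s = idio.std()
            if s > 0:
                vol += cfg.between_sd * idio / s
        beta_long[i] = vol
    beta_short = np.zeros_like(beta_long)

    # expression is defined on the pattern at measurement resolution (the
    # acquisition smoothing applied to the true betas): couplings carried
    # by spatial scales the measurement cannot represent would make the
    # outcome unrecoverable by construction
    if sig > 0:
        measured = np.stack([ndimage.gaussian_filter(beta_long[i], sig)
                             for i in range(n)])
    else:
        measured = beta_long
    expr = measured.reshape(n, -1)[:, roi_flat] @ w
    z = (expr - expr.mean()) / expr.std() if expr.std() > 0 else expr * 0.0
    eps = child_rng(cfg.seed, "heterogeneity").normal(0.0, 1.0, size=n)
    logits = (cfg.coupling_intercept + cfg.coupling_b * z
              + cfg.logit_noise_sd * eps)
    true_p_fail = np.clip(_sigmoid(logits), 1e-6, 1.0 - 1e-6)
    latent = -z

    subjects = []
    for i in range(n):
        sid = f"sub-{i + 1:02d}"
        ratings = simulate_ratings(cfg, child_rng(cfg.seed, "ratings", i))
        trials = simulate_decisions(ratings, float(latent[i]), cfg,
                                    child_rng(cfg.seed, "decisions", i))
        classes = classify_subject(trials, {r.item_id: r for r in ratings})
        ema = simulate_ema(float(true_p_fail[i]), cfg,
                           child_rng(cfg.seed, "ema", i), subject_id=sid)
        if keep_bold:
            bold, motion = simulate_bold(trials, classes, beta_long[i],
                                         beta_short[i], cfg,
                                         child_rng(cfg.seed, "bold", i))
            ns = bold.shape[0]
        else:
            bold, motion, ns = None, None, n_scans_for(trials, cfg)
        subjects.append(SubjectData(sid, ratings, trials, classes, ema,
                                    bold, motion, ns))

    gt = GroundTruth(roi_mask, roi_labels, w, latent, z, true_p_fail,
                     beta_long, beta_short)
    return SimulatedStudy(cfg, subjects, gt)
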