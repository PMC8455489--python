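import numpy as np
import pytest

from prefdecode.behavior import ItemKind, TrialClass, classify_item
from prefdecode.glm import build_design_matrix, compute_contrast, fit_glm
from prefdecode.simulate import (SimulationConfig, simulate_bold,
                                 simulate_dataset, simulate_decisions,
                                 simulate_ema, simulate_ratings)
from tests.conftest import small_config


class TestRatings:
    def test_forced_divergence(self):
        cfg = small_config(divergence_frac=1.0, n_items=50)
        rs = simulate_ratings(cfg, np.random.default_rng(0))
        assert all(classify_item(r) is ItemKind.DIVERGENT for r in rs)

    def test_no_divergence(self):
        cfg = small_config(divergence_frac=0.0, n_items=50)
        rs = simulate_ratings(cfg, np.random.default_rng(0))
        assert not any(classify_item(r) is ItemKind.DIVERGENT for r in rs)

    def test_default_fraction_near_half(self):
        # binomial CI: 10,000 items at p=0.5 -> fraction within 0.5 +/- 0.02
        cfg = small_config(n_items=10_000)
        rs = simulate_ratings(cfg, np.random.default_rng(1))
        frac = np.mean([classify_item(r) is ItemKind.DIVERGENT for r in rs])
        assert abs(frac - 0.5) < 0.02

    def test_no_zero_ratings(self):
        cfg = small_config(n_items=500)
        rs = simulate_ratings(cfg, np.random.default_rng(2))
        assert all(r.short_term != 0 and r.long_term != 0 for r in rs)

    def test_invalid_divergence_fraction(self):
        with pytest.raises(ValueError):
            small_config(divergence_frac=1.5)


class TestDecisions:
    def test_all_missed(self):
        cfg = small_config(miss_prob=1.0)
        rs = simulate_ratings(cfg, np.random.default_rng(0))
        ts = simulate_decisions(rs, 0.0, cfg, np.random.default_rng(0))
        assert all(t.decision is None for t in ts)

    def test_logistic_saturation_all_long(self):
        # latent -> +inf: every divergent-item decision is long-consistent
        cfg = small_config(n_items=100, miss_prob=0.0, divergence_frac=1.0)
        rs = simulate_ratings(cfg, np.random.default_rng(3))
        ts = simulate_decisions(rs, 50.0, cfg, np.random.default_rng(3))
        rmap = {r.item_id: r for r in rs}
        for t in ts:
            r = rmap[t.item_id]
            accept = t.decision > 0
            assert accept == (r.long_term > 0)

    def test_onset_spacing(self):
        cfg = small_config(n_items=40, n_reps=3)
        rs = simulate_ratings(cfg, np.random.default_rng(4))
        ts = simulate_decisions(rs, 0.0, cfg, np.random.default_rng(4))
        gaps = np.diff([t.onset_s for t in ts])
        assert set(np.round(gaps, 6)) <= {8.5, 9.5, 10.5}

    def test_trial_count(self):
        cfg = small_config(n_items=10, n_reps=3)
        rs = simulate_ratings(cfg, np.random.default_rng(5))
        ts = simulate_decisions(rs, 0.0, cfg, np.random.default_rng(5))
        assert len(ts) == 30


class TestEma:
    def test_no_responses(self):
        cfg = small_config(p_respond=0.0)
        recs = simulate_ema(0.5, cfg, np.random.default_rng(0))
        assert all(not r.answered for r in recs)

    def test_failure_fraction_calibrated(self):
        # pool >= 10,000 conflicts; binomial CI half-width ~0.01
        cfg = small_config(n_alarms=56, p_conflict=1.0, p_desire=1.0,
                           p_respond=1.0)
        enacted = []
        for i in range(200):
            recs = simulate_ema(0.5, cfg, np.random.default_rng(1000 + i))
            enacted += [r.enacted for r in recs if r.conflict]
        assert len(enacted) >= 10_000
        assert abs(np.mean(enacted) - 0.5) < 0.015

    def test_conditional_structure(self):
        cfg = small_config()
        recs = simulate_ema(0.3, cfg, np.random.default_rng(2))
        for r in recs:
            if r.conflict:
                assert r.desire
            if r.enacted is not None:
                assert r.conflict


class TestBold:
    def test_deterministic_components_only(self):
        cfg = small_config(noise_sd=0.0, drift_amp=0.0, motion_load_sd=0.0,
                           effect_size=0.0, pattern_sd=0.0, between_sd=0.0)
        study = simulate_dataset(cfg, keep_bold=True)
        bold = study.subjects[0].bold
        assert np.allclose(bold, 0.0)

    def test_noise_free_glm_recovers_true_betas(self):
        # the downstream GLM is the oracle: without noise, drift or
        # smoothing, OLS must return the planted betas exactly
        cfg = small_config(noise_sd=0.0, drift_amp=0.0, motion_load_sd=0.0,
                           smooth_fwhm_mm=0.0, between_sd=0.0, miss_prob=0.0,
                           n_items=20)
        study = simulate_dataset(cfg, keep_bold=True)
        s = study.subjects[0]
        design = build_design_matrix(s.trials, s.classes, s.motion,
                                     s.bold.shape[0], cfg.tr_s)
        fit = fit_glm(s.bold.reshape(s.bold.shape[0], -1), design)
        contrast = compute_contrast(fit, s.subject_id).values
        true_c = (study.ground_truth.true_beta_long[0]
                  - study.ground_truth.true_beta_short[0]).ravel()
        assert np.allclose(contrast, true_c, atol=1e-8)

    def test_ar1_autocorrelation_recovered(self):
        # Monte-Carlo: pure AR(1) noise, lag-1 autocorrelation ~ rho; the
        # series must be long enough that the O(1/T) small-sample bias of
        # the sample autocorrelation stays well inside the tolerance
        cfg = small_config(grid_dims=(22, 22, 22), ar1_rho=0.4,
                           effect_size=0.0, pattern_sd=0.0, between_sd=0.0,
                           drift_amp=0.0, motion_load_sd=0.0,
                           smooth_fwhm_mm=0.0, n_items=60, n_reps=1,
                           roi_specs=(((11, 11, 11), 4.5),))
        study = simulate_dataset(cfg, keep_bold=False)
        s = study.subjects[0]
        bold, _ = study.subject_bold(0)
        x = bold.reshape(bold.shape[0], -1)
        x = x - x.mean(axis=0)
        r1 = (x[1:] * x[:-1]).sum(axis=0) / (x * x).sum(axis=0)
        assert x.shape[1] >= 10_000
        assert abs(r1.mean() - 0.4) < 0.02

    def test_scan_length_validation(self):
        cfg = small_config()
        study = simulate_dataset(cfg, keep_bold=False)
        s = study.subjects[0]
        with pytest.raises(ValueError, match="scan length"):
            simulate_bold(s.trials, s.classes,
                          study.ground_truth.true_beta_long[0],
                          study.ground_truth.true_beta_short[0],
                          cfg, np.random.default_rng(0), n_scans=10)


class TestDataset:
    def test_determinism_byte_identical_tables(self, tmp_path):
        cfg = small_config()
        a = simulate_dataset(cfg, keep_bold=False)
        b = simulate_dataset(cfg, keep_bold=False)
        pa, pb = tmp_path / "a", tmp_path / "b"
        a.write(pa, write_bold=False)
        b.write(pb, write_bold=False)
        for rel in sorted(p.relative_to(pa) for p in pa.rglob("*.tsv")):
            assert (pa / rel).read_bytes() == (pb / rel).read_bytes(), rel

    def test_subject_directories(self, tmp_path):
        cfg = small_config(n_subjects=3)
        simulate_dataset(cfg, keep_bold=False).write(tmp_path / "ds",
                                                     write_bold=False)
        subs = sorted(p.name for p in (tmp_path / "ds").glob("sub-*"))
        assert subs == ["sub-01", "sub-02", "sub-03"]

    def test_bold_regeneration_matches_kept_volumes(self):
        cfg = small_config(n_subjects=2)
        kept = simulate_dataset(cfg, keep_bold=True)
        lazy = simulate_dataset(cfg, keep_bold=False)
        bold, motion = lazy.subject_bold(1)
        assert np.array_equal(bold, kept.subjects[1].bold)
        assert np.array_equal(motion, kept.subjects[1].motion)

    def test_null_coupling_decorrelates_outcome(self):
        cfg = small_config(n_subjects=36, coupling_b=0.0, seed=11)
        study = simulate_dataset(cfg, keep_bold=False)
        gt = study.ground_truth
        r = np.corrcoef(gt.true_p_fail, gt.pattern_expression)[0, 1]
        assert abs(r) < 2.0 / np.sqrt(cfg.n_subjects)

    def test_ground_truth_zero_contrast_outside_roi(self):
        cfg = small_config(n_subjects=6, between_sd=0.0)
        study = simulate_dataset(cfg, keep_bold=False)
        gt = study.ground_truth
        diff = gt.true_beta_long - gt.true_beta_short
        assert np.all(diff[:, ~gt.roi_mask] == 0.0)
        # with idiosyncratic variability the outside mean is zero only in
        # expectation; check the planted component directly above instead
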