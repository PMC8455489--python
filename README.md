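# prefdecode

Analysis pipeline linking laboratory preference decisions to real-life
self-control, for researchers combining task fMRI with smartphone-based
ecological momentary assessment (EMA).

Subjects decide, in the scanner, whether they would enact everyday
behaviors ("drink alcohol", "prepare for exam", …) and later rate each
behavior's anticipated short- and long-term consequences on six-point
scales. Trials on *divergent* items (ratings of opposite sign) are
classified as decisions in line with long-term or short-term
consequences. The package then:

1. builds per-subject GLMs (canonical HRF, 128-s cosine high-pass,
   motion nuisance) and the **decisions long-term > short-term**
   contrast;
2. runs second-level inference with random-field-theory voxel-level FWE
   (p < 0.05), cluster-forming threshold p < 0.001 and a 270 mm³ extent
   rule, and unions the surviving clusters into a region-of-interest
   mask;
3. decodes each subject's real-life self-control failure probability
   p̂ = failures/conflicts (from a week of EMA, 8 alarms/day) from the
   ROI activity pattern, using L1-regularized logistic regression with
   fractional responses (the `lassoglm` estimator), leave-one-subject-out
   cross-validation with nested penalty selection over
   {2⁻⁸, 2⁻⁸·⁵, …, 2⁻¹³·⁵}, and a permutation test of the
   prediction–outcome correlation.

A synthetic-data module generates complete multi-subject studies (EMA
records, ratings, decisions with onsets, 4-D BOLD with AR(1) noise and
planted parietal-like effects, ground truth) so the whole chain is
testable and parameter recovery demonstrable without any download.
`docs/methods.md` describes the model, the generator, and every
numerical choice.

## Worked example

```python
from prefdecode.experiments import recovery_config
from prefdecode.pipeline import run_pipeline

cfg = recovery_config(seed=1)      # 40 subjects, 16^3 grid, 3 planted ROIs
cfg.n_perm = 10_000
report = run_pipeline(cfg)
g = report["stages"]["group"]; d = report["stages"]["decode"]
print("clusters:", g["n_clusters"], "peak t:",
      round(max(c["peak_t"] for c in g["cluster_table"]), 2))
print("ROI Dice vs ground truth:", round(g["dice_vs_ground_truth"], 3))
print("decoding r =", round(d["r"], 3), " RMSE =", round(d["rmse"], 3),
      " p =", report["stages"]["permutation"]["p_str"])
```

prints (seed 1):

```
clusters: 4 peak t: 8.64
ROI Dice vs ground truth: 0.677
decoding r = 0.847  RMSE = 0.173  p = < 0.0001
```

Read: the group stage found the three planted parietal-like clusters
(plus one noise cluster) with strong overlap against the ground-truth
masks; the decoder predicted each held-out subject's real-life failure
probability from their ROI pattern with cross-validated r = 0.85, and no
more than ~1 in 10⁴ permuted prediction vectors correlated as strongly.
(The planted coupling is deliberately strong at this desk scale; the
original cohort effect was r ≈ 0.24 at N = 266.)

The same stages are exposed as a CLI:

```bash
prefdecode simulate --out ds/ --seed 1
prefdecode classify --ratings ds/sub-01/beh/sub-01_ratings.tsv \
                    --events ds/sub-01/beh/sub-01_events.tsv --out classes.tsv
prefdecode run-all --seed 1 --out report.json
```

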