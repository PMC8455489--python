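# Methods

`prefdecode` implements a complete analysis chain linking a laboratory
preference decision-making fMRI task to real-life self-control measured
by ecological momentary assessment (EMA), together with a synthetic-data
generator that makes every stage testable without any acquisition.

## The analysis model

**Outcome.** Each subject's real-life self-control failure probability is
`p_scf = n_failures / n_conflicts`, where a failure is an enacted desire
that the subject reported as conflicting with a superordinate goal.
Subjects with zero reported conflicts (the ratio is undefined) or
incomplete EMA acquisition are excluded; "incomplete" is operationalised
as fewer than `min_answered` answered alarms (default 1), since the study
protocol does not define it more precisely.

**Trial classification.** Items are divergent when the six-point
short-term and long-term consequence ratings (recoded to −3…−1, 1…3; the
scale has no neutral point) have opposite signs. Each answered trial
falls into exactly one of eight categories — the four divergent-item
cells (accept/decline × sign pattern) and the four congruent-item cells —
and the two long-term-consistent cells collapse to LONG, the two
short-term-consistent cells to SHORT. Subjects are excluded for more
than 15 % missed trials (strictly greater than 18 of 120), for more than
9 consecutive misses, or for floor/ceiling behavior, operationalised as
an empty collapsed LONG or SHORT set (the contrast would not exist).
Boundary cases (exactly 18 missed, exactly 9 consecutive) are retained,
following the strict reading of "more than".

**First level.** The GLM has one regressor per nonempty category (3.5-s
boxcars convolved with the canonical double-gamma HRF at microtime
resolution TR/16), a missed-trial regressor, six motion parameters,
discrete-cosine drift columns for periods above 128 s, and a constant.
Events are modelled as 3.5-s boxcars because the item stays on screen for
the full stimulation period; the duration is a parameter. Estimation is
OLS; an optional one-pass Cochrane–Orcutt AR(1) prewhitening mode exists
because the generator produces AR(1) noise, making the option testable.
The LONG > SHORT contrast averages each side's category betas (weight
1/2 each, or 1 for a lone survivor when a subject lacks one
sub-category); collapsing at the contrast level is algebraically
identical under OLS to refitting a two-condition model.

**Group level.** A voxelwise one-sample t on the contrast images (on
difference images this equals the paired t-test between conditions).
Smoothness is estimated from the variance of spatial derivatives of the
voxelwise-normalised residual images (Kiebel/Worsley); for unsmoothed
noise this estimator converges to √(2 ln 2) ≈ 1.18 voxels, and it
overestimates an applied kernel by a few percent through the
forward-difference discretisation — both properties are tested. Resel
counts use the lattice point/edge/face/cube construction, so arbitrary
masks are supported. Voxel-level FWE uses the expected Euler
characteristic of a t field (Worsley's closed-form densities ρ₀…ρ₃),
capped at the Bonferroni bound over in-mask voxels: at low smoothness the
raw EC approximation can exceed Bonferroni, and the cap (as in SPM)
restores the guarantee that the correction is never stricter than
Bonferroni. The critical threshold is found by root-finding on the
decreasing branch of the expected-EC curve (the 3-D density is negative
below t ≈ 1, so the curve is not monotone near the origin). Clusters
form at uncorrected p < 0.001 under 18-connectivity (6/26 selectable;
the original convention is not stated) with a 270 mm³ extent rule
(10 voxels at 3 mm isotropic); retained clusters are ordered by peak t
with lexicographic coordinate tie-breaks, and their union is the
decoding ROI (`all_clusters` default; `fwe_peaks_only` restricts to
clusters whose peak survives voxel FWE).

**Decoding.** Features are the contrast values at ROI voxels, one row
per subject, columns in canonical C-order of the mask. The decoder is an
L1-penalized logistic regression with *fractional* responses: it
minimises mean binomial negative log-likelihood plus λ‖β‖₁ with an
unpenalised intercept (the estimator behind Matlab's `lassoglm`), so a
probability outcome is regressed directly and predictions live in (0,1).
The solver is IRLS with cyclic soft-thresholded coordinate descent,
warm-started along the descending λ path and accelerated by active-set
sweeps; a numba-compiled kernel backs a pure-Python fallback.
Cross-validation is leave-one-subject-out; features are standardised on
training rows only; λ is chosen per outer fold by an inner LOSO loop
over the grid {2⁻⁸, 2⁻⁸·⁵, …, 2⁻¹³·⁵} minimising held-out binomial
deviance (squared error selectable), ties resolved toward the largest
(sparsest) penalty. Inner-fold fits start cold: warm-starting them from
a fit on all training rows leaks the held-out subject into the selection
(we measured the selection collapsing to the smallest penalty).
Performance is Pearson r between cross-validated predictions and
observed outcomes plus RMSE; significance comes from permuting the
prediction vector (1,000,000 draws by default) and counting null
correlations ≥ the observed one; with a zero count the p-value is
reported as "< 1/n_perm", and the (b+1)/(m+1) estimator is reported
alongside. A seeded, outcome-quantile-stratified k-fold variant
(identical to LOSO at k = n) and a per-ROI univariate/decoding baseline
are provided. ROI selection has two modes: `paper` derives the ROI from
the full analysed sample (feature selection sees the test subjects — the
original procedure, which can be optimistic), `honest` re-derives the
ROI inside each outer fold from training subjects only, predicting the
training-mean outcome for folds in which no cluster survives.

## The synthetic-data generator

The forward model mirrors the analysis GLM exactly — boxcar ⊛
double-gamma HRF per category, cosine drift with random coefficients,
motion series (random walks) with small spatial loadings, stationary
AR(1) Gaussian noise, then 3-D Gaussian smoothing — so with noise, drift,
motion, and smoothing disabled, OLS recovers the planted betas to
machine precision (tested). Timing and rates follow the study design:
40 items × 3 repetitions, 3.5-s stimuli, ISIs drawn from {5, 6, 7} s,
TR 2 s, 2 % missed trials; EMA with 56 alarms, response rate 0.785,
desire rate 0.724, conflict rate 0.365, and a mean failure rate 0.531
(logit intercept 0.124).

**Planted effect and coupling.** Each subject's true LONG beta inside
the planted spherical ROIs is `effect_size` plus a smooth
subject-specific deviation (sd `pattern_sd`); SHORT betas are zero. A
mean-zero smooth idiosyncratic field (sd `between_sd`) is added over the
whole grid: without it the only outside-ROI variance would be
first-level estimation noise, which is so small that smoothing spill
makes detected clusters dilate far beyond the planted ROIs. A fixed
random unit weight vector w over ROI voxels maps each subject's pattern
to a scalar expression; the expression is evaluated on the pattern *at
measurement resolution* (acquisition smoothing applied), because a
coupling carried by spatial scales the measurement cannot represent
would be unrecoverable by construction, for any decoder. The
standardised expression zᵢ enters the failure-probability logit with
slope `coupling_b` alongside independent subject heterogeneity
(`logit_noise_sd`), and −zᵢ is the latent self-control driving
divergent-item decisions through a logistic choice rule (bias −0.24,
matching ≈44 % long-term-consistent divergent decisions).

**Desk-scale calibration.** Defaults are 24³ voxels at 3 mm (16³ for the
recovery experiments) instead of whole-brain 64×64×34 — small enough for
laptop runs while preserving 3-D cluster geometry. `effect_size = 0.15`
(in units of the AR(1) noise sd) was calibrated once so that an N = 40
run yields peak t ≈ 6.5–10 with all three planted ROIs recovered
reliably; pushing peaks down to the observed 4.4–4.7 made per-ROI
cluster formation too fragile at desk n, and recovery reliability was
prioritised. `coupling_b = 2.0` likewise defines a clearly detectable
brain–behavior coupling at n = 40 (cross-validated r ≈ 0.5–0.9, versus
the much smaller effect observable at the real N = 266); the generator
is therefore a power-friendly caricature, and passing tests demonstrate
correctness of the machinery, not that effects of the published size are
detectable at n = 40.

**What the generator does not emulate:** anatomy and tissue contrast,
physiological noise, true motion artefacts (only additive nuisance
loadings), slice timing, registration error, spatial nonstationarity,
EMA timestamp dynamics within days.

## Validation experiments

* **RFT calibration** — 500 replicates of 30 smooth null maps (16³,
  FWHM 3 voxels): empirical voxel-FWE ≈ 0.03 at α = 0.05 (mildly
  conservative, as expected at 3-voxel smoothness with the Bonferroni
  cap).
* **Permutation-test calibration** — 500 null replicates in which
  realistic cross-validated predictions are tested against an
  independent outcome draw: rejection ≈ 0.05 and uniform p-values, as
  exchangeability holds exactly there.
* **End-to-end null** — testing cross-validated predictions against the
  very outcomes they were trained alongside is only approximately
  exchangeable: subject i's prediction depends on yⱼ and vice versa.
  At the study's N = 266 this contamination is negligible, but at desk
  scale it inflates the false-positive rate above nominal (≈ 9–10 % at
  n = 16 in our measurements, for fixed-penalty L1, ridge, and iid
  features alike). This is a property of the published significance
  procedure itself, reported honestly by the paired recovery experiment.
* **Parameter recovery** — 20 paired replicates at n = 40, 16³, three
  ROIs: Dice ≥ 0.5 between recovered and planted ROI sets and
  permutation p < 0.05 with coupling present; the matched null arm
  re-simulates the same cohort with `coupling_b = 0` (decisions and BOLD
  are bit-identical by seed construction, only EMA outcomes decouple),
  so both arms share one set of first-level fits.

## Numerical choices

Seeding is hierarchical: every stochastic operation derives its
generator from (master seed, stage name, subject index), so stages can
be replayed in isolation and whole studies are bit-reproducible. The
L1 solver uses coefficient-change tolerance 1e-5 (1e-4 inside
cross-validation, where only the ranking of penalties matters; we
verified selections and predictions are unchanged). Zero-variance
voxels in the group t-map get signed-infinite t and are counted;
zero-variance feature columns get unit scale in standardisation.
Degenerate inputs (constant outcomes, empty collapsed conditions, empty
cluster tables) raise informative errors rather than propagating NaNs;
the pipeline halts with stage context.

## Known limitations

RFT smoothness estimation is slightly biased by forward-difference
discretisation (a few percent at 8 mm / 3 mm voxels); no cluster-level
FWE p-values; prewhitening is a single Cochrane–Orcutt pass, not a full
ReML AR model; the k for the k-fold variant must be supplied (none is
canonical); the end-to-end permutation null is anticonservative at small
n as described above.
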