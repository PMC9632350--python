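# Methods

## Data model

The unit of analysis is a subject row: chronological age (years), optional
sex/protocol labels, and mean fractional anisotropy (FA, dimensionless,
typically 0.2–0.7) for 21 named white-matter tract systems. The canonical
tract order (`tractage.TRACT_NAMES`) is fixed across every table, matrix
and report, so index *i* always refers to the same tract.

## Synthetic cohort generator

Per subject *i* and tract *t*:

```
FA_t(i) = baseline_t − slope_t · max(0, age_i + δ_i − onset_t)
          + protocol_offset_t + ε,     ε ~ N(0, noise_sd_t)
```

with ages uniform on [20, 82] and a subject-level latent shift
δ_i ~ N(0, gap_sd). δ is the synthetic *brain-age gap*: it moves the
subject's effective age in every tract coherently, so a well-behaved
age-correction should preserve it. The generator records δ (`true_gap`)
and provides the exact gap- and noise-preserving ground truth corrector

```
FA_corr = FA_obs + slope_t · (max(0, age+δ−onset_t) − max(0, target+δ−onset_t)).
```

Defaults (one fixed literal table, `synthetic.py`): baselines 0.35–0.60,
decline onsets 30–50 y, slopes 0.0005–0.0020 FA/y, noise SD 0.010–0.030,
gap SD 5 y, n = 217 — the regime in which healthy-adult tract FA is
usually reported, with two zero-slope cerebellar tracts (SCP, MCP).

What the generator does *not* emulate: scanner/protocol nuisance beyond
additive tract-level offsets, non-Gaussian noise, tract-tract noise
correlations, cohort age structure other than uniform, and any disease
effects. Synthetic cohorts are therefore "cleaner" than real data — the
pipeline reaches test R² ≈ 0.8 here versus ≈ 0.5 reported on real
tract-FA cohorts — so passing tests demonstrate correctness of the
algorithms, not expected field performance.

## Preprocessing

Rows with any missing FA are dropped (each row counts once). The cohort
is split 80:20 uniformly at random (test size = floor(0.2·n); 217 → 174/43),
reproducibly by seed and unstratified. Per-tract FA means/SDs and the age
mean/SD are estimated on training rows only (population SDs, ddof = 0);
all model mathematics happens in this z-space and public outputs are
transformed back. Z-scoring the age target makes the ridge intercept
exactly 0, which in turn anchors the identity-initialized network.

Multi-protocol tables can be harmonized at the tract level: per
non-reference protocol and tract, the mean FA difference to the reference
protocol within shared decade age bins is subtracted. This is a
deliberate tract-level adaptation — voxel-wise difference-map
harmonization needs imaging data this package does not consume.

## Models

**Ridge.** Closed-form normal equations on centered data with an
unpenalized intercept. The L2 grid is 100 → 0 in steps of 0.1 (1001
points) scored by exact LOOCV. LOOCV residuals use the linear-smoother
leverage identity `e_loo = e/(1 − h_ii)` (verified against explicit
refits to 1e-10 in the tests), so the full grid costs one small solve per
alpha.

**Network.** `y = ReLU(xW + b)·v + c` with square 21×21 `W`. At
initialization `W = I`, `b = 0`, `v` = ridge coefficients, `c` = ridge
intercept, so the starting network reproduces the ridge prediction for
inputs with non-negative pre-activations. Training is full-batch Adam
(step 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on
`mean(err²)/2 + α(‖W‖² + ‖v‖²)/(2n)`, stopping when the loss fails to
improve by 1e-4 for 10 consecutive iterations or at 100,000 iterations.
With a fixed initialization and full batches training is deterministic —
no training seed exists.

The network α grid is 20 → 0 in steps of 0.1 scored by LOOCV, with each
fold re-pretraining its own ridge output layer. Because 201 alphas × n
folds × a full training run is expensive, the default *fast* mode uses a
10-point coarse grid with 5-fold CV and capped per-fold iterations; the
exhaustive mode stays available (`fast=False`). Grid ties break toward
the larger alpha (more regularization).

**Pruning.** After training, the smallest-magnitude nonzero entry of `W`
is zeroed repeatedly until total nonzero parameters (nonzeros of W + both
bias vectors + output weights + output bias) ≤ n_train. The budget is
read as "the whole network's free parameters", and only hidden-matrix
entries are prunable. If a removal would push cond(W) above 1e8 the entry
is restored and pruning stops early with a warning — the correction
algorithm needs `W⁻¹`. At n_train = 174 this leaves ≈ 70 % zeros in `W`.

## Inspection

Permutation importance shuffles one test-set column at a time (1,000
repeats by default) and reports the mean/SD drop in R². R² is used as the
scoring metric (it is the package's reported prediction metric); negative
importances are kept internally, with clipping to zero offered only as a
display transform. Diagonal dominance asks, per hidden neuron *j*,
whether `W_jj` is the highest *signed* value in column *j*. Convergent
neurons are columns with ≥ 10 nonzero incoming weights (boundary
inclusive), labeled by their largest-weight input tract.

## Age correction

For one subject with z-scored FA row `x`:

1. `y = forward(x)`; target `y_target = y + (global_target − chron_age)`
   — fixed once from the initial prediction, never recomputed. Shifting
   the prediction rather than replacing it preserves the brain-age gap.
2. `E = y − y_target`; one plain gradient step on the hidden matrix,
   `W′ = W − lr·E·∂y/∂W` (lr = 0.001, no momentum — a single step from a
   fresh optimizer makes momentum machinery irrelevant). Only `W` takes
   the transient step; bias/output gradients do not enter `x·W′·W⁻¹`.
3. `x ← x·W′·W⁻¹`.
4. Constraints, checked each iteration against the *original* input: when
   the target is older FA may only decrease (and vice versa), and the
   frozen tracts (SCP, MCP) never change; offending entries are reset to
   their original values.

The loop stops when `|E| ≤ 1/12 year` (converted to z-units via the age
SD). Safeguards absent from the original procedure but needed in
practice: an iteration cap (10,000) and stall detection (no |E|
improvement > 1e-10 over 200 iterations — e.g. all updates reverted),
both raising typed errors; cohort-level correction flags failed subjects
instead of aborting. Entries pinned to their original z-value get their
original FA back verbatim, so frozen tracts are bit-identical in the
output. Constraints act in z-space, which is equivalent to FA units
because the transform is affine with positive slope.

The comparison baseline fits per-tract OLS `FA ~ age` on the training set
(slope forced to 0 for SCP/MCP, so both methods leave those tracts
untouched) and moves each subject along the fitted lines:
`FA + β_t(target − age)`.

## Evaluation

R² is `1 − Σ(est − ref)²/Var(ref)` with the *linearly corrected* values
as reference in agreement analyses — the only convention that can go
negative when the two corrections disagree, which is informative. MAE is
the mean absolute error in years. CIs are percentile bootstrap (1,000
subject-level resamples; degenerate resamples skipped and counted).
Bland-Altman reports the mean difference and mean ± 1.96·SD limits; in
agreement reports the difference is oriented linear − ANN, so a positive
mean difference means the ANN produced the lower FA. The combined
agreement row pools all tract-subject pairs (bootstrap still resamples
subjects). Shapiro-Wilk (scipy) tests normality of prediction errors.

## Known limitations

* The input update moves every subject along essentially one direction in
  tract space, `(v∘mask)·W⁻¹`, whereas true aging moves each tract by its
  own slope. The correction therefore matches the *prediction-level*
  contract exactly (shift of the predicted age by target − chron within
  one month) but can concentrate FA change in a few tracts and barely
  move others; with no mechanism bounding the per-tract range,
  implausible values are possible for weakly constrained tracts. On
  low-noise synthetic cohorts the per-tract RMSE against the generator's
  ground-truth correction is accordingly several times the noise SD.
  Practical consequence: prefer group-level use and small intended age
  shifts.
* A handful of subjects may fail to converge (all updates blocked by the
  sign constraints, or dead hidden units); they are flagged and excluded
  from agreement reports rather than silently filled.
* Tract-specific target ages are impossible by construction — the
  algorithm corrects the whole profile to one global target.
* The fast CV mode is a pragmatic approximation; alpha selection can
  differ slightly from the exhaustive LOOCV mode.
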