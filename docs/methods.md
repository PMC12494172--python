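# Methods

## Task model

The simulated session mirrors the conditioning task's structure: 8 shaping
trials (CS types in descending then ascending reward order) followed by 64
experimental trials — 16 per CS type in pseudorandomized blocks of four, so
each type appears once per block. Per-trial timing is fixation 1.5 s, CS
3 s, double fixation 1.5 s, reward delivery 3 s, inter-trial interval 7.5 s
(16.5 s per trial, ≈ 20 min per session). The monitor/dispenser orientation
flips from CS-left to CS-right after experimental trial 32; AOI geometry is
symmetric about the vertical midline so the flip is an exact mirror.

## Gaze generation and the I-VT filter

Gaze is generated at 50 Hz directly in scene coordinates measured in visual
degrees, sidestepping scene-camera calibration (hardware-bound, out of
scope). Within the late half of each CS presentation, gaze alternates
between fixation bouts of 200–400 ms; the bout lands on the CS AOI with
probability `expit(k·θ)` on rewarding trials (k = 1.5 per SD of the latent
propensity θ ~ N(0, propensity_sd²)), and on zero-value trials favors the
reward location/background (0.05/0.55/0.40) independent of θ. The logistic
link is the simplest monotone map producing the full gaze-index range, with
exact saturation (index → 1) in the θ → ∞ limit. Within-fixation jitter is
0.12° per sample (≈ 8°/s, safely below the 30°/s cut); between-bout jumps
are single-sample saccades far above it. Blinks are Poisson-injected
invalid runs of 60–200 ms (rate 0.15 s⁻¹), exercising the filter's handling
of invalid samples; the resulting gaze-sample quality (~97–98%) sits inside
the realistic 84–100% range, and the participant-level QC threshold
defaults to 80%.

The I-VT classifier computes point-to-point angular velocity between
consecutive valid samples (Euclidean angle difference / Δt, no smoothing
window by default); runs of samples whose internal velocities stay strictly
below the threshold and that span ≥ 50 ms become fixations with the mean
position as centroid. Invalid samples terminate runs; optional gap fill-in
and adjacent-fixation merging are exposed (`max_gap_ms`, `merge_max_ms`,
`merge_max_deg`) but off by default, since only the threshold and minimum
duration are part of the published filter settings. AOI membership is
decided by fixation centroid (not per-sample extent), and fixations
straddling the 1.5 s analysis window contribute pro-rated overlap time —
all-or-nothing assignment would create discretization artifacts at the
window edge.

## Phenotype statistics

The ST/GT coefficient is the OLS slope of the per-trial gaze index on CS
reward value over the 48 retained trials; trials with no valid fixation
time in the window are dropped rather than imputed, and a slope needs at
least 24 usable trials (50%) to enter group assignment. The 2/5–1/5–2/5
group split takes `round(0.4 n)` (half-up) participants at each tail,
pinned by the 47 → 19/9/19 case; slope ties break by stable input order.

Association models (`outcome ~ WHR|BMI + age + sex + hunger`) are classical
OLS with 95% CIs; standardized estimates come from refitting with the
outcome and continuous terms z-scored while binary indicators stay on their
original scale (both conventions are computable; the reported one is
documented in the output). The outcome is the ST/GT coefficient, the
adiposity measure the predictor. Group contrasts use Welch's
unequal-variance t with Satterthwaite df.

The AOI × CS-type repeated-measures ANOVA is computed from the standard
three-way sums-of-squares decomposition; the Greenhouse–Geisser epsilon for
the interaction comes from the covariance matrix of the orthonormal
interaction contrasts (Kronecker product of Helmert contrasts),
ε = tr(S)² / (d · tr(S²)), capped at 1; corrected df are ε·d and
ε·d·(n−1). The implementation reproduces R's `car::Anova` type-3
within-subject results to 8 significant digits on a fixed test table
(pingouin's two-way epsilon is known-inaccurate and is not used).
Trend-over-trials uses the two-stage summary-statistics approach —
per-participant OLS slope on trial number, then a one-sample t-test of
slopes against zero — as a documented simplification of a random-effects
regression; exactly flat data return p = 1 by convention.

## Timecourses and connectivity

Node timecourses follow a k = 10 latent-factor model with contiguous
loading blocks mimicking canonical-network structure (block loading 0.8,
off-block N(0, 0.1), observation noise sd 1.0). For each planted edge
(i, j), node j receives node i's standardized series with weight
γ·standardized(θ), so the (i, j) correlation is monotone in θ; planted
pairs span different blocks so their baseline correlation is near zero.
Confounds are 6 motion random walks, their first derivatives, global/CSF/
white-matter signals and framewise displacement with a configurable
spike fraction (default 5%); small motion and linear-drift components leak
into the node signals so confound regression is non-trivial.

Cleaning order is detrend → standardize → joint regression of the 16
confounds plus one indicator per spike volume (and an intercept); residuals
are not re-standardized. Spikes are censored by regression rather than row
deletion — the indicators annihilate flagged rows exactly while keeping the
row count, and correlations run over all rows with the unflagged count
reported. Fisher's transform clips |r| at 1 − 1e−7 so degenerate pairs keep
a finite z without reordering. Edges are indexed 0-based, strict upper
triangle, row-major (220 nodes → 24,090 edges).

## CPM

Partial Spearman: edge values and behavior are rank-transformed (average
ranks on ties) and residualized on the covariate design — covariates enter
unranked, categoricals indicator-coded — then the residuals are
Pearson-correlated; with no covariates this is plain Spearman's ρ.
Selection uses strict cuts ρ > 0.3 / ρ < −0.3. Per fold, behavior is
regressed on summed network strength and the held-out subject's strength
gives the prediction; a fold with an empty selection (or constant training
strengths) predicts the training mean, which keeps all n predictions and is
conservative. Accuracy is Spearman's ρ of predicted vs observed.

Permutation inference shuffles the behavior vector against the matrices —
covariates stay aligned with the matrices by default (a
Freedman–Lane-style joint shuffle is exposed but off) — and re-runs the
entire LOOCV per permutation; p is the plain proportion of permuted
accuracies ≥ the observed one (an add-one-smoothed option exists because
the plain estimator can return 0). Permuted accuracies that are undefined
(constant predictions) never count as exceeding. For speed, per-fold
rank-transformed, covariate-residualized edge matrices are cached and
reused across permutations; this is algebraically identical to re-running
from scratch and is verified against a naive fold-by-fold reimplementation
in the tests. LOOCV is deterministic, so the consensus network is defined
over the n folds (edges selected in ≥ 90% of folds); an optional repeated
subsample mode is deliberately not provided. Degree tables report incident
consensus edges per node and their proportion of the network's edge count;
ties at the top-10% degree cutoff are all included and flagged.

## Problem sizes and seeds

Recovery and calibration runs use desk-scale studies chosen once: the
planted-effect study has 60 participants, 40 nodes, 200 volumes, 10 planted
edges with coupling γ = 1.2 ("strong": edge r ≈ ±0.77 at θ = ±1 SD), WHR
coupling 0.05 per SD of θ against residual sd 0.04, and 500 permutations;
null calibration uses 50 replicate studies of 24 participants, 16 nodes,
120 volumes and 100 permutations each with γ = 0 and zero WHR coupling. All
randomness descends from a single root seed via spawned seed sequences, so
identical seeds give identical studies, predictions and permutation
p-values.

## What the generator does and does not emulate

It reproduces the statistical structure the pipeline relies on — task
scheduling, velocity-separable fixations with blinks, θ-linked gaze
allocation, WHR coupling, block-structured connectivity with planted
θ-scaled coupling, motion confounds and FD spikes. It does not emulate
smooth pursuit, pupil dynamics, calibration drift, spatially correlated
measurement error, hemodynamics, scanner-specific noise spectra, or
non-planted brain-behavior structure. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
assumptions, not performance on real recordings; effect sizes (γ, WHR
coupling) are free parameters of the generator documented here, not
calibrated to any empirical dataset.

## Known limitations

- The trend test is a two-stage stand-in for a full random-effects model
  (a GLS variant can be slotted in behind the same interface).
- Partial Spearman residualizes ranks on unranked covariates; other
  conventions (ranking covariates too) exist and give slightly different ρ.
- The consensus definition assumes deterministic LOOCV folds; with heavy
  subject exclusion the fold count (and hence the 90% rule's granularity)
  shrinks.
- Group-split rounding is only externally pinned at n = 47; other n follow
  round-half-up by construction.
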