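# Methods

`insightrc` re-implements, as a tested library, the computational analysis
of an insight-memory fMRI study design: participants solve two-tone
(Mooney) object-identification puzzles in the scanner, rate each solution
on suddenness, positive emotion and certainty, and return five days later
for a memory test. The package covers the full path from trial-level
behavioral coding to the two representational-change statistics, network
statistics and the mixed-model inference scaffold — all exercisable on
synthetic data with known ground truth, since the original subject-level
recordings are not public.

## The synthetic study

`SimulationConfig` declares one study; the defaults are the generative
conditions the rest of the package is validated against.

**Trials.** 31 subjects x 120 items x 4 runs (30 trials per run, item-to-run
assignment permuted per subject). Each solved trial draws a latent insight
factor eta ~ N(0, 1). The three 4-point ratings are generated as
`lambda_k * eta + sqrt(1 - lambda_k^2) * e_k` with loadings
(0.65, 0.60, 0.53) and discretized at standard-normal quartile thresholds
into 1-4; the compound insight score is their sum (3-12). Discretization
attenuates the observable inter-rating correlations below `lambda_i *
lambda_j`; the test suite checks them against the closed-form value obtained
by integrating the bivariate normal over the 4x4 cell grid.

Log solution time is `1.25 - 0.30 * eta + 0.45 * e` (seconds; median ~3.5 s,
clipped to the 10-s stimulus window), so more insightful solutions are
faster. Solving occurs at rate 0.684 independently of eta; correctness given
solving follows a logistic model with base rate 0.77 and an odds ratio of
2.4 per SD of eta — with the 18.7% false-correct adjustment this puts
chance-adjusted accuracy near 43% of presented trials and makes correct
trials skew toward high insight.

**Insight classes.** The generative high/low split uses the same rule the
analysis applies: a per-subject median over solved trials inside the
1.5-9.5 s analysis window, strictly-above-median -> high, ties -> low.
Computing the generative class on the analyzable trials makes the
generative memory effect exactly the estimand of the downstream model
(no label-misclassification attenuation). Note that with a strict
above-median rule at most half the solved trials can be high-insight;
marginal shares above 50% would require counting median-tied trials as
high.

**Memory.** Remembering a correctly solved item is Bernoulli with
`logit p = logit(0.35) + b_subject + b_item + log(2.10) * HI`, where the
crossed random intercepts have SD 0.35 (logits). The base rate (~35%
recall for low-insight items after five days) and moderate heterogeneity
are realistic for week-delayed episodic recall; the conditional odds
ratio of 2.10 is the study's generative insight-memory effect. The
three-gate questionnaire responses (old/new recognition, solved-in-scanner
judgment, solution naming) are generated consistently with the drawn
outcome, with forgotten trials split ~53/47 between not-recognized and
incorrectly-remembered, so the compound memory coder reproduces the binary
outcome exactly.

**Embeddings.** Items carry coordinates in a 12-dimensional latent
"conceptual" space mapped into 300-dimensional unit-norm vectors through a
random orthonormal basis. Low latent dimensionality is essential: random
full-rank vectors are mutually near-orthogonal and would leave the model
similarity matrices with no exploitable spread. The image-model and
word-model stand-ins share a configurable fraction (default 0.3) of their
latent coordinates; 1.0 makes their similarity matrices identical, 0.0
independent.

**Voxel patterns.** Every (subject, ROI, item) has a stable baseline
pattern (SD 0.8) shared by the pre- and post-solution timepoints, plus
i.i.d. N(0, 1) noise per timepoint. Solved trials in the
representational-change ROIs (defaults: iLOC, pFusG) additionally receive,
at post only, the item's embedding projected through one fixed Gaussian
matrix per ROI, scaled by `signal_gain * g`, with the linear insight ramp
`g = (composite - 3) / 9` in [0, 1] (the analysis treats insight as a
linear predictor, and no dose-response curve is otherwise established).
The injected signal simultaneously (i) aligns the post-solution neural
geometry with the conceptual model in proportion to insight and (ii)
displaces the post pattern from the shared baseline, lowering pre/post
pattern similarity with insight — the two signatures the RSA module is
built to detect.

**Time series.** Each trial is a 10-s stimulus block after a jittered
~3-s fixation, sampled at TR = 0.8 s. All ROIs load sqrt(0.10) on a
network-wide common fluctuation; during high-insight blocks the
4-ROI subnetwork additionally loads sqrt(0.30), raising its pairwise
correlation by `fc_condition_delta = 0.30` over low-insight blocks.

**What the generator does not emulate:** hemodynamic confounds between
trial events within the pattern simulation (patterns are generated at the
beta level; the BOLD/GLM path is validated separately on designs with
known betas), head motion, physiological noise, scanner drift beyond what
the high-pass basis absorbs, and spatial structure within ROIs. Passing
tests therefore demonstrate the statistical machinery and its calibration,
not robustness to realistic fMRI artifacts.

## Single-trial GLM

One regressor per event (least-squares-all): a boxcar of the event's
duration convolved with the canonical double-gamma HRF (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot 6, 32-s support,
peak-normalized; built on a 16x oversampled grid and sampled at scan
times), plus six motion regressors, a run-mean column and a discrete-cosine
high-pass basis with 128-s cutoff (orders 1..floor(2T/128)). Pre- and
post-solution events belong in separate models because fast solutions make
their regressors nearly collinear; the design object flags any event-pair
correlation above 0.9. Estimation is per-voxel OLS; an optional AR(1) step
estimates a single pooled lag-1 coefficient from the residuals and refits
after quasi-differencing (off by default — full restricted-likelihood
AR estimation is out of scope). Rank-deficient designs raise unless a
pseudo-inverse is explicitly requested.

## Representational change

Two statistics per (subject, item, ROI):

* **Pre/post similarity** — Spearman correlation (average ranks for ties)
  between the pre-solution (0.5 s after stimulus onset) and post-solution
  (button press) pattern vectors; *MVPS change* is `1 - rho`. Trials whose
  events are less than 2 s apart are excluded (hemodynamic overlap).
* **Representational strength** — for each solved, correctly identified
  item: the Pearson partial correlation between that item's row of the
  neural RSM (pairwise Spearman of item patterns) and the same row of a
  model RSM (Spearman for the image-model, cosine for the word-model),
  with the partners' run order (1-4, numeric) partialled out via the
  first-order closed form. The self-pair is excluded (its unit similarity
  would inflate every correlation) and partner items are restricted to
  solved items symmetrically on both sides. Records with fewer than 4
  usable partners are masked, never imputed. Strength values are carried
  to the models untransformed; Fisher-z transformation is available as a
  configuration switch.

## Network statistics

Condition-wise functional connectivity is the Fisher z (atanh) of the
Pearson correlation between ROI time series over the concatenated stimulus
blocks of that condition, per run (optional zero-phase 0.008-0.09 Hz
band-pass first). The high>low contrast is a paired t per connection on
run-averaged z values. Network-level inference screens connections at
one-sided p < 0.05 and sums squared t statistics over the surviving
connections (the mass); its familywise p value comes from sign-flipping
each subject's condition-difference matrix (1 + #{null >= observed}) /
(1 + n_perm). Sign-flipping is the natural exchangeability argument for a
within-subject contrast; permuting condition labels within subject is
equivalent here.

Graph measures use standard binary-graph definitions on adjacency matrices
thresholded at back-transformed correlations 0.1..0.8 (positive edges
only): degree, clustering coefficient, local efficiency (global efficiency
of the neighbor-induced subgraph), per-node average shortest path to
reachable nodes, and network global efficiency as the mean of 1/d over
distinct pairs with unreachable pairs contributing 0. Measures are averaged
(unweighted) over thresholds per subject and condition before one-sided
paired t tests (high > low), with Benjamini-Hochberg correction across ROIs
within each measure. Subjects with a measure undefined at every threshold
are dropped for that measure, with the df reported.

## Mixed-model inference

All models are (generalized) linear mixed models with crossed random
intercepts for subject and item, fitted by maximum likelihood — never
REML, so log-likelihoods are comparable across fixed-effect structures in
likelihood-ratio tests. The fitter is authored here because no installed
Python library offers ML-fitted crossed random intercepts for the binomial
family:

* **Gaussian:** profiled ML deviance. For relative random-effect SDs
  theta, the sparse penalized normal equations are reduced by block
  Cholesky; the residual variance profiles out analytically and a
  Nelder-Mead search over the two theta parameters minimizes the profiled
  deviance. Agrees with statsmodels `MixedLM` (ML, variance components) to
  ~1e-7.
* **Binomial:** Laplace approximation with penalized IRLS over the joint
  (fixed, random) coefficient vector — the strategy lme4 uses at
  `nAGQ = 0` — with step-halving on the penalized deviance and the
  log-determinant evaluated at the joint mode. Verified against
  `glmer(..., nAGQ = 0)` to ~1e-5 on coefficients; the default
  one-argument Laplace (`nAGQ = 1`) differs by ~1-3% on coefficients for
  the problem sizes used here. The joint-mode variant was chosen because
  the bootstrap and permutation routines refit thousands of models.

Numerical choices: theta is optimized on a folded (absolute-value) scale so
boundary (singular) fits at zero variance are reachable; fits with a
random-effect SD below 1e-4 are flagged singular; a negative LRT statistic
beyond tolerance triggers refits from four fixed starting points before
erroring; repeated refits warm-start both theta and the PIRLS mode.

On top of the fitter: nested LRTs (chi-square reference), permutation LRTs
(the tested predictor shuffled within subject, both models refitted per
draw, p = (1 + #{chi2_perm >= chi2_obs}) / (1 + n_valid); the published
permutation procedure's internals are not documented, so the within-subject
shuffle is a documented, configurable stand-in), subject-level
case-resampling bootstrap odds ratios with percentile CIs (subjects
resampled with replacement and re-identified so duplicated subjects remain
distinct clusters), per-level simple slopes with Bonferroni correction,
and Benjamini-Hochberg FDR.

## Calibration and problem sizes

The test suite validates: exact arithmetic identities (misclassification
rate, chance level, graph hand cases), oracle equivalences (partial
correlation vs. residual regression at 1e-10, Spearman vs. Pearson on
ranks, graph measures vs. a brute-force BFS/triangle oracle, Fisher z vs.
atanh), type-I calibration of the LRT, permutation LRT and NBS under null
generators, power of the representational-strength interaction at the
generator's default effect sizes, and recovery of the generative
insight-memory odds ratio at the full 31 x 120 design. Monte-Carlo suites
run at reduced replicate counts and subject/item counts chosen so the whole
suite completes in a few minutes; every stochastic routine is seeded and
the suite is bit-reproducible.

A note on the odds-ratio recovery margin: at 31 subjects x 120 items with
the calibrated solve/accuracy rates, one replicate yields ~1700-1900
analyzable correct trials, which bounds the sampling SD of the log odds
ratio below by ~0.098 (the estimator attains this bound empirically). The
replicate mean recovers the generative odds ratio of 2.10 without bias,
but individual replicate estimates scatter more widely than a +/-0.15
log-unit interval can contain 95% of the time — a property of the study
size itself, not of the implementation.

## Known limitations

* The binomial Laplace likelihood is an approximation; with very few
  clusters or extreme rates it shares the usual small-sample GLMM biases.
* No random slopes (by design — the modeled studies use intercepts only);
  no REML; no Bayesian alternatives.
* The pipeline's GLM stage demonstrates beta recovery on simulated BOLD
  runs; the RSA stages consume generator-level patterns directly rather
  than betas estimated from simulated BOLD, keeping the two validation
  concerns separable.
* Graph measures implement the standard binary conventions; weighted
  variants, modularity and rich-club coefficients are out of scope.
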