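# Methods

`meridian` re-creates, on synthetic data, a complete analysis of horizontal
versus vertical attentional reorienting: a two-run Posner spatial-cueing
experiment, behavioral Bayes-factor ANOVAs, a node-level event-related GLM,
cross-run decoding of the cueing condition, bilinear dynamic causal
modeling (DCM) with hierarchical random-effects Bayesian model selection
(BMS) and Bayesian model averaging (BMA), and a generative input-swap test.
This note records the models, the conventions chosen where the design was
genuinely open, and what the synthetic data do and do not establish.

## Synthetic experiment

One run presents 5 blocks of 40 trials (32 validly and 8 invalidly cued,
80% cue validity); targets lie on the horizontal meridian (left/right) in
one run and the vertical meridian (down/up) in the other.  Each trial is
alerting signal (500 ms), a central cue 1,000 ms later (200 ms), the target
after a 400 or 600 ms SOA (250 ms), and an inter-trial interval drawn
uniformly from {2.0, 2.7, 3.2, 3.9, 4.5} s.  The 8 target-property cells
(position x response finger x SOA) are exactly balanced within a block and
trial order is fully randomized.  Between blocks the generator inserts a
break drawn uniformly from [10, 13] s (only the range is constrained).  The
ITI is measured target-offset-to-alerting-onset — a documented convention,
since nothing anchors the interval otherwise.  A run must fit into 552
volumes at TR 2.2 s; the generator raises if a drawn sequence does not.
`DESK_SPEC` is a reduced profile (1 block of 40 trials, 110 volumes) with
identical timing grid, cell balance and validity, used for fast tests.

Reaction times are shifted-lognormal: `RT = exp(N(mu, sigma)) + cost *
[invalid] + effect * [vertical]` in ms, with defaults mu = log 650,
sigma = 0.18, invalidity cost 50 ms, direction effect 0 ms, error
probabilities 3.3% (valid) / 5% (invalid) and 0.5% misses — magnitudes in
the range typically reported for speeded cueing tasks.  The lognormal was
chosen because only the medians enter the analysis and its median,
exp(mu), makes the condition effects an exact oracle for tests.

BOLD is generated from a known ground-truth DCM (below) plus white
observation noise (by default scaled per node to signal SD / SNR, SNR 1)
and optionally a low-frequency cosine drift mixture.  An optional voxel
expansion replicates each node's series into voxels with independent noise
for eigenvariate testing.

## Behavioral cleaning

Exclusion rules apply in a fixed order (first match claims the trial):
error (incorrect, non-missed), post-error (the following trial within the
run; no cascade), miss, RT < 200 ms, and RT > Q3 + 1.5 IQR.  Quartiles use
linear interpolation (type 7); the IQR bound is computed per cueing x
position cell over the trials surviving the earlier rules, mirroring the
granularity at which such exclusions are conventionally reported; cells
with fewer than 4 survivors skip the rule with a logged warning.  Whether
the IQR criterion should pool over cells is not determined by any external
constraint; the per-cell choice is ours.  Error rates are computed on the
raw record (mean of incorrect-or-missed per cueing x direction cell);
medians on cleaned trials.  Cleaning is idempotent on realistic
(lognormal-tailed) data, though adversarial configurations exist where a
second pass could remove more — the property is asserted on generator
output only.

## Bayes factors

`bf_anova` implements the default mixed-model Bayes factor for the 2x2
within-subject design with participants as a random factor.  Factors are
coded with orthonormal sum-to-zero contrasts; each factor's standardized
effects carry a Zellner–Siow mixture of g-priors, g ~ Inv-Gamma(1/2,
r^2/2), with the "medium" scale r = 0.5 on fixed effects (cueing,
direction, their interaction) and r = 1 on the participant factor.  Given
g, the location and scale integrate out analytically under the Jeffreys
prior, leaving a closed-form conditional marginal; the BF against the null
(grand mean + participant) is a Monte-Carlo average over 10,000 prior
draws of g (Woodbury identities keep the cost at the number of design
columns).  Log BFs are used internally; Monte-Carlo standard errors are
reported.  The paired JZS t-test BF (`bf_paired_ttest`, default Cauchy
scale sqrt(2)/2) is computed by adaptive quadrature over g; the test suite
checks it against an independent quadrature over the effect-size
parameterization to 1e-6 relative.  An identically-zero difference vector
is treated as a perfect null (t = 0, BF < 1); a constant nonzero
difference raises, since t is undefined.  The two-level-factor reduction
of the ANOVA tracks the paired t-test at the matching scale (r = 0.5 on
the orthonormal coding implies Cauchy(0, 0.5) on the standardized pair
difference) only approximately: the ANOVA integrates the random-subject g
while the t-test conditions it out.

## GLM

Both runs enter one design matrix: 8 condition regressors (iL, iR, vL,
vR, iD, iU, vD, vU) as zero-duration sticks at target onsets convolved
with the canonical double-gamma HRF (nilearn's first-level machinery, SPM
parameterization), optional per-run error/post-error and outlier stick
regressors (duration 0, like conditions), per-run motion/FD confounds when
provided, a per-run orthonormal cosine drift set with 128 s cutoff, and
per-run intercepts.  The column order is frozen (conditions first) so beta
tables are stable.  Fitting is ordinary least squares per node; rank
deficiency falls back to the pseudoinverse with a logged warning.  Planned
contrasts: main cueing effect, run-specific reorienting, main direction
effect, interaction, and the four visual-field contrasts; by construction
the main cueing contrast equals the sum of the two run-specific ones.
Group inference at node level uses a two-sided sign-flip permutation test
on the per-participant contrast values (exact enumeration when 2^n fits
the permutation budget, otherwise Monte-Carlo with add-one smoothing).
The eigenvariate of a voxels x time matrix is the first principal
component over time, sign-aligned to a positive mean voxel loading and
rescaled to the mean voxel SD.

## Decoding

Observations are condition regressors (4 per participant per run), with
the 6 VOI betas as features and cueing as the label.  Within-run accuracy:
nested stratified 5-fold CV; the inner 5-fold selects the L2 logistic
regularization C over {1e-4 ... 1e4} by mean inner accuracy (ties go to
the strongest regularization), the winner refits on the outer training
split.  Cross-run generalization selects C by 5-fold CV inside the
training run, refits on that whole run, and scores the untouched other
run.  Standardization uses training-split statistics only (inside every
fold) to avoid leakage.  Observations of one participant may fall into
different folds (grouped CV is available behind a flag but off by
default).  Permutation tests shuffle labels within run and re-run the
entire selection pipeline, p = (1 + #{perm >= obs}) / (n_perm + 1) — the
add-one-smoothed estimator.  Two numerical notes: small-sample CV is
slightly pessimistic at chance (mean accuracy ~0.47 on null features at 80
observations), and accuracy ties make the permutation p mildly
conservative; both cancel from the permutation comparison, which stays
calibrated.

## DCM forward model

Neural dynamics follow the bilinear form dz/dt = (A + sum_j u_j B^j) z +
C u over six nodes (IPS, FEF, TPJ bilaterally).  A is supported on full
intra-hemispheric coupling plus homologous inter-hemispheric pairs.  The
four inputs are the target onsets of invalid-horizontal (u1),
valid-horizontal (u2), invalid-vertical (u3) and valid-vertical (u4)
trials, as one-microtime-bin impulses of unit area (height 1/dt).  B^2 and
B^4 are structurally zero (valid-trial dynamics live in A); B^1 and B^3
share one support mask.  Each node's hemodynamics follow the
balloon-Windkessel model (signal decay 0.65 s^-1, autoregulation 0.41
s^-1, transit 0.98 s, stiffness 0.32, resting extraction 0.34, V0 0.04,
k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2), with inflow, volume and
deoxyhemoglobin integrated in log space.  Integration is fixed-step RK4
at 36 bins per TR — the same microtime resolution in the generator and the
inverter — with inputs constant within a bin; the BOLD series is read out
at the mid-TR bin (offset 18) of each volume, and each run restarts from
rest.  The ground-truth defaults (self-connections -0.5 Hz, lateral
couplings 0.08-0.10 Hz, modulations 0.4 Hz, driving weights 0.10) are
typical effective-connectivity magnitudes and keep A comfortably stable;
simulation refuses any A with a non-negative eigenvalue real part.  A
numba-compiled kernel integrates batches (many parameter vectors sharing
inputs, or one model under many input assignments); a pure-numpy path
computes identical trajectories when numba is unavailable.

## DCM inversion

`invert` is a variational-Laplace scheme: Gauss-Newton ascent on the
posterior log-joint with a finite-difference Jacobian (all parameter
perturbations integrated as one batch), step-halving on rejection,
per-node noise variances re-estimated by empirical Bayes each iteration
(with the usual trace correction for posterior uncertainty), convergence
at dF < 0.01 or 64 iterations, and a non-converged flag rather than a
silent answer when the step floor is reached.  The free energy is the
Laplace evidence approximation: log likelihood at the posterior mode minus
the prior penalty plus half log det of posterior over prior covariance.
Priors (zero mean): A off-diagonal 1/16, A self log-scaling 1/64 (diagonal
is -0.5 exp(theta)), B entries 1, C weights 1/16, hemodynamic decay and
transit log-scalings 1/64.  Per-run cosine drifts, intercepts and any
supplied nuisance columns are projected out of data and prediction alike,
with the effective number of observations reduced by the confound rank.
The scheme is deterministic.

One identifiability choice matters and is ours: **driving weights are tied
across the four input streams** (one weight per node).  The experiment
matches visual stimulation across conditions — every trial presents a
target plus three distractors — so condition-specific driving is not part
of the data-generating story; condition differences belong to B.  With
per-stream free C the likelihood cannot separate a modulation B^1 from a
small deviation of the invalid-stream driving weight (both act in the same
impulse bins), and B estimates collapse toward zero with arbitrary sign.
Tying C removes that ridge; the per-stream variant remains available
(`tie_c_streams=False`).

Under these conditions, parameter recovery at SNR 1 on a 2-block (80
trials/run, 200 volumes/run) design recovers a planted B^1 = 0.4 with mean
absolute error ~0.10 over replicate seeds; single-seed estimates still
scatter by ~0.15 SD, consistent with the broad between-participant spreads
that event-related modulation estimates show in practice.

## Model space, BMS, BMA

The candidate space crosses laterality (left/right/bilateral; bilateral
mirrors the pattern — the only reading consistent with the printed total
of 72), the admissible TPJ-IPS x TPJ-FEF patterns (3 x 3 minus the
all-none cell, no bidirectional pairs), and the inter-hemispheric IPS
direction (L->R, R->L, bidirectional): (9-1) x 3 x 3 = 72 structures in a
frozen order.  Group selection is random-effects BMS: the variational
Dirichlet scheme (uniform prior concentration 1 per model) with exceedance
probabilities from 1e5 seeded Dirichlet draws.  Family comparisons place
prior concentration 1/|family| on each member so every family carries
equal prior mass; because the mean-field update degenerates for
concentrations below 1 (mass collapses onto small families even under flat
evidence), family posteriors are sampled by Gibbs (assignments and
frequencies alternately), which keeps aggregated frequencies unbiased.
Selection is hierarchical: laterality families first, then IPS-direction
families within the winner.  BMA is per-participant and fixed-effects:
weights softmax(F - max F) over the winning family, absent parameters
entering as zero.

## Generative input-swap test

Given a participant's BMA-averaged DCM and observed series, the test
simulates BOLD under the original inputs, under swapped inputs (u1<->u3,
u2<->u4 — the horizontal run driven as if vertical and vice versa), and
under a null ensemble in which every impulse keeps its onset but draws a
uniformly random stream (a count-preserving permutation variant sits
behind a flag).  Fits are scored by RMSE pooled over nodes and time (a
per-node-averaged variant behind a flag), and p = (1 + #{null RMSE <=
candidate RMSE}) / (n_null + 1) for the original and swapped inputs; the
cohort statistic is the proportion of participants with swapped p < .05.
Under a direction-agnostic ground truth (B^1 = B^3, tied C) the swap is
exactly neutral, so swapped and original p-values coincide — the sharpest
form of the no-direction-effect prediction.

## Problem sizes and what the tests show

The default test and acceptance runs use the reduced profiles: desk-scale
designs (1-2 blocks, 110-200 volumes per run), cohorts of 6-10 simulated
participants for the DCM stages, permutation counts of 49-300, and a
3-model subspace (one representative per laterality family) for the
end-to-end run; the full study dimensions (28/26 participants, 5 blocks,
552 volumes, all 72 models) remain available through the `full` profile
of the CLI.  Passing tests establish that each stage does what its
contract says on data with the assumed statistical structure —
lognormal RTs, Gaussian observation noise, drift confined to the cosine
subspace, a ground truth inside the model class.  They do not establish
robustness to the things real recordings add: physiological noise and
motion correlated with the task, hemodynamic variability across regions
beyond the two fitted scalings, imperfect ROI definitions, or model
mismatch in the neural dynamics themselves.

## Known limitations

* One-state bilinear DCM only; no stochastic or nonlinear (D-matrix)
  variants, no PEB group hierarchy.
* The free energy uses profile (empirical-Bayes) noise estimates rather
  than a full hyperparameter posterior; comparisons are consistent across
  models fitted the same way.
* Event-impulse modulations are weakly identified by construction; at
  desk scale, single-participant B estimates are noisy (SD ~0.2) even
  with tied driving weights.
* The behavioral ANOVA's Monte-Carlo marginals use prior sampling; with
  10,000 draws the MC SE on log BFs is typically < 0.05 for designs of
  this size, but extreme BFs carry larger relative error.
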