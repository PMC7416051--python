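# meridian

Does the brain reorient spatial attention differently along the horizontal
and the vertical meridian of the visual field?  `meridian` implements, end
to end on synthetic data, the analysis chain used to answer that question
with a two-run Posner spatial-cueing fMRI experiment: one run cues and
presents targets only left/right, the other only up/down, with 80% cue
validity, and every stage of the analysis asks whether *invalid* (reorienting)
trials behave differently across the two directions.

The package is aimed at researchers who want a tested, self-contained
reference implementation of this kind of attention-network analysis —
from design generation to effective-connectivity model comparison — that
runs without any imaging data.

## What it implements

* **Synthetic experiment** (`meridian.synthetic`): randomized trial
  sequences (5 blocks x 32 valid + 8 invalid trials per run, balanced
  target-property cells, SOA 400/600 ms, jittered ITIs), shifted-lognormal
  reaction times with a configurable invalidity cost and (default zero)
  direction effect, and six-node BOLD generated from a known ground-truth
  DCM plus drift and noise.
* **Behavior** (`meridian.behavior`): the RT cleaning rules (error,
  post-error, miss, < 200 ms, per-cell Q3 + 1.5 IQR) with an exclusion
  ledger, and condition medians / error rates.
* **Bayes factors** (`meridian.bayes`): JZS Bayes-factor ANOVA for the
  2 x 2 (cueing x direction) within-subject design with participants as a
  random factor (medium prior scale, Monte-Carlo g-integration), and the
  JZS paired t-test by quadrature.
* **GLM** (`meridian.glm`): a two-run event-related design matrix
  (8 condition regressors iL...vU convolved with the canonical HRF, cosine
  drifts, per-run confounds), OLS betas per node, the planned contrasts
  such as (iL + iR + iD + iU) − (vL + vR + vD + vU), direction-collapsed
  betas, ROI eigenvariates, and sign-flip permutation tests.
* **DCM** (`meridian.dcm`, `meridian.inversion`): the bilinear neural
  state equation dz/dt = (A + Σ_j u_j B^j) z + C u with balloon-Windkessel
  hemodynamics, RK4-integrated at 36 microtime bins per TR (numba-
  accelerated), and a deterministic variational-Laplace inversion
  returning posterior means, covariance, free energy and per-node R².
* **Model space and group inference** (`meridian.model_space`): the 72
  admissible modulation structures (laterality x TPJ-dorsal patterns x
  inter-hemispheric IPS direction), random-effects BMS with exceedance
  probabilities, hierarchical family comparison, and per-participant BMA.
* **Decoding** (`meridian.predictive`): logistic-regression decoding of
  the cueing condition from VOI betas with nested 5-fold CV over
  C ∈ {1e-4 ... 1e4}, cross-run generalization, and label-permutation tests.
* **Generative input-swap test** (`meridian.generative`): simulate BOLD
  with horizontal and vertical input streams exchanged (u1↔u3, u2↔u4),
  score by RMSE, and compare against a random-input-assignment null.
* **Pipeline + CLI** (`meridian.pipeline`, `meridian` command): a seeded,
  resumable orchestration of all stages with YAML config.

See `docs/methods.md` for the models, priors, and numerical conventions.

## Worked example

Simulate a small cohort under a direction-agnostic ground truth
(B¹ = B³: invalid-trial modulations identical across runs) and run the
full chain.  `demo.yaml`:

```yaml
seed: 5
profile: desk            # 1-block runs of 110 volumes
scenario: null-direction # B1 = B3, no behavioral direction effect
cohort_behavior: 10
cohort_dcm: 6
n_perm_decode: 49
n_null_swap: 199
model_subset: [11, 35, 59]  # one structure per laterality family
out_dir: demo
```

```bash
meridian run-all --config demo.yaml
```

This prints (actual output; about seven minutes on one CPU):

```
meridian pipeline summary
profile=desk scenario=null-direction seed=5

Behavioral BF-ANOVA:
  RT cueing: log BF10 = 7.25
  RT direction: log BF10 = -1.18
  RT cueing+direction: log BF10 = 5.94
  RT cueing+direction+interaction: log BF10 = 6.13
VOI BF-ANOVA best models: IPS_L=cueing, IPS_R=cueing, FEF_L=cueing, FEF_R=cueing, TPJ_L=cueing, TPJ_R=cueing+direction
  decode within_horizontal: accuracy = 1.000 (p = 0.020)
  decode within_vertical: accuracy = 0.920 (p = 0.020)
  decode cross_h_to_v: accuracy = 0.833 (p = 0.020)
  decode cross_v_to_h: accuracy = 0.917 (p = 0.020)
BMS: laterality winner = left (ep = 0.82); IPS winner = r_to_l (ep = 1.00)

behavior: best RT model = cueing -> no direction effect
connectivity: median paired BF10 (B1 vs B3) = 0.6 -> no direction effect
generative: swapped inputs beat the random null for 100% of participants -> no direction effect
```

Reading it: the Bayes-factor ANOVA strongly prefers the cueing-only
model for reaction times (log BF₁₀ = 7.25 — an invalidity cost exists,
but adding a direction term only hurts the evidence); decoding the
cueing condition from the six VOI betas generalizes across runs at
accuracies comparable to within-run (0.83–0.92 vs 0.92–1.00, all
permutation p = .02, the floor at 49 permutations); the paired Bayes
factors on the BMA connectivity parameters sit below 1 (median 0.6 —
evidence *for* equal horizontal and vertical modulations); and for every
simulated participant the DCM driven by the swapped inputs still
out-predicts the random-input null — the generative restatement of
"reorienting dynamics do not care about direction".  Per-stage artifacts
(`behavior_summary.csv`, `beta_table.tsv`, `log_evidence.tsv`,
`bms_report.json`, `swap_report.json`, `summary.json`) land in `demo/`.

Running with `scenario: direction-effect` plants a horizontal-only
modulation (B³ = 0) plus a 30 ms vertical RT cost, and the evidence
lines flip.

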