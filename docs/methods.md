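# Methods

This note documents the models, estimators and design choices behind
`dualproc`, in the spirit of a statistical software methods appendix.

## Dual-process signal-detection (DPSD) model

Recognition confidence for a studied item is modelled as a mixture of a
threshold recollection process (probability `R`, always yielding the
highest-confidence "old" response) and an equal-variance Gaussian
familiarity process with discriminability `d′` (foil strength ~ N(0,1),
target strength ~ N(d′,1)). With ordered criteria `c_1 < … < c_5`, the
cumulative hit and false-alarm rates at criterion `i` (cumulating from
"definitely old" downward) are

    H_i  = R + (1 − R)·Φ(d′ − c_i)
    FA_i = Φ(−c_i)

`R ∈ [0,1]`; `d′` is not sign-constrained (negative values indicate
below-chance familiarity and are reported as-is).

**Fitting.** The default objective is the sum of squared errors over the
five cumulative (H, FA) pairs, the classic spreadsheet approach for this
model; a multinomial negative log-likelihood over the six response
categories is available (`objective="mle"`). Criteria are parameterised as
`c_1` plus log-increments so ordering is guaranteed; `R` is box-bounded.
Optimisation is multi-start L-BFGS-B (10 seeded restarts by default; the
SSE gradient is analytic) with a data-driven first start (criteria from the
inverse-normal of the observed false-alarm rates, `d′` from the mean zROC
displacement). Restarting stops early once two additional starts reproduce
the incumbent optimum. Degenerate data (all responses in one category)
return a flagged non-converged boundary fit rather than raising.

**Empty-bin smoothing.** At realistic trial counts (80 targets/80 foils)
extreme confidence categories are frequently empty. Fitting raw cumulative
proportions then pushes the outer criteria toward ±∞ and, because the model
must still reach the observed perfect outer proportions, biases `d′` upward
at a rate that grows with true `R` (measured: E[d̂′] drifts from 1.11 to
1.34 as R goes 0 → 0.7 at d′ = 1.2). This couples the two process
estimates and contaminates between-participant brain–behavior analyses.
Add-half smoothing of the category counts before cumulation removes the
drift (E[d̂′] flat at 1.03–1.08 over the same range) while leaving
large-sample fits unchanged, so it is the package default (`smooth=False`
restores raw-proportion fitting). The separate `zero_one_adjust` flag
implements the conventional 1/(2N) replacement of exact 0/1 proportions,
needed for zROC coordinates; it is off by default for SSE fitting, which
requires no inverse-normal transform.

## Response-deadline estimator

Per deadline condition, `d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate)` with a
log-linear correction (0.5 added to each cell, 1 to each denominator) as
the default guard against 0/1 rates at 30 trials per class; a 1/(2N) clamp
is the alternative. Familiarity is the short-deadline `d′`; recollection is
the long-minus-short difference, retained unclipped when negative so group
means stay unbiased. Trials without an in-window response carry no decision
and are excluded from numerator and denominator.

Under the generative model (single criterion `c`, short deadline driven by
familiarity alone), short `d′` recovers the generating `d′` exactly and the
long-minus-short gap converges to `Φ⁻¹(R + (1−R)Φ(d′−c)) + c − d′`, which
is what recovery tests check against.

## Synthetic cohort generator

The generator emulates a two-paradigm patient/control study: 9 patients,
14 behavioral controls and 48 volumetric controls by default; faces and
scenes as materials; 80 targets/80 foils per material in the
confidence-rating paradigm; 30 targets/30 foils per deadline and material
in the deadline paradigm. Two behavioral controls lack confidence-rating
data and five lack deadline data, mirroring typical missingness that the
imputation stage must handle.

* **Criteria** default to (−1.2, −0.6, 0, 0.6, 1.2), spanning the foil
  distribution so all six confidence categories are used, and the deadline
  paradigm uses a single old/new criterion at their midpoint (0).
* **Ground truth.** Per-(ROI, process) slopes map a patient's bilateral
  volume Z to shifts in true `R` (probability scale) and `d′`; defaults
  plant HPC→recollection and PHC→familiarity slopes of 0.35 with all
  cross-slopes 0. Baselines are `R = 0.40`, `d′ = 1.2`: the baseline `R`
  is placed so that the linear volume→R map stays inside [0,1] across the
  lesion-profile range at the default slope — outside that window the
  probability scale clips (handled, with a warning, but then the planted
  effect is no longer linear) and near R→1 the model's `d′` becomes
  unidentifiable.
* **Between-subject noise** (SD 0.08 on `R`, 0.15 on `d′`) is drawn
  independently for every material × paradigm cell. The only
  participant-level structure shared across cells is therefore the
  volume-driven signal itself, which is what the analysis models' random
  effects assume.
* **Lesion profiles.** A study-like default assigns nine patients: one
  selective right-PRC case, seven hippocampal cases with variable
  entorhinal involvement and subthreshold parahippocampal loss, one mixed
  case. Larger cohorts draw bilateral Z per ROI from N(0, 0.75) truncated
  to [−3, +1] (a damage cohort spans intact to severely atrophic, not
  appreciably above control norms), independently across ROIs so that null
  ROIs stay null.
* **Volumes.** Control TIV-corrected ratios are drawn around realistic ROI
  means (e.g. HPC ≈ 3.2 cm³ per hemisphere, TIV ≈ 1.5 L) with 10% relative
  SD, so Z-scoring controls against their own norms gives mean 0, SD 1;
  patient ratios are shifted to hit their profile's target Z.

**What the generator does not emulate:** response times and the
speed–accuracy tradeoff within the deadline window, item-level effects and
the fixed stimulus order, within-session learning or fatigue, correlated
atrophy across ROIs (real MTL damage co-occurs regionally; the generator
keeps ROIs independent so specificity is testable), word stimuli, and any
imaging-level artefact. Passing recovery tests therefore demonstrates that
the estimators and inference machinery behave correctly under the stated
generative assumptions, not that real data meet those assumptions.

## Volumetry

Corrected volume = raw volume / TIV; norms are per (ROI, hemisphere) means
and unbiased (n−1) SDs over the control sample; `z = (corrected − mean)/SD`.
A structure is lesioned when `z < −1.67` (strict inequality; the 5th
percentile of a normal control distribution), and a patient is
"HPC-lesioned" when either hemisphere falls below the cutoff. Bilateral
summaries average the two hemispheres' Z-scores. Lesion calls are invariant
to any uniform rescaling of volumes and TIV.

## Categorical inference

Behavioral scores are Z-transformed per design cell (process × material ×
paradigm) against the behavioral-control mean and unbiased SD, excluding
missing controls cell-wise. Missing control scores are multiply imputed by
chained equations (statsmodels `MICEData`, predictive mean matching, 10
iterations, m = 5); observed cells are never altered, and downstream tests
report the min and max of F and p across the m completed datasets. A
Bayesian-ridge chained alternative (`method="normal"`) uses scikit-learn's
IterativeImputer with posterior sampling.

The mixed between×within ANOVA uses the contrast-score reduction: with
2-level within factors, each within effect corresponds to one ±1 contrast
over a participant's cells, and the between-group test of that effect is a
one-way ANOVA on the per-participant contrast scores (the grand mean for
the Group main effect). For g groups and N participants every reported test
is F(g−1, N−g), which is the classical univariate repeated-measures answer
for such designs and accommodates a single-case "group" (one patient vs.
controls). Follow-up simple effects rerun the reduction within each level
of an interacting factor.

Demographics: Pearson χ² of independence without continuity correction
(the correction is deliberately not applied; the uncorrected statistic is
what 2×2 sex-ratio comparisons in this literature print), and a two-sided
Mann–Whitney U reported under the smaller-sample rank-sum convention with
tie-corrected p-values.

## Continuous brain–behavior models

Per ROI, Z-scored behavior is modelled as a linear mixed model with fully
factorial fixed effects of the ROI's bilateral volume Z, Process, Material
and Paradigm (sum-to-zero coding throughout, so with 2-level factors each
Type-III test is the marginal Wald F of one coefficient), and participant
random effects estimated by REML. Variance components are optimised on the
log scale by multi-start L-BFGS-B over a closed-form profiled REML
criterion (per-participant blocks, batched Cholesky).

**Random-effects structure.** Follow-up models within one process use a
single random intercept; if that fit is singular (a variance component at
the boundary, < 1e-4 of the residual), the model is refit adding
uncorrelated random slopes for Material and Paradigm and the refit is
reported alongside the intercept-only fit. Cross-process models add an
uncorrelated random Process slope from the start: both estimators induce
negative within-participant covariance between the two process scores (the
DPSD fit trades R̂ against d̂′; the deadline subtraction shares the short-d′
term), and without a process random effect the Volume×Process tests are
anti-conservative (observed type-I ≈ 0.3 at 40 participants in null-ROI
simulations, nominal once the slope is included).

**Satterthwaite degrees of freedom.** For each 1-df contrast `l`,
`df = 2·(l'C(v)l)² / (g'Ag)` where `C(v) = (X'V(v)⁻¹X)⁻¹`, `g` is the
finite-difference gradient of `l'C(v)l` in the variance components `v`,
and `A` is the inverse observed information of the REML criterion
(finite-difference Hessian on the natural scale). Components at the
optimiser's boundary are excluded from `g` and `A`. The implementation is
validated against R's lmerTest on a frozen fixture (F, df and p agree to
4 decimals) and against statsmodels MixedLM for the point estimates. The
df are floored at 1 and capped at the residual df; because they come from
numerical derivatives they are reproducible to ~0.01 rather than machine
precision.

**Permutation p-values.** Freedman–Lane residual permutation: the data and
design are whitened with the fitted marginal covariance (so rows are
exchangeable to the accuracy of the fitted model), the reduced model
excluding the tested column is fit by OLS, its residuals are permuted and
added back to the reduced fit, and the full-model F is recomputed;
`p = (b+1)/(n_perm+1)`. This treats the variance components as fixed at
their estimates — the standard practical compromise — and is verified to
give uniform p-values under the null and the same effect ordering as the
parametric tests. Fewer than 100 permutations are rejected.

## Numerical and reproducibility choices

* One integer seed drives everything; named substreams (cohort, per
  participant, restarts, imputation, permutation) are derived via
  CRC32-keyed `SeedSequence`s, so regenerating one stage never perturbs
  another, and identical configurations rerun to identical outputs (the
  pipeline manifest records a hash of the analysis-relevant config).
* Criteria ordering uses an epsilon of 1e-4; REML variance components are
  bounded in [1e-8, 1e3]×Var(y); the singularity threshold is
  τ² < 1e-4·σ².
* Degenerate designs error early: constant volume Z across participants
  (rank-deficient fixed effects), fewer than 5 participants, within-design
  cells missing after imputation.

## Problem sizes in the test and acceptance suites

Recovery and calibration checks run at sizes chosen to keep the whole
suite in the minutes range while leaving comfortable statistical margins:
200 simulated 80/80 ROC datasets for DPSD recovery (Monte-Carlo SE of the
mean R̂ ≈ 0.013 against a ±0.05 band), 5000-trial deadline conditions for
RDP convergence, 500–1000 null simulations for ANOVA type-I calibration,
200 null datasets × 199 permutations for permutation uniformity, and
100 forty-patient cohorts for the end-to-end double-dissociation rate
(Monte-Carlo SE ≈ 3.5 points on the rate).

## Known limitations

* The DPSD SSE objective ignores the multinomial error structure; MLE is
  provided but the SSE default is retained for comparability with standard
  practice. Neither propagates estimation uncertainty in R̂/d̂′ into the
  second-stage mixed models (a single-stage hierarchical treatment is out
  of scope).
* R̂ is attenuated toward the interior at extreme true values (bounded
  parameter), so very severe or ceiling-level cohorts dilute linear
  brain–behavior slopes; the probability-scale slope model is only locally
  linear by construction.
* Satterthwaite df and the permutation scheme condition on estimated
  variance components; with very few participants both are approximations,
  which is precisely why the permutation route is offered alongside.
* The mixed ANOVA's contrast reduction requires complete 2-level within
  factors per participant (after imputation); unbalanced designs are
  rejected rather than approximated.
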