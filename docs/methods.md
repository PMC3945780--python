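# Methods

## Model and problem

Right-censored survival data are triples (tᵢ, δᵢ, xᵢ): observed time
tᵢ = min(Tᵢ, Cᵢ), event indicator δᵢ = I(Tᵢ ≤ Cᵢ), and a p-vector of
baseline covariates. All fitting assumes the Cox proportional hazards
model λ(t|x) = λ₀(t) exp(xᵀβ) with an unspecified baseline hazard. The
package's goal is to decide which covariates — and which *products of
covariate pairs* — belong in a sparse β when p ≫ n.

## Componentwise Cox boosting

Estimation maximizes the Breslow partial log-likelihood

PLL(β) = Σᵢ δᵢ [xᵢᵀβ − log Σⱼ I(tᵢ ≤ tⱼ) exp(xⱼᵀβ)],

whose risk-set indicator handles tied times by the Breslow convention
(the matching Breslow estimator supplies the cumulative baseline hazard,
so the β = 0 baseline reduces exactly to Nelson–Aalen). Starting from
β = 0, step k evaluates for every candidate j the score Uⱼ and Fisher
information Iⱼ of the PLL in direction j at the current fit (computed
analytically via reverse-cumulative risk-set moments; exponentials are
handled in log space so large linear predictors cannot overflow), selects
the maximizer of the penalized score statistic Uⱼ²/(Iⱼ + ρ), and updates
that single coefficient by Uⱼ/(Iⱼ + ρ).

Parameters:

- ν (default 0.05) — relative step size; the penalty is derived as
  ρ = (number of events)·(1/ν − 1), so smaller ν means more, smaller steps.
- step count — the only tuned parameter; chosen by K-fold (default 10)
  cross-validation of the Verweij–van Houwelingen predictive partial
  likelihood, PLL(all data; β_fold) − PLL(training part; β_fold), with
  folds stratified by event status and refolded (incremented seed) if a
  training part would contain no events. The search cap is 200 steps;
  hitting the cap is logged.
- mandatory covariates (clinical set K) — refit by one unpenalized
  componentwise Newton cycle at the start of every step, before the
  penalized selection, and excluded from it.

Covariates are standardized internally (sample sd, constant columns get
scale 1 with a warning); coefficients are stored on the standardized scale
where score statistics are comparable, and predictions rescale inputs.
Predicted survival is S(t|x) = exp(−Ĥ₀(t) exp(xᵀβ̂)); the Brier machinery
uses the event probability π(t,x) = 1 − S(t|x).

## Random survival forest and permutation importance

Each of ntree (default 1000) unpruned trees is grown on an independent
0.632 *without-replacement* subsample. At a node, mtry (default
round(√p)) candidate covariates are drawn; all midpoints between adjacent
unique in-node values are scored by the absolute standardized two-sample
log-rank statistic and the best split taken. A node becomes terminal when
it has fewer than 3 distinct event times or no candidate split with a
positive statistic. Terminal nodes store the Nelson–Aalen cumulative
hazard of their cases on the forest grid (union of training event times);
the ensemble CHF of a case averages the terminal CHFs it reaches, and its
*mortality* — the risk score — sums the ensemble CHF over the grid.

Permutation accuracy importance (PAM) of covariate j is
err(permuted) − err(baseline), where err = 1 − Harrell's C of out-of-bag
ensemble mortality and "permuted" means one seeded global permutation of
column j. Only trees that split on j are re-evaluated; a covariate used
by no tree has PAM exactly 0. Harrell's C counts pairs with tᵢ < tⱼ and
δᵢ = 1 (plus tᵢ = tⱼ with exactly one event) as usable, score ties as 1/2.

## Screening strategies

One outer 0.632 split separates a training part Z_b from a holdout Z'_b
(splits with an event-free training part are redrawn, at most 100 times).
Main effects M are the nonzero coefficients of a CV-tuned boosting fit on
Z_b. The four pre-selection variants are:

- **rsf-VIF-res** — every covariate outside M ∪ K is replaced by its
  least-squares residual (with intercept) on the M ∪ K columns; S (default
  50) inner 0.632 subsamples each grow a forest, and every unordered pair
  of covariates with PAM > 0 in that subsample is counted. The R (default
  10000) most frequent pairs are kept; ties at rank R are all included.
- **rsf-VIF** — identical without the residualization step.
- **cb-VIF** — CV-tuned boosting instead of a forest on each inner
  subsample; per-variable inclusion frequencies (VIFs); pairs of
  ever-selected variables ranked by min(VIF_a, VIF_b), ties broken by
  VIF_a + VIF_b then index order (the ranking of pairs from per-variable
  VIFs is underdetermined in principle; this choice is deterministic and
  symmetric), with the same rank-R tie inclusion.
- **cb-crossp** — all C(|M|, 2) cross products of the detected main
  effects, or a seeded uniform subset of R if there are more pairs than R
  (the "more pairs than R" reading is used because comparing |M| itself to
  R could not bound the number of product terms).

The final model is a CV-tuned boosting fit on Z_b over {K, M, selected
products}, with K unpenalized. Product columns are built from the
*original* (non-residualized) covariate values — residualization is a
screening device only — and standardized like any covariate. If the
candidate set is empty the final predictor is the training Kaplan–Meier,
making its rIPEC exactly 0 by construction. Per-variable PAM > 0 is
evaluated within each inner subsample separately (so the inclusion
frequency has denominator S); one outer split is performed per call, and
replication across datasets or splits is the caller's job.

## Prediction error

The censoring survival P(C > t) is the marginal reverse Kaplan–Meier
(event indicator flipped) estimated on the *training* part; conditional
censoring models are out of scope. The IPCW Brier score at t averages
Wᵢ(t)·(δᵢ(t) − π(t, xᵢ))² over the holdout, with weight
I(tᵢ ≤ t)δᵢ/P(tᵢ⁻) + I(tᵢ > t)/P(t); cases censored by t get weight 0.
The evaluation grid is the unique holdout event times up to the largest
time with P(t) > 0.05 (weight stability; grid points with P(t) = 0 are
dropped with a log message). IPEC integrates the curve trapezoidally;
rIPEC = (IPEC_KM − IPEC_model)/IPEC_KM, positive when the model beats the
covariate-free Kaplan–Meier.

## Simulator

Twelve benchmark scenarios (n = 150, p = 1000 unless reduced): covariates
standard normal, Bernoulli(1/2) for designated binary variables, or
5-blocks from a 5-variate normal with unit variances and uniform
off-diagonal correlation c. The log hazard is
η = Σ βₘ xₘ + Σ γ_ab x_a x_b; event times are Exponential(λ·exp(η)) and
censoring times Exponential(λ) with λ = 1/20, giving ≈50% censoring at
η = 0. The same λ is used for both races — the censoring rate is a
modelling choice here, made because the equal-rate reading produces the
realistic ~50% censoring level. Sim42 places main effects (3, 3, −3, −3)
on the first four covariates and interactions (5, −5) on their pairs;
the Sim22 family places mains (0.9, −0.9) and interactions (±x) on four
further variables with zero main effect (Bernoulli-coded in Sim22_bin;
in correlated scenarios every true variable heads a distinct block, so
main-effect and interaction variables never share a block). Effect sizes
are log-hazard-scale coefficients. Ground truth (indices, pairs, the
per-subject linear predictor) travels with each dataset.

Scored metrics per strategy: IntScreen (mean pre-selected pair count),
IntSensiA (true pairs available after screening), MainSensi / IntSensi
(true terms with nonzero final coefficient — IntSensi ≤ IntSensiA by
construction), VarsTotal, and rIPEC of the main-effects-only and final
models, each with its standard error over replicates.

What the generator does *not* emulate: non-proportional hazards,
time-dependent or higher-order effects, informative censoring, and the
heavy-tailed intensity distributions and batch structure of real
expression data. Passing tests therefore demonstrate the pipeline's
mechanics and its behavior under the stated generating law, not
performance on real cohorts.

## Problem sizes used in the shipped checks

The full-scale benchmark protocol averages 50 datasets of a heavy
pipeline (50 inner subsamples × 1000-tree forests at p = 1000), which is
cluster-scale. The
shipped checks keep n = 150 and all effect sizes but reduce dimension and
replication, a single-CPU choice: boosting-only pipelines run at p = 300
with 10–25 replicates and 5-fold CV; forest pipelines at p = 150, S = 10,
ntree = 150 with 6 replicates. Selection sensitivities are compared
within three standard errors of the full-scale benchmark values; reduced dimension mainly shifts
the pre-selection *count* (IntScreen scales with the number of covariates
and, for cross products, with the square of the first-pass selection
size), which is reported as computed.

## Numerical and design notes

- Determinism: every stochastic step (data generation, outer split, CV
  folds, inner subsamples, tree resamples and candidate draws,
  permutations) descends from one seed via `numpy` `SeedSequence`
  spawning; rerunning any entry point with the same seed is bit-identical.
- The subsample fraction 0.632 is drawn *without* replacement (a subsample
  scheme, not a bootstrap), size round(0.632·n), also inside the forest.
- Degenerate inputs: constant covariate columns standardize to 0 with
  scale 1; a root node that cannot split yields a single-leaf tree; an
  all-censored leaf has a flat zero CHF; rank-deficient orthogonalization
  anchors fall back to the minimum-norm regression with a warning.
- Tie-breaks: boosting selection takes the first maximizer of the score
  statistic; forest split search keeps the first best split; pair ranking
  breaks count ties by index order (after the rank-R inclusion rule).
- The wide-penalty regime (ν = 0.05) makes each boosting step small, so
  the CV criterion can be nearly flat in misspecified scenarios (strong
  unmodeled interactions); the selected step count then scatters widely
  across replicates. This is a property of the method at these settings,
  visible in Sim42, and the main driver of dispersion in the reproduced
  sensitivities.

## Known limitations

Two-way interactions only; no competing risks, left truncation or
missing-data handling; the conditional censoring model P(t|x) is not
implemented; the forest exposes only permutation importance (no minimal
depth or Gini); real-data workflows (pathway post-processing, manual
step-count escalation) are out of scope.
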