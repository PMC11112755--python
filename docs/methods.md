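# Methods

This note records the statistical models implemented in `crossomix`, the
defaults and why they were chosen, the numerical strategies, and the known
limits of what the synthetic-data validation can show.

## Study design assumed throughout

A two-condition crossover: each participant is exposed once at a
high-exposure site and once at a low-exposure site (order randomized), with
profiles at three occasions per visit (pre, +2 h, +24 h) — six occasions
per participant. Exposure is measured per visit and shared by the visit's
three occasions. Participants carry age, sex, BMI and a three-level health
group; profiles carry technical factors (plate, box) assigned over samples.

## Synthetic-data generator

The generator emulates the statistical structure the analysis relies on,
with every "truth" returned for recovery testing:

- **Feature correlation** from a sparse precision matrix Θ: Erdős–Rényi
  support at a configurable density, off-diagonal magnitudes uniform in
  [0.2, 0.5] with random sign, diagonal set to the absolute row sum plus a
  margin (default 1.0) — diagonal dominance guarantees positive
  definiteness and the support is exactly the drawn edge set. Features are
  drawn MVN(0, Θ⁻¹) per profile.
- **Within-person correlation** via a participant random intercept
  (default SD 0.5 on the log2 scale).
- **Exposure effects**: a configurable feature subset gains β·x on the
  log2 scale. By default effects act on the post-exposure occasions only
  (+2 h, +24 h) — the within-person contrast a crossover exploits; a
  visit-level "main" mode is available since the effect-entry convention
  is a modelling choice, not an observable.
- **Technical batch effects**: one offset per factor level (two crossed
  factors), additive on log2 — i.e. multiplicative on raw intensity —
  consistent with the downstream log2 models. Default SD 0.3.
- **Left-censoring**: exactly the lowest ⌊f·n⌋ values of each feature are
  set missing (hard detection-limit mechanism, the one QRILC assumes).
- **Exposure levels**: five pollutants with the first site's means above
  the second's for every pollutant (e.g. NO2 88 vs 27 µg/m³), plus
  visit-level noise. Units are fixed but arbitrary.

Defaults emulate 50 participants × 2 visits × 3 time points = 300
profiles; a 42-participant subcohort (252 profiles) mirrors the
transcriptomics setting.

What the generator does **not** emulate: chromatographic drift, isotope and
in-source fragment structure beyond simple adduct relationships,
probe-level microarray noise, non-normal intensity distributions, and
exposure measurement error. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
every artifact of real LC-MS or microarray data.

## Preprocessing

Order is filter → log2 → impute → outlier-flag → denoise, enforced by the
container's scale and missingness invariants and recorded in the run
manifest (imputation before outlier flagging because PCA needs a complete
matrix; denoising last so BLUPs are estimated on complete, transformed
data).

- **Missingness filter**: a feature is removed when missing in ≥ 40% of
  participants (threshold inclusive); a participant counts as observed if
  any of their profiles is observed. A per-profile variant is available.
- **QRILC imputation** operates per profile (column). With missing
  fraction f, the observed order statistics are regressed on
  standard-normal quantiles at Blom plotting positions for ranks
  ⌊fn⌋+1…n, giving (μ̂, σ̂) of the latent complete distribution; missing
  values are drawn from N(μ̂, tune_sigma·σ̂) truncated above at
  μ̂ + σ̂·Φ⁻¹(f). `tune_sigma` defaults to 1.0. A profile with fewer than
  4 observed values falls back to half-minimum imputation with a warning.
- **PCA outlier flags**: standardized features, first 3 components,
  |score − median| > 5 × 1.4826·MAD on any component. The 3-component /
  5-MAD rule is a reproducible stand-in for visual PCA screening; the
  number of flagged profiles is data-dependent by construction.
- **Technical denoising**: per feature, an intercept-only model with
  crossed random intercepts for the technical factors, REML-estimated.
  The implementation profiles out the mean and residual variance and
  optimizes the two variance ratios (Nelder-Mead, tolerance 1e-8 on the
  restricted log-likelihood) with all linear algebra in the
  total-number-of-levels dimension via the Woodbury identity, so a
  feature costs ~O(q³) with q ≈ 11; BLUPs are subtracted, the fixed mean
  retained. statsmodels' MixedLM reproduces the BLUPs in tests.
  Non-convergence falls back to sequential one-factor fits; single-level
  factors are dropped with a warning.

## Repeated-measures association

`RepeatedMeasuresGLS` fits, per feature, y_i ~ MVN(X_i β, Σ) across each
participant's occasions with fully unstructured Σ (equivalently D·R·D with
unit-diagonal R and occasion SDs D: 21 parameters). REML estimation
iterates two exact steps — the GLS normal equation for β at fixed Σ and
the closed-form REML moment update for Σ at fixed β (an EM-type fixed
point) — rather than a generic quasi-Newton search; with missing occasions
participants contribute their observed sub-vectors and the E-step uses
conditional expectations. The fitter is batched over features (a few
einsum contractions per iteration fit hundreds of features at once) and
agrees with `nlme::gls` (corSymm + varIdent, REML) to 6+ decimals on β,
SE and restricted log-likelihood. Convergence: relative change of Σ and β
below 1e-8; non-converged features are refitted under compound symmetry
and flagged `downgraded`.

**Small-sample inference.** The model-based Wald SE ignores that the GLS
weights use the estimated Σ; with 21 covariance parameters from ~50–100
participants the exposure statistic is visibly heavier-tailed than normal
(observed variance ≈ 1.11 at 100 participants; far-tail rejection ~4×
nominal). The default reference therefore applies the leading
Kackar–Harville/Kenward–Roger variance correction to the tested contrast,

  Var_adj = c'Φc + 2·c'Φ[Σ_rs W_rs (Q_rs − B_r Φ B_s)]Φc,

with Φ the GLS coefficient covariance, B_r and Q_rs the first- and
second-order design-weighted covariance derivatives, and W the inverse
REML expected information of vech(Σ); degrees of freedom follow
Satterthwaite, df = 2·Var_adj²/(g'Wg). Under a global-null simulation this
brings the family-wise error of the ENT-Bonferroni correction from ~0.20
to ~0.03–0.075 (nominal 0.05) and the 95%-interval coverage to ~0.94.
`fit(reference=...)` also offers the plain normal and residual-df t
references.

- **Exposure coding**: visit-level exposure on all occasions; the tested
  coefficient is the main effect (`effect_mode="main"`). An
  exposure×post-walk interaction mode tests the interaction instead; the
  crossover contrast itself is carried by the covariance structure.
- **Covariates**: age, sex, health group always; BMI included by default.
- **ENT**: smallest k with the top-k principal components of the
  standardized feature matrix explaining strictly more than 99% of total
  variance (zero-variance features dropped with a warning). Corrections
  use strict inequality at the per-test threshold.

## Stability-calibrated networks

The graphical LASSO maximizes log det Θ − tr(SΘ) − Σ_{j≠k} λ_jk|Θ_jk| on
the correlation matrix (diagonal unpenalized). The solver is block
coordinate descent over columns with cyclic coordinate descent in each
lasso subproblem (numba-compiled; exact zeros from soft thresholding);
accuracy is verified three ways in tests: sub-gradient stationarity
(~1e-15), agreement with sklearn's independent implementation, and with a
generic constrained optimizer of the penalized objective at p = 4 (≤1e-5).

Calibration refits the model on K subsamples (default 500 draws of 80% of
participants — the resampling unit is the participant where participant
ids are supplied, otherwise the profile) over 25 log-spaced penalties from
λ_max (smallest penalty giving an empty graph) down to 0.01·λ_max, and
picks (λ*, π*) maximizing the stability score: under an exchangeable
Binomial(K, q) null (q the average selection probability at that penalty),
each edge contributes the log null probability of its category —
stably selected (proportion ≥ π), stably unselected (≤ 1 − π), or
unstable — and the score is minus their sum, so bimodal selection
patterns score high. The stable adjacency is {selection proportion ≥ π*}.

**Known limitation.** Because 80% subsamples share most of their rows, an
edge whose *sample* correlation happens to be among the largest is selected
in most subsamples even when the population graph is empty; the
bimodality-rewarding score then keeps a handful (typically 1–8 at n = 300,
p = 20) of such sample-specific edges rather than returning the empty
graph. No function of the selection counts can separate these from true
edges — subsampling does not create fresh data. An optional
`pfer_threshold` restricts calibration to (λ, π) whose
Meinshausen–Bühlmann bound on expected false edges is below a budget; it
empties null networks but under-selects when the true graph has more edges
than the budget, so it is off by default.

The multiomic variant partitions variables into two blocks and calibrates
three penalty groups (within-1, within-2, cross) over the product of their
grids with the same score; identical penalties reduce it exactly to the
single-block procedure (shared subsample stream). Networks per time point
are compared edge-wise into stable / baseline-only / acute / persistent /
lagged / resolving / reverting classes.

## Consensus clustering

Base clusterer: hierarchical clustering, Ward linkage, distance
1 − |Pearson r| — chosen for determinism within each subsample (k-medoids
would need its own seed policy). Comembership proportions are accumulated
over 500 subsamples of 80% of profiles for each candidate G, and (G, π_c)
maximize the same stability score applied to comembership counts. The
consensus partition cuts the comembership graph at π_c and takes connected
components, merging the closest pair (highest between-cluster mean
comembership) while above G and splitting the loosest cluster (2-way
average-linkage on 1 − comembership) while below. Medoid: the member with
the highest summed |r| to its co-members; ties break to the lowest feature
index. Retention-time coherence of clusters is exposed as a report, never
asserted.

## Annotation and enrichment

Adduct shifts are monoisotopic: [M+H]+ (+1.007276 Da), [M−H2O+H]+
(−17.003289), [M+Na]+ (+22.989218); a match requires the implied neutral
mass within ±8 ppm (inclusive) of a reference mass, and all candidates are
returned ordered by |ppm error|. Over-representation uses the one-sided
Fisher exact test (equal to the hypergeometric tail), on user-supplied
pathway maps over an explicit compound universe; per-pollutant p-value
thresholds for building the selected set (0.05 PM2.5/PM10, 0.01 PCNT/BC,
0.005 NO2) are a configuration knob. No bundled pathway database and no
permutation-based adjustment: raw Fisher p-values are reported.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → associate → cluster →
network → enrich under one `RunConfig`; each stage draws randomness from a
stream derived from the master seed and a stable stage label, so toggling
one stage never shifts another's draws, and rerunning a config is
bit-identical. A `manifest.json` records the resolved configuration and
per-stage logs; `report.md` summarizes counts, clusters and rewiring
classes. A stage failure aborts with the stage name and preserves earlier
outputs.

## Problem sizes used in validation

The validation suite runs the family-wise-error study at 100 participants
× 200 correlated features × 200 replicates; coefficient recovery at 100
participants × 200 replicates (β = 0.5 on a unit-scale exposure, effects
entering at the visit level to match the fitted main-effect model);
network recovery at p = 20, density 0.1, n = 300, K = 100 (the
paper-faithful K = 500 default is used by the pipeline); consensus
clustering at 3 blocks × 10 features, within-block |r| = 0.9, 500
subsamples. The end-to-end pipeline demo uses 15–20 participants and a few
dozen features. The acceptance script reports the median network F1 over 5
replicates because a single-draw F1 at these sizes has seed-to-seed spread
of roughly ±0.2.

## Known limitations

- Small-sample inference adjusts the tested exposure contrast only; the
  covariate columns keep model-based SEs.
- The E-step/REML combination for participants with missing occasions uses
  the complete-data REML correction term; with many incomplete
  participants the Σ estimate is approximate (the β step is exact).
- The Satterthwaite/KR machinery uses complete participants only.
- The stability score's behavior on structure-free data keeps a few
  sample-specific edges (see above); interpret very sparse stable networks
  with the selection-proportion table, not the adjacency alone.
- QRILC assumes a hard detection limit and near-normal log2 intensities;
  heavy-tailed features bias σ̂ upward.
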