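# crossomix

Statistical analysis of **crossover exposure studies with multiomic
readouts** — the design in which each participant is their own control:
every subject is exposed under two contrasting conditions (for example a
2-hour walk along a high-traffic street versus a park), with blood profiles
taken 2 h before and 2 h and 24 h after each exposure session. Untargeted
metabolomics (LC-MS feature tables with m/z and retention time) and blood
transcriptomics measured on those profiles are related to personal pollutant
exposures (PM10, PM2.5, NO2, black carbon, particle counts).

The package is aimed at biostatisticians and exposome researchers who need
the full chain as tested, reusable code: preprocessing and technical
denoising, repeated-measures association testing with a principled
multiple-testing correction, redundancy-aware clustering of ions, and
conditional-independence networks calibrated by stability — plus a
synthetic-study generator with known ground truth so every stage can be
validated without access to any cohort data.

## What it computes

**Repeated-measures association (GLS/MVN model).** Each feature *Y* over a
participant's six occasions (2 sites × 3 time points) follows

```
y_i ~ MVN(X_i β, Σ),    Σ = D R D,
```

with *R* an unstructured 6×6 correlation matrix and *D* occasion-specific
SDs — 21 free covariance parameters estimated by REML. Fixed effects are
the visit-level exposure plus age, sex, health group and BMI. Because the
21-parameter covariance is estimated from a limited number of participants,
the Wald statistic for the exposure is noticeably heavier-tailed than
normal; the default inference uses a Kackar–Harville/Kenward–Roger-style
adjusted standard error with Satterthwaite degrees of freedom (see
`docs/methods.md`). Significance is called under Bonferroni at two
denominators: the **effective number of tests** (ENT — the number of
principal components explaining >99% of the variance of the feature
matrix) and the full feature count.

**Preprocessing.** Features missing in ≥40% of participants are removed;
intensities are log2 transformed; left-censored values are imputed by
**QRILC** (quantile regression on the observed order statistics of each
profile, then truncated-normal draws below the estimated detection limit);
outlying profiles are flagged on PCA scores; technical batch structure
(e.g. plate and box) is removed by subtracting BLUPs of crossed random
intercepts fitted per feature by REML.

**Stability-calibrated networks and clustering.** Conditional-independence
networks are estimated with the **graphical LASSO**
(ℓ1-penalized precision estimation; block coordinate descent with an
elementwise penalty matrix, so block-specific penalties for multiomic data
are a special case). The penalty λ and the selection-proportion threshold π
are calibrated jointly by refitting on K = 500 subsamples of 80% of
participants and maximizing a likelihood-based stability score that
contrasts the observed bimodality of edge-selection proportions against an
exchangeable binomial null. The same score calibrates **consensus
clustering** (hierarchical/Ward on 1 − |r| over subsamples) of redundant
ions; each cluster is represented by its medoid. Networks are estimated
separately at the three time points and compared edge-by-edge (stable /
acute / persistent / lagged / reverting rewiring classes).

**Annotation and enrichment.** m/z values are matched to a reference mass
list through [M+H]+, [M−H2O+H]+ and [M+Na]+ adducts within a ppm tolerance
(default ±8 ppm), and compound sets are tested for pathway
over-representation with a one-sided Fisher exact test against
user-supplied pathway maps.

## Worked example

```python
import numpy as np
from crossomix import (DesignConfig, ExposureModel, EffectSpec, PrecisionSpec,
                       generate_design, generate_exposures,
                       generate_precision_matrix, generate_omics,
                       effective_number_tests, apply_corrections)
from crossomix.association import association_scan
from crossomix import preprocess as pp

# a 50-participant crossover with 8 NO2-responsive features planted
design = generate_design(DesignConfig(n_participants=50, seed=1))
expo = generate_exposures(design, ExposureModel(), seed=2)
theta, edges = generate_precision_matrix(PrecisionSpec(p=120, density=0.03), seed=3)
effects = EffectSpec(affected=np.arange(8), beta=0.02, pollutant="NO2")
raw, truth = generate_omics(design, expo, theta, effects,
                            batch_sd=0.3, censor_fraction=0.1, seed=4)

m, _ = pp.filter_missingness(raw, 0.40, sample_meta=design)
m = pp.log2_transform(m)
m, _ = pp.impute_qrilc(m, seed=5)
flags = pp.flag_pca_outliers(m)
m = m.select_samples(flags.index[~flags])
m, _ = pp.denoise_technical(m, design.loc[m.values.columns, ["plate", "box"]])

meta = design.loc[m.values.columns]
ent = effective_number_tests(m)
results = association_scan(m, meta, expo, pollutants=["NO2"])
results = apply_corrections(results, ent=ent, n_features=m.n_features)
print(f"profiles: {len(design)}, features kept: {m.n_features}, ENT = {ent}")
sig = results[results["significant_ent"]]
print(f"ENT-significant features for NO2: {len(sig)}")
```

prints

```
profiles: 300, features kept: 120, ENT = 112
ENT-significant features for NO2: 8
```

— all 8 planted features and nothing else. A single-feature model summary
(`RepeatedMeasuresGLS(...).fit().summary(0)`) shows the estimate against
the planted effect of 0.02 log2 units per µg/m³ NO2:

```
Repeated-measures GLS (REML), unstructured 6x6 covariance
Feature: M0001   Participants: 50   Restricted loglik: -610.980
               coef  std err        z   P>|z|   [0.025   0.975]
const       18.6386   1.3618  13.6871  0.0000  15.9321  21.3451
NO2          0.0197   0.0027   7.1646  0.0000   0.0142   0.0251
age          0.0082   0.0147   0.5600  0.5769  -0.0209   0.0374
...
```

The whole chain — simulation through networks, enrichment and a run
manifest — is also available as one seeded command:

```bash
crossomix run --config run.yaml --out results/run1 --seed 1
```

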