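# Methods

## The problem

Randomized trials of intensive systolic blood-pressure (SBP) control report
an *average* treatment effect; clinically, the effect may vary across
multivariate patient profiles.  One-variable-at-a-time subgroup analysis is
both underpowered and blind to profile combinations.  The approach
implemented here discovers subgroups *without looking at outcomes*: an
unsupervised self-organizing map (SOM) is trained on the seven Framingham
risk score components, the map is split into contiguous subgroups, and only
then are treatment effects estimated per subgroup and compared.  Because
subgroup membership is a function of baseline covariates alone, and
treatment is randomized, the per-subgroup hazard-ratio contrasts remain
internally valid; the split-by-variable design protects the subsequent
inference from the selection optimism that supervised clustering would
introduce.

## Synthetic cohort generator

The generator draws participants from a mixture of *archetypes*.  Each
archetype specifies Gaussian means/SDs for the continuous FRS components
(age in years, SBP in mmHg, TC and HDL in mg/dL) and Bernoulli prevalences
for the binary ones (female sex, antihypertensive use, current smoking).
Treatment is Bernoulli(0.5), independent of covariates.  For each endpoint
the event time is exponential with rate
`base_rate × exp(log_hr × 1[intensive])`, censored administratively at 3.26
years (the follow-up horizon used throughout); proportional hazards
therefore holds *exactly*, making Cox-model recovery a clean oracle.
Missingness is MCAR per predictor cell.  Nine additional pretreatment
covariates (race, BMI, statin and aspirin use, eGFR, glucose,
triglycerides, urine albumin/creatinine, CVD history) are drawn from
cohort-level distributions for adjustment and balance checks.

The default specification has four archetypes whose pooled moments
reproduce a SPRINT-like baseline table (age 67.9 ± 9.4 y, SBP
139.7 ± 15.8 mmHg, TC 190.4 ± 41.7, HDL 52.9 ± 14.4 mg/dL, 35.4% female,
90.7% antihypertensive use, 13.5% smokers; archetype weights proportional
to 2874/2048/2216/1635):

| archetype | profile | defining contrasts |
|---|---|---|
| I | older men, lowest TC/HDL | TC 143.6, HDL 38.4, 3% female |
| II | highest SBP, little BP medication | SBP 165.4, 65% antihypertensive |
| III | women, highest TC/HDL | TC 249.3, HDL 72.9, 92% female |
| IV | youngest, smokers | age 51.3, 55% smokers |

Within-archetype SDs are deliberately narrow (e.g. TC 12 mg/dL): the
between-archetype spread supplies the remaining variance so the *pooled*
SDs match the trial-scale values, while archetype centroids stay 4–9
within-SDs apart on their defining variables.  This makes recovery of the
planted partition well-posed — at this separation a Bayes-optimal
classifier reaches adjusted Rand index ≈ 0.99, leaving headroom to measure
the pipeline's own losses.  Real cohorts are far more overlapping: passing
recovery tests on these defaults demonstrates the machinery is correct,
*not* that real trial populations contain such crisp subgroups.  Separation
is fully configurable through `ArchetypeSpec` to study degradation.

Default planted effects: intensive control is protective (HR 0.75) for
every endpoint except non-MI ACS, where archetype II is harmed (HR 3.62)
and the other archetypes are null.  Per-archetype base rates follow the
published subgroup incidence gradients (e.g. composite 10.1% in archetype I
down to 6.4% in III over 3.26 y), converted to exponential rates by
`λ = −ln(1−p)/t`.

Limitations the generator does **not** emulate: trial eligibility
screening, visit schedules and treatment titration, competing risks,
informative censoring or dropout, within-archetype covariate correlation
(off by default; a correlation-matrix hook exists), and outcome-dependent
missingness.

## SOM engine

*Geometry.*  A circular map: hexagonal cells with hex-distance ≤ R from a
center cell (1 + 3R(R+1) districts; default R = 5 → 91).  Grid distances
are Euclidean over the planar cell coordinates; adjacent cells are at
distance 1.

*Standardization.*  Training variables (binaries coded 0/1) are centered
and scaled to unit SD; zero-variance variables and missing values are
refused.  Columns ending in `_event`/`_time` are rejected outright — the
split-by-variable contract is enforced at the lowest level of the call
path.

*Training.*  Batch Kohonen updates: each epoch assigns every row to its
best-matching district (BMU, Euclidean; ties to the smallest district id)
and sets each prototype to the Gaussian-neighborhood-weighted mean of the
assigned rows, `h = exp(−d²/2σ²)` over grid distance d.  σ decays linearly
from R to 1 over the epochs (default 50).  Districts receiving zero weight
keep their previous prototype.  Prototypes are initialized on the plane of
the top two principal components of the training matrix (scaled to the
per-component score SDs) plus small seeded jitter — deterministic and
rotation-meaningful.  Training is exactly reproducible from
(matrix, grid, epochs, seed); quantization error per epoch is recorded.

*Transfer.*  A trained map is a frozen bundle (grid spec, standardizer,
prototype matrix, SHA-256 checksum).  External cohorts are standardized
with the *training* standardizer and projected by BMU only; nothing refits.

## Permutation map statistics

For a variable y, the district layer is the kernel-weighted mean
`Σ K(d, b_i) y_i / Σ K(d, b_i)` with `K = exp(−d²/2·bw²)` over grid
distance from each participant's BMU `b_i` (default bandwidth 1 grid unit;
bandwidth 0 is the plain per-district mean).  The regionality summary is
the SD of the layer across defined districts — the simplest statistic that
is large exactly when the map shows coherent regions.  The null
distribution comes from random colorings: y is permuted across participants
(positions fixed) and the amplitude recomputed, n_perm = 20,000 by default
(tests use 500 for speed; the p-value resolution is 1/(n_perm+1) either
way).  The layer p-value is the permutation rank
`(1 + #{null ≥ observed}) / (n_perm + 1)` — never 0 — and district scores
are `(value − grand mean) / mean(null amplitude)`, which cancels affine
rescalings of the variable, so binary prevalence layers and continuous mean
layers share one color scale with the same statistical meaning.  Variables
are permuted one at a time (per-variable significance); empty districts are
excluded from the amplitude rather than imputed.

## Subgrouping

The primary path is an explicit district→label YAML: visual boundary
selection on the colored maps is expert judgment and inherently
irreproducible, so the artifact records its outcome as config.  The
automated suggestion is Ward agglomeration of the district prototype
vectors with merges restricted to grid-adjacent clusters, guaranteeing k
connected patches; it is deterministic, and the `seed` argument is recorded
in provenance only.  Subgroup labels propagate to participants through
their BMU district, so label transfer to an external cohort needs only the
config file and the frozen map.

Balance: for each subgroup × covariate, the between-arm standardized mean
difference uses the two-group pooled-variance form
`|m₁−m₀| / √((s₁²+s₀²)/2)`, with Bernoulli variances `p(1−p)` substituted
for binary covariates — one formula, one closed-form test value (means 0
and 1 with unit SDs give exactly 1).  The acceptability threshold (default
0.1) is configurable; an external-validation-style relaxed check can use
0.15.

PCA sensitivity: top-3 principal components of the standardized training
matrix (deterministic full SVD), reported with loadings and
variance-explained fractions, as a linear cross-check that the subgroup
contrasts are visible outside the SOM.

## HTE analysis

One code path serves all six endpoints (MI, non-MI ACS, stroke, HF, CVD
death, composite).  Per subgroup: a Cox PH fit of the treatment indicator
with a configurable adjustment set — default sex, age, race, smoking, BMI,
antihypertensive use; a named variant swaps antihypertensive use for statin
use (the two sets seen in practice); sensitivity models use no adjustment
(model 1) and the lipid panel TC/HDL/triglycerides (model 2).  Ties are
handled by Efron's method (a standard low-bias default; the generator's
continuous times make ties measure-zero anyway).  Newton iterations run to
a step-norm tolerance of 1e-11 so the estimate matches an independent
partial-likelihood maximizer to ≤ 1e-6; standard errors are Wald, CIs
`exp(β ± 1.96·se)`.  Constant covariates within a subgroup are dropped
before fitting; a fit with no events in one arm (monotone likelihood) or a
runaway coefficient (|β| > 20, quasi-separation) is flagged with an
unbounded CI and excluded from Q with a warning rather than contributing a
fabricated SE.  Q needs ≥ 2 usable subgroups, otherwise the endpoint's
heterogeneity is reported undefined.

Cochran's Q: `w = 1/se²`, pooled `θ̂ = Σwθ/Σw`, `Q = Σw(θ−θ̂)²`, p from
χ²(k−1).  ARR and NNH/NNT use crude cumulative proportions (events/n), the
same arithmetic as the printed incidence percentages; they are exact
rational functions of the four integer counts.  Nelson–Aalen cumulative
hazards are computed per arm without small-sample smoothing so
`H(t) = Σ d/n` holds exactly.  No multiplicity adjustment is applied across
the six endpoints; results are reported as-is and should be read as
exploratory.

## Pipeline

`run_pipeline` executes simulate/load → complete-case filter → train →
color → subgroup → balance → HTE (→ external validation) and writes CSV/
YAML/JSON artifacts plus a manifest (config hash, seed, versions, Q
summary, bundle checksum).  Reruns with the same config are byte-identical.
The bundle hash is asserted unchanged at the end of the run and around
external validation.  All randomness in a run derives from the single
mandatory seed.

## Problem sizes and test design

Unit tests run on cohorts of 500–2,000 with small grids; the calibration
and power checks use the sizes at which their statistical claims are sharp:
KS uniformity of Q p-values over 200 replicates of n = 4,000; permutation-p
uniformity over 200 replicates at n_perm = 500; archetype recovery at
n = 8,000 with the default map; heterogeneity power (planted HR 3.0, one of
four subgroups) and size over 50 replicates at n = 20,000; balance over 100
replicates at n = 10,000.  Replicate-loop Cox fits use the unadjusted model
(model 1) — on randomized data the adjusted and unadjusted treatment HRs
coincide up to noise, and the toy/oracle equivalence is checked separately.
All stochastic tests are seeded and deterministic.

## Known limitations

- Suggested subgroups depend on the map's seed through the SOM layout; the
  adjusted Rand index against planted truth varies by a few points across
  seeds (≈ 0.84–0.89 at default settings).
- The Ward suggestion assumes the interesting partition aligns with
  prototype variance; profiles whose defining contrast is weak relative to
  within-region gradients may be split or merged.  The manual config path
  exists precisely for this case.
- Count-based NNH can differ in the second decimal from values derived
  from adjusted/unrounded incidences (e.g. a published 84.24 versus 84.12
  from the printed counts 17/1016 vs 5/1032); this package always reports
  the count arithmetic.
- The heterogeneity Q test treats subgroup estimates as independent, which
  holds here because subgroups partition the cohort.
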