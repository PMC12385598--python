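# Methods

This note documents the models, parameter choices, and numerical conventions
behind `lagerscale`, and what its synthetic-data tests do and do not
establish.

## Data model

The analysis is coordinatized by an **attribute hierarchy**: ordered sensory
dimensions, each with ordered sub-attributes, plus a merge map (groups of
perceptually similar sub-attributes consolidated before scale construction)
and an exclusion list. The default hierarchy encodes pale lager: appearance
(beer color, clarity, foam abundance), aroma (malt, hop, fruit, floral,
sweet, fermentation), taste (sourness, sweetness, bitterness, umami,
astringency), and drinking sensation (smoothness, fullness, refreshment,
body coordination, prickliness, alcohol warmth, aftertaste, persistence,
foam fineness). Foam fineness is placed under drinking sensation because
that is where the published weight tables carry it, even though it is
visually assessed.

Ratings are integers on a 1–5 Likert scale, one row per respondent, with an
explicit `NA` missing marker (never silent zeros). Missing ratings are
excluded pairwise; an attribute with fewer than two ratings in a cohort
aborts with an error rather than being imputed, matching the valid-case
screening philosophy of survey work in this area.

**Dimension-level scores.** The weighting engine needs per-respondent scores
for whole dimensions as well as sub-attributes. The package derives a
respondent's dimension score as the mean of their non-missing ratings on
that dimension's sub-attributes. A survey instrument may instead ask
dimension-importance questions directly; if so, those can be appended as
extra columns and the hierarchy adjusted. This is a deliberate design
choice: it keeps the input schema minimal and makes dimension and
sub-attribute weights consistent by construction.

## Reliability screening

Cronbach's α, the KMO sampling-adequacy statistic, and Bartlett's test of
sphericity are computed per dimension scale on complete cases, using Pearson
correlations. Polychoric correlations would arguably suit ordinal Likert
items better, but these diagnostics are conventionally defined and
benchmarked (α ≥ 0.70, KMO ≥ 0.70, Bartlett p < 0.05) on product-moment
correlations, so Pearson is used. Exploratory factor analysis is out of
scope.

## Weighting engine

**Ratings-driven AHP.** Cohort attribute means are min–max mapped onto
Saaty's 1–9 scale, v = 1 + 8(m − min)/(max − min). The comparison matrix is
the ratio matrix a_ij = v_i/v_j (entries clipped to [1/9, 9]), which is
perfectly consistent, so its principal eigenvector is v and the weights are
w = v/Σv. The construction rule is not uniquely determined by the published
description; the ratio-matrix rule was adopted because it reproduces the
published per-cohort AHP shares (a dominant dimension mapping to ≈65% for
the low-frequency cohort). Consequences worth knowing:

- CR = 0 by construction; `consistency_ratio` exists to guard user-supplied
  expert matrices (standard random-index table, threshold 0.1 reported but
  not enforced).
- The mapping is scale-dependent: the min attribute always maps to v = 1,
  the max to v = 9, amplifying small mean differences. That is the intended
  behavior — it counteracts the central-tendency compression of Likert
  ratings.
- All means equal is degenerate: every attribute maps to mid-scale 5
  (uniform weights) with a warning. Exact ties map to exactly equal values;
  no tie-breaking is needed here.

**Entropy weight method.** Standard EWM on the raw respondent × attribute
score matrix (1–5 scores are already positive; no shift). Natural log; the
1/ln n normalization makes the base irrelevant. 0·ln 0 ≡ 0. A constant
column has entropy 1 and weight 0; if every column is constant the method
degenerates to uniform weights with a warning. Whether the original
analysis applied EWM to individual ratings or some aggregate is unstated;
individual ratings (the standard definition) are used.

**Fusion.** Composite = α·AHP + (1−α)·EWM with α = 0.7, a constant fixed by
Delphi expert consultation in the source study, exposed as `fusion_alpha`.

**Cohort aggregation.** Frequency factors f = (2, 6, 14) represent the low
(1–3), mid (4–8), and high (≥9 occasions/month) cohorts. Coefficients
C_i = f_i·N_i/Σf_j·N_j use the observed cohort sizes N. The aggregation
W_a = ΣC_k·W_k,a is a convex combination, renormalized only if floating
drift exceeds 1e-9.

**Which layer is aggregated.** The method description states that the fused
composite weights are aggregated across cohorts, but the published
comprehensive figures arise from aggregating the per-cohort **AHP** layer
(65.32/38.59/13.61 → 30.92 for drinking sensation; 7.26/4.29/49.49 → 24.77
for aroma — both reproduce exactly only with the AHP layer). The package
defaults to `aggregate_layer: ahp`, reproducing the published arithmetic,
and exposes `composite` as the formula-as-stated alternative. The choice is
logged on every run.

## Scale construction

Order of operations: merge → exclude → top-k selection → local
normalization → weighted integration → global normalization → largest-
remainder integerization.

- **Merge rule is summation** of comprehensive weights. The published
  description states which attributes were merged but not the arithmetic;
  summation reproduces every printed final weight, so it is adopted.
- **Merging precedes top-k.** Otherwise the merged fruity–fermentation
  aroma (10.35% + 20.31%) could never rank in aroma's top 3, and the
  published scale could not be reproduced.
- **Exclusions do not renormalize**; all renormalization happens inside the
  three-step standardization. Excluding an absent name warns and is a
  no-op.
- **Appearance is excluded at dimension level** in the default
  configuration. The published final scale contains no appearance attribute
  even though the stated procedure implies top-3 per dimension; the package
  treats this as a config-visible exclusion rather than guessing a reason,
  and logs it. Similarly, the excluded "alcohol sensation" is mapped to the
  tables' "alcohol warmth".
- **Ties at rank k** are broken by larger pre-merge AHP weight, then
  lexicographically — fully deterministic.
- **Integerization** uses the largest-remainder method (floor, then
  distribute the shortfall to largest fractional remainders; ties by larger
  fraction, then name). Integer weights sum to exactly 100. Display
  percents in written reports use the same largest-remainder rule at
  0.01-point resolution so every printed table totals 100.00 exactly.

## Tasting validation

Professional composites under the consumer scale are per-assessor weighted
averages of attribute scores (fractional weights), averaged over assessors —
by linearity identical to weighting the mean attribute scores, but kept
per-assessor for diagnostics. The existing industry scale contributes a
single overall score per assessor; its composite is the plain mean.
Rankings use rank 1 = best with average ranks on ties. Concordance is
Kendall's τ-b and Spearman's ρ on tie-averaged ranks (identical to the
untied definitions for the four-sample validation data). No significance
tests are reported: with n = 4 samples, p-values are meaningless.

## Synthetic data generator

The generator emulates the stated survey world: n = 1837 respondents,
cohort shares 38.54% / 42.49% / 18.97% (the high-frequency share is the
unprinted remainder), integer cohort sizes by largest remainder, and
per-attribute Likert ratings drawn as latent N(μ, σ), rounded to the nearest
integer and clamped to [1, 5]. Default targets are drawn per attribute from
μ ∈ [3.6, 4.0] and σ ∈ [1.0, 1.25], the ranges occupied by the study's
per-attribute summaries. Tasting sessions default to 4 samples, a 10-expert
panel, and 30 consumers on the 1–9 scale, with truth-plus-Gaussian-noise
scores (default noise SD 0.5, a typical trained-panel residual spread)
discretized the same way.

Two honest caveats about clamping and independence:

- Rounding-and-clamping biases moments: a latent N(3.7, 1.1) yields a
  discrete variable with mean 3.645 and SD 1.031. Tests therefore compare
  empirical moments against the exact bin-probability oracle
  (`discretized_normal_moments`), not the latent targets.
- Attributes are generated independently (marginals only). Real Likert
  items within a dimension correlate strongly — that correlation is what
  Cronbach's α and KMO measure — so reliability statistics on default
  synthetic surveys hover near zero. A green synthetic-pipeline test
  establishes computational correctness and normalization invariants, not
  realistic inter-item structure. Correlated generation would need a copula
  or factor model and is out of scope.

A single seed determines everything; independent substreams are derived via
`numpy.random.SeedSequence.spawn`, so parameter defaults do not shift when
sample sizes change.

## Numerical conventions

Weights are computed in double precision and validated to sum to 1 within
1e-9 at every stage; percent renderings use 2 decimals. Sample (n−1)
variances throughout. Bartlett's χ² uses the −(n − 1 − (2k+5)/6)·ln det R
statistic with df = k(k−1)/2. Singular correlation matrices, constant
score vectors, all-missing attributes, and empty cohorts raise typed errors
(`SchemaError`, `ValidationError`, `ConfigError`) rather than propagating
NaNs.

## Known limitations

- The published per-cohort weight tables are reproduced from the printed
  dimension-level values; sub-attribute AHP/EWM layers for each cohort were
  only partially printed and are not asserted.
- Exact per-cohort sample sizes were never printed; the printed population
  coefficients (0.1285, 0.4269, 0.4446) are shipped as constants, and
  share-derived sizes reproduce them only to ±0.001.
- The existing industry scale is modeled as one overall score per assessor;
  its internal descriptor content is not specified anywhere.
- Demographic effects on preference (education, spending willingness) are
  out of scope; demographic columns are carried through as labels only.
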