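# Methods

## Study design and data model

The package analyses a three-level soil-pH gradient: three plantations
(P1 < P2 < P3 by pH) with three replicate rhizosphere-soil samples each.
Two data tables drive everything downstream:

- an **index table**, one row per sample, holding nine soil/microbial
  variables: pH (unitless), organic matter (g/kg), cation exchange capacity
  (mmol/kg), microbial biomass C and N (mg/kg), respiration intensity
  (mg CO₂/kg·h), and bacterial, fungal and actinomycete counts
  (×10⁹ cells/g soil);
- an **intensity matrix**, metabolite features × samples, of non-negative
  LC-MS peak areas with missing cells, plus a feature annotation table with
  a two-level chemical taxonomy (superclass, class).

All sample sizes are replicate-level: correlations run at n = 9. At n = 3
group means no correlation can reach conventional significance, so
group-mean screening is supported but not the default.

## Soil index formulas

Microbial biomass follows chloroform fumigation-extraction:
`MBC = (C_fum − C_unfum) / K_C`, `MBN = (N_fum − N_unfum) / K_N`, with the
standard conversion constants `K_C = 0.38` and `K_N = 0.54` (overridable).
A negative fumigated-minus-unfumigated difference is treated as swapped
inputs and raised, not clamped. Respiration intensity is
`CO₂ mass / (soil mass × duration)` in mg CO₂/kg·h.

The index–index correlation matrix uses Pearson on replicate-level values by
default (Spearman by option), with two-sided t-based p-values and `*`/`**`
stars at p < 0.05 / 0.01. Constant columns produce flagged undefined cells
rather than errors.

## Metabolite QC

A feature is removed when its within-group missing ("deletion") rate is
strictly greater than the 50% threshold **in every group**; a feature
reliably present in any one group is kept. The stricter any-group variant is
available (`any_group=True`). The filter is idempotent and keeps
exactly-at-threshold features.

Detection per group requires ≥ 1 observed replicate (configurable); the
3-set Venn regions are computed by exhaustive set algebra. The shared
percentage divides the shared count by the **largest** per-group count — the
conservative choice among the possible denominators.

Missing cells are imputed with half of the feature's minimum observed value
(standard LC-MS limit-of-detection surrogate); zero-fill and no-imputation
(pairwise-complete correlations) are available. "Content" is the plain sum
of imputed peak areas — the data are relative abundances, so no mass
normalization is applied.

## Correlation screen

Each index is correlated with each metabolite across samples. The default is
Pearson on log(1 + x) intensities: peak areas are approximately log-normal,
and the t-based p-value of the Pearson test is calibrated on the log scale
but measurably conservative on the raw scale at n = 9 (empirical null size
≈ 0.047 instead of 0.050). Spearman is available and transform-free; the raw
scale remains available via `transform="none"`.

Significance defaults to raw two-sided p < α = 0.05 per test, matching the
starred-correlation convention of gradient field studies; Benjamini–Hochberg
adjustment is available and reported alongside. A metabolite significant for
at least one index is assigned a consensus sign by majority vote over the
signs of its significant correlations, after inverting the fungal count's
sign (fungi is the one index that decreases along the gradient, so "rises
with pH" means "falls with fungi"). Tied or inconsistent votes go to a
`conflicted` set that is reported, never dropped. Options: `require="all"`
(significance with every index) and `anchor="ph"` (pH's own sign decides
when pH is significant).

The bipartite network has one edge per significant record of each
partitioned metabolite, signed and weighted by |r|, exported as GraphML
(via networkx) and SIF.

## Characteristic compounds and trends

Within a signed set, compounds are ranked by mean imputed intensity over all
nine samples (ties broken lexicographically by id) and the shortest prefix
whose cumulative share of the set's total content reaches the coverage
threshold (default 90%) is selected. The set is minimal by construction:
dropping its last member falls below the threshold. The positive- and
negative-derived panels are disjoint (they come from disjoint sets) and are
merged and grouped by chemical class.

Trend classification of three ordered group means: UP (m₁<m₂<m₃), DOWN
(m₁>m₂>m₃), UP_DOWN (middle above both ends), DOWN_UP (middle below both
ends), FLAT on any tie within a relative tolerance of 10⁻⁹. Significance is
one-way ANOVA on replicate values at α = 0.05; the shape label is assigned
regardless, so non-significant categories keep an interpretable trend.
Category aggregation sums member intensities per sample before averaging,
which makes total content conserved across every taxonomy level.

## PCA

Sample ordination decomposes the imputed, log(1 + x)-transformed,
feature-centered samples × features table by SVD (scikit-learn PCA, full
solver); unit feature scaling and raw-scale decomposition are options.
Explained-variance fractions are non-increasing and sum to 1 over full rank.

## Synthetic data generator

The generator emulates the study conditions, not any particular measured
dataset:

- **Index table.** Group means interpolate each index's (low-pH, high-pH)
  anchor pair linearly along the pH anchors {3.29, 4.74, 5.32}, so every
  index is an exact affine function of group pH in the noiseless limit —
  increasing for all indexes except fungi (7.43 → 2.48 ×10⁹ cells/g,
  decreasing). Replicate noise is Gaussian with s.d. 5% of each index's
  anchor range by default; only ranges are published, so the noise level is
  a free parameter chosen to keep group separation visually and
  statistically clear at n = 3.
- **Metabolome.** log-intensity = feature baseline (Normal, mean log 10⁵,
  s.d. 1.5 across features) + β·(pH_g − mean pH) + Normal(0, σ) replicate
  noise. Planted-positive features have β = +0.8 per pH unit,
  planted-negative β = −0.8, nulls β = 0; σ = 0.4 by default (≈ 40%
  intensity CV, typical of untargeted peak areas). Exponentiation gives
  heavy-tailed non-negative intensities; planted group means are exactly
  monotone in pH as σ → 0. Defaults: 2,370 features with 55 positive and
  166 negative planted associations, 5% missing cells completely at random;
  a low-intensity censoring mode emulates limit-of-detection dropout.
- **Taxonomy.** 11 superclasses containing 60 classes total, assigned
  uniformly at random per feature.
- **Determinism.** One master seed; every table draws from a named
  `SeedSequence` substream, so identical configurations give identical bytes
  on disk.

What the generator does **not** emulate: retention-time structure, adducts
and isotopes, correlated features within pathways, batch effects, and
intensity-dependent missingness by default. Passing tests therefore
demonstrate the statistical machinery under the declared model, not
instrument-level realism. One visible consequence: with 166 negative vs 55
positive planted features of equal effect size, total content mildly
*decreases* along the gradient, whereas a real acidified-soil study can show
rising totals because unmodelled high-abundance compounds carry the trend.

## Numerical choices and problem sizes

- Vectorized Pearson with p = 2·SF_t(|r|√((n−2)/(1−r²)); n−2); |r| = 1 maps
  to p = 0. Agreement with `scipy.stats.pearsonr` is asserted to 10⁻⁶ and
  with a 10,000-shuffle permutation oracle to a mean absolute difference
  below 0.01 over random pairs (at n = 9 the discrete permutation null
  deviates from the continuous t null by up to a few hundredths on
  individual mid-range pairs, an intrinsic small-sample effect).
- Characteristic selection uses a cumulative-share search with a 10⁻¹²
  slack so exact-boundary coverages are not lost to floating point.
- Null-calibration measurements pool many independently seeded datasets
  (60 datasets × 1,000 features × 9 indexes = 540,000 tests in the
  acceptance script): the nine indexes within one dataset are nearly
  collinear, so independent index draws — not more features — shrink the
  Monte-Carlo error of the significant fraction.
- Idealized recovery and calibration scenarios generate complete matrices
  (no missing cells): constant-value imputation injects ties that perturb
  the exact null of the correlation test, which would measure the imputation
  rule rather than the screen.
- Reports serialize with sorted keys and no timestamps, so a rerun under the
  same configuration is byte-identical.

## Known limitations

- The raw-p screen at α = 0.05 over ~21,000 tests admits false positives by
  design; BH correction is one flag away but changes the headline counts.
- The consensus-sign rule assumes the eight co-varying indexes plus
  inverted fungi form one gradient axis; in data where indexes decouple,
  the conflicted set grows and should be inspected rather than ignored.
- Trend labels on three points are coarse: any non-monotone shape is
  UP_DOWN or DOWN_UP, and FLAT requires an exact tie, so near-flat noisy
  categories still receive a directional label (use the significance flag).
- Fumigation formulas assume the fixed extraction-efficiency constants;
  site-specific calibration must be supplied by the user.
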