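# Methods

This note records the models the package implements, the defaults it ships
with and why, and what its synthetic data can and cannot say about real
cohorts.

## Synthetic cohort model

Taxon counts follow a Dirichlet–multinomial (DM): for sample *j* in group
*g*, composition **p**ⱼ ~ Dirichlet(c·**μ**₉) and counts ~
Multinomial(Nⱼ, **p**ⱼ) with depth Nⱼ uniform on `depth_range`. The DM is
the standard overdispersed model for 16S count tables; it captures
between-infant compositional variation and depth-dependent counting noise,
which are the two properties the downstream tests are sensitive to.

Defaults, chosen once as study-style conditions and not revisited:

| parameter | default | rationale |
|---|---|---|
| cohort sizes | 23/60 and 70/27 | the two emulated cohorts' group sizes (83 and 97 infants) |
| `n_taxa` | 20 | typical count of prevalent genera in infant-gut tables after a 10% prevalence filter |
| baseline | focal 0.58, geometric tail (decay 0.9) | dominant *Bacteroides*-like genus; skewed genus-rank profile |
| `focal_effect` | 0.407 | realizes a 58% → 36% exposed-group contrast after renormalization |
| `concentration` c | 100 | overdispersion θ ≈ 0.01, inside the range of published DM fits to 16S stool data; makes the focal contrast detectable at n ≈ 80–100, as it was in the emulated study |
| `depth_range` | [1200, 60000] | uneven depths; the 1000-read filter is exercised but rarely triggered |
| `n_pathways` | 60, block of 10 | scaled-down pathway space (real predicted tables have hundreds) |

The exposed-group mean rescales the focal taxon by `focal_effect` and
renormalizes. With a `replacement_taxon_index`, the lost focal mass is
instead absorbed by one designated taxon — the replacement structure real
depletions show, where specific minor taxa take over the vacated niche
rather than the whole community scaling up. The focal taxon's realized
mean is identical in both modes, so `focal_effect` has one meaning. The
replacement mode is what makes the paired-cohort transfer experiment
meaningful: under pure renormalization every non-focal taxon shifts
concordantly in both cohorts, and taxon-level models transfer trivially.

Pathway tables are integer-rounded linear mixtures of taxon counts through
a non-negative genome-content matrix (copy number per unit taxon
abundance); the stratified decomposition keeps the unrounded per-taxon
terms. Real genome-content prediction additionally applies pathway
inference and per-genome normalization — a documented simplification. Block
pathways carry copy number 5 on the focal taxon against a weak 0.1–0.5
background, so their abundances track the focal taxon.

All draws derive from one cohort seed through deterministic
`SeedSequence` stream splits; identical configs give bit-identical tables.

The generator does **not** emulate: sequencing error, chimeras or taxonomy
misclassification; phylogenetic correlation among taxa; longitudinal
structure; batch effects between cohorts beyond the engineered focal/
replacement differences. Passing tests therefore show the *procedures*
behave correctly under a faithful compositional noise model, not that real
cohorts would yield the same effect sizes — real-data PERMANOVA R² (~0.02)
and AUCs (~0.7) are far smaller than on these single-signal simulations.
Per-group dispersions of the original cohorts are unpublished; c = 100 is a
field-plausible default, not an estimate of those data.

## Filtering and diversity

Presence for prevalence filtering is a strictly positive count; thresholds
use ≥. The joint (cross-cohort) filter keeps a feature only if it meets the
threshold in every table; study-style defaults are 0.30 for taxa and 0.50
for pathways. Rarefaction is a single without-replacement draw per seed
(multivariate hypergeometric), to the conventional depths of 1000 (taxa)
and 10000 (pathways); samples below depth are dropped.

Shannon diversity uses base 2. PCoA eigendecomposes the Gower-centered
matrix −½·J D² J; axes with negative eigenvalues (non-Euclidean
Bray–Curtis input) are dropped from the coordinates, `proportion_explained`
is computed over the positive spectrum, and the negative eigenvalues are
reported for diagnostics. Group ellipses are 2σ contours from each group's
2×2 sample covariance (equivalently the Pearson structure scaled by the
per-axis SDs); a zero-variance axis or |r| = 1 flags the ellipse
degenerate.

PERMANOVA partitions tr(H G) with sequential (Type I) hat matrices, in the
term order given — the `adonis` default, verified against
`vegan::adonis2` to 5 decimal places on a fixed example. Permutations are
free (unrestricted) over samples; p = (1 + #{F* ≥ F}) / (1 + n_perm) with
n_perm = 999 by default, or exact enumeration of all n! orderings for
n ≤ 8. A vanishing residual (perfect separation) reports F = +∞ so the
permutation p-value remains well defined. Beta diversity defaults to
rarefied tables, with a switch (`beta_on_rarefied`).

## Differential abundance

ANCOM-style W: for feature *i*, the per-sample log-ratio
log((xᵢ+1)/(xⱼ+1)) is tested against every other feature *j* — a Welch
t-test, or the exposure coefficient of the additive linear model
ratio ~ exposure + covariate when adjusting. The m−1 p-values of feature
*i*'s family are BH-corrected; Wᵢ is the rejected fraction, significant at
W ≥ 0.7. A pseudocount of 1 replaces structural-zero modelling (documented
deviation from the full ANCOM2 machinery). The self-ratio is never
counted, so W is a multiple of 1/(m−1).

ALDEx-style test: per Monte-Carlo instance (default 128), each sample's
composition is drawn from Dirichlet(counts + 0.5), CLR-transformed and
Welch-tested per feature with BH across features; `expected_q` averages
the adjusted p over instances. The effect is the median over instances of
(median CLR difference between classes) / max(within-class SD), the SD
being this implementation's reading of "within-class dispersion"; its sign
is positive when the feature is more abundant in the exposed class, and
label swap flips it exactly.

## Machine learning

Nested CV: stratified outer folds (default 5), stratified inner folds
(default 3) built only from the outer-train split; grids are scored by mean
inner AUC only, the winner refit on the outer-train split and evaluated
once on the held-out fold; repeated (default 40) with fresh fold seeds.
Fold counts and the small default grids (trees ∈ {100, 300}, depth ∈
{None, 8}; AdaBoost learners ∈ {50, 200}, rate ∈ {0.1, 1.0}) are package
choices, config-exposed. AUC is the Mann–Whitney probability with ties at
½. AUC SDs are across repetitions of per-repetition means. Importances are
impurity-based, normalized to sum 1; per repetition and family the vector
is the mean over the outer-fold best models. Rank aggregation gives rank 1
to the largest importance with average-rank ties and sorts features by
ascending median over all families × repetitions.

Cross-study: features are harmonized by id intersection plus the joint
prevalence filter. Per outer iteration the three families' best models form
an unweighted soft-vote ensemble predicting a fresh stratified random
subsample (default 80%) of the other cohort; the overall transfer AUC pools
all predictions. Permutation importance shuffles one feature's values
across test samples (others fixed), n_shuffles ≥ 5 (default 10), with one
baseline per ensemble; mean and SD pool over shuffles × ensembles. The
pooled stratified AUC is computed within each stratum of the pooled
predictions; single-class strata are flagged, not computed.

## Problem sizes in tests and drivers

The test-suite and acceptance-script simulations use scaled-down settings —
single-point or two-point grids, 50–100 trees, 1–10 CV repetitions, 5–20
simulation seeds, 100–200 null replicates — sizes at which every property
they check is already stable. The 120-ranks-per-feature structure is
checked at the full default of 40 repetitions × 3 families. The analysis
drivers default to 10 repetitions and note where the library default is
larger.

## Known limitations

* No structural-zero handling or bias correction in the ANCOM-style test;
  heavily zero-inflated features lean on the pseudocount.
* Tree learners are feature-order sensitive on exact ties, so feature-order
  permutation invariance holds only approximately for model outputs.
* The exact inner test ANCOM2 uses under covariate adjustment in the
  emulated study is unspecified; the linear-model choice here is documented,
  not asserted identical.
* Ordering of the "found in more than one sample" pre-filter versus the 10%
  prevalence filter in the original QIIME workflow is unspecified; both are
  exposed as independent filters.
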