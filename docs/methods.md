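# Methods

`colonynet` reimplements, as a tested pipeline over synthetic data, an
analysis linking single-forager brain gene expression in ant colonies to
colony-level phenotypes: colony sensitivity of foraging activity to
humidity, and the mean forager-brain dopamine-to-serotonin ratio
(DA:5HT). The pipeline has six stages: data simulation, expression
preprocessing, expression–trait association, omnibus gene-set
enrichment, signed weighted coexpression network analysis, and
integration with per-gene evolutionary constraint (dN/dS).

## The synthetic study

The generator emulates a study of ~9 colonies × ~10 foragers, one brain
transcriptome per forager. On the log2 scale, expression of gene *g* in
sample *s* is

    x[g,s] = b_g + c[g, colony(s)] + λ_g f[m(g), s]
             + e_g z_t(colony(s)) + batch(s) + ε,   ε ~ N(0, σ_noise)

with gene baselines `b_g ~ N(5, 2)`, per-gene-per-colony shifts
`c ~ N(0, σ_colony)` (these create the colony-specific expression
signatures that PCA, LDA and the per-gene F statistics detect), one
latent factor per planted module with loadings `λ_g ~ N(1, 0.3)` scaled
by a module amplitude, direct trait effects `e_g` (±`trait_effect_size`)
on a sign-balanced subset of background genes, and additive batch
shifts. A module factor mixes a colony-level component (weight
`colony_loading_sd`) with sample-level noise; a trait-linked module's
factor instead has correlation `link_strength` with the standardized
colony trait. TPM is emitted by exponentiating and rescaling columns to
10⁶; Poisson counts with uniform gene lengths are available to exercise
the counts→TPM conversion. dN/dS is drawn per species around a shared
gene-level component `log(dN/dS) = log(μ₀) − β_c·z(centrality) −
β_t·z(|trait effect|) + noise`, so centrality and trait association are
planted as negative (constraint-increasing) effects.

Defaults (chosen once for the study conditions): 9 colonies × 10
foragers, trait ranges humidity ∈ (0.5, 3) fewer trips per % humidity
drop and DA:5HT ∈ (0.5, 2), `σ_colony = 0.3`, `σ_noise = 0.3`,
`trait_effect_size = 1.0` log2 units per trait SD, module link strength
0.8 where linked, dN/dS baseline 0.15 with dispersion 0.3 over 6
species. Within-colony variance components are not reported for the real
data, so these are set for recoverability at the stated link strengths,
not calibrated realism. All draws derive from
`default_rng([seed, stream_offset])` with one fixed offset per
operation, so identical config + seed reproduce bit-identical outputs
and partial reruns are stable.

What the generator does not emulate: read-level noise and mapping
artifacts, non-linear trait–expression relationships, correlated module
factors, GO-DAG structure (terms are flat sets), phylogenetic
non-independence across the dN/dS species columns beyond a shared gene
component, and any forager-level covariates (age, experience). Passing
recovery tests therefore show the estimators are consistent under the
assumed generative model, not that the model captures real brains.

## Preprocessing

Fixed stage order, each stamping provenance: counts→TPM (per sample,
`10⁶·(c/l)/Σ(c/l)`), gene filtering (drop zero-variance genes, median
TPM strictly below 0.5, or zero expression in strictly more than ⅓ of
samples — genes exactly at either boundary are kept), `log2(TPM + 1)`,
the iterative outlier loop, quantile normalization, then location-scale
batch adjustment. The outlier loop masks values more than 3 SD from
their gene's mean (over unmasked values), then removes samples whose
mean inter-sample Pearson correlation lies more than 2 SD from the
overall mean, repeating to a fixed point; masked cells are imputed by
the gene's unmasked mean before quantile normalization. The batch
adjuster regresses protected covariates (colony by default) out per
gene, standardizes residual location and scale within each batch to the
pooled residual scale, and restores the protected fit — a deliberate
simplification of empirical-Bayes batch correction that satisfies the
same contracts (batch means equalized; protected effects preserved,
recovered within 10% on planted fixtures).

On colony-structured data the sample criterion can cascade: a colony
whose samples correlate mainly with one another sits low in the mean
inter-sample correlation distribution and may be removed as a block,
shrinking the panel over several iterations. The study-scale run removes
39 of 90 samples this way — comparable attrition to the source study's
33 of 85 — and this range restriction is the main reason downstream
trait statistics vary across simulation seeds.

## Expression–trait association

Each gene's correlation with a colony trait is computed two ways: the
per-sample estimator (Pearson over samples with the colony trait value
replicated to every nestmate; N = samples) and the colony-mean estimator
(Pearson over colony mean expression; N = colonies). The two coincide
exactly under zero within-colony variance with balanced colonies, and
their genome-wide agreement is reported as Pearson r / R². The
per-sample estimator is the pipeline's summary coefficient. Colony
structure is quantified by sample PCA on gene-centered log expression,
LDA on the retained PCs (≤ colonies − 1 axes), a k-nearest-neighbor
sample graph on 1 − Pearson distance (k = 3, undirected, deduplicated)
whose nestmate-edge fraction gets a label-permutation p, and per-gene
one-way ANOVA F across colonies (+∞ sentinel when within-colony variance
is zero). Candidate gene lists are tested by a two-sided one-sample t
test of their members' summary coefficients against zero; missing
correlations (constant genes) propagate as missing and are excluded
pairwise.

## Omnibus enrichment

For a per-gene ranking, a one-sided Fisher's exact (hypergeometric
upper-tail) test is run at top-fractions 50%, 45%, …, 5% (ties at a cut
all included), and the per-threshold p-values are combined by Fisher's
method (X² = −2Σln p, df = 2×10) into an omnibus p per term; terms with
fewer than 10 annotated genes in the universe are dropped and
Benjamini–Hochberg is applied across terms. The nested thresholds make
the per-threshold p's positively dependent, so the chi-square reference
is anticonservative: measured null rejection at 0.05 is roughly 8–10%
rather than 5%. The package therefore also provides a clearly labeled
empirical alternative (`permutation_omnibus_p`, recomputing the combined
statistic under gene-score permutations) which is calibrated; the
chi-square version remains the default because it is the method the
analysis defines.

## Coexpression network

Signed adjacency `a_ij = ((1 + cor_ij)/2)^β` (zero diagonal), β chosen
as the smallest candidate whose signed scale-free fit R² reaches 0.8
(log10 p(k) on log10 k over 10 connectivity bins, R² negated for a
rising slope), topological overlap
`TO_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, and average
linkage on 1 − TO.

**Tree cut.** Modules are *persistent branches* of the dendrogram: an
internal node with at least `min_module_size` leaves whose parent merge
sits more than `split_gap` above its own merge height. A genuine module
finishes its internal merges low and then waits; branches carved from a
structureless region are absorbed almost immediately. When qualifying
branches nest, the finest wins (this is what splits large branches with
real internal structure); the root never qualifies, and a tree with no
qualifying branch yields no modules. `split_gap = 0.01` was set from a
null-versus-planted separation analysis: on pure-noise networks (1,000
i.i.d. genes, 40–90 samples) no minimum-size branch persists beyond
~0.001, while planted module branches persist 0.03–0.18 across seeds —
an order of magnitude of margin on both sides. Genes left unassigned by
the cut are offered to the module whose eigengene they correlate with
best (assignment accepted at kME ≥ 0.6), mirroring the assignment stage
of dynamic tree cutting.

**Eigengenes and kME.** A module eigengene is the first principal
component (unit-norm per-sample vector) of the gene-standardized module
submatrix, sign-oriented so the mean member kME is non-negative; kME is
a gene's Pearson correlation with the eigengene.

**Density filter.** Module density is the mean off-diagonal within-
module TO; its p-value is the fraction of `n_pseudo` same-size random
gene sets from the network with density *strictly greater* (no +1
correction, so p can be exactly 0). Modules with p > 0.01 are removed
along with unassigned genes and the network is rebuilt, iterating until
every module passes. Two termination details: (i) once all modules pass,
remaining unassigned genes are dropped and small straggler tails
(≤ max(5, 2%) of the network) are absorbed by best-kME assignment rather
than triggering another rebuild — re-deriving a network from module
genes alone would leave the pseudo-module null without a background to
sample, and in the single-module case degenerates to the module spanning
the whole network; (ii) the filtered gene set is a fixed point:
re-running the filter on it reproduces the same set and labels.
Module quality Z compares each module's density with label-permutation
densities, Z = (obs − mean)/SD over permutations (Z > 10 read as a
dense, distinct module); this is a single-statistic stand-in for
multi-statistic preservation summaries, keeping the same threshold
semantics.

**Module–trait analyses.** Eigengene–trait Pearson correlations (trait
replicated to samples), per-module regression of member |trait r| on
kME, eigengene ANOVA across colonies with pairwise Welch contrasts
(BH-corrected), and, when a dN/dS decile table is supplied, the
cross-module regression of mean trait correlation on mean decile.

## Evolutionary constraint

Per species, non-missing dN/dS values are recoded to deciles 1–10 by
rank: provisional position-based bins of near-equal size (within one of
n/10), with any tie group collapsed to its lowest provisional decile —
deterministic, monotone, and invariant under strictly monotone
transforms of the input. The cross-species per-gene mean decile is the
aggregate constraint measure. The constraint model is an identity-link
Gaussian GLM of the decile on |trait r| per trait, kME, median TPM and
expression SD (predictors standardized; near-collinearity rejected by
condition number); deciles are near-uniform, so the Gaussian likelihood
is serviceable, and a proportional-odds ordinal-logit alternative
(`family="ordinal"`) is provided for sensitivity analysis — on planted
fixtures the two agree in sign. Module-level tests: one-sample t of a
module's deciles against the genomic mean decile (the mean over all
decile-bearing genes, not a fixed 5.5, since ties and missingness shift
it; a zero-variance module returns t = 0 when its mean equals the
reference), a Welch two-sample t of in-module vs unassigned genes, and
per-species decile-on-kME slopes with a sign-consistency summary
(species with < 30 usable genes skipped).

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the largest
sizes that keep the full suite fast while leaving every statistical
check well-powered: shared fixtures of 600–2,000 genes × 90 samples;
module recovery on 1,200 genes (two 100-gene planted modules);
permutation nulls at 300–2,000 pseudo-modules; power checks at 15–20
replicates against ≥ 90% thresholds; calibration checks at 60–200
replicates with KS p > 0.01. Discrete test statistics (exact and
permutation p-values) are checked for calibration by one-sided KS
(super-uniformity) plus rejection-rate bounds, because their p-values
are stochastically larger than uniform by construction.

## Known limitations

- The tree cut resolves modules whose branch separation exceeds
  `split_gap`; a module whose variance is almost entirely colony-level
  can blur into the colony-correlation background after the outlier
  loop's attrition and mean-imputation, and may be lost (the study-scale
  demonstration retains the sample-level module but not the
  colony-dominated trait-linked one).
- The Fisher-combination omnibus p is anticonservative under the null
  (see above); treat marginal corrected p-values with care or use the
  permutation variant.
- The density-filter p with strict ">" and no +1 correction can be
  exactly 0; it is a Monte-Carlo estimate, not an exact bound.
- The batch adjuster does not shrink across genes; with very few
  samples per batch its per-gene scale estimates are noisy.
- An entire network that is one cohesive module is reported as no
  modules by the cut (the root is excluded by design).
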