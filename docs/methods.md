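# Methods

This note documents the models, parameter choices and numerical
conventions behind `myxopan`, and what the synthetic generators do and
do not emulate.

## Pan-genome tiering

Orthogroups are tiered by the fraction *f* of genomes carrying them,
with half-open intervals anchored at the conventional percentages:
hard core *f* ≥ 0.99, soft core 0.95 ≤ *f* < 0.99, shell
0.15 ≤ *f* < 0.95, cloud *f* < 0.15. Anchoring the boundaries this
way makes the hard/soft split meaningful at realistic collection
sizes: at *N* = 24, presence in 24/24 genomes is hard core and 23/24
(*f* ≈ 0.958) is the one attainable soft-core count. "Core" in all
summary ratios means hard + soft. The "average % of genes in the
core" divides the core total by the mean genome gene count rather than
averaging per-genome ratios; the two differ slightly and the former is
how published pan-genome tables compute the row. Orthogroups absent
from every genome are rejected at construction — an empty row is
evidence of an upstream filtering bug, not data.

## Rarefaction and openness

Rarefaction samples `permutations` random genome orderings (default
100, seeded; published studies rarely state their permutation count)
and records, per prefix length *n*, the pan size (union) and core size
(intersection) of the first *n* genomes. Both curves are summarized
by per-*n* medians, which is what rarefaction figures display; the
median curve, not the pooled points, is the fitting target. Fitting
pooled points is available implicitly by passing a single-permutation
result per ordering, but the median is the default and the documented
behavior.

The pan curve is fitted to Heaps' law P(n) = κ·n^γ by nonlinear least
squares on the original scale (`scipy.optimize.curve_fit`), seeded by
a log–log linear fit; the log–log fit itself is available as
`method="loglog"`. The original-scale fit is the default because the
extrapolations it feeds are on the original scale, so that is where
residuals should be minimized. A constant curve is degenerate and
returned as κ = the constant, γ = 0, flagged closed.

Extrapolations round to the nearest gene. The new-gene increment is
the finite difference P(n) − P(n−1), not the derivative κγn^(γ−1):
the finite difference is what "the n-th genome adds" means, and the
two differ by a few genes at large *n*. The novelty horizon (smallest
*n* whose increment falls below a threshold) is seeded by the closed
form κγn^(γ−1) = threshold and refined by a local scan of the finite
difference, which is exact and costs a handful of evaluations.

The core curve is regressed on 1/n by ordinary least squares using
*n* ≥ 2 only: core(1) = pan(1) is an artifact of the definitions and
would otherwise leverage the fit. A negative intercept is clamped to
zero and flagged.

## Species delimitation

Grouping is single linkage — connected components of the graph with
edges where the pairwise value passes the threshold. Published
delimitations of this kind are typically read off the matrix by eye
without naming an algorithm; single linkage is the weakest rule
consistent with "groups of genomes", and anything it gets wrong shows
up in the conflict report rather than being hidden. Conflicts cover
(a) pairs in the (92, 93)% ANI gap that the tier definitions leave
unnamed and (b) within-species pairs at or below 92%, which contradict
the transitive grouping. The package reports them; it does not
adjudicate.

Definite species are components at ≥95% ANI. Components linked by any
pair in the [93, 95)% band merge into one species whose member
components become subspecies; the species count is therefore reported
as a range (after merging, before merging). The genus check is global:
all pairs ≥ 75%. dDDH thresholds are strict (>70, >50, >30) per their
conventional phrasing. Note the tier correspondence is inverted
relative to naive reading: the *looser* dDDH cut-off (>30%) mirrors
the merged species tier and >50% mirrors the strict ≥95% ANI tier,
since lowering a cut-off can only merge groups.

## COG enrichment

Profiles are percentages over annotated genes only, with the
unannotated count reported separately; multi-letter assignments split
fractionally so profiles stay normalized and ratios comparable.
Enrichment is the descriptive fold/abundance filter
(|log₂ ratio| > 1, favored-set abundance > 2%), not a significance
test, and is labeled as such; no multiple-testing correction applies.
The abundance gate is applied to the set in which the category is
favored — its purpose is to stop negligible categories from being
called on large but meaningless folds. A category absent from one set
is reported as "absent", never as an infinite fold.

## Trees and congruence

K2P distances use pairwise deletion (sites where both sequences are
unambiguous), which maximizes usable sites; note MEGA's default
differs by setting. Pairs whose log argument is non-positive
(saturation) are reported as undefined rather than given a number.
Neighbor joining is the standard Q-criterion agglomeration with
deterministic lexicographic tie-breaking, so trees are reproducible
across platforms; negative branch lengths from non-additive input are
clamped to zero. On additive input the tree reproduces the input
distances exactly (property-tested against brute-force path lengths
and cross-checked against scikit-bio's NJ). Bootstrap support
resamples alignment columns; replicates with undefined distances are
dropped from the denominator.

The ANI-to-distance transform is linear, d = (100 − ANI)/100; the
"relative distance" used in published ANI trees is not given a formula
there, and the linear choice is documented and configurable.
Predation profiles use standardized Euclidean distance by default
(killing-zone diameters are continuous); binary complements use
Jaccard.

Tanglegram optimization is an alternating subtree-rotation hill climb
minimizing connector crossings (inversion count between leaf orders).
Entanglement normalizes the final crossing count by the maximum over
100 random leaf-order baselines; 0 means perfectly untangleable.
Because published congruence claims are qualitative, the package adds
two quantitative companions, labeled as extensions: normalized
Robinson–Foulds distance and a leaf-permutation null test whose
p-value is the fraction of label-shuffled trees achieving at most the
observed optimized crossing count (with the +1 correction).

## Synthetic generators

`simulate_pangenome` grows an open pan-genome: core genes present
everywhere; genome *i* contributes Poisson(κγ·i^(γ−1)) new accessory
genes — the derivative of the Heaps curve, so the expected pan
trajectory follows κ·n^γ up to constant adjustments — and re-samples
each previously seen accessory gene with probability
retention × (its frequency among earlier genomes). Defaults are a
24-genome collection with core_size = 2486 and κ = 8000, γ = 0.55,
matching the observed scale of a large open myxobacterial pan-genome.
Retention is the one free parameter; the default 0.6 was calibrated so
the realized gene-frequency spectrum matches the reported shape of
such collections (cloud ≈ 72–74% of the pan, >75% of accessory genes
in fewer than 4 of 24 genomes). At these defaults, rarefaction plus
Heaps fitting recovers γ to within ±0.05 and κ to within ±10% (200
replicates). The generator does not emulate genome-size variation,
paralog inflation, or lineage structure in gene sharing — accessory
genes spread frequency-proportionally, not phylogenetically — so
recovery tests show the estimator works under Heaps-law growth, not
that real collections follow it.

`simulate_identity_matrix` draws each pair's value uniformly from the
range its planted relationship dictates (genus/species/subspecies/
within), inset by 3·noise_sd, plus Gaussian noise truncated at ±3 sd,
so no draw can cross a tier boundary and the planted truth stays
unambiguous; range configurations that could overlap after noise are
rejected up front. The 24-genome preset plants nine species in two
genus-level groups with two subspecies pairs (11 groups at the ≥95%
tier). Real ANI matrices have correlated, distance-dependent values;
the generator's independence across pairs is a simplification that
single-linkage clustering does not see.

`simulate_annotations` draws per-gene COG letters from a base profile
for core genes and from the same profile with planted categories
multiplied by 2^fold (renormalized) for accessory genes. The
renormalization means a planted fold of *f* realizes slightly below
*f*; recovery tests compensate when they need an exact realized fold.

`simulate_predation` mixes a per-prey Brownian trait on the reference
tree (standardized across strains) with i.i.d. Gaussian noise at
weight `congruence`, then maps to diameters (base 10 mm, scale 4 mm,
clamped at 0). Euclidean distance on such profiles scales as the
square root of tree distance, which is monotone but not additive; on
well-resolved trees NJ still recovers the topology at congruence 1
with a few dozen prey, but trees with near-zero internal branches may
not be exactly recovered — a property of the distance, not a bug.

`simulate_contigs` partitions the genome into multinomial contig
lengths (each ≥ 1 bp), draws per-contig coverage uniformly, and
generates bases i.i.d. at the requested GC; headers carry the
SPAdes-style `_length_<L>_cov_<C>` tokens the coverage filter parses.

## Assembly statistics

L50 is the smallest number of largest contigs whose lengths sum to
*more than* half the assembly — strictly more, following the
definition's wording; with four equal contigs of 10, two reach exactly
half and L50 is 3. N50 is the length of the L50-th largest contig.
Ties in lengths are resolved by sorted order, which cannot change
either value. The coverage filter keeps contigs at exactly the
threshold ("less than 7-fold removed" means 7.0 survives).

## Problem sizes in the test suite

Recovery suites use the full generator defaults where the check is
about the defaults (24 genomes, 100 rarefaction permutations, 200
replicate datasets for the Heaps recovery; 100 seeds for delimitation
and enrichment recovery) and smaller instances (4–16 genomes, 10–50
permutations) where the check is structural, e.g. the exhaustive
4-genome rarefaction oracle enumerates all 24 orderings exactly. The
enrichment recovery plants its signal on a 4,195-gene core — the scale
of a within-group core — because the 2.4-fold/6%-abundance
configuration sits only 0.26 log₂ units above the calling threshold
and smaller cores leave that margin inside sampling noise.
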