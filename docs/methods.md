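# Methods

This note records the models and conventions soilnet implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical corner cases. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Data model

The pipeline's central object is a validated samples × OTUs integer count
matrix (`OtuTable`). Sample metadata (`EnvTable`) carries one categorical
group label plus numeric covariates; taxonomy (`TaxonomyMap`) maps each
OTU to a fixed six-rank lineage with explicit `unclassified` for missing
ranks. Readers accept TSV and BIOM v1 JSON; orientation (samples-as-rows
vs taxa-as-rows) is auto-detected from overlap with known sample ids, or
from the shape heuristic that taxa outnumber samples, and can always be
forced. All randomised stages draw from substreams derived from one run
seed and the stage name, so a run is bit-reproducible and stages are
mutually independent.

## Diversity

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric draw) to ⌊f × min depth⌋, f = 0.9 by default; OTU columns
that become all-zero are kept and flagged so downstream joins stay
aligned. Estimators follow the mothur-style conventions:

- Shannon in nats over nonzero proportions.
- Simpson is reported under an explicit convention tag. The dominance
  form Σpᵢ² is the default; the complement 1 − Σpᵢ² is available. Both
  usages circulate in the amplicon literature and published tables are
  often ambiguous about which was used, so the output says which one it is.
- Chao1 is always the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)), which
  is defined when F₂ = 0. A consequence worth knowing: a single singleton
  adds nothing (equality with Sobs at F₁ ∈ {0, 1}; the estimator exceeds
  Sobs only from F₁ ≥ 2).
- ACE uses the rare-abundance cutoff 10. ACE is undefined when every rare
  taxon is a singleton; that case is reported as NaN, consistent with the
  general rule that undefined indices are flagged NA, never coerced to 0
  (the same holds for an all-zero sample across all indices).

Presence for the shared/unique OTU partition is evaluated after
rarefaction (an OTU is present in a group iff nonzero in ≥ 1 of its
samples); the pre-rarefaction variant is a flag away since the order of
operations differs between published workflows.

Group comparisons are one-way ANOVA + Tukey HSD per variable. The compact
letter display is derived deterministically from the pairwise
significance matrix: letters are the maximal cliques of the
"not-significantly-different" graph, ordered so that `a` marks the clique
containing the highest group mean. Two groups share a letter iff their
difference is not significant at the chosen α. Variables with zero
within-group variance everywhere are flagged degenerate and lettered from
exact equality of means.

## Ordination and association

Bray–Curtis, PCoA (via classical eigendecomposition of the
Gower-centred −d²/2 matrix; negative-eigenvalue mass is reported) and
PERMANOVA operate on the rarefied table. PERMANOVA uses the standard
distance-based decomposition — SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within from
within-group pairs — and free, seeded label permutation with
p = (#{F* ≥ F} + 1)/(n_perm + 1). No strata are supported. With small
groups the attainable p floor is set by the permutation group (for two
groups of 3, exhaustively 1/10), not by 1/(n_perm + 1).

RDA Hellinger-transforms the community by default (square root of
relative abundance), since a linear method on raw abundances gives
spurious weight to dominant taxa; the raw option is retained. Covariates
are standardised, collinearity is detected by a QR diagonal test and the
offending column is named. Constrained axes are the principal axes of the
fitted values of the multivariate least-squares fit; the proportion per
axis is its eigenvalue over the total (transformed, centred) community
sum of squares, so constrained + unconstrained ≤ 1 by construction and
adding covariates never decreases the constrained proportion.

The taxa × environment correlation screen emits r, raw p and BH-adjusted
p for every cell. BH is OFF by default for the per-cell significance
stars (mirroring the per-cell convention of published heatmaps) but both
p columns are always present, so the corrected decision is one column
away.

## Co-occurrence networks

Networks are built strictly per group from that group's samples. Defaults
(all exposed in `RunConfig` and stamped into every output): Spearman on
relative abundances, |r| ≥ 0.7, BH-adjusted p ≤ 0.05 across the pair
matrix, dominance filter at 0.01 % mean relative abundance and ≥ 1/3
prevalence, and a hard floor of 5 samples per group — correlation
estimates below that are not meaningful. These are field-standard
settings; provenance, not authority, is the reproducibility mechanism.

A practical consequence users should expect: with ~10²–10³ dominant OTUs
the BH correction runs over 10⁴–10⁵ tests, and at n = 10 samples the
smallest attainable two-sided p (t approximation) is ~10⁻⁵, so networks
built from 10 replicates are very sparse. Meaningful network inference
under these defaults needs roughly n ≥ 30; the demonstration cohort in
`scripts/acceptance.py` uses 30 samples per group for exactly this
reason, and the planted-module recovery condition uses n = 50.

Topology, modularity and roles are computed on the unweighted graph (the
correlation sign is kept as an edge attribute): density 2E/(N(N−1)), mean
degree 2E/N, mean local clustering with degree < 2 nodes contributing 0,
characteristic path length over the largest connected component.
Modules come from greedy agglomerative (CNM) modularity maximisation,
which is deterministic for a given graph; module ids are assigned by
decreasing community size with lexicographic tie-break. Note that
detected-partition Q on a null (Erdős–Rényi) graph is not 0 but typically
0.15–0.25 — greedy optimisers always find some structure — whereas the Q
of a planted/true partition on such a graph is ~0.

Zi–Pi: Zi is the within-module degree z-score (Zi = 0 when the module's
degree sd is 0), Pi = 1 − Σₘ (kᵢₘ/kᵢ)². Role cutoffs are the
Guimerà–Amaral conventions Zi = 2.5 and Pi = 0.62. Isolated nodes have
undefined Pi and are flagged peripheral.

## Stability metrics

Natural connectivity λ̄ = ln((1/N) Σ exp λⱼ) is evaluated with a
log-sum-exp so large dense graphs cannot overflow, and on the largest
connected component by default because the spectrum of a disconnected
graph mixes component contributions (a full-graph flag exists). λ̄ ≥ 0
with equality iff edgeless, and it is monotone under edge addition.

Robustness removes ⌈0.10 N⌉ uniformly chosen nodes per replicate (100
replicates by default, seeded) and reports the mean ± sd of the retained
fraction λ̄_after/λ̄_before. The retained-fraction reading was chosen over
an absolute difference or an area-under-curve because it is scale-free
across networks of different size and density; it is reported per
replicate in the removal trace for audit. Because of the 1/N
renormalisation the retained fraction can slightly exceed 1 on unusual
graphs; the documented tolerance is ≤ 1.05. Beware that the retained
fraction is only weakly density-dependent on Erdős–Rényi-like graphs —
ordering two networks by robustness is meaningful only when the density
contrast is large.

Vulnerability is Vᵢ = (E − E₋ᵢ)/E with E the global efficiency
(unreachable pairs contribute 0; E₋ᵢ is computed on the N−1 node graph);
the network value is maxᵢ Vᵢ. Keystones are all nodes classified module
hub, connector or network hub; a keystone's impact is the relative λ̄
loss when it alone is removed, and redundancy = 1 − mean impact (an empty
keystone set reports redundancy 1 with a flag). Note that λ̄ weights
closed walks, so a dense clique member can out-impact a topological cut
vertex; the two notions of "important node" coincide only on hub-and-spoke
structures.

No single composite "stability" number is reported: modularity and
keystone redundancy are exposed separately rather than folded into an
undocumented index.

## Synthetic cohorts

The generator emulates a replicated multi-group amplicon survey through a
latent-Gaussian copula: per group, each sample's latent log-abundance
vector is the group's rank-abundance profile (lognormal, `evenness` = sd
of the log profile) plus correlated noise, pushed through a softmax and a
multinomial draw at a lognormal per-sample depth (mean 20 000, σ = 0.2 by
default). Depths are conserved exactly by construction. The copula was
chosen over per-taxon Dirichlet-multinomial because the analysis needs
controllable pairwise correlation structure.

Planted structure and the reasoning behind the defaults:

- **Correlation blocks** (default four blocks of 10–12 taxa at ρ = 0.9,
  one with a 20 % anti-correlated sign mix) occupy consecutive abundance
  ranks starting at rank 10, not rank 0. Two reasons: ecologically,
  tight co-occurrence guilds are dominant-but-not-top specialists rather
  than the generalist head of the curve; numerically, blocks at the
  extreme head hold so much compositional mass that closure distorts the
  observed correlations well below their latent value. Block covariance
  is assembled explicitly and Cholesky-checked, so an infeasible
  (non-positive-definite) request — e.g. a strongly negative
  equicorrelation — fails with a message suggesting a smaller ρ.
- **Group composition effects** (`group_effect_sd` = 0.75, per-group
  taxon-level latent shifts) make the groups compositionally distinct, as
  treatment groups in real land-use surveys are; without them PERMANOVA
  would have nothing to detect.
- **Group-exclusive taxa**: groups share the dominant core (head +
  blocks) but draw their tail taxa from a common pool 1.4× the largest
  richness, so shared-core and unique-OTU Venn regions are non-trivial.
- **Covariate effects** add β·x (x standard normal per sample) to the
  latent abundance of an affected taxon set, overlapping the blocks as
  environmental filtering overlaps guild structure in real soils.
- The default cohort is 3 groups × 10 samples with richness 400/700/500
  — a deliberately modest, survey-sized fixture whose richness ordering
  echoes the forest < wetland < arable pattern of land-use networks.

What the generator does **not** emulate: sequencing error, chimeras,
phylogenetic signal, spatial autocorrelation, or overdispersion beyond
the lognormal-softmax compositional noise. Passing tests on these cohorts
show the pipeline recovers planted structure under idealised sampling;
they do not certify performance on real data with batch effects or
structured zeros. Compositional closure is real in the generator (it is a
composition), and its attenuating effect on pairwise correlations is the
main realistic difficulty the tests do exercise.

## Problem sizes and numerical choices

The test suite's simulation studies use sizes chosen to make each
statistical check decisive at desk scale: 1000 null simulations for the
PERMANOVA type-I check (n = 12, 199 permutations each), 1000 replicates
for the ANOVA power comparison against the noncentral-F closed form, 100
seeded replicates for richness-recovery and planted-partition checks, and
100 random graphs (N ≤ 50) for every brute-force oracle equivalence
(Floyd–Warshall paths, dense eigendecomposition, direct triangle
counting). The demonstration script's cohort is 3 × 30 samples.

Ties in Spearman are handled by average ranks; correlation p-values use
the two-sided t approximation with |r| = 1 mapped to p = 0. Constant
vectors yield NaN correlations and are excluded from edge formation.
Eigenvalues come from symmetric eigensolvers; shortest paths from
C-level BFS (scipy.sparse.csgraph). The compact-letter, module-id and
CNM tie-breaks are all deterministic, which is what makes the
byte-identical reproducibility guarantee testable.
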