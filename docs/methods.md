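# Methods

`connharm` studies how well matrix-level harmonization removes site effects
from multi-site structural connectomes while preserving biological
(age-related) variability. Everything operates on per-subject 84×84 symmetric
nonnegative connectivity matrices in two weightings — streamline count and
mean streamline length — plus a cohort manifest (subject, site, age, sex).

## The harmonization problem

Two cohorts acquired on different scanners/protocols differ systematically in
their connectivity matrices even when the cohorts are age- and sex-matched and
cognitively normal. Such site effects contaminate pooled analyses. A
harmonization method should (1) make the two sites' graph-measure
distributions statistically indistinguishable and (2) leave (ideally,
unmask) real biological structure such as age trends.

## Harmonization methods

**Mean shift.** Let S̄₁ and S̄₂ be the element-wise means of the two sites'
matrices. Shifting site 1 toward site 2 maps every site-1 matrix S to

    S'[i,j] = max(0, S[i,j] − S̄₁[i,j] + S̄₂[i,j]).

This aligns site means exactly wherever the clamp does not fire but does not
touch per-site variances. Both directions (shift site 1, shift site 2) are
exposed.

**ComBat.** The vectorized cohort stacks the (i, j), i ≥ j triangle of every
subject's matrix into a features-by-subjects table (3570 × 168 at full scale).
Each feature y_ijg follows a location/scale batch model

    y_ijg = α_g + X_j β_g + γ_ig + δ_ig ε_ijg ,   ε ~ N(0, σ_g²),

with covariates X = (age, sex) whose contribution is retained in the output.
Per-feature, per-site location γ̂ and scale δ̂² are shrunk across features by
parametric empirical Bayes — normal prior on γ (moments γ̄, τ² estimated from
the feature ensemble), inverse-gamma prior on δ² (method-of-moments a, b) —
via the standard fixed-point iteration, here run to an absolute tolerance of
1e-6 (cap 1000 iterations). Features with zero variance across the whole
cohort (edges absent in every subject) are masked out and passed through
untouched, so the matrix layout survives devectorization. Adjusted columns are
reassembled into symmetric matrices with negatives clamped to zero.

`combat_fit(eb=False)` disables shrinkage; that variant equalizes per-feature
site means exactly on its training data, a property the empirical-Bayes
variant only approximates (shrinkage deliberately leaves a small residual).
The EB variant is the default, matching standard practice. The implementation
is cross-checked in the test suite against the Bioconductor reference
(`sva::ComBat`) to 1e-3.

**GAN input normalizations.** An image-translation network expects inputs in
[−1, 1]. Counts are mapped log-linearly, lengths linearly, both anchored at
the global maximum entry M* over all matrices of both sites:

    counts:  M' = ln(M) / (0.5 ln M*) − 1        lengths: M' = M / (0.5 M*) − 1

Zero counts map to −1 (the floor) to preserve sparsity, and the inverse maps
−1 back to 0. A count of exactly 1 also lands on −1 (ln 1 = 0), so 0 and 1
collide: the inverse returns 0. Counts must be 0 or ≥ 1 — values in (0, 1)
would fall below −1 and are rejected. Only these deterministic pre/post
transforms are implemented; the adversarial network itself is out of scope and
can be plugged in between them.

## Graph measures

All measures zero the matrix diagonal first (self-connections are
vectorization artifacts, not edges) and are "streamline-count invariant":
rescaling a count matrix by any positive constant changes nothing.

* **Modularity Q** (on raw counts): Q = Σ_c (e_cc − a_c²) for the partition
  found by Newman leading-eigenvector bisection with Kernighan–Lin style
  fine-tuning, recursing until no split increases Q. The solver is fully
  deterministic (dense symmetric eigendecomposition, node-index tie-breaks,
  gains measured in per-total-weight units with a 1e-10 tolerance), which a
  stochastic Louvain-type solver could not guarantee. On all tested small
  graphs the partition's Q is verified against brute-force enumeration of
  every partition.
* **Global efficiency E** (on per-subject max-normalized counts): connection
  lengths are 1/weight, d_ij the weighted shortest-path length, and
  E = mean over ordered pairs of 1/d_ij with 1/∞ = 0. A complete unit-weight
  graph scores exactly 1.
* **Average betweenness centrality** (on mean-length matrices, entries used
  directly as lengths): unnormalized Brandes betweenness counting ordered
  (s, t) pairs with fractional credit on ties, averaged over nodes. A star
  center on n nodes scores (n−1)(n−2).

Whether counts should be normalized per subject or over the pooled cohort for
efficiency is not pinned down by the study design this mirrors; per-subject
normalization was chosen (each subject's strongest connection defines their
scale), and only between-site comparisons are interpreted.

## Evaluation framework

Per method and measure: pooled two-site coefficient of variation
(sample SD / mean); two-sided Mann-Whitney U with midrank tie handling,
normal approximation and continuity correction, U reported for site 1
(not min(U₁, U₂)); Pearson r between age and measure with p from the exact
t reference (df = n − 2) plus the OLS slope/intercept. Significance is
starred at 0.05 / 0.005 / 0.001 with no multiple-testing correction — a
deliberate convention, noted as a statistical limitation. p > 0.05 on the U test counts as successful
site-effect removal; p < 0.05 on the age correlation counts as preserved
biological variability.

## The synthetic cohort generator

Real multi-site cohorts of this kind are not publicly deposited, so the
package ships a generator whose defaults *are* the study conditions: two
cohorts of 84 subjects (50% female, ages truncated-normal 72.4 ± 6.0 on
60–89), 84-node matrices with 6 modules nested in two 42-node hemispheres.

Structure shared by all subjects of a cohort: a block-structured edge skeleton
(within-module density 0.95, between-module 0.55, inter-hemispheric 0.08) with
lognormal base weights (σ = 1.75, tail truncated at +2σ). Two stabilizers keep
the cohort-level graph statistics reproducible across seeds:

* block totals are standardized to fixed fractions of the within-module total
  (between 0.11, inter-hemispheric 0.145), pinning the weight balance that
  determines modularity;
* one hub edge per module is set to 30× the mean within-module weight, fixing
  the maximum entry that anchors max-normalized efficiency.

Per-subject variation: multiplicative lognormal edge noise (CV 0.30, tail
truncated at 2.5σ), one lognormal "integration" factor per subject on all
between-module edges (CV 0.06), and a linear age effect around the cohort mean
age — between-module/inter-hemispheric counts shrink by 0.65%/year while hub
edges grow by 0.8%/year. Older subjects thus have more modular, less
integrated networks: age–modularity correlates positively and age–efficiency
negatively, the direction reported for normal ageing. Counts are rounded to
integers; lengths are Gaussian around 55 mm (SD 10) plus 55 mm for
inter-hemispheric edges, with 5% CV noise.

Site effect (all on site 2's counts unless noted): inter-hemispheric counts
scaled by 0.33 (fewer crossing streamlines), per-edge additive offsets
N(0, 2) drawn once and shared by all site-2 subjects, and site-1
inter-hemispheric lengths exceeding site-2's by 14 mm. A *global*
multiplicative factor would be invisible to the two scale-invariant count
measures, so the factor acts on the inter-hemispheric block — the site
difference multi-site acquisitions actually localize there (anisotropic
voxels losing long crossing streamlines). Both site-effect components are
per-edge location/scale effects, i.e. exactly the model class ComBat assumes.

Block fractions, densities, σ, the hub ratio and the site factor were
calibrated once against anchor statistics representative of two age-matched
elderly cohorts scanned on different equipment (site-1 modularity 0.627,
site-2 0.692; site-1 efficiency 0.018, site-2 0.012) and frozen as the
packaged defaults above.

**What the generator does not emulate:** integer count marginals of real
tractography (heavy power-law tails beyond the truncated lognormal), distance
dependence of connection probability, subject-specific parcellation error,
sex effects (none are injected; sex is still carried as a covariate), and any
nonlinearity in the age trend. Passing tests therefore demonstrate that the
pipeline removes the *modeled* class of site effects while preserving linear
age structure — not that it handles every artifact of real dMRI data.

The greedy age/sex matching pairs each site-1 subject, in manifest order,
with the unused same-sex site-2 subject minimizing the absolute age
difference, accepting pairs within 1 year (earliest-order tie-break, making
the procedure deterministic).

## Numerical and design choices

* Matrices are validated symmetric to 1e-9 relative (then exactly
  symmetrized); larger asymmetry is an error, since structural connectomes
  are symmetric by construction.
* Matrix files print `%.17g`, so write/read round-trips are bit-exact
  (readers parse with exact rounding).
* Vectorization order is row-major over i = 0..n−1, j = 0..i; any fixed order
  works, this one is canonical.
* Sex is coded F→0, M→1 in covariates; sites are coded 1 and 2 in the batch
  vector.
* All randomness flows from a single integer seed through one generator;
  identical seed ⇒ bit-identical cohorts, measures and reports.
* Problem sizes in the test suite: the simulation study runs 20 seeds at the
  full default conditions (84 + 84 subjects, 84 nodes) evaluating modularity
  and efficiency; betweenness (the costliest measure) is exercised on the
  single-cohort pipeline runs and small oracle graphs. Brute-force oracles
  (all partitions; exhaustive path enumeration) run on ~200 random graphs per
  measure with n ≤ 7, where enumeration is exact.

## Known limitations

* Empirical-Bayes ComBat leaves small residual per-feature site-mean
  differences by design (shrinkage); exactness holds only with `eb=False`.
* The Mann-Whitney p uses the normal approximation (appropriate at n = 84+84;
  exact enumeration is intractable there and unnecessary).
* Mean shift can clamp at zero for sparse edges, slightly biasing shifted
  means upward at those entries; the effect is confined to entries where the
  shift exceeds a subject's weight.
* Harmonizing mean-length matrices is fragile in general (the betweenness
  measure is noisy and rank-based tests detect small distributional shifts);
  the package reports it rather than claiming to solve it.
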