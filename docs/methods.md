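# Methods

`phenodiv` analyses panels of crop accessions scored on *qualitative
phenotypic descriptors*: categorical traits such as lemma-palea colour or
culm angle, each taking one of a small fixed set of states. Treating each
trait as a single-observation, multi-allelic marker, the package carries the
classical population-genetic toolkit — diversity indices, genetic distances,
AMOVA, admixture-model clustering — over to morphological descriptor data,
and adds a fingerprinting layer ("phenoprints") for accession identification
and core-collection selection.

## Data model and encoding

A **trait catalogue** fixes the vocabulary: an ordered list of traits, each
with its ordered allowed states, every state carrying a global integer code
1..V. The bundled `odisha_asg_catalog` describes 24 descriptors with 70
states for an aromatic short-grain rice landrace collection; its code order
fixes the column order of everything downstream, so fingerprints are
bit-stable even if the trait list is re-sorted.

A panel is an N × T matrix of state labels with unique accession ids,
optional repeated display names, and an optional group label per accession
(district of collection). The one-hot **binary matrix** view has one column
per catalogue state; each fully scored trait contributes exactly one 1 per
row. A missing cell removes that accession from that trait's denominator
only; nothing is imputed except in PCA (column means, flagged on the
result).

## Diversity statistics

For a trait with state proportions `p_i` over n scored accessions:

* observed states `Na = #{p_i > 0}`;
* effective states `Ne = 1 / Σ p_i²`;
* gene diversity `h = 1 − Σ p_i²` (so `h = 1 − 1/Ne` identically);
* Shannon index `I = −Σ p_i ln p_i`, with `0·ln 0 := 0`.

The plug-in estimator of `h` is the default; the small-sample correction
`n/(n−1)·(1 − Σ p̂_i²)` is available via `unbiased=True`. The plug-in form
is the one whose 3-decimal values reproduce the published per-trait table
for this data type (e.g. a 125/1 split of 126 gives 1.016 / 0.016 / 0.046
for Ne / h / I), which is why it is the default despite "unbiased" being the
more common label in software manuals.

Percent polymorphism (%P) counts segregating variables within a subset; its
denominator defaults to the catalogue's V = 70 and is configurable, because
published tables for this kind of data are not always consistent about
whether the denominator is the catalogue count or the observed count.
Probability of identity multiplies the per-trait match probabilities
`Σ p_i²` across traits (monomorphic traits contribute a factor 1); this
assumes independence between traits, which one-hot descriptor data does not
guarantee — the reported value is an independence approximation, and its
reciprocal (the "differentiation capacity") should be read as an order of
magnitude. Printed-style outputs round half-up to 3 decimals; nothing is
rounded internally.

## Distances and trees

Between genotypes the default metric is the trait-mismatch proportion `m`
(share of co-scored traits with different states); `−ln(1 − m)` is offered
as a log-scale variant. For one-hot categorical profiles every Nei-type
identity is a monotone transform of `m`, so the choice does not affect
neighbour-joining topology. Between groups, Nei's standard identity
`I = J_xy / √(J_x J_y)` is computed from per-group state frequencies with
the J terms averaged across traits and `D = −ln I`; `unbiased=True` applies
the haploid small-sample correction `(n Σ p̂² − 1)/(n − 1)` per trait,
floored at 1e−12. Zero identity yields an infinite distance with a warning.

Neighbour joining is the classical Saitou–Nei agglomeration. Two numerical
conventions are pinned down so results are deterministic: Q-criterion ties
(within 1e−12) resolve to the pair whose sorted representative labels are
lexicographically smallest (an internal cluster is represented by its
smallest leaf label), and negative branch lengths are clamped to zero with
the deficit transferred to the sister branch, preserving the pair's summed
length. On additive matrices the output reproduces every input path length
to better than 1e−9 (verified against randomly generated trees, and against
an independent implementation for topology). Trees are unrooted; newick
serialization roots at the last internal node, and the two-cluster report
cuts the longest internal edge.

## AMOVA

One level of hierarchy (among vs within groups) on one-hot rows, using the
squared-Euclidean sum-of-squares decomposition and the standard moment
equations; Φ_ST = σ²_a/(σ²_a + σ²_w). Degrees of freedom are haploid:
(G−1, N−G, N−1), i.e. one observation per genotype. Significance is a group
label permutation test with the add-one correction
`p = (#{Φ* ≥ Φ} + 1)/(n_perm + 1)` (10 000 permutations by default, seed
mandatory in the CLI). A negative among-group component is floored at zero
for percentage reporting; the raw moment estimate is retained on the result
object. The per-variable one-way variance-component decomposition sums to
exactly the same Φ, which the test suite uses as a cross-check.

## Admixture model

The Bayesian clustering model: K clusters with per-trait state frequencies
P, each accession an ancestry vector q on the K-simplex, and each observed
state arising by picking a cluster of origin `z ~ Cat(q_i)` then a state
`~ Cat(p_{z,t})`. The likelihood is haploid-categorical — one observation
per trait — which matches descriptor data. Priors: Dirichlet(α) on q with α
*fixed* (default 1.0, not sampled — a deliberate simplification of the full
reference model) and Dirichlet(1) on each cluster's per-trait frequencies.

Inference is Gibbs sampling over (z, q, P), fully vectorized over accessions
and traits (~0.8 ms per sweep at N = 120, T = 24, K = 5). Defaults are
desk-scale: 2 000 burn-in + 5 000 kept sweeps and 4 runs per K; larger runs
are a flag away. Reported Q and P are posterior means over kept sweeps. The
per-run `ln P(data)` is the deviance-style estimator `mean(L) − var(L)/2`
over the kept sweeps, with L the observed-data mixture log-likelihood — an
approximation to the marginal likelihood, claimed only as a relative
model-choice score. K is then selected by the ΔK heuristic: the
second-order difference of mean ln P across K divided by its between-run
standard deviation, defined only for interior K with nonzero sd. Accessions
with maximum membership ≤ 0.80 are reported admixed. Cluster labels are
aligned across runs by Hungarian assignment on Q-column overlap. A
per-cluster fixation index is provided as the Φ_ST of the hard-assigned
cluster against the pooled remainder — a two-group proxy for the model-based
per-cluster F, documented as such.

Because α enters as a fixed smoothing constant, posterior memberships are
shrunk toward uniform when the number of traits is small; with 24 traits
this costs roughly 0.05–0.1 in membership sharpness. When the generating
concentration is known (simulation studies), fitting with that α is the
calibrated choice and recovers memberships with mean absolute error ≈ 0.02
on strongly diverged two-cluster panels; hard assignment accuracy is ≥ 95 %
either way.

## Ordination and trait ranking

PCA runs on the column-centered, unscaled one-hot matrix via SVD. The
one-hot columns of a trait sum to one, so the matrix is rank-deficient; all
columns are kept rather than dropping a reference state, because loadings
should not depend on an arbitrary baseline choice. Sign convention: the
largest-magnitude loading of each component is positive. Trait importance is
the eigenvalue-weighted sum of squared loadings of a trait's columns over
the retained components (default 3); summed over all traits and components
this equals total variance exactly, so the scores are a variance partition
by trait. Ties rank in catalogue order. This importance score is this
package's stand-in for stepwise "subset regression" style trait selection,
whose exact procedure is rarely reported in characterization studies.

## Phenoprints, duplicates, core subsets

A phenoprint is the ordered presence/absence vector over all V catalogue
states, rendered one row per accession as black (present) / grey (absent) /
white (trait unscored) bars in an SVG whose geometry and attribute order are
fixed — identical inputs give byte-identical files, so outputs double as
golden references. Duplicate detection groups bit-identical rows (missing
mask included).

Core-subset selection is set cover over the variables observed in the panel
(unobserved catalogue states cannot be covered): find few accessions whose
union reaches a coverage threshold (default 98 %). Panels of ≤ 16 accessions
are solved exactly by iterative-deepening branch and bound; larger panels
use greedy selection with ties to panel order, which carries the classical
(ln V + 1)-approximation guarantee. Plain greedy is measurably suboptimal on
small dense panels (often by one accession), which is why the exact solver
exists and is the default at small N; both paths are deterministic, and the
reported selection order is by sequential marginal gain so the coverage path
is strictly increasing. The subset's mean per-trait gene diversity is
reported alongside for comparison with the full panel.

## Synthetic panels

The generator draws each accession's state per trait independently from a
per-trait frequency vector. The bundled `odisha_like` specification encodes
every published marginal of the 126-genotype Odisha aromatic short-grain
rice collection — the full 8-state lemma-palea colour distribution
(50/14/11/10/10/2/2/1 %), the two-state splits (99/1 culm angle and
auricles, 91/9 awns and panicle curvature, 86/14 branch attitude, 63/37
secondary branching), the published modes of the remaining polymorphic
traits, and the 19-district sample sizes (Koraput 17 … Anugul 2). Where only
a mode was published, the residual mass is spread uniformly over the
remaining states — a stated convention, not data; it inflates multi-state
trait diversity somewhat relative to the published table (panel mean h ≈
0.32 vs 0.286 published), which is the expected signature of that
convention.

With `exact_counts=True` (default) per-trait counts are the
largest-remainder rounding of p·N (ties to earlier states), so
frequency-based statistics are exactly reproducible; state-to-accession
assignment is still shuffled with the seeded generator. Admixture structure
layers on top: subpopulation frequencies drawn from Dirichlet(base /
divergence) — larger `divergence` means more diverged, more nearly fixed
subpopulations — and ancestries from a symmetric Dirichlet(α), with K = 1
collapsing to the base panel exactly.

What the generator does **not** emulate: linkage or correlation between
traits, district-specific frequency shifts, missing data patterns, scoring
error, or temporal structure. Passing tests therefore demonstrate
correctness of the algorithms under independent-trait sampling at the
published marginals, not agreement with any particular real panel; published
figures that depend on the unpublished raw matrix (exact PCA percentages,
distance extremes, the 54.8/45.2 subpopulation split, the 92/8 AMOVA split,
the identity of the 16 core accessions) are not reproduction targets.

## Problem sizes and numerical choices

Simulation-based checks use N = 120–126 accessions (the scale of the
motivating collection), 10–40 for oracle comparisons against brute-force
enumeration, and N = 10 000 for law-of-large-numbers checks. The admixture
recovery study fits K ∈ 1..5 with 4 runs each at the default 2 000 + 5 000
sweeps. Frequency vectors must sum to 1 within 1e−9; distance and SS
identities are asserted at 1e−9; NJ tie detection uses 1e−12; permutation
p-values carry the add-one correction and so are never exactly zero. All
randomness flows from explicit integer seeds; the CLI requires a seed for
every stochastic subcommand and embeds it (never a timestamp) in output
headers, so end-to-end pipelines are byte-reproducible.
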