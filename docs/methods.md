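# Methods

## Input model

The unit of analysis is a gene-by-gene similarity matrix: Pearson
correlations between genetic-interaction profiles (vectors of epistasis
scores of each gene against a common panel of mutants). Entries lie in
[-1, 1]; positive values mean functional similarity, negative values
dissimilarity, zero no relation. The matrix is symmetric and its diagonal
is forced to zero on construction — all the measures below are about
distinct gene pairs, and a unit diagonal would corrupt degrees, traces of
adjacency powers, and the diagonal of the matrix exponential.

Thresholding at `|w_ij| >= t` produces a weighted signed undirected
network. Boundary semantics: weights strictly below the cutoff are
discarded, the boundary value itself is kept, and exact zeros are never
edges at any threshold. Two aligned unweighted views accompany the
retained weights: the signed adjacency A(S) with entries sign(w_ij) in
{-1, 0, +1} and the unsigned adjacency A(|S|) in {0, 1}. Default
thresholds are 0.05 for the census/indicator stage and 0.2 for the
walk-balance stage; both are per-stage configurable.

## Synthetic generator

The generator emulates the statistical shape of a profile-similarity
matrix, not the underlying colony-size assay. Genes are split into
`n_modules` near-equal contiguous modules; module m carries a latent
unit-variance signal g_m of length `profile_length`, and gene i's profile
is

    x_i = sqrt(rho_w) * g_m(i) + sqrt(1 - rho_w) * noise_sd * z_i,

with i.i.d. standard-normal z_i. At the default `noise_sd = 1` the
expected Pearson correlation of a same-module pair is exactly
`rho_w = within_module_corr`; `noise_sd = 0` collapses same-module
profiles onto the shared signal (correlation 1). Negative between-module
targets come from anti-correlated module signals,
Corr(g_a, g_b) = rho_b / rho_w, which makes the expected cross-module
profile correlation equal `rho_b = between_module_corr`. Positive
semidefiniteness of the module-signal correlation matrix bounds how
negative rho_b can be: rho_b / rho_w >= -1/(n_modules - 1); parameters
outside that region are rejected.

Default study conditions used by the acceptance script and headline tests:
300 genes, 5 modules, profiles of length 500, within-module correlation
0.5, between-module correlation -0.125 (the PSD boundary for 5 modules,
which also centers the mean matrix entry near zero and gives 4 structured
eigenvalues). These sizes keep a full analysis — about 4 million triangles
— under a minute per stage on one core while leaving the balance signature
orders of magnitude above null fluctuation.

What the generator does *not* emulate: heavy-tailed degree distributions,
experimental noise correlated across queries, module-size heterogeneity,
and the near-critical density of real interaction screens. Passing tests
on synthetic data therefore demonstrate correctness of the measures and
qualitative behavior under modular signed structure, not quantitative
agreement with any particular organism's network.

## Triad census and surprise

A triangle with 0, 1, 2, 3 negative edges is of type T3 [+ + +]
(strongly balanced), T2 [+ + -] (strongly unbalanced), T1 [- - +]
(weakly balanced), T0 [- - -] (weakly unbalanced). Balanced and
unbalanced totals follow from trace identities,

    b = [tr(A(|S|)^3) + tr(A(S)^3)] / 12,
    u = [tr(A(|S|)^3) - tr(A(S)^3)] / 12,

and per-type counts are obtained by explicit triangle enumeration
(edge-iterator with neighbor-set intersection); the two routes are
reconciled exactly on every call, so the census is self-checking. For the
null ensemble, where only counts are needed, per-type counts use the
equivalent trace route on the positive/negative adjacency split
(tr(P^3)/6, tr(P P N)/2, tr(P N N)/2, tr(N^3)/6), which avoids
re-enumerating triangles per realization.

The null model fixes the topology and uniformly permutes the multiset of
edge signs across edges (optionally whole signed weights, for weighted
comparisons), preserving the exact positive/negative sign fractions while
destroying their arrangement. The default ensemble size is M = 20 with a
logged seed: null fractions p0(T_i) are means over millions of triads per
realization, so their ensemble error is far below the effect sizes of
interest; M is configurable where tighter p0 error is wanted. The
surprise

    s(T_i) = (|T_i| - Delta * p0(T_i)) / sqrt(Delta * p0(T_i) (1 - p0(T_i)))

treats each triad as a Bernoulli draw under the null; types with
degenerate p0 (0 or 1) are flagged rather than scored, and the
size-corrected s/Delta is reported alongside for cross-network comparison.

## Energy landscape

Each triangle carries energy -(w_ij w_jk w_ki): negative for balanced
triads, positive for frustrated ones, magnitude set by the weight product.
The network energy E = -sum(products) / sum(|products|) is the
magnitude-normalized total, invariant under uniform positive rescaling of
the weights, bounded in [-1, +1], with E = -1 iff every triangle is
balanced. Per-type energy distributions, mean energies, and relative
frequencies are reported from the same enumerated triangle list.

## Mixing pattern

For every unordered pair of distinct triangles sharing exactly one edge
(two distinct triangles can share at most one edge, and sharing two nodes
implies sharing that edge), the pair is routed to a 4 x 4 block grid by
the two triad types and binned inside each block by the triads' positions
in their type's energy-sorted spectrum (equal-width rank bins, default
B = 50). Rank binning rather than raw-energy binning follows from sorting
the energy spectra; raw-value bins would be dominated by sparse tails.
Cells hold log10(1 + count).

Counting convention: pairs accumulate as *ordered* occurrences — each
unordered pair contributes once to block (a, b) and once to (b, a). This
keeps block (a, b) exactly the transpose of block (b, a), makes same-type
blocks symmetric, and makes the grid total equal twice the number of
unordered pairs (exposed as `total_pairs`). A per-edge outer-product
accumulation computes the grid without materializing pairs (quadratic in
triangles-per-edge, not in triangles); an explicit pair iterator is kept
as the independent slow route and the two are tested for exact equality.

## Walk balance

K = tr(exp(A(S))) / tr(exp(A(|S|))) sums closed walks of all lengths with
1/k! weight; K = 1 iff the network is balanced (equivalently: switching-
equivalent to an all-positive network), and random sign placement drives
K toward zero. U = (1 - K)/(1 + K) rescales the lack of balance to [0, 1].
Per-node K_i ratios the diagonal entries of the two exponentials; K_i = 1
(tolerance 1e-12 relative) flags nodes participating only in balanced
walks.

Numerics: both traces and both diagonals are computed from symmetric
eigendecompositions in log space (logsumexp over eigenvalues, with
eigenvector-squared weights for the diagonals). This is exact for
symmetric matrices and avoids the overflow of e^lambda (lambda beyond
~709) that direct exponentiation hits at the leading eigenvalues of dense
networks, while keeping ratios like K ~ 1e-13 representable. K and K_i
are clipped at 1 to absorb last-bit rounding; the mathematical bound
K <= 1 holds exactly.

## Graph indicators

Mean degree, <k^2>/<k>^2, assortativity, clustering C and path length L
are computed on the unsigned, unweighted thresholded graph (weighted
variants are out of scope); L averages over the largest connected
component to avoid infinite distances on disconnected graphs. Modularity
uses a greedy (CNM) modularity-maximizing partition of the absolute-weight
graph — the algorithm is deterministic, and Q is reported for qualitative
comparison only. The random reference for C/L normalization is a uniform
G(N, M) ensemble matched in density only (not degree sequence), averaged
over a seeded ensemble (default 5 realizations); the lattice reference is
the ring lattice with round(k) neighbors per node, forced even as a ring
lattice requires. SW = (C/C_rand)/(L/L_rand);
phi = 1 - sqrt((Delta_C^2 + Delta_L^2)/2) with the deviations clipped to
[0, 1].

The spectral check permutes the upper-triangle entries of the weighted
matrix (mirrored, preserving symmetry and the weight multiset) and counts
original eigenvalues outside the [min, max] envelope of the shuffled
ensemble — the fingerprint of structure beyond pairwise statistics.

## Degenerate inputs and tie-breaks

Thresholds of 1.0 (or matrices with no strong entries) produce empty
networks: the census reports zero triads, energy/surprise/mixing stages
are skipped with a logged notice, and the walk balance of an empty signed
network is K = 1 (only trivial walks). Types absent from a network yield
empty (all-zero) mixing blocks, not errors. Triangle enumeration orders
nodes i < j < k; energy-rank ties are broken by stable sort.

## Known limitations

- Null fractions p0 are ensemble means; surprise values inherit their
  sampling error, which is negligible at millions of triads but matters
  on toy networks (use larger M there).
- The density-only random reference makes SW and phi slightly different
  from degree-preserving alternatives; the choice follows the definition
  of the reference as sharing only node count and connectivity density.
- All-pairs shortest paths make the indicator stage the asymptotic
  bottleneck (O(N * M)); the balance measures themselves are eigvalsh- or
  trace-bound and comfortably handle thousands of nodes.
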