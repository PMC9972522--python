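# Methods

## Problem setting

Many questions in functional genomics reduce to comparing two networks
defined over the same (or overlapping) gene/protein labels: coexpression
networks of two disease subtypes, coexpression measured at the mRNA vs
the protein level, or protein–protein interaction (PPI) maps assayed in
different cell lines. `contrastnet` extracts **contrast subgraphs** —
node sets whose induced subgraph is dense in one network and sparse in
the other — and wraps them in the statistics that make the output
biologically interpretable.

## The contrast objective and the miner

Given networks A and B with induced edge-weight sums e_A(S), e_B(S),
the mined objective is the density of the **signed difference graph**
D = A − B:

    f(S) = (e_A(S) − e_B(S)) / |S| = e_D(S) / |S|.

This is the densest-subgraph objective on a graph whose weights may be
negative, which makes the problem NP-hard (maximum-flow exact solvers
apply only to non-negative weights). The miner is a generalised greedy
peeling: starting from all nodes, repeatedly remove the node v with the
minimum removal score

    C·deg⁺(v) + deg⁻(v),     C ∈ (0, ∞),

where deg⁺/deg⁻ are the sums of positive/negative incident weights in
the current graph, keeping every intermediate node set as a candidate,
and return the candidate with maximal f. For C = 1 the returned density
is guaranteed to be at least ρ*/2 − Δ/2, where ρ* is the true optimum
and Δ = max_v |deg⁻(v)|. Since a singleton has f = 0, the returned
objective is never negative.

A second, size-regularised score e_A(S) − e_B(S) − α·C(|S|,2) is exposed
for *evaluation* (`alpha_objective`); it is never optimised here. Exact
SDP-style solvers for that formulation are out of scope.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `c_grid` | {0.25, 0.5, 1, 2, 4} | C values swept per mining round; log-spaced around 1 to cover both deg⁺-dominated and deg⁻-dominated removal regimes. No canonical value exists; the grid is cheap because one peel is O(n²). |
| `k` | 2 | number of ranked contrast subgraphs per direction. |
| `min_objective` | 0 | early-stop threshold for top-k mining; f = 0 is attainable by any singleton, so only positive density carries signal. |
| `alpha` | 0 | size penalty of the evaluation-only regularised score. |

### Determinism and tie-breaking

Node labels are canonicalised by lexicographic sort at graph
construction, so results do not depend on input row order. Ties in the
removal score go to the lexicographically smallest label; ties among
equally dense candidates go to the smallest set (the latest candidate,
since candidates are nested); ties across the C grid go to the smaller
C, then the lexicographically smaller node tuple. The enumeration oracle
breaks ties toward smaller sets, then lexicographic order. With these
rules the entire mining stack is deterministic.

### Top-k extraction

Ranks are produced by iterating the sweep and, after each rank, setting
to zero all within-set edge weights of the *current* difference graph
(nodes are retained). Consequently the nonzero edge supports of
different ranks are pairwise disjoint, while node sets may overlap. The
two mining directions (dense-in-A and dense-in-B) are handled by
negating the signed graph and are treated independently: zeroing in one
direction does not alter the other's substrate.

### Complexity and storage

Both network flavours share one dense `float64` matrix contract.
Peeling uses incremental degree updates and a vectorised masked argmin:
O(n²) per C value. A complete signed graph with n = 2,000 (~2·10⁶
pairs) peels in well under a second per C on one CPU; the acceptance
script measures this directly. Dense storage is also used for sparse
PPI inputs — at the node counts PPI maps reach (~10⁴) this stays within
ordinary memory budgets and keeps a single code path; a dedicated sparse
backend is a possible future optimisation, not a correctness issue.

The exact oracle (`brute_force_densest`) enumerates all subsets with a
bitmask dynamic programme, e(S) = e(S∖{v}) + w(v, S∖{v}), and is guarded
to ≤ 20 nodes; it exists to validate the heuristic, never to replace it.

## Coexpression network construction

The build path follows the WGCNA convention for unsigned weighted
networks:

1. **Filter** — drop genes whose value is below `filter_threshold`
   (default 1, in FPKM/TPM-like units) in *more than* `filter_max_low`
   samples (default 50, an absolute count appropriate for cohorts of
   ~1,000 samples; a fractional variant `filter_max_frac` is available
   for smaller designs). The boundary is strict: low in exactly 50
   samples is retained.
2. **Log transform** — log2(x + 1). Base 2 with unit pseudocount; the
   base does not affect rank-based association and only rescales clr
   variances uniformly, so it matters only for reproducibility of
   intermediates.
3. **Association** — either Spearman correlation (average ranks for
   ties, pairwise-complete over missing values) or the ρ
   proportionality coefficient for compositional data:
   ρ(i,j) = 1 − var(a_i − a_j)/(var a_i + var a_j) = 2·cov(a_i,a_j)/(var
   a_i + var a_j), computed on centred-log-ratio (clr) vectors, i.e.
   per-sample log2(x + offset) centred by the per-sample mean over
   genes. The clr reference is the geometric mean of all retained genes;
   alternative references (alr) are not offered. Note a 2-gene panel is
   degenerate under clr (ρ ≡ −1): proportionality needs a realistic
   panel size.
4. **Soft threshold** — w = (0.5·(1 + ρ))^β with β = 12. ρ = 1 → 1,
   ρ = −1 → 0, ρ = 0 → 2⁻¹² ≈ 2.44·10⁻⁴. No hard cutoff: the network is
   complete, and negative associations are smoothly suppressed (the
   unsigned convention; a signed option is deliberately not provided).

Genes with more than 20% missing values are dropped with a warning
(motivated by proteomic data); zero-variance genes get association 0
with a warning rather than NaN propagation. Duplicate gene labels in
input files are collapsed to the row with the highest mean expression —
mean, rather than median or total, is an explicit choice and is logged.

## Downstream statistics

* **Degree-distribution test** — per-node weighted degrees of the
  contrast set, by default within the induced subgraph (the quantity the
  objective actually optimises; full-network degrees are one flag away),
  compared between the two networks with a two-sided Mann–Whitney U
  test. Small samples (both groups ≤ 20) use an exact p: scipy's exact
  recurrence when there are no ties, otherwise direct enumeration of
  group assignments conditional on the observed tie structure (bounded
  at 5·10⁵ arrangements, beyond which the tie- and continuity-corrected
  normal approximation is used, as for large samples).
* **Overlap statistics** — Jaccard index and a one-sided (enrichment)
  Fisher exact test with an explicit universe; the expected overlap
  |S₁||S₂|/N is reported alongside. One-sided matches the
  "observed vs expected by chance" reading; a two-sided option exists.
* **Enrichment** — hypergeometric upper-tail over-representation of a
  query set against a GMT collection, always conditioned on the declared
  universe, with Benjamini–Hochberg adjustment across all tested sets
  (the standard default for over-representation tools); zero-overlap
  sets report p = 1.
* **Upregulation calls** — log2 fold change on pseudocounted values
  (unit pseudocount), strict threshold |log2FC| > 1; equality is
  excluded by design.
* **mRNA–protein agreement** — per-gene Pearson correlation across
  shared samples, and Cohen's d (pooled, Bessel-corrected SD) between
  named gene groups; constant groups yield ±inf with a warning,
  zero-variance genes are excluded and counted.

## Synthetic data

The generators define the package's test conditions; they are not meant
to match the marginal statistics of any real cohort.

* `planted_contrast_pair`: n nodes, a module wired with probability
  `p_in_a` in A and `p_in_b` in B, all other pairs `p_background` in
  both (independent draws per network). Weighted mode draws Beta(6,2)
  magnitudes for module pairs and Beta(2,2) for background pairs — the
  same distribution in both networks, so contrast still comes from the
  wiring probabilities only. Default study condition: n = 200, module
  20, p_in_a = 0.9, p_in_b = p_background = 0.05.
* `planted_expression_pair`: on the log2 scale, module genes follow
  loading·latent + N(0, noise_sd²) with a standard-normal latent per
  sample, others pure noise; values are 2^(z+5), i.e. log-normal-like
  abundances centred near 32 so the default filter passes unperturbed
  genes and the preprocessing path is exercised. Default study
  condition: 200 genes, 200 samples per condition, one 25-gene module
  active in A with loading 0.8 and noise 0.5 (within-module correlation
  ≈ 0.64/0.89 ≈ 0.72).

All randomness flows through a single seeded PCG64
(`numpy.random.default_rng`) generator, making every fixture
reproducible bit-for-bit.

What passing these simulations shows — and what it does not: recovery of
a single strong planted block demonstrates that the miner and the
network build interlock correctly, not that real tumour cohorts (with
correlated backgrounds, batch structure, overlapping modules and
library-size effects) would be resolved equally cleanly. One behaviour
worth knowing: because mining maximises over exponentially many subsets,
the rank-1 objective of a pure-noise pair is *positive* (any all-positive
triangle in the ±noise difference graph already has density 1), so "no
signal" manifests as a *small* objective relative to planted signal, not
as an objective near zero, and the early-stop rule generally does not
fire on dense noise at these sizes. The test suite asserts the
comparative property.

## Numerical choices

* Weights are 64-bit floats; symmetry/diagonal checks use 1e-9 absolute
  tolerance; matrices are exactly symmetrised ((W + Wᵀ)/2) on ingest.
* The density of the returned candidate is recomputed from the node set
  rather than taken from the incremental running sum, eliminating
  accumulation drift on large graphs.
* TSV output uses 6 significant digits; JSON keeps full precision.
* Associations are clipped to [−1, 1] before soft thresholding; values
  outside that range beyond 1e-6 are an error.

## Known limitations

* No confidence measure accompanies a contrast subgraph; robustness must
  be established extrinsically (independent cohorts, alternative
  association measures), as the overlap statistics support.
* Dense storage caps practical graph sizes at roughly 3·10⁴ nodes on
  a 16 GiB machine.
* The ρ-proportionality implementation covers the clr-reference rho
  variant only.
* Identifier matching is exact and case-sensitive; ortholog/probe
  mapping belongs upstream.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` reruns the stack at: 200 random signed graphs
(n = 10) against the enumeration oracle; 50 planted-graph seeds
(n = 200, module 20); 25 end-to-end expression seeds (200 genes,
200 + 200 samples) for both association measures; the exhaustive
small-sample exact-test sweeps (Mann–Whitney n+m ≤ 12, Fisher N ≤ 30);
100 top-k disjointness instances; and one complete 2,000-node peel.
These sizes keep a full run around a quarter of a minute of compute
while leaving every quantity estimable with low variance.
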