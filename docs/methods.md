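# Methods

## The question the package answers

Disease genes do their damage through interactions: in an interactome —
an undirected graph whose nodes are gene symbols and whose edges are
documented functional links — where a gene *sits* may matter as much as
what it is. `netloci` quantifies "where it sits" with four classic
topological parameters and asks whether a designated gene set occupies
distinctive positions: it contrasts the set against equal-size random
gene sets and against its own first-order neighbors, and checks how
redundant the four parameters are with each other.

## The four parameters

For a node *v* in a simple undirected graph with *N* nodes:

- **degree** `k(v)` — number of incident edges.
- **average shortest path length** `aspl(v) = (1/|R|) Σ_{j∈R} d(v, j)`,
  where `d` is the hop-count (BFS) distance and `R` the set of nodes
  reachable from *v* (self-distance is 0 and is excluded). The
  network-level average is provided with two denominators: the
  conventional mean over the `N(N−1)/2` distinct pairs, and a variant
  that divides the same distance total by `N(N+1)/2`, i.e. counts
  self-pairs in the denominator. Published network-level figures are
  sometimes quoted with the second convention, and per-gene tables
  cannot adjudicate, so both are exposed (`normalization="conventional"`
  / `"inclusive"`).
- **clustering coefficient** `cc(v) = 2n / (k(k−1))`, with `n` the
  number of edges among *v*'s neighbors, counted as half the symmetric
  adjacency incidences. Nodes with `k < 2` have no neighbor pair; their
  `cc` is defined as 0 so the parameter is totally ordered over all
  genes.
- **betweenness centrality**
  `bc(v) = Σ_{{i,j}: i≠v≠j} σ_ij(v)/σ_ij`, where `σ_ij` counts shortest
  *i–j* paths and `σ_ij(v)` those passing through *v*. The sum runs over
  **unordered** pairs with endpoints excluded; unreachable pairs
  contribute 0. It is computed by Brandes' single-source dependency
  accumulation (each unordered pair is accumulated from both endpoints,
  hence the final halving) and reported normalized by `(N−1)(N−2)/2` by
  default, giving values in [0, 1]; the raw sum is available via
  `normalized=False`. The test suite verifies the Brandes result against
  a literal enumeration of all shortest paths.

Per-node ASPL is only well-defined when every other node is reachable,
so the pipeline restricts to the largest connected component by default
(ties in component size break toward the component containing the
lexicographically smallest symbol). A whole-graph mode is available in
which unreachable pairs are simply excluded from per-node averages.

All computations are deterministic: nodes are iterated in lexicographic
order and no global random state is used, so outputs are byte-stable.

## Statistical comparisons

**Random-set null.** For a disease set of size *s* (genes absent from
the network are skipped with a warning), `replicates` (default 10) gene
sets of size *s* are drawn uniformly without replacement from the
analyzed component minus the disease genes. Sets may overlap one another
across replicates but never the disease set. Per parameter the module
reports per-replicate means and sample standard deviations (ddof = 1),
the pooled null values, and a **two-sided Mann–Whitney U test** of
disease values against the pooled null, with the direction of the median
difference reported separately. Pooling gives the single headline
p-value; per-replicate p-values are also emitted for transparency. The
two-sided default is deliberately conservative given that directions are
reported alongside.

**Mann–Whitney implementation.** The rank-sum statistic is for the first
sample, with tied observations receiving average ranks. The exact
permutation null is used when both samples have ≤ 10 observations and no
ties; otherwise the Gaussian approximation with tie-corrected variance
and continuity correction. Both routes are delegated to
`scipy.stats.mannwhitneyu`; the exact route is validated in the tests
against a full enumeration of the `C(m+n, m)` label assignments, and the
normal route is checked to agree with the exact one within 0.02 at the
pipeline's 10-vs-100 shape.

**Neighbor comparison.** The disease set is contrasted with the union of
its first-order neighbors, seed genes excluded (including them would be
circular, since the contrast is *between* the set and its neighborhood).
The neighbor union is treated as a single comparison population.

**Grouped analysis.** Larger disease lists are shuffled (seeded) and
split into `group_count` groups whose sizes differ by at most one —
lists of 171 or 168 genes cannot be split into 10 truly equal groups —
and per-group parameter means are reported.

**Spearman correlations.** The all-against-all (6 distinct pairs)
Spearman coefficients over the four parameters are computed as the
Pearson product-moment correlation of tie-averaged ranks. This is the
module's central numerical decision: published parameter tables are
rounded and therefore full of ties (and degree is integer-valued), and
the popular tie-free shortcut `1 − 6Σd²/(n(n²−1))` is *wrong* under
ties — on the packaged ten-gene table it gives ≈ −0.982 for the
(ASPL, CC) pair where the correct tie-aware computation gives −0.994.
Pairs involving a parameter that is constant across the gene set have no
defined rank correlation and are flagged as undefined (NaN), never
silently zeroed. No p-values are attached to the coefficients.

## The synthetic interactome and its planted signature

Because the integrated interactome underlying the published per-gene
table is not redistributable, the package ships a generator that
reproduces the *statistical* setting rather than the data.

**Growth model.** Communities are grown by clique-seeded preferential
attachment with triadic closure: starting from a clique on `m =
edges_per_new_node` nodes, each new node makes `m` links; each link
follows preferential attachment (target chosen proportionally to current
degree), except that with probability `triangle_probability` it instead
attaches to a random neighbor of the previously chosen target, closing a
triangle. Edge count is exactly `C(m,2) + m(n−m)`. Plain preferential
attachment produces vanishing clustering as *n* grows, which is
unrealistic for interactomes; triadic closure (default 0.6) raises mean
local clustering several-fold while keeping the degree distribution
heavy-tailed, connectivity guaranteed, and the graph simple. Setting
`triangle_probability = 0` recovers plain preferential attachment.

**Planting.** `plant_disease_genes` grows `n_communities` (default 2)
independent communities of `n_nodes` (default 200) genes and adds
`planted_count` (default 22) connector genes, each linked to
`connector_links_per_community` (default 2) distinct low-degree members
(current degree ≤ m, widened to the lowest-degree nodes if the pool runs
short) of *every* community. Connectors are the only bridges, so they
acquire high betweenness and low ASPL; their neighbors lie in different
communities (and are mutually unconnected low-degree picks), so their
clustering is ≈ 0; and their degree — exactly
`n_communities × connector_links_per_community = 4` — sits at the null
median, so degree is *not* prominent. The low-degree attachment rule is
deliberate: it dissociates betweenness prominence from degree
prominence, the dissociation the analysis is designed to detect.

**Why 22 connectors.** The connector count controls two competing
designed properties. With few connectors (~10) the neighbor union is a
handful of bridge-adjacent genes whose profile inherits much of the
planted ASPL advantage; with many (≥ 30) the constant connector degree
becomes detectable by a rank test at sample size 30 even though its
median matches the null. Twenty-two connectors (≈ 5% of the 422-gene
network) keeps both: the planted signature is recovered with the correct
directions, degree stays non-significant in most seeds, and the neighbor
profile sits closer to the random null than to the planted set.

**Neighbor-closeness score.** "The neighbor profile resembles random
genes" is operationalized at the profile level: per parameter, the
absolute difference between the neighbor median and the null (resp.
planted) median is standardized by the null sample's SD and summed over
the four parameters; the neighbor set is called null-like when the
summed distance to the null is smaller. Parameter-by-parameter the
picture is more nuanced — in this construction neighbors genuinely
inherit part of the bridge-adjacency path-length advantage (their ASPL
median falls between null and planted, nearer the planted side), while
their degree, clustering and betweenness are null-like. The profile
score reflects the overall resemblance.

**What the generator does not emulate.** Real interactomes mix evidence
channels with heterogeneous noise, have hub degrees in the hundreds
(where disease-gene neighborhoods span thousands of genes), contain
multiple overlapping pathway communities rather than two clean blocks,
and their disease genes are not structurally identical clones. Passing
the synthetic checks therefore demonstrates that the *pipeline*
faithfully measures and detects the planted topological signature — not
that any particular disease list will show it in any particular network.

## Problem sizes and numerical choices

- Default synthetic analyses use 2 × 200-gene communities + 22
  connectors (422 nodes, ≈ 1240 edges); oracle-equivalence checks use
  ~100 random graphs of up to 30 nodes, where brute-force enumeration is
  exact and fast; the null-calibration study uses 2000 simulated null
  gene sets on one fixed synthetic network (betweenness computed once
  and reused).
- Exact betweenness/BFS tolerance against oracles: 1e−9 (pure float
  accumulation error).
- Spearman/rank oracles: 1e−12.
- Mann–Whitney p on fully tied (zero-variance) data is defined as 1.0.
- Random sampling uses `numpy.random.default_rng` seeded per call;
  node pools are sorted before sampling so draws are platform-stable.
- Metrics tables render floats with 6 significant digits; re-reading a
  written table therefore reproduces values to that precision.

## Known limitations

- Per-node betweenness normalization assumes the analyzed component;
  in whole-graph mode normalized values of small components are not
  comparable across components.
- The neighbor comparison treats the neighbor union as one population;
  it does not weight by multiplicity (a gene adjacent to several disease
  genes counts once).
- No multiple-testing correction across parameters or gene sets is
  applied; the four parameters are correlated and the reported p-values
  are per-parameter.
- Identifier handling is verbatim and case-sensitive; no symbol
  normalization or aliasing is attempted.
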