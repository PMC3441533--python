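# Methods

## Statistical model

All three edge types reduce to a one-sided Fisher's exact test on a 2×2
contingency table. The right tail is used throughout — an edge asserts a
significantly *high* count (overlapping genes, inter-set interactions,
jointly enriched lists), never a deficit — so the p-value is the upper
hypergeometric tail P(X ≥ a) with the table's margins. It equals 1 whenever
the observed count sits at the distribution's minimum, which covers every
degenerate case (zero margins, disjoint sets) without special handling.

Multiple testing is controlled with the Benjamini–Hochberg step-up
procedure and edges are drawn at q ≤ 0.05 (inclusive). The BH family for
the pair-level tests is always exactly the N(N−1)/2 unordered set pairs:
degenerate pairs (e.g. an empty residual after shared-gene removal) are
assigned p = 1 rather than dropped, so the family size — and therefore the
correction — is identical no matter how many pairs are testable. Ties in
p-values need no extra rule; the step-up minimum handles them.

### Backgrounds

- Co-membership: the collection's gene universe, defined as the union of
  all member sets. A collection read from GMT therefore carries its own
  background; no genome-wide universe is assumed.
- Linkage: the edge set of the reference molecular network *after* a
  single global restriction to the collection universe (performed once,
  before any pair is tested). An edge with at least one endpoint in a
  residual set counts toward that set's margin; the intra-set edge of a
  residual therefore inflates only its own margin, never the joint count.
- Co-enrichment: the set of all M gene lists for the pair-level test; the
  collection universe for the per-list enrichment tests, with each gene
  list intersected with the universe first. A user-supplied universe can
  be substituted where a genome-wide background is preferred.

### Per-list enrichment family (co-enrichment)

For a pair (A, B) the per-list BH family is the N original sets plus the
two residuals A′ and B′ (size N + 2), applied within each list. This is
the default reading of testing "all gene sets, including the pair whose
shared genes have been removed"; the plausible alternative — one joint
family pooling all lists — is implemented behind
`BuildConfig.enrichment_scope = "across_lists"`. Within-list correction
keeps each list's enrichment calls independent of how many lists the
compendium happens to contain, which is the behaviour a practitioner
comparing compendia of different sizes will usually want.

Per-list p-values of the N unmodified sets are computed once and cached;
each pair recomputes only its two residual columns and the (N+2)-sized BH
step, so the total cost is O(N·M) plus O(N²·M) cheap vector operations,
matching the quadratic-with-M structure of the construction. Pairs with
no shared genes reuse the cached columns directly.

## GO term preparation

Annotations are propagated up the DAG (true-path closure: each term's gene
set is the union of its own and all descendants' direct annotations)
before any cardinality is computed. Propagation makes cardinality
monotone along lineages, which the informative-term filter relies on.
`is_a` and `part_of` are both treated as lineage relations; other
relations and cross-namespace links are ignored, and obsolete terms are
skipped.

The filter first removes terms with propagated cardinality outside
[10, 200], then retains a surviving term T iff no surviving ancestor or
descendant is strictly closer to the target cardinality (default 50).
Closeness ties along a lineage are resolved toward the deeper term; with
this tie rule the retained terms provably form an antichain (for any
ancestor–descendant pair, one side always eliminates the other).
Comparators are the bounds survivors, not the full lineage — applying the
bounds first is one of two defensible orderings, chosen so that an
out-of-bounds giant ancestor can never veto an informative descendant.
Retained terms with identical membership are merged, the merged id being
the "+"-joined sorted constituent ids (the same convention used when
loading any collection). The filter is idempotent: an already-filtered
set of terms passes through unchanged.

## Clustering

Modules are found by recursive bisection with a density-improvement
acceptance rule: a split of a cluster with density d = 2E/[V(V−1)] is
accepted iff both children have at least 5 vertices and both child
densities strictly exceed d. The bisection itself is a deterministic
spectral (Fiedler-vector) cut: nodes sorted, dense symmetric
eigendecomposition of the Laplacian, partition by sign with a fixed sign
convention, median-split fallback for degenerate vectors. Multilevel
kernel k-means partitioners satisfy the same accept/reject contract but
produce different cuts; exact cut equivalence with any particular
partitioner is explicitly not promised — the enforced (and tested)
contract is the density rule, the ≥5-vertex floor, determinism, and the
recovery of bridged cliques. Connected components form the initial
frontier; a component smaller than twice the minimum size is never split.
Every accept/reject decision is logged with the densities that decided it.

## Randomization nulls

Network-level statistics are compared with a degree-preserving null:
each randomization applies double edge swaps — two edges drawn uniformly
from the current edge list, endpoints exchanged, proposals creating
self-loops or parallel edges rejected and redrawn — and "n swaps" counts
*accepted* swaps (1000 by default, configurable; the alternative
proposal-counting reading would leave sparse networks under-mixed). For a
pair of networks the null value is the absolute difference of the
statistic on the two randomized copies; with n random pairs the p-value
is the exceedance fraction, reported as "< 1/n" when no null value
reaches the observed difference. Degree sequences and edge counts of
every randomized network equal the originals by construction, and are
asserted per sample in the tests.

## Loci and chromosome statistics

Locus coordinates are 0-based half-open; contact bins are fixed-size
half-open intervals [k·size, (k+1)·size), 1 Mb by default. A locus pair's
contact sum adds each unordered bin pair once, consulting the symmetric
table under either key order. Pairs are grouped by (same vs different
chromosome) × (in-network vs not) and compared with two-sided
Wilcoxon–Mann–Whitney rank-sum tests, BH-corrected across the group
pairs. Chromosome tokens are parsed from cytogenetic names by stripping a
leading "chr" and taking the maximal prefix before the first arm letter
(p/q); X and Y are kept as letters.

## Context networks

A user gene list is intersected with the collection universe (an empty
intersection is an error pointing at identifier mismatch — with the
universe defined as the union of the sets, a list disjoint from every set
cannot be tested at all), each set Fisher-tested, and BH applied across
the collection. The context network contains exactly the precomputed
edges whose endpoints are both enriched — no on-the-fly edge computation
— with one typed edge per loaded network. A node is highlighted when its
unique user-input genes (input genes belonging to no other enriched set)
outnumber the input genes it shares with any single other enriched set;
"any other" is read as the maximum pairwise sharing among enriched sets,
computed on input genes only (summed sharing and full-membership variants
are the documented alternatives). Enriched sets with no edge are reported
separately as functionally disjoint.

## Synthetic data

The generators produce the exact statistical structure each builder
detects, with defaults describing a desk-scale experiment: a 2000-gene
pool, 20 sets of 25 genes (201 sets of 10 for family-size checks), a
background interaction probability of 0.002 per gene pair (≈ 4 edges per
gene, a realistic PPI density), and 200 lists of ≥ 50 genes with a 5%
baseline chance that any set is activated in a list. Planted signals:
an overlap pair shares an exact number of transplanted genes; a linkage
pair receives a fixed number of extra edges placed uniformly between the
residual members; a coactivation pair is jointly activated by an extra
Bernoulli draw (rate 0.3 in the recovery experiments) that overrides the
independent baseline draws when it fires. An activated set contributes
60% of its residual members to the list; remaining slots are filled
uniformly from the pool. Unplanted sets are sampled disjointly, so an
unplanted spec is an exact null for co-membership and an approximate null
for the other two builders.

What the generators deliberately do not emulate: correlated background
overlap between sets (real pathways share genes ubiquitously), scale-free
degree structure in the interaction network, expression-level noise, or
the cancer bias of real differential-expression compendia. Passing the
planted-recovery tests therefore demonstrates the statistical machinery —
correct tables, correct tails, correct family corrections — not
robustness to the confounders of real collections.

All sampling flows through one numpy PCG64 generator per operation,
seeded from the spec seed plus a per-operation stream index, so outputs
are bit-reproducible across platforms. Gene ids are zero-padded
("g000001") so lexicographic and numeric orders agree.

## Numerical choices

- Hypergeometric tails come from scipy's survival function; exactness is
  verified against direct tail summation for every table with total ≤ 60
  (agreement within 1e−12) and exact rational enumeration for totals ≤ 20.
- BH adjustment delegates to statsmodels and is verified against the
  textbook step-up loop; a vectorized row-wise variant used in the
  co-enrichment inner loop is checked against the scalar path.
- Edge pairs are stored in canonical lexicographic order and all outputs
  sorted, so written files are byte-stable. Archive TSVs print p-values
  with 17 significant digits; a write→read round trip preserves them to
  1e−12.
- Self-loops in molecule networks are dropped (with a logged count):
  the linkage tables assume a simple graph.
- Problem sizes in the test-suite and acceptance runs (201-set family
  checks, 20-seed null batteries, 100-sample swap checks, cliques of 6)
  were chosen as the smallest sizes at which each property is
  non-trivially exercised.

## Known limitations

- The informative-term filter does not correct for lineage breadth:
  sibling terms from a broad lineage can all survive.
- The linkage builder iterates pairs in Python; collections far beyond
  ~10³ sets would want a sparse-matrix edge-counting path.
- Archive files store only edges; isolated nodes must be re-attached from
  the collection when a full node set matters (the CLI does this).
- No gene identifier mapping is performed anywhere: collections, networks
  and lists must already share an identifier scheme.
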