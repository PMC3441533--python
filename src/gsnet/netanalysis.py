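"""Downstream analysis of gene set networks.

Covers module detection by recursive density-improving bisection, pairwise
network comparison with Fisher overlap significance and shared-gene
stratification, degree-preserving edge-swap null models for network-level
statistics, label-based edge statistics, pathway-participation Jaccard
similarity, chromosome-contact (Hi-C style) summation over fixed-size bins,
and same-chromosome edge enrichment for locus networks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.stats import mannwhitneyu

from .core import (
    ContingencyTable,
    GeneSetCollection,
    GeneSetNetwork,
    InvalidInputError,
    MoleculeNetwork,
    canonical_pair,
)
from .netbuild import bh_adjust, fisher_right_tail

logger = logging.getLogger("gsnet")


# ---------------------------------------------------------------------------
# Density and clustering
# ---------------------------------------------------------------------------

def network_density(network: GeneSetNetwork | nx.Graph | tuple[int, int]
                    ) -> float:
    """Graph density 2E / [V * (V - 1)].

    Accepts a gene set network, a networkx graph, or a (V, E) pair.
    """
    if isinstance(network, tuple):
        v, e = network
    elif isinstance(network, GeneSetNetwork):
        v, e = len(network.nodes), network.n_edges
    else:
        v, e = network.number_of_nodes(), network.number_of_edges()
    if v < 2:
        raise InvalidInputError("density needs at least 2 vertices")
    return 2.0 * e / (v * (v - 1))


@dataclass
class SplitRecord:
    parent: tuple[str, ...]
    children: tuple[tuple[str, ...], tuple[str, ...]] | None
    parent_density: float | None
    child_densities: tuple[float, float] | None
    accepted: bool
    reason: str


@dataclass
class Clustering:
    """A partition of a network's nodes into clusters.

    ``split_log`` records every bisection considered with the densities that
    decided acceptance.
    """

    clusters: list[frozenset[str]]
    split_log: list[SplitRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_of(self, node: str) -> frozenset[str]:
        for c in self.clusters:
            if node in c:
                return c
        raise KeyError(node)


def _fiedler_bisection(graph: nx.Graph) -> tuple[set[str], set[str]]:
    """Deterministic spectral bisection via the Fiedler vector.

    Nodes are sorted, the Laplacian's second-smallest eigenvector computed
    with a dense symmetric eigensolver, and the graph split by sign (zero
    entries join the non-negative side, with a fixed sign convention that the
    first node's entry is non-negative). A degenerate all-one-side vector
    falls back to a median split on the vector's order.
    """
    nodes = sorted(graph.nodes)
    lap = nx.laplacian_matrix(graph, nodelist=nodes).toarray().astype(float)
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1]
    # fixed sign convention: first nonzero entry non-negative
    for x in fiedler:
        if abs(x) > 1e-12:
            if x < 0:
                fiedler = -fiedler
            break
    left = {n for n, x in zip(nodes, fiedler) if x < -1e-12}
    right = set(nodes) - left
    if not left or not right:
        order = sorted(range(len(nodes)), key=lambda i: (fiedler[i], nodes[i]))
        half = len(nodes) // 2
        left = {nodes[i] for i in order[:half]}
        right = set(nodes) - left
    return left, right


def cluster_network(network: GeneSetNetwork | nx.Graph,
                    min_size: int = 5) -> Clustering:
    """Find clusters by recursive density-improving bisection.

    Each connected component is a starting cluster. A cluster is bisected
    (deterministic Fiedler split); the split is accepted iff both children
    have at least ``min_size`` vertices and both child densities strictly
    exceed the parent's density 2E/[V*(V-1)]. Accepted children are split
    recursively; every decision is logged.
    """
    g = network.to_networkx() if isinstance(network, GeneSetNetwork) else network
    if g.number_of_nodes() == 0:
        raise InvalidInputError("cannot cluster an empty network")
    log: list[SplitRecord] = []
    final: list[frozenset[str]] = []

    def consider(nodes: frozenset[str]) -> None:
        sub = g.subgraph(nodes)
        key = tuple(sorted(nodes))
        if len(nodes) < 2 * min_size:
            log.append(SplitRecord(parent=key, children=None,
                                   parent_density=None, child_densities=None,
                                   accepted=False,
                                   reason="too small to split"))
            final.append(nodes)
            return
        parent_d = network_density(sub)
        left, right = _fiedler_bisection(sub)
        kids = (tuple(sorted(left)), tuple(sorted(right)))
        if len(left) < min_size or len(right) < min_size:
            log.append(SplitRecord(parent=key, children=kids,
                                   parent_density=parent_d,
                                   child_densities=None, accepted=False,
                                   reason="child below min size"))
            final.append(nodes)
            return
        d_left = network_density(g.subgraph(left))
        d_right = network_density(g.subgraph(right))
        if d_left > parent_d and d_right > parent_d:
            log.append(SplitRecord(parent=key, children=kids,
                                   parent_density=parent_d,
                                   child_densities=(d_left, d_right),
                                   accepted=True, reason="density improved"))
            consider(frozenset(left))
            consider(frozenset(right))
        else:
            log.append(SplitRecord(parent=key, children=kids,
                                   parent_density=parent_d,
                                   child_densities=(d_left, d_right),
                                   accepted=False,
                                   reason="child density not above parent"))
            final.append(nodes)

    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        consider(frozenset(comp))
    final.sort(key=lambda c: sorted(c)[0])
    return Clustering(clusters=final, split_log=log)


def label_modules(clustering: Clustering, groups: Mapping[str, str],
                  alpha: float = 0.05) -> dict[frozenset[str], list[str]]:
    """Label clusters with significantly over-represented group names.

    Per (cluster, group), a 2x2 table over all clustered nodes
    (in-cluster x in-group) is tested with the right-tail Fisher test; BH is
    applied across all (cluster, group) tests and labels assigned where
    q <= alpha.
    """
    all_nodes = {n for c in clustering.clusters for n in c}
    labels = sorted(set(groups.values()))
    tests: list[tuple[frozenset[str], str]] = []
    pvals: list[float] = []
    for cluster in clustering.clusters:
        for lab in labels:
            in_group = {n for n in all_nodes if groups.get(n) == lab}
            a = len(cluster & in_group)
            tab = ContingencyTable(a=a, b=len(cluster) - a,
                                   c=len(in_group) - a,
                                   d=len(all_nodes) - len(cluster | in_group))
            tests.append((cluster, lab))
            pvals.append(fisher_right_tail(tab))
    out: dict[frozenset[str], list[str]] = {c: [] for c in clustering.clusters}
    if not tests:
        return out
    for (cluster, lab), q in zip(tests, bh_adjust(pvals)):
        if q <= alpha:
            out[cluster].append(lab)
    return out


# ---------------------------------------------------------------------------
# Network comparison
# ---------------------------------------------------------------------------

@dataclass
class NetworkComparison:
    shared_edges: int
    unique_a: int
    unique_b: int
    possible_pairs: int
    overlap_p: float
    mean_shared_pct: float
    stratification: dict[str, dict[str, int]]


def shared_gene_percentage(members_a: frozenset[str],
                           members_b: frozenset[str]) -> float:
    """Percentage of genes of a pair that are shared: 100*|A∩B|/|A∪B|."""
    union = members_a | members_b
    if not union:
        return 0.0
    return 100.0 * len(members_a & members_b) / len(union)


def compare_networks(net_a: GeneSetNetwork, net_b: GeneSetNetwork,
                     collection: GeneSetCollection) -> NetworkComparison:
    """Compare two gene set networks built over the same collection.

    Overlap significance is the right-tail Fisher test on
    (shared, |A|-shared, |B|-shared, P-|A|-|B|+shared) with P = N(N-1)/2
    possible pairs. Each network's edges are additionally stratified by
    whether the pair's shared-gene percentage exceeds the mean over all
    overlapping set pairs in the collection.
    """
    if net_a.nodes != net_b.nodes:
        raise InvalidInputError("networks must share the same node set")
    n = len(collection.sets)
    possible = n * (n - 1) // 2
    ea, eb = net_a.edge_pairs, net_b.edge_pairs
    shared = len(ea & eb)
    tab = ContingencyTable(a=shared, b=len(ea) - shared, c=len(eb) - shared,
                           d=possible - len(ea) - len(eb) + shared)
    p = fisher_right_tail(tab)

    members = {s.id: s.members for s in collection.sets}
    ids = collection.set_ids
    pcts: dict[tuple[str, str], float] = {}
    overlapping: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = canonical_pair(ids[i], ids[j])
            pct = shared_gene_percentage(members[ids[i]], members[ids[j]])
            pcts[pair] = pct
            if members[ids[i]] & members[ids[j]]:
                overlapping.append(pct)
    mean_pct = float(np.mean(overlapping)) if overlapping else 0.0

    strat: dict[str, dict[str, int]] = {}
    for name, edges in (("a", ea), ("b", eb)):
        above = sum(1 for e in edges if pcts.get(e, 0.0) > mean_pct)
        strat[name] = {"above_mean": above, "below_mean": len(edges) - above}
    return NetworkComparison(shared_edges=shared, unique_a=len(ea) - shared,
                             unique_b=len(eb) - shared,
                             possible_pairs=possible, overlap_p=p,
                             mean_shared_pct=mean_pct, stratification=strat)


# ---------------------------------------------------------------------------
# Edge-swap randomization
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """A randomization null for a pairwise network-difference statistic."""

    observed: float
    null_values: np.ndarray
    n_random: int
    n_swaps: int
    p_value: float
    p_report: str


def edge_swap(graph: nx.Graph, n_swaps: int,
              rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Proposals draw two distinct edges uniformly from the current edge list
    and exchange endpoints; proposals creating self-loops or parallel edges
    are rejected and redrawn. ``n_swaps`` counts accepted swaps. Raises if
    the graph is too small or rigid for any valid swap.
    """
    g = graph.copy()
    edges = [canonical_pair(u, v) for u, v in g.edges()]
    if len(edges) < 2:
        raise InvalidInputError("graph has fewer than 2 edges; cannot swap")
    accepted = 0
    attempts = 0
    max_attempts = max(10000, 200 * n_swaps)
    while accepted < n_swaps:
        if attempts >= max_attempts:
            raise InvalidInputError(
                "no valid edge swap found; network too small or rigid")
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (u, v), (x, y) = edges[i], edges[j]
        if rng.integers(0, 2):
            x, y = y, x
        # propose u-x, v-y
        if u == x or v == y:
            continue
        e1, e2 = canonical_pair(u, x), canonical_pair(v, y)
        if g.has_edge(*e1) or g.has_edge(*e2):
            continue
        g.remove_edge(u, v)
        g.remove_edge(x, y)
        g.add_edge(*e1)
        g.add_edge(*e2)
        edges[i], edges[j] = e1, e2
        accepted += 1
        attempts = 0
    return g


def edge_swap_null(net_a: GeneSetNetwork | nx.Graph,
                   net_b: GeneSetNetwork | nx.Graph,
                   statistic: Callable[[nx.Graph], float],
                   n_random: int = 10000, n_swaps: int = 1000,
                   seed: int | None = None) -> NullDistribution:
    """Randomization p-value for the difference of a statistic on two networks.

    ``n_random`` pairs of random networks are generated by applying
    ``n_swaps`` accepted degree-preserving edge swaps to each input network;
    the null value per pair is |stat(randA) - stat(randB)|, and the p-value
    is the fraction of null values >= the observed absolute difference,
    reported as "< 1/n_random" when that count is zero.
    """
    ga = net_a.to_networkx() if isinstance(net_a, GeneSetNetwork) else net_a
    gb = net_b.to_networkx() if isinstance(net_b, GeneSetNetwork) else net_b
    rng = np.random.default_rng(seed)
    observed = abs(statistic(ga) - statistic(gb))
    null = np.empty(n_random, dtype=float)
    for r in range(n_random):
        ra = edge_swap(ga, n_swaps, rng)
        rb = edge_swap(gb, n_swaps, rng)
        null[r] = abs(statistic(ra) - statistic(rb))
    exceed = int(np.sum(null >= observed))
    if exceed == 0:
        p = 0.0
        report = f"< {1.0 / n_random:g}"
    else:
        p = exceed / n_random
        report = f"{p:g}"
    return NullDistribution(observed=observed, null_values=null,
                            n_random=n_random, n_swaps=n_swaps,
                            p_value=p, p_report=report)


# ---------------------------------------------------------------------------
# Edge label statistics
# ---------------------------------------------------------------------------

@dataclass
class EdgeLabelStats:
    same_label_pct: float
    n_edges: int
    interacting_pct: float | None
    n_eligible_pairs: int


def edge_label_statistics(network: GeneSetNetwork | nx.Graph,
                          node_labels: Mapping[str, str],
                          ppi: MoleculeNetwork | None = None
                          ) -> EdgeLabelStats:
    """Same-label and self-interaction percentages of a network's edges.

    ``same_label_pct`` is the percentage of edges whose endpoints carry the
    same label. If a reference interaction network is given,
    ``interacting_pct`` is computed among edges whose two endpoint entities
    each have at least one interaction: the percentage whose endpoint pair
    is itself an interaction edge; it is None (flagged) when no edge is
    eligible.
    """
    g = network.to_networkx() if isinstance(network, GeneSetNetwork) else network
    edges = [canonical_pair(u, v) for u, v in g.edges()]
    scorable = [(u, v) for u, v in edges
                if u in node_labels and v in node_labels]
    if not scorable:
        raise InvalidInputError("network has no scorable edges")
    same = sum(1 for u, v in scorable if node_labels[u] == node_labels[v])
    same_pct = 100.0 * same / len(scorable)
    interacting_pct = None
    n_eligible = 0
    if ppi is not None:
        with_ppi = {n for e in ppi.edges for n in e}
        eligible = [(u, v) for u, v in edges
                    if u in with_ppi and v in with_ppi]
        n_eligible = len(eligible)
        if eligible:
            hits = sum(1 for u, v in eligible
                       if canonical_pair(u, v) in ppi.edges)
            interacting_pct = 100.0 * hits / len(eligible)
        else:
            logger.warning("no edge has both endpoints with a reported "
                           "interaction; interacting_pct undefined")
    return EdgeLabelStats(same_label_pct=same_pct, n_edges=len(scorable),
                          interacting_pct=interacting_pct,
                          n_eligible_pairs=n_eligible)


# ---------------------------------------------------------------------------
# Pathway participation similarity
# ---------------------------------------------------------------------------

def jaccard_pathway_similarity(genes_a: Iterable[str], genes_b: Iterable[str],
                               pathway_annot: Mapping[str, Iterable[str]]
                               ) -> float:
    """Jaccard similarity of the pathway-participation profiles of two
    gene sets: the pathways any member of each set participates in are
    collected and |KP_a ∩ KP_b| / |KP_a ∪ KP_b| returned (0 when both
    profiles are empty)."""
    kp_a: set[str] = set()
    for g in genes_a:
        kp_a.update(pathway_annot.get(g, ()))
    kp_b: set[str] = set()
    for g in genes_b:
        kp_b.update(pathway_annot.get(g, ()))
    union = kp_a | kp_b
    if not union:
        return 0.0
    return len(kp_a & kp_b) / len(union)


# ---------------------------------------------------------------------------
# Chromosome loci: contact sums and same-chromosome enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A genomic locus: 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def bins(self, bin_size: int) -> frozenset[tuple[str, int]]:
        """Fixed-size bins [k*size, (k+1)*size) overlapping this locus."""
        if self.end <= self.start:
            return frozenset()
        first = self.start // bin_size
        last = (self.end - 1) // bin_size
        return frozenset((self.chrom, k) for k in range(first, last + 1))


def contact_sum(contacts: Mapping[tuple[Hashable, Hashable], float],
                bins_a: Iterable[Hashable],
                bins_b: Iterable[Hashable]) -> float:
    """Sum contact counts over all bin pairs covered by two loci.

    The contact table is symmetric: a count stored under (i, j) is also
    consulted under (j, i); each unordered bin pair contributes once.
    """
    total = 0.0
    bset_b = set(bins_b)
    seen: set[frozenset[Hashable]] = set()
    for i in bins_a:
        for j in bset_b:
            key = frozenset((i, j))
            if key in seen:
                continue
            seen.add(key)
            total += contacts.get((i, j), contacts.get((j, i), 0.0))
    return total


@dataclass
class LociContactResult:
    pair_sums: dict[tuple[str, str], float]
    groups: dict[str, list[float]]
    comparisons: dict[tuple[str, str], tuple[float, float]]  # (p_raw, q_bh)


def loci_contact_analysis(contacts: Mapping[tuple[Hashable, Hashable], float],
                          loci: Mapping[str, Locus],
                          pairs_in_network: set[tuple[str, str]],
                          bin_size: int = 1_000_000) -> LociContactResult:
    """Sum binned contact counts per locus pair and compare groups.

    Every unordered locus pair is summed over the bin pairs its coordinates
    cover, grouped by (same vs different chromosome) x (in-network vs not),
    and the groups compared pairwise with two-sided rank-sum
    (Wilcoxon-Mann-Whitney) tests, BH-corrected. Loci overlapping no bin sum
    to 0 with a warning.
    """
    bin_cache: dict[str, frozenset[tuple[str, int]]] = {}
    for lid, locus in loci.items():
        b = locus.bins(bin_size)
        if not b:
            logger.warning("locus %s overlaps no bin; contact sums are 0", lid)
        bin_cache[lid] = b
    network = {canonical_pair(*p) for p in pairs_in_network}
    ids = sorted(loci)
    pair_sums: dict[tuple[str, str], float] = {}
    groups: dict[str, list[float]] = {
        "same_chrom_in_network": [], "same_chrom_not_in_network": [],
        "diff_chrom_in_network": [], "diff_chrom_not_in_network": [],
    }
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            s = contact_sum(contacts, bin_cache[a], bin_cache[b])
            pair = canonical_pair(a, b)
            pair_sums[pair] = s
            same = loci[a].chrom == loci[b].chrom
            in_net = pair in network
            key = (("same" if same else "diff") + "_chrom_"
                   + ("in_network" if in_net else "not_in_network"))
            groups[key].append(s)
    names = sorted(groups)
    comps: dict[tuple[str, str], tuple[float, float]] = {}
    tests: list[tuple[str, str]] = []
    pvals: list[float] = []
    for x in range(len(names)):
        for y in range(x + 1, len(names)):
            ga, gb = groups[names[x]], groups[names[y]]
            if not ga or not gb:
                continue
            stat = mannwhitneyu(ga, gb, alternative="two-sided")
            tests.append((names[x], names[y]))
            pvals.append(float(stat.pvalue))
    for (na, nb), p, q in zip(tests, pvals, bh_adjust(pvals)):
        comps[(na, nb)] = (p, q)
    return LociContactResult(pair_sums=pair_sums, groups=groups,
                             comparisons=comps)


_CHROM_RE = re.compile(r"^(?:chr)?([0-9]+|[XYxy])", re.IGNORECASE)


def parse_chromosome(locus_name: str) -> str:
    """Chromosome token of a cytogenetic locus name (e.g. "chr8p11" -> "8").

    The leading "chr" is stripped and the token is the maximal prefix before
    the first arm letter (p or q); X and Y are kept as letters.
    """
    m = _CHROM_RE.match(locus_name)
    if not m:
        raise InvalidInputError(f"cannot parse chromosome from {locus_name!r}")
    return m.group(1).upper()


@dataclass
class SameChromosomeResult:
    same_chrom_edges: int
    total_edges: int
    p_value: float
    table: ContingencyTable


def same_chromosome_edge_enrichment(network: GeneSetNetwork,
                                    locus_chrom: Mapping[str, str] | None = None
                                    ) -> SameChromosomeResult:
    """Test whether a locus network is enriched for same-chromosome edges.

    All N(N-1)/2 node pairs are classified (edge vs not) x (same chromosome
    vs not) and the right-tail Fisher test applied. Chromosomes are taken
    from ``locus_chrom`` or parsed from node names like "chr8p11".
    """
    nodes = sorted(network.nodes)
    if locus_chrom is None:
        locus_chrom = {n: parse_chromosome(n) for n in nodes}
    else:
        for n in nodes:
            if n not in locus_chrom:
                raise InvalidInputError(f"no chromosome for node {n!r}")
    edges = network.edge_pairs
    a = b = c = d = 0
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            pair = (nodes[i], nodes[j])
            same = locus_chrom[nodes[i]] == locus_chrom[nodes[j]]
            is_edge = pair in edges
            if is_edge and same:
                a += 1
            elif is_edge:
                b += 1
            elif same:
                c += 1
            else:
                d += 1
    tab = ContingencyTable(a=a, b=b, c=c, d=d)
    p = 1.0 if (a + b) == 0 else fisher_right_tail(tab)
    return SameChromosomeResult(same_chrom_edges=a, total_edges=a + b,
                                p_value=p, table=tab)


__all__ = [
    "network_density", "Clustering", "SplitRecord", "cluster_network",
    "label_modules", "NetworkComparison", "compare_networks",
    "shared_gene_percentage", "NullDistribution", "edge_swap",
    "edge_swap_null", "EdgeLabelStats", "edge_label_statistics",
    "jaccard_pathway_similarity", "Locus", "contact_sum",
    "LociContactResult", "loci_contact_analysis", "parse_chromosome",
    "SameChromosomeResult", "same_chromosome_edge_enrichment",
]
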