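"""Construction of co-membership, linkage and co-enrichment gene set networks.

All three builders share one statistical kernel: a one-sided (right-tail)
Fisher's exact test on a 2x2 contingency table, followed by Benjamini-Hochberg
correction across exactly the N*(N-1)/2 pair tests, with an edge drawn
whenever the adjusted p-value is <= alpha (0.05 by default).

* Co-membership tests the overlap of two sets' members against the
  collection's gene universe.
* Linkage tests the number of reference-network edges (e.g. PPI) joining the
  two sets' unique members against all edges of the universe-restricted
  reference network; shared genes are removed from both sets first.
* Co-enrichment tests, over a compendium of experimentally derived gene
  lists, whether the two sets' unique members are simultaneously enriched in
  significantly many lists.

Degenerate pairs (empty residual after shared-gene removal, zero margins) are
assigned p = 1 rather than skipped, so the BH family size is identical for
every pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import (
    ContingencyTable,
    GSNEdge,
    GeneListCompendium,
    GeneSet,
    GeneSetCollection,
    GeneSetNetwork,
    InvalidInputError,
    MoleculeNetwork,
)

logger = logging.getLogger("gsnet")


@dataclass
class BuildConfig:
    """Thresholds shared by the three construction algorithms.

    alpha: BH-adjusted significance threshold for drawing an edge.
    enrichment_alpha: per-list BH threshold declaring a set enriched in a
        gene list (co-enrichment step 3).
    min_unique_size: minimum residual set size after shared-gene removal for
        a pair to be testable; smaller residuals yield a degenerate p = 1.
    enrichment_scope: BH family for per-list enrichment, either
        "within_list" (each list corrected over its N+2 set tests, default)
        or "across_lists" (one joint family pooling all lists).
    """

    alpha: float = 0.05
    enrichment_alpha: float = 0.05
    min_unique_size: int = 1
    enrichment_scope: str = "within_list"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise InvalidInputError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 < self.enrichment_alpha <= 1.0):
            raise InvalidInputError(
                f"enrichment_alpha must be in (0, 1], got {self.enrichment_alpha}")
        if self.enrichment_scope not in ("within_list", "across_lists"):
            raise InvalidInputError(
                f"unknown enrichment_scope {self.enrichment_scope!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one gene set in one experimentally derived gene list."""

    list_id: str
    set_id: str
    table: ContingencyTable | None
    p_raw: float
    q_bh: float
    enriched: bool


# ---------------------------------------------------------------------------
# Statistical kernel
# ---------------------------------------------------------------------------

def fisher_right_tail(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher's exact test p-value.

    Returns P(X >= a) for X hypergeometric with the table's margins
    (population total, draw size a+c, successes a+b). Equals 1.0 when a is
    at the distribution's minimum or a margin is zero.
    """
    p = hypergeom.sf(table.a - 1, table.total, table.margin_a, table.margin_b)
    return float(min(1.0, max(0.0, p)))


def _fisher_sf(a: np.ndarray, k: np.ndarray, n: np.ndarray,
               total: np.ndarray | int) -> np.ndarray:
    """Vectorized right-tail hypergeometric p-values P(X >= a)."""
    return np.clip(hypergeom.sf(a - 1, total, k, n), 0.0, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input.

    q_i >= p_i elementwise and every q is capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return [float(v) for v in np.maximum(q, p)]


def _bh_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise BH step-up adjustment for a 2-D array of p-values."""
    m = p.shape[1]
    order = np.argsort(p, axis=1, kind="stable")
    ranked = np.take_along_axis(p, order, axis=1)
    q = ranked * (m / np.arange(1, m + 1))
    q = np.minimum.accumulate(q[:, ::-1], axis=1)[:, ::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(q)
    np.put_along_axis(out, order, q, axis=1)
    return np.maximum(out, p)


# ---------------------------------------------------------------------------
# Co-membership
# ---------------------------------------------------------------------------

def overlap_contingency(set_a: GeneSet, set_b: GeneSet,
                        universe: frozenset[str] | set[str]) -> ContingencyTable:
    """2x2 table for member overlap of two gene sets over a universe."""
    if not set_a.members <= universe or not set_b.members <= universe:
        raise InvalidInputError("gene set members must lie inside the universe")
    a = len(set_a.members & set_b.members)
    b = len(set_a.members) - a
    c = len(set_b.members) - a
    d = len(universe) - len(set_a.members | set_b.members)
    return ContingencyTable(a=a, b=b, c=c, d=d)


def _membership_matrix(collection: GeneSetCollection
                       ) -> tuple[np.ndarray, list[str]]:
    genes = sorted(collection.universe)
    idx = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(collection.sets), len(genes)), dtype=bool)
    for si, s in enumerate(collection.sets):
        mat[si, [idx[g] for g in s.members]] = True
    return mat, genes


def _finalize_network(collection: GeneSetCollection, edge_type: str,
                      pairs: list[tuple[int, int]],
                      tables: list[ContingencyTable | None],
                      p_raw: np.ndarray, alpha: float) -> GeneSetNetwork:
    """BH-correct the pair family and keep edges with q <= alpha."""
    ids = collection.set_ids
    q = np.asarray(bh_adjust(p_raw)) if len(p_raw) else np.array([])
    edges: list[GSNEdge] = []
    for (i, j), tab, p, qv in zip(pairs, tables, p_raw, q):
        if qv <= alpha:
            sa, sb = sorted((ids[i], ids[j]))
            edges.append(GSNEdge(set_a=sa, set_b=sb, edge_type=edge_type,
                                 table=tab, p_raw=float(p), q_bh=float(qv)))
    edges.sort(key=lambda e: e.pair)
    return GeneSetNetwork(collection_id=collection.id, edge_type=edge_type,
                          nodes=set(ids), edges=edges, n_tests=len(pairs))


def build_comembership(collection: GeneSetCollection,
                       config: BuildConfig | None = None) -> GeneSetNetwork:
    """Build a co-membership gene set network.

    All N*(N-1)/2 unordered pairs are tested for member overlap with the
    right-tail Fisher test over the collection universe, BH-corrected across
    that family; pairs with q <= alpha become edges. Isolated sets remain as
    nodes. The collection should have passed through
    :func:`gsnet.core.merge_identical_sets`.
    """
    config = config or BuildConfig()
    n = len(collection.sets)
    if n < 2:
        logger.warning("collection %s has <2 sets; returning edgeless network",
                       collection.id)
        return GeneSetNetwork(collection_id=collection.id,
                              edge_type="co_membership",
                              nodes=set(collection.set_ids), edges=[], n_tests=0)
    mat, _ = _membership_matrix(collection)
    sizes = mat.sum(axis=1)
    inter = (mat.astype(np.int32) @ mat.astype(np.int32).T)
    total = mat.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    a = inter[iu, ju]
    ka = sizes[iu]
    kb = sizes[ju]
    p = _fisher_sf(a, ka, kb, total)
    pairs = list(zip(iu.tolist(), ju.tolist()))
    tables = [ContingencyTable(a=int(av), b=int(kav - av), c=int(kbv - av),
                               d=int(total - kav - kbv + av))
              for av, kav, kbv in zip(a, ka, kb)]
    net = _finalize_network(collection, "co_membership", pairs, tables, p,
                            config.alpha)
    logger.info("co-membership: %d pair tests, %d edges", net.n_tests,
                net.n_edges)
    return net


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------

def linkage_contingency(unique_a: set[str] | frozenset[str],
                        unique_b: set[str] | frozenset[str],
                        network: MoleculeNetwork) -> ContingencyTable:
    """2x2 table of reference-network edges joining two residual gene sets.

    With K_A (K_B) the number of edges having at least one endpoint in
    unique_a (unique_b), k the number of edges with one endpoint in each,
    and T the total edge count, the table is
    (a=k, b=K_A-k, c=K_B-k, d=T-K_A-K_B+k). The inputs must be disjoint
    (shared genes already removed).
    """
    if set(unique_a) & set(unique_b):
        raise InvalidInputError("residual gene sets must be disjoint")
    k_a = k_b = k = 0
    for u, v in network.edges:
        in_a = (u in unique_a) or (v in unique_a)
        in_b = (u in unique_b) or (v in unique_b)
        if in_a:
            k_a += 1
        if in_b:
            k_b += 1
        if ((u in unique_a and v in unique_b)
                or (u in unique_b and v in unique_a)):
            k += 1
    t = network.n_edges
    return ContingencyTable(a=k, b=k_a - k, c=k_b - k, d=t - k_a - k_b + k)


def build_linkage(collection: GeneSetCollection, network: MoleculeNetwork,
                  config: BuildConfig | None = None) -> GeneSetNetwork:
    """Build a linkage gene set network against a reference molecule network.

    The reference network is first restricted to the collection universe
    (once, globally). For every pair, shared genes are removed from both
    sets, then the right-tail Fisher test is applied to the edge-count table
    with the restricted network's full edge set as background. BH across all
    pairs; edges where q <= alpha.
    """
    config = config or BuildConfig()
    ids = collection.set_ids
    n = len(ids)
    if n < 2:
        logger.warning("collection %s has <2 sets; returning edgeless network",
                       collection.id)
        return GeneSetNetwork(collection_id=collection.id, edge_type="linkage",
                              nodes=set(ids), edges=[], n_tests=0)
    restricted = network.restrict(collection.universe)
    if restricted.n_edges == 0:
        logger.warning("reference network has no edges within the universe; "
                       "returning edgeless network")
        return GeneSetNetwork(collection_id=collection.id, edge_type="linkage",
                              nodes=set(ids), edges=[],
                              n_tests=n * (n - 1) // 2)
    # adjacency as per-gene edge-index sets for fast per-pair counting
    edge_list = sorted(restricted.edges)
    incident: dict[str, set[int]] = {}
    for ei, (u, v) in enumerate(edge_list):
        incident.setdefault(u, set()).add(ei)
        incident.setdefault(v, set()).add(ei)
    t = len(edge_list)

    members = [s.members for s in collection.sets]
    pairs: list[tuple[int, int]] = []
    tables: list[ContingencyTable | None] = []
    pvals: list[float] = []
    degenerate = 0
    min_sz = max(1, config.min_unique_size)
    for i in range(n):
        for j in range(i + 1, n):
            ua = members[i] - members[j]
            ub = members[j] - members[i]
            pairs.append((i, j))
            if len(ua) < min_sz or len(ub) < min_sz:
                tables.append(None)
                pvals.append(1.0)
                degenerate += 1
                continue
            ea = set().union(*(incident.get(g, set()) for g in ua))
            eb = set().union(*(incident.get(g, set()) for g in ub))
            k = 0
            for ei in ea & eb:
                u, v = edge_list[ei]
                if ((u in ua and v in ub) or (u in ub and v in ua)):
                    k += 1
            tab = ContingencyTable(a=k, b=len(ea) - k, c=len(eb) - k,
                                   d=t - len(ea) - len(eb) + k)
            tables.append(tab)
            pvals.append(fisher_right_tail(tab))
    net = _finalize_network(collection, "linkage", pairs, tables,
                            np.asarray(pvals), config.alpha)
    logger.info("linkage: %d pair tests (%d degenerate), %d edges",
                net.n_tests, degenerate, net.n_edges)
    return net


# ---------------------------------------------------------------------------
# Co-enrichment
# ---------------------------------------------------------------------------

def per_list_enrichment(sets_under_test: Sequence[GeneSet],
                        gene_list,  # ExperimentGeneList
                        universe: frozenset[str] | set[str],
                        config: BuildConfig | None = None
                        ) -> list[EnrichmentResult]:
    """Enrichment of each gene set in one experimentally derived gene list.

    The gene list is intersected with the universe before testing; BH is
    applied across the ``sets_under_test`` family for this list, and the
    ``enriched`` flag is set at ``config.enrichment_alpha``.
    """
    config = config or BuildConfig()
    universe = frozenset(universe)
    lg = frozenset(gene_list.genes) & universe
    results: list[EnrichmentResult] = []
    if not lg:
        logger.warning("gene list %s shares no genes with the universe",
                       gene_list.id)
        for s in sets_under_test:
            results.append(EnrichmentResult(list_id=gene_list.id, set_id=s.id,
                                            table=None, p_raw=1.0, q_bh=1.0,
                                            enriched=False))
        return results
    tables: list[ContingencyTable] = []
    pvals: list[float] = []
    for s in sets_under_test:
        a = len(s.members & lg)
        tab = ContingencyTable(a=a, b=len(s.members) - a, c=len(lg) - a,
                               d=len(universe) - len(s.members | lg))
        tables.append(tab)
        pvals.append(fisher_right_tail(tab))
    qvals = bh_adjust(pvals)
    for s, tab, p, q in zip(sets_under_test, tables, pvals, qvals):
        results.append(EnrichmentResult(list_id=gene_list.id, set_id=s.id,
                                        table=tab, p_raw=p, q_bh=q,
                                        enriched=q <= config.enrichment_alpha))
    return results


def build_coenrichment(collection: GeneSetCollection,
                       compendium: GeneListCompendium,
                       config: BuildConfig | None = None) -> GeneSetNetwork:
    """Build a co-enrichment gene set network from a gene list compendium.

    Per pair (A, B): shared genes are removed (A' = A\\B, B' = B\\A); for
    every gene list the enrichment of A' and B' is assessed within the BH
    family of all N original sets plus A' and B'; m_A and m_B count the lists
    where each residual is enriched and m_AB the lists where both are; the
    pair-level right-tail Fisher test is applied to
    (m_AB, m_A-m_AB, m_B-m_AB, M-m_A-m_B+m_AB) over the M lists; BH across
    pairs; edges where q <= alpha.

    Per-list p-values of the unmodified sets are computed once and cached;
    only residual sets are recomputed per pair.
    """
    config = config or BuildConfig()
    n = len(collection.sets)
    m = len(compendium.lists)
    if m < 1:
        raise InvalidInputError("compendium must contain at least one list")
    if n < 2:
        logger.warning("collection %s has <2 sets; returning edgeless network",
                       collection.id)
        return GeneSetNetwork(collection_id=collection.id,
                              edge_type="co_enrichment",
                              nodes=set(collection.set_ids), edges=[], n_tests=0)

    mat, genes = _membership_matrix(collection)
    gidx = {g: i for i, g in enumerate(genes)}
    u_size = len(genes)
    smat = mat.astype(np.int32)
    lmat = np.zeros((m, u_size), dtype=bool)
    for li, gl in enumerate(compendium.lists):
        keep = [gidx[g] for g in gl.genes if g in gidx]
        lmat[li, keep] = True
        if not keep:
            logger.warning("gene list %s shares no genes with the universe",
                           gl.id)
    lsizes = lmat.sum(axis=1)            # |L ∩ universe| per list
    ssizes = mat.sum(axis=1)             # |S| per set

    # cached per-list p-values of the N unmodified sets: shape (M, N)
    olap = lmat.astype(np.int32) @ smat.T
    p_orig = _fisher_sf(olap, ssizes[None, :], lsizes[:, None], u_size)
    p_orig[lsizes == 0, :] = 1.0

    def residual_pvals(row: np.ndarray) -> np.ndarray:
        """Per-list enrichment p-values of one residual set (bool row)."""
        size = int(row.sum())
        a = lmat.astype(np.int32) @ row.astype(np.int32)
        p = _fisher_sf(a, size, lsizes, u_size)
        p[lsizes == 0] = 1.0
        return p

    inter = smat @ smat.T
    min_sz = max(1, config.min_unique_size)
    pairs: list[tuple[int, int]] = []
    tables: list[ContingencyTable | None] = []
    pvals: list[float] = []
    degenerate = 0
    cache_hits = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append((i, j))
            shared = int(inter[i, j])
            res_a_size = int(ssizes[i]) - shared
            res_b_size = int(ssizes[j]) - shared
            if res_a_size < min_sz or res_b_size < min_sz:
                tables.append(None)
                pvals.append(1.0)
                degenerate += 1
                continue
            if shared == 0:
                p_a, p_b = p_orig[:, i], p_orig[:, j]
                cache_hits += 1
            else:
                p_a = residual_pvals(mat[i] & ~mat[j])
                p_b = residual_pvals(mat[j] & ~mat[i])
            family = np.concatenate([p_orig, p_a[:, None], p_b[:, None]],
                                    axis=1)
            if config.enrichment_scope == "within_list":
                q = _bh_rows(family)
            else:  # one joint family pooling all lists
                q = _bh_rows(family.reshape(1, -1)).reshape(family.shape)
            enr_a = q[:, n] <= config.enrichment_alpha
            enr_b = q[:, n + 1] <= config.enrichment_alpha
            m_a = int(enr_a.sum())
            m_b = int(enr_b.sum())
            m_ab = int((enr_a & enr_b).sum())
            tab = ContingencyTable(a=m_ab, b=m_a - m_ab, c=m_b - m_ab,
                                   d=m - m_a - m_b + m_ab)
            tables.append(tab)
            pvals.append(fisher_right_tail(tab))
    net = _finalize_network(collection, "co_enrichment", pairs, tables,
                            np.asarray(pvals), config.alpha)
    logger.info("co-enrichment: %d pair tests (%d degenerate, %d cache hits), "
                "%d edges over %d lists", net.n_tests, degenerate, cache_hits,
                net.n_edges, m)
    return net


__all__ = [
    "BuildConfig", "EnrichmentResult",
    "fisher_right_tail", "bh_adjust",
    "overlap_contingency", "build_comembership",
    "linkage_contingency", "build_linkage",
    "per_list_enrichment", "build_coenrichment",
]
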