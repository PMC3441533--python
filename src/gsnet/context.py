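"""Context-specific gene set networks for user-supplied gene lists.

A user gene list is tested for enrichment against every set in a collection;
the enriched sets are then placed in the context of precomputed gene set
networks: the context network is the subgraph induced on the enriched sets,
with typed multi-edges drawn from each loaded network (no on-the-fly edge
computation). Nodes whose user-input genes are mostly unique to them — more
unique input genes than input genes shared with any other enriched set — are
highlighted; enriched sets with no edge are reported as functionally
disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import (
    GeneSetCollection,
    GeneSetNetwork,
    InvalidInputError,
)
from .netbuild import BuildConfig, EnrichmentResult, per_list_enrichment

logger = logging.getLogger("gsnet")


@dataclass(frozen=True)
class _UserList:
    id: str
    source: str
    genes: frozenset[str]


@dataclass
class ContextNode:
    set_id: str
    q_bh: float
    input_overlap: int
    highlighted: bool


@dataclass
class ContextNetwork:
    """Enriched gene sets overlaid on precomputed network edges."""

    nodes: dict[str, ContextNode] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    isolated_nodes: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def enrich_user_list(collection: GeneSetCollection,
                     user_genes: set[str] | frozenset[str],
                     config: BuildConfig | None = None
                     ) -> list[EnrichmentResult]:
    """Enrichment of every set in the collection within a user gene list.

    The user list is intersected with the collection universe; each set gets
    a right-tail Fisher p over the universe, BH-corrected across all sets of
    the collection; results are sorted by adjusted p-value.
    """
    config = config or BuildConfig()
    if not user_genes:
        raise InvalidInputError("user gene list is empty")
    universe = collection.universe
    inside = frozenset(user_genes) & universe
    if not inside:
        raise InvalidInputError(
            "user gene list shares no genes with the collection universe; "
            "check that the gene identifiers match the collection's")
    user = _UserList(id="user", source="user input", genes=inside)
    results = per_list_enrichment(collection.sets, user, universe, config)
    return sorted(results, key=lambda r: (r.q_bh, r.p_raw, r.set_id))


def build_context_network(enriched: list[EnrichmentResult] | list[str],
                          precomputed: list[GeneSetNetwork],
                          user_genes: set[str] | frozenset[str],
                          collection: GeneSetCollection) -> ContextNetwork:
    """Induce a typed multi-edge context network on enriched gene sets.

    Edges are exactly the precomputed edges with both endpoints enriched,
    one per (pair, edge type). A node is highlighted iff its number of
    unique user-input genes (input genes in no other enriched set) strictly
    exceeds the largest number of input genes it shares with any other
    enriched set. Enriched sets with no edge are listed as isolated.
    """
    if enriched and isinstance(enriched[0], EnrichmentResult):
        kept = [r for r in enriched if r.enriched]
        qmap = {r.set_id: r.q_bh for r in kept}
    else:
        qmap = {sid: float("nan") for sid in enriched}  # pre-selected ids
    enriched_ids = sorted(qmap)
    universe = collection.universe
    inside = frozenset(user_genes) & universe
    overlaps = {sid: inside & collection[sid].members for sid in enriched_ids}

    nodes: dict[str, ContextNode] = {}
    for sid in enriched_ids:
        mine = overlaps[sid]
        shared_max = 0
        for o in enriched_ids:
            if o == sid:
                continue
            shared_max = max(shared_max, len(mine & collection[o].members))
        unique = {g for g in mine
                  if all(g not in collection[o].members
                         for o in enriched_ids if o != sid)}
        nodes[sid] = ContextNode(set_id=sid, q_bh=qmap[sid],
                                 input_overlap=len(mine),
                                 highlighted=len(unique) > shared_max)

    edges: list[tuple[str, str, str]] = []
    enriched_set = set(enriched_ids)
    for net in precomputed:
        for e in net.edges:
            if e.set_a in enriched_set and e.set_b in enriched_set:
                edges.append((e.set_a, e.set_b, e.edge_type))
    edges = sorted(set(edges))
    touched = {x for a, b, _ in edges for x in (a, b)}
    isolated = sorted(enriched_set - touched)
    if isolated:
        logger.info("functionally disjoint enriched sets: %s",
                    ", ".join(isolated))
    return ContextNetwork(nodes=nodes, edges=edges, isolated_nodes=isolated)


__all__ = ["ContextNode", "ContextNetwork", "enrich_user_list",
           "build_context_network"]
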