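"""GO DAG parsing, annotation propagation, and informative-term filtering.

Gene Ontology terms form a directed acyclic graph per namespace; child terms
are subsets of their parents, so a gene set collection built naively from GO
terms is dominated by trivial ancestor-descendant overlap. The filter here
retains, within each lineage, the term whose propagated annotation count
(cardinality) is closest to a target (50 by default), after removing terms
smaller than 10 or larger than 200 genes. The retained terms form an
antichain in the DAG: no retained term is an ancestor of another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .core import GeneSet, GeneSetCollection, InvalidInputError, ParseError, \
    merge_identical_sets

logger = logging.getLogger("gsnet")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
LINEAGE_RELATIONS = ("is_a", "part_of")


@dataclass
class GOTerm:
    id: str
    name: str
    namespace: str
    parents: set[str] = field(default_factory=set)
    obsolete: bool = False


@dataclass
class GODag:
    """A GO DAG: terms with is_a/part_of parents, one namespace per term.

    Cross-namespace parent links are dropped at construction time so every
    lineage stays inside a single namespace.
    """

    terms: dict[str, GOTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.terms.values():
            t.parents = {p for p in t.parents
                         if p in self.terms
                         and self.terms[p].namespace == t.namespace}
        self._assert_acyclic()
        self._anc_cache: dict[str, frozenset[str]] = {}

    def _assert_acyclic(self) -> None:
        color: dict[str, int] = {}

        def visit(tid: str, stack: list[str]) -> None:
            color[tid] = 1
            for p in self.terms[tid].parents:
                if color.get(p) == 1:
                    raise InvalidInputError(
                        f"cycle in ontology involving {p}")
                if color.get(p, 0) == 0:
                    visit(p, stack)
            color[tid] = 2

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, len(self.terms) * 2 + 100))
        try:
            for tid in self.terms:
                if color.get(tid, 0) == 0:
                    visit(tid, [])
        finally:
            sys.setrecursionlimit(old)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All strict ancestors of a term along is_a/part_of."""
        cached = self._anc_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.terms[term_id].parents:
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._anc_cache[term_id] = result
        return result

    def children_map(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for tid, t in self.terms.items():
            for p in t.parents:
                kids[p].add(tid)
        return kids

    def topological_order(self) -> list[str]:
        """Terms ordered children-before-parents."""
        order: list[str] = []
        seen: set[str] = set()
        # iterative DFS from each node following parent links; a node is
        # emitted after all of its... we need children first, so emit a term
        # once all terms whose parent sets contain it are... simpler: count
        # outstanding children and peel leaves.
        kids = self.children_map()
        pending = {tid: len(kids[tid]) for tid in self.terms}
        frontier = [tid for tid, n in pending.items() if n == 0]
        while frontier:
            tid = frontier.pop()
            order.append(tid)
            seen.add(tid)
            for p in self.terms[tid].parents:
                pending[p] -= 1
                if pending[p] == 0:
                    frontier.append(p)
        if len(order) != len(self.terms):
            raise InvalidInputError("ontology graph is not acyclic")
        return order


@dataclass
class GOFilterConfig:
    """Cardinality bounds and target for informative-term selection."""

    target_cardinality: int = 50
    min_cardinality: int = 10
    max_cardinality: int = 200

    def __post_init__(self) -> None:
        if not (self.min_cardinality < self.target_cardinality
                < self.max_cardinality):
            raise InvalidInputError(
                "require min_cardinality < target_cardinality < max_cardinality")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_obo(path: str | Path) -> GODag:
    """Read an OBO 1.2 ontology, keeping is_a and part_of relations only."""
    import obonet

    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    terms: dict[str, GOTerm] = {}
    for tid, data in graph.nodes(data=True):
        namespace = data.get("namespace", "")
        parents: set[str] = set()
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[tid] = GOTerm(id=tid, name=data.get("name", tid),
                            namespace=namespace, parents=parents,
                            obsolete=obsolete)
    for child, parent, key in graph.edges(keys=True):
        if key in LINEAGE_RELATIONS and child in terms and parent in terms:
            terms[child].parents.add(parent)
    return GODag(terms=terms)


def read_annotations(path: str | Path, dialect: str = "tsv"
                     ) -> dict[str, set[str]]:
    """Read direct gene->term annotations as a term->genes map.

    ``tsv``: two columns, gene<TAB>term. ``gaf``: GAF 2.x, using columns 2
    (gene id) and 5 (GO id); lines starting with '!' are headers.
    """
    path = Path(path)
    direct: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            toks = line.split("\t")
            if dialect == "gaf":
                if len(toks) < 5:
                    raise ParseError(f"{path}:{lineno}: short GAF record")
                gene, term = toks[1], toks[4]
            else:
                if len(toks) < 2:
                    raise ParseError(f"{path}:{lineno}: need gene<TAB>term")
                gene, term = toks[0], toks[1]
            direct.setdefault(term, set()).add(gene)
    return direct


# ---------------------------------------------------------------------------
# Propagation and filtering
# ---------------------------------------------------------------------------

def propagate_annotations(dag: GODag, direct: dict[str, set[str]]
                          ) -> dict[str, frozenset[str]]:
    """Propagate direct annotations up the DAG (true-path closure).

    Each term's gene set becomes the union of its own direct annotations and
    those of all its descendants; each gene is counted once per term.
    Annotations to unknown or obsolete terms are skipped with a warning.
    """
    skipped = 0
    genes: dict[str, set[str]] = {tid: set() for tid in dag.terms}
    for tid, gs in direct.items():
        term = dag.terms.get(tid)
        if term is None or term.obsolete:
            skipped += 1
            continue
        genes[tid] |= gs
    if skipped:
        logger.warning("skipped annotations to %d unknown/obsolete term(s)",
                       skipped)
    for tid in dag.topological_order():  # children before parents
        for p in dag.terms[tid].parents:
            genes[p] |= genes[tid]
    return {tid: frozenset(gs) for tid, gs in genes.items()}


def filter_go_terms(dag: GODag, term_genes: dict[str, frozenset[str]],
                    config: GOFilterConfig | None = None,
                    namespace: str | None = None) -> GeneSetCollection:
    """Select non-redundant informative GO terms as a gene set collection.

    Terms with propagated cardinality outside [min, max] are removed first.
    Among the survivors, a term T is retained iff no surviving ancestor or
    descendant is strictly closer to the target cardinality; closeness ties
    along a lineage are resolved toward the deeper (more specific) term.
    Retained terms with identical membership are merged. The result contains
    no ancestor-descendant pair.
    """
    config = config or GOFilterConfig()
    candidates = {tid for tid, gs in term_genes.items()
                  if tid in dag.terms
                  and not dag.terms[tid].obsolete
                  and config.min_cardinality <= len(gs) <= config.max_cardinality}
    if namespace is not None:
        candidates = {tid for tid in candidates
                      if dag.terms[tid].namespace == namespace}
    if not candidates:
        logger.warning("no GO terms survive the cardinality bounds"
                       + (f" in namespace {namespace}" if namespace else ""))
        return GeneSetCollection(id=namespace or "go_filtered", sets=[])

    def closeness(tid: str) -> int:
        return abs(len(term_genes[tid]) - config.target_cardinality)

    retained: list[str] = []
    for tid in sorted(candidates):
        anc = dag.ancestors(tid) & candidates
        desc = {o for o in candidates if tid in dag.ancestors(o)}
        cl = closeness(tid)
        beaten = any(closeness(o) < cl for o in anc | desc) \
            or any(closeness(o) == cl for o in desc)
        if not beaten:
            retained.append(tid)

    sets = [GeneSet(id=tid, name=dag.terms[tid].name,
                    members=term_genes[tid]) for tid in retained]
    collection = GeneSetCollection(id=namespace or "go_filtered", sets=sets)
    return merge_identical_sets(collection)


__all__ = [
    "GOTerm", "GODag", "GOFilterConfig", "NAMESPACES",
    "read_obo", "read_annotations",
    "propagate_annotations", "filter_go_terms",
]
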