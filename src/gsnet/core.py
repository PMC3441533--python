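"""Core domain types and I/O for gene set networks.

The central objects are :class:`GeneSetCollection` (named gene sets over a
background universe derived from their union), :class:`MoleculeNetwork`
(an undirected simple graph over gene identifiers, e.g. a protein-protein
interaction network) and :class:`GeneSetNetwork` (an undirected graph whose
nodes are gene sets and whose edges carry the contingency counts and
raw/adjusted p-values that established them).

Gene identifiers are opaque strings; no identifier mapping is performed.
All edge pairs are stored in canonical lexicographic order so that written
files are byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger("gsnet")

EDGE_TYPES = ("co_membership", "linkage", "co_enrichment")


class GsnError(Exception):
    """Base error for the package."""


class ParseError(GsnError):
    """A file could not be parsed; message names the offending line."""


class InvalidInputError(GsnError):
    """An operation received arguments violating its preconditions."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered pair lexicographically."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers.

    ``id`` must be unique within its collection; ``members`` is non-empty.
    """

    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidInputError("gene set id must be non-empty")
        if not self.members:
            raise InvalidInputError(f"gene set {self.id!r} has no members")

    @property
    def cardinality(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets.

    The background ``universe`` is always the union of all member sets: it is
    the population every overlap test in the package is performed against.
    """

    id: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate gene set ids: {dup}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list[str]:
        return [s.id for s in self.sets]


@dataclass
class MoleculeNetwork:
    """Undirected simple graph over gene ids (e.g. a PPI network).

    No self-loops; each unordered pair is stored once in canonical order.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]],
                   extra_nodes: Iterable[str] = ()) -> "MoleculeNetwork":
        nodes: set[str] = set(extra_nodes)
        edges: set[tuple[str, str]] = set()
        dropped = 0
        for u, v in pairs:
            if u == v:
                dropped += 1
                continue
            edges.add(canonical_pair(u, v))
            nodes.add(u)
            nodes.add(v)
        if dropped:
            logger.info("dropped %d self-loop(s) while building molecule network",
                        dropped)
        return cls(nodes=nodes, edges=edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def restrict(self, keep: set[str] | frozenset[str]) -> "MoleculeNetwork":
        """Induced subgraph on ``keep`` (both endpoints must survive)."""
        return MoleculeNetwork(
            nodes=self.nodes & set(keep),
            edges={e for e in self.edges if e[0] in keep and e[1] in keep},
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class ExperimentGeneList:
    """One experimentally derived gene list (e.g. a DE gene list)."""

    id: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise InvalidInputError(f"gene list {self.id!r} is empty")


@dataclass
class GeneListCompendium:
    """A labeled collection of experimentally derived gene lists."""

    id: str
    lists: list[ExperimentGeneList] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [l.id for l in self.lists]
        if len(ids) != len(set(ids)):
            raise InvalidInputError("duplicate gene list ids in compendium")

    def __len__(self) -> int:
        return len(self.lists)

    def __iter__(self) -> Iterator[ExperimentGeneList]:
        return iter(self.lists)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 contingency counts (a, b, c, d), all non-negative, total > 0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise InvalidInputError(f"negative/non-integer count in {self}")
        if self.total == 0:
            raise InvalidInputError("contingency table total is zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margin_a(self) -> int:
        """Row margin a+b (size of the first set)."""
        return self.a + self.b

    @property
    def margin_b(self) -> int:
        """Column margin a+c (size of the second set)."""
        return self.a + self.c


@dataclass(frozen=True)
class GSNEdge:
    """An edge between two gene sets with the statistics that supported it."""

    set_a: str
    set_b: str
    edge_type: str
    table: ContingencyTable | None
    p_raw: float
    q_bh: float

    def __post_init__(self) -> None:
        if self.set_a == self.set_b:
            raise InvalidInputError(f"self-edge on {self.set_a!r}")
        if self.set_a > self.set_b:
            raise InvalidInputError("edge endpoints must be in canonical order")
        if not (0.0 <= self.p_raw <= self.q_bh <= 1.0 + 1e-15):
            raise InvalidInputError(
                f"require 0 <= p_raw <= q_bh <= 1, got p={self.p_raw} q={self.q_bh}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.set_a, self.set_b)


@dataclass
class GeneSetNetwork:
    """Undirected simple network over gene set ids.

    ``nodes`` includes isolated gene sets; ``n_tests`` records how many pair
    tests were performed when the network was built (N*(N-1)/2 for the
    construction algorithms).
    """

    collection_id: str
    edge_type: str
    nodes: set[str] = field(default_factory=set)
    edges: list[GSNEdge] = field(default_factory=list)
    n_tests: int | None = None

    def __post_init__(self) -> None:
        pairs = [e.pair for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise InvalidInputError("parallel edges in gene set network")
        for e in self.edges:
            if e.set_a not in self.nodes or e.set_b not in self.nodes:
                raise InvalidInputError(
                    f"edge endpoint not in node set: {e.pair}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e.pair)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(e.set_a, e.set_b, edge_type=e.edge_type,
                       p_raw=e.p_raw, q_bh=e.q_bh)
        return g


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name<TAB>description<TAB>gene1<TAB>...).

    Duplicate gene tokens within a line are deduplicated; line order is
    preserved. An empty file yields an empty collection.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least "
                                 f"name<TAB>description, got {len(fields)} field(s)")
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(id=name, name=desc or name, members=genes))
    return GeneSetCollection(id=path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.id, s.name] + sorted(s.members)) + "\n")


def merge_identical_sets(collection: GeneSetCollection) -> GeneSetCollection:
    """Combine gene sets with exactly identical membership.

    The merged set's id is the "+"-joined sorted ids of its constituents; the
    universe is unchanged. Collections are expected to pass through this step
    before network construction.
    """
    by_members: dict[frozenset[str], list[GeneSet]] = {}
    order: list[frozenset[str]] = []
    for s in collection.sets:
        if s.members not in by_members:
            by_members[s.members] = []
            order.append(s.members)
        by_members[s.members].append(s)
    merged: list[GeneSet] = []
    for members in order:
        group = by_members[members]
        if len(group) == 1:
            merged.append(group[0])
        else:
            new_id = "+".join(sorted(g.id for g in group))
            merged.append(GeneSet(id=new_id, name=new_id, members=members))
    if len(merged) < len(collection.sets):
        logger.info("merged %d identical gene set(s) in collection %s",
                    len(collection.sets) - len(merged), collection.id)
    return GeneSetCollection(id=collection.id, sets=merged)


def read_molecule_network(path: str | Path, dialect: str = "tsv") -> MoleculeNetwork:
    """Read an undirected molecule network from SIF or 2-column TSV.

    SIF lines are ``node relation node``; TSV lines are ``node<TAB>node``
    (whitespace-delimited tokens are accepted in both). Self-loops are
    dropped (with a logged count) and duplicate edges collapsed.
    """
    if dialect not in ("sif", "tsv"):
        raise InvalidInputError(f"unknown dialect {dialect!r}")
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if dialect == "sif":
                if len(tokens) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF record needs "
                                     "node<TAB>relation<TAB>node")
                u, rest = tokens[0], tokens[2:]
                for v in rest:
                    pairs.append((u, v))
            else:
                if len(tokens) < 2:
                    raise ParseError(f"{path}:{lineno}: need two node ids")
                pairs.append((tokens[0], tokens[1]))
    return MoleculeNetwork.from_edges(pairs)


def read_gene_list(path: str | Path, list_id: str | None = None,
                   source: str = "") -> ExperimentGeneList:
    """Read one gene list: one gene id per line (blank/# lines skipped)."""
    path = Path(path)
    genes = set()
    with path.open() as fh:
        for raw in fh:
            tok = raw.strip()
            if tok and not tok.startswith("#"):
                genes.add(tok.split("\t")[0])
    return ExperimentGeneList(id=list_id or path.stem, source=source or str(path),
                              genes=frozenset(genes))


def read_compendium(paths: Iterable[str | Path],
                    compendium_id: str = "compendium") -> GeneListCompendium:
    """Read a compendium as one gene-list file per experiment."""
    lists = [read_gene_list(p) for p in paths]
    return GeneListCompendium(id=compendium_id, lists=lists)


# ---------------------------------------------------------------------------
# Gene set network archive I/O
# ---------------------------------------------------------------------------

ARCHIVE_COLUMNS = ["set_a", "set_b", "p_raw", "q_bh", "a",
                   "margin_a", "margin_b", "total"]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_gene_set_network_archive(path: str | Path,
                                  edge_type: str = "co_membership",
                                  collection_id: str | None = None,
                                  ) -> GeneSetNetwork:
    """Read a tab-delimited gene set network archive.

    Two layouts are sniffed per file: the full 8-column layout
    (set_a, set_b, p_raw, q_bh, a, margin_a, margin_b, total) written by
    :func:`write_gene_set_network`, and a minimal 3+-column layout
    (set_a, set_b, p[, q]) as distributed in archived network dumps.
    Duplicate rows in either orientation collapse onto one canonical edge;
    self-edge rows are rejected with a warning.
    """
    path = Path(path)
    edges: dict[tuple[str, str], GSNEdge] = {}
    nodes: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 3:
                raise ParseError(f"{path}:{lineno}: need at least 3 columns")
            if (lineno == 1 and not _is_number(toks[2])
                    and toks[2].strip().lower() in
                    {"p", "p_raw", "pvalue", "p_value", "p-value", "q", "q_bh"}):
                continue  # header row
            sa, sb = toks[0], toks[1]
            if sa == sb:
                logger.warning("%s:%d: self-edge row on %r rejected",
                               path, lineno, sa)
                continue
            nums = toks[2:]
            for i, tok in enumerate(nums):
                if not _is_number(tok):
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {tok!r} in column "
                        f"{i + 3}")
            vals = [float(t) for t in nums]
            if len(vals) >= 6:
                p_raw, q_bh = vals[0], vals[1]
                a, ma, mb, tot = (int(round(v)) for v in vals[2:6])
                table = ContingencyTable(a=a, b=ma - a, c=mb - a,
                                         d=tot - ma - mb + a)
            else:
                p_raw = vals[0]
                q_bh = vals[1] if len(vals) >= 2 else vals[0]
                table = None
            pair = canonical_pair(sa, sb)
            edge = GSNEdge(set_a=pair[0], set_b=pair[1], edge_type=edge_type,
                           table=table, p_raw=p_raw, q_bh=max(p_raw, q_bh))
            edges[pair] = edge
            nodes.update(pair)
    return GeneSetNetwork(
        collection_id=collection_id or path.stem,
        edge_type=edge_type,
        nodes=nodes,
        edges=[edges[p] for p in sorted(edges)],
    )


def write_gene_set_network(network: GeneSetNetwork, path: str | Path,
                           format: str = "tsv",
                           collection: GeneSetCollection | None = None) -> None:
    """Write a gene set network as TSV (archive layout), SIF or GraphML.

    TSV round-trips through :func:`read_gene_set_network_archive` preserving
    the edge set and p/q values. Edges are written in canonical sorted order.
    """
    path = Path(path)
    edges = sorted(network.edges, key=lambda e: e.pair)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("\t".join(ARCHIVE_COLUMNS) + "\n")
            for e in edges:
                t = e.table
                if t is None:
                    t = ContingencyTable(a=0, b=0, c=0, d=1)
                fh.write("\t".join([
                    e.set_a, e.set_b, f"{e.p_raw:.17g}", f"{e.q_bh:.17g}",
                    str(t.a), str(t.margin_a), str(t.margin_b), str(t.total),
                ]) + "\n")
    elif format == "sif":
        with path.open("w") as fh:
            for e in edges:
                fh.write(f"{e.set_a}\tet_{e.edge_type}\t{e.set_b}\n")
            for n in sorted(network.nodes - {x for e in edges for x in e.pair}):
                fh.write(f"{n}\n")
    elif format == "graphml":
        _write_graphml(network, path, collection)
    else:
        raise InvalidInputError(f"unknown format {format!r}")


def _write_graphml(network: GeneSetNetwork, path: Path,
                   collection: GeneSetCollection | None) -> None:
    g = nx.Graph()
    card: Mapping[str, int] = {}
    if collection is not None:
        card = {s.id: s.cardinality for s in collection.sets}
    for n in sorted(network.nodes):
        attrs = {"set_id": n}
        if n in card:
            attrs["cardinality"] = card[n]
        g.add_node(n, **attrs)
    for e in sorted(network.edges, key=lambda e: e.pair):
        attrs = {"edge_type": e.edge_type, "p_raw": e.p_raw, "q_bh": e.q_bh}
        if e.table is not None:
            attrs.update(a=e.table.a, b=e.table.b, c=e.table.c, d=e.table.d)
        g.add_edge(e.set_a, e.set_b, **attrs)
    nx.write_graphml(g, path)


__all__ = [
    "GsnError", "ParseError", "InvalidInputError",
    "GeneSet", "GeneSetCollection", "MoleculeNetwork",
    "ExperimentGeneList", "GeneListCompendium",
    "ContingencyTable", "GSNEdge", "GeneSetNetwork",
    "canonical_pair", "read_gmt", "write_gmt", "merge_identical_sets",
    "read_molecule_network", "read_gene_list", "read_compendium",
    "read_gene_set_network_archive", "write_gene_set_network",
    "EDGE_TYPES",
]
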