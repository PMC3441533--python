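"""Seeded synthetic-data generators for gene set network algorithms.

Each generator plants the statistical structure one construction algorithm
detects: pairwise member overlap (co-membership), excess interaction edges
between the unique members of a set pair (linkage), and joint activation of
a set pair across a compendium of gene lists (co-enrichment). Away from the
planted pairs the defaults produce pairwise-disjoint sets, uniform background
edges and independent baseline activation, so a builder run on an unplanted
spec is a null experiment.

All sampling goes through one numpy PCG64 generator per operation, seeded
from ``spec.seed`` and a per-operation stream index, so outputs are
reproducible bit-for-bit across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ExperimentGeneList,
    GeneListCompendium,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
    MoleculeNetwork,
)

logger = logging.getLogger("gsnet")

_STREAM_COLLECTION = 1
_STREAM_NETWORK = 2
_STREAM_COMPENDIUM = 3


@dataclass
class SynthSpec:
    """Parameters of a synthetic study.

    Defaults describe a desk-scale experiment: 20 sets of 25 genes over a
    2000-gene universe, a background interaction probability of 0.002 per
    gene pair, and 200 gene lists of 50 genes with a 5% baseline chance of
    any set being activated in a list. Planted pairs are given as
    (set index, set index, strength) triples: number of shared genes for
    overlap, number of extra inter-set edges for linkage, and a joint
    activation probability for coactivation.
    """

    universe_size: int = 2000
    n_sets: int = 20
    set_size: int = 25
    planted_overlap_pairs: list[tuple[int, int, int]] = field(default_factory=list)
    planted_linkage_pairs: list[tuple[int, int, int]] = field(default_factory=list)
    planted_coactivation_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    background_edge_prob: float = 0.002
    n_lists: int = 200
    list_size: int = 50
    baseline_activation: float = 0.05
    contribution_fraction: float = 0.6
    seed: int = 17

    def __post_init__(self) -> None:
        for p in (self.background_edge_prob, self.baseline_activation,
                  self.contribution_fraction):
            if not (0.0 <= p <= 1.0):
                raise InvalidInputError(f"probability {p} outside [0, 1]")
        for i, j, rate in self.planted_coactivation_pairs:
            self._check_pair(i, j)
            if not (0.0 <= rate <= 1.0):
                raise InvalidInputError(f"activation rate {rate} outside [0, 1]")
        for i, j, n_shared in self.planted_overlap_pairs:
            self._check_pair(i, j)
            if not (0 <= n_shared <= self.set_size):
                raise InvalidInputError(
                    f"n_shared={n_shared} exceeds set_size={self.set_size}")
        for i, j, n_extra in self.planted_linkage_pairs:
            self._check_pair(i, j)
            if n_extra < 0:
                raise InvalidInputError("n_extra_edges must be >= 0")

    def _check_pair(self, i: int, j: int) -> None:
        if i == j or not (0 <= i < self.n_sets) or not (0 <= j < self.n_sets):
            raise InvalidInputError(f"invalid planted pair indices ({i}, {j})")

    def with_seed(self, seed: int) -> "SynthSpec":
        return replace(self, seed=seed)


def _gene_ids(universe_size: int) -> np.ndarray:
    width = max(6, len(str(universe_size)))
    return np.array([f"g{k:0{width}d}" for k in range(1, universe_size + 1)])


def gen_collection(spec: SynthSpec) -> GeneSetCollection:
    """Generate a gene set collection with planted pairwise overlaps.

    Sets are sampled without replacement across sets (pairwise disjoint by
    construction); each planted (i, j, n_shared) pair then shares exactly
    n_shared genes, transplanted from set i into set j.
    """
    if spec.n_sets * spec.set_size > spec.universe_size:
        raise InvalidInputError(
            f"universe of {spec.universe_size} genes cannot host "
            f"{spec.n_sets} disjoint sets of {spec.set_size}")
    rng = np.random.default_rng([spec.seed, _STREAM_COLLECTION])
    genes = _gene_ids(spec.universe_size)
    perm = rng.permutation(spec.universe_size)
    members: list[set[str]] = []
    for s in range(spec.n_sets):
        block = perm[s * spec.set_size:(s + 1) * spec.set_size]
        members.append(set(genes[block]))
    for i, j, n_shared in spec.planted_overlap_pairs:
        if n_shared == 0:
            continue
        donors = rng.choice(sorted(members[i]), size=n_shared, replace=False)
        recipients = rng.choice(sorted(members[j] - members[i]),
                                size=n_shared, replace=False)
        members[j] = (members[j] - set(recipients)) | set(donors)
    sets = [GeneSet(id=f"S{k:03d}", name=f"synthetic set {k}",
                    members=frozenset(m)) for k, m in enumerate(members)]
    return GeneSetCollection(id=f"synth_seed{spec.seed}", sets=sets)


def _decode_pair(index: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map flat row-major indices of the strict upper triangle of an n x n
    grid back to (i, j) pairs with i < j."""
    idx = index.astype(np.int64)
    rows = np.arange(n, dtype=np.int64)
    firsts = rows * (n - 1) - rows * (rows - 1) // 2  # flat index of (i, i+1)
    i = np.searchsorted(firsts, idx, side="right") - 1
    j = idx - firsts[i] + i + 1
    return i, j


def gen_molecule_network(collection: GeneSetCollection,
                         spec: SynthSpec) -> MoleculeNetwork:
    """Generate an interaction network with planted inter-set edge bundles.

    Background: every unordered gene pair of the universe is an edge
    independently with ``background_edge_prob`` (sampled as a binomial edge
    count followed by a uniform draw of that many distinct pairs). Planting:
    for each (i, j, n_extra) pair, n_extra additional edges are placed
    uniformly between the two sets' residual (non-shared) members.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_NETWORK])
    genes = np.array(sorted(collection.universe))
    u = len(genes)
    edges: set[tuple[str, str]] = set()
    if u >= 2 and spec.background_edge_prob > 0:
        n_pairs = u * (u - 1) // 2
        m = rng.binomial(n_pairs, spec.background_edge_prob)
        chosen = rng.choice(n_pairs, size=m, replace=False)
        ii, jj = _decode_pair(np.sort(chosen), u)
        for a, b in zip(genes[ii], genes[jj]):
            edges.add((a, b) if a <= b else (b, a))
    sets = collection.sets
    for i, j, n_extra in spec.planted_linkage_pairs:
        res_a = sorted(sets[i].members - sets[j].members)
        res_b = sorted(sets[j].members - sets[i].members)
        candidates = [
            (a, b) if a <= b else (b, a)
            for a in res_a for b in res_b
        ]
        candidates = sorted(set(candidates) - edges)
        if n_extra > len(candidates):
            raise InvalidInputError(
                f"cannot plant {n_extra} edges between sets {i} and {j}: "
                f"only {len(candidates)} free cross pairs")
        picked = rng.choice(len(candidates), size=n_extra, replace=False)
        for k in picked:
            edges.add(candidates[k])
    return MoleculeNetwork.from_edges(edges, extra_nodes=genes.tolist())


def gen_compendium(collection: GeneSetCollection,
                   spec: SynthSpec) -> GeneListCompendium:
    """Generate a compendium of gene lists with planted joint enrichment.

    Per list, each set is independently activated with
    ``baseline_activation``; for each planted (i, j, rate) pair a joint draw
    with probability ``rate`` activates both sets at once (overriding the
    independent draws when it fires). An activated set contributes
    ``contribution_fraction`` of its residual members to the list; remaining
    slots up to ``list_size`` are filled uniformly from the universe.
    """
    if spec.list_size > spec.universe_size:
        raise InvalidInputError("list_size exceeds universe_size")
    rng = np.random.default_rng([spec.seed, _STREAM_COMPENDIUM])
    genes = np.array(sorted(collection.universe))
    sets = collection.sets
    n = len(sets)
    planted_partner: dict[int, set[str]] = {}
    for i, j, _ in spec.planted_coactivation_pairs:
        planted_partner.setdefault(i, set()).update(sets[j].members)
        planted_partner.setdefault(j, set()).update(sets[i].members)
    residuals = [sorted(sets[k].members - planted_partner.get(k, set()))
                 for k in range(n)]
    lists: list[ExperimentGeneList] = []
    for li in range(spec.n_lists):
        activated = rng.random(n) < spec.baseline_activation
        for i, j, rate in spec.planted_coactivation_pairs:
            if rng.random() < rate:
                activated[i] = activated[j] = True
        chosen: set[str] = set()
        for k in np.flatnonzero(activated):
            res = residuals[k]
            take = int(round(spec.contribution_fraction * len(res)))
            if take:
                picked = rng.choice(len(res), size=take, replace=False)
                chosen.update(res[p] for p in picked)
        if len(chosen) < spec.list_size:
            pool = np.array(sorted(set(genes) - chosen))
            fill = rng.choice(len(pool), size=spec.list_size - len(chosen),
                              replace=False)
            chosen.update(pool[fill])
        lists.append(ExperimentGeneList(id=f"list{li:04d}",
                                        source="synthetic",
                                        genes=frozenset(chosen)))
    return GeneListCompendium(id=f"synth_compendium_seed{spec.seed}",
                              lists=lists)


__all__ = ["SynthSpec", "gen_collection", "gen_molecule_network",
           "gen_compendium"]
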