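"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (exact rational
enumeration of the hypergeometric tail, the textbook BH step-up loop) kept
independent of the implementation paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from gsnet import GeneSet, GeneSetCollection


def hypergeom_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact right-tail hypergeometric probability P(X >= a) by enumeration."""
    n_total = a + b + c + d
    k_succ = a + b
    n_draw = a + c
    hi = min(k_succ, n_draw)
    num = sum(comb(k_succ, x) * comb(n_total - k_succ, n_draw - x)
              for x in range(a, hi + 1))
    return Fraction(num, comb(n_total, n_draw))


def bh_step_up(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def enumerate_tables(max_total: int):
    """All 2x2 tables (a, b, c, d) with 1 <= a+b+c+d <= max_total."""
    for t in range(1, max_total + 1):
        for a in range(t + 1):
            for b in range(t - a + 1):
                for c in range(t - a - b + 1):
                    yield (a, b, c, t - a - b - c)


def make_collection(memberships: dict[str, set[str]],
                    cid: str = "test") -> GeneSetCollection:
    sets = [GeneSet(id=k, name=k, members=frozenset(v))
            for k, v in memberships.items()]
    return GeneSetCollection(id=cid, sets=sets)


@pytest.fixture
def small_collection() -> GeneSetCollection:
    """Ten disjoint sets of 5 genes over a 50-gene universe."""
    genes = [f"g{k:03d}" for k in range(50)]
    return make_collection(
        {f"S{i}": set(genes[5 * i:5 * (i + 1)]) for i in range(10)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
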