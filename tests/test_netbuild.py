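"""Statistical kernel and the three network construction algorithms."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsnet import (
    BuildConfig,
    ContingencyTable,
    ExperimentGeneList,
    GeneListCompendium,
    GeneSet,
    GeneSetCollection,
    InvalidInputError,
    MoleculeNetwork,
    SynthSpec,
    bh_adjust,
    build_coenrichment,
    build_comembership,
    build_linkage,
    fisher_right_tail,
    gen_collection,
    gen_compendium,
    gen_molecule_network,
    linkage_contingency,
    overlap_contingency,
    per_list_enrichment,
)
from gsnet.netbuild import _bh_rows
from conftest import bh_step_up, enumerate_tables, hypergeom_tail_exact, \
    make_collection


class TestFisherRightTail:
    @pytest.mark.parametrize("table,expected", [
        ((0, 10, 10, 80), 1.0),
        ((5, 0, 0, 5), 1 / 252),        # P(X >= 5), N=10, K=5, n=5
        ((4, 1, 1, 4), 26 / 252),
    ])
    def test_reference_values(self, table, expected):
        assert fisher_right_tail(ContingencyTable(*table)) == \
            pytest.approx(expected, abs=1e-12)

    def test_exhaustive_small_tables_match_exact_enumeration(self):
        for tab in enumerate_tables(20):
            got = fisher_right_tail(ContingencyTable(*tab))
            want = float(hypergeom_tail_exact(*tab))
            assert math.isclose(got, want, abs_tol=1e-12), tab

    def test_zero_margin_gives_one(self):
        assert fisher_right_tail(ContingencyTable(0, 0, 5, 5)) == 1.0
        assert fisher_right_tail(ContingencyTable(0, 5, 0, 5)) == 1.0


class TestBhAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.1], [0.01, 0.1]),
    ])
    def test_reference_values(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(InvalidInputError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=40))
    def test_matches_textbook_step_up(self, p):
        got = bh_adjust(p)
        want = bh_step_up(p)
        assert got == pytest.approx(want, abs=1e-12)
        assert all(q >= pi for q, pi in zip(got, p))

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariant(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        direct = bh_adjust(p)
        permuted = bh_adjust([p[i] for i in idx])
        assert [direct[i] for i in idx] == pytest.approx(permuted, abs=1e-12)

    def test_vectorized_rows_agree_with_scalar_path(self, rng):
        p = rng.random((8, 15))
        rows = _bh_rows(p)
        for r in range(p.shape[0]):
            assert rows[r].tolist() == pytest.approx(bh_adjust(p[r]),
                                                     abs=1e-12)


class TestOverlapContingency:
    def test_disjoint(self):
        a = GeneSet("A", "A", frozenset(f"a{i}" for i in range(10)))
        b = GeneSet("B", "B", frozenset(f"b{i}" for i in range(10)))
        uni = a.members | b.members | {f"u{i}" for i in range(80)}
        assert overlap_contingency(a, b, uni) == ContingencyTable(0, 10, 10, 80)

    def test_identical(self):
        a = GeneSet("A", "A", frozenset(f"g{i}" for i in range(7)))
        uni = a.members | {f"u{i}" for i in range(43)}
        assert overlap_contingency(a, a, uni) == ContingencyTable(7, 0, 0, 43)

    def test_partial_overlap(self):
        shared = {f"s{i}" for i in range(5)}
        a = GeneSet("A", "A", frozenset(shared | {f"a{i}" for i in range(15)}))
        b = GeneSet("B", "B", frozenset(shared | {f"b{i}" for i in range(25)}))
        uni = a.members | b.members | {f"u{i}" for i in range(155)}
        assert overlap_contingency(a, b, uni) == \
            ContingencyTable(5, 15, 25, 155)

    def test_member_outside_universe_rejected(self):
        a = GeneSet("A", "A", frozenset({"g1"}))
        with pytest.raises(InvalidInputError):
            overlap_contingency(a, a, {"other"})


class TestBuildComembership:
    def test_pairwise_disjoint_collection_yields_no_edges(self, small_collection):
        net = build_comembership(small_collection)
        assert net.n_edges == 0
        assert net.n_tests == 45
        assert net.nodes == set(small_collection.set_ids)

    def test_planted_overlap_recovered_exactly(self):
        spec = SynthSpec(planted_overlap_pairs=[(0, 1, 15)])
        net = build_comembership(gen_collection(spec))
        assert net.edge_pairs == {("S000", "S001")}
        assert net.edges[0].table.a == 15

    def test_single_set_collection_is_edgeless(self):
        coll = make_collection({"A": {"g1", "g2"}})
        net = build_comembership(coll)
        assert net.n_edges == 0 and net.n_tests == 0

    def test_set_order_does_not_change_edges(self):
        spec = SynthSpec(n_sets=8, planted_overlap_pairs=[(0, 1, 15)])
        coll = gen_collection(spec)
        reordered = GeneSetCollection(id=coll.id, sets=list(reversed(coll.sets)))
        assert build_comembership(coll).edge_pairs == \
            build_comembership(reordered).edge_pairs

    def test_edge_p_matches_exact_enumeration(self):
        coll = make_collection({
            "A": {"g1", "g2", "g3"}, "B": {"g2", "g3", "g4"},
            "C": {"g5", "g6"},
        })
        net = build_comembership(coll, BuildConfig(alpha=1.0))
        edge = {e.pair: e for e in net.edges}[("A", "B")]
        t = edge.table
        assert edge.p_raw == pytest.approx(
            float(hypergeom_tail_exact(t.a, t.b, t.c, t.d)), abs=1e-12)


class TestLinkageContingency:
    def test_no_touching_edges(self):
        net = MoleculeNetwork.from_edges(
            [("x1", "x2"), ("x3", "x4"), ("x5", "x6"), ("x7", "x8")])
        tab = linkage_contingency({"a"}, {"b"}, net)
        assert tab == ContingencyTable(0, 0, 0, 4)

    def test_manual_edge_classification(self):
        net = MoleculeNetwork.from_edges(
            [("1", "3"), ("2", "5"), ("4", "6"), ("5", "6")])
        tab = linkage_contingency({"1", "2"}, {"3", "4"}, net)
        assert tab == ContingencyTable(1, 1, 1, 1)

    def test_intra_set_edge_counts_in_own_margin_only(self):
        net = MoleculeNetwork.from_edges([("1", "2")])
        tab = linkage_contingency({"1", "2"}, {"3"}, net)
        assert tab == ContingencyTable(0, 1, 0, 0)

    def test_overlapping_inputs_rejected(self):
        net = MoleculeNetwork.from_edges([("1", "2")])
        with pytest.raises(InvalidInputError):
            linkage_contingency({"1"}, {"1", "3"}, net)


class TestBuildLinkage:
    def test_empty_reference_network_gives_no_edges(self, small_collection):
        net = build_linkage(small_collection, MoleculeNetwork())
        assert net.n_edges == 0

    def test_identical_sets_pair_untested(self):
        members = frozenset({"g1", "g2", "g3"})
        coll = GeneSetCollection(id="c", sets=[
            GeneSet("A", "A", members), GeneSet("B", "B", members)])
        mol = MoleculeNetwork.from_edges([("g1", "g2")])
        net = build_linkage(coll, mol, BuildConfig(alpha=1.0))
        # residuals are empty: the pair is degenerate with p = 1, no edge
        assert net.edge_pairs == set() or all(
            e.p_raw == 1.0 for e in net.edges)

    def test_planted_bundle_recovered_exactly(self):
        spec = SynthSpec(n_sets=10, planted_linkage_pairs=[(0, 1, 20)])
        coll = gen_collection(spec)
        mol = gen_molecule_network(coll, spec)
        net = build_linkage(coll, mol)
        assert net.edge_pairs == {("S000", "S001")}

    def test_shared_genes_do_not_change_residual_test(self):
        spec = SynthSpec(n_sets=6, planted_linkage_pairs=[(0, 1, 15)],
                         background_edge_prob=0.001)
        coll = gen_collection(spec)
        mol = gen_molecule_network(coll, spec)
        base = build_linkage(coll, mol, BuildConfig(alpha=1.0))
        # give sets 0 and 1 an identical extra gene: residuals are unchanged
        extra = "gSHARED"
        sets = [GeneSet(s.id, s.name, s.members | {extra}) if i < 2 else s
                for i, s in enumerate(coll.sets)]
        coll2 = GeneSetCollection(id=coll.id, sets=sets)
        mod = build_linkage(coll2, mol, BuildConfig(alpha=1.0))
        p_base = {e.pair: e.p_raw for e in base.edges}
        p_mod = {e.pair: e.p_raw for e in mod.edges}
        assert p_base[("S000", "S001")] == \
            pytest.approx(p_mod[("S000", "S001")], abs=1e-12)

    def test_pair_table_matches_direct_count(self):
        spec = SynthSpec(n_sets=5, background_edge_prob=0.004)
        coll = gen_collection(spec)
        mol = gen_molecule_network(coll, spec)
        net = build_linkage(coll, mol, BuildConfig(alpha=1.0))
        tables = {e.pair: e.table for e in net.edges}
        for e_pair, tab in tables.items():
            sa = coll[e_pair[0]].members
            sb = coll[e_pair[1]].members
            want = linkage_contingency(sa - sb, sb - sa,
                                       mol.restrict(coll.universe))
            assert tab == want


class TestPerListEnrichment:
    def _sets(self):
        return [GeneSet("S", "S", frozenset(f"s{i}" for i in range(10)))]

    def test_list_equal_to_universe_gives_p_one(self):
        sets = self._sets()
        uni = sets[0].members | {f"u{i}" for i in range(90)}
        gl = ExperimentGeneList("L", "", frozenset(uni))
        res = per_list_enrichment(sets, gl, uni)
        assert res[0].p_raw == 1.0 and not res[0].enriched

    def test_disjoint_list_gives_p_one(self):
        sets = self._sets()
        uni = sets[0].members | {f"u{i}" for i in range(90)}
        gl = ExperimentGeneList("L", "", frozenset(f"u{i}" for i in range(10)))
        assert per_list_enrichment(sets, gl, uni)[0].p_raw == 1.0

    def test_half_overlap_table(self):
        sets = self._sets()
        uni = sets[0].members | {f"u{i}" for i in range(90)}
        lst = frozenset(list(sets[0].members)[:5]) | \
            frozenset(f"u{i}" for i in range(5))
        gl = ExperimentGeneList("L", "", lst)
        res = per_list_enrichment(sets, gl, uni)[0]
        assert res.table == ContingencyTable(5, 5, 5, 85)
        assert res.p_raw == pytest.approx(
            float(hypergeom_tail_exact(5, 5, 5, 85)), abs=1e-12)

    def test_list_outside_universe_warns_and_degenerates(self, caplog):
        sets = self._sets()
        uni = sets[0].members
        gl = ExperimentGeneList("L", "", frozenset({"nowhere"}))
        with caplog.at_level("WARNING", logger="gsnet"):
            res = per_list_enrichment(sets, gl, uni)
        assert res[0].p_raw == 1.0 and not res[0].enriched
        assert "no genes" in caplog.text


class TestBuildCoenrichment:
    def test_never_enriched_compendium_gives_no_edges(self, small_collection):
        lists = [ExperimentGeneList(f"L{i}", "", frozenset({f"g{i:03d}"}))
                 for i in range(5)]
        comp = GeneListCompendium("c", lists)
        assert build_coenrichment(small_collection, comp).n_edges == 0

    def test_identical_pair_gets_no_edge(self):
        members = frozenset(f"g{i}" for i in range(10))
        coll = GeneSetCollection(id="c", sets=[
            GeneSet("A", "A", members), GeneSet("B", "B", members)])
        comp = GeneListCompendium("c", [
            ExperimentGeneList("L", "", frozenset(list(members)[:5]))])
        net = build_coenrichment(coll, comp)
        assert net.n_edges == 0

    def test_planted_coactivation_recovered_exactly(self):
        spec = SynthSpec(n_sets=12, n_lists=200,
                         planted_coactivation_pairs=[(0, 1, 0.3)])
        coll = gen_collection(spec)
        comp = gen_compendium(coll, spec)
        net = build_coenrichment(coll, comp)
        assert net.edge_pairs == {("S000", "S001")}

    def test_pair_counts_match_direct_recount(self):
        """m_A, m_B, m_AB recomputed by explicit per-list BH agree with the
        cached/vectorized path, and the pair p equals enumeration."""
        spec = SynthSpec(n_sets=6, n_lists=40, list_size=30,
                         planted_coactivation_pairs=[(0, 1, 0.4)])
        coll = gen_collection(spec)
        comp = gen_compendium(coll, spec)
        cfg = BuildConfig(alpha=1.0)
        net = build_coenrichment(coll, comp, cfg)
        edge = {e.pair: e for e in net.edges}[("S000", "S001")]
        a_set, b_set = coll["S000"], coll["S001"]
        res_a = GeneSet("A'", "", a_set.members - b_set.members)
        res_b = GeneSet("B'", "", b_set.members - a_set.members)
        family = list(coll.sets) + [res_a, res_b]
        m_a = m_b = m_ab = 0
        for gl in comp:
            res = per_list_enrichment(family, gl, coll.universe, cfg)
            ea = res[-2].enriched
            eb = res[-1].enriched
            m_a += ea
            m_b += eb
            m_ab += ea and eb
        assert edge.table == ContingencyTable(
            m_ab, m_a - m_ab, m_b - m_ab, len(comp) - m_a - m_b + m_ab)
        t = edge.table
        assert edge.p_raw == pytest.approx(
            float(hypergeom_tail_exact(t.a, t.b, t.c, t.d)), abs=1e-12)

    def test_shared_genes_removed_from_residual_inputs(self):
        """A gene added to both members of a pair never enters the pair's
        residual test: the build's stored counts equal a direct recount from
        the shared-gene-free residuals."""
        spec = SynthSpec(n_sets=6, n_lists=60,
                         planted_coactivation_pairs=[(0, 1, 0.4)])
        coll = gen_collection(spec)
        comp = gen_compendium(coll, spec)
        extra = "gSHARED"
        sets = [GeneSet(s.id, s.name, s.members | {extra}) if i < 2 else s
                for i, s in enumerate(coll.sets)]
        coll2 = GeneSetCollection(id=coll.id, sets=sets)
        res_a = coll2["S000"].members - coll2["S001"].members
        res_b = coll2["S001"].members - coll2["S000"].members
        assert extra not in res_a | res_b
        assert res_a == coll["S000"].members - coll["S001"].members
        cfg = BuildConfig(alpha=1.0)
        net = build_coenrichment(coll2, comp, cfg)
        edge = {e.pair: e for e in net.edges}[("S000", "S001")]
        family = list(coll2.sets) + [GeneSet("A'", "", res_a),
                                     GeneSet("B'", "", res_b)]
        m_a = m_b = m_ab = 0
        for gl in comp:
            res = per_list_enrichment(family, gl, coll2.universe, cfg)
            m_a += res[-2].enriched
            m_b += res[-1].enriched
            m_ab += res[-2].enriched and res[-1].enriched
        assert edge.table == ContingencyTable(
            m_ab, m_a - m_ab, m_b - m_ab, len(comp) - m_a - m_b + m_ab)

    def test_empty_compendium_rejected(self, small_collection):
        with pytest.raises(InvalidInputError):
            build_coenrichment(small_collection, GeneListCompendium("c", []))


class TestBuilderFamilySizes:
    @pytest.mark.parametrize("n", [3, 7])
    def test_number_of_tests_is_all_pairs(self, n):
        genes = [f"g{k}" for k in range(5 * n)]
        coll = make_collection(
            {f"S{i}": set(genes[5 * i:5 * (i + 1)]) for i in range(n)})
        mol = MoleculeNetwork.from_edges([(genes[0], genes[5])])
        comp = GeneListCompendium("c", [
            ExperimentGeneList("L", "", frozenset(genes[:3]))])
        expected = n * (n - 1) // 2
        assert build_comembership(coll).n_tests == expected
        assert build_linkage(coll, mol).n_tests == expected
        assert build_coenrichment(coll, comp).n_tests == expected
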