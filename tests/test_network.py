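"""Signed network assembly, PPI projection, DEG overlay, neighborhood."""

import numpy as np
import pytest

from coexkit import (
    ASCENDING,
    DESCENDING,
    DataError,
    DEGRecord,
    DEGTable,
    OrthologMap,
    build_signed_network,
    generate_ortholog_fixture,
    mutual_rank,
    neighborhood,
    overlay_degs,
    pearson_matrix,
    project_ppi,
    rank_matrix,
)
from coexkit.coexpr import CorrelationMatrix, MutualRankMatrix
from coexkit.network import CoexpressionEdge, Network

from test_coexpr import expr_from


def hand_built(pcc_pairs, mr_pos_pairs, mr_neg_pairs, ids):
    """Construct corr/MR matrices directly so boundary values are exact."""
    g = len(ids)

    def mat(pairs, diag):
        m = np.full((g, g), np.nan)
        np.fill_diagonal(m, diag)
        for (i, j), v in pairs.items():
            m[i, j] = m[j, i] = v
        return m

    corr = mat(pcc_pairs, 1.0)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    c = CorrelationMatrix(ids, corr, np.ones((g, g), dtype=bool))
    big = {  # unspecified pairs rank far outside any cut
        (i, j): 1000.0 for i in range(g) for j in range(i + 1, g)
    }
    mp = MutualRankMatrix(ids, mat({**big, **mr_pos_pairs}, np.nan), DESCENDING)
    mn = MutualRankMatrix(ids, mat({**big, **mr_neg_pairs}, np.nan), ASCENDING)
    return c, mp, mn


class TestThresholdSemantics:
    IDS = ["a", "b", "c", "d", "e", "f", "g", "h"]

    def build(self, **kwargs):
        # pair (a,b): PCC 0.65, MR_pos 30  -> positive edge
        # pair (c,d): PCC 0.65, MR_pos 60  -> excluded (MR too high)
        # pair (e,f): PCC -0.55, MR_neg 30 -> negative edge
        # pair (g,h): boundary PCC 0.6 / MR 50 exactly -> excluded (strict)
        c, mp, mn = hand_built(
            {(0, 1): 0.65, (2, 3): 0.65, (4, 5): -0.55, (6, 7): 0.6},
            {(0, 1): 30.0, (2, 3): 60.0, (6, 7): 50.0},
            {(4, 5): 30.0},
            self.IDS,
        )
        return build_signed_network(c, mp, mn, top_k=0, **kwargs)

    def test_operating_point_inclusion(self):
        net = self.build()
        assert net.has_edge("a", "b")
        assert net.edge_data("a", "b")["sign"] == "positive"
        assert net.edge_data("a", "b")["origin"] == "threshold"

    def test_high_mr_excluded(self):
        assert not self.build().has_edge("c", "d")

    def test_negative_operating_point(self):
        net = self.build()
        assert net.has_edge("e", "f")
        assert net.edge_data("e", "f")["sign"] == "negative"

    def test_boundaries_are_strict(self):
        # PCC exactly 0.6 fails PCC > 0.6; MR exactly 50 fails MR < 50
        net = self.build()
        assert not net.has_edge("g", "h")
        c, mp, mn = hand_built(
            {(0, 1): 0.65}, {(0, 1): 50.0}, {}, self.IDS
        )
        assert not build_signed_network(c, mp, mn, top_k=0).has_edge("a", "b")

    def test_isolated_nodes_present(self):
        net = self.build()
        assert net.n_nodes == 8


class TestTopK:
    def random_inputs(self, seed=0, g=12, s=8):
        rng = np.random.default_rng(seed)
        c = pearson_matrix(expr_from(rng.uniform(0, 10, size=(g, s))))
        mp = mutual_rank(rank_matrix(c, DESCENDING))
        mn = mutual_rank(rank_matrix(c, ASCENDING))
        return c, mp, mn

    def test_sub_threshold_best_partners_retained(self):
        # gene with best partner PCC ~0.4 still gets its top-3, origin topk
        ids = ["a", "b", "c", "d", "e"]
        c, mp, mn = hand_built(
            {(0, 1): 0.4, (0, 2): 0.3, (0, 3): 0.2, (0, 4): 0.1},
            {},
            {},
            ids,
        )
        net = build_signed_network(c, mp, mn, top_k=3)
        nbrs = {e.gene_b if e.gene_a == "a" else e.gene_a for e in neighborhood(net, "a")}
        assert {"b", "c", "d"} <= nbrs
        assert net.edge_data("a", "b")["origin"] == "topk"

    def test_origin_both_when_topk_also_passes(self):
        ids = ["a", "b", "c"]
        c, mp, mn = hand_built({(0, 1): 0.9, (0, 2): 0.1, (1, 2): 0.1}, {(0, 1): 2.0}, {}, ids)
        net = build_signed_network(c, mp, mn, top_k=1)
        assert net.edge_data("a", "b")["origin"] == "both"

    def test_union_never_removes_threshold_edges(self):
        c, mp, mn = self.random_inputs()
        base = {(e.gene_a, e.gene_b) for e in build_signed_network(c, mp, mn, top_k=0).edges()}
        with_topk = {
            (e.gene_a, e.gene_b) for e in build_signed_network(c, mp, mn, top_k=3).edges()
        }
        assert base <= with_topk

    def test_cap_mode_restricts_to_topk(self):
        c, mp, mn = self.random_inputs(seed=4)
        capped = build_signed_network(
            c, mp, mn, pcc_pos_cut=0.1, mr_cut=1000, top_k=1, topk_mode="cap"
        )
        for e in capped.edges("positive"):
            # every positive edge must be in some endpoint's top-1 list
            from coexkit import topk_partners

            tops = topk_partners(c, 1)
            assert (e.gene_b, pytest.approx(e.pcc)) in tops[e.gene_a] or (
                e.gene_a,
                pytest.approx(e.pcc),
            ) in tops[e.gene_b]

    def test_signs_disjoint_by_construction(self, synthetic_run_anticorrelated):
        _, _, corr, mr_pos, mr_neg = synthetic_run_anticorrelated
        net = build_signed_network(corr, mr_pos, mr_neg)
        for e in net.edges():
            assert (e.sign == "positive") == (e.pcc > 0)


class TestMonotonicityAndReduction:
    def test_loosening_thresholds_never_removes_edges(self):
        rng = np.random.default_rng(8)
        c = pearson_matrix(expr_from(rng.uniform(0, 10, size=(15, 8))))
        mp = mutual_rank(rank_matrix(c, DESCENDING))
        mn = mutual_rank(rank_matrix(c, ASCENDING))
        grids = [(p, m) for p in (0.7, 0.5, 0.3) for m in (3.0, 6.0, 12.0)]
        edge_sets = {
            (p, m): {
                (e.gene_a, e.gene_b)
                for e in build_signed_network(
                    c, mp, mn, pcc_pos_cut=p, mr_cut=m, top_k=0
                ).edges()
            }
            for p, m in grids
        }
        for p1, m1 in grids:
            for p2, m2 in grids:
                if p2 <= p1 and m2 >= m1:  # (p2, m2) at least as loose
                    assert edge_sets[(p1, m1)] <= edge_sets[(p2, m2)]

    def test_reduces_to_plain_pcc_thresholding(self):
        rng = np.random.default_rng(2)
        c = pearson_matrix(expr_from(rng.uniform(0, 10, size=(10, 8))))
        mp = mutual_rank(rank_matrix(c, DESCENDING))
        mn = mutual_rank(rank_matrix(c, ASCENDING))
        net = build_signed_network(c, mp, mn, pcc_pos_cut=0.4, mr_cut=np.inf, top_k=0)
        expected = {
            tuple(sorted((c.gene_ids[i], c.gene_ids[j])))
            for i in range(10)
            for j in range(i + 1, 10)
            if c.values[i, j] > 0.4
        }
        assert {(e.gene_a, e.gene_b) for e in net.edges("positive")} == expected


def brute_force_projection(mapping, source_edges):
    out = set()
    for s1, s2 in source_edges:
        for t1 in mapping.get(s1, set()):
            for t2 in mapping.get(s2, set()):
                if t1 != t2:
                    out.add((min(t1, t2), max(t1, t2)))
    return sorted(out)


class TestProjectPpi:
    def test_one_to_one_edge(self):
        omap = OrthologMap([("a1", "t1"), ("a2", "t2")])
        edges, n_un = project_ppi(omap, [("a1", "a2")])
        assert edges == [("t1", "t2")] and n_un == 0

    def test_many_to_many_join(self):
        omap = OrthologMap([("a1", "t1"), ("a1", "t2"), ("a2", "t3")])
        edges, _ = project_ppi(omap, [("a1", "a2")])
        assert edges == [("t1", "t3"), ("t2", "t3")]

    def test_self_loop_dropped(self):
        omap = OrthologMap([("a1", "t1"), ("a2", "t1")])
        edges, n_un = project_ppi(omap, [("a1", "a2")])
        assert edges == [] and n_un == 1

    def test_unprojected_counted(self):
        omap = OrthologMap([("a1", "t1")])
        _, n_un = project_ppi(omap, [("a1", "a2"), ("a3", "a4")])
        assert n_un == 2

    def test_matches_nested_loop_oracle_on_fixtures(self):
        for seed in (0, 1, 2):
            omap, edges = generate_ortholog_fixture(30, 25, 0.3, seed=seed)
            got, _ = project_ppi(omap, edges)
            assert got == brute_force_projection(omap.as_dict(), edges)

    def test_empty_map_warns(self):
        import warnings

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            edges, _ = project_ppi(OrthologMap([]), [("a", "b")])
        assert edges == [] and caught


def star_network():
    net = Network()
    for i, (nbr, pcc) in enumerate([("b", 0.9), ("c", 0.8), ("d", -0.7), ("e", 0.65)]):
        a, b = sorted(("a", nbr))
        net.add_edge(
            CoexpressionEdge(a, b, pcc, float(i + 2), "positive" if pcc > 0 else "negative", "threshold")
        )
    return net


class TestOverlayAndNeighborhood:
    def test_overlay_sets_status(self):
        net = star_network()
        degs = DEGTable([DEGRecord("a", "c1", "up"), DEGRecord("b", "c1", "down")])
        net, n_missing = overlay_degs(net, degs, "c1")
        assert net.graph.nodes["a"]["deg::c1"] == "up"
        assert net.graph.nodes["b"]["deg::c1"] == "down"
        assert net.graph.nodes["c"]["deg::c1"] == "none"
        assert n_missing == 0

    def test_absent_deg_gene_ignored_and_counted(self):
        net = star_network()
        degs = DEGTable([DEGRecord("zzz", "c1", "up"), DEGRecord("a", "c1", "down")])
        n_edges = net.n_edges
        net, n_missing = overlay_degs(net, degs, "c1")
        assert n_missing == 1 and net.n_edges == n_edges  # topology unchanged

    def test_contrasts_are_independent_columns(self):
        net = star_network()
        degs = DEGTable([DEGRecord("a", "c1", "up"), DEGRecord("a", "c2", "down")])
        net, _ = overlay_degs(net, degs, "c1")
        net, _ = overlay_degs(net, degs, "c2")
        assert net.graph.nodes["a"]["deg::c1"] == "up"
        assert net.graph.nodes["a"]["deg::c2"] == "down"

    def test_unknown_contrast_rejected(self):
        with pytest.raises(DataError):
            overlay_degs(star_network(), DEGTable([DEGRecord("a", "c1", "up")]), "c9")

    def test_star_center_filtered_by_sign(self):
        net = star_network()
        assert len(neighborhood(net, "a", "positive")) == 3
        assert len(neighborhood(net, "a", "negative")) == 1
        assert neighborhood(net, "b", "negative") == []

    def test_sorted_by_abs_pcc(self):
        edges = neighborhood(star_network(), "a")
        assert [abs(e.pcc) for e in edges] == [0.9, 0.8, 0.7, 0.65]

    def test_matches_brute_force_scan(self, synthetic_run):
        _, _, corr, mr_pos, mr_neg = synthetic_run
        net = build_signed_network(corr, mr_pos, mr_neg)
        gene = corr.gene_ids[0]
        expected = sorted(
            (e for e in net.edges() if gene in (e.gene_a, e.gene_b)),
            key=lambda e: (-abs(e.pcc), e.gene_a, e.gene_b),
        )
        assert neighborhood(net, gene) == expected

    def test_unknown_gene_rejected(self):
        with pytest.raises(DataError):
            neighborhood(star_network(), "nope")
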