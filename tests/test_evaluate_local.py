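"""Local ensemble metrics: TPR, KS, Ds/ANOVA, motifs, categories, leaf edges."""

import numpy as np
import pytest

from conftest import inferred_from_pairs
from grnilab import (
    ACTIVATOR,
    REPRESSOR,
    DirectedNetwork,
    EdgeStat,
    categorize_edges,
    categorize_tpr,
    classify_motif,
    ds_value,
    edge_sign_ks_test,
    edge_stats,
    edge_tpr,
    enumerate_motifs,
    leaf_edge_report,
    motif_trr,
    tpr_by_ds_anova,
)
from oracles import classify_motif_oracle, enumerate_motifs_oracle, trr_oracle


def stat(tpr, sign=ACTIVATOR, ds=2, edge=("A", "B")):
    return EdgeStat(edge, sign, tpr, ds, categorize_tpr(tpr))


class TestEdgeTpr:
    def test_fractions(self, chain_net):
        runs = [
            inferred_from_pairs(chain_net.nodes, [(0, 1), (1, 2)]),
            inferred_from_pairs(chain_net.nodes, [(0, 1)]),
            inferred_from_pairs(chain_net.nodes, []),
            inferred_from_pairs(chain_net.nodes, [(0, 1)]),
        ]
        tpr = edge_tpr(chain_net, runs)
        assert tpr[("A", "B")] == 0.75
        assert tpr[("B", "C")] == 0.25

    def test_empty_ensemble_rejected(self, chain_net):
        with pytest.raises(ValueError):
            edge_tpr(chain_net, [])


class TestKsTest:
    def test_identical_distributions(self):
        stats = [stat(t, ACTIVATOR) for t in (0.2, 0.4, 0.6)] + [
            stat(t, REPRESSOR) for t in (0.2, 0.4, 0.6)
        ]
        d, p, _ = edge_sign_ks_test(stats)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stats = [stat(t, ACTIVATOR) for t in (0.1, 0.2)] + [
            stat(t, REPRESSOR) for t in (0.8, 0.9)
        ]
        d, _, _ = edge_sign_ks_test(stats)
        assert d == 1.0

    def test_hand_computed_statistic(self):
        stats = [stat(t / 4, ACTIVATOR) for t in (1, 2, 3)] + [
            stat(t / 4, REPRESSOR) for t in (2, 3, 4)
        ]
        d, _, _ = edge_sign_ks_test(stats)
        assert d == pytest.approx(1 / 3)

    def test_missing_class_named(self):
        with pytest.raises(ValueError, match="repressor"):
            edge_sign_ks_test([stat(0.5, ACTIVATOR)])


class TestDs:
    def test_isolated_edge(self):
        net = DirectedNetwork(["A", "B"], {("A", "B")})
        assert ds_value(net, ("A", "B")) == 2

    def test_hand_counted(self):
        net = DirectedNetwork(["A", "B", "C", "D"], {("A", "B"), ("A", "C"), ("D", "B")})
        assert ds_value(net, ("A", "B")) == 2 + 2

    def test_out_edge_increments_source_term(self):
        base = DirectedNetwork(["A", "B", "C"], {("A", "B")})
        grown = DirectedNetwork(["A", "B", "C"], {("A", "B"), ("A", "C")})
        assert ds_value(grown, ("A", "B")) == ds_value(base, ("A", "B")) + 1

    def test_non_edge_rejected(self):
        net = DirectedNetwork(["A", "B"], {("A", "B")})
        with pytest.raises(ValueError):
            ds_value(net, ("B", "A"))


class TestAnova:
    def test_identical_groups(self):
        stats = [stat(t, ds=2) for t in (0.2, 0.4)] + [stat(t, ds=4) for t in (0.2, 0.4)]
        f, p, _ = tpr_by_ds_anova(stats)
        assert f == 0.0 and p == pytest.approx(1.0)

    def test_separated_groups(self):
        stats = [stat(0.0, ds=2), stat(0.0, ds=2), stat(1.0, ds=4), stat(1.0, ds=4)]
        _, p, _ = tpr_by_ds_anova(stats)
        assert p < 1e-6

    def test_hand_computed_f(self):
        stats = [stat(t, ds=2) for t in (0.1, 0.2, 0.3)] + [
            stat(t, ds=5) for t in (0.2, 0.3, 0.4)
        ]
        f, _, table = tpr_by_ds_anova(stats)
        assert f == pytest.approx(1.5)
        assert list(table["ds"]) == [2, 5]

    def test_single_edge_levels_kept_in_table_only(self):
        stats = [stat(0.1, ds=2), stat(0.2, ds=2), stat(0.3, ds=3),
                 stat(0.5, ds=4), stat(0.6, ds=4)]
        _, _, table = tpr_by_ds_anova(stats)
        assert list(table["ds"]) == [2, 3, 4]  # ds=3 shown though untestable


class TestMotifs:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ({("A", "B"), ("B", "C")}, "chain"),
            ({("A", "B"), ("C", "B")}, "collider"),
            ({("B", "A"), ("B", "C")}, "fork"),
            ({("A", "B"), ("B", "C"), ("A", "C")}, "triangle"),
            ({("A", "B"), ("B", "A")}, "none"),
            ({("A", "B")}, "none"),
        ],
    )
    def test_classification(self, edges, expected):
        assert classify_motif(("A", "B", "C"), edges) == expected

    def test_relabeling_invariance(self):
        import itertools

        edges = {("A", "B"), ("B", "C")}
        for perm in itertools.permutations(("A", "B", "C")):
            relabel = dict(zip(("A", "B", "C"), perm))
            remapped = {(relabel[u], relabel[v]) for u, v in edges}
            assert classify_motif(perm, remapped) == "chain"

    def test_wrong_node_count(self):
        with pytest.raises(ValueError):
            classify_motif(("A", "B"), set())

    def test_enumerate_chain_and_star(self, chain_net, star_net):
        chain_motifs = enumerate_motifs(chain_net)
        assert len(chain_motifs) == 1 and chain_motifs[0].type == "chain"
        star_motifs = enumerate_motifs(star_net)
        assert len(star_motifs) == 3
        assert all(m.type == "fork" for m in star_motifs)

    def test_empty_network(self):
        assert enumerate_motifs(DirectedNetwork(["A", "B", "C"])) == []

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_on_random_graphs(self, seed):
        from grnilab import generate_random

        net = generate_random(8, 0.3, seed)
        expected = enumerate_motifs_oracle(net.nodes, net.edges)
        got = {m.nodes: m.type for m in enumerate_motifs(net)}
        assert got == expected

    def test_classify_matches_oracle_on_random_triples(self):
        rng = np.random.default_rng(0)
        nodes = ("X", "Y", "Z")
        pairs = [(u, v) for u in nodes for v in nodes if u != v]
        for _ in range(300):
            k = rng.integers(0, 5)
            chosen = rng.choice(len(pairs), size=k, replace=False)
            edges = {pairs[i] for i in chosen}
            assert classify_motif(nodes, edges) == classify_motif_oracle(nodes, edges)


class TestMotifTrr:
    def test_perfect_ensemble(self, chain_net):
        runs = [inferred_from_pairs(chain_net.nodes, [(0, 1), (1, 2)])] * 3
        summary = motif_trr(enumerate_motifs(chain_net), chain_net, runs)
        assert summary["chain"].mean_trr == 1.0

    def test_empty_ensemble_rates(self, chain_net):
        runs = [inferred_from_pairs(chain_net.nodes, [])] * 3
        summary = motif_trr(enumerate_motifs(chain_net), chain_net, runs)
        assert summary["chain"].mean_trr == pytest.approx(1 / 3)
        # a triangle has no absent pair to score as a true negative
        tri = DirectedNetwork(["A", "B", "C"], {("A", "B"), ("B", "C"), ("A", "C")})
        summary = motif_trr(enumerate_motifs(tri), tri, [inferred_from_pairs(tri.nodes, [])])
        assert summary["triangle"].mean_trr == 0.0

    def test_half_recovered_chain(self, chain_net):
        runs = [
            inferred_from_pairs(chain_net.nodes, [(0, 1), (1, 2)]),
            inferred_from_pairs(chain_net.nodes, []),
        ]
        summary = motif_trr(enumerate_motifs(chain_net), chain_net, runs)
        assert summary["chain"].mean_trr == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_toy_ensembles(self, seed):
        from grnilab import generate_random

        rng = np.random.default_rng(seed)
        net = generate_random(8, 0.25, seed)
        pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        runs = []
        for _ in range(10):
            chosen = rng.choice(len(pairs), size=rng.integers(0, 10), replace=False)
            runs.append(inferred_from_pairs(net.nodes, [pairs[i] for i in chosen]))
        run_sets = [r.pairs() for r in runs]
        motifs = enumerate_motifs(net)
        summary = motif_trr(motifs, net, runs)
        per_type = {}
        for m in motifs:
            per_type.setdefault(m.type, []).append(trr_oracle(m.nodes, net.edges, run_sets))
        for t, vals in per_type.items():
            assert summary[t].count == len(vals)
            assert summary[t].mean_trr == pytest.approx(np.mean(vals))


class TestCategories:
    @pytest.mark.parametrize(
        "tpr,expected",
        [
            (0.8, "black"),
            (0.76, "black"),
            (0.75, "blue"),   # boundary belongs to the lower bin
            (0.5, "green"),
            (0.25, "red"),
            (0.0, "red"),
            (1.0, "black"),
        ],
    )
    def test_bin_boundaries(self, tpr, expected):
        assert categorize_tpr(tpr) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_tpr(1.2)

    def test_counts(self):
        stats = [stat(0.9, edge=("A", "B")), stat(0.1, edge=("B", "C"))]
        categories, counts = categorize_edges(stats)
        assert categories == {("A", "B"): "black", ("B", "C"): "red"}
        assert counts["black"] == counts["red"] == 1


class TestLeafEdges:
    def test_chain(self, chain_net):
        runs = [inferred_from_pairs(chain_net.nodes, [(1, 2)])] * 2
        stats = edge_stats(chain_net, runs)
        report = leaf_edge_report(chain_net, stats)
        assert report["leaf"] == 1.0      # B->C: C has in 1, out 0
        assert report["internal"] == 0.0  # A->B missed everywhere

    def test_star_all_leaf(self, star_net):
        stats = edge_stats(star_net, [inferred_from_pairs(star_net.nodes, [])])
        report = leaf_edge_report(star_net, stats)
        assert report["internal"] is None
        assert report["leaf"] == 0.0

    def test_cycle_has_no_leaf(self):
        net = DirectedNetwork(["A", "B"], {("A", "B"), ("B", "A")})
        stats = edge_stats(net, [inferred_from_pairs(net.nodes, [(0, 1)])])
        assert leaf_edge_report(net, stats)["leaf"] is None
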