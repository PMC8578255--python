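"""Co-expression construction, disparity backbone, core split, pathway layers."""

import numpy as np
import pytest

from plexprop.builders import (
    ExpressionMatrix,
    build_coexpression,
    build_pathway_layer,
    disparity_filter,
    disparity_pvalues,
    split_core_and_specific,
)
from plexprop.multiplex import Layer, canonical_edge
from plexprop.simulate import make_expression

from conftest import random_layer


class TestBuildCoexpression:
    def test_perfect_monotone_pair(self):
        x = ExpressionMatrix(
            genes=["g1", "g2"],
            samples=["s1", "s2", "s3", "s4"],
            values=np.array([[1, 2, 3, 4], [2, 4, 6, 8]]),
        )
        layer = build_coexpression(x, rho_cutoff=0.9)
        assert ("g1", "g2") in layer.edges
        assert layer.weights[("g1", "g2")] == pytest.approx(1.0)

    def test_constant_gene_excluded(self):
        x = ExpressionMatrix(
            genes=["flat", "g1", "g2"],
            samples=["s1", "s2", "s3", "s4"],
            values=np.array([[5, 5, 5, 5], [1, 2, 3, 4], [2, 4, 6, 8]]),
        )
        layer = build_coexpression(x, rho_cutoff=0.5)
        assert "flat" not in layer.nodes

    def test_too_few_samples_rejected(self):
        x = ExpressionMatrix(
            genes=["g1", "g2"], samples=["s1", "s2"], values=np.ones((2, 2))
        )
        with pytest.raises(ValueError, match="three samples"):
            build_coexpression(x)

    def test_anticorrelation_kept_with_absolute_weight(self):
        x = ExpressionMatrix(
            genes=["g1", "g2"],
            samples=["s1", "s2", "s3", "s4"],
            values=np.array([[1, 2, 3, 4], [8, 6, 4, 2]]),
        )
        layer = build_coexpression(x, rho_cutoff=0.75)
        assert layer.weights[("g1", "g2")] == pytest.approx(1.0)

    def test_block_structure_recovered(self):
        x = make_expression(
            n_blocks=2, genes_per_block=10, n_samples=100, latent_corr=0.9, seed=7
        )
        layer = build_coexpression(x, rho_cutoff=0.75)
        within = between = within_hit = between_hit = 0
        for i, g1 in enumerate(x.genes):
            for g2 in x.genes[i + 1 :]:
                same = g1[:2] == g2[:2]
                hit = canonical_edge(g1, g2) in layer.edges
                if same:
                    within += 1
                    within_hit += hit
                else:
                    between += 1
                    between_hit += hit
        assert within_hit / within > 0.9
        assert between_hit / between < 0.01

    def test_block_recovery_holds_across_seeds(self):
        for seed in range(20):
            x = make_expression(n_blocks=2, genes_per_block=5, n_samples=100, seed=seed)
            layer = build_coexpression(x, rho_cutoff=0.75)
            for e in layer.edges:
                assert e[0][:2] == e[1][:2], f"cross-block edge {e} at seed {seed}"


def brute_force_disparity(layer, alpha, or_rule=False):
    """Direct per-edge evaluation of (1-w)^(k-1), independent of the filter."""
    adj = layer.adjacency()
    kept = set()
    for u, v in layer.edges:
        ps = []
        for a, b in ((u, v), (v, u)):
            k = len(adj[a])
            total = sum(layer.weights[canonical_edge(a, x)] for x in adj[a])
            if k == 1:
                ps.append(1.0)
            else:
                ps.append((1.0 - layer.weights[canonical_edge(a, b)] / total) ** (k - 1))
        ok = (ps[0] < alpha or ps[1] < alpha) if or_rule else (ps[0] < alpha and ps[1] < alpha)
        if ok:
            kept.add((u, v))
    return kept


class TestDisparityFilter:
    def test_hand_pvalues_star(self):
        # node c with incident weights (6, 3, 1): normalized (0.6, 0.3, 0.1),
        # k=3, p = (0.4^2, 0.7^2, 0.9^2)
        layer = Layer(
            "w",
            [("c", "x"), ("c", "y"), ("c", "z")],
            weights={("c", "x"): 6, ("c", "y"): 3, ("c", "z"): 1},
        )
        ps = disparity_pvalues(layer)
        assert ps[("c", "x")][0] == pytest.approx(0.16)
        assert ps[("c", "y")][0] == pytest.approx(0.49)
        assert ps[("c", "z")][0] == pytest.approx(0.81)

    def test_degree_two_equal_weights_fail(self):
        layer = Layer(
            "w", [("a", "b"), ("b", "c")], weights={("a", "b"): 1, ("b", "c"): 1}
        )
        ps = disparity_pvalues(layer)
        # from b's side: w = 0.5, k = 2 -> p = 0.5 for both edges
        assert ps[("a", "b")][1] == pytest.approx(0.5)
        assert disparity_filter(layer, alpha=0.05).n_edges == 0

    def test_pendant_edges_never_pass_and_rule(self):
        layer = Layer("w", [("a", "b")], weights={("a", "b"): 3.0})
        ps = disparity_pvalues(layer)
        assert ps[("a", "b")] == (1.0, 1.0)  # (1-1)^0 defined as 1
        assert disparity_filter(layer, alpha=0.5).n_edges == 0

    def test_missing_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            disparity_filter(Layer("u", [("a", "b")]))

    @pytest.mark.parametrize("or_rule", [False, True])
    def test_matches_brute_force_on_random_graphs(self, or_rule):
        for seed in range(50):
            layer = random_layer(12, 20, seed=seed, weighted=True)
            for alpha in (0.05, 0.3, 0.7):
                expected = brute_force_disparity(layer, alpha, or_rule=or_rule)
                got = disparity_filter(layer, alpha=alpha, or_rule=or_rule).edges
                assert got == expected, (seed, alpha)

    def test_output_subset_and_monotone_in_alpha(self):
        for seed in range(10):
            layer = random_layer(12, 25, seed=seed, weighted=True)
            prev = set()
            for alpha in (0.01, 0.05, 0.2, 0.5, 0.9):
                kept = disparity_filter(layer, alpha=alpha).edges
                assert kept <= layer.edges
                assert prev <= kept  # larger alpha keeps at least as much
                prev = set(kept)


class TestSplitCoreAndSpecific:
    def _layers(self):
        return [
            Layer("t1", [("a", "b"), ("x", "y")]),
            Layer("t2", [("a", "b"), ("p", "q")]),
            Layer("t3", [("a", "b")]),
        ]

    def test_threshold_membership(self):
        core, specific = split_core_and_specific(self._layers(), min_count=3)
        assert ("a", "b") in core.edges
        assert all(("a", "b") not in s.edges for s in specific)

    def test_private_edge_stays_specific(self):
        core, specific = split_core_and_specific(self._layers(), min_count=2)
        assert ("x", "y") not in core.edges
        assert ("x", "y") in specific[0].edges

    def test_min_count_one_moves_everything_to_core(self):
        layers = self._layers()
        core, specific = split_core_and_specific(layers, min_count=1)
        assert core.edges == frozenset().union(*(l.edges for l in layers))
        assert all(s.n_edges == 0 for s in specific)

    def test_partition_no_edge_lost_or_duplicated(self):
        layers = [random_layer(15, 25, seed=s, name=f"t{s}") for s in range(4)]
        core, specific = split_core_and_specific(layers, min_count=2)
        for l, s in zip(layers, specific):
            assert s.edges | (l.edges & core.edges) == l.edges
            assert s.edges & core.edges == frozenset()


class TestBuildPathwayLayer:
    def test_shared_set_threshold(self):
        sets = {f"S{i}": {"g1", "g2"} for i in range(5)}
        sets["S5"] = {"g1", "g3"}
        layer = build_pathway_layer(sets, min_shared=5)
        assert ("g1", "g2") in layer.edges
        assert ("g1", "g3") not in layer.edges

    def test_below_threshold_absent(self):
        sets = {f"S{i}": {"g1", "g2"} for i in range(4)}
        assert build_pathway_layer(sets, min_shared=5).n_edges == 0

    def test_min_shared_one_is_comembership_graph(self):
        sets = {"S1": {"a", "b"}, "S2": {"b", "c"}}
        layer = build_pathway_layer(sets, min_shared=1)
        assert layer.edges == frozenset({("a", "b"), ("b", "c")})

    def test_empty_collection(self):
        assert build_pathway_layer({}, min_shared=1).n_edges == 0
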