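"""Relevance weighting, layer kernel, and the informed random walk."""

import math

import numpy as np
import pytest

from plexprop.multiplex import Layer, MultiplexNetwork
from plexprop.propagation import (
    RelevanceProfile,
    SeedVector,
    aggregate_and_rank,
    informed_rwr,
    layer_transition_kernel,
    relevance_scores,
    solve_rwr_exact,
)

from conftest import er_layer, random_layer


def random_pi(n_layers, rng):
    pi = rng.random(n_layers) + 1e-3
    pi /= pi.sum()
    return RelevanceProfile(
        pi={f"l{i}": float(pi[i]) for i in range(n_layers)},
        informative=tuple(f"l{i}" for i in range(n_layers)),
    )


class TestRelevanceScores:
    def test_hand_normalization(self):
        prof = relevance_scores({"L1": 3.29, "L2": 1.0, "L3": 6.58})
        assert prof.informative == ("L1", "L3")
        assert prof.pi["L1"] == pytest.approx(3.29 / 9.87)
        assert prof.pi["L2"] == 0.0
        assert prof.pi["L3"] == pytest.approx(6.58 / 9.87)

    def test_single_layer_above_threshold(self):
        prof = relevance_scores({"L1": 2.0, "L2": 0.5})
        assert prof.pi == {"L1": 1.0, "L2": 0.0}

    def test_uniform_fallback_when_nothing_informative(self):
        prof = relevance_scores({"L1": 0.2, "L2": -1.0})
        assert prof.fallback
        assert prof.pi == {"L1": 0.5, "L2": 0.5}

    def test_nan_z_treated_as_uninformative(self):
        prof = relevance_scores({"L1": float("nan"), "L2": 3.0})
        assert prof.informative == ("L2",)

    def test_pi_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = {f"l{i}": float(rng.normal(2, 2)) for i in range(5)}
            prof = relevance_scores(z)
            assert sum(prof.pi.values()) == pytest.approx(1.0, abs=1e-12)


class TestLayerKernel:
    def test_hand_metropolis_values(self):
        prof = RelevanceProfile(pi={"a": 0.75, "b": 0.25}, informative=("a", "b"))
        k = layer_transition_kernel(prof)
        assert k.t[0, 1] == pytest.approx(1 / 6)
        assert k.t[1, 0] == pytest.approx(1 / 2)
        assert k.t[0, 0] == pytest.approx(5 / 6)
        assert k.t[1, 1] == pytest.approx(1 / 2)
        # stationarity of the 2-state chain: 0.75 * 1/6 == 0.25 * 1/2
        assert 0.75 * k.t[0, 1] == pytest.approx(0.25 * k.t[1, 0])

    def test_uniform_pi_gives_flat_kernel(self):
        prof = RelevanceProfile.uniform(["a", "b", "c"])
        k = layer_transition_kernel(prof)
        assert np.allclose(k.t, 1 / 3)

    def test_single_layer_kernel(self):
        k = layer_transition_kernel(RelevanceProfile.single("only"))
        assert k.t.shape == (1, 1) and k.t[0, 0] == 1.0

    def test_rows_stochastic_balance_and_stationarity(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            L = int(rng.integers(2, 8))
            prof = random_pi(L, rng)
            k = layer_transition_kernel(prof)
            assert np.allclose(k.t.sum(axis=1), 1.0, atol=1e-12)
            assert (np.diag(k.t) >= 0).all()
            for n in range(L):
                for m in range(L):
                    assert abs(k.pi[n] * k.t[n, m] - k.pi[m] * k.t[m, n]) < 1e-12
            assert np.abs(k.pi @ k.t - k.pi).max() < 1e-12


def two_layer_fixture(seed=0):
    a = er_layer(12, 0.3, seed=seed, name="a")
    b = er_layer(12, 0.3, seed=seed + 100, name="b")
    return MultiplexNetwork([a, b])


class TestInformedRWR:
    def test_restart_one_returns_seed_distribution(self):
        m = two_layer_fixture()
        kernel = layer_transition_kernel(RelevanceProfile.uniform(m.layer_names))
        seeds = SeedVector.uniform(sorted(m.universe)[:3])
        res = informed_rwr(m, kernel, seeds, r=1.0)
        for g, w in seeds.weights.items():
            for ln in kernel.layer_names:
                assert res.visiting_probability(g, ln) == pytest.approx(w / 2)

    def test_total_probability_conserved(self):
        m = two_layer_fixture(3)
        kernel = layer_transition_kernel(
            RelevanceProfile(pi={"a": 0.8, "b": 0.2}, informative=("a", "b"))
        )
        seeds = SeedVector.uniform(sorted(m.universe)[:2])
        res = informed_rwr(m, kernel, seeds)
        assert res.visiting.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.converged

    def test_single_layer_matches_classical_rwr_linear_solve(self):
        layer = er_layer(30, 0.15, seed=7, name="only")
        m = MultiplexNetwork([layer])
        kernel = layer_transition_kernel(RelevanceProfile.single("only"))
        seeds = SeedVector.uniform(sorted(m.universe)[:4])
        res = informed_rwr(m, kernel, seeds, r=0.7, tol=1e-14)
        # independent oracle: direct solve of p = (1-r) W p + r p0 with a
        # column-normalized adjacency matrix built from scratch
        genes = sorted(m.universe)
        idx = {g: i for i, g in enumerate(genes)}
        W = np.zeros((len(genes), len(genes)))
        adj = layer.adjacency()
        for g in genes:
            for h in adj.get(g, ()):  # column-stochastic
                W[idx[h], idx[g]] = 1 / len(adj[g])
        p0 = np.zeros(len(genes))
        for g, w in seeds.weights.items():
            p0[idx[g]] = w
        p = np.linalg.solve(np.eye(len(genes)) - 0.3 * W, 0.7 * p0)
        got = np.array([res.visiting_probability(g, "only") for g in genes])
        assert np.abs(got - p).max() < 1e-8

    def test_iterative_matches_direct_solver_two_layers(self):
        m = two_layer_fixture(11)
        kernel = layer_transition_kernel(
            RelevanceProfile(pi={"a": 0.6, "b": 0.4}, informative=("a", "b"))
        )
        seeds = SeedVector.uniform(sorted(m.universe)[:3])
        it = informed_rwr(m, kernel, seeds, tol=1e-14)
        ex = solve_rwr_exact(m, kernel, seeds)
        assert np.abs(it.visiting - ex.visiting).max() < 1e-10

    def test_relevant_layer_weighting_prefers_its_neighbors(self):
        # seed's neighbors differ by layer; pi concentrated on layer a
        a = Layer("a", [("s", "x"), ("x", "q")])
        b = Layer("b", [("s", "y"), ("y", "q")])
        m = MultiplexNetwork([a, b])
        prof = relevance_scores({"a": 5.0, "b": 0.0})
        kernel = layer_transition_kernel(prof)
        seeds = SeedVector.uniform(["s"])
        res = informed_rwr(m, kernel, seeds)
        scores = res.aggregated
        assert scores["x"] > scores["y"]

    def test_seeds_outside_universe_rejected(self):
        m = two_layer_fixture()
        with pytest.raises(ValueError, match="universe"):
            informed_rwr(
                m,
                layer_transition_kernel(RelevanceProfile.uniform(m.layer_names)),
                SeedVector.uniform(["nope"]),
            )

    def test_nonconvergence_flagged(self):
        m = two_layer_fixture()
        kernel = layer_transition_kernel(RelevanceProfile.uniform(m.layer_names))
        seeds = SeedVector.uniform(sorted(m.universe)[:2])
        with pytest.warns(UserWarning, match="converge"):
            res = informed_rwr(m, kernel, seeds, tol=1e-16, max_iter=3)
        assert not res.converged

    def test_dangling_mass_redirected_keeps_operator_stochastic(self):
        # gene z exists only in layer b; in layer a its intra-layer mass
        # must return to the seeds rather than vanish
        a = Layer("a", [("s", "x")])
        b = Layer("b", [("s", "z"), ("z", "x")])
        m = MultiplexNetwork([a, b])
        kernel = layer_transition_kernel(RelevanceProfile.uniform(["a", "b"]))
        seeds = SeedVector.uniform(["s"])
        res = informed_rwr(m, kernel, seeds, tol=1e-12)
        assert res.visiting.sum() == pytest.approx(1.0, abs=1e-9)
        ex = solve_rwr_exact(m, kernel, seeds)
        assert np.abs(res.visiting - ex.visiting).max() < 1e-9

    def test_stay_policy_also_stochastic(self):
        a = Layer("a", [("s", "x")])
        b = Layer("b", [("s", "z"), ("z", "x")])
        m = MultiplexNetwork([a, b])
        kernel = layer_transition_kernel(RelevanceProfile.uniform(["a", "b"]))
        res = informed_rwr(
            m, kernel, SeedVector.uniform(["s"]), dangling_policy="stay", tol=1e-12
        )
        assert res.visiting.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fixed_point_residual(self):
        m = two_layer_fixture(5)
        kernel = layer_transition_kernel(
            RelevanceProfile(pi={"a": 0.7, "b": 0.3}, informative=("a", "b"))
        )
        seeds = SeedVector.uniform(sorted(m.universe)[:2])
        res = informed_rwr(m, kernel, seeds, tol=1e-8)
        assert res.residual < 10 * 1e-8


class TestAggregateAndRank:
    def _result(self):
        m = two_layer_fixture(9)
        kernel = layer_transition_kernel(RelevanceProfile.uniform(m.layer_names))
        seeds = SeedVector.uniform(sorted(m.universe)[:3])
        return informed_rwr(m, kernel, seeds), seeds

    def test_seeds_omitted_by_default(self):
        res, seeds = self._result()
        ranking = aggregate_and_rank(res, seeds)
        assert not any(g in seeds.support for g, _ in ranking)

    def test_all_candidates_seeds_gives_empty_ranking(self):
        res, seeds = self._result()
        with pytest.warns(UserWarning):
            ranking = aggregate_and_rank(res, seeds, restrict_to=set(seeds.support))
        assert ranking == []

    def test_restriction_disjoint_from_universe_warns(self):
        res, seeds = self._result()
        with pytest.warns(UserWarning):
            assert aggregate_and_rank(res, seeds, restrict_to={"absent"}) == []

    def test_ties_broken_lexicographically(self):
        res, seeds = self._result()
        # force exact ties by overwriting the visiting matrix
        res.visiting[:] = 1.0 / res.visiting.size
        ranking = aggregate_and_rank(res, seeds)
        genes = [g for g, _ in ranking]
        assert genes == sorted(genes)

    def test_mean_aggregation_consistent_with_visiting(self):
        res, _ = self._result()
        for i, g in enumerate(res.genes):
            assert res.aggregated[g] == pytest.approx(res.visiting[i].mean())
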