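import numpy as np
import pandas as pd
import pytest

from ddpcm import parse_newick, simulate_pure_birth
from ddpcm.discretize import SigmoidParams
from ddpcm.likelihood import edge_propagator
from ddpcm.simulate import (sim_bm, sim_bounded, sim_mk_history,
                            sim_semithreshold, sim_statedep, sim_threshold,
                            sim_xdep)


class TestSimBM:
    def test_reference_tree_moments(self, two_taxon_tree):
        # tip variances sigma2*(1.0, 0.7) = (0.80, 0.56); covariance 0.32
        X = sim_bm(two_taxon_tree, 0.0, 0.8, seed=1, reps=10_000)
        labs = two_taxon_tree.tip_labels
        i, j = labs.index("T1"), labs.index("T2")
        se_var = 0.8 * np.sqrt(2 / 10_000)  # Var(s^2) ~ 2 sigma^4 / n
        assert abs(X[:, i].var() - 0.80) < 3 * se_var
        assert abs(X[:, j].var() - 0.56) < 3 * se_var * 0.7
        cov = np.cov(X[:, i], X[:, j])[0, 1]
        assert abs(cov - 0.32) < 3 * 0.02

    def test_zero_rate_keeps_root_value(self):
        t = simulate_pure_birth(10, 1.0, seed=0)
        x = sim_bm(t, 1.7, 0.0, seed=1)
        assert np.allclose(x, 1.7)

    def test_seed_reproducibility(self):
        t = simulate_pure_birth(10, 1.0, seed=0)
        assert sim_bm(t, 0, 1, seed=5).equals(sim_bm(t, 0, 1, seed=5))
        assert not sim_bm(t, 0, 1, seed=5).equals(sim_bm(t, 0, 1, seed=6))


class TestSimBounded:
    def test_long_time_marginal_is_uniform(self):
        # past the relaxation time the tip law is Uniform(a, b)
        tree = parse_newick("(A:6.0,B:6.0);")  # >> 2(b-a)^2/(pi s2) = 3.4
        X = sim_bounded(tree, 0.0, 3.0, -2.0, 2.0, dt=0.01, seed=2, reps=4000)
        v = X[:, 0]
        assert abs(v.mean()) < 3 * np.sqrt(16 / 12 / 4000) + 0.05
        assert v.var() == pytest.approx(16 / 12, rel=0.1)
        assert v.min() >= -2 and v.max() <= 2

    def test_wide_bounds_match_unbounded_bm(self, two_taxon_tree):
        Xb = sim_bounded(two_taxon_tree, 0.0, 0.8, -50, 50, dt=0.01, seed=3,
                         reps=4000)
        labs = two_taxon_tree.tip_labels
        v = Xb[:, labs.index("T1")]
        assert v.var() == pytest.approx(0.8, rel=0.1)
        assert abs(v.mean()) < 0.05

    def test_inside_bounds_required(self, two_taxon_tree):
        with pytest.raises(ValueError):
            sim_bounded(two_taxon_tree, 5.0, 1.0, -1, 1)


class TestSimThreshold:
    def test_levels_follow_liability_intervals(self):
        t = simulate_pure_birth(50, 3.0, seed=4)
        levels, liab = sim_threshold(t, 0.5, 1.0, [0.0, 0.8, 1.0], seed=9)
        expect = np.searchsorted([0.0, 0.8, 1.0], liab.to_numpy(), side="right")
        assert np.array_equal(levels.to_numpy(), expect)
        assert levels.max() <= 3

    def test_liability_shares_stream_with_bm(self):
        t = simulate_pure_birth(20, 1.0, seed=0)
        _, liab = sim_threshold(t, 0.3, 1.5, [0.0], seed=7)
        assert liab.equals(sim_bm(t, 0.3, 1.5, seed=7))

    def test_symmetric_case_balanced_levels(self):
        t = parse_newick("(A:1,B:1);")
        hits = []
        for s in range(500):
            lv, _ = sim_threshold(t, 0.0, 1.0, [0.0], seed=s)
            hits.append(lv.iloc[0])
        p = np.mean(hits)
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 500)


class TestSimSemithreshold:
    def test_tiny_rate_all_points(self):
        t = simulate_pure_birth(30, 1.0, seed=1)
        obs, _ = sim_semithreshold(t, 0.0, 1e-6, (-1, 1), seed=2)
        assert all(o.kind == "point" for o in obs)

    def test_huge_rate_mostly_censored(self):
        t = simulate_pure_birth(30, 1.0, seed=1)
        obs, _ = sim_semithreshold(t, 0.0, 100.0, (-1, 1), seed=2)
        frac = np.mean([o.kind == "censored" for o in obs])
        assert frac > 0.8

    def test_censored_side_matches_liability(self):
        t = simulate_pure_birth(50, 1.0, seed=3)
        obs, liab = sim_semithreshold(t, 0.0, 2.0, (-1, 1), seed=4)
        for o in obs:
            v = liab[o.taxon]
            if o.kind == "point":
                assert -1 < v < 1
            else:
                assert (v <= -1) if o.side == "low" else (v >= 1)


class TestSimMkHistory:
    def test_zero_rate_constant_history(self):
        t = simulate_pure_birth(10, 1.0, seed=0)
        h = sim_mk_history(t, np.zeros((2, 2)), root_level=1, seed=1)
        assert (h.tip_levels == 1).all()
        assert h.n_changes() == 0

    def test_no_change_probability_is_exponential(self):
        # single edge of length t: P(no transition) = exp(-q t) for binary ER
        tree = parse_newick("(A:0.8,B:1e-9);")
        q = 1.3
        Q = np.array([[-q, q], [q, -q]])
        zero = 0
        n = 3000
        for s in range(n):
            h = sim_mk_history(tree, Q, 0, seed=s)
            a_node = [i for i in tree.tip_ids if tree.labels[i] == "A"][0]
            zero += len(h.segments[a_node]) == 1
        p = zero / n
        expect = np.exp(-q * 0.8)
        assert abs(p - expect) < 3 * np.sqrt(expect * (1 - expect) / n)

    def test_tip_frequencies_match_propagator(self):
        tree = parse_newick("(A:0.6,B:0.6);")
        Q = np.array([[-2.0, 2.0], [0.5, -0.5]])
        n = 4000
        ones = sum(int(sim_mk_history(tree, Q, 0, seed=s).tip_levels["A"])
                   for s in range(n))
        expect = edge_propagator(Q, 0.6)[0, 1]
        assert abs(ones / n - expect) < 3 * np.sqrt(expect * (1 - expect) / n)

    def test_durations_sum_to_edge_lengths(self):
        t = simulate_pure_birth(20, 2.0, seed=5)
        h = sim_mk_history(t, np.array([[-3, 3], [3, -3.0]]), 0, seed=6)
        for node, segs in h.segments.items():
            assert sum(d for _, d in segs) == pytest.approx(t.edge_length[node])

    def test_simmap_roundtrip_text(self):
        t = parse_newick("(A:1,B:1);")
        h = sim_mk_history(t, np.array([[-2, 2], [2, -2.0]]), 0, seed=8)
        text = h.to_simmap()
        assert text.endswith(";") and "{" in text


class TestSimStatedep:
    def test_single_level_reduces_to_bm_moments(self):
        t = parse_newick("(A:1.0,B:1.0);")
        h = sim_mk_history(t, np.zeros((2, 2)), 0, seed=0)
        vals = np.array([sim_statedep(t, h, [2.0, 99.0], x0=0.0, seed=s)["A"]
                         for s in range(3000)])
        assert vals.var() == pytest.approx(2.0, rel=0.12)
        assert abs(vals.mean()) < 0.08

    def test_conditional_variance_identity(self):
        t = simulate_pure_birth(10, 1.0, seed=1)
        h = sim_mk_history(t, np.array([[-3, 3], [3, -3.0]]), 0, seed=2)
        s2 = np.array([1.0, 10.0])
        durs = h.durations_by_level(2)
        tip = t.tip_ids[0]
        expect = 0.0
        node = tip
        while t.parent[node] >= 0:
            expect += durs[node] @ s2
            node = t.parent[node]
        vals = np.array([sim_statedep(t, h, s2, x0=0.0, seed=s)[t.labels[tip]]
                         for s in range(2000)])
        assert vals.var() == pytest.approx(expect, rel=0.15)

    def test_trend_direction_follows_level(self):
        t = parse_newick("(A:4.0,B:4.0);")
        ha = sim_mk_history(t, np.zeros((2, 2)), 0, seed=0)
        hb = sim_mk_history(t, np.zeros((2, 2)), 1, seed=0)
        xa = np.mean([sim_statedep(t, ha, [0.2, 0.2], [1.0, -0.7], 0.0, seed=s)["A"]
                      for s in range(300)])
        xb = np.mean([sim_statedep(t, hb, [0.2, 0.2], [1.0, -0.7], 0.0, seed=s)["A"]
                      for s in range(300)])
        assert xa == pytest.approx(4.0, abs=0.25)   # mu_a * t
        assert xb == pytest.approx(-2.8, abs=0.25)  # mu_b * t


class TestSimXdep:
    def test_zero_asymptotes_never_switch(self):
        t = simulate_pure_birth(20, 1.0, seed=0)
        none = SigmoidParams(0.0, 0.0, 0.0, 1.0)
        _, levels = sim_xdep(t, 0.0, 1.0, none, none, seed=1)
        assert (levels == 0).all()

    def test_flat_sigmoid_matches_constant_rate_switch_count(self):
        tree = parse_newick("(A:2.0,B:1e-9);")
        q = 0.8
        flat = SigmoidParams(q, q, 0.0, 1.0)
        n = 1000
        switched = sum(
            int(sim_xdep(tree, 0.0, 1.0, flat, flat, dt=0.005, seed=s)[1]["A"] == 1)
            for s in range(n))
        Q = np.array([[-q, q], [q, -q]])
        expect = edge_propagator(Q, 2.0)[0, 1]
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(switched / n - expect) < 3 * se + 0.01

    def test_association_between_trait_and_level(self):
        # q_ab high at low x, q_ba high at high x -> b accumulates at high x
        tree = simulate_pure_birth(150, 3.0, seed=3)
        p_ab = SigmoidParams(0.05, 2.0, 0.0, 3.0)
        p_ba = SigmoidParams(0.05, 2.0, 0.0, -3.0)
        x, y = sim_xdep(tree, 0.0, 1.0, p_ab, p_ba, dt=0.01, seed=4)
        if y.nunique() == 2:
            assert x[y == 1].mean() > x[y == 0].mean()
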