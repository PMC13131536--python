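import warnings

import numpy as np
import pandas as pd
import pytest

from ddpcm import oracles, parse_newick, simulate_pure_birth
from ddpcm.fitmodels import (FitResult, MkModel, MultiTrendBM, StateDependentBM,
                             akaike_weights, fit_bm_analytic, fit_bounded_bm,
                             fit_mk, fit_semithreshold, fit_statedep_bm,
                             fit_threshold)
from ddpcm.likelihood import TipObservation, edge_propagator
from ddpcm.simulate import (sim_bm, sim_bounded, sim_mk_history,
                            sim_semithreshold, sim_statedep, sim_threshold)


class TestAkaikeWeights:
    def _fit(self, lnl, k, fp=1):
        return FitResult("m", {}, lnl, k, fingerprint=fp)

    def test_equal_aic_splits_evenly(self):
        w = akaike_weights([self._fit(-10, 2), self._fit(-11, 1)])
        assert np.allclose(w, 0.5)

    def test_delta_two_ratio(self):
        w = akaike_weights([self._fit(-10, 1), self._fit(-11, 1)])
        expect = np.array([1.0, np.exp(-1.0)])
        assert np.allclose(w, expect / expect.sum(), atol=1e-12)
        assert w[0] == pytest.approx(0.731, abs=1e-3)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        fits = [self._fit(-rng.uniform(5, 50), rng.integers(1, 6))
                for _ in range(5)]
        assert akaike_weights(fits).sum() == pytest.approx(1.0)

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            akaike_weights([self._fit(-1, 1, fp=1), self._fit(-1, 1, fp=2)])


class TestAnalyticBM:
    def test_star_tree_sigma2_is_mean_square(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        x = pd.Series([0.3, -0.5, 1.1, 0.2, -0.9],
                      index=["A", "B", "C", "D", "E"])
        r = fit_bm_analytic(t, x)
        # on a star tree the GLS mean is the plain mean, sigma2 the ML variance
        assert r.params["x0"] == pytest.approx(x.mean())
        assert r.params["sigma2"] == pytest.approx(np.mean((x - x.mean()) ** 2))

    def test_loglik_is_exact_mvn(self, three_taxon_tree):
        x = pd.Series([0.4, -0.1, 0.8], index=["A", "B", "C"])
        r = fit_bm_analytic(three_taxon_tree, x)
        direct = oracles.bm_logdensity(three_taxon_tree, r.params["x0"],
                                       r.params["sigma2"], x.to_numpy())
        assert r.loglik == pytest.approx(direct)
        assert r.aic == pytest.approx(2 * 2 - 2 * r.loglik)

    def test_constant_data_hits_zero_boundary(self):
        t = simulate_pure_birth(10, 1.0, seed=0)
        r = fit_bm_analytic(t, pd.Series(2.0, index=t.tip_labels))
        assert r.params["sigma2"] == 0.0


class TestBoundedBM:
    def test_wide_bounds_recover_analytic_bm(self):
        tree = simulate_pure_birth(50, 1.0, seed=5)
        x = sim_bm(tree, 0.0, 1.0, seed=7)
        rb = fit_bounded_bm(tree, x, bounds=(-8, 8), bins=800, restarts=0)
        ra = fit_bm_analytic(tree, x)
        assert abs(rb.loglik - ra.loglik) < 0.05
        assert rb.params["sigma2"] == pytest.approx(ra.params["sigma2"], rel=0.05)

    def test_default_bounds_are_observed_range(self):
        tree = simulate_pure_birth(30, 1.0, seed=8)
        x = sim_bounded(tree, 0.0, 2.0, -1, 1, seed=9)
        r = fit_bounded_bm(tree, x, bins=60, restarts=0)
        assert r.params["a"] == pytest.approx(float(x.min()))
        assert r.params["b"] == pytest.approx(float(x.max()))
        assert r.n_params == 4  # sigma2, x0 and the two estimated bounds

    def test_too_few_tips_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="tips"):
            fit_bounded_bm(t, {"A": 0.1, "B": 0.4})

    def test_seed_reproducibility(self):
        tree = simulate_pure_birth(20, 1.0, seed=1)
        x = sim_bounded(tree, 0.0, 1.5, -1, 1, seed=2)
        r1 = fit_bounded_bm(tree, x, bins=50, restarts=1, seed=11)
        r2 = fit_bounded_bm(tree, x, bins=50, restarts=1, seed=11)
        assert r1.params == r2.params and r1.loglik == r2.loglik


class TestThresholdModel:
    def test_binary_balanced_deep_tree_symmetric_estimates(self):
        tree = simulate_pure_birth(80, 3.0, seed=3)
        levels, _ = sim_threshold(tree, 0.0, 1.0, [0.0], seed=4)
        r = fit_threshold(tree, levels, bins=100, restarts=0)
        assert r.params["thresholds"] == [0.0]
        assert abs(r.params["root_liability"]) < 1.5
        assert r.n_params == 1  # root liability only for a binary character

    def test_single_level_rejected(self):
        t = simulate_pure_birth(10, 1.0, seed=0)
        with pytest.raises(ValueError):
            fit_threshold(t, pd.Series(1, index=t.tip_labels))

    def test_sigma2_fixed_to_one(self):
        tree = simulate_pure_birth(40, 3.0, seed=5)
        levels, _ = sim_threshold(tree, 0.5, 1.0, [0.0, 0.8], seed=6)
        if levels.nunique() >= 2:
            r = fit_threshold(tree, levels, bins=80, restarts=0)
            assert r.params["sigma2"] == 1.0
            assert list(np.diff(r.params["thresholds"])) == sorted(
                np.diff(r.params["thresholds"]).tolist())


class TestSemiThreshold:
    def test_no_censoring_near_analytic_bm(self):
        tree = simulate_pure_birth(40, 1.0, seed=10)
        x = sim_bm(tree, 0.0, 0.5, seed=11)
        obs = [TipObservation(t, "point", value=float(v)) for t, v in x.items()]
        rs = fit_semithreshold(tree, obs, clamp=(float(x.min()) - 1e-6,
                                                 float(x.max()) + 1e-6),
                               bins=600, padding=1.0, restarts=0)
        ra = fit_bm_analytic(tree, x)
        assert abs(rs.loglik - ra.loglik) < 0.15
        assert rs.params["sigma2"] == pytest.approx(ra.params["sigma2"], rel=0.1)

    def test_one_sided_censoring_rejected(self):
        t = parse_newick("(A:1,B:1,C:1);")
        obs = [TipObservation(l, "censored", value=-1.0, side="low")
               for l in "ABC"]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_semithreshold(t, obs, clamp=(-1, 1))

    def test_recovery_with_censoring(self):
        tree = simulate_pure_birth(100, 1.0, seed=12)
        obs, _ = sim_semithreshold(tree, 0.2, 1.5, (-1, 1), seed=13)
        n_cens = sum(o.kind == "censored" for o in obs)
        assert n_cens > 5
        r = fit_semithreshold(tree, obs, clamp=(-1, 1), bins=150, restarts=0)
        assert r.params["sigma2"] == pytest.approx(1.5, rel=0.5)


class TestMk:
    def test_single_level_rejected(self):
        t = simulate_pure_birth(10, 1.0, seed=0)
        with pytest.raises(ValueError):
            fit_mk(t, pd.Series(0, index=t.tip_labels))

    def test_matches_grid_search_oracle(self):
        tree = parse_newick("(((A:0.3,B:0.3):0.4,C:0.7):0.3,(D:0.5,E:0.5):0.5);")
        y = pd.Series({"A": 0, "B": 0, "C": 1, "D": 1, "E": 1})
        r = fit_mk(tree, y, variant="ER", restarts=1, seed=0)

        def lnl(q):
            from ddpcm.likelihood import prune_loglik
            Q = np.array([[-q, q], [q, -q]])
            tips = {l: np.eye(2)[v] for l, v in y.items()}
            return prune_loglik(tree, Q, tips, np.array([0.5, 0.5]))

        qs = np.linspace(0.01, 20, 4000)
        qbest = qs[np.argmax([lnl(q) for q in qs])]
        assert r.params["q"] == pytest.approx(qbest, rel=0.05)

    def test_ordered_variants_restrict_moves(self):
        from ddpcm.fitmodels import _mk_generator
        Q = _mk_generator(4, "ordered-symmetric", [0.7, 0.8, 0.9])
        off = Q - np.diag(np.diag(Q))
        assert np.count_nonzero(off) == 6  # only nearest-level moves
        assert Q[1, 2] == Q[2, 1] == 0.8
        Qa = _mk_generator(4, "ordered-asymmetric", [0.7, 0.8, 0.9,
                                                     0.2, 0.3, 0.4])
        assert Qa[0, 1] == 0.7 and Qa[1, 0] == 0.2 and Qa[0, 2] == 0.0

    def test_parameter_counts_and_nesting(self):
        tree = simulate_pure_birth(40, 3.0, seed=1)
        levels, _ = sim_threshold(tree, 0.5, 1.0, [0.0, 0.8], seed=2)
        k = int(levels.max()) + 1
        rs = fit_mk(tree, levels, variant="ordered-symmetric", restarts=0)
        ra = fit_mk(tree, levels, variant="ordered-asymmetric", restarts=0)
        assert rs.n_params == k - 1 and ra.n_params == 2 * (k - 1)
        assert ra.loglik >= rs.loglik - 1e-6  # nesting


@pytest.fixture(scope="module")
def statedep_data():
    tree = simulate_pure_birth(60, 1.0, seed=20)
    q = 3.0
    hist = sim_mk_history(tree, np.array([[-q, q], [q, -q]]), 0, seed=21)
    x = sim_statedep(tree, hist, [1.0, 8.0], x0=0.0, seed=22)
    return tree, x, hist.tip_levels


class TestJointModels:
    def test_statedep_recovers_rate_ordering(self, statedep_data):
        tree, x, y = statedep_data
        r = fit_statedep_bm(tree, x, y, bins=60, restarts=0, maxfev=400)
        s2a, s2b = r.params["sigma2_by_state"]
        assert s2b > s2a
        assert s2b / s2a == pytest.approx(8.0, rel=0.8)

    def test_multitrend_nests_statedep(self, statedep_data):
        # richer model on the same data, grid and bins: lnL must not drop
        tree, x, y = statedep_data
        rs = fit_statedep_bm(tree, x, y, bins=60, restarts=0, maxfev=400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rm = MultiTrendBM(bins=60, restarts=0, maxfev=700, seed=0).fit(
                tree, x, y)
        assert rm.loglik_ >= rs.loglik - 0.2  # optimizer slack only
        assert rm.result_.n_params == 6 and rs.n_params == 4

    def test_multitrend_warns_on_ultrametric(self, statedep_data):
        tree, x, y = statedep_data
        with pytest.warns(UserWarning, match="non-identifiable"):
            MultiTrendBM(bins=40, restarts=0, maxfev=50, seed=0).fit(tree, x, y)

    def test_xdep_fit_smoke(self):
        # tiny capped fit of the trait-dependent switch model: correct
        # parameter count and a finite, improvable likelihood
        from ddpcm.fitmodels import ContinuousDependentMk
        tree = simulate_pure_birth(25, 1.0, seed=40)
        hist = sim_mk_history(tree, np.array([[-1.5, 1.5], [1.5, -1.5]]), 0,
                              seed=41)
        x = sim_statedep(tree, hist, [1.0, 1.0], x0=0.0, seed=42)
        y = hist.tip_levels
        if y.nunique() < 2:
            pytest.skip("monomorphic draw")
        m = ContinuousDependentMk(bins=30, restarts=0, maxfev=60,
                                  seed=0).fit(tree, x, y)
        assert np.isfinite(m.loglik_)
        assert m.n_params_ == 10
        assert m.params_["sigmoid_ab"].lower >= 0

    def test_joint_likelihood_flat_sigmoid_equals_constant_q(self):
        # xdep likelihood at flat sigmoids == statedep likelihood at same params
        from ddpcm.discretize import (SigmoidParams, generator_joint,
                                      generator_xdep, grid_for_data)
        from ddpcm.likelihood import (Propagator, PruningEngine, encode_tip,
                                      loglik_density)
        tree = simulate_pure_birth(30, 1.0, seed=30)
        hist = sim_mk_history(tree, np.array([[-1, 1], [1, -1.0]]), 0, seed=31)
        x = sim_statedep(tree, hist, [1.0, 1.0], x0=0.0, seed=32)
        y = hist.tip_levels
        g = grid_for_data(x.to_numpy(), 40)
        flat = SigmoidParams(0.6, 0.6, 0.0, 2.0)
        Q1 = generator_xdep(g, 1.0, flat, flat)
        Q2 = generator_joint(g, [1.0, 1.0], None, np.full((2, 2), 0.6))
        assert np.allclose(Q1, Q2)
        eng = PruningEngine(tree)
        tips = {lab: encode_tip(TipObservation(lab, "joint", value=v, level=int(y[lab])),
                                g, 2) for lab, v in x.items()}
        prior = np.zeros(2 * g.n)
        prior[[g.bin_of(0.0), g.n + g.bin_of(0.0)]] = 0.5
        l1 = eng.loglik(Propagator(Q1), tips, prior)
        l2 = eng.loglik(Propagator(Q2), tips, prior)
        assert l1 == pytest.approx(l2, abs=1e-8)
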