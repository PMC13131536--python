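"""Maximum-likelihood fitting of discretized-diffusion models on phylogenies.

Each model family is an estimator class in the scikit-learn idiom: constructor
takes hyperparameters (bin count, padding, optimizer settings), ``fit(tree,
data)`` estimates parameters by maximum likelihood and stores fitted
attributes with trailing underscores (``params_``, ``loglik_``, ``aic_``,
``result_``), and ``fit`` returns ``self``.  Module-level ``fit_*`` functions
are thin wrappers returning the :class:`FitResult` record.

Shared conventions
------------------
* Rates and diffusion rates are optimized on log scale; bounded quantities
  (root state within the grid, trends within the nonnegativity box
  ``|mu| <= 0.99 sigma^2/delta``) via tanh maps; ordered thresholds via
  log-increments above the fixed first threshold.
* The trait grid is fixed once per fit from the data, so likelihoods of
  nested models are comparable on a common discretization.
* Continuous tips contribute densities (``log f = log p - m log delta``);
  discrete and censored tips contribute probabilities.
* Optimization is Nelder-Mead with random restarts.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import oracles
from .discretize import (SigmoidParams, TraitGrid, build_grid, generator_diffusion,
                         generator_joint, generator_xdep, grid_for_data,
                         reversibility_weights)
from .likelihood import (Propagator, PruningEngine, TipObservation, encode_tip,
                         loglik_density)
from .treesim import Tree

__all__ = [
    "FitResult",
    "BrownianMotionML",
    "BoundedBrownianMotion",
    "ThresholdModel",
    "SemiThresholdModel",
    "StateDependentBM",
    "MultiTrendBM",
    "ContinuousDependentMk",
    "MkModel",
    "akaike_weights",
    "fit_bm_analytic",
    "fit_bounded_bm",
    "fit_threshold",
    "fit_semithreshold",
    "fit_statedep_bm",
    "fit_multitrend",
    "fit_xdep_mk",
    "fit_mk",
]


@dataclass
class FitResult:
    """Maximum-likelihood fit summary for one model on one dataset."""

    model: str
    params: dict
    loglik: float
    n_params: int
    converged: bool = True
    restarts_used: int = 0
    n_evals: int = 0
    grid: TraitGrid = None
    fingerprint: int = None
    extra: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def akaike_weights(fits) -> np.ndarray:
    """Akaike weights ``w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)``."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted models")
    fps = [f.fingerprint for f in fits if f.fingerprint is not None]
    if len(set(fps)) > 1:
        raise ValueError("models were fitted to different data")
    aic = np.array([f.aic for f in fits])
    d = aic - aic.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


# -- shared helpers --------------------------------------------------------

def _as_series(tree: Tree, data) -> pd.Series:
    labels = tree.tip_labels
    if isinstance(data, pd.Series):
        s = data.reindex(labels)
        if s.isna().any():
            raise ValueError("data missing for some taxa")
        return s
    if isinstance(data, dict):
        return pd.Series([data[l] for l in labels], index=labels)
    arr = np.asarray(data)
    if arr.shape[0] != len(labels):
        raise ValueError("data length does not match tip count")
    return pd.Series(arr, index=labels)


def _fingerprint(*parts) -> int:
    buf = []
    for p in parts:
        if isinstance(p, pd.Series):
            buf.append(";".join(f"{i}={v!r}" for i, v in p.items()))
        else:
            buf.append(repr(p))
    return zlib.crc32("|".join(buf).encode())


def _maximize(fun, x0, restarts: int, rng, maxfev=None, fatol=1e-6, xatol=1e-4,
              step=0.3):
    """Nelder-Mead maximization with random restarts; returns best raw point.

    The initial simplex uses an absolute coordinate step (default 0.3 on the
    transformed scale): the discretized likelihood is piecewise constant in
    grid-snapped parameters (root state, thresholds), and the default
    proportional simplex can start entirely inside one flat plateau.
    """
    x0 = np.asarray(x0, dtype=float)
    starts = [x0] + [x0 + rng.normal(0.0, 0.5, x0.size) for _ in range(restarts)]
    best = None
    nfev = 0
    for s in starts:
        simplex = np.vstack([s] + [s + step * e for e in np.eye(s.size)])
        res = minimize(lambda u: -fun(u), s, method="Nelder-Mead",
                       options=dict(maxfev=maxfev, fatol=fatol, xatol=xatol,
                                    adaptive=x0.size > 3,
                                    initial_simplex=simplex))
        nfev += res.nfev
        if best is None or -res.fun > best[1]:
            best = (res.x, -res.fun, bool(res.success))
    return best[0], best[1], best[2], len(starts) - 1, nfev


def _gls_bm(tree: Tree, x: np.ndarray):
    """Closed-form ML (x0, sigma2, loglik) under unbounded BM."""
    C = oracles.bm_cov(tree, 1.0)
    N = x.size
    cf = cho_factor(C)
    one = np.ones(N)
    Ci1 = cho_solve(cf, one)
    x0 = float(one @ cho_solve(cf, x) / (one @ Ci1))
    r = x - x0
    s2 = float(r @ cho_solve(cf, r) / N)
    if s2 <= 0:
        return x0, 0.0, np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (N * np.log(2 * np.pi * s2) + logdet + N)
    return x0, s2, ll


class _DiscretizedEstimator(BaseEstimator):
    """Shared scaffolding: grid, engine, optimizer bookkeeping."""

    def _rng(self):
        return np.random.default_rng(self.seed)

    def _finish(self, name, params, loglik, n_params, grid, opt, fingerprint,
                extra=None):
        raw, ll, conv, used, nfev = opt
        self.params_ = params
        self.loglik_ = float(loglik)
        self.n_params_ = int(n_params)
        self.converged_ = bool(conv)
        self.grid_ = grid
        self.result_ = FitResult(name, params, float(loglik), int(n_params),
                                 bool(conv), used, nfev, grid, fingerprint,
                                 extra or {})
        self.aic_ = self.result_.aic
        return self


# -- unbounded BM (analytic comparator) ------------------------------------

class BrownianMotionML(_DiscretizedEstimator):
    """Closed-form ML fit of unbounded Brownian motion (multivariate normal).

    The exact Gaussian comparator: no discretization is involved.
    """

    def __init__(self):
        pass

    def fit(self, tree: Tree, x):
        xs = _as_series(tree, x).astype(float)
        if tree.n_tips < 3:
            raise ValueError("need at least 3 tips")
        x0, s2, ll = _gls_bm(tree, xs.to_numpy())
        params = {"sigma2": s2, "x0": x0}
        fp = _fingerprint(xs)
        return self._finish("bm", params, ll, 2, None,
                            (None, ll, True, 0, 0), fp)


# -- bounded BM ------------------------------------------------------------

class BoundedBrownianMotion(_DiscretizedEstimator):
    """ML fit of Brownian motion with reflecting bounds via the discretized
    diffusion approximation.

    Unless fixed, the bounds default to the observed trait range (their MLE).
    The generator scales linearly with sigma2, so a single symmetric
    eigendecomposition serves every optimizer step (edge lengths are rescaled
    by sigma2 instead).
    """

    def __init__(self, bins=200, boundary="reassign", bounds=None, restarts=3,
                 seed=None, maxfev=None):
        self.bins = bins
        self.boundary = boundary
        self.bounds = bounds
        self.restarts = restarts
        self.seed = seed
        self.maxfev = maxfev

    def fit(self, tree: Tree, x):
        xs = _as_series(tree, x).astype(float)
        if tree.n_tips < 3:
            raise ValueError("need at least 3 tips (too few for inference)")
        xv = xs.to_numpy()
        bounds_fixed = self.bounds is not None
        a, b = self.bounds if bounds_fixed else (float(xv.min()), float(xv.max()))
        if not b > a:
            raise ValueError("degenerate bounds")
        grid = build_grid(a, b, self.bins)
        Q0 = generator_diffusion(grid, 1.0, self.boundary)
        prop = Propagator(Q0, weights=reversibility_weights(grid.n, self.boundary))
        engine = PruningEngine(tree)
        tip_bins = grid.bin_of(xv)
        partials = {lab: np.eye(grid.n)[bi] for lab, bi in zip(xs.index, tip_bins)}
        N = tree.n_tips
        span = b - a

        def loglik(raw):
            log_s2, z = raw
            s2 = np.exp(log_s2)
            x0 = a + span * (0.5 + 0.5 * np.tanh(z))
            prior = np.zeros(grid.n)
            prior[grid.bin_of(x0)] = 1.0
            lp = engine.loglik(prop, partials, prior, time_scale=s2)
            return loglik_density(lp, grid.delta, N)

        x0_init, s2_init, _ = _gls_bm(tree, xv)
        x0_init = min(max(x0_init, a + 0.6 * grid.delta), b - 0.6 * grid.delta)
        z0 = np.arctanh(np.clip(2 * (x0_init - a) / span - 1, -0.99, 0.99))
        opt = _maximize(loglik, [np.log(max(s2_init, 1e-6)), z0],
                        self.restarts, self._rng(), self.maxfev)
        raw, ll = opt[0], opt[1]
        s2 = float(np.exp(raw[0]))
        x0 = float(a + span * (0.5 + 0.5 * np.tanh(raw[1])))
        params = {"sigma2": s2, "x0": x0, "a": a, "b": b}
        k = 2 + (0 if bounds_fixed else 2)
        return self._finish("bounded_bm", params, ll, k, grid, opt,
                            _fingerprint(xs))


# -- threshold model -------------------------------------------------------

class ThresholdModel(_DiscretizedEstimator):
    """Multi-state threshold model fitted via discretized liability diffusion.

    The liability evolves by BM with sigma2 fixed to 1 (liability is
    unitless); the first threshold is fixed at 0.  Free parameters are the
    remaining threshold positions (as log-increments) and the root liability.
    """

    def __init__(self, k=None, bins=150, span=None, boundary="reassign",
                 restarts=3, seed=None, maxfev=None):
        self.k = k
        self.bins = bins
        self.span = span
        self.boundary = boundary
        self.restarts = restarts
        self.seed = seed
        self.maxfev = maxfev

    def fit(self, tree: Tree, levels):
        ys = _as_series(tree, levels).astype(int)
        k = int(self.k) if self.k is not None else int(ys.max()) + 1
        if ys.nunique() < 2:
            raise ValueError("single observed level carries no information")
        T = tree.depth
        half = self.span if self.span is not None else 5.0 * np.sqrt(T)
        grid = build_grid(-half, half, self.bins)
        prop = Propagator(generator_diffusion(grid, 1.0, self.boundary),
                          weights=reversibility_weights(grid.n, self.boundary))
        engine = PruningEngine(tree)
        c = grid.centers
        n_free = k - 2
        yv = ys.to_numpy()

        def unpack(raw):
            h0 = 0.9 * half * np.tanh(raw[0])
            inc = np.exp(np.clip(raw[1:1 + n_free], -8.0, 8.0))
            thr = np.concatenate([[0.0], np.cumsum(inc)]) if n_free else np.array([0.0])
            return h0, thr

        def loglik(raw):
            h0, thr = unpack(raw)
            if thr.max() >= grid.hi - grid.delta:
                return -np.inf
            edges = np.concatenate([[-np.inf], thr, [np.inf]])
            partials = {}
            ok = True
            for lab, j in ys.items():
                v = ((c >= edges[j]) & (c < edges[j + 1])).astype(float)
                if not v.any():
                    ok = False
                    break
                partials[lab] = v
            if not ok:
                return -np.inf
            prior = np.zeros(grid.n)
            prior[grid.bin_of(h0)] = 1.0
            return engine.loglik(prop, partials, prior)

        raw0 = np.zeros(1 + n_free)
        raw0[1:] = np.log(0.5 * np.sqrt(T))
        opt = _maximize(loglik, raw0, self.restarts, self._rng(), self.maxfev,
                        step=0.5)
        h0, thr = unpack(opt[0])
        params = {"root_liability": float(h0),
                  "thresholds": [float(t) for t in thr], "sigma2": 1.0}
        return self._finish("threshold", params, opt[1], 1 + n_free, grid, opt,
                            _fingerprint(ys), extra={"k": k})


# -- semi-threshold model --------------------------------------------------

class SemiThresholdModel(_DiscretizedEstimator):
    """Censored ("semi-threshold") BM: the trait is observed on an interval and
    only its clamp side is known outside it, while the latent value keeps
    diffusing.  Point tips contribute densities; clamped tips semi-infinite
    interval probabilities.
    """

    def __init__(self, clamp=None, bins=200, padding=0.5, boundary="reassign",
                 restarts=3, seed=None, maxfev=None):
        self.clamp = clamp
        self.bins = bins
        self.padding = padding
        self.boundary = boundary
        self.restarts = restarts
        self.seed = seed
        self.maxfev = maxfev

    def fit(self, tree: Tree, observations):
        obs = list(observations)
        labels = set(tree.tip_labels)
        if {o.taxon for o in obs} != labels:
            raise ValueError("need exactly one observation per taxon")
        if self.clamp is not None:
            low, high = self.clamp
        else:
            lows = [o.value for o in obs if o.kind == "censored" and o.side == "low"]
            highs = [o.value for o in obs if o.kind == "censored" and o.side == "high"]
            pts = [o.value for o in obs if o.kind == "point"]
            low = min(lows) if lows else min(pts)
            high = max(highs) if highs else max(pts)
        pts = np.array([o.value for o in obs if o.kind == "point"])
        sides = {o.side for o in obs if o.kind == "censored"}
        if pts.size == 0 and len(sides) < 2:
            raise ValueError("all tips censored to one side: sigma2 unidentifiable")
        anchor = np.concatenate([pts, [low, high]])
        grid = grid_for_data(anchor, self.bins, self.padding)
        prop = Propagator(generator_diffusion(grid, 1.0, self.boundary),
                          weights=reversibility_weights(grid.n, self.boundary))
        engine = PruningEngine(tree)
        partials = {o.taxon: encode_tip(o, grid) for o in obs}
        m_point = int(pts.size)
        half_lo, half_hi = grid.lo, grid.hi

        def loglik(raw):
            log_s2, z = raw
            s2 = np.exp(log_s2)
            x0 = half_lo + (half_hi - half_lo) * (0.5 + 0.5 * np.tanh(z))
            prior = np.zeros(grid.n)
            prior[grid.bin_of(x0)] = 1.0
            lp = engine.loglik(prop, partials, prior, time_scale=s2)
            return loglik_density(lp, grid.delta, m_point)

        mid = np.mean(anchor)
        z0 = np.arctanh(np.clip(2 * (mid - half_lo) / (half_hi - half_lo) - 1,
                                -0.99, 0.99))
        s2_init = max(np.var(pts) / max(tree.depth, 1e-9), 1e-3) if pts.size > 2 else 0.5
        opt = _maximize(loglik, [np.log(s2_init), z0], self.restarts,
                        self._rng(), self.maxfev)
        raw = opt[0]
        x0 = float(half_lo + (half_hi - half_lo) * (0.5 + 0.5 * np.tanh(raw[1])))
        params = {"sigma2": float(np.exp(raw[0])), "x0": x0,
                  "clamp": (float(low), float(high))}
        fp = _fingerprint(pd.Series({o.taxon: (o.kind, o.value, o.side) for o in obs}))
        return self._finish("semithreshold", params, opt[1], 2, grid, opt, fp)


# -- Mk models -------------------------------------------------------------

def _mk_generator(k: int, variant: str, rates) -> np.ndarray:
    Q = np.zeros((k, k))
    if variant == "ER":
        Q[:] = rates[0]
    elif variant == "ordered-symmetric":
        # one rate per adjacent pair, shared between directions: k-1 rates
        for i in range(k - 1):
            Q[i, i + 1] = Q[i + 1, i] = rates[i]
    elif variant == "ordered-asymmetric":
        # separate up and down rate per adjacent pair: 2(k-1) rates
        for i in range(k - 1):
            Q[i, i + 1] = rates[i]
            Q[i + 1, i] = rates[k - 1 + i]
    else:
        raise ValueError(f"unknown Mk variant {variant!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _mk_n_rates(k: int, variant: str) -> int:
    return {"ER": 1, "ordered-symmetric": k - 1,
            "ordered-asymmetric": 2 * (k - 1)}[variant]


class MkModel(_DiscretizedEstimator):
    """ML fit of the Mk model for an ordered or unordered discrete character.

    Variants: ``ER`` (all transitions share one rate), ``ordered-symmetric``
    (nearest-level moves, one rate per adjacent level pair),
    ``ordered-asymmetric`` (nearest-level moves, separate up and down rates
    per pair).  Root prior is flat over levels.  Rates are capped at
    ``max_rate`` (default 100 times the tree depth, the convention of
    standard Mk software) because the likelihood can be monotone in a rate
    when the data are phylogenetically saturated.
    """

    def __init__(self, variant="ER", k=None, restarts=3, seed=None,
                 maxfev=None, max_rate=None):
        self.variant = variant
        self.k = k
        self.restarts = restarts
        self.seed = seed
        self.maxfev = maxfev
        self.max_rate = max_rate

    def fit(self, tree: Tree, levels):
        ys = _as_series(tree, levels).astype(int)
        k = int(self.k) if self.k is not None else int(ys.max()) + 1
        if ys.nunique() < 2:
            raise ValueError("single observed level carries no information")
        engine = PruningEngine(tree)
        eye = np.eye(k)
        partials = {lab: eye[j] for lab, j in ys.items()}
        prior = np.full(k, 1.0 / k)
        n_rates = _mk_n_rates(k, self.variant)
        cap = self.max_rate if self.max_rate is not None else 100.0 * tree.depth
        log_cap = np.log(cap)

        def rates_of(raw):
            return np.exp(np.minimum(raw, log_cap))

        def loglik(raw):
            Q = _mk_generator(k, self.variant, rates_of(raw))
            return engine.loglik(Propagator(Q), partials, prior)

        # crude rate scale: one expected change per tree depth; the
        # asymmetric ordered variant warm-starts from the symmetric fit
        raw0 = np.full(n_rates, np.log(max(1.0 / tree.depth, 1e-3)))
        if self.variant == "ordered-asymmetric" and k > 2:
            pre = MkModel(variant="ordered-symmetric", k=k, restarts=0,
                          seed=self.seed, max_rate=cap).fit(tree, ys)
            raw0 = np.log(np.tile(np.maximum(pre.params_["rates"], 1e-4), 2))
        opt = _maximize(loglik, raw0, self.restarts, self._rng(), self.maxfev)
        rates = rates_of(opt[0])
        if self.variant == "ER":
            params = {"q": float(rates[0])}
        elif self.variant == "ordered-symmetric":
            params = {"rates": [float(r) for r in rates],
                      "q": float(rates[0])}
        else:
            params = {"rates_up": [float(r) for r in rates[:k - 1]],
                      "rates_down": [float(r) for r in rates[k - 1:]]}
        return self._finish(f"mk[{self.variant}]", params, opt[1], n_rates,
                            None, opt, _fingerprint(ys), extra={"k": k})


# -- joint discrete + continuous models ------------------------------------

def _joint_prior(grid: TraitGrid, k: int, x0: float) -> np.ndarray:
    prior = np.zeros(k * grid.n)
    prior[int(grid.bin_of(x0)) + np.arange(k) * grid.n] = 1.0 / k
    return prior


class StateDependentBM(_DiscretizedEstimator):
    """Joint model: a discrete character (Mk) sets the BM rate of a continuous
    trait; both processes are fitted simultaneously on the k*n discretized
    state space.

    Default is a single symmetric transition rate (q_ab = q_ba); set
    ``equal_rates=False`` for separate directional rates.
    """

    def __init__(self, bins=100, padding=0.5, boundary="reassign",
                 equal_rates=True, restarts=3, seed=None, maxfev=None):
        self.bins = bins
        self.padding = padding
        self.boundary = boundary
        self.equal_rates = equal_rates
        self.restarts = restarts
        self.seed = seed
        self.maxfev = maxfev

    def _q_matrix(self, k, rates):
        Q = np.zeros((k, k))
        if self.equal_rates:
            Q[:] = rates[0]
        else:
            idx = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = rates[idx]
                        idx += 1
        np.fill_diagonal(Q, 0.0)
        return Q

    def fit(self, tree: Tree, x, y):
        xs = _as_series(tree, x).astype(float)
        ys = _as_series(tree, y).astype(int)
        k = int(ys.max()) + 1
        if k < 2:
            raise ValueError("need at least 2 observed levels")
        for lvl in range(k):
            if not (ys == lvl).any():
                warnings.warn(f"level {lvl} has no tips; its rate is weakly identified")
        grid = grid_for_data(xs.to_numpy(), self.bins, self.padding)
        engine = PruningEngine(tree)
        partials = {
            lab: encode_tip(TipObservation(lab, "joint", value=v, level=j), grid, k)
            for (lab, v), j in zip(xs.items(), ys.to_numpy())
        }
        N = tree.n_tips
        n_q = 1 if self.equal_rates else k * (k - 1)

        def unpack(raw):
            s2 = np.exp(np.clip(raw[:k], -20, 20))
            q = np.exp(np.clip(raw[k:k + n_q], -20, 20))
            x0 = grid.lo + (grid.hi - grid.lo) * (0.5 + 0.5 * np.tanh(raw[-1]))
            return s2, q, x0

        wts = (reversibility_weights(grid.n, self.boundary, k)
               if self.equal_rates else None)

        def loglik(raw):
            s2, q, x0 = unpack(raw)
            Q = generator_joint(grid, s2, None, self._q_matrix(k, q), self.boundary)
            lp = engine.loglik(Propagator(Q, weights=wts), partials,
                               _joint_prior(grid, k, x0))
            return loglik_density(lp, grid.delta, N)

        x0_init, s2_init, _ = _gls_bm(tree, xs.to_numpy())
        mk = MkModel(variant="ER", k=k, restarts=0, seed=self.seed).fit(tree, ys)
        z0 = np.arctanh(np.clip(2 * (x0_init - grid.lo) / (grid.hi - grid.lo) - 1,
                                -0.99, 0.99))
        raw0 = np.concatenate([np.full(k, np.log(max(s2_init, 1e-6))),
                               np.full(n_q, np.log(max(mk.params_["q"], 1e-3))),
                               [z0]])
        opt = _maximize(loglik, raw0, self.restarts, self._rng(), self.maxfev)
        s2, q, x0 = unpack(opt[0])
        params = {"sigma2_by_state": [float(v) for v in s2],
                  "q": float(q[0]) if self.equal_rates else self._q_matrix(k, q).tolist(),
                  "x0": float(x0)}
        n_par = k + n_q + 1
        return self._finish("statedep_bm", params, opt[1], n_par, grid, opt,
                            _fingerprint(xs, ys), extra={"k": k})


class MultiTrendBM(_DiscretizedEstimator):
    """Joint model with state-dependent diffusion rates *and* linear trends.

    Trends enter the chain as asymmetric neighbor rates
    ``q_c +- mu/(2 delta)``; during optimization each trend is kept inside the
    nonnegativity box via ``mu = 0.99 (sigma_i^2/delta) tanh(u_i)``.  Trend
    and root state are jointly non-identifiable on ultrametric trees, so a
    warning is emitted there.
    """

    def __init__(self, bins=120, padding=0.5, boundary="reassign",
                 restarts=3, seed=None, maxfev=None):
        self.bins = bins
        self.padding = padding
        self.boundary = boundary
        self.restarts = restarts
        self.seed = seed
        self.maxfev = maxfev

    def fit(self, tree: Tree, x, y):
        xs = _as_series(tree, x).astype(float)
        ys = _as_series(tree, y).astype(int)
        k = int(ys.max()) + 1
        if tree.is_ultrametric():
            warnings.warn("trend and root state are non-identifiable on "
                          "ultrametric trees; results will be unreliable")
        grid = grid_for_data(xs.to_numpy(), self.bins, self.padding)
        delta = grid.delta
        engine = PruningEngine(tree)
        partials = {
            lab: encode_tip(TipObservation(lab, "joint", value=v, level=j), grid, k)
            for (lab, v), j in zip(xs.items(), ys.to_numpy())
        }
        N = tree.n_tips

        def unpack(raw):
            s2 = np.exp(np.clip(raw[:k], -20, 20))
            mu = 0.99 * (s2 / delta) * np.tanh(raw[k:2 * k])
            q = np.exp(np.clip(raw[2 * k], -20, 20))
            x0 = grid.lo + (grid.hi - grid.lo) * (0.5 + 0.5 * np.tanh(raw[-1]))
            return s2, mu, q, x0

        def loglik(raw):
            s2, mu, q, x0 = unpack(raw)
            qm = np.full((k, k), q)
            Q = generator_joint(grid, s2, mu, qm, self.boundary)
            lp = engine.loglik(Propagator(Q), partials, _joint_prior(grid, k, x0))
            return loglik_density(lp, grid.delta, N)

        x0_init, s2_init, _ = _gls_bm(tree, xs.to_numpy())
        mk = MkModel(variant="ER", k=k, restarts=0, seed=self.seed).fit(tree, ys)
        # crude per-level trend start: mean displacement per unit height
        h = tree.heights()[tree.tip_ids]
        mu0 = np.zeros(k)
        yv = ys.to_numpy()
        for lvl in range(k):
            sel = yv == lvl
            if sel.sum() >= 2 and np.ptp(h[sel]) > 1e-3 * tree.depth:
                mu0[lvl] = np.polyfit(h[sel], xs.to_numpy()[sel], 1)[0]
        s2v = np.full(k, max(s2_init, 1e-6))
        u0 = np.arctanh(np.clip(mu0 * delta / (0.99 * s2v), -0.9, 0.9))
        z0 = np.arctanh(np.clip(2 * (x0_init - grid.lo) / (grid.hi - grid.lo) - 1,
                                -0.99, 0.99))
        raw0 = np.concatenate([np.log(s2v), u0,
                               [np.log(max(mk.params_["q"], 1e-3)), z0]])
        opt = _maximize(loglik, raw0, self.restarts, self._rng(), self.maxfev)
        s2, mu, q, x0 = unpack(opt[0])
        at_box = bool(np.any(np.abs(mu) > 0.95 * s2 / delta))
        if at_box:
            warnings.warn("a trend estimate sits near its grid-imposed bound; "
                          "consider a finer grid")
        params = {"sigma2_by_state": [float(v) for v in s2],
                  "mu_by_state": [float(v) for v in mu],
                  "q": float(q), "x0": float(x0)}
        return self._finish("multitrend_bm", params, opt[1], 2 * k + 2, grid,
                            opt, _fingerprint(xs, ys),
                            extra={"k": k, "trend_at_bound": at_box})


class ContinuousDependentMk(_DiscretizedEstimator):
    """Inverse joint model: the continuous trait sets the discrete switch rates
    through a four-parameter sigmoid per direction (8 sigmoid parameters, plus
    sigma2 and x0).
    """

    def __init__(self, bins=100, padding=0.5, boundary="reassign",
                 restarts=3, seed=None, maxfev=None):
        self.bins = bins
        self.padding = padding
        self.boundary = boundary
        self.restarts = restarts
        self.seed = seed
        self.maxfev = maxfev

    def fit(self, tree: Tree, x, y):
        xs = _as_series(tree, x).astype(float)
        ys = _as_series(tree, y).astype(int)
        if ys.max() > 1:
            raise ValueError("this model is for a binary discrete trait")
        grid = grid_for_data(xs.to_numpy(), self.bins, self.padding)
        engine = PruningEngine(tree)
        partials = {
            lab: encode_tip(TipObservation(lab, "joint", value=v, level=j), grid, 2)
            for (lab, v), j in zip(xs.items(), ys.to_numpy())
        }
        N = tree.n_tips
        xmid, xscale = float(xs.mean()), max(float(xs.std()), 1e-6)

        def unpack(raw):
            s2 = np.exp(np.clip(raw[0], -20, 20))
            x0 = grid.lo + (grid.hi - grid.lo) * (0.5 + 0.5 * np.tanh(raw[1]))
            sig = []
            for d in range(2):
                lo, up, mid, st = raw[2 + 4 * d: 6 + 4 * d]
                sig.append(SigmoidParams(np.exp(np.clip(lo, -20, 20)),
                                         np.exp(np.clip(up, -20, 20)),
                                         xmid + mid * xscale, st / xscale))
            return s2, x0, sig[0], sig[1]

        def loglik(raw):
            s2, x0, p_ab, p_ba = unpack(raw)
            Q = generator_xdep(grid, s2, p_ab, p_ba, self.boundary)
            lp = engine.loglik(Propagator(Q), partials, _joint_prior(grid, 2, x0))
            return loglik_density(lp, grid.delta, N)

        x0_init, s2_init, _ = _gls_bm(tree, xs.to_numpy())
        mk = MkModel(variant="ER", k=2, restarts=0, seed=self.seed).fit(tree, ys)
        lq = np.log(max(mk.params_["q"], 1e-3))
        z0 = np.arctanh(np.clip(2 * (x0_init - grid.lo) / (grid.hi - grid.lo) - 1,
                                -0.99, 0.99))
        raw0 = np.array([np.log(max(s2_init, 1e-6)), z0,
                         lq, lq, 0.0, 1.0,
                         lq, lq, 0.0, -1.0])
        opt = _maximize(loglik, raw0, self.restarts, self._rng(), self.maxfev)
        s2, x0, p_ab, p_ba = unpack(opt[0])
        params = {"sigma2": float(s2), "x0": float(x0),
                  "sigmoid_ab": p_ab, "sigmoid_ba": p_ba}
        return self._finish("xdep_mk", params, opt[1], 10, grid, opt,
                            _fingerprint(xs, ys))


# -- functional wrappers ---------------------------------------------------

def fit_bm_analytic(tree, x) -> FitResult:
    return BrownianMotionML().fit(tree, x).result_


def fit_bounded_bm(tree, x, bounds=None, **kw) -> FitResult:
    return BoundedBrownianMotion(bounds=bounds, **kw).fit(tree, x).result_


def fit_threshold(tree, levels, k=None, **kw) -> FitResult:
    return ThresholdModel(k=k, **kw).fit(tree, levels).result_


def fit_semithreshold(tree, observations, clamp=None, **kw) -> FitResult:
    return SemiThresholdModel(clamp=clamp, **kw).fit(tree, observations).result_


def fit_statedep_bm(tree, x, y, **kw) -> FitResult:
    return StateDependentBM(**kw).fit(tree, x, y).result_


def fit_multitrend(tree, x, y, **kw) -> FitResult:
    return MultiTrendBM(**kw).fit(tree, x, y).result_


def fit_xdep_mk(tree, x, y, **kw) -> FitResult:
    return ContinuousDependentMk(**kw).fit(tree, x, y).result_


def fit_mk(tree, levels, variant="ER", **kw) -> FitResult:
    return MkModel(variant=variant, **kw).fit(tree, levels).result_
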