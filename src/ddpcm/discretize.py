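"""Trait-space discretization and generator (rate) matrix construction.

A continuous diffusion with rate sigma^2 (and optionally a linear trend mu) is
approximated by a nearest-neighbor continuous-time Markov chain on a lattice of
n bins of width delta.  The approximation becomes exact as delta -> 0.  Rates:

* symmetric diffusion: neighbor rate ``q_c = sigma^2 / (2 delta^2)``
* trended diffusion:   ``q_plus = q_c + mu/(2 delta)``,
                       ``q_minus = q_c - mu/(2 delta)`` (requires
                       ``|mu| <= sigma^2 / delta`` so both stay nonnegative)
* reflecting bounds: outward transitions at the edge rows are removed and
  either reassigned inward (boundary rate ``2 q_c``; more accurate at finite
  n) or simply omitted (rate ``q_c``); both converge as delta -> 0.

Joint discrete+continuous models stack k diffusion blocks of size n into a
``k n x k n`` generator whose off-diagonal blocks carry the discrete-character
transition rates (constant, or a sigmoid function of the trait value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraitGrid",
    "SigmoidParams",
    "build_grid",
    "grid_for_data",
    "generator_diffusion",
    "generator_trend",
    "generator_joint",
    "sigmoid_rate",
    "generator_xdep",
    "max_trend",
    "reversibility_weights",
]


@dataclass(frozen=True)
class TraitGrid:
    """n equally spaced bins of width delta covering ``[lo, hi]``."""

    lo: float
    hi: float
    n: int

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValueError("degenerate interval: hi must exceed lo")
        if self.n < 3:
            raise ValueError("need at least 3 bins")

    @property
    def delta(self) -> float:
        return (self.hi - self.lo) / self.n

    @property
    def centers(self) -> np.ndarray:
        return self.lo + self.delta * (np.arange(self.n) + 0.5)

    def bin_of(self, x) -> np.ndarray:
        """Index of the bin containing x (values at ``hi`` map to the last bin)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lo) or np.any(x > self.hi):
            raise ValueError("value outside the grid span")
        idx = np.floor((x - self.lo) / self.delta).astype(np.int64)
        return np.minimum(idx, self.n - 1)


@dataclass(frozen=True)
class SigmoidParams:
    """Four-parameter logistic relating a trait value to a transition rate.

    ``rate(x) = lower + (upper - lower) / (1 + exp(-steepness (x - midpoint)))``

    Both asymptotes must be nonnegative so the rate is nonnegative everywhere;
    ``steepness = 0`` gives the constant ``(lower + upper)/2`` (the
    trait-independent special case).
    """

    lower: float
    upper: float
    midpoint: float
    steepness: float

    def __post_init__(self):
        if self.lower < 0 or self.upper < 0:
            raise ValueError("sigmoid asymptotes must be nonnegative")


def reversibility_weights(n: int, boundary: str = "reassign", k: int = 1) -> np.ndarray:
    """Stationary weights of the trend-free reflecting diffusion chain.

    With the 'reassign' boundary the edge bins carry half the stationary mass
    of interior bins (weights 1,2,...,2,1); with 'omit' the chain is doubly
    stochastic and the weights are uniform.  The chain is reversible with
    respect to these weights, so ``diag(sqrt(w)) Q diag(sqrt(w))^-1`` is
    symmetric -- the basis for the fast eigendecomposition propagator.  For k
    levels with equal switch rates the weights tile across levels.
    """
    if boundary == "reassign":
        w = np.full(n, 2.0)
        w[0] = w[-1] = 1.0
    else:
        w = np.ones(n)
    return np.tile(w, k)


def build_grid(lo: float, hi: float, n: int) -> TraitGrid:
    """Discretize ``[lo, hi]`` into ``n`` bins of width ``(hi - lo)/n``."""
    return TraitGrid(float(lo), float(hi), int(n))


def grid_for_data(x, n: int, padding: float = 0.5) -> TraitGrid:
    """Data-driven grid for unbounded-type models.

    Spans ``[min(x) - padding*R, max(x) + padding*R]`` for observed range R.
    The padding keeps the artificial reflecting edges far from the data so
    they do not act as spurious bounds.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    r = max(hi - lo, 1e-8)
    return build_grid(lo - padding * r, hi + padding * r, n)


def _tridiag(n: int, up: np.ndarray, down: np.ndarray, boundary: str) -> np.ndarray:
    """Tridiagonal generator with reflecting edges.

    ``up[i]`` is the rate i -> i+1 and ``down[i]`` the rate i+1 -> i.
    boundary='reassign' doubles the inward rate at the two edge rows.
    """
    if boundary not in ("reassign", "omit"):
        raise ValueError("boundary must be 'reassign' or 'omit'")
    up = np.broadcast_to(np.asarray(up, dtype=float), (n - 1,)).copy()
    down = np.broadcast_to(np.asarray(down, dtype=float), (n - 1,)).copy()
    if boundary == "reassign":
        up[0] *= 2.0
        down[-1] *= 2.0
    Q = np.zeros((n, n))
    idx = np.arange(n - 1)
    Q[idx, idx + 1] = up
    Q[idx + 1, idx] = down
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q


def generator_diffusion(grid: TraitGrid, sigma2: float, boundary: str = "reassign") -> np.ndarray:
    """Generator of discretized diffusion with reflecting bounds at the grid edges."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    qc = sigma2 / (2.0 * grid.delta**2)
    return _tridiag(grid.n, qc, qc, boundary)


def max_trend(grid: TraitGrid, sigma2: float) -> float:
    """Largest |mu| representable on this grid: ``sigma^2 / delta``."""
    return sigma2 / grid.delta


def generator_trend(grid: TraitGrid, sigma2: float, mu: float,
                    boundary: str = "reassign") -> np.ndarray:
    """Generator of trended (directional) discretized diffusion.

    Upward neighbor rate ``q_c + mu/(2 delta)``, downward ``q_c - mu/(2 delta)``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if abs(mu) > sigma2 / grid.delta:
        raise ValueError(
            f"trend bound violated: |mu|={abs(mu):.4g} exceeds "
            f"sigma2/delta={sigma2 / grid.delta:.4g}; refine the grid"
        )
    qc = sigma2 / (2.0 * grid.delta**2)
    drift = mu / (2.0 * grid.delta)
    return _tridiag(grid.n, qc + drift, qc - drift, boundary)


def generator_joint(grid: TraitGrid, sigma2_by_state, mu_by_state=None,
                    q_discrete=None, boundary: str = "reassign") -> np.ndarray:
    """``k n x k n`` generator for joint discrete+continuous evolution.

    Diagonal blocks are per-state diffusion (or trended-diffusion) generators;
    block (i, j) for i != j is ``q_discrete[i, j] * I`` (the discrete character
    switches level without moving the continuous trait).  State order is
    (level 0, bins...), (level 1, bins...), ...
    """
    sigma2_by_state = np.atleast_1d(np.asarray(sigma2_by_state, dtype=float))
    k = sigma2_by_state.size
    if mu_by_state is None:
        mu_by_state = np.zeros(k)
    mu_by_state = np.atleast_1d(np.asarray(mu_by_state, dtype=float))
    if mu_by_state.size != k:
        raise ValueError("sigma2_by_state and mu_by_state sizes differ")
    if q_discrete is None:
        q_discrete = np.zeros((k, k))
    q_discrete = np.asarray(q_discrete, dtype=float)
    if q_discrete.shape != (k, k):
        raise ValueError("q_discrete must be k x k")
    off = q_discrete[~np.eye(k, dtype=bool)]
    if np.any(off < 0):
        raise ValueError("discrete transition rates must be nonnegative")
    n = grid.n
    Q = np.zeros((k * n, k * n))
    for i in range(k):
        sl = slice(i * n, (i + 1) * n)
        Q[sl, sl] = generator_trend(grid, sigma2_by_state[i], mu_by_state[i], boundary)
        for j in range(k):
            if i != j:
                Q[sl, slice(j * n, (j + 1) * n)] = q_discrete[i, j] * np.eye(n)
    Q[np.arange(k * n), np.arange(k * n)] = 0.0
    Q[np.arange(k * n), np.arange(k * n)] = -Q.sum(axis=1)
    return Q


def sigmoid_rate(x, p: SigmoidParams) -> np.ndarray:
    """Evaluate the sigmoid transition-rate curve at trait value(s) x."""
    x = np.asarray(x, dtype=float)
    z = np.clip(p.steepness * (x - p.midpoint), -500.0, 500.0)
    return p.lower + (p.upper - p.lower) / (1.0 + np.exp(-z))


def generator_xdep(grid: TraitGrid, sigma2: float, p_ab: SigmoidParams,
                   p_ba: SigmoidParams, boundary: str = "reassign") -> np.ndarray:
    """``2n x 2n`` generator where discrete switch rates vary with the trait.

    Both diffusion blocks share ``sigma2``; the level-switch rate out of bin i
    is the sigmoid evaluated at that bin's center, separately per direction.
    """
    n = grid.n
    c = grid.centers
    Q = np.zeros((2 * n, 2 * n))
    D = generator_diffusion(grid, sigma2, boundary)
    Q[:n, :n] = D
    Q[n:, n:] = D
    Q[np.arange(n), np.arange(n) + n] = sigmoid_rate(c, p_ab)
    Q[np.arange(n) + n, np.arange(n)] = sigmoid_rate(c, p_ba)
    idx = np.arange(2 * n)
    Q[idx, idx] = 0.0
    Q[idx, idx] = -Q.sum(axis=1)
    return Q
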