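"""Tip encoding, edge propagation, pruning, and the probability-to-density
back-transform for discretized-diffusion models on trees.

The probability of the discretized data is computed with Felsenstein's pruning
algorithm.  Edge propagation decomposes the generator once per likelihood
evaluation: symmetric generators by a real eigendecomposition, non-symmetric
ones (trends, asymmetric or trait-dependent switch rates) by stable sparse
uniformization.  Edges whose child subtrees are complete at the same pruning
"wave" are propagated together as one batched product, and partial likelihoods
are rescaled per node to avoid underflow on large trees.

For m point-valued (continuous) tips the probability p of the discretized data
relates to the probability density f of the original continuous data as
``log f = log p - m log delta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sparse

from .discretize import TraitGrid
from .treesim import Tree

__all__ = [
    "TipObservation",
    "encode_tip",
    "encode_tips",
    "edge_propagator",
    "Propagator",
    "PruningEngine",
    "prune_loglik",
    "loglik_density",
]


@dataclass(frozen=True)
class TipObservation:
    """A single tip datum.

    kind:
      * ``point``    - continuous value ``value`` (contributes a density)
      * ``interval`` - liability known to lie in ``(lo, hi]``
      * ``discrete`` - ordered level index ``level`` (threshold or Mk models)
      * ``joint``    - discrete ``level`` plus continuous ``value``
      * ``censored`` - clamped at ``value`` on ``side`` ('low' or 'high')
      * ``missing``  - fully ambiguous
    """

    taxon: str
    kind: str
    value: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    level: Optional[int] = None
    side: Optional[str] = None

    def __post_init__(self):
        if self.kind in ("point", "joint") and not np.isfinite(self.value):
            raise ValueError(f"{self.kind} observation needs a finite value")
        if self.kind == "interval" and not self.lo < self.hi:
            raise ValueError("interval needs lo < hi")
        if self.kind == "censored" and self.side not in ("low", "high"):
            raise ValueError("censored side must be 'low' or 'high'")


def _interval_mask(centers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return ((centers >= lo) & (centers < hi)).astype(float)


def encode_tip(obs: TipObservation, grid: TraitGrid, k: int = 1,
               thresholds=None) -> np.ndarray:
    """Encode one tip observation as a partial-likelihood vector of length k*n.

    States are ordered (level 0, bins...), ..., (level k-1, bins...).  Discrete
    observations under a threshold model use the liability intervals implied by
    the ordered ``thresholds`` (with -inf/+inf end intervals); under joint
    models (no thresholds) they select a whole level block.
    """
    n = grid.n
    c = grid.centers
    if thresholds is not None:
        thresholds = np.asarray(thresholds, dtype=float)
        if np.any(np.diff(thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if thresholds.min() <= grid.lo or thresholds.max() >= grid.hi:
            raise ValueError("thresholds must lie inside the grid span")

    if obs.kind == "missing":
        return np.ones(k * n)
    if obs.kind == "point":
        v = np.zeros(k * n)
        b = int(grid.bin_of(obs.value))
        v[b::n] = 1.0  # ambiguous over levels if k > 1
        return v
    if obs.kind == "joint":
        if obs.level is None or not 0 <= obs.level < k:
            raise ValueError("joint observation needs a level in [0, k)")
        v = np.zeros(k * n)
        v[obs.level * n + int(grid.bin_of(obs.value))] = 1.0
        return v
    if obs.kind == "interval":
        v = np.tile(_interval_mask(c, obs.lo, obs.hi), k)
        return v
    if obs.kind == "censored":
        mask = (c >= obs.value) if obs.side == "high" else (c <= obs.value)
        return np.tile(mask.astype(float), k)
    if obs.kind == "discrete":
        j = int(obs.level)
        if thresholds is not None:
            edges = np.concatenate([[-np.inf], thresholds, [np.inf]])
            if not 0 <= j < edges.size - 1:
                raise ValueError("level index outside threshold intervals")
            return np.tile(_interval_mask(c, edges[j], edges[j + 1]), k)
        if not 0 <= j < k:
            raise ValueError("level index outside [0, k)")
        v = np.zeros(k * n)
        v[j * n:(j + 1) * n] = 1.0
        return v
    raise ValueError(f"unknown observation kind {obs.kind!r}")


def encode_tips(observations, grid: TraitGrid, k: int = 1, thresholds=None) -> dict:
    """Encode a list of observations into {taxon: partial-likelihood vector}."""
    return {o.taxon: encode_tip(o, grid, k, thresholds) for o in observations}


# -- propagation -----------------------------------------------------------

class Propagator:
    """Action of ``exp(Q t)`` for many t at once, decomposing Q only once.

    Symmetric generators (reversible chains with uniform weights: plain and
    state-dependent diffusion with equal switch rates) use one real orthogonal
    eigendecomposition; every edge then costs two matrix products.

    Non-symmetric generators (trended diffusion, asymmetric switch rates,
    trait-dependent switch rates) are handled by uniformization:
    ``exp(Q t) v = sum_k Pois(k; Omega t) R^k v`` with ``R = I + Q/Omega`` and
    ``Omega >= max_i |Q_ii|``.  All series terms are nonnegative, so the
    scheme is unconditionally stable even where the eigenvector basis of the
    drifted chain is exponentially ill-conditioned; R is applied as a sparse
    matrix and all edges of a batch advance through the series together.
    """

    _POIS_TAIL = 1e-12
    _MAX_LAMBDA = 500.0  # split longer intervals to keep exp(-lambda) in range

    def __init__(self, Q: np.ndarray, weights=None):
        Q = np.asarray(Q, dtype=float)
        self.Q = Q
        self.m = Q.shape[0]
        tol = 1e-10 * max(1.0, np.abs(Q).max())
        self._D = None
        if weights is not None:
            D = np.sqrt(np.asarray(weights, dtype=float))
            S = Q * (D[:, None] / D[None, :])
            if np.allclose(S, S.T, rtol=0, atol=tol):
                self.symmetric = True
                self._D = D
                self.w, self.U = sla.eigh(0.5 * (S + S.T))
                return
        self.symmetric = np.allclose(Q, Q.T, rtol=0, atol=tol)
        self._eig = None
        if self.symmetric:
            self.w, self.U = sla.eigh(Q)
        else:
            if self.m <= 12:
                # small discrete-character generators: complex eig is cheap
                # and safe (uniformization series explode at high rates)
                w, V = sla.eig(Q)
                if np.isfinite(V).all() and np.linalg.cond(V) < 1e8:
                    self._eig = (w, V, sla.lu_factor(V))
            self.Omega = float(-Q.diagonal().min()) * (1.0 + 1e-9)
            if self.Omega > 0:
                R = Q / self.Omega
                R[np.arange(self.m), np.arange(self.m)] += 1.0
                self.R = sparse.csr_matrix(np.where(np.abs(R) > 0, R, 0.0))

    def matrix(self, t: float) -> np.ndarray:
        """Dense ``exp(Q t)``."""
        if self.symmetric:
            P = (self.U * np.exp(self.w * t)) @ self.U.T
            if self._D is not None:
                P = (P / self._D[:, None]) * self._D[None, :]
            return P
        return sla.expm(self.Q * t)

    def propagate(self, B: np.ndarray, ts: np.ndarray) -> np.ndarray:
        """Column j of the result is ``exp(Q ts[j]) @ B[:, j]``."""
        ts = np.asarray(ts, dtype=float)
        if self.symmetric:
            Bs = B * self._D[:, None] if self._D is not None else B
            Y = self.U.T @ Bs
            Y *= np.exp(self.w[:, None] * ts[None, :])
            out = self.U @ Y
            if self._D is not None:
                out = out / self._D[:, None]
            return out
        if self._eig is not None:
            w, V, lu = self._eig
            Y = sla.lu_solve(lu, B.astype(complex))
            Y *= np.exp(w[:, None] * ts[None, :])
            return np.maximum((V @ Y).real, 0.0)
        if self.Omega <= 0:
            return B.copy()
        lam_max = self.Omega * ts.max(initial=0.0)
        chunks = max(int(np.ceil(lam_max / self._MAX_LAMBDA)), 1)
        out = B
        for _ in range(chunks):
            out = self._uniformize(out, ts / chunks)
        return out

    def _uniformize(self, B: np.ndarray, ts: np.ndarray) -> np.ndarray:
        lam = self.Omega * ts
        K = int(np.ceil(lam.max() + 8.0 * np.sqrt(lam.max() + 1.0) + 20.0))
        w = np.exp(-lam)          # Poisson weight at k per column
        done = np.exp(-lam)       # accumulated weight mass
        acc = B * w
        C = B
        for k in range(1, K + 1):
            C = self.R @ C
            w = w * lam / k
            acc += C * w
            done += w
            if done.min() > 1.0 - self._POIS_TAIL:
                break
        return acc


def edge_propagator(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition-probability matrix ``P = exp(Q t)`` for one edge."""
    if t < 0:
        raise ValueError("negative branch length")
    return sla.expm(np.asarray(Q, dtype=float) * t)


# -- pruning ---------------------------------------------------------------

class PruningEngine:
    """Precomputed traversal structure for repeated pruning on one tree.

    Nodes are grouped into "waves" by distance-from-tips so that all edges
    whose child partials are ready can be propagated in a single batched
    matrix product.
    """

    def __init__(self, tree: Tree):
        self.tree = tree
        n = tree.n_nodes
        children = tree.children
        level = np.zeros(n, dtype=np.int64)
        for node in tree.postorder:
            if children[node]:
                level[node] = 1 + max(level[c] for c in children[node])
        self.level = level
        self.n_waves = int(level[tree.root]) + 1
        # wave w: all non-root nodes with level == w, propagated along their edge
        self.wave_nodes = [np.array([i for i in range(n)
                                     if level[i] == w and i != tree.root], dtype=np.int64)
                           for w in range(self.n_waves)]
        self.tip_ids = tree.tip_ids
        self.tip_order = {tree.labels[t]: t for t in self.tip_ids}

    def loglik(self, prop: Propagator, tip_partials: dict, root_prior: np.ndarray,
               time_scale: float = 1.0) -> float:
        """Log probability of the encoded tip data under the generator.

        ``tip_partials`` maps taxon label -> state vector; ``root_prior`` is a
        distribution over generator states.  ``time_scale`` multiplies every
        branch length, which evaluates ``exp((time_scale * Q) t)`` from a
        single decomposition when the generator scales linearly with a rate.
        """
        tree = self.tree
        m = prop.m
        V = np.zeros((tree.n_nodes, m))
        logscale = np.zeros(tree.n_nodes)
        for lab, vec in tip_partials.items():
            V[self.tip_order[lab]] = vec
        msg = np.zeros((tree.n_nodes, m))  # message arriving at the parent
        children = tree.children
        for w in range(self.n_waves):
            nodes = self.wave_nodes[w]
            if w > 0:
                for i in nodes:  # non-root nodes at level w are all internal
                    v = np.prod([msg[c] for c in children[i]], axis=0)
                    s = v.max()
                    if s <= 0 or not np.isfinite(s):
                        return -np.inf
                    V[i] = v / s
                    logscale[i] = np.log(s) + sum(logscale[c] for c in children[i])
            if nodes.size:
                B = V[nodes].T
                ts = tree.edge_length[nodes] * time_scale
                msg[nodes] = prop.propagate(B, ts).T
        root = tree.root
        v = np.prod([msg[c] for c in children[root]], axis=0)
        p = float(root_prior @ v)
        if p <= 0 or not np.isfinite(p):
            return -np.inf
        return np.log(p) + sum(logscale[c] for c in children[root])


def prune_loglik(tree: Tree, Q: np.ndarray, tip_partials: dict,
                 root_prior: np.ndarray) -> float:
    """One-shot pruning log-probability (builds engine and propagator)."""
    return PruningEngine(tree).loglik(Propagator(Q), tip_partials, root_prior)


def loglik_density(log_p: float, delta: float, m_point: int) -> float:
    """Back-transform a discretized probability to a log density.

    Only tips contributing a point observation divide by the bin width;
    censored and discrete tips contribute probabilities, not densities.
    """
    if m_point < 0:
        raise ValueError("m_point must be nonnegative")
    return log_p - m_point * np.log(delta)
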