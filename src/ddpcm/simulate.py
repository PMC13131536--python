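"""Forward simulators for every generating process in the package.

All simulators are seeded and return their latent state (liabilities, discrete
histories) alongside the observable tip data, so that independent oracle tests
can condition on the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import SigmoidParams, sigmoid_rate
from .likelihood import TipObservation
from .treesim import Tree

__all__ = [
    "DiscreteHistory",
    "sim_bm",
    "sim_bounded",
    "sim_threshold",
    "sim_semithreshold",
    "sim_mk_history",
    "sim_statedep",
    "sim_xdep",
]


@dataclass
class DiscreteHistory:
    """Piecewise-constant discrete-character history along every edge.

    ``segments[node]`` lists ``(level, duration)`` pairs for the edge above
    ``node``, ordered rootward to tipward; durations sum to the edge length.
    """

    tree: Tree
    root_level: int
    segments: dict = field(default_factory=dict)

    @property
    def node_levels(self) -> np.ndarray:
        """Level at the end of each node's subtending edge (root: root_level)."""
        lv = np.full(self.tree.n_nodes, self.root_level, dtype=np.int64)
        for node, segs in self.segments.items():
            lv[node] = segs[-1][0]
        return lv

    @property
    def tip_levels(self) -> pd.Series:
        lv = self.node_levels
        tips = self.tree.tip_ids
        return pd.Series([int(lv[t]) for t in tips],
                         index=[self.tree.labels[t] for t in tips])

    def n_changes(self) -> int:
        return sum(len(s) - 1 for s in self.segments.values())

    def durations_by_level(self, k: int) -> dict:
        """``{node: length-k array of durations per level}`` for every edge."""
        out = {}
        for node, segs in self.segments.items():
            d = np.zeros(k)
            for lvl, dur in segs:
                d[lvl] += dur
            out[node] = d
        return out

    def to_simmap(self) -> str:
        """Simmap-style annotated Newick (edge segments as {state,duration})."""
        tree = self.tree

        def render(node):
            lab = tree.labels[node] or ""
            kids = tree.children[node]
            inner = "(" + ",".join(render(c) for c in kids) + ")" if kids else ""
            if node == tree.root:
                return inner + lab
            segs = self.segments[node]
            # simmap lists segments from the tipward end rootward
            ann = ":".join(f"{lvl},{dur:.9g}" for lvl, dur in reversed(segs))
            return f"{inner}{lab}:{{{ann}}}"

        return render(tree.root) + ";"


def _tip_series(tree: Tree, values: np.ndarray) -> pd.Series:
    tips = tree.tip_ids
    return pd.Series(values[tips], index=[tree.labels[t] for t in tips])


def sim_bm(tree: Tree, x0: float, sigma2: float, seed=None, reps: int = None,
           return_internal: bool = False):
    """Brownian motion on the tree: independent N(0, sigma2*t) edge increments.

    With ``reps`` set, returns an (reps, n_tips) array (tips in
    ``tree.tip_labels`` order); otherwise a pandas Series indexed by taxon.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(seed)
    r = 1 if reps is None else int(reps)
    vals = np.zeros((r, tree.n_nodes))
    vals[:, tree.root] = x0
    order = tree.postorder[::-1]  # preorder
    sd = np.sqrt(sigma2 * tree.edge_length)
    for node in order:
        p = tree.parent[node]
        if p >= 0:
            vals[:, node] = vals[:, p] + rng.normal(0.0, sd[node], size=r)
    if reps is not None:
        return vals[:, tree.tip_ids]
    if return_internal:
        return _tip_series(tree, vals[0]), vals[0]
    return _tip_series(tree, vals[0])


def _reflect(x: np.ndarray, a: float, b: float) -> np.ndarray:
    # fold into [a, b]; loop handles (rare) multi-crossing steps
    for _ in range(100):
        over, under = x > b, x < a
        if not (over.any() or under.any()):
            break
        x = np.where(over, 2 * b - x, x)
        x = np.where(under, 2 * a - x, x)
    return x


def sim_bounded(tree: Tree, x0: float, sigma2: float, a: float, b: float,
                dt: float = None, seed=None, reps: int = None):
    """Brownian motion with reflecting bounds, by Euler-Maruyama with folding."""
    if not a < x0 < b:
        raise ValueError("x0 must lie strictly inside the bounds")
    if dt is None:
        dt = tree.depth / 1000.0
    rng = np.random.default_rng(seed)
    r = 1 if reps is None else int(reps)
    vals = np.zeros((r, tree.n_nodes))
    vals[:, tree.root] = x0
    for node in tree.postorder[::-1]:
        p = tree.parent[node]
        if p < 0:
            continue
        t = tree.edge_length[node]
        nstep = max(int(np.ceil(t / dt)), 1)
        h = t / nstep
        x = vals[:, p].copy()
        sd = np.sqrt(sigma2 * h)
        for _ in range(nstep):
            x = _reflect(x + rng.normal(0.0, sd, size=r), a, b)
        vals[:, node] = x
    if reps is not None:
        return vals[:, tree.tip_ids]
    return _tip_series(tree, vals[0])


def sim_threshold(tree: Tree, x0: float, sigma2: float, thresholds, seed=None):
    """Threshold model: BM liability; level = index of the liability interval.

    Returns ``(levels, liabilities)`` as taxon-indexed Series.  The liability
    draw is exactly ``sim_bm`` with the same seed (shared stream).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    liab = sim_bm(tree, x0, sigma2, seed=seed)
    levels = pd.Series(np.searchsorted(thresholds, liab.to_numpy(), side="right"),
                       index=liab.index)
    return levels, liab


def sim_semithreshold(tree: Tree, x0: float, sigma2: float, clamp=(-1.0, 1.0),
                      seed=None):
    """Semi-threshold model: liability observable only inside ``clamp``.

    Returns ``(observations, liabilities)``; tips outside the observable range
    are reported as censored on the corresponding side.
    """
    low, high = clamp
    if not low < high:
        raise ValueError("clamp low must be below clamp high")
    liab = sim_bm(tree, x0, sigma2, seed=seed)
    obs = []
    for taxon, v in liab.items():
        if v <= low:
            obs.append(TipObservation(taxon, "censored", value=low, side="low"))
        elif v >= high:
            obs.append(TipObservation(taxon, "censored", value=high, side="high"))
        else:
            obs.append(TipObservation(taxon, "point", value=float(v)))
    return obs, liab


def sim_mk_history(tree: Tree, Q_discrete: np.ndarray, root_level: int = 0,
                   seed=None) -> DiscreteHistory:
    """Exact (Gillespie) simulation of a k-state Markov chain along the tree."""
    Q = np.asarray(Q_discrete, dtype=float)
    k = Q.shape[0]
    if Q.shape != (k, k):
        raise ValueError("Q_discrete must be square")
    rng = np.random.default_rng(seed)
    hist = DiscreteHistory(tree, int(root_level))
    start = np.full(tree.n_nodes, -1, dtype=np.int64)
    start[tree.root] = root_level
    for node in tree.postorder[::-1]:
        p = tree.parent[node]
        if p < 0:
            continue
        state = start[p]
        t_left = tree.edge_length[node]
        segs = []
        while True:
            rate = -Q[state, state]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if wait >= t_left:
                segs.append((int(state), float(t_left)))
                break
            segs.append((int(state), float(wait)))
            t_left -= wait
            probs = Q[state].copy()
            probs[state] = 0.0
            probs /= probs.sum()
            state = rng.choice(k, p=probs)
        hist.segments[node] = segs
        start[node] = state
    return hist


def sim_statedep(tree: Tree, history: DiscreteHistory, sigma2_by_level,
                 mu_by_level=None, x0: float = 0.0, seed=None) -> pd.Series:
    """State-dependent (multi-rate, multi-trend) BM given a discrete history.

    Each history segment contributes a Gaussian increment with mean
    ``mu_level * duration`` and variance ``sigma2_level * duration``.
    """
    if history.tree is not tree and history.tree.n_nodes != tree.n_nodes:
        raise ValueError("history does not cover this tree")
    s2 = np.asarray(sigma2_by_level, dtype=float)
    mu = np.zeros_like(s2) if mu_by_level is None else np.asarray(mu_by_level, dtype=float)
    rng = np.random.default_rng(seed)
    vals = np.zeros(tree.n_nodes)
    vals[tree.root] = x0
    for node in tree.postorder[::-1]:
        p = tree.parent[node]
        if p < 0:
            continue
        x = vals[p]
        for lvl, dur in history.segments[node]:
            x += mu[lvl] * dur + rng.normal(0.0, np.sqrt(s2[lvl] * dur))
        vals[node] = x
    return _tip_series(tree, vals)


def sim_xdep(tree: Tree, x0: float, sigma2: float, p_ab: SigmoidParams,
             p_ba: SigmoidParams, dt: float = None, seed=None,
             root_level: int = 0):
    """Continuous trait BM whose value sets the discrete switch hazard.

    Euler scheme: per step the trait takes a N(0, sigma2*dt) increment and the
    binary level switches with probability ``rate(x) * dt``.  Returns
    ``(values, levels)`` as taxon-indexed Series.
    """
    if dt is None:
        dt = tree.depth / 1000.0
    rng = np.random.default_rng(seed)
    max_rate = max(np.max(sigmoid_rate(np.array([-1e6, 0.0, 1e6]), p)) for p in (p_ab, p_ba))
    if max_rate * dt > 0.1:
        import warnings
        warnings.warn("dt too coarse for the switch hazard; refine dt")
    vals = np.zeros(tree.n_nodes)
    levels = np.zeros(tree.n_nodes, dtype=np.int64)
    vals[tree.root] = x0
    levels[tree.root] = root_level
    for node in tree.postorder[::-1]:
        p = tree.parent[node]
        if p < 0:
            continue
        t = tree.edge_length[node]
        nstep = max(int(np.ceil(t / dt)), 1)
        h = t / nstep
        x, lvl = vals[p], levels[p]
        sd = np.sqrt(sigma2 * h)
        for _ in range(nstep):
            x += rng.normal(0.0, sd)
            rate = sigmoid_rate(x, p_ab if lvl == 0 else p_ba)
            if rng.random() < rate * h:
                lvl = 1 - lvl
        vals[node] = x
        levels[node] = lvl
    return _tip_series(tree, vals), pd.Series(
        levels[tree.tip_ids], index=[tree.labels[t] for t in tree.tip_ids])
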