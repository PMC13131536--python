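"""Classic two-step state-dependent rate estimation.

The comparator for the joint discretized model: (1) sample stochastic
character maps of the discrete trait in proportion to their probability,
(2) fit the Gaussian state-dependent BM model to each map (tip covariance is
the per-level shared branch duration scaled by that level's rate), and
(3) average rate estimates across maps.  Edge paths are sampled by
uniformization, which stays robust at high transition rates where naive
rejection sampling fails.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, expm
from scipy.optimize import minimize
from scipy.stats import poisson

from .fitmodels import MkModel, _as_series
from .simulate import DiscreteHistory
from .treesim import Tree

__all__ = ["stochastic_map", "statedep_bm_gaussian_fit", "fit_twostep"]


def _endpoint_conditioned_path(Q, R, Omega, a, b, t, rng, n_cap=400):
    """Sample a CTMC path on [0, t] given endpoint states a -> b (uniformization)."""
    k = Q.shape[0]
    # R powers and the distribution of the number of virtual jumps
    pows = [np.eye(k)]
    probs = []
    pn = poisson.pmf(np.arange(n_cap + 1), Omega * t)
    for n in range(n_cap + 1):
        if n > 0:
            pows.append(pows[-1] @ R)
        probs.append(pn[n] * pows[n][a, b])
        if n > 5 and pn[n:].sum() < 1e-12 * max(sum(probs), 1e-300):
            break
    probs = np.array(probs)
    tot = probs.sum()
    if tot <= 0:
        raise RuntimeError("endpoint-conditioned sampling failed (impossible endpoints?)")
    n = rng.choice(probs.size, p=probs / tot)
    states = [a]
    for i in range(n):
        s = states[-1]
        w = R[s] * pows[n - i - 1][:, b]
        states.append(rng.choice(k, p=w / w.sum()))
    times = np.sort(rng.uniform(0.0, t, size=n))
    # collapse virtual (self) jumps into segments
    segs = []
    cur, t0 = a, 0.0
    for s, tj in zip(states[1:], times):
        if s != cur:
            segs.append((int(cur), float(tj - t0)))
            cur, t0 = s, tj
    segs.append((int(cur), float(t - t0)))
    return segs


def stochastic_map(tree: Tree, tip_levels, Q_discrete, n_maps: int = 100,
                   seed=None, root_prior=None) -> list:
    """Sample discrete-character histories in proportion to their probability.

    Node states are drawn from the pruning conditionals (forward-filtering,
    backward-sampling down the tree); each edge path is then sampled
    conditional on its endpoint states by uniformization.
    """
    ys = _as_series(tree, tip_levels).astype(int)
    Q = np.asarray(Q_discrete, dtype=float)
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    children = tree.children
    post = tree.postorder
    tip_level = {lab: j for lab, j in ys.items()}

    # per-node conditional likelihoods (rescaled) and per-edge transition matrices
    P = {int(i): expm(Q * tree.edge_length[i]) for i in range(tree.n_nodes)
         if i != tree.root}
    L = np.zeros((tree.n_nodes, k))
    for node in post:
        if children[node]:
            v = np.ones(k)
            for c in children[node]:
                v = v * (P[c] @ L[c])
            L[node] = v / v.max()
        else:
            L[node] = np.eye(k)[tip_level[tree.labels[node]]]

    Omega = float(-Q.diagonal().min()) * 1.05 + 1e-12
    R = np.eye(k) + Q / Omega
    maps = []
    for _ in range(n_maps):
        state = np.zeros(tree.n_nodes, dtype=np.int64)
        w = prior * L[tree.root]
        state[tree.root] = rng.choice(k, p=w / w.sum())
        hist = DiscreteHistory(tree, int(state[tree.root]))
        for node in post[::-1]:
            p = tree.parent[node]
            if p < 0:
                continue
            w = P[node][state[p]] * L[node]
            state[node] = rng.choice(k, p=w / w.sum())
            hist.segments[node] = _endpoint_conditioned_path(
                Q, R, Omega, int(state[p]), int(state[node]),
                float(tree.edge_length[node]), rng)
        maps.append(hist)
    return maps


def _level_durations_to_root(tree: Tree, history: DiscreteHistory, k: int):
    """Cumulative per-level durations along each node's root path."""
    d = np.zeros((tree.n_nodes, k))
    by_edge = history.durations_by_level(k)
    for node in tree.postorder[::-1]:
        p = tree.parent[node]
        if p >= 0:
            d[node] = d[p] + by_edge[node]
    return d


def statedep_bm_gaussian_fit(tree: Tree, history: DiscreteHistory, x, k: int = None):
    """Exact-Gaussian ML fit of per-level BM rates given one discrete history.

    Tip covariance is ``sum_i sigma_i^2 C_i`` with ``C_i[u, v]`` the duration
    spent in level i on the shared root path of u and v.  Returns
    ``(sigma2_by_level, loglik)``; levels absent from the history get NaN.
    """
    xs = _as_series(tree, x).astype(float).to_numpy()
    if k is None:
        k = int(max(max(lvl for lvl, _ in segs) for segs in history.segments.values())) + 1
        k = max(k, history.root_level + 1)
    d = _level_durations_to_root(tree, history, k)
    tips = tree.tip_ids
    N = tips.size
    C = np.zeros((k, N, N))
    for i in range(N):
        C[:, i, i] = d[tips[i]]
        for j in range(i + 1, N):
            a = d[tree.mrca(tips[i], tips[j])]
            C[:, i, j] = C[:, j, i] = a
    present = np.array([C[i].diagonal().sum() > 0 for i in range(k)])
    one = np.ones(N)

    def negll(log_s2):
        s2 = np.exp(np.clip(log_s2, -20, 20))
        Sig = np.tensordot(s2, C[present], axes=1)
        try:
            cf = cho_factor(Sig)
        except np.linalg.LinAlgError:
            return np.inf
        x0 = one @ cho_solve(cf, xs) / (one @ cho_solve(cf, one))
        r = xs - x0
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return 0.5 * (N * np.log(2 * np.pi) + logdet + r @ cho_solve(cf, r))

    tot = np.var(xs) / max(tree.depth, 1e-9)
    res = minimize(negll, np.full(int(present.sum()), np.log(max(tot, 1e-6))),
                   method="Nelder-Mead", options=dict(xatol=1e-5, fatol=1e-8))
    s2 = np.full(k, np.nan)
    s2[present] = np.exp(res.x)
    return s2, -float(res.fun)


def fit_twostep(tree: Tree, y, x, n_maps: int = 100, seed=None) -> dict:
    """Mk fit -> stochastic maps -> per-map Gaussian fits -> averaged rates.

    Per-level rate estimates are averaged across maps (a level missing from a
    map is skipped in its average).
    """
    ys = _as_series(tree, y).astype(int)
    k = int(ys.max()) + 1
    mk = MkModel(variant="ER", k=k, restarts=1, seed=seed).fit(tree, ys)
    q = mk.params_["q"]
    Q = np.full((k, k), q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    maps = stochastic_map(tree, ys, Q, n_maps=n_maps, seed=seed)
    per_map = np.array([statedep_bm_gaussian_fit(tree, h, x, k)[0] for h in maps])
    mean_s2 = np.nanmean(per_map, axis=0)
    return {"q": float(q), "sigma2_by_state": mean_s2,
            "per_map_sigma2": per_map, "n_maps": len(maps)}
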