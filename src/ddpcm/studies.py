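"""Turnkey simulation studies: generate -> fit -> tabulate, at configurable scale.

Each study reproduces one of the package's simulation experiments: data are
generated under a model family's own process on stochastic pure-birth trees,
the corresponding discretized-diffusion model (plus its competitors) is fitted
to every replicate, and a tidy per-replicate table of generating vs estimated
parameters is returned.  ``scale='full'`` uses the original experiment sizes;
``scale='desk'`` reduces replicate counts (and, where safe, bin numbers) so a
study runs on a single workstation core in minutes.

All randomness flows from the one top-level ``seed``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .fitmodels import (BoundedBrownianMotion, BrownianMotionML, MkModel,
                        MultiTrendBM, SemiThresholdModel, StateDependentBM,
                        ThresholdModel, akaike_weights)
from .simulate import (sim_bounded, sim_mk_history, sim_semithreshold,
                       sim_statedep, sim_threshold)
from .treesim import make_nonultrametric, simulate_pure_birth
from .twostep import fit_twostep

__all__ = ["run_study", "summarize", "STUDIES"]

log = logging.getLogger("ddpcm.studies")

# (replicates, taxa) at each scale; other knobs are per-study below
# Desk scale trims replicate counts but keeps the tree size of the original
# experiments: several estimators change behavior qualitatively on smaller
# trees (the Mk rate likelihood saturates and loses its interior maximum on
# 100-taxon depth-1 trees), so tip count is a study condition, not a knob.
_SCALES = {
    "bounded": {"full": (100, 200), "desk": (25, 100)},
    "threshold": {"full": (100, 200), "desk": (25, 200)},
    "semithreshold": {"full": (100, 200), "desk": (25, 100)},
    "statedep": {"full": (40, 200), "desk": (40, 200)},
    "multitrend": {"full": (20, 200), "desk": (10, 200)},
}

STUDIES = tuple(_SCALES)


def _rep_seeds(seed, n):
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=max(n, 1))


def run_study(study: str, scale: str = "desk", seed=None, n_reps: int = None,
              n_taxa: int = None, **options) -> pd.DataFrame:
    """Run one replication study and return its per-replicate results table."""
    if study not in _SCALES:
        raise ValueError(f"unknown study {study!r}; choose from {STUDIES}")
    reps, taxa = _SCALES[study][scale]
    reps = n_reps if n_reps is not None else reps
    taxa = n_taxa if n_taxa is not None else taxa
    fn = globals()[f"_study_{study}"]
    rows = []
    for rep, s in enumerate(_rep_seeds(seed, reps)[:reps]):
        row = fn(int(s), taxa, scale, **options)
        row.update(rep=rep, seed=int(s))
        log.info("study=%s rep=%d seed=%d done", study, rep, s)
        rows.append(row)
    return pd.DataFrame(rows)


# -- individual studies ----------------------------------------------------

def _study_bounded(seed, taxa, scale, depth=1.0, bins=None):
    """Bounded-BM recovery: log sigma2 ~ N(0,1), reflecting bounds [-1, 1]."""
    rng = np.random.default_rng(seed)
    bins = bins or (100 if scale == "desk" else 200)
    tree = simulate_pure_birth(taxa, depth, rng.integers(2**31))
    s2 = float(np.exp(rng.normal(0.0, 1.0)))
    x0 = float(rng.uniform(-0.5, 0.5))
    x = sim_bounded(tree, x0, s2, -1.0, 1.0, seed=rng.integers(2**31))
    fit_b = BoundedBrownianMotion(bins=bins, restarts=1, seed=seed).fit(tree, x)
    fit_u = BrownianMotionML().fit(tree, x)
    return {"gen_sigma2": s2, "gen_x0": x0,
            "est_sigma2_bounded": fit_b.params_["sigma2"],
            "est_x0_bounded": fit_b.params_["x0"],
            "est_sigma2_bm": fit_u.params_["sigma2"],
            "est_x0_bm": fit_u.params_["x0"],
            "lnL_bounded": fit_b.loglik_, "lnL_bm": fit_u.loglik_,
            "converged": fit_b.converged_}


def _study_threshold(seed, taxa, scale, depth=3.0, bins=None,
                     thresholds=(0.0, 0.8, 1.0)):
    """Threshold-model selection: liability BM (sigma2=1, x0 ~ U[-1,3])."""
    rng = np.random.default_rng(seed)
    bins = bins or (150 if scale == "desk" else 300)
    tree = simulate_pure_birth(taxa, depth, rng.integers(2**31))
    x0 = float(rng.uniform(-1.0, 3.0))
    levels, _ = sim_threshold(tree, x0, 1.0, thresholds, seed=rng.integers(2**31))
    if levels.nunique() < 2:  # monomorphic replicate: no model is fittable
        return {"gen_x0": x0, "n_levels": 1, "top_model": None}
    fits = {}
    fits["threshold"] = ThresholdModel(bins=bins, restarts=1, seed=seed).fit(
        tree, levels).result_
    for name, variant in (("mk_sym", "ordered-symmetric"),
                          ("mk_asym", "ordered-asymmetric")):
        fits[name] = MkModel(variant=variant, restarts=1, seed=seed).fit(
            tree, levels).result_
    names = list(fits)
    w = akaike_weights([fits[n] for n in names])
    est_thr = fits["threshold"].params["thresholds"]
    row = {"gen_x0": x0, "n_levels": int(levels.nunique()),
           "est_root_liability": fits["threshold"].params["root_liability"],
           "top_model": names[int(np.argmax(w))]}
    for n, wi in zip(names, w):
        row[f"w_{n}"] = float(wi)
        row[f"aic_{n}"] = fits[n].aic
    for j, t in enumerate(thresholds):
        row[f"gen_threshold{j}"] = t
        row[f"est_threshold{j}"] = est_thr[j] if j < len(est_thr) else np.nan
    return row


def _study_semithreshold(seed, taxa, scale, depth=1.0, bins=None,
                         clamp=(-1.0, 1.0)):
    """Semi-threshold recovery: log sigma2 ~ N(0,1), x0 ~ U[-1,1], clamp [-1,1]."""
    rng = np.random.default_rng(seed)
    bins = bins or (120 if scale == "desk" else 200)
    tree = simulate_pure_birth(taxa, depth, rng.integers(2**31))
    s2 = float(np.exp(rng.normal(0.0, 1.0)))
    x0 = float(rng.uniform(-1.0, 1.0))
    obs, liab = sim_semithreshold(tree, x0, s2, clamp, seed=rng.integers(2**31))
    n_cens = sum(o.kind == "censored" for o in obs)
    fit_s = SemiThresholdModel(clamp=clamp, bins=bins, restarts=1,
                               seed=seed).fit(tree, obs)
    clamped = pd.Series({o.taxon: (o.value if o.kind == "point"
                                   else (clamp[0] if o.side == "low" else clamp[1]))
                         for o in obs})
    fit_u = BrownianMotionML().fit(tree, clamped)
    return {"gen_sigma2": s2, "gen_x0": x0, "n_censored": n_cens,
            "est_sigma2_semi": fit_s.params_["sigma2"],
            "est_x0_semi": fit_s.params_["x0"],
            "est_sigma2_bm": fit_u.params_["sigma2"],
            "est_x0_bm": fit_u.params_["x0"],
            "converged": fit_s.converged_}


def _study_statedep(seed, taxa, scale, depth=1.0, bins=None,
                    include_twostep=False, n_maps=100):
    """State-dependent BM: q ~ U[1,10], sigma2_a ~ U[0.5,2], sigma2_b ~ U[5,20]."""
    rng = np.random.default_rng(seed)
    bins = bins or (100 if scale == "desk" else 150)
    tree = simulate_pure_birth(taxa, depth, rng.integers(2**31))
    q = float(rng.uniform(1.0, 10.0))
    s2a = float(rng.uniform(0.5, 2.0))
    s2b = float(rng.uniform(5.0, 20.0))
    Q = np.array([[-q, q], [q, -q]])
    hist = sim_mk_history(tree, Q, root_level=int(rng.integers(2)),
                          seed=rng.integers(2**31))
    x = sim_statedep(tree, hist, [s2a, s2b], x0=0.0, seed=rng.integers(2**31))
    y = hist.tip_levels
    row = {"gen_q": q, "gen_sigma2_a": s2a, "gen_sigma2_b": s2b,
           "n_changes": hist.n_changes()}
    if y.nunique() < 2:  # monomorphic tips: nothing to fit jointly
        row.update(est_q_joint=np.nan, est_q_mk=np.nan,
                   est_sigma2_a=np.nan, est_sigma2_b=np.nan, converged=False)
        return row
    fit_j = StateDependentBM(bins=bins, restarts=0, seed=seed,
                             maxfev=600).fit(tree, x, y)
    fit_mk = MkModel(variant="ER", k=2, restarts=1, seed=seed).fit(tree, y)
    row.update(est_q_joint=fit_j.params_["q"], est_q_mk=fit_mk.params_["q"],
               est_sigma2_a=fit_j.params_["sigma2_by_state"][0],
               est_sigma2_b=fit_j.params_["sigma2_by_state"][1],
               converged=fit_j.converged_)
    if include_twostep:
        ts = fit_twostep(tree, y, x, n_maps=n_maps, seed=int(rng.integers(2**31)))
        row["twostep_sigma2_a"] = ts["sigma2_by_state"][0]
        row["twostep_sigma2_b"] = ts["sigma2_by_state"][1]
    return row


def _study_multitrend(seed, taxa, scale, depth=10.0, bins=None, q=0.5):
    """Multi-trend BM on non-ultrametric trees: mu_a ~ U[0.2,1],
    mu_b ~ U[-1,-0.2], sigma2 ~ U[0.3,1], q_ab = q_ba = 0.5."""
    rng = np.random.default_rng(seed)
    tree = simulate_pure_birth(taxa, depth, rng.integers(2**31))
    tree = make_nonultrametric(tree, seed=rng.integers(2**31))
    mua = float(rng.uniform(0.2, 1.0))
    mub = float(rng.uniform(-1.0, -0.2))
    s2a = float(rng.uniform(0.3, 1.0))
    s2b = float(rng.uniform(0.3, 1.0))
    Q = np.array([[-q, q], [q, -q]])
    hist = sim_mk_history(tree, Q, root_level=int(rng.integers(2)),
                          seed=rng.integers(2**31))
    x = sim_statedep(tree, hist, [s2a, s2b], [mua, mub], x0=0.0,
                     seed=rng.integers(2**31))
    y = hist.tip_levels
    if bins is None:
        # grid fine enough that the trend box |mu| <= 0.99 sigma^2/delta is
        # roomy for the generating regime (delta around 0.3 trait units)
        span = 2.0 * np.ptp(x.to_numpy())
        bins = int(np.clip(np.ceil(span / 0.3), 60, 120))
    row = {"gen_q": q, "gen_mu_a": mua, "gen_mu_b": mub,
           "gen_sigma2_a": s2a, "gen_sigma2_b": s2b,
           "n_changes": hist.n_changes()}
    if y.nunique() < 2:
        row.update(est_q_joint=np.nan, est_q_mk=np.nan, converged=False)
        return row
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_j = MultiTrendBM(bins=bins, restarts=0, seed=seed,
                             maxfev=800).fit(tree, x, y)
    fit_mk = MkModel(variant="ER", k=2, restarts=1, seed=seed).fit(tree, y)
    row.update(est_q_joint=fit_j.params_["q"], est_q_mk=fit_mk.params_["q"],
               est_mu_a=fit_j.params_["mu_by_state"][0],
               est_mu_b=fit_j.params_["mu_by_state"][1],
               est_sigma2_a=fit_j.params_["sigma2_by_state"][0],
               est_sigma2_b=fit_j.params_["sigma2_by_state"][1],
               converged=fit_j.converged_, bins=bins)
    return row


# -- summaries -------------------------------------------------------------

def _pair_stats(df, gen, est):
    g = df[gen].to_numpy(dtype=float)
    e = df[est].to_numpy(dtype=float)
    ok = np.isfinite(g) & np.isfinite(e)
    g, e = g[ok], e[ok]
    out = {"n": int(ok.sum()), "mean_est": float(np.mean(e)) if ok.any() else np.nan,
           "sd_est": float(np.std(e, ddof=1)) if ok.sum() > 1 else np.nan,
           "bias": float(np.mean(e - g)) if ok.any() else np.nan}
    spread = np.std(g) > 1e-12 * max(1.0, float(np.abs(g).max(initial=0.0)))
    if ok.sum() > 2 and spread and np.std(e) > 0:
        out["r"] = float(np.corrcoef(g, e)[0, 1])
        out["slope"] = float(np.polyfit(g, e, 1)[0])
    else:
        out["r"] = np.nan
        out["slope"] = np.nan
    return out


def summarize(table: pd.DataFrame) -> dict:
    """Per-parameter correlation/slope/bias/SD plus Akaike-weight tallies."""
    if table.empty:
        return {"n_reps": 0}
    out = {"n_reps": int(len(table))}
    for col in table.columns:
        if not col.startswith("gen_"):
            continue
        name = col[4:]
        for est in table.columns:
            if est.startswith(("est_", "twostep_")) and name in est:
                out[est] = _pair_stats(table, col, est)
    if "top_model" in table:
        counts = table["top_model"].value_counts()
        out["top_model_fraction"] = {m: float(c) / len(table)
                                     for m, c in counts.items()}
    return out
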