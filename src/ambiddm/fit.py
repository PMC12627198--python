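"""Per-participant Bayesian estimation of any drift-rate model.

Parameters are sampled on transformed scales (log for positivity-constrained
parameters, logit for the relative starting point) under wide normal priors
(SD 5) that mimic uniform priors.  Sampling uses an affine-invariant ensemble
sampler; one independent, separately seeded ensemble plays the role of one
MCMC chain, so the two-chain default supports split-R-hat convergence checks
(threshold 1.005).  Each fit returns posterior draws, the pointwise
log-likelihood matrix needed for PSIS-LOO model comparison, and convergence
diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, stats

from .ddm_core import (DDMParams, DriftModelSpec, POSITIVE_PARAMS, UNIT_PARAMS,
                       get_model, loglik_trials, trial_attributes)

PRIOR_SD = 5.0
# Weakly informative prior centers on the transformed scales.  t0 centers at
# 0.1 s so the prior mean never exceeds observed RTs.
_PRIOR_CENTERS = {"t0": math.log(0.1)}

RHAT_THRESHOLD = 1.005
MIN_ACCEPTANCE = 0.05   # below this the ensemble is effectively stuck


@dataclass
class MCMCConfig:
    """Sampler settings.  The defaults reproduce the full-scale fitting
    protocol (2 chains, 3,500 warm-up + 4,500 sampling iterations); tests use
    a scaled-down 500/500 configuration."""

    n_chains: int = 2
    n_warmup: int = 3500
    n_sampling: int = 4500
    seed: int = 0
    n_walkers: int | None = None      # default: max(24, 4 * ndim)
    min_trials: int = 50
    max_loo_draws: int = 8000         # pointwise log-lik computed on a thinned set

    def walkers_for(self, ndim: int) -> int:
        return self.n_walkers if self.n_walkers is not None else max(24, 4 * ndim)


SCALED_DOWN = MCMCConfig(n_chains=2, n_warmup=500, n_sampling=500)


@dataclass
class PosteriorFit:
    """Posterior draws (natural scale) plus pointwise log-likelihoods."""

    model_id: str
    participant: int
    param_names: tuple[str, ...]
    draws: np.ndarray               # (n_chains, n_draws_per_chain, ndim)
    pointwise_loglik: np.ndarray    # (n_loo_draws, n_trials)
    loo_chain_shape: tuple[int, int]  # pointwise draws as (chain, draw)
    rhat: dict[str, float]
    acceptance: float
    usable: bool
    n_trials: int

    def posterior_mean(self) -> dict[str, float]:
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        return dict(zip(self.param_names, flat.mean(axis=0)))

    def draws_for(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.draws[..., j].ravel()

    def params_at_mean(self, spec: DriftModelSpec) -> DDMParams:
        return DDMParams.from_vector(
            spec, np.array([self.posterior_mean()[n] for n in self.param_names]))

    def max_rhat(self) -> float:
        return max(self.rhat.values())


# ---------------------------------------------------------------------------
# Transforms and posterior evaluation
# ---------------------------------------------------------------------------

def _transform_flags(spec: DriftModelSpec):
    names = spec.param_names
    is_log = np.array([n in POSITIVE_PARAMS for n in names])
    is_logit = np.array([n in UNIT_PARAMS for n in names])
    centers = np.array([_PRIOR_CENTERS.get(n, 0.0) for n in names])
    return is_log, is_logit, centers


def to_unconstrained(spec: DriftModelSpec, natural: np.ndarray) -> np.ndarray:
    is_log, is_logit, _ = _transform_flags(spec)
    x = np.array(natural, dtype=float)
    x[is_log] = np.log(x[is_log])
    x[is_logit] = np.log(x[is_logit] / (1.0 - x[is_logit]))
    return x


def to_natural(spec: DriftModelSpec, x: np.ndarray) -> np.ndarray:
    is_log, is_logit, _ = _transform_flags(spec)
    nat = np.array(x, dtype=float)
    nat[..., is_log] = np.exp(nat[..., is_log])
    nat[..., is_logit] = 1.0 / (1.0 + np.exp(-nat[..., is_logit]))
    return nat


@njit(cache=True)
def _logpost_batch(code, X, is_log, is_logit, centers, prior_sd,
                   V, D, P, amb, rt, chose_upper, switched):
    m, d = X.shape
    out = np.empty(m)
    nat = np.empty(d)
    ll = np.empty(rt.shape[0])
    for i in range(m):
        lp = 0.0
        bad = False
        for j in range(d):
            x = X[i, j]
            if abs(x) > 50.0:       # exp/logit overflow guard
                bad = True
                break
            c = (x - centers[j]) / prior_sd
            lp -= 0.5 * c * c
            if is_log[j]:
                nat[j] = math.exp(x)
            elif is_logit[j]:
                nat[j] = 1.0 / (1.0 + math.exp(-x))
            else:
                nat[j] = x
        if bad:
            out[i] = -np.inf
            continue
        loglik_trials(code, nat, V, D, P, amb, rt, chose_upper, switched, ll)
        s = 0.0
        for t in range(ll.shape[0]):
            s += ll[t]
        out[i] = lp + s
    return out


def _data_arrays(records: pd.DataFrame | list):
    """Pack usable (non-outlier, non-catch) trials into likelihood arrays."""
    if isinstance(records, pd.DataFrame):
        df = records
        keep = (~df["is_rt_outlier"]) & (df["kind"] != "catch")
        df = df[keep]
        V = df["amount"].to_numpy(float)
        D = df["delay_days"].to_numpy(float)
        P = df["prob_win"].to_numpy(float)
        amb = np.where(df["domain"].to_numpy() == "delay",
                       df["amb_days"].to_numpy(float),
                       df["amb_prob"].to_numpy(float))
        rt = df["rt"].to_numpy(float)
        cu = (df["choice"].to_numpy() == "variable")
        sw = df["n_switches"].to_numpy(int) >= 1
    else:
        recs = [r for r in records
                if not r.is_rt_outlier and r.trial.kind != "catch"]
        V, D, P, amb = map(np.array, zip(*[trial_attributes(r.trial) for r in recs]))
        rt = np.array([r.rt for r in recs])
        cu = np.array([r.choice == "variable" for r in recs])
        sw = np.array([r.n_switches >= 1 for r in recs])
    return (V, D, P, amb, rt, np.ascontiguousarray(cu), np.ascontiguousarray(sw))


def log_posterior(spec: DriftModelSpec, x_unconstrained: np.ndarray, data) -> float:
    """Log posterior density at one point in the unconstrained space."""
    is_log, is_logit, centers = _transform_flags(spec)
    X = np.atleast_2d(np.asarray(x_unconstrained, dtype=float))
    return float(_logpost_batch(spec.code, X, is_log, is_logit, centers,
                                PRIOR_SD, *data)[0])


def _map_estimate(spec: DriftModelSpec, data) -> np.ndarray:
    """Posterior mode on the unconstrained scale (sampler initialization)."""
    is_log, is_logit, centers = _transform_flags(spec)
    rt = data[4]
    start_nat = []
    for n in spec.param_names:
        start_nat.append({"A": 1.5, "t0": min(0.85 * float(rt.min()), 0.4),
                          "z": 0.5, "eta": 0.05, "k": 0.01, "s": 1.0,
                          "alpha": 0.8}.get(n, 0.0))
    x0 = to_unconstrained(spec, np.array(start_nat))

    def neg(x):
        lp = _logpost_batch(spec.code, x[None, :], is_log, is_logit, centers,
                            PRIOR_SD, *data)[0]
        return -lp if np.isfinite(lp) else 1e12

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6,
                                     "fatol": 1e-8})
    res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                             options={"maxiter": 2000})
    return res2.x if res2.fun <= res.fun else res.x


def split_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split-R-hat for one parameter; chains: (n_chain, n_draw)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("split-R-hat needs a (n_chain >= 2, n_draw) array")
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(
            az.rhat(az.convert_to_dataset(chains))["x"].values).max())


def fit_participant(records, spec: DriftModelSpec, cfg: MCMCConfig,
                    participant: int = 0) -> PosteriorFit:
    """Fit one participant's usable trials under ``spec``.

    Chains are initialized in a tight ball around the posterior mode; warm-up
    draws are discarded.  A fit whose ensembles stop moving (mean acceptance
    below 5%) is marked unusable rather than silently returned.
    """
    data = _data_arrays(records)
    n_trials = data[4].shape[0]
    if n_trials < cfg.min_trials:
        raise ValueError(f"only {n_trials} usable trials; "
                         f"floor is {cfg.min_trials}")
    is_log, is_logit, centers = _transform_flags(spec)
    ndim = spec.n_params
    nwalk = cfg.walkers_for(ndim)
    x_map = _map_estimate(spec, data)

    def log_prob(X):
        return _logpost_batch(spec.code, np.atleast_2d(X), is_log, is_logit,
                              centers, PRIOR_SD, *data)

    chain_draws, accept = [], []
    for chain in range(cfg.n_chains):
        ss = np.random.SeedSequence([cfg.seed, participant, chain])
        rs = np.random.RandomState(ss.generate_state(1)[0] % (2**31 - 1))
        p0 = x_map[None, :] + 0.05 * rs.randn(nwalk, ndim)
        # ensure all walkers start at finite posterior density
        lp0 = log_prob(p0)
        for i in np.where(~np.isfinite(lp0))[0]:
            for _ in range(100):
                p0[i] = x_map + 0.01 * rs.randn(ndim)
                if np.isfinite(log_prob(p0[i][None, :])[0]):
                    break
        # differential-evolution moves mix far better than the default
        # stretch move on the correlated weight posteriors
        sampler = emcee.EnsembleSampler(
            nwalk, ndim, log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8),
                   (emcee.moves.DESnookerMove(), 0.2)])
        sampler.random_state = rs.get_state()
        state = sampler.run_mcmc(p0, cfg.n_warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, cfg.n_sampling, progress=False)
        chain_draws.append(sampler.get_chain())   # (steps, walkers, ndim)
        accept.append(float(np.mean(sampler.acceptance_fraction)))

    # step-major flattening keeps time order within each chain
    draws_t = np.stack([c.reshape(-1, ndim) for c in chain_draws])
    draws_nat = to_natural(spec, draws_t)

    rhat = {}
    for j, name in enumerate(spec.param_names):
        rhat[name] = split_rhat(draws_t[:, :, j])

    # pointwise log-likelihood on an evenly thinned subset of draws
    per_chain = draws_t.shape[1]
    step = max(1, int(np.ceil(cfg.n_chains * per_chain / cfg.max_loo_draws)))
    idx = np.arange(0, per_chain, step)
    ll = np.empty((cfg.n_chains, idx.size, n_trials))
    buf = np.empty(n_trials)
    for c in range(cfg.n_chains):
        for a, i in enumerate(idx):
            loglik_trials(spec.code, draws_nat[c, i], *data[:4], data[4],
                          data[5], data[6], buf)
            ll[c, a] = buf
    pointwise = ll.reshape(-1, n_trials)

    acc = float(np.mean(accept))
    return PosteriorFit(model_id=spec.model_id, participant=participant,
                        param_names=spec.param_names, draws=draws_nat,
                        pointwise_loglik=pointwise,
                        loo_chain_shape=(cfg.n_chains, idx.size),
                        rhat=rhat, acceptance=acc,
                        usable=acc >= MIN_ACCEPTANCE, n_trials=n_trials)


def check_convergence(fit: PosteriorFit,
                      threshold: float = RHAT_THRESHOLD) -> tuple[float, bool]:
    """Max split-R-hat across parameters and whether all pass the threshold."""
    if fit.draws.shape[0] < 2:
        raise ValueError("split-R-hat needs at least two chains")
    mx = fit.max_rhat()
    return mx, bool(mx < threshold)


def recover_parameters(behavior: pd.DataFrame, truth: pd.DataFrame,
                       spec: DriftModelSpec, cfg: MCMCConfig) -> pd.DataFrame:
    """Parameter-recovery table: Pearson r between ground-truth values and
    posterior means, one row per parameter.

    Parameters with degenerate (zero-variance) truth columns are reported
    with r = NaN and flagged rather than dropped.
    """
    pids = sorted(truth["participant"])
    if len(pids) < 10:
        raise ValueError("parameter recovery needs at least 10 participants")
    est_rows = []
    for pid in pids:
        sub = behavior[behavior["participant"] == pid]
        fit = fit_participant(sub, spec, cfg, participant=int(pid))
        row = {"participant": pid}
        row.update(fit.posterior_mean())
        est_rows.append(row)
    est = pd.DataFrame(est_rows).set_index("participant")
    tru = truth.set_index("participant")
    rows = []
    for name in spec.param_names:
        t = tru[name].to_numpy(float)
        e = est[name].to_numpy(float)
        if np.ptp(t) == 0.0:
            rows.append(dict(parameter=name, r=np.nan, degenerate=True))
        else:
            rows.append(dict(parameter=name,
                             r=float(stats.pearsonr(t, e)[0]),
                             degenerate=False))
    return pd.DataFrame(rows)
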