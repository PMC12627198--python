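"""Cross-domain individual differences.

Tools for asking whether ambiguity attitudes travel across decision domains:
sign classification of each participant's ambiguity effect on the drift rate,
a Bayesian robust correlation (bivariate Student-t likelihood with unknown
degrees of freedom, insensitive to outliers), and the ROPE + HDI three-way
decision rule.  The cross-domain report correlates (a) log pseudo-inclusion
Bayes factors and (b) ambiguity parameters between the delay and probability
domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import emcee
import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .ddm_core import DriftModelSpec, _drift_kernel, get_model
from .fit import PosteriorFit
from .task_design import (AMB_DELAY_MIDPOINT, AMB_DELAY_WIDTHS,
                          AMB_PROB_MIDPOINT, AMB_PROB_WIDTHS)

# ---------------------------------------------------------------------------
# Ambiguity-preference classification
# ---------------------------------------------------------------------------

# reference trial per domain: mid amount, midpoint attribute, maximal range
_REF = {"delay": (29.0, AMB_DELAY_MIDPOINT, 1.0, max(AMB_DELAY_WIDTHS)),
        "probability": (29.0, 0.0, AMB_PROB_MIDPOINT, max(AMB_PROB_WIDTHS))}


@njit(cache=True)
def _delta_v_draws(code, P_draws, V, D, Pwin, amb):
    S = P_draws.shape[0]
    out = np.empty(S)
    for s in range(S):
        out[s] = (_drift_kernel(code, P_draws[s], V, D, Pwin, amb, False)
                  - _drift_kernel(code, P_draws[s], V, D, Pwin, 0.0, False))
    return out


def ambiguity_effect_draws(fit: PosteriorFit,
                           spec: DriftModelSpec | None = None) -> np.ndarray:
    """Posterior draws of the drift change caused by raising ambiguity from
    zero to its maximal range at a reference mid-level trial."""
    spec = spec or get_model(fit.model_id)
    if not spec.has_ambiguity:
        raise ValueError(f"{spec.model_id} has no ambiguity term")
    V, D, Pwin, amb = _REF[spec.domain]
    flat = fit.draws.reshape(-1, fit.draws.shape[-1])
    P_draws = np.ascontiguousarray(flat[:, 3:])   # drift params follow A,t0,z
    return _delta_v_draws(spec.code, P_draws, V, D, Pwin, amb)


def classify_ambiguity_preference(fit: PosteriorFit,
                                  spec: DriftModelSpec | None = None,
                                  threshold: float = 0.5) -> str:
    """'averse' | 'seeking' | 'indeterminate' from the posterior sign of the
    ambiguity effect on drift toward the variable option.

    With the default threshold 0.5 the verdict follows the posterior median
    sign; larger thresholds require the posterior to put that much mass on
    one sign.
    """
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0.5, 1)")
    dv = ambiguity_effect_draws(fit, spec)
    p_neg = float(np.mean(dv < 0))
    p_pos = float(np.mean(dv > 0))
    if p_neg > threshold:
        return "averse"
    if p_pos > threshold:
        return "seeking"
    return "indeterminate"


# ---------------------------------------------------------------------------
# HDI and the ROPE decision rule
# ---------------------------------------------------------------------------

def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval holding ``mass`` of the pooled draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


@dataclass
class RopeDecision:
    hdi_low: float
    hdi_high: float
    rope_low: float
    rope_high: float
    frac_in_rope: float
    verdict: str    # significant | practically_equivalent | inconclusive


def rope_decision(draws, rope: tuple[float, float],
                  hdi_mass: float = 0.95) -> RopeDecision:
    """Three-way ROPE + HDI rule: significant when HDI and ROPE are disjoint,
    practically equivalent when the HDI lies inside the ROPE, else
    inconclusive."""
    lo, hi = rope
    if not lo < hi:
        raise ValueError("rope_low must be below rope_high")
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 1000:
        raise ValueError("need at least 1000 posterior draws")
    h_lo, h_hi = hdi(draws, hdi_mass)
    frac = float(np.mean((draws >= lo) & (draws <= hi)))
    if h_hi < lo or h_lo > hi:
        verdict = "significant"
    elif h_lo >= lo and h_hi <= hi:
        verdict = "practically_equivalent"
    else:
        verdict = "inconclusive"
    return RopeDecision(h_lo, h_hi, lo, hi, frac, verdict)


# ---------------------------------------------------------------------------
# Bayesian robust correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationPosterior:
    rho: np.ndarray
    nu: np.ndarray
    mu: np.ndarray       # draws x 2
    sigma: np.ndarray    # draws x 2

    def summary(self, hdi_mass: float = 0.95) -> dict:
        lo, hi = hdi(self.rho, hdi_mass)
        return {"mean": float(self.rho.mean()),
                "hdi_low": lo, "hdi_high": hi,
                "nu_mean": float(self.nu.mean())}


_NU_PRIOR_MEAN = 29.0   # nu = 1 + Exponential(mean 29), i.e. E[nu] = 30


def _robust_corr_logpost(theta, x, y, mx, my, sx, sy):
    mu1, mu2, ls1, ls2, u, w = theta
    if abs(u) > 10 or abs(w) > 20 or abs(ls1) > 20 or abs(ls2) > 20:
        return -np.inf
    rho = math.tanh(u)
    nu = 1.0 + math.exp(w)
    s1, s2 = math.exp(ls1), math.exp(ls2)
    # priors: weakly informative around the sample moments; uniform on rho
    # (tanh jacobian); shifted-exponential on nu (with exp jacobian)
    lp = (-0.5 * ((mu1 - mx) / (5 * sx)) ** 2
          - 0.5 * ((mu2 - my) / (5 * sy)) ** 2
          - 0.5 * ((ls1 - math.log(sx)) / 2.0) ** 2
          - 0.5 * ((ls2 - math.log(sy)) / 2.0) ** 2
          + math.log(1.0 - rho * rho)
          + w - math.exp(w) / _NU_PRIOR_MEAN)
    dx = (x - mu1) / s1
    dy = (y - mu2) / s2
    om = 1.0 - rho * rho
    q = (dx * dx - 2.0 * rho * dx * dy + dy * dy) / om
    n = x.size
    ll = n * (gammaln((nu + 2.0) / 2.0) - gammaln(nu / 2.0)
              - math.log(nu * math.pi) - math.log(s1 * s2 * math.sqrt(om)))
    ll -= (nu + 2.0) / 2.0 * np.sum(np.log1p(q / nu))
    return lp + ll


def robust_correlation(x, y, n_warmup: int = 600, n_sampling: int = 600,
                       n_walkers: int = 16, seed: int = 0) -> CorrelationPosterior:
    """Posterior over the correlation of a bivariate Student-t model with
    unknown degrees of freedom (gross outliers carry little weight)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 10:
        raise ValueError("need two equal-length vectors with >= 10 entries")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    sx, sy = float(x.std(ddof=1)), float(y.std(ddof=1))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    mx, my = float(x.mean()), float(y.mean())
    r0 = float(np.clip(np.corrcoef(x, y)[0, 1], -0.99, 0.99))
    center = np.array([mx, my, math.log(sx), math.log(sy),
                       math.atanh(r0), math.log(_NU_PRIOR_MEAN)])

    rs = np.random.RandomState(seed % (2**31 - 1))
    p0 = center[None, :] + 0.05 * rs.randn(n_walkers, 6)
    sampler = emcee.EnsembleSampler(
        n_walkers, 6, _robust_corr_logpost, args=(x, y, mx, my, sx, sy))
    sampler.random_state = rs.get_state()
    state = sampler.run_mcmc(p0, n_warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_sampling, progress=False)
    flat = sampler.get_chain(flat=True)
    return CorrelationPosterior(rho=np.tanh(flat[:, 4]),
                                nu=1.0 + np.exp(flat[:, 5]),
                                mu=flat[:, :2],
                                sigma=np.exp(flat[:, 2:4]))


# ---------------------------------------------------------------------------
# Cross-domain report
# ---------------------------------------------------------------------------

DEFAULT_ROPE = (-0.06, 0.06)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def cross_domain_report(table: pd.DataFrame, rope=DEFAULT_ROPE,
                        seed: int = 0) -> dict:
    """Cross-domain correlation report.

    ``table`` needs one row per participant fitted in both domains, columns
    log_pbf_delay, log_pbf_prob, amb_param_delay, amb_param_prob.  Inputs are
    z-standardized before the robust correlation; each correlation gets a
    ROPE verdict.
    """
    required = ["log_pbf_delay", "log_pbf_prob",
                "amb_param_delay", "amb_param_prob"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    tab = table.dropna(subset=required)
    if len(tab) < 10:
        raise ValueError("need >= 10 participants fitted in both domains")
    out = {"n_participants": int(len(tab))}
    for label, (cx, cy) in {
            "log_pbf": ("log_pbf_delay", "log_pbf_prob"),
            "ambiguity_param": ("amb_param_delay", "amb_param_prob")}.items():
        post = robust_correlation(_zscore(tab[cx].to_numpy(float)),
                                  _zscore(tab[cy].to_numpy(float)),
                                  seed=seed)
        dec = rope_decision(post.rho, rope)
        out[label] = {"correlation": post.summary(), "rope": dec.__dict__}
    return out
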