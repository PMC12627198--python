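"""Model comparison: PSIS-LOO, Akaike-type weights, pseudo-inclusion Bayes
factors, and random-effects Bayesian model selection (RE-BMS).

Per participant, each candidate model's predictive performance is the
expected log predictive density estimated by Pareto-smoothed importance
sampling leave-one-out cross-validation (PSIS-LOO) on the pointwise
log-likelihood matrix of its posterior fit.  Softmax ("Akaike-type") weights
over the per-participant elpd values support the pseudo-inclusion Bayes
factor

    PBF = (posterior mass of the model family / mass of its complement)
          / (prior family odds),

with uniform priors over models (the prior-odds correction matters because
the families have unequal sizes).  At the group level, RE-BMS treats model
identity as a random effect: a variational Dirichlet posterior over model
frequencies yields expected frequencies, exceedance probabilities (EP), the
Bayes omnibus risk (BOR, the posterior probability that all frequencies are
equal) and the protected exceedance probability PXP = (1-BOR)*EP + BOR/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .ddm_core import get_model
from .fit import PosteriorFit


@dataclass
class LooResult:
    elpd_loo: float
    se: float
    pointwise: np.ndarray      # per-trial elpd contributions
    pareto_k: np.ndarray
    degenerate: bool = False   # exact log-lik fallback (collapsed posterior)

    def __post_init__(self):
        assert np.isclose(self.elpd_loo, float(np.sum(self.pointwise)))


def psis_loo(fit: PosteriorFit) -> LooResult:
    """PSIS-LOO from a fit's pointwise log-likelihood matrix.

    If the posterior draws are degenerate (all identical), importance ratios
    carry no information; the exact pointwise log-likelihood is returned with
    a warning instead.
    """
    import arviz as az

    ll = fit.pointwise_loglik
    if ll.shape[0] < 100:
        raise ValueError("need at least 100 draws for PSIS-LOO")
    if np.ptp(ll, axis=0).max() < 1e-12:
        warnings.warn("degenerate posterior draws; PSIS-LOO falls back to "
                      "the exact pointwise log-likelihood")
        pw = ll[0]
        return LooResult(float(pw.sum()),
                         float(np.sqrt(len(pw) * np.var(pw))),
                         pw, np.zeros(len(pw)), degenerate=True)
    nc, nd = fit.loo_chain_shape
    idata = az.from_dict(
        posterior={"dummy": np.zeros((nc, nd))},
        log_likelihood={"obs": ll.reshape(nc, nd, -1)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    return LooResult(float(res.elpd_loo), float(res.se),
                     np.asarray(res.loo_i.values),
                     np.asarray(res.pareto_k.values))


def akaike_weights(elpds) -> np.ndarray:
    """Softmax weights over K model elpd values (shift-invariant)."""
    elpds = np.asarray(elpds, dtype=float)
    if elpds.ndim != 1 or elpds.size < 2:
        raise ValueError("need a vector of at least two model scores")
    if not np.all(np.isfinite(elpds)):
        raise ValueError("non-finite model score")
    w = np.exp(elpds - elpds.max())
    return w / w.sum()


PBF_CAP = 1e12


@dataclass
class InclusionResult:
    weights: np.ndarray        # per-participant x model, rows sum to 1
    pbf: np.ndarray            # per participant
    log_pbf: np.ndarray
    in_group: np.ndarray       # boolean per model
    capped: np.ndarray         # True where the out-group mass vanished


def pbf_inclusion(weights: np.ndarray, in_group) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-inclusion Bayes factor per participant.

    ``weights``: (N participants x K models) softmax weights; ``in_group``:
    boolean mask of the model family.  Uniform model priors give prior family
    odds n_in/n_out.  A vanished out-group mass yields the capped sentinel.
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    g = np.asarray(in_group, dtype=bool)
    if g.size != W.shape[1]:
        raise ValueError("in_group length must match the number of models")
    if g.all() or not g.any():
        raise ValueError("both model groups must be non-empty")
    prior_odds = g.sum() / (~g).sum()
    w_in = W[:, g].sum(axis=1)
    w_out = W[:, ~g].sum(axis=1)
    capped = w_out <= 0.0
    pbf = np.where(capped, PBF_CAP, (w_in / np.where(capped, 1.0, w_out))
                   / prior_odds)
    return pbf, capped


def inclusion_analysis(elpd_matrix: np.ndarray, model_ids,
                       feature: str) -> InclusionResult:
    """Per-participant weights and PBF for a named model feature
    ('ambiguity' or 'attribute_wise')."""
    specs = [get_model(m) for m in model_ids]
    if feature == "ambiguity":
        g = np.array([s.has_ambiguity for s in specs])
    elif feature == "attribute_wise":
        g = np.array([s.is_attribute_wise for s in specs])
    else:
        raise ValueError("feature must be 'ambiguity' or 'attribute_wise'")
    E = np.atleast_2d(np.asarray(elpd_matrix, dtype=float))
    W = np.stack([akaike_weights(row) for row in E])
    pbf, capped = pbf_inclusion(W, g)
    return InclusionResult(weights=W, pbf=pbf, log_pbf=np.log(pbf),
                           in_group=g, capped=capped)


# ---------------------------------------------------------------------------
# Random-effects Bayesian model selection
# ---------------------------------------------------------------------------

@dataclass
class BmsResult:
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    bor: float
    pxp: np.ndarray
    model_posteriors: np.ndarray   # per participant x model responsibilities


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    aS, a0S = alpha.sum(), alpha0.sum()
    return float(gammaln(aS) - gammaln(alpha).sum()
                 - gammaln(a0S) + gammaln(alpha0).sum()
                 + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(aS))))


def re_bms(scores: np.ndarray, alpha0: float = 1.0, tol: float = 1e-8,
           max_iter: int = 500, n_ep_samples: int = 100_000,
           seed: int = 0) -> BmsResult:
    """RE-BMS over an (N participants x K models) matrix of log evidences
    (elpd values are consumed directly).

    Variational update of a Dirichlet over population model frequencies;
    EP by Monte-Carlo sampling of that Dirichlet; BOR from the free-energy
    comparison against the equal-frequency null.
    """
    L = np.atleast_2d(np.asarray(scores, dtype=float))
    N, K = L.shape
    if N < 2:
        raise ValueError("random-effects model selection needs >= 2 participants")
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite model score")

    a0 = np.full(K, alpha0)
    alpha = a0.copy()
    g = np.full((N, K), 1.0 / K)
    for _ in range(max_iter):
        logu = L + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        g_new = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = a0 + g_new.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha, g = alpha_new, g_new
            break
        alpha, g = alpha_new, g_new

    expected = alpha / alpha.sum()

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_ep_samples)
    ep = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_ep_samples

    # free energy of the random-effects model
    elog_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_g = -np.nansum(g * np.log(np.where(g > 0, g, 1.0)))
    f1 = (np.sum(g * L) + np.sum(g * elog_r[None, :]) + entropy_g
          - _dirichlet_kl(alpha, a0))
    # null model: frequencies fixed at 1/K
    f0 = float(np.sum(logsumexp(L, axis=1) - np.log(K)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * ep + bor / K
    return BmsResult(dirichlet_alpha=alpha, expected_freq=expected,
                     exceedance_prob=ep, bor=bor, pxp=pxp, model_posteriors=g)
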