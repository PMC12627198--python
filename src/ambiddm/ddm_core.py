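"""Drift-diffusion core: drift-rate model family, WFPT likelihood, choice rule.

The decision process is a unit-variance Wiener diffusion between absorbing
boundaries at 0 and A, starting at z*A, with a trial-specific drift v given by
a value model of the trial attributes.  Evidence reaching the upper boundary
means choosing the variable (later-larger / risky) option; the lower boundary
means the constant 5-euro option.  The drift of the integrated-value models is

    v = eta * (SV_variable - SV_constant),

with eta a scaling parameter; attribute-wise models build v directly as a
weighted sum of attribute differences.  Ambiguity enters the formulas as the
half-range Amb/2 except where a model uses the full range (implemented exactly
as each model is defined).

The WFPT density uses the dual small-time / large-time series with an
automatic regime switch and truncation chosen for absolute density error
below 1e-9.  On trials with preference switches only the closed-form choice
probability

    P(upper) = (exp(-2*A*z*v) - 1) / (exp(-2*A*v) - 1)

is used, since the recorded RT no longer reflects a single accumulation run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .task_design import Trial, V_CONSTANT, D_CONSTANT, P_CONSTANT

# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

_CORE_PARAMS = ("A", "t0", "z")


@dataclass(frozen=True)
class DriftModelSpec:
    """Identifies one drift-rate model of the candidate family."""

    model_id: str
    domain: str                     # "delay" | "probability"
    code: int                       # dispatch code for the compiled kernel
    drift_param_names: tuple[str, ...]
    has_ambiguity: bool
    is_attribute_wise: bool
    parent_id: str | None = None    # same model with ambiguity terms removed

    @property
    def param_names(self) -> tuple[str, ...]:
        return _CORE_PARAMS + self.drift_param_names

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _spec(mid, domain, code, names, amb, aw, parent=None):
    return DriftModelSpec(mid, domain, code, tuple(names), amb, aw, parent)


MODELS: dict[str, DriftModelSpec] = {m.model_id: m for m in [
    # --- intertemporal (delay) family ---
    _spec("itc_hyp",        "delay", 0, ("eta", "k"), False, False),
    _spec("itc_hyp_add",    "delay", 1, ("eta", "k", "beta_itc"), True, False, "itc_hyp"),
    _spec("itc_hyp_tp",     "delay", 2, ("eta", "k", "beta_itc"), True, False, "itc_hyp"),
    _spec("itc_ghyp",       "delay", 3, ("eta", "k", "s"), False, False),
    _spec("itc_ghyp_add",   "delay", 4, ("eta", "k", "s", "beta_itc"), True, False, "itc_ghyp"),
    _spec("itc_ghyp_tp",    "delay", 5, ("eta", "k", "s", "beta_itc"), True, False, "itc_ghyp"),
    _spec("itc_aw",         "delay", 6, ("w_r", "w_t"), False, True),
    _spec("itc_aw_rxd",     "delay", 7, ("w_r", "w_t", "w_inter"), False, True),
    _spec("itc_aw_amb",     "delay", 8, ("w_r", "w_t", "w_amb"), True, True, "itc_aw"),
    _spec("itc_aw_amb_rxd", "delay", 9, ("w_r", "w_t", "w_amb", "w_inter"), True, True, "itc_aw_rxd"),
    _spec("itc_aw_amb_rxa", "delay", 10, ("w_r", "w_t", "w_amb", "w_inter_amb"), True, True, "itc_aw"),
    _spec("itc_aw_full",    "delay", 11, ("w_r", "w_t", "w_amb", "w_inter", "w_inter_amb"), True, True, "itc_aw_rxd"),
    # --- risky (probability) family ---
    _spec("risk_eu",        "probability", 20, ("eta", "alpha"), False, False),
    _spec("risk_gs",        "probability", 21, ("eta", "alpha", "beta_risk"), True, False, "risk_eu"),
    _spec("risk_eu_add",    "probability", 22, ("eta", "alpha", "beta_risk"), True, False, "risk_eu"),
    _spec("risk_aw",        "probability", 23, ("w_r", "w_p"), False, True),
    _spec("risk_aw_rxp",    "probability", 24, ("w_r", "w_p", "w_inter"), False, True),
    _spec("risk_aw_amb",    "probability", 25, ("w_r", "w_p", "w_amb"), True, True, "risk_aw"),
    _spec("risk_aw_amb_rxp", "probability", 26, ("w_r", "w_p", "w_amb", "w_inter"), True, True, "risk_aw_rxp"),
    _spec("risk_aw_amb_rxa", "probability", 27, ("w_r", "w_p", "w_amb", "w_inter_amb"), True, True, "risk_aw"),
    _spec("risk_aw_full",   "probability", 28, ("w_r", "w_p", "w_amb", "w_inter", "w_inter_amb"), True, True, "risk_aw_rxp"),
]}

# Parameters constrained positive (sampled on the log scale during fitting).
POSITIVE_PARAMS = frozenset({"A", "t0", "eta", "k", "s", "alpha"})
UNIT_PARAMS = frozenset({"z"})  # sampled on the logit scale


def get_model(model_id: str) -> DriftModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; "
                       f"known: {sorted(MODELS)}") from None


@dataclass
class DDMParams:
    """Boundary A, non-decision time t0, relative start z, plus the drift
    parameters required by one DriftModelSpec (by name)."""

    A: float
    t0: float
    z: float
    drift: dict[str, float] = field(default_factory=dict)

    def vector(self, spec: DriftModelSpec) -> np.ndarray:
        return np.array([self.A, self.t0, self.z]
                        + [self.drift[n] for n in spec.drift_param_names])

    @classmethod
    def from_vector(cls, spec: DriftModelSpec, vec) -> "DDMParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (spec.n_params,):
            raise ValueError(f"expected {spec.n_params} parameters for "
                             f"{spec.model_id}, got {vec.shape}")
        return cls(A=float(vec[0]), t0=float(vec[1]), z=float(vec[2]),
                   drift=dict(zip(spec.drift_param_names, vec[3:])))

    def validate(self, spec: DriftModelSpec) -> None:
        if not self.A > 0:
            raise ValueError("boundary separation A must be positive")
        if not self.t0 >= 0:
            raise ValueError("non-decision time t0 must be non-negative")
        if not 0 < self.z < 1:
            raise ValueError("relative start z must lie in (0, 1)")
        missing = set(spec.drift_param_names) - set(self.drift)
        if missing:
            raise ValueError(f"missing drift parameters for {spec.model_id}: "
                             f"{sorted(missing)}")


# ---------------------------------------------------------------------------
# Drift-rate kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _drift_kernel(code, p, V, D, P, amb, strict_printed):
    """Drift for one trial.  p holds the model's drift parameters in registry
    order; amb is the full range width (days or probability fraction)."""
    half = 0.5 * amb
    V_ss = V if strict_printed else V_CONSTANT

    if code == 0:    # hyperbolic
        return p[0] * (V / (1.0 + p[1] * D) - V_ss / (1.0 + p[1] * D_CONSTANT))
    elif code == 1:  # hyperbolic + additive ambiguity
        return p[0] * (V / (1.0 + p[1] * D) - V_ss / (1.0 + p[1] * D_CONSTANT)
                       - p[2] * half)
    elif code == 2:  # hyperbolic + time perception (full range; floored at 0)
        d_eff = D - p[2] * amb
        if d_eff < 0.0:
            d_eff = 0.0
        return p[0] * (V / (1.0 + p[1] * d_eff) - V_ss / (1.0 + p[1] * D_CONSTANT))
    elif code == 3:  # generalized hyperbolic
        return p[0] * (V / (1.0 + (p[1] * D) ** p[2])
                       - V_ss / (1.0 + (p[1] * D_CONSTANT) ** p[2]))
    elif code == 4:  # generalized hyperbolic + additive ambiguity
        return p[0] * (V / (1.0 + (p[1] * D) ** p[2])
                       - V_ss / (1.0 + (p[1] * D_CONSTANT) ** p[2])
                       - p[3] * half)
    elif code == 5:  # generalized hyperbolic + time perception (half range)
        inner = p[1] * D - p[3] * half
        if inner < 0.0:
            inner = 0.0
        return p[0] * (V / (1.0 + inner ** p[2])
                       - V_ss / (1.0 + (p[1] * D_CONSTANT) ** p[2]))
    elif code == 6:  # attribute-wise
        return p[0] * (V - V_CONSTANT) + p[1] * (D - D_CONSTANT)
    elif code == 7:  # attribute-wise + reward x delay
        return (p[0] * (V - V_CONSTANT) + p[1] * (D - D_CONSTANT)
                + p[2] * (V - V_CONSTANT) * (D - D_CONSTANT))
    elif code == 8:  # attribute-wise + ambiguity (half range)
        return p[0] * (V - V_CONSTANT) + p[1] * (D - D_CONSTANT) + p[2] * half
    elif code == 9:  # attribute-wise + ambiguity + reward x delay
        return (p[0] * (V - V_CONSTANT) + p[1] * (D - D_CONSTANT)
                + p[2] * half
                + p[3] * (V - V_CONSTANT) * (D - D_CONSTANT))
    elif code == 10:  # aw + ambiguity (full) + reward x ambiguity (half)
        return (p[0] * (V - V_CONSTANT) + p[1] * (D - D_CONSTANT)
                + p[2] * amb + p[3] * (V - V_CONSTANT) * half)
    elif code == 11:  # aw + ambiguity (full) + both interactions
        return (p[0] * (V - V_CONSTANT) + p[1] * (D - D_CONSTANT)
                + p[2] * amb
                + p[3] * (V - V_CONSTANT) * (D - D_CONSTANT)
                + p[4] * (V - V_CONSTANT) * half)
    elif code == 20:  # expected utility
        return p[0] * (P * V ** p[1] - P_CONSTANT * V_CONSTANT ** p[1])
    elif code == 21:  # Gilboa-Schmeidler (perceived probability shift)
        return p[0] * ((P - p[2] * half) * V ** p[1]
                       - P_CONSTANT * V_CONSTANT ** p[1])
    elif code == 22:  # expected utility + additive ambiguity
        return p[0] * (P * V ** p[1] - P_CONSTANT * V_CONSTANT ** p[1]
                       - p[2] * half)
    elif code == 23:  # attribute-wise
        return p[0] * (V - V_CONSTANT) + p[1] * (P - P_CONSTANT)
    elif code == 24:  # attribute-wise + reward x probability
        return (p[0] * (V - V_CONSTANT) + p[1] * (P - P_CONSTANT)
                + p[2] * (V - V_CONSTANT) * (P - P_CONSTANT))
    elif code == 25:  # attribute-wise + ambiguity (half range)
        return p[0] * (V - V_CONSTANT) + p[1] * (P - P_CONSTANT) + p[2] * half
    elif code == 26:  # aw + ambiguity (full) + reward x probability
        return (p[0] * (V - V_CONSTANT) + p[1] * (P - P_CONSTANT)
                + p[2] * amb
                + p[3] * (V - V_CONSTANT) * (P - P_CONSTANT))
    elif code == 27:  # aw + ambiguity (full) + reward x ambiguity (half)
        return (p[0] * (V - V_CONSTANT) + p[1] * (P - P_CONSTANT)
                + p[2] * amb + p[3] * (V - V_CONSTANT) * half)
    elif code == 28:  # aw + ambiguity (full) + both interactions
        return (p[0] * (V - V_CONSTANT) + p[1] * (P - P_CONSTANT)
                + p[2] * amb
                + p[3] * (V - V_CONSTANT) * (P - P_CONSTANT)
                + p[4] * (V - V_CONSTANT) * half)
    return np.nan


def trial_attributes(trial: Trial) -> tuple[float, float, float, float]:
    """(V, D, P, Amb) of the variable option; Amb is the full range width in
    the domain's units."""
    amb = trial.amb_days if trial.domain == "delay" else trial.amb_prob
    return trial.amount, trial.delay_days, trial.prob_win, amb


def drift_rate(spec: DriftModelSpec, params: DDMParams, trial: Trial,
               strict_printed: bool = False) -> float:
    """Evaluate the model's drift-rate formula on one trial."""
    if trial.domain != spec.domain:
        raise ValueError(f"trial domain {trial.domain!r} does not match model "
                         f"{spec.model_id!r} ({spec.domain})")
    params.validate(spec)
    V, D, P, amb = trial_attributes(trial)
    p = np.array([params.drift[n] for n in spec.drift_param_names])
    v = _drift_kernel(spec.code, p, V, D, P, amb, strict_printed)
    if not math.isfinite(v):
        raise FloatingPointError(f"non-finite drift for {spec.model_id}")
    return float(v)


@njit(cache=True)
def drift_rate_array(code, p, V, D, P, amb, strict_printed=False):
    n = V.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = _drift_kernel(code, p, V[i], D[i], P[i], amb[i], strict_printed)
    return out


# ---------------------------------------------------------------------------
# Wiener first-passage-time density
# ---------------------------------------------------------------------------

_WFPT_EPS = 1e-12  # truncation tolerance of the normalized-time series


@njit(cache=True)
def _wfpt_lower_logpdf(td, A, z, v):
    """Log density of first passage through the LOWER boundary at decision
    time td, for boundary separation A, relative start z, drift v (positive
    drift points to the upper boundary)."""
    if td <= 0.0 or A <= 0.0 or z <= 0.0 or z >= 1.0:
        return -np.inf
    u = td / (A * A)  # normalized time
    eps = _WFPT_EPS

    # terms needed by each expansion (Navarro-Fuss style bounds)
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        acc = 0.0
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + 1):
            w = z + 2.0 * k
            acc += w * math.exp(-w * w / (2.0 * u))
        f = acc / math.sqrt(2.0 * math.pi * u * u * u)
    else:        # large-time expansion
        K = int(math.ceil(kl))
        acc = 0.0
        for k in range(1, K + 1):
            acc += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) \
                * math.sin(k * math.pi * z)
        f = math.pi * acc

    if f <= 0.0:  # truncation can undershoot in the extreme tails
        return -np.inf
    return math.log(f) - v * A * z - v * v * td / 2.0 - 2.0 * math.log(A)


@njit(cache=True)
def _wfpt_logpdf_scalar(t, upper, A, t0, z, v):
    td = t - t0
    if td <= 0.0:
        return -np.inf
    if upper:
        return _wfpt_lower_logpdf(td, A, 1.0 - z, -v)
    return _wfpt_lower_logpdf(td, A, z, v)


def wfpt_logpdf(t: float, boundary: str, A: float, t0: float, z: float,
                v: float) -> float:
    """Log first-passage density at observed time ``t`` (seconds, including
    the non-decision time t0) through ``boundary`` ("upper" or "lower").

    ``t <= t0`` is an impossible observation and returns -inf; invalid
    parameters raise.
    """
    if not A > 0:
        raise ValueError("A must be positive")
    if not 0 < z < 1:
        raise ValueError("z must lie in (0, 1)")
    if not t0 >= 0:
        raise ValueError("t0 must be non-negative")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    return float(_wfpt_logpdf_scalar(t, boundary == "upper", A, t0, z, v))


def wfpt_pdf(t, boundary, A, t0, z, v):
    """Density counterpart of :func:`wfpt_logpdf` (vectorized over t)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    up = boundary == "upper"
    out = np.array([math.exp(_wfpt_logpdf_scalar(ti, up, A, t0, z, v))
                    for ti in t])
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Choice probability (switch trials)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _choice_prob_upper(A, z, v):
    x = A * v
    if abs(x) < 1e-8:
        # limit of (exp(-2Azv)-1)/(exp(-2Av)-1) as v -> 0
        return z * (1.0 + x * (1.0 - z))
    num = math.expm1(-2.0 * A * z * v)
    den = math.expm1(-2.0 * A * v)
    return num / den


def choice_prob_upper(A: float, z: float, v: float) -> float:
    """Probability of absorption at the upper (variable-option) boundary;
    continuous at v = 0 with limit z."""
    if not A > 0:
        raise ValueError("A must be positive")
    if not 0 < z < 1:
        raise ValueError("z must lie in (0, 1)")
    return float(_choice_prob_upper(A, z, v))


# ---------------------------------------------------------------------------
# Per-trial likelihood
# ---------------------------------------------------------------------------

@njit(cache=True)
def loglik_trials(code, params_vec, V, D, P, amb, rt, chose_upper, switched,
                  out, strict_printed=False):
    """Per-trial log likelihood into ``out``.  params_vec = [A, t0, z, drift...]."""
    A = params_vec[0]
    t0 = params_vec[1]
    z = params_vec[2]
    p = params_vec[3:]
    n = rt.shape[0]
    for i in range(n):
        v = _drift_kernel(code, p, V[i], D[i], P[i], amb[i], strict_printed)
        if switched[i]:
            pu = _choice_prob_upper(A, z, v)
            if pu <= 0.0:
                pu = 1e-300
            elif pu >= 1.0:
                pu = 1.0 - 1e-16
            out[i] = math.log(pu) if chose_upper[i] else math.log1p(-pu)
        else:
            out[i] = _wfpt_logpdf_scalar(rt[i], bool(chose_upper[i]), A, t0, z, v)
    return out


def trial_loglik(record, spec: DriftModelSpec, params: DDMParams,
                 strict_printed: bool = False) -> float:
    """Log likelihood of one behavioral record.

    Switch trials (n_switches >= 1) contribute only the choice probability;
    clean trials contribute the full WFPT density of (RT, choice).  Records
    flagged as RT outliers are excluded upstream and refused here.
    """
    if record.is_rt_outlier:
        raise ValueError("likelihood is undefined for outlier-flagged trials")
    params.validate(spec)
    v = drift_rate(spec, params, record.trial, strict_printed)
    upper = record.choice == "variable"
    if record.n_switches >= 1:
        pu = choice_prob_upper(params.A, params.z, v)
        return float(np.log(pu) if upper else np.log1p(-pu))
    return wfpt_logpdf(record.rt, "upper" if upper else "lower",
                       params.A, params.t0, params.z, v)
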