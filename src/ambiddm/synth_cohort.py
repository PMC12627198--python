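"""Synthetic cohorts with known ground truth.

Generates participants whose choices and RTs come from the forward DDM under
a chosen drift-rate model, with between-participant parameter heterogeneity
(a majority ambiguity-averse, matching the empirical prevalence of roughly
70%), plus the contaminants the preprocessing stage must handle: RT outliers
outside [0.3 s, 10 s] and preference-switch trials.  Every downstream stage
(exclusion cascade, fitting, model comparison, individual differences) is
exercised on these cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import math
import json

import numpy as np
import pandas as pd
from numba import njit

from . import task_design
from .task_design import Trial, Session, assemble_session
from .ddm_core import (DriftModelSpec, DDMParams, get_model, trial_attributes,
                       drift_rate_array, _choice_prob_upper)

RT_OUTLIER_LOW = 0.3    # seconds
RT_OUTLIER_HIGH = 10.0

# Parameters whose sign encodes the ambiguity attitude, and the sign an
# ambiguity-AVERSE participant carries (w_amb adds +w*Amb terms to the drift;
# the beta coefficients enter the formulas with a minus sign or shrink the
# perceived attribute, so aversion flips between the two conventions).
_AMBIGUITY_PARAM_SIGN = {
    "w_amb": -1.0, "beta_itc": +1.0, "beta_risk": +1.0,
}


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal population distribution of one parameter."""
    loc: float
    scale: float
    low: float = -np.inf
    high: float = np.inf

    def sample(self, rng: np.random.Generator) -> float:
        if self.scale == 0.0:
            return self.loc
        for _ in range(1000):
            x = rng.normal(self.loc, self.scale)
            if self.low <= x <= self.high:
                return float(x)
        raise ValueError(f"population bounds [{self.low}, {self.high}] "
                         f"unsatisfiable around {self.loc}+-{self.scale}")


# Population defaults per parameter.  Magnitudes keep single-trial drifts in
# a plausible +-4 evidence/s band over the task's attribute ranges; ambiguity
# parameters are stored as magnitude distributions and signed per participant.
_DEFAULT_DISTS = {
    "A": ParamDist(1.4, 0.35, 0.6, 3.0),
    # RT is the first mouse click, so encoding + cursor movement keeps the
    # non-decision time well above the 300 ms exclusion bound; a clean
    # (contaminant-free) cohort then never trips the RT-outlier filter
    "t0": ParamDist(0.45, 0.08, 0.32, 0.8),
    "z": ParamDist(0.5, 0.08, 0.2, 0.8),
    "eta": ParamDist(0.06, 0.02, 0.01, 0.3),
    "k": ParamDist(0.012, 0.006, 0.001, 0.1),
    "s": ParamDist(1.0, 0.15, 0.5, 1.8),
    "alpha": ParamDist(0.85, 0.1, 0.4, 1.4),
    # attribute weights disperse widely across people (empirical cohorts
    # span near-zero to several-fold the typical weight)
    "w_r": ParamDist(0.06, 0.035, 0.005, 0.25),
    "w_t": ParamDist(-0.012, 0.008, -0.05, -0.0005),
    "w_p": ParamDist(3.0, 1.2, 0.5, 7.0),
    # interaction weights, delay domain: multiply (V-5)*D (range ~0..8500)
    "w_inter": ParamDist(-1.5e-4, 1.2e-4, -6.0e-4, 5.0e-5),
    "w_inter_amb": ParamDist(-1.5e-4, 1.2e-4, -6.0e-4, 5.0e-5),
    # ambiguity-attitude magnitudes (signed by frac_ambiguity_averse)
    "w_amb": ParamDist(0.009, 0.004, 0.002, 0.03),       # per day
    "beta_itc": ParamDist(0.3, 0.15, 0.05, 0.9),
    "beta_risk": ParamDist(0.4, 0.2, 0.05, 1.2),
}
# probability-domain overrides: the same symbols act on much smaller
# attribute ranges (fractions, not days)
_PROB_OVERRIDES = {
    "w_inter": ParamDist(-0.02, 0.01, -0.08, 0.0),
    "w_inter_amb": ParamDist(-0.3, 0.15, -1.2, 0.0),
    "w_amb": ParamDist(1.0, 0.4, 0.2, 3.0),              # per unit range
}


@dataclass
class PopulationSpec:
    """Population distributions plus contamination rates for one model."""

    model_id: str
    dists: dict[str, ParamDist]
    frac_ambiguity_averse: float = 0.70
    p_rt_outlier: float = 0.079       # matches the observed mean outlier rate
    p_switch_trial: float = 0.05
    catch_error_rate: float = 0.02

    def __post_init__(self):
        spec = get_model(self.model_id)
        missing = set(spec.param_names) - set(self.dists)
        if missing:
            raise ValueError(f"missing population distributions: {sorted(missing)}")
        if not 0.0 <= self.frac_ambiguity_averse <= 1.0:
            raise ValueError("frac_ambiguity_averse must lie in [0, 1]")

    def to_json(self) -> str:
        d = {"model_id": self.model_id,
             "frac_ambiguity_averse": self.frac_ambiguity_averse,
             "p_rt_outlier": self.p_rt_outlier,
             "p_switch_trial": self.p_switch_trial,
             "catch_error_rate": self.catch_error_rate,
             "dists": {k: [v.loc, v.scale, v.low, v.high]
                       for k, v in self.dists.items()}}
        return json.dumps(d, default=float, indent=1)


def default_population(model_id: str, **overrides) -> PopulationSpec:
    """Default population spec for any registered model."""
    spec = get_model(model_id)
    dists = {}
    for name in spec.param_names:
        if spec.domain == "probability" and name in _PROB_OVERRIDES:
            dists[name] = _PROB_OVERRIDES[name]
        else:
            dists[name] = _DEFAULT_DISTS[name]
    return PopulationSpec(model_id=model_id, dists=dists, **overrides)


def sample_participant(pop: PopulationSpec, rng: np.random.Generator) -> DDMParams:
    """Draw one participant's parameter set; the ambiguity parameter's sign is
    averse with probability ``frac_ambiguity_averse``."""
    spec = get_model(pop.model_id)
    values = {}
    for name in spec.param_names:
        x = pop.dists[name].sample(rng)
        if name in _AMBIGUITY_PARAM_SIGN:
            averse = rng.random() < pop.frac_ambiguity_averse
            sign = _AMBIGUITY_PARAM_SIGN[name] if averse else -_AMBIGUITY_PARAM_SIGN[name]
            x = sign * abs(x)
        values[name] = x
    return DDMParams(A=values["A"], t0=values["t0"], z=values["z"],
                     drift={n: values[n] for n in spec.drift_param_names})


# ---------------------------------------------------------------------------
# Forward simulation of the diffusion
# ---------------------------------------------------------------------------

SIM_DT = 1e-3      # Euler step (s)
SIM_T_MAX = 30.0   # hard cap on decision time


@njit(cache=True)
def _simulate_dt_batch(A, z, v_arr, dt, t_max, u_seedling):
    """Euler-Maruyama first-passage simulation; one path per drift value.
    u_seedling seeds numba's RNG so batches are reproducible."""
    np.random.seed(u_seedling)
    n = v_arr.shape[0]
    rts = np.empty(n)
    upper = np.empty(n, dtype=np.bool_)
    sq = math.sqrt(dt)
    # continuity correction for the O(sqrt(dt)) boundary-overshoot bias of
    # discretely monitored first passage (boundaries shifted inward by
    # 0.5826 * sigma * sqrt(dt))
    shift = 0.5826 * sq
    hi = A - shift
    lo = shift
    max_steps = int(t_max / dt)
    for i in range(n):
        x = z * A
        v = v_arr[i]
        hit = False
        for step in range(1, max_steps + 1):
            x += v * dt + sq * np.random.normal()
            if x >= hi:
                rts[i] = step * dt
                upper[i] = True
                hit = True
                break
            if x <= lo:
                rts[i] = step * dt
                upper[i] = False
                hit = True
                break
        if not hit:  # censored at t_max; absorb by the closer boundary
            rts[i] = t_max
            upper[i] = x >= A / 2.0
    return rts, upper


@dataclass(frozen=True)
class BehavioralRecord:
    """One observed trial: design cell plus choice, RT and switch count."""
    trial: Trial
    choice: str          # "variable" | "constant"
    rt: float            # seconds (first click)
    n_switches: int = 0
    is_rt_outlier: bool = False


def simulate_trial(params: DDMParams, spec: DriftModelSpec, trial: Trial,
                   rng: np.random.Generator,
                   p_rt_outlier: float = 0.0,
                   p_switch_trial: float = 0.0) -> BehavioralRecord:
    """Simulate one trial; contaminants injected at the given rates."""
    V, D, P, amb = trial_attributes(trial)
    p = np.array([params.drift[n] for n in spec.drift_param_names])
    v = float(drift_rate_array(spec.code, p, np.array([V]), np.array([D]),
                               np.array([P]), np.array([amb]))[0])
    switched = rng.random() < p_switch_trial
    if switched:
        pu = _choice_prob_upper(params.A, params.z, v)
        upper = rng.random() < pu
        # RT from an interrupted accumulation: not DDM-distributed; lognormal
        dt = float(rng.lognormal(math.log(1.2), 0.5))
        n_switches = 1 + int(rng.poisson(0.5))
    else:
        seed = int(rng.integers(0, 2**31 - 1))
        rts, uppers = _simulate_dt_batch(params.A, params.z, np.array([v]),
                                         SIM_DT, SIM_T_MAX, seed)
        dt, upper = float(rts[0]), bool(uppers[0])
        n_switches = 0
    rt = params.t0 + dt
    if rng.random() < p_rt_outlier:
        # exercise both exclusion arms
        if rng.random() < 0.5:
            rt = float(rng.uniform(0.05, RT_OUTLIER_LOW - 1e-3))
        else:
            rt = float(rng.uniform(RT_OUTLIER_HIGH + 1e-3, 12.0))
    flagged = rt < RT_OUTLIER_LOW or rt > RT_OUTLIER_HIGH
    return BehavioralRecord(trial=trial,
                            choice="variable" if upper else "constant",
                            rt=rt, n_switches=n_switches, is_rt_outlier=flagged)


def _simulate_choice_trials(params, spec, trials, rng, pop=None):
    """Vectorized simulation of many same-domain trials for one participant."""
    p_out = pop.p_rt_outlier if pop is not None else 0.0
    p_sw = pop.p_switch_trial if pop is not None else 0.0
    V = np.array([t.amount for t in trials])
    D = np.array([t.delay_days for t in trials])
    P = np.array([t.prob_win for t in trials])
    amb = np.array([trial_attributes(t)[3] for t in trials])
    p = np.array([params.drift[n] for n in spec.drift_param_names])
    v = drift_rate_array(spec.code, p, V, D, P, amb)
    seed = int(rng.integers(0, 2**31 - 1))
    dts, uppers = _simulate_dt_batch(params.A, params.z, v, SIM_DT, SIM_T_MAX, seed)
    records = []
    for i, t in enumerate(trials):
        switched = rng.random() < p_sw
        if switched:
            pu = _choice_prob_upper(params.A, params.z, v[i])
            upper = rng.random() < pu
            dt = float(rng.lognormal(math.log(1.2), 0.5))
            nsw = 1 + int(rng.poisson(0.5))
        else:
            upper, dt, nsw = bool(uppers[i]), float(dts[i]), 0
        rt = params.t0 + dt
        if rng.random() < p_out:
            if rng.random() < 0.5:
                rt = float(rng.uniform(0.05, RT_OUTLIER_LOW - 1e-3))
            else:
                rt = float(rng.uniform(RT_OUTLIER_HIGH + 1e-3, 12.0))
        flagged = rt < RT_OUTLIER_LOW or rt > RT_OUTLIER_HIGH
        records.append(BehavioralRecord(t, "variable" if upper else "constant",
                                        rt, nsw, flagged))
    return records


def _simulate_catch(trial, rng, catch_error_rate, t0):
    # Attention check: choice driven by attention, not evidence accumulation.
    err = rng.random() < catch_error_rate
    rt = t0 + float(rng.lognormal(math.log(0.8), 0.4))
    return BehavioralRecord(trial, "variable" if err else "constant",
                            rt, 0, rt < RT_OUTLIER_LOW or rt > RT_OUTLIER_HIGH)


BEHAVIOR_COLUMNS = ["participant"] + task_design.TRIAL_COLUMNS + [
    "choice", "rt", "n_switches", "is_rt_outlier"]


def records_to_frame(records, participant: int = 0) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        t = r.trial
        rows.append(dict(participant=participant, block=t.block, trial_index=i,
                         domain=t.domain, kind=t.kind, amount=t.amount,
                         delay_days=t.delay_days, prob_win=t.prob_win,
                         amb_days=t.amb_days, amb_prob=t.amb_prob,
                         choice=r.choice, rt=r.rt, n_switches=r.n_switches,
                         is_rt_outlier=r.is_rt_outlier))
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)


def records_from_frame(df: pd.DataFrame) -> list[BehavioralRecord]:
    out = []
    for row in df.itertuples(index=False):
        t = Trial(row.domain, row.kind, float(row.amount), float(row.delay_days),
                  float(row.prob_win), float(row.amb_days), float(row.amb_prob),
                  block=int(row.block))
        out.append(BehavioralRecord(t, row.choice, float(row.rt),
                                    int(row.n_switches), bool(row.is_rt_outlier)))
    return out


def simulate_session(params: DDMParams, spec: DriftModelSpec, session: Session,
                     rng: np.random.Generator, pop: PopulationSpec | None = None):
    """Simulate a full 210-trial session, preserving trial order."""
    catch_rate = pop.catch_error_rate if pop is not None else 0.0
    choice_trials = [t for t in session.trials if t.kind != "catch"]
    domain_trials = [t for t in choice_trials if t.domain == spec.domain]
    other_trials = [t for t in choice_trials if t.domain != spec.domain]
    if other_trials:
        raise ValueError("session contains trials outside the model's domain; "
                         "simulate each domain with its own model")
    recs = _simulate_choice_trials(params, spec, domain_trials, rng, pop)
    by_trial = {id(t): r for t, r in zip(domain_trials, recs)}
    out = []
    for t in session.trials:
        if t.kind == "catch":
            out.append(_simulate_catch(t, rng, catch_rate, params.t0))
        else:
            out.append(by_trial[id(t)])
    return out


def simulate_cohort(n_participants: int, pop: PopulationSpec, seed: int,
                    session: str = "domain"):
    """Simulate ``n_participants`` sessions under ``pop``'s model.

    session="domain" simulates only the model's own 98-trial grid (no catch
    trials); session="full" assembles a complete 210-trial session and
    simulates the model's domain plus its 14 catch trials, dropping the other
    domain's trials (which this model cannot generate).

    Returns (behavior DataFrame, ground-truth DataFrame, manifest dict);
    reproducible given ``seed`` — each participant consumes a named RNG
    stream spawned from (seed, participant id).
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    spec = get_model(pop.model_id)
    behav_frames, truth_rows = [], []
    for pid in range(n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([seed, pid]))
        params = sample_participant(pop, rng)
        if session == "domain":
            grid = (task_design.build_intertemporal_grid()
                    if spec.domain == "delay" else task_design.build_risky_grid())
            order = rng.permutation(len(grid))
            trials = [grid[i] for i in order]
            records = _simulate_choice_trials(params, spec, trials, rng, pop)
        elif session == "full":
            sess = assemble_session(int(rng.integers(0, 2**31 - 1)))
            kept = [t for t in sess.trials
                    if t.domain == spec.domain]
            choice = [t for t in kept if t.kind != "catch"]
            catch = [t for t in kept if t.kind == "catch"]
            records = _simulate_choice_trials(params, spec, choice, rng, pop)
            records += [_simulate_catch(t, rng, pop.catch_error_rate, params.t0)
                        for t in catch]
        else:
            raise ValueError("session must be 'domain' or 'full'")
        behav_frames.append(records_to_frame(records, participant=pid))
        row = {"participant": pid, "A": params.A, "t0": params.t0, "z": params.z}
        row.update(params.drift)
        truth_rows.append(row)
    behavior = pd.concat(behav_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    manifest = {"seed": seed, "n_participants": n_participants,
                "session": session, "population": json.loads(pop.to_json())}
    return behavior, truth, manifest


# ---------------------------------------------------------------------------
# Joint two-domain cohorts with a shared latent ambiguity trait
# ---------------------------------------------------------------------------

def _signed_gaussian_amb(dist: ParamDist, frac_averse: float, averse_sign: float,
                         g: float) -> float:
    """Ambiguity parameter as a Gaussian in the latent trait g ~ N(0,1).

    The marginal is N(m, s) with s equal to the magnitude scale (dist.loc)
    and m placed so that the averse sign occurs with probability
    ``frac_averse``; the trait enters linearly, so two domains sharing a
    correlated trait inherit exactly that correlation in their parameters.
    """
    from scipy.stats import norm
    s = dist.loc
    m = averse_sign * norm.ppf(frac_averse) * s
    return float(m + averse_sign * s * g)


def simulate_joint_cohort(n_participants: int, pop_delay: PopulationSpec,
                          pop_prob: PopulationSpec, seed: int,
                          rho_amb: float = 0.0, session: str = "full"):
    """Simulate both domains for every participant.

    Each participant's two ambiguity parameters are driven by a shared latent
    trait: their cross-domain Pearson correlation equals ``rho_amb``.  All
    other parameters are sampled independently per domain.  session="full"
    yields complete 210-trial sessions (both domains plus 14 catch trials);
    session="domain" concatenates the two bare 98-trial grids.

    Returns (behavior, truth, manifest); truth columns carry _delay/_prob
    suffixes.
    """
    if not -1.0 <= rho_amb <= 1.0:
        raise ValueError("rho_amb must lie in [-1, 1]")
    spec_d = get_model(pop_delay.model_id)
    spec_p = get_model(pop_prob.model_id)
    if spec_d.domain != "delay" or spec_p.domain != "probability":
        raise ValueError("pop_delay/pop_prob must carry a model of their domain")
    amb_names = {}
    for spec in (spec_d, spec_p):
        cand = [n for n in spec.drift_param_names if n in _AMBIGUITY_PARAM_SIGN]
        if len(cand) != 1:
            raise ValueError(f"{spec.model_id} needs exactly one ambiguity "
                             "parameter for the joint trait construction")
        amb_names[spec.domain] = cand[0]

    behav_frames, truth_rows = [], []
    for pid in range(n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([seed, pid]))
        # correlated latent traits
        u = rng.standard_normal()
        e1, e2 = rng.standard_normal(2)
        a = math.sqrt(abs(rho_amb))
        b = math.sqrt(1.0 - abs(rho_amb))
        sgn = 1.0 if rho_amb >= 0 else -1.0
        g1 = a * u + b * e1
        g2 = sgn * a * u + b * e2

        params = {}
        for spec, pop, g in ((spec_d, pop_delay, g1), (spec_p, pop_prob, g2)):
            p = sample_participant(pop, rng)
            name = amb_names[spec.domain]
            p.drift[name] = _signed_gaussian_amb(
                pop.dists[name], pop.frac_ambiguity_averse,
                _AMBIGUITY_PARAM_SIGN[name], g)
            params[spec.domain] = p

        if session == "full":
            sess = assemble_session(int(rng.integers(0, 2**31 - 1)))
            records = []
            for t in sess.trials:
                p = params[t.domain]
                if t.kind == "catch":
                    pop = pop_delay if t.domain == "delay" else pop_prob
                    records.append(_simulate_catch(t, rng, pop.catch_error_rate,
                                                   p.t0))
                else:
                    records.append(None)
            for domain, spec, pop in (("delay", spec_d, pop_delay),
                                      ("probability", spec_p, pop_prob)):
                idx = [i for i, t in enumerate(sess.trials)
                       if t.domain == domain and t.kind != "catch"]
                recs = _simulate_choice_trials(
                    params[domain], spec, [sess.trials[i] for i in idx], rng, pop)
                for i, r in zip(idx, recs):
                    records[i] = r
        elif session == "domain":
            records = []
            for grid_fn, spec, pop, domain in (
                    (task_design.build_intertemporal_grid, spec_d, pop_delay, "delay"),
                    (task_design.build_risky_grid, spec_p, pop_prob, "probability")):
                grid = grid_fn()
                order = rng.permutation(len(grid))
                records += _simulate_choice_trials(
                    params[domain], spec, [grid[i] for i in order], rng, pop)
        else:
            raise ValueError("session must be 'domain' or 'full'")

        behav_frames.append(records_to_frame(records, participant=pid))
        row = {"participant": pid}
        for domain, suffix in (("delay", "_delay"), ("probability", "_prob")):
            p = params[domain]
            row[f"A{suffix}"] = p.A
            row[f"t0{suffix}"] = p.t0
            row[f"z{suffix}"] = p.z
            for k, v in p.drift.items():
                row[f"{k}{suffix}"] = v
        truth_rows.append(row)

    behavior = pd.concat(behav_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    manifest = {"seed": seed, "n_participants": n_participants,
                "session": session, "rho_amb": rho_amb,
                "model_delay": pop_delay.model_id,
                "model_prob": pop_prob.model_id}
    return behavior, truth, manifest
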