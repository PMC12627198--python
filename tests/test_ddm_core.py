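"""Drift-rate formulas, WFPT likelihood, and the choice rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import ambiddm as am
from ambiddm.ddm_core import MODELS, DDMParams, get_model
from ambiddm.synth_cohort import BehavioralRecord, _simulate_dt_batch
from ambiddm.task_design import Trial

# plausible drift-parameter values for property checks, by name
_PARAM_VALUES = {"eta": 0.06, "k": 0.012, "s": 1.1, "alpha": 0.85,
                 "beta_itc": 0.3, "beta_risk": 0.4, "w_r": 0.06,
                 "w_t": -0.012, "w_p": 3.0, "w_amb": -0.6,
                 "w_inter": -1e-4, "w_inter_amb": -1e-4}


def make_params(spec, **over):
    drift = {n: over.get(n, _PARAM_VALUES[n]) for n in spec.drift_param_names}
    return DDMParams(A=over.get("A", 1.5), t0=over.get("t0", 0.3),
                     z=over.get("z", 0.5), drift=drift)


def domain_grid(spec):
    return (am.build_intertemporal_grid() if spec.domain == "delay"
            else am.build_risky_grid())


class TestDriftRate:
    def test_attribute_wise_linear_arithmetic(self):
        spec = get_model("itc_aw")
        p = make_params(spec, w_r=0.1, w_t=-0.02)
        t = Trial("delay", "exact", 50.0, delay_days=100.0)
        assert am.drift_rate(spec, p, t) == pytest.approx(0.1 * 45 - 0.02 * 100)
        assert am.drift_rate(spec, p, t) == pytest.approx(2.5)

    def test_hyperbolic_without_discounting_is_the_amount_difference(self):
        spec = get_model("itc_hyp")
        p = make_params(spec, eta=1.0, k=0.0)
        t = Trial("delay", "exact", 50.0, delay_days=100.0)
        assert am.drift_rate(spec, p, t) == pytest.approx(45.0)

    def test_gilboa_schmeidler_collapses_to_eu_without_ambiguity(self):
        gs, eu = get_model("risk_gs"), get_model("risk_eu")
        p_gs, p_eu = make_params(gs), make_params(eu)
        for t in domain_grid(gs):
            if (t.amb_prob if t.kind == "ambiguous" else 0.0) == 0.0:
                assert am.drift_rate(gs, p_gs, t) == \
                    pytest.approx(am.drift_rate(eu, p_eu, t))

    def test_negative_ambiguity_weight_makes_drift_decrease_with_range(self):
        spec = get_model("itc_aw_amb")
        p = make_params(spec, w_amb=-0.01)
        widths = [0.0, 48.0, 100.0, 148.0, 200.0]
        vs = [am.drift_rate(spec, p, Trial("delay", "ambiguous", 29.0,
                                           delay_days=100.0, amb_days=w))
              for w in widths]
        assert all(b < a for a, b in zip(vs, vs[1:]))
        # finite-difference slope matches the formula's dv/dAmb = w_amb / 2
        slope = (vs[1] - vs[0]) / 48.0
        assert slope == pytest.approx(-0.01 / 2)

    @pytest.mark.parametrize("model_id", [m for m, s in MODELS.items()
                                          if s.has_ambiguity])
    def test_ambiguity_models_collapse_to_their_parent_at_zero_range(self, model_id):
        child = get_model(model_id)
        parent = get_model(child.parent_id)
        pc = make_params(child)
        pp = make_params(parent)
        for t in domain_grid(child):
            amb = t.amb_days if child.domain == "delay" else t.amb_prob
            if t.kind == "exact" or amb == 0.0:
                assert am.drift_rate(child, pc, t) == \
                    pytest.approx(am.drift_rate(parent, pp, t), abs=1e-12)

    def test_strict_as_printed_hyperbolic_is_nonpositive(self):
        # the literal formula discounts V_LL in both terms; with an
        # immediate constant option the drift can never be positive
        spec = get_model("itc_hyp")
        p = make_params(spec, eta=0.05, k=0.01)
        for t in domain_grid(spec)[:20]:
            assert am.ddm_core.drift_rate(spec, p, t, strict_printed=True) <= 0.0

    def test_domain_mismatch_raises(self):
        spec = get_model("itc_aw")
        with pytest.raises(ValueError, match="domain"):
            am.drift_rate(spec, make_params(spec),
                          Trial("probability", "exact", 8.0, prob_win=0.5))


class TestWfpt:
    @pytest.mark.parametrize("A,z,v", [(1.0, 0.5, 0.0), (2.0, 0.3, 1.2),
                                       (0.8, 0.7, -2.0), (1.5, 0.5, 0.8)])
    def test_density_normalizes_and_matches_choice_probability(self, A, z, v):
        up = quad(lambda t: am.wfpt_pdf(t, "upper", A, 0.0, z, v),
                  0, 200, limit=200)[0]
        lo = quad(lambda t: am.wfpt_pdf(t, "lower", A, 0.0, z, v),
                  0, 200, limit=200)[0]
        assert up + lo == pytest.approx(1.0, abs=1e-6)
        assert up == pytest.approx(am.choice_prob_upper(A, z, v), abs=1e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(t=st.floats(0.05, 8.0), A=st.floats(0.5, 3.0),
           z=st.floats(0.1, 0.9), v=st.floats(-4.0, 4.0))
    def test_reflection_symmetry(self, t, A, z, v):
        f_up = am.wfpt_logpdf(t, "upper", A, 0.0, z, v)
        f_lo = am.wfpt_logpdf(t, "lower", A, 0.0, 1.0 - z, -v)
        assert f_up == pytest.approx(f_lo, rel=1e-10)

    def test_observation_before_nondecision_time_is_impossible(self):
        assert am.wfpt_logpdf(0.2, "upper", 1.0, 0.3, 0.5, 1.0) == -np.inf

    @pytest.mark.parametrize("bad", [dict(A=-1.0), dict(z=0.0), dict(z=1.2),
                                     dict(t0=-0.1)])
    def test_invalid_parameters_raise(self, bad):
        kw = dict(t=1.0, boundary="upper", A=1.0, t0=0.0, z=0.5, v=0.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            am.wfpt_logpdf(**kw)

    def test_mean_decision_time_matches_closed_form(self):
        # E[DT] at z = 1/2 is (A / 2v) * tanh(A v / 2)
        for A, v in [(1.5, 1.0), (2.0, 0.5), (1.0, 2.0)]:
            m = quad(lambda t: t * (am.wfpt_pdf(t, "upper", A, 0, 0.5, v)
                                    + am.wfpt_pdf(t, "lower", A, 0, 0.5, v)),
                     0, 200, limit=200)[0]
            assert m == pytest.approx((A / (2 * v)) * math.tanh(A * v / 2),
                                      abs=1e-6)

    def test_density_matches_euler_maruyama_simulation(self):
        # forward-simulation oracle: binned first-passage frequencies
        # against the analytic density
        A, z, v, dt, n = 1.5, 0.4, 0.8, 5e-4, 200_000
        rts, upper = _simulate_dt_batch(A, z, np.full(n, v), dt, 30.0, 123)
        p_up_emp = upper.mean()
        p_up = am.choice_prob_upper(A, z, v)
        se = math.sqrt(p_up * (1 - p_up) / n)
        assert abs(p_up_emp - p_up) < 4 * se + 2 * dt  # discretization bias

        edges = np.linspace(0.0, 3.0, 31)
        hist = np.histogram(rts[upper], bins=edges)[0] / n
        grid = np.linspace(1e-4, 3.0, 1200)
        dens = am.wfpt_pdf(grid, "upper", A, 0.0, z, v)
        for i in range(len(edges) - 1):
            m = (grid >= edges[i]) & (grid < edges[i + 1])
            p_bin = np.trapezoid(dens[m], grid[m])
            se_bin = math.sqrt(max(p_bin * (1 - p_bin), 1e-12) / n)
            assert abs(hist[i] - p_bin) < 5 * se_bin + 0.004


class TestChoiceProb:
    def test_limit_at_zero_drift_is_the_starting_point(self):
        assert am.choice_prob_upper(1.0, 0.5, 0.0) == pytest.approx(0.5)
        assert am.choice_prob_upper(2.0, 0.3, 1e-12) == pytest.approx(0.3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(A=st.floats(0.3, 4.0), v=st.floats(-5.0, 5.0))
    def test_symmetry_at_central_start(self, A, v):
        p = am.choice_prob_upper(A, 0.5, v) + am.choice_prob_upper(A, 0.5, -v)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_printed_example(self):
        expected = (math.exp(-2) - 1) / (math.exp(-4) - 1)
        assert am.choice_prob_upper(2.0, 0.5, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.881, abs=5e-4)

    def test_continuity_across_the_zero_drift_switch(self):
        eps = 1e-9
        left = am.choice_prob_upper(1.5, 0.4, -eps)
        right = am.choice_prob_upper(1.5, 0.4, eps)
        assert left == pytest.approx(right, abs=1e-8)


class TestTrialLoglik:
    spec = get_model("itc_aw")

    def _record(self, **kw):
        t = Trial("delay", "exact", 50.0, delay_days=100.0)
        args = dict(trial=t, choice="variable", rt=1.2, n_switches=0,
                    is_rt_outlier=False)
        args.update(kw)
        return BehavioralRecord(**args)

    def test_switch_trial_uses_only_the_choice_probability(self):
        p = make_params(self.spec)
        r = self._record(n_switches=2)
        v = am.drift_rate(self.spec, p, r.trial)
        expected = math.log(am.choice_prob_upper(p.A, p.z, v))
        assert am.trial_loglik(r, self.spec, p) == pytest.approx(expected)

    def test_clean_trial_is_the_wfpt_density(self):
        p = make_params(self.spec)
        r = self._record()
        v = am.drift_rate(self.spec, p, r.trial)
        expected = am.wfpt_logpdf(r.rt, "upper", p.A, p.t0, p.z, v)
        assert am.trial_loglik(r, self.spec, p) == pytest.approx(expected)

    def test_switch_trial_likelihood_is_a_bernoulli(self):
        p = make_params(self.spec)
        total = sum(math.exp(am.trial_loglik(self._record(n_switches=1,
                                                          choice=c),
                                             self.spec, p))
                    for c in ("variable", "constant"))
        assert total == pytest.approx(1.0)

    def test_outlier_records_are_refused(self):
        with pytest.raises(ValueError, match="outlier"):
            am.trial_loglik(self._record(rt=0.2, is_rt_outlier=True),
                            self.spec, make_params(self.spec))
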