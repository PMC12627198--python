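"""Ambiguity-preference classification, robust correlation, ROPE rule."""

import numpy as np
import pandas as pd
import pytest

import ambiddm as am
from ambiddm.fit import PosteriorFit
from ambiddm.individual_diff import hdi, rope_decision


def _fake_fit(model_id, drift_draws: dict, S=2000):
    """PosteriorFit with hand-built drift-parameter draws."""
    spec = am.get_model(model_id)
    draws = np.zeros((2, S // 2, spec.n_params))
    draws[..., 0] = 1.5   # A
    draws[..., 1] = 0.4   # t0
    draws[..., 2] = 0.5   # z
    for j, name in enumerate(spec.drift_param_names):
        vals = np.asarray(drift_draws[name], dtype=float).reshape(2, S // 2)
        draws[..., 3 + j] = vals
    return PosteriorFit(model_id, 0, spec.param_names, draws,
                        np.zeros((S, 1)), (2, S // 2),
                        {n: 1.0 for n in spec.param_names}, 0.3, True, 1)


class TestClassification:
    def test_negative_ambiguity_weight_posterior_is_averse(self):
        rng = np.random.default_rng(0)
        f = _fake_fit("itc_aw_amb", {
            "w_r": rng.normal(0.06, 0.01, 2000),
            "w_t": rng.normal(-0.01, 0.002, 2000),
            "w_amb": -np.abs(rng.normal(0.01, 0.003, 2000))})
        assert am.classify_ambiguity_preference(f) == "averse"

    def test_positive_beta_is_averse_under_the_subtractive_convention(self):
        # beta shrinks the perceived win probability, so beta > 0 lowers the
        # drift toward the risky option
        rng = np.random.default_rng(1)
        f = _fake_fit("risk_gs", {
            "eta": np.abs(rng.normal(0.06, 0.01, 2000)),
            "alpha": np.abs(rng.normal(0.85, 0.05, 2000)),
            "beta_risk": np.abs(rng.normal(0.4, 0.1, 2000))})
        assert am.classify_ambiguity_preference(f) == "averse"

    def test_symmetric_posterior_is_indeterminate(self):
        sym = np.concatenate([np.linspace(-1, -1e-3, 1000),
                              np.linspace(1e-3, 1, 1000)])
        f = _fake_fit("itc_aw_amb", {"w_r": np.full(2000, 0.06),
                                     "w_t": np.full(2000, -0.01),
                                     "w_amb": sym})
        assert am.classify_ambiguity_preference(f, threshold=0.6) == \
            "indeterminate"

    def test_nonambiguity_model_is_refused(self):
        f = _fake_fit("itc_aw", {"w_r": np.full(2000, 0.06),
                                 "w_t": np.full(2000, -0.01)})
        with pytest.raises(ValueError, match="ambiguity"):
            am.classify_ambiguity_preference(f)

    def test_generator_roundtrip_matches_the_averse_prevalence(self):
        # sign of the true generating parameter across a large sample
        pop = am.default_population("itc_aw_amb_rxd")
        rng = np.random.default_rng(6)
        n = 800
        frac = np.mean([am.sample_participant(pop, rng).drift["w_amb"] < 0
                        for _ in range(n)])
        assert frac == pytest.approx(0.70, abs=3 * np.sqrt(0.21 / n))


class TestHdiRope:
    def test_hdi_of_a_normal_sample_matches_the_quantile_interval(self):
        rng = np.random.default_rng(2)
        lo, hi = hdi(rng.normal(0.0, 1.0, 200_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    @pytest.mark.parametrize("center,rope,verdict", [
        (0.25, (-0.06, 0.06), "significant"),
        (0.0, (-0.06, 0.06), "practically_equivalent"),
        (0.07, (-0.06, 0.06), "inconclusive"),
    ])
    def test_three_way_rule(self, center, rope, verdict):
        rng = np.random.default_rng(3)
        draws = rng.normal(center, 0.005 if verdict != "inconclusive" else 0.05,
                           5000)
        assert rope_decision(draws, rope).verdict == verdict

    def test_widening_the_rope_moves_toward_equivalence(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(0.10, 0.01, 5000)
        order = {"significant": 0, "inconclusive": 1,
                 "practically_equivalent": 2}
        verdicts = [rope_decision(draws, (-w, w)).verdict
                    for w in (0.05, 0.09, 0.3)]
        assert verdicts == ["significant", "inconclusive",
                            "practically_equivalent"]
        ranks = [order[v] for v in verdicts]
        assert ranks == sorted(ranks)

    def test_verdict_is_invariant_to_draw_order(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(0.05, 0.03, 4000)
        d1 = rope_decision(draws, (-0.06, 0.06))
        d2 = rope_decision(rng.permutation(draws), (-0.06, 0.06))
        assert d1.verdict == d2.verdict
        assert d1.hdi_low == pytest.approx(d2.hdi_low)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            rope_decision(np.zeros(5000), (0.1, -0.1))
        with pytest.raises(ValueError):
            rope_decision(np.zeros(10), (-0.1, 0.1))


class TestRobustCorrelation:
    def test_perfect_dependence(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100)
        post = am.robust_correlation(x, x, seed=1)
        assert np.mean(post.rho > 0.95) > 0.99

    def test_recovers_a_moderate_correlation(self):
        rng = np.random.default_rng(8)
        n = 500
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        post = am.robust_correlation(x, y, seed=2)
        assert post.rho.mean() == pytest.approx(0.5, abs=0.1)
        s = post.summary()
        assert s["hdi_low"] < 0.5 < s["hdi_high"]

    def test_gross_outliers_move_the_estimate_less_than_pearson(self):
        rng = np.random.default_rng(9)
        n = 100
        x = rng.standard_normal(n)
        y = 0.8 * x + 0.6 * rng.standard_normal(n)
        x_c, y_c = x.copy(), y.copy()
        x_c[:5], y_c[:5] = 6.0, -6.0    # 5% gross contamination
        r_clean = np.corrcoef(x, y)[0, 1]
        r_pearson = np.corrcoef(x_c, y_c)[0, 1]
        post = am.robust_correlation(x_c, y_c, seed=3)
        assert abs(post.rho.mean() - r_clean) < abs(r_pearson - r_clean)
        assert post.nu.mean() < 20   # heavy tails engaged

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            am.robust_correlation(np.ones(50), np.arange(50.0))
        with pytest.raises(ValueError):
            am.robust_correlation(np.arange(5.0), np.arange(5.0))


class TestCrossDomainReport:
    @staticmethod
    def _table(rho, n, seed):
        rng = np.random.default_rng(seed)
        cov = [[1, rho], [rho, 1]]
        pbf = rng.multivariate_normal([0.5, 0.5], cov, size=n)
        amb = rng.multivariate_normal([-0.3, -0.3], cov, size=n)
        return pd.DataFrame({"log_pbf_delay": pbf[:, 0],
                             "log_pbf_prob": pbf[:, 1],
                             "amb_param_delay": amb[:, 0],
                             "amb_param_prob": amb[:, 1]})

    def test_identical_domains_yield_near_perfect_correlation(self):
        t = self._table(0.0, 60, 10)
        t["log_pbf_prob"] = t["log_pbf_delay"]
        t["amb_param_prob"] = t["amb_param_delay"]
        rep = am.cross_domain_report(t, seed=4)
        assert rep["log_pbf"]["correlation"]["mean"] > 0.95
        assert rep["log_pbf"]["rope"]["verdict"] == "significant"

    def test_shared_trait_correlation_is_recovered(self):
        rep = am.cross_domain_report(self._table(0.3, 150, 11), seed=5)
        est = rep["log_pbf"]["correlation"]
        assert est["hdi_low"] < 0.3 < est["hdi_high"]
        assert est["mean"] == pytest.approx(0.3, abs=0.15)

    def test_independent_domains_are_not_declared_significant(self):
        rep = am.cross_domain_report(self._table(0.0, 200, 12), seed=6)
        assert rep["log_pbf"]["rope"]["verdict"] != "significant"

    def test_small_or_incomplete_tables_refused(self):
        with pytest.raises(ValueError):
            am.cross_domain_report(self._table(0.0, 5, 13))
        with pytest.raises(ValueError, match="missing"):
            am.cross_domain_report(pd.DataFrame({"log_pbf_delay": [1.0]}))
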