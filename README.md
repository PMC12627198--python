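# ambiddm

Drift-diffusion modelling of **ambiguity preferences** in intertemporal and
risky choice.

People routinely decide between a safe, immediate option and a variable one
whose delay or win probability may be known only as a range ("you will get
€36 in 26–174 days") — that range width is the *ambiguity* of the option.
`ambiddm` is a research pipeline for asking (i) which value model best
explains choices and response times under time ambiguity and probability
ambiguity, and (ii) whether a person's aversion to ambiguous delays travels
with their aversion to ambiguous probabilities.  It targets computational
cognitive modellers working with two-alternative preferential choice data
(choice + RT + preference-switch counts per trial).

## The model

Evidence accumulates as a unit-variance Wiener diffusion between absorbing
boundaries 0 and A, starting at zA, with non-decision time t0.  Hitting the
upper boundary selects the variable (later-larger / risky) option.  The
trial-wise drift rate v is supplied by a value model — for integrated-value
models

v = η · (SV_variable − SV_constant),

with SV from hyperbolic / generalized-hyperbolic discounting (delay domain)
or (Gilboa–Schmeidler-shifted) expected utility (probability domain), and
for attribute-wise models a weighted sum of attribute differences, e.g.

v = w_r (V − 5) + w_t (D − 0) + w_amb · Amb/2 + w_inter (V − 5)·D.

The registry (`ambiddm.MODELS`) holds all 12 intertemporal and 9 risky drift
models.  Trials without a preference switch contribute the Wiener
first-passage-time density of (RT, choice); switch trials contribute only
the closed-form choice probability

P(upper) = (e^{−2Azv} − 1) / (e^{−2Av} − 1).

Around this core the package provides: the deterministic 210-trial task
design (14 alternating delay/probability blocks, one catch trial each), a
synthetic-cohort generator with known ground truth and realistic
contaminants, the exclusion cascade (catch errors / RT outliers /
preference switches), per-participant Bayesian fitting with wide-normal
priors on transformed scales and split-R̂ convergence checks, model
comparison via PSIS-LOO, Akaike-type softmax weights, pseudo-inclusion
Bayes factors and random-effects Bayesian model selection (protected
exceedance probabilities), plus Bayesian robust correlation and the
ROPE + HDI decision rule for cross-domain individual differences.

## Worked example

Simulate three participants from the attribute-wise + ambiguity model, fit
the generating model and its non-ambiguity parent to one participant, and
ask which family the data support:

```python
import ambiddm as am

pop = am.default_population("itc_aw_amb", p_rt_outlier=0.0, p_switch_trial=0.0)
behavior, truth, _ = am.simulate_cohort(3, pop, seed=5, session="domain")

cfg = am.MCMCConfig(n_chains=2, n_warmup=500, n_sampling=500, seed=5)
sub = behavior[behavior.participant == 0]
elpd = {}
for mid in ("itc_aw_amb", "itc_aw"):
    fit = am.fit_participant(sub, am.get_model(mid), cfg)
    elpd[mid] = am.psis_loo(fit).elpd_loo
    if mid == "itc_aw_amb":
        mx, ok = am.check_convergence(fit)
        print(f"max split-R-hat: {mx:.4f} (converged: {ok})")
        print(f"true w_amb: {truth.loc[0,'w_amb']:+.4f}   "
              f"posterior mean: {fit.posterior_mean()['w_amb']:+.4f}")
        print(f"ambiguity attitude: {am.classify_ambiguity_preference(fit)}")

w = am.akaike_weights(list(elpd.values()))
pbf, _ = am.pbf_inclusion(w[None, :], [True, False])
print(f"ambiguity-model weight: {w[0]:.3f}   PBF_inclusion: {pbf[0]:.1f}")
```

prints

```
max split-R-hat: 1.0026 (converged: True)
true w_amb: -0.0094   posterior mean: -0.0118
ambiguity attitude: averse
ambiguity-model weight: 0.856   PBF_inclusion: 5.9
```

The sampler converged (split-R̂ below the 1.005 criterion); the negative
ambiguity weight — recovered close to its generating value — marks this
participant as time-ambiguity averse, and the pseudo-inclusion Bayes factor
of 5.9 says their data are about six times better explained by the model
family that carries an ambiguity term.

A thin CLI mirrors the pipeline stages:

```sh
ambiddm design --seed 1 --out trials.csv
ambiddm simulate --model itc_aw_amb_rxd --n 20 --seed 7 --out cohort/
ambiddm preprocess --behavior cohort/behavior.csv --out prep/
ambiddm fit --model itc_aw_amb_rxd --behavior cohort/behavior.csv --out fits/
ambiddm compare --elpd elpd.csv --partition ambiguity --out bms.json
```

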