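# Methods

## Task design

A session is 210 trials: 14 blocks of 15, alternating between delay and
probability blocks (which domain opens is decided by seed parity).  The
constant option is always €5, immediate, certain, and is never shown as
varying; the variable option crosses 7 amounts (€8–€50) with 9 exact delays
(10–190 days) or 5 delay-ambiguity widths (0–200 days, midpoint always 100
days) in the delay domain, and with 9 exact win probabilities (5%–95%) or 5
probability-ambiguity widths (0%–100%, midpoint 50%) in the probability
domain — 98 unique trials per domain.  The exact-delay ladder is printed in
the source task description with eight values against a claimed nine
levels; this package inserts 124 days, restoring the ladder symmetric
around 100 days and matching the 76–124 endpoint pair of the 48-day
ambiguous range.  Each block carries one catch trial whose variable amount
equals the constant €5 (any attentive participant should decline it); its
remaining attributes are fixed at the mid-level exact cell (100 days / 50%)
since the attention check depends only on the amount.

## Drift-rate models

All 21 models map a trial's attributes (V, D, P, Amb) to a drift rate.
Ambiguity enters as the half-range Amb/2 except in those formulas defined
on the full range; the family is implemented formula-by-formula as defined,
including its asymmetries (e.g. the one-parameter hyperbolic
time-perception model subtracts β·Amb from the delay while the generalized
variant subtracts β·Amb/2 inside the discount term; some attribute-wise
variants carry a full-range main effect next to a half-range interaction).
Two deliberate deviations from the literal table text:

* the discounted sooner-smaller term of the integrated-value delay models
  is evaluated at the constant option's amount (V_SS = 5).  Taken
  literally, with D_SS = 0 the printed V_LL in that term forces a
  non-positive drift for every parameter value; the literal form remains
  available via `strict_printed=True`.
* effective delays in the time-perception models are floored at zero
  before entering the hyperbola/power, since negative perceived delays are
  meaningless and produce complex powers.

The diffusion coefficient is fixed at 1 (its scale is not identifiable
jointly with A and v), z is the relative starting fraction, and units are
seconds, days, euros and probability fractions.  For attribute-wise models
the scaling η is fixed at 1: the weights absorb it, and freeing it would
create pure multiplicative non-identifiability.

## Likelihood

The WFPT density uses the dual small-time/large-time series with the
standard truncation bounds and an automatic regime switch; the internal
tolerance 1e-12 on the normalized-time density keeps the absolute density
error well below 1e-9 over the plausible parameter range.  Observations at
or before t0 have zero density (−inf log likelihood), which is a statement
about the data point, not a parameter error.  Trials with one or more
preference switches indicate multiple accumulation episodes, so their RT is
not WFPT-distributed; they contribute only the Bernoulli choice probability
(numerically stabilized around v = 0 by a series limit, continuous with
value z).  RT-outlier trials are excluded from all likelihoods.

## Synthetic cohorts

The generator is the package's testbed: participants are drawn from
truncated-normal population distributions per parameter, behaviour is
simulated forward from the DDM (Euler–Maruyama, dt = 1 ms, with the 0.5826·σ√dt
boundary continuity correction for the discretization bias of first
passage), and contaminants are injected at configurable rates.  Defaults
and their rationale:

* 70% of participants are ambiguity-averse (sign of the ambiguity
  parameter), matching the empirical prevalence (469/669).
* per-trial RT-outlier probability 0.079, the observed mean outlier rate;
  contaminated RTs are drawn half below 0.3 s and half above 10 s so both
  exclusion arms are exercised.
* per-trial switch probability 0.05 and per-catch-trial error rate 0.02,
  modest rates chosen so that typical cohorts survive the cascade while
  every criterion fires occasionally in large cohorts.
* non-decision time 0.45 ± 0.08 s, bounded to [0.32, 0.8] s.  RT is the
  first mouse click, so encoding plus cursor travel keeps t0 well above
  300 ms; this also makes contaminant-free cohorts genuinely free of
  RT-window violations.
* population dispersions are wide (e.g. w_r 0.06 ± 0.035, w_t −0.012 ±
  0.008, z 0.5 ± 0.08) to emulate the several-fold between-participant
  heterogeneity of empirical cohorts — the recovery experiment is defined
  on "truth" of that dispersion.

Catch-trial behaviour is attention-driven (constant option chosen with
probability 1 − error rate), not evidence accumulation.  Switch trials are
*flagged* at random with the choice drawn from the closed-form choice rule;
this reproduces how such trials enter the likelihood but not the process
that causes switching.  The generator also does not model learning or
block-order effects, so passing tests speak to estimator correctness under
the model, not to those aspects of real data.  A joint two-domain generator
drives both ambiguity parameters from a shared latent Gaussian trait whose
cross-domain correlation is exact by construction (the marginal aversion
prevalence is preserved), for calibrating the cross-domain analyses.

## Fitting

Sampling is per participant (model comparison consumes individual
pointwise log likelihoods; no hierarchy).  Parameters are transformed to an
unconstrained space (log for A, t0, η, k, s, α; logit for z; identity for
weights and β) and given independent normal priors with SD 5 — wide enough
to be effectively flat.  Prior centers are weakly informative (log t0
centered at log 0.1 s, all else at 0) so the log posterior is finite at the
prior means for every model.

The sampler is an affine-invariant ensemble (emcee) with 80%
differential-evolution and 20% snooker moves, which mix far better than
stretch moves on the correlated weight posteriors.  One independently
seeded ensemble of max(24, 4·ndim) walkers plays the role of one MCMC
chain; walkers start in a small ball around the posterior mode
(Nelder–Mead).  The full-scale configuration is 2 chains × 3,500 warm-up +
4,500 sampling iterations; tests and the acceptance script use scaled-down
configurations (500/500 and 1,000/1,000) whose problem sizes are stated
with each experiment.  Convergence is assessed by rank-normalized
split-R̂ per parameter with the criterion R̂ < 1.005; fits whose ensembles
stop moving (mean acceptance < 5%) are marked unusable rather than
returned silently.  Fits require at least 50 usable trials (configurable).

The pointwise log-likelihood matrix is computed on an evenly thinned
subset of draws (default cap 8,000) — ample for PSIS-LOO while keeping the
matrix small at full-scale draw counts.

## Model comparison

PSIS-LOO runs through ArviZ on the pointwise matrix; a collapsed posterior
(identical draws) falls back to the exact pointwise log likelihood with a
warning.  Akaike-type weights are the softmax of per-participant elpd
values.  The pseudo-inclusion Bayes factor divides the posterior family
odds (summed weights in vs out of a feature family) by the prior family
odds under uniform model priors — the prior correction matters because the
ambiguity and attribute-wise families are not half of the candidate set.
A vanished out-group mass returns a capped sentinel (1e12) with a flag.

RE-BMS follows the variational Dirichlet treatment of population model
frequencies: responsibilities and Dirichlet pseudo-counts are iterated to
convergence, exceedance probabilities are estimated from 10^5 seeded
Dirichlet draws (MC error ≈ 0.003), the Bayes omnibus risk compares the
free energy of the random-effects model against the equal-frequency null,
and PXP = (1 − BOR)·EP + BOR/K.  Elpd values are consumed directly as log
model evidences; no rescaling is applied.

## Individual differences

A participant's ambiguity attitude is classified from the posterior of the
drift *change* induced by raising ambiguity from zero to its maximal range
at a reference mid-level trial — this derivative-based definition handles
both sign conventions (additive weights where aversion is negative, and
subtractive β coefficients where aversion is positive) uniformly.  The
default criterion is the posterior median sign; a stricter posterior-mass
threshold is configurable.

The robust correlation is a bivariate Student-t likelihood with unknown
degrees of freedom: uniform prior on ρ, shifted-exponential prior on ν
(ν = 1 + Exp, mean 30), weakly informative normal priors on locations and
log scales anchored at the sample moments.  With no outliers the ν
posterior drifts large and the estimate approaches Pearson behaviour; with
gross outliers the heavy tails discount them.  HDIs use the
shortest-interval method on pooled chains; the ROPE + HDI rule returns
significant / practically equivalent / inconclusive by disjointness /
containment / overlap.  The cross-domain report z-standardizes inputs and
correlates log PBF values (not raw PBFs) and ambiguity parameters between
domains, with a default ROPE of ±0.06.

## Numerical and testing choices

* The forward-simulation oracle for the WFPT density uses 2×10^5
  Euler–Maruyama paths at dt = 5×10^-4 with tolerances set from the
  Monte-Carlo error of that size.
* The exact-LOO oracle for PSIS-LOO uses a conjugate normal-mean problem
  where the leave-one-out predictive density is available in closed form.
* Acceptance experiments: parameter recovery uses 20 participants × 98
  trials with the 500/500 sampler; convergence uses one participant with
  the 1,000/1,000 sampler.  All sub-seeds derive from a single seed.

## Known limitations

* No across-trial variability parameters (sv, st0, sz); the canonical
  four-parameter DDM only.
* No hierarchical (group-level) priors; fitting is strictly per
  participant.
* The regression-based (GLMM) analysis path and KDE-based log model
  evidence are out of scope; correlation targets are model-derived
  quantities.
* The interaction weight w_inter is weakly identified at 98 trials per
  participant: its recovery correlation typically sits below the other
  parameters', consistent with "most", not all, parameters recovering
  well.
* Whether catch trials belong in the outlier-percentage denominator is
  ambiguous in the source description; the package includes them by
  default and exposes a switch.
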