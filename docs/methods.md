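# Methods

## The measurement problem

A two-interval temporal-bisection trial yields three observations: two
bisection estimates of the same interval, `I1` and `I2` (seconds, each
necessarily inside `[0, T]` where `T` is the total duration), and a
forced second-order choice `r ∈ {1, 2}` of which estimate the observer
believes was closer to the veridical midpoint `T/2`. The package measures
two latent precisions from such data: how precisely the observer times
(the interval-estimate SDs) and how precisely the observer knows how well
they timed (the metacognitive SD), plus the subjective midpoint the
estimates are organised around.

## Descriptive layer

*Re-sorting.* Each trial pair is split into a best and a worst member
either by the observer's choice (subjective) or by absolute distance to
the veridical midpoint (ideal). Re-sorting permutes values, never alters
them, so the union of best and worst sets is always the multiset of all
estimates (property-tested). Exact distance ties in the ideal sort go to
interval 1; for continuous data this is a measure-zero event and the
choice only serves determinism.

*Metacognitive Index.* `MCI = (Vi.best/Vi.worst) / (Vs.best/Vs.worst)`
with unbiased (n−1) sample variances throughout. The n−1 convention is a
package choice; the normalisation cancels in each ratio except through
the usual small-sample noise, and the analytic anchors (MCI = 1 for an
ideal chooser) hold under either convention. Zero variances raise a
`DegenerateVarianceError` rather than propagating infinities, because the
MCI is a ratio of ratios and silent infinities would corrupt group
summaries.

*Series statistics.* Binned trial series use t-based 95% CIs (the CI
family is otherwise unspecified in the field's descriptions); a final
partial bin is kept and flagged. Histograms use 150 equal bins on
`[0, T]`, half-open except the closed last bin, so counts always sum
to n. Autocorrelation at lag k is the Pearson correlation of the series
with its k-shifted copy over the overlap, which makes a strictly
alternating series score exactly −1 at lag 1 (an FFT/biased estimator
would give −(n−1)/n). Coefficient of variation is sample SD over mean;
its constancy across base durations is the scalar-timing signature the
summary is intended to probe.

## Generative model (simulator)

Per trial, with condition-specific parameters:

    I1 ~ Normal(φ, σ_I1),  I2 ~ Normal(φ, σ_I2),  truncated to [0, T]
    Δk = |Ik − φ|,  dΔ = Δ1 − Δ2
    P(choose interval 1) = P(Normal(dΔ, σ_m) < 0) = Φ(−dΔ/σ_m)

Truncation is by resampling: a button release cannot precede stimulus
onset or follow its offset. The inference model is deliberately left
untruncated (see below); at the parameter scales of interest
(φ ≈ T/2, σ_I ≲ 0.3 T) the truncated mass is negligible.

Two modelling choices deserve emphasis:

- **Absolute errors.** The error entering the comparison is `|Ik − φ|`,
  not the signed residual. With signed errors, dΔ would collapse to
  `I1 − I2` independent of the midpoint, and the "choose the smaller
  perceived error" semantics — and the closeness-to-target meaning of the
  choice — would be lost. The signed variant is retained behind
  `signed_errors=True` for sensitivity analysis only.
- **Static midpoint.** φ is constant across trials, matching the
  measurement model's assumption. An optional exponential drift
  `(offset, decay-constant in trials)` emulates the initial learning
  transient seen in real trial series; it is off by default and exists
  for robustness checks, not for inference.

At `σ_m = 0` the choice rule becomes deterministic (probability 1, 0, or
0.5 at exact equality) and the observer is the ideal chooser of their own
smaller-error interval; if additionally φ equals the veridical midpoint,
subjective and ideal sortings coincide and MCI = 1 exactly. This limit is
the package's primary analytic anchor.

*Observer populations.* `sample_observers` draws subject midpoints
normally around group means and draws the three SD roles lognormally
(median = group value, log-scale spread `sigma_spread`), with the
log-values correlated across the V/A/AV conditions by a
compound-symmetric correlation ρ — the same repeated-measures coupling
the hierarchical model assumes. Defaults (φ = 0.75 s for the 1500 ms
condition, σ_I = 0.15 s, σ_m = 0.5 s, ρ = 0.6, spread 0.2) sit at the
centre of the subject-level values such experiments report for the
1500 ms condition; they are the package's reference conditions, not
tuning knobs. Five subjects, 500 trials per condition in blocks of 100,
is the reference design.

## Hierarchical model

For one base duration, subjects s, conditions c ∈ {V, A, AV}, roles
r ∈ {I1, I2, meta}:

    mu0        ~ Normal(T/2, σ_Mid)          grand subjective midpoint
    muc[c]     ~ Normal(mu0, σ_Φ)            condition midpoints
    mus[s,c]   ~ Normal(muc[c], σ_subj)      subject midpoints (likelihood mean)
    λ[s,·,r]   ~ MVN(log μτ[·,r], Σ_s)       subject log-precisions
    Σ_s        = scale² · R(ρ_s) + ε·I,  ε = 0.1
    μτ[c,r]    ~ Uniform(0, 100)             group precisions
    ρ_s        ~ Uniform(0, 1);  scale ~ Uniform(0, 10)

with the likelihood of the generative model above evaluated at
`σ = exp(−λ/2)` and the subject midpoint. The three midpoint-layer
precisions (1/σ²_Mid, 1/σ²_Φ, 1/σ²_subj) carry the same Uniform(0, 100)
priors as every other precision. The *constrained* variant replaces
`λ[s,c,r]` with a single `λ[s,r]` shared across conditions
(`Normal(log μτ[r], sqrt(scale² + ε))`), which removes ρ.

Design choices where the construction was genuinely open:

- **Subject-level midpoints.** The midpoint hierarchy includes a
  subject layer (subject → condition → grand → veridical): subject-level
  midpoint posteriors are a required output and the likelihood should
  absorb between-subject bias rather than inflating σ_I.
- **MVN on log-precisions.** The cross-condition coupling acts on
  log-precisions, which guarantees positivity and keeps the ε-regularised
  covariance interpretable; group means keep their Uniform(0, 100) priors
  on the precision scale. A literal precision-scale MVN (truncated at
  zero) is an alternative reading of the coupling; the log-scale form is
  the numerically stable default.
- **σ_m shared across intervals.** One metacognitive SD per
  subject-condition (not one per interval), matching the one-column
  summary such fits report.
- **Untruncated likelihood.** The inference model ignores the [0, T]
  truncation the simulator enforces; the approximation error is far below
  posterior width at realistic parameter scales and keeps the normal
  conjugacies.
- **Bernoulli floor.** Choice probabilities are clamped at 1e−12 before
  taking logs, so a single model-impossible choice contributes a large
  but finite penalty (with a warning) instead of −inf.

## Sampling

Adaptive Metropolis-within-Gibbs, exploiting the block structure of the
posterior (each subject-condition's data enter through two normal
sufficient-statistic terms and one Bernoulli-probit term, all cached):

- conjugate Gibbs draws for `muc`, `mu0` (normal) and the three
  midpoint-layer precisions (gamma, truncated to the prior box);
- componentwise random-walk Metropolis for subject midpoints,
  log-precisions (with a 10% chance of a 5× proposal to traverse the
  heavy upper tail of weakly identified metacognitive SDs), group
  precisions and the coupling parameters;
- a joint *shift* move that translates a whole group's log-precisions
  and its group mean together. The MVN prior depends only on
  `λ − log μτ`, so this move crosses the hierarchical ridge along which
  componentwise updates diffuse slowly; it is what makes 2 × 2500-sweep
  runs converge (max split-R-hat ≲ 1.01 on the reference designs) where
  purely componentwise sampling needed an order of magnitude more.

Proposal SDs adapt toward 0.44 acceptance during burn-in only (every 25
sweeps), then freeze, preserving detailed balance for retained draws.
Defaults mirror the reference analysis: 2 chains, 2000 burn-in, 5000
sampling sweeps thinned by 20. Convergence is rank-normalized split
R-hat (via arviz) on every reported parameter; a maximum above 1.05
flags the result and warns — never silently passes. Chains are
initialised at jittered empirical estimates (block means and variances).

**HDI.** The 95% highest-density interval is the shortest window of
⌈0.95·n⌉ consecutive order statistics — exact for unimodal posteriors
and verified against an exhaustive window scan. (arviz's HDI uses a
window one order statistic wider; the two agree to draw spacing.)

**DIC.** `D(θ) = −2 log L(y|θ)` per retained draw;
`p_D = 2·var[log L]`; and, by default, the literal composition
`DIC = D̄ + 2·p_D`. This composition double-counts relative to the
standard Spiegelhalter form `D̄ + p_D`, which is available via
`convention="spiegelhalter"`; only the relative ordering of variants
matters for model selection and the ordering is convention-invariant
when both sides use the same one (tested).

**Posterior-predictive MCI.** Each retained draw's subject-level
parameters are pushed through the simulator (a fresh session per subject
and condition), the MCI computed exactly as for data, and averaged
across subjects; draws with degenerate variances are dropped and
counted. This closes the loop between the model and the descriptive
index it is meant to explain.

## Problem sizes and what the tests show

The test suite and acceptance script run everything at sizes the package
treats as reference or smoke scale: recovery fits use 5 subjects × 3
conditions × 100 trials with 2 chains × (1000 burn-in + 3750 sweeps,
thin 5; 1500 retained draws); coverage uses 3 seeded replications of that
design (27 group-SD HDI checks, ≥ 85% must cover); DIC direction uses 3
replications per generating variant with 3 subjects; the MCI-vs-σ_m
monotonicity grid uses 200 sessions per point with common random numbers
across grid points (a variance-reduction pairing, not a change of
conditions). Full-size studies (500 trials, more subjects, more
replications) use the identical code paths — only `ScheduleSpec` and the
MCMC settings change.

What passing these tests shows: the estimators are internally correct
(oracle equalities), the sampler converges and recovers known parameters
at realistic scales, and model selection points to the generating
variant. What they do not show: that real observers satisfy the model.
The simulator produces stationary, normally distributed, truncation-
bounded estimates with a probit choice rule; real data exhibit learning
transients, sequential dependencies (autocorrelation), occasional lapses,
and possibly non-normal estimate distributions (the ideal-worst set is
visibly bimodal by construction), none of which the generator emulates
except the optional drift.

## Known limitations

- The midpoint is static across trials; fitting the learning transient
  requires a trial-varying extension out of scope here.
- The MVN coupling shares one ρ per subject across the three roles; a
  role-specific ρ is a straightforward extension but is not identified
  well at five subjects.
- DIC is the only model-comparison criterion implemented (no WAIC/LOO).
- Uniform(0, 100) precision priors bound group SDs below at 0.1 — at
  sub-0.1 s true SDs the group posterior piles at the prior edge, as it
  would in any implementation with these priors.
- The choice model has no lapse parameter; a handful of stimulus-
  independent errors will inflate σ_m rather than being absorbed.
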