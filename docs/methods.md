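# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `moralcomp`.

## Task and data model

One experimental ("self-error") trial is defined by a harm level H ∈ {1..4}
(shock intensity delivered to the receiver) and a wrongdoer count
W ∈ {1..4} (how many of the four deciders erred, the participant included);
responsibility is R = 5 − W, and the two are stored with W as the single
source of truth so the invariant W + R = 5 holds by construction.  The
default design crosses all 16 (H, R) cells 4 times (64 experimental trials)
and adds 48 filler trials (participant correct), split into 4 sessions of
16 + 12.  Fillers carry no harm/wrongdoer fields and never enter any
analysis; their composition is not modelled further.  Within a session the
order is a uniform shuffle constrained so that no (H, R) cell repeats on
consecutive experimental trials; the constraint is abandoned after 1000
failed shuffles (with the default one-factorial-per-session layout it is
always satisfiable).  The token economy: a 10-token endowment per trial at
0.5 yuan/token, decisions on the integer grid 0–10; four deciders give the
receiver at most 40 tokens per trial, and a decider can forgo at most
5 yuan.

## Utility models

Eight variants over two families (diffusion A = H/W, amplification
A = H·R), with optional greed θ and baseline η:

| id  | family        | greed θ | baseline η | free parameters |
|-----|---------------|---------|------------|-----------------|
| 1.1 | diffusion     | yes     | yes        | θ, κ, η, λ (4)  |
| 1.2 | diffusion     | yes     | no         | θ, κ, λ (3)     |
| 1.3 | diffusion     | no      | yes        | κ, η, λ (3)     |
| 1.4 | diffusion     | no      | no         | κ, λ (2)        |
| 2.x | amplification | as 1.x  | as 1.x     | as 1.x          |

U(D) = θ(10 − D) − (1 − θ)|κA + η − D| (θ ≡ 0 without greed, η ≡ 0 without
baseline).  Ideal points κA + η may be non-integer; no rounding is applied
inside the utility — the absolute-value distance handles it.  Choice
probabilities are a softmax with inverse temperature λ ≥ 0, computed with
max-subtraction stabilisation so large λ·U cannot overflow; λ = 0 yields
the uniform distribution over the 11 options.

**Deterministic limit.** λ = ∞ is accepted by the generator and the choice
rule and is implemented as the mathematical limit of the softmax: the
uniform distribution over the argmax set.  In particular an ideal point
exactly halfway between two options (e.g. κ = 2, η = 1 at H/W = 0.25, ideal
point 1.5) splits 50/50.  This matters for identifiability: the 50/50
mixture at a boundary cell pins the ideal point exactly, whereas a fixed
tie-break convention would place the generating parameters on the edge of
the decision-consistent set and bias any refit.  Even so, deterministic
decisions identify (κ, η) only up to the polytope of parameters consistent
with the observed roundings, so noise-free refits carry an irreducible
dispersion of a few hundredths to ~0.1 in each parameter, and noise-free
recovery correlations are ≈ 0.995 rather than exactly 1.

## Fitting

Per-participant maximum likelihood.  Bounds: κ ∈ [0, 10] (diffusion) or
[0, 2.5] (amplification, since A ≤ 16), η ∈ [0, 10], θ ∈ [0, 1],
λ ∈ [0, 20].  Initialisation is a coarse lattice — 5 evenly spaced points
per free parameter, with the λ axis log-spaced over [0.1, 20] plus 0 —
evaluated in one vectorised pass; the best lattice point seeds a bounded
L-BFGS-B search (objective tolerance 1e−6) followed by a Nelder–Mead
polish, because the absolute-value kinks occasionally stall the
quasi-Newton step short of the optimum.  The best of {grid point, L-BFGS-B,
polish} is returned, so the fitted log-likelihood is never below the grid
optimum; if neither local search improves on the grid the fit is flagged
unconverged.  Participants whose decisions are all zero are excluded from
modelling (κ and η are unidentifiable there) and reported on the results
object.

Model comparison sums BIC = k·ln(n_trials) − 2·logL across participants
(fixed-effects comparison; a random-effects model-selection scheme is out
of scope).  Ties within 1e−9 go to the model with fewer free parameters.

## Validation battery

* **Predictive accuracy**: simulate each participant's decisions from their
  fitted parameters (default 50 sets), score the fraction of
  (trial × set) draws matching the observed decision, summarise with a
  t-interval across participants and a one-sample t test against the
  analytic chance level 1/11 ≈ 9%.
* **Parameter recovery**: simulate from a table of generating parameters,
  refit, and correlate generating against recovered values across
  participants — one Pearson r per simulation set, summarised as the mean
  over sets with a 95% percentile interval.  With synthetic cohorts the
  generating values are the *true* parameters, a stricter and
  self-contained version of the fitted-vs-refitted design used with real
  data.  Per-set seeds are spawned from the master seed.
* **Parameter independence**: Pearson r (two-sided p) between fitted κ and
  η; requires ≥3 participants and non-constant vectors.

## Synthetic-data generator

The generator defines the study conditions every analysis is tested under.

* **Utility-model cohorts**: κ ~ U(0.5, 4) and η ~ U(0, 3) keep ideal
  points κ·H/W + η inside the 0–10 token range for most cells; λ is fixed
  at 2.0 (clearly stochastic but far from uniform); θ ~ U(0, 0.5) when the
  generating model includes greed.  Amplification cohorts use
  κ ~ U(0.1, 0.6) because A = H·R reaches 16.  No population distributions
  for these parameters are reported anywhere; these are the package's
  choices and are flagged in the config.
* **Emotion ratings** are generated once per (H, R) cell, as in the
  post-game survey, and broadcast to the 4 trials of a cell when merged
  onto decisions: rating = intercept + slope_H·H + slope_R·R + N(0, σ),
  rounded half away from zero and clipped to the 0–10 scale.  Fixed slopes
  default to the study's point estimates (guilt: 0.74 on harm, 0.57 on
  responsibility; shame: 0.23 and 0.93; so the guilt-minus-shame
  interaction is 0.51 on harm and −0.36 on responsibility).  The
  between-participant slope SD defaults to 0.5, derived from the study's
  group statistics: a fixed slope of 0.74 with T ≈ 8.9 at n = 42 implies a
  group SE near 0.083, hence SE·√42 ≈ 0.5 of between-participant spread.
  Residual SD defaults to 1.0 rating unit.  A `discretize` flag disables
  Likert rounding; the exact algebraic limits (e.g. interaction exactly
  0.51) hold only for continuous ratings, because rounding perturbs slopes
  by a few hundredths.
* **Emotion-mediated decisions** (for the sensitivity analyses):
  D = round(2.0 + w_g·guilt + w_s·shame + N(0, 1)) clipped to 0–10, with
  mean weights 0.22 and 0.10 (the study's compensation coefficients) and
  participant-level weight SDs 0.10 and 0.05, giving true between-person
  variation in emotion-to-behavior coupling.
* **Manipulation checks**: pain means (2.0, 3.5, 5.5, 7.5) on the 0–10
  scale across harm levels and responsibility means (3.0, 4.5, 6.0, 7.5) on
  the 1–9 scale across responsibility levels, plus a correct-estimate
  condition with mean 1.5 (below level 1 by construction); shared
  participant shift SD 0.5 and rating noise SD 1.0.
* **Traits** are independent Gaussians (mean 4, SD 1) unless explicitly
  coupled to a behavioral summary.

What the generator does *not* emulate: sequential/order effects, learning
across trials, missing responses, emotion dynamics within a session, or any
dependence of emotion ratings on the participant's own decisions.  Passing
tests therefore demonstrate that the pipeline recovers what this generative
structure encodes, not that human data satisfy that structure.

## Behavioral statistics

Mixed models are statsmodels MixedLM fitted by ML (not REML, so BICs are
comparable across fixed-effect structures), with participant random
intercepts and random slopes for each fixed effect.  If the full correlated
random structure fails to converge the fit falls back to independent
(diagonal) random slopes, then to a random intercept only; data with
essentially zero residual variance (noise-free limits) go straight to OLS.
The fallback used is recorded on every result.  Fixed-effect tests use the
normal approximation; no Satterthwaite-style denominator degrees of freedom
are available in this stack, so printed dfs from other implementations are
not expected to reproduce and small-sample CIs can undercover slightly
(measured ≈90% at 15 participants, nominal at ≈30 under a correctly
specified generator; under strong slope heterogeneity the single-predictor
emotion model is deliberately misspecified — the omitted factor acts as
clustered noise — and coverage drops to ≈85–90%).

Emotion type is coded guilt = 1, shame = 0, so the predictor-by-type
interaction equals the guilt slope minus the shame slope, and simple slopes
per emotion are linear contrasts of the same fit.  The compensation family
(I guilt; II shame; III guilt + shame; IV + interaction) shares outcome and
random structure and differs only in fixed effects; BIC counts fixed
effects plus covariance parameters plus the residual variance.  The
guilt-vs-shame comparison is a 1-df Wald chi-square on the coefficient
contrast in the model containing both (degenerate identical columns give
chi-square 0 by exchangeability).

Per-participant sensitivities are fixed effect + predicted random deviation
(BLUP) when the full random structure was fitted; otherwise per-participant
OLS over the complete fixed design is substituted and flagged.  Under the
default generator these estimates correlate ≈0.8–0.9 with the true
participant slopes; the ceiling is the per-participant information (16
cells at residual SD 1 give a slope SE near 0.22).

Pairwise repeated-measures ANOVAs are computed from the paired-differences
formulation, where the two-level F equals the squared paired t (the
algebraic identity is itself a test oracle).  The dependent-correlation
test is Pearson–Filon's Z for two overlapping correlations; its type-I
error calibrates to ≈5–6% at n = 50.  Bootstrap mediation draws
observations with replacement (default 5000 resamples; the calibration
test uses 1000), recomputes the a (M~X) and b (Y~X+M) paths per resample,
and calls the indirect effect a·b significant when the 95% percentile
interval excludes zero; when M and X are exactly collinear the shared path
is attributed to the mediator, so the indirect effect equals the total
effect.  Percentile coverage for a·b measures ≈94% at n = 100 — the usual
slight anticonservatism of the percentile method at small n.

## Pipeline and reproducibility

`run_pipeline` executes simulate → fit → compare → validate → stats,
stamping every bundle with a SHA-256 config hash and the master seed; all
randomness flows from numpy `SeedSequence` spawns of that seed, so exact
stages are bit-reproducible and stochastic ones are statistically
equivalent across reruns.  Cohorts too small for a statistic (e.g. fewer
than 3 participants for correlations) produce warnings rather than
failures.  A column-mapping shim in `load_trials` renames foreign CSV
columns onto the TrialRecord schema so external deposits can be ingested
without code changes.

## Problem sizes

The shipped tests and the acceptance script run cohorts of up to 40
participants, 50 simulation sets for recovery, 10 replicate cohorts for
model recovery, and 500–1000 replicates for the calibration checks; these
sizes give Monte-Carlo error well inside the asserted margins while keeping
a full run in the minutes range on a single core.

## Known limitations

* BIC aggregation across participants is fixed-effects; group-level
  Bayesian model selection is not implemented.
* MixedLM p-values are normal-approximation; no Satterthwaite dfs.
* Deterministic-limit refits are identified only up to the
  decision-consistent polytope (see above), so "exact" recovery claims in
  that corner hold to ~0.05–0.1, not to optimizer tolerance.
* The recovery correlation for η under the default cohort tops out near
  0.98: with η ~ U(0, 3) the true spread (SD ≈ 0.87) is only ~4–5 times the
  intrinsic MLE error (SD ≈ 0.19 at λ = 2 with 64 trials).  Wider η spreads
  yield higher correlations.
* Trait scoring, fMRI modelling, and the deception protocol of the original
  paradigm are out of scope; trait scores are consumed as numbers.
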