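# moralcomp

Computational modelling of guilt- and shame-driven compensation in a
harm × responsibility interpersonal game.

## The problem

After a moral transgression, how much do people pay to repair the harm they
caused — and how do they weigh *how bad* the harm was against *how
responsible* they were for it?  In the game this package models, a
participant is one of four "deciders".  When deciders err, a receiver gets a
painful electric shock whose intensity is the harm level H (1–4); the number
of deciders who erred is the wrongdoer count W (1–4), so the participant's
responsibility level is R = 5 − W.  After each outcome the participant
splits a 10-token endowment (1 token = 0.5 yuan) between themselves and the
receiver; the compensation decision D is an integer 0–10.  The design
crosses 4 harm × 4 responsibility levels with 4 repeats (64 experimental
trials, plus 48 fillers, in 4 sessions).  A post-game survey collects guilt
and shame ratings (0–10) for each of the 16 cells.

`moralcomp` is for researchers who want to fit, compare and validate the
utility models of this paradigm, and to run its behavioral statistics, on
their own or simulated data.  It has no real-data dependency: a first-class
synthetic-data module generates complete study datasets (decisions, emotion
ratings, manipulation checks, trait scores) with the structure the analyses
assume.

## The model

Eight candidate utilities for giving D tokens, in two families that differ
in how harm and responsibility combine into attributed harm A:

* **responsibility diffusion** (family 1): A = H / W — harm is mentally
  divided among the wrongdoers;
* **amplification** (family 2): A = H · R — responsibility multiplies harm.

Within a family the variants toggle a greed term and a compensatory
baseline; the full model is

    U(D) = θ·(10 − D) − (1 − θ)·|κ·A + η − D|

with compensatory sensitivity κ, baseline η, and greed θ ∈ [0, 1]; reduced
variants drop θ and/or η.  κ·A + η is the compensation the participant
believes the receiver deserves, and the absolute value penalises both under-
and over-compensation.  Choices follow a softmax over the 11 options with
inverse temperature λ:

    P(D) = exp(λ·U(D)) / Σⱼ exp(λ·U(Dⱼ))

Each participant is fitted by maximum likelihood (coarse-grid start, bounded
quasi-Newton search with a simplex polish); models are compared by summed
BIC across participants.  The winner is validated by simulation (predictive
accuracy against the 9% = 1/11 chance level), parameter recovery
(generating-vs-recovered Pearson correlations over 50 simulation sets), and
the κ–η intercorrelation.  A mixed-effects stats layer estimates how harm
and responsibility drive guilt and shame, how guilt and shame drive
compensation (regression models I–IV with BIC selection and a Wald
coefficient comparison), per-participant sensitivities, trait correlations,
Pearson–Filon tests for dependent correlations, and percentile-bootstrap
mediation.

## Worked example

```python
import moralcomp as mc

ds = mc.generate_dataset(n_participants=40, seed=7)   # synthetic cohort, Model 1.3
table = mc.compare_models(ds.trials)                  # fit all eight variants
print(table.summary())

res = table.results[table.winner]                     # CompensationChoiceResults
print(res.summary())

rep = mc.validate_winning_model(res, ds.trials, n_sets=50, seed=7)
```

Output:

```
Model comparison (summed BIC across participants)
==================================================
winner: 1.3
--------------------------------------------------
model     k   summed BIC     delta BIC
1.1       4      5690.07       195.65
1.2       3      7830.87      2336.46
1.3       3      5494.42         0.00
1.4       2      7660.73      2166.31
2.1       4      6943.81      1449.39
2.2       3      8494.43      3000.01
2.3       3      6810.91      1316.49
2.4       2      8331.73      2837.31

Compensation choice model results
==============================================
model id:          1.3 (diffusion)
free parameters:   kappa, eta, lam (k=3)
participants:      40
total log-lik:     -2497.68
summed BIC:        5494.42
----------------------------------------------
parameter    mean      sd       min      max
kappa        1.900    1.005    0.620    3.749
eta          1.486    0.878    0.130    2.916
lam          2.043    0.225    1.629    2.560
```

The cohort was generated from Model 1.3 (diffusion, no greed, with
baseline), and the comparison attributes it to 1.3 by a wide BIC margin — a
model-recovery check in one screen.  The validation report for this run
gives predictive accuracy 0.49 (95% CI [0.47, 0.50]) against the 9% chance
level, recovery correlations r_κ = 0.99 and r_η = 0.99 between generating
and recovered parameters, and no κ–η correlation (r = −0.10, p = 0.52):
the two parameters capture separable aspects of behavior.

The emotion-side statistics run the same way:

```python
harm = mc.emotion_regression(ds.emotions, "harm")            # rating ~ harm * type
comp = mc.compensation_regression(mc.merge_emotions(ds.trials, ds.emotions))
sens = mc.extract_sensitivities(harm,
                                mc.emotion_regression(ds.emotions, "responsibility"),
                                comp)                        # per-participant slopes
```

A `moralcomp` command-line tool wraps the stages
(`simulate` / `fit` / `compare` / `validate` / `stats` / `run`); `moralcomp
run -n 40 --seed 7 --outdir out/` executes the whole pipeline and writes a
reproducible artifact bundle stamped with the config hash and seed.

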