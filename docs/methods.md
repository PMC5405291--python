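# Methods

`sleepcare` implements an automated coaching engine for cognitive
behavioral therapy for insomnia (CBT-I) centred on a *negotiable* variant
of sleep restriction, together with the statistical machinery used to
evaluate such a program in a two-arm waitlist-controlled trial, and a
synthetic-sleeper simulator so that every component is testable without
participant data. This note records the models, the defaults and the
design choices that were genuinely open.

## Diary metrics

One diary record describes one night with raw clock times (stored as
integer minutes-of-day, 0–1439) and wakefulness latencies in minutes. The
derived metrics are definitional:

* TIB = arising time − bed time, adding 24 h when the interval crosses
  midnight (arising at or before bed time). Equal clock times are
  rejected: a zero-length night cannot be distinguished from a 24-hour
  one. Terminal wakefulness (TWAK) is derived from the final-awakening
  and arising times with the same rule rather than asked directly.
* TST = TIB − SOL − WASO − TWAK; entries where wakefulness exceeds time in
  bed are impossible nights and fail validation.
* SE = 100·TST/TIB (percent).

Weekly summaries are unweighted means over the entries present in a
trailing calendar window; missing nights are skipped, never imputed, and
`n_entries` is carried so eligibility rules can count diaries. The weekly
sleep efficiency is the mean of the *nightly* efficiencies, which is the
natural reading of a coach that shows weekly SE averages; total-TST over
total-TIB weighting is exposed as `se_mode="aggregate"` for callers who
want the aggregate ratio.

Sleep quality is stored on the raw 1–10 diary scale. Published cohort
tables print quality near 3 on an apparently compressed scale whose
transformation is not stated; no rescaling is guessed, so any mapping is
the caller's job.

## The restriction algorithm

Eligibility after the baseline week requires at least 6 filled diaries and
mean SE strictly below 85%. The prescription window is

* ideal TIB = mean TST of the basis week, floored at 300 min (the 5-hour
  safety floor);
* maximum TIB = mean TIB − 60 min, clamped up to the ideal when the window
  would collapse.

The published rule list for this algorithm is internally inconsistent: one
rule sets the ideal equal to the average TIB while the others force the
advised window at least an hour below it and between average TST and
average TIB. The only reading that makes all rules and the negotiation
range jointly satisfiable — and that matches the classical
sleep-restriction prescription of "time in bed ≈ measured sleep time" —
is ideal = mean TST, and that is what is implemented. All TIB values are
whole minutes, rounded half-up.

Negotiation is upward only: accept takes the ideal, any request in
(ideal, max] is granted, a request above the maximum is answered with a
counter-offer at the maximum (not an error), and a request below the ideal
is refused. Opting out declines the exercise entirely.

Weekly titration: SE > 85% earns +15 min; SE < 85% tightens by 15 min
*only if the participant adhered* to the current prescription (deviation
below 60 min — restricting further is only meaningful when the current
window was actually kept); otherwise the window holds. SE exactly 85%
changes nothing, because both printed conditions are strict inequalities.
Extensions may carry the window above the original maximum: restriction is
being relaxed deliberately, and the history records every step.

Safety: when the trailing 5 *reported* nights (missing diaries don't
count) average under 300 min of sleep, a sleepiness warning fires;
escalation to the GP-referral warning and automatic stop requires a second
full window of 5 fresh nights after the first warning. The cadence of the
follow-up warning is not specified anywhere; the fresh-window rule is the
minimal deterministic reading.

## The program engine

The engine is a pure fold over a dated event stream: no wall-clock reads,
so a given stream reproduces the same final state and event log bit for
bit, and a state serialized to JSON mid-stream resumes identically. The
protocol is: baseline diary week; restriction introduction after day 7
once 6 diaries exist (postponed day by day otherwise, extending the
program by up to 7 days beyond its 42-day base); weekly evaluation
conversations during restriction whose structured outcomes drive the
titration; a relaxation-adherence conversation exactly once, 4 days after
the relaxation exercise is introduced, if it was done fewer than 3 times.
Conversations are typed stubs (id, trigger, structured-outcome slots);
dialogue text is out of scope. Only one conversation may be open at a
time, and unfinished conversations get exactly one reminder per day at
noon.

## Adherence

Four components are scored: diaries filled, relaxation exercises,
percentage of scheduled conversations finished, and the mean absolute
nightly deviation |actual TIB − agreed TIB| over nights with an active
agreement (absent — not zero — if restriction was never agreed).
Deviation averages over nights; per-direction overstay/understay means are
also reported because the simulator is calibrated against them. The
adequate-dose thresholds are strict exactly as printed: >35 diaries, >35
relaxations, >90% conversations, <60 min deviation.

## The simulator

The sleeper model is statistical, not mechanistic. A night is: habitual
bed/arising clock times with Gaussian jitter (SD 30 min each, giving a
nightly TIB SD of ~42 min around the 506-min default); SOL/WASO/TWAK drawn
from zero-truncated normals whose *location is solved so the realized mean
equals the configured parameter* (33/45/35 min, SDs 20/32/22) — without
that correction the truncation would inflate the means by 1–2 min each and
drag mean SE about 2 points under the configured baseline. The implied
baseline SE is ≈77.5–77.6%; `expected_baseline_se()` gives the
delta-method expectation (the ratio of independent TIB and wake draws
carries a small Jensen term) so Monte-Carlo tests can assert a sharp
3-standard-error agreement instead of a loose band.

Under a prescription the intended TIB is the agreed window distorted by an
overstay draw (probability 0.84, mean 67, SD 45 min) or an understay draw
(mean 42, SD 29 min), and the wakefulness components shrink by
`responsiveness` per restriction week, so SE drifts upward — the
behaviour the titration loop assumes. Diary compliance defaults to 0.59
and relaxation to 1.5 exercises/week, the observed component-completion
levels of the reference cohort; runs that need denser diaries (e.g. to
guarantee eligibility) override the compliance explicitly.

Trial outcomes come from a random-intercept Gaussian model
`y_it = μ + b_t·t + b_int·t·cond + u_i + e_it` with `Var(u) = ρ·sd²`,
`Var(e) = (1−ρ)·sd²` and ρ = 0.5 by default. The between-group effect is
specified as a standardized change-score d and converted by
`b_int = d·√2·σ_e`, which makes the change-score Cohen-d estimator
unbiased for the configured value (the random intercept cancels in the
change score, whose SD is √2·σ_e per arm). Baseline means/SDs default to
the reference cohort's pooled baseline; the headline truths are d = −0.66
for insomnia severity and +0.71 for sleep efficiency. Outcome draws are
*not* clipped to their questionnaire ranges: clipping would bias the
tails and the recovered effects, and boundary violations are rare at these
parameters (the classification step clips only there, where a discrete
rule needs in-range scores). Posttest missingness is MAR through a
logistic model in the covariates associated with dropout (age, baseline
sleep quality and terminal wakefulness in the app arm; number of
awakenings in the waitlist arm), so covariate adjustment has something
real to absorb. One root seed fans out to per-participant substreams;
adding a participant never perturbs the others.

What the simulator does *not* emulate: circadian structure, night-to-night
autocorrelation, floor/ceiling effects of the questionnaires,
heteroscedastic post-treatment variances, and informative (MNAR) dropout.
Passing tests therefore demonstrate the correctness of the algorithms and
the calibration of the estimators under the stated generative model, not
performance on real sleepers.

## Statistics

**Random-intercept models.** Two-level linear models are estimated by full
maximum likelihood (not REML), because the model ladder is compared by
likelihood-ratio chi-square across *fixed*-effect specifications and REML
likelihoods are not comparable there. The likelihood is profiled over the
variance ratio θ = σ_u²/σ_e²: for fixed θ, the per-group covariance
I + θJ has an analytic inverse (Woodbury) and determinant, so GLS
coefficients and the residual variance are closed-form and only a
one-dimensional bounded search over θ remains (tolerance ~1e-12, zero
boundary checked explicitly). Participants with a single observation are
retained, which is what makes intention-to-treat analysis possible.
The fitter agrees with an independent mixed-model implementation to
~1e-13 in coefficients on test problems.

**Model ladder.** Per outcome: model 0 (intercept + covariates), 1 (+time),
2 (+condition), 3 (+time×condition) on pre/post; models 4 (null) and 5
(+time) on the app arm's pre/follow-up (no condition term — the waitlist
has no follow-up, and rows there are a design violation that raises).
Comparisons 0v1, 1v2, 2v3, 0v3, 4v5 report χ² = 2Δll, df = parameter
difference, and a level-1 R²: the proportional reduction in level-1
residual variance versus the compared null. Negative R² values are
reported as computed, not truncated.

**Effect sizes.** Between-group d = (mean change WL − mean change app) /
pooled SD of the change scores, change = pre − post; within-group
d = (mean pre − mean post)/SD pooled over pre and post. The 95% CI uses
the standard large-sample SE of a standardized mean difference. Time is
coded 0/1 (pre/post) and condition 0/1 (waitlist/app), so interaction
coefficients and d values share sign conventions: on lower-is-better
scales an app advantage is negative, on sleep efficiency positive.

**Classification.** Clinically meaningful change is a drop of ≥8 ISI
points; remission is a posttest ISI ≤7. Group comparisons of these
proportions use the Pearson chi-square *without* continuity correction —
the uncorrected statistic reproduces the reference values exactly on the
printed counts, which fixes the dialect.

**Imputation.** Predictive mean matching with k = 5 donors: per target
variable, a linear model on the other variables predicts means; each
missing cell takes the observed value of one of the k nearest-predicted
complete rows, drawn at random. Coefficients get a posterior-style normal
perturbation per completion so the m completions differ; m = 10 by
default, chained over variables for 3 passes, sub-seeded from one root
seed. Only k and the matching metric were open choices and both are
configurable. Pooling across completions uses Rubin's rules.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks use 10⁴ nights for simulator calibration (3·SEM
acceptance, plus ±0.5 min for whole-minute rounding of TWAK), 10⁵ nights
for the validity property, 2000 replicates of a 100-participant balanced
null trial for the type-I-error calibration of the interaction test
(binomial 3σ band around .05), and 200 replicates at 500 participants per
arm for end-to-end recovery of the configured effect sizes within ±0.05.
These sizes make the full suite run in well under a minute apart from the
calibration tests.

## Known limitations

* The restriction formulas are an interpretation of an inconsistent
  published rule list whose authoritative version is unpublished; the
  implementation flags them as such.
* The exact per-week activity grid of the original program beyond the
  textual rules (introduction, postponement, weekly evaluation, reminders)
  is not reproduced; scheduling beyond those rules is deliberately
  minimal.
* The trial simulator's homoscedastic Gaussian outcome model cannot
  reproduce cohort-specific features like the larger posttest variance of
  treated arms.
* PMM is single-model chained imputation; it does not implement the full
  Bayesian bootstrap variants found in dedicated imputation packages.
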