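# sleepcare

An automated coaching engine for cognitive behavioral therapy for insomnia
(CBT-I), built around a *negotiable* sleep-restriction algorithm, plus the
statistical pipeline used to evaluate such a program in a two-arm
waitlist-controlled trial and a synthetic-sleeper simulator that makes the
whole system testable with no participant data.

It is written for two audiences: developers of digital sleep-coaching
tools who need a tested, deterministic protocol engine (diary metrics,
titration, safety monitoring, adherence scoring), and methodologists who
need the matching analysis stack (random-intercept multilevel models,
likelihood-ratio model comparison, change-score effect sizes, predictive
mean matching, clinical-change classification).

## The core algorithms

**Diary metrics.** From a consensus sleep diary night: time in bed
TIB = arising − bed time (cross-midnight aware), total sleep time
TST = TIB − SOL − WASO − TWAK, and sleep efficiency SE = 100·TST/TIB.

**Sleep restriction with negotiation.** After a baseline week with ≥6
diaries and mean SE < 85%, the coach proposes

```
ideal TIB   = max(mean TST, 300 min)          # never below 5 hours
maximum TIB = max(mean TIB − 60 min, ideal)
```

The participant may accept the ideal, negotiate upward to at most the
maximum (higher requests get a counter-offer at the maximum), or decline.
Weekly titration moves the agreed window by ±15 min: up when SE > 85%,
down when SE < 85% *and* the participant adhered, unchanged otherwise. A
safety monitor warns after 5 reported nights averaging under 5 h of sleep
and stops the exercise after a second fresh short-sleep window.

**Trial statistics.** Outcomes are analysed with two-level
random-intercept models fitted by full maximum likelihood (profile
likelihood over the variance ratio, closed-form GLS at each step):
model 0 (intercept) → 1 (+time) → 2 (+condition) → 3 (+time×condition),
compared by likelihood-ratio χ² with a level-1 R² (proportional reduction
of residual variance). Between-group Cohen
d = (Δ̄_waitlist − Δ̄_app)/SD_pooled on change scores Δ = pre − post;
meaningful change is ΔISI ≥ 8, remission ISI ≤ 7, compared by Pearson χ²
without continuity correction; missing data handled by predictive mean
matching (m = 10, k = 5 donors) with Rubin pooling.

## Worked example

```python
from sleepcare import restriction as rc
from sleepcare.diary import WeeklySummary

week = WeeklySummary(n_entries=7, mean_tib=506.0, mean_tst=393.0, mean_se=77.7)
print(rc.check_eligibility(week).eligible)
proposal = rc.compute_proposal(week)
print(proposal.ideal_tib, proposal.max_tib)
result = rc.negotiate(proposal, 460)
print(result.accepted, result.counter_offer)
```

prints

```
True
393 446
False 446
```

— a sleeper averaging 506 min in bed but only 393 min asleep (SE 77.7%)
is eligible; the coach proposes 393 min in bed (their measured sleep
time) and will bargain up to 446 (an hour less than their habitual time
in bed); a request for 460 min is countered with the 446-min maximum.

The `examples/` directory has one short narrative script per capability
(diary metrics, the restriction coach, the full program engine, trial
simulation, trial analysis). `examples/05_trial_analysis.py` simulates a
400-participant trial with a configured insomnia-severity effect of
d = −0.66 and prints the fitted model-3 interaction
(B = −1.98, SE 0.32, p = 3.4e-10), the likelihood-ratio test
(χ²₁ = 37.60) and the recovered between-group d = −0.63.

A thin CLI mirrors the library for shell use:

```
sleepcare coach --state state.json --init --date 2015-09-07
sleepcare coach --state state.json --diary today.csv
sleepcare report --state state.json
sleepcare simulate --weeks 7 --seed 13 --out diary.csv
sleepcare simulate-trial --n-app 74 --n-wl 77 --out trial.csv
sleepcare analyze --trial trial.csv
```

## Layout

```
src/sleepcare/
  diary.py        consensus-diary records, nightly metrics, CSV/JSON I/O
  restriction.py  eligibility, proposal, negotiation, titration, safety
  engine.py       protocol state machine: scheduling, conversations, reminders
  adherence.py    adherence components and adequate-dose flags
  sim.py          synthetic sleepers and synthetic two-arm trials
  stats/          LMM fitter, model comparison, effect sizes, PMM, χ² tests,
                  full analysis pipeline
  cli.py          thin command-line front end
docs/methods.md   models, defaults, design decisions, limitations
examples/         one narrative script per capability
```
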