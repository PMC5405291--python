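"""Drive a synthetic participant through the full coaching program.

A simulated sleeper fills diaries, does relaxation exercises and answers
the coach's conversations; the engine schedules the protocol (baseline
week, restriction introduction, weekly evaluations) deterministically from
the seed.  Afterwards the adherence report scores the run against the
adequate-dose thresholds.
"""

from collections import Counter

from sleepcare import adherence, sim

profile = sim.SleeperProfile(diary_compliance=0.9, responsiveness=0.2)
state, events = sim.run_participant(profile, seed=13)

print(f"program finished after {state.day_index} days; "
      f"restriction status: {state.restriction.status.value}, "
      f"final agreed TIB: {state.restriction.agreed_tib} min")

print("event counts:")
for code, n in sorted(Counter(e["event_code"] for e in events).items()):
    print(f"  {code:35s} {n}")

report = adherence.report_from_state(state)
print(f"diaries {report.n_diaries}, relaxations {report.n_relaxations}, "
      f"conversations {report.conversation_completion:.0f}% finished")
print(f"adequate-dose flags: {report.adequate}")

# The titration history shows the coach's weekly decisions: extend after a
# week above 85% efficiency, restrict after an adherent week below it.
for rec in state.restriction.titration_history:
    print(f"  week {rec.week}: SE {rec.se:.1f}% -> {rec.decision} "
          f"(TIB {rec.new_tib})")
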