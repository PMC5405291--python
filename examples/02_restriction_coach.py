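"""The negotiable sleep-restriction algorithm, step by step.

Shows eligibility checking, the ideal/maximum time-in-bed proposal, an
upward negotiation, weekly titration against achieved sleep efficiency, and
the short-sleep safety monitor.
"""

from sleepcare import restriction as rc
from sleepcare.diary import WeeklySummary

# Baseline week: 506 min in bed but only 393 min asleep (SE 77.7%).
week = WeeklySummary(n_entries=7, mean_tib=506.0, mean_tst=393.0, mean_se=77.7)

verdict = rc.check_eligibility(week)
print(f"eligible: {verdict.eligible} ({verdict.reason})")

proposal = rc.compute_proposal(week)
print(f"proposal: ideal TIB {proposal.ideal_tib} min, "
      f"maximum {proposal.max_tib} min")

# The participant wants more than the coach's maximum -> counter-offer.
result = rc.negotiate(proposal, 460)
print(f"request 460 -> accepted={result.accepted}, "
      f"counter-offer {result.counter_offer} min")

# They settle on the counter-offer.
result = rc.negotiate(proposal, result.counter_offer)
state = result.state
print(f"agreed time in bed: {state.agreed_tib} min")

# Weekly titration: a good week (+15), then a poor but adherent week (−15).
state = rc.weekly_titration(state, weekly_se=88.0, adherent=True)
print(f"after SE 88%: {state.agreed_tib} min "
      f"({state.titration_history[-1].decision})")
state = rc.weekly_titration(state, weekly_se=80.0, adherent=True)
print(f"after SE 80%, adherent: {state.agreed_tib} min "
      f"({state.titration_history[-1].decision})")

# The agreed window moves in 15-minute steps and can never drop below the
# 5-hour floor (300 min); sleeping under 5 h on average for 5 reported
# nights would trigger the safety warnings instead.
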