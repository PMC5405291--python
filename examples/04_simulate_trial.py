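"""Generate a synthetic two-arm waitlist-controlled trial.

Participants get pre/post questionnaire and diary-aggregate scores from a
random-intercept Gaussian model whose between-group effects are configured
as standardized change-score d values; the app arm also gets a follow-up.
Posttest missingness is MAR in the covariates associated with dropout.
"""

from sleepcare import sim
from sleepcare.stats import cohen_d_between

trial = sim.simulate_trial(
    n_app=74, n_wl=77, seed=13,
    missingness={"post_app": 1 - 45 / 74, "post_wl": 1 - 62 / 77,
                 "followup": 1 - 29 / 74},
)

print(f"{len(trial.data)} long-format rows, "
      f"{trial.covariates.shape[0]} participants")
post = trial.data[trial.data["time"] == "post"]
print(f"posttest missingness: {post['value'].isna().mean():.0%}")

# Estimate the between-group effect on insomnia severity from the
# complete pre/post pairs (change = pre − post; negative d favours the app
# on a lower-is-better scale).
w = trial.wide("ISI").dropna(subset=["pre", "post"])
change = w["pre"] - w["post"]
d = cohen_d_between(change[w["condition"] == "waitlist"].to_numpy(),
                    change[w["condition"] == "app"].to_numpy())
lo, hi = d.ci95
print(f"ISI between-group d: {d.d:.2f} (95% CI {lo:.2f} to {hi:.2f}); "
      f"configured truth {trial.truth['ISI']['d_between']}")
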