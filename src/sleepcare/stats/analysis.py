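"""End-to-end trial analysis: multilevel models, effect sizes, classification.

For every outcome, a ladder of random-intercept models is fitted to the
pre/post observations by maximum likelihood:

* model 0 — intercept (+ covariates) only;
* model 1 — adds time;
* model 2 — adds condition;
* model 3 — adds the time x condition interaction;

and, on the app arm's pre/follow-up observations,

* model 4 — intercept (+ covariates) only;
* model 5 — adds time  (no condition term: the waitlist has no follow-up).

Adjacent models are compared by likelihood-ratio chi-square with a level-1
R²; the report mirrors a standard coefficients table (model 3: B, SE, p)
plus a model-comparison table for 0v1, 1v2, 2v3, 0v3 and 4v5.  The report
also carries change-score effect sizes per outcome and, when insomnia
severity is among the outcomes, the clinically-meaningful-change and
remission counts with their chi-square tests.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..sim import TrialDataset
from . import effects as eff
from .contingency import pearson_chi2
from .lmm import FitResult, ModelComparison, compare_models, fit_random_intercept

__all__ = ["run_analysis", "prepare_long"]

_TIME_CODE = {"pre": 0.0, "post": 1.0, "followup": 1.0}
_COND_CODE = {"waitlist": 0.0, "app": 1.0}


def prepare_long(
    trial: TrialDataset,
    outcome: str,
    times: Sequence[str] = ("pre", "post"),
    covariates: Sequence[str] = (),
    condition: Optional[str] = None,
) -> pd.DataFrame:
    """Numeric long-format frame for one outcome: time 0/1, condition 0/1."""
    sub = trial.data[
        (trial.data["outcome"] == outcome) & trial.data["time"].isin(list(times))
    ].copy()
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    sub["time"] = sub["time"].map(_TIME_CODE)
    sub["condition"] = sub["condition"].map(_COND_CODE)
    if covariates:
        sub = sub.merge(
            trial.covariates[["participant", *covariates]], on="participant",
            how="left",
        )
    return sub.dropna(subset=["value"])


def _comparison_dict(c: ModelComparison) -> dict:
    return {
        "chi_square": c.chi_square,
        "df": c.df,
        "p_value": c.p_value,
        "r2_level1": c.r2_level1,
    }


def run_analysis(
    trial: TrialDataset,
    outcomes: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = (),
    isi_outcome: str = "ISI",
) -> dict:
    """Run the full analysis pipeline on a long-format trial dataset.

    Waitlist rows at follow-up violate the design and raise.  Returns a
    nested dict: per-outcome model-3 coefficient tables, model comparisons
    (0v1, 1v2, 2v3, 0v3, 4v5), between/within effect sizes, and — if the
    insomnia-severity outcome is present — meaningful-change and remission
    counts with chi-square tests.
    """
    wl_fu = trial.data[
        (trial.data["condition"] == "waitlist")
        & (trial.data["time"] == "followup")
        & trial.data["value"].notna()
    ]
    if len(wl_fu):
        raise ValueError("design violation: waitlist rows present at follow-up")

    if outcomes is None:
        outcomes = list(trial.data["outcome"].unique())
    covs = list(covariates)

    report: dict = {"outcomes": {}, "covariates": covs}
    for outcome in outcomes:
        entry: dict = {}
        long = prepare_long(trial, outcome, ("pre", "post"), covs)
        specs = {
            0: covs,
            1: covs + ["time"],
            2: covs + ["time", "condition"],
            3: covs + ["time", "condition", "time:condition"],
        }
        fits: dict[int, FitResult] = {
            k: fit_random_intercept(long, "value", spec) for k, spec in specs.items()
        }
        entry["model3"] = {
            term: {
                "B": float(fits[3].params[term]),
                "SE": float(fits[3].bse[term]),
                "p": float(fits[3].pvalues()[term]),
            }
            for term in fits[3].terms
        }
        entry["comparisons"] = {
            "0v1": _comparison_dict(compare_models(fits[0], fits[1])),
            "1v2": _comparison_dict(compare_models(fits[1], fits[2])),
            "2v3": _comparison_dict(compare_models(fits[2], fits[3])),
            "0v3": _comparison_dict(compare_models(fits[0], fits[3])),
        }
        # models 4/5: app arm, pre vs follow-up
        fu = prepare_long(trial, outcome, ("pre", "followup"), covs, condition="app")
        if (fu["time"] == 1.0).any():
            fit4 = fit_random_intercept(fu, "value", covs)
            fit5 = fit_random_intercept(fu, "value", covs + ["time"])
            entry["comparisons"]["4v5"] = _comparison_dict(compare_models(fit4, fit5))

        wide = trial.wide(outcome)
        complete = wide.dropna(subset=["pre", "post"])
        change = complete["pre"] - complete["post"]
        wl = change[complete["condition"] == "waitlist"]
        app = change[complete["condition"] == "app"]
        if len(wl) >= 2 and len(app) >= 2:
            between = eff.cohen_d_between(wl.to_numpy(), app.to_numpy())
            entry["d_between"] = {"d": between.d, "ci95": between.ci95}
            entry["d_within"] = {}
            for arm, mask in (("waitlist", complete["condition"] == "waitlist"),
                              ("app", complete["condition"] == "app")):
                sub = complete[mask]
                w = eff.cohen_d_within(sub["pre"].to_numpy(), sub["post"].to_numpy())
                entry["d_within"][arm] = w.d
        report["outcomes"][outcome] = entry

    if isi_outcome in report["outcomes"]:
        wide = trial.wide(isi_outcome).dropna(subset=["pre", "post"])
        cls = wide.apply(
            lambda r: eff.classify_change(
                float(np.clip(r["pre"], 0, 28)), float(np.clip(r["post"], 0, 28))
            ),
            axis=1,
            result_type="expand",
        )
        wide = pd.concat([wide, cls], axis=1)
        counts = {}
        tables = {}
        for flag in ("meaningful_change", "remitted"):
            tab = []
            for arm in ("app", "waitlist"):
                sub = wide[wide["condition"] == arm]
                yes = int(sub[flag].sum())
                tab.append([yes, len(sub) - yes])
                counts[f"{flag}_{arm}"] = {"yes": yes, "n": len(sub)}
            chi, df, p = pearson_chi2(tab)
            tables[flag] = {"chi_square": chi, "df": df, "p_value": p}
        report["classification"] = {"counts": counts, "tests": tables}
    return report
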