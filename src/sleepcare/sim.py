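"""Synthetic sleepers and synthetic two-arm trials.

Everything downstream of real participants — diary streams for the coaching
engine and long-format outcome datasets for the analysis pipeline — can be
generated here with a fixed seed, so the whole system is testable without
any external data.

The night generator is statistical, not mechanistic: habitual bed and
arising times with Gaussian jitter, truncated-normal wakefulness components
(sleep-onset latency, wake after sleep onset, terminal wakefulness), and a
behavioural layer for prescription nights (overstay/understay deviations
from the agreed time in bed, weekly shrinkage of wakefulness under
restriction).  Defaults reproduce the baseline week of a mildly insomniac
cohort: mean time in bed ~506 min, SOL 33, WASO 45, TWAK 35, hence sleep
efficiency ~77-78%.

The trial generator draws pre/post(/follow-up) outcome scores from a
random-intercept Gaussian model: ``y_it = mu + b_time*t + b_int*t*cond +
u_i + e_it`` with ``Var(u)=rho*sd^2`` and ``Var(e)=(1-rho)*sd^2``.  The
between-group effect is configured as a standardized change-score d and
converted internally via ``b_int = d * sqrt(2) * sd_e``, so the change-score
Cohen d estimator recovers the configured value in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import engine as eng
from . import restriction as rc
from .diary import MINUTES_PER_DAY, DiaryEntry

__all__ = [
    "SleeperProfile",
    "OutcomeSpec",
    "TrialDataset",
    "DEFAULT_OUTCOMES",
    "simulate_night",
    "simulate_diary_week",
    "run_participant",
    "simulate_trial",
]


# ---------------------------------------------------------------------------
# sleeper profiles and nightly diaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SleeperProfile:
    """Generative parameters for one synthetic participant.

    Defaults describe the baseline condition of a mildly insomniac sleeper:
    about 8.4 h in bed with ~113 min of nightly wakefulness, i.e. sleep
    efficiency around 77-78%, diary compliance ~0.59 and ~1.5 relaxation
    exercises per week.  ``responsiveness`` is the fraction of the nightly
    wakefulness shed per week while the restriction prescription is active.
    """

    habitual_bed_time: int = 1380  # 23:00
    habitual_arising_time: int = 446  # 07:26 -> TIB 506 min
    bed_jitter_sd: float = 30.0
    arise_jitter_sd: float = 30.0
    baseline_sol: float = 33.0
    sol_sd: float = 20.0
    baseline_waso: float = 45.0
    waso_sd: float = 32.0
    baseline_twak: float = 35.0
    twak_sd: float = 22.0
    mean_awakenings: float = 1.94
    quality_mean: float = 5.5
    quality_sd: float = 1.5
    medication_prob: float = 0.05
    diary_compliance: float = 0.59
    relaxation_rate: float = 1.5  # exercises per week
    overstay_prob: float = 0.84
    overstay_mean: float = 67.0
    overstay_sd: float = 45.0
    understay_mean: float = 42.0
    understay_sd: float = 29.0
    responsiveness: float = 0.15
    dropout_hazard: float = 0.0  # per week

    def __post_init__(self) -> None:
        for name in ("medication_prob", "diary_compliance", "overstay_prob",
                     "responsiveness", "dropout_hazard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def expected_night_means(self, week: int = 0, restricted: bool = False) -> dict:
        """Expected wakefulness components and TIB for one night.

        Duration draws are truncated normals whose location is solved so the
        *realized* mean equals the configured parameter, so the expectations
        here are simply the (possibly responsiveness-shrunk) parameters.
        """
        f = (1.0 - self.responsiveness) ** week if restricted else 1.0
        return {
            "sol": self.baseline_sol * f,
            "waso": self.baseline_waso * f,
            "twak": self.baseline_twak * f,
            "tib": float(
                (self.habitual_arising_time - self.habitual_bed_time)
                % MINUTES_PER_DAY
            ),
        }

    def expected_baseline_se(self) -> float:
        """Second-order (delta-method) expectation of nightly sleep efficiency.

        E[100·(TIB−W)/TIB] with W the total wakefulness: the ratio of two
        independent draws picks up a small Jensen correction from the TIB
        jitter, E[1/TIB] ≈ (1/μ)(1 + σ²/μ²).
        """
        m = self.expected_night_means()
        mu_tib = m["tib"]
        var_tib = self.bed_jitter_sd**2 + self.arise_jitter_sd**2
        inv_tib = (1.0 / mu_tib) * (1.0 + var_tib / mu_tib**2)
        wake = m["sol"] + m["waso"] + m["twak"]
        return 100.0 * (1.0 - wake * inv_tib)


from functools import lru_cache

from scipy.special import ndtr, ndtri


@lru_cache(maxsize=512)
def _trunc_loc(target_mean: float, sd: float) -> tuple[float, float]:
    """Location of a zero-truncated normal whose *mean* is ``target_mean``.

    The truncation at zero pulls the mean upward; solving for the location
    keeps the realized mean of the draws equal to the configured parameter.
    Returns ``(mu, Phi(-mu/sd))`` — the location and the truncated tail mass.
    """
    from scipy.optimize import brentq

    def gap(mu: float) -> float:
        a = -mu / sd
        # E[X | X > 0] = mu + sd * phi(a) / (1 - Phi(a))
        tail = 1.0 - ndtr(a)
        return mu + sd * np.exp(-0.5 * a * a) / np.sqrt(2 * np.pi) / tail - target_mean

    lo = target_mean - 8 * sd
    hi = target_mean + sd
    mu = float(brentq(gap, lo, hi, xtol=1e-10))
    return mu, float(ndtr(-mu / sd))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One zero-truncated normal draw with realized mean ``mean`` (inverse CDF)."""
    if sd <= 0 or mean <= 0:
        return max(mean, 0.0)
    mu, phi_a = _trunc_loc(round(mean, 6), sd)
    u = phi_a + rng.random() * (1.0 - phi_a)
    return mu + sd * float(ndtri(u))


def simulate_night(
    profile: SleeperProfile,
    prescription: Optional[int],
    rng: np.random.Generator,
    *,
    date: _date = _date(2015, 9, 1),
    week: int = 0,
) -> DiaryEntry:
    """Draw one diary night.

    Without a prescription the night follows the habitual parameters.  With
    an agreed time in bed the intended window equals the prescription
    distorted by an overstay/understay draw, and the wakefulness components
    shrink by ``responsiveness`` per restriction week so nightly sleep
    efficiency drifts upward under restriction.
    """
    arise = int(round(profile.habitual_arising_time
                      + rng.normal(0.0, profile.arise_jitter_sd))) % MINUTES_PER_DAY
    if prescription is None:
        bed = int(round(profile.habitual_bed_time
                        + rng.normal(0.0, profile.bed_jitter_sd))) % MINUTES_PER_DAY
        f = 1.0
    else:
        if rng.random() < profile.overstay_prob:
            dev = _trunc_normal(rng, profile.overstay_mean, profile.overstay_sd)
        else:
            dev = -_trunc_normal(rng, profile.understay_mean, profile.understay_sd)
        tib_target = int(round(min(max(prescription + dev, 240), MINUTES_PER_DAY - 1)))
        bed = (arise - tib_target) % MINUTES_PER_DAY
        f = (1.0 - profile.responsiveness) ** week
    if bed == arise:
        bed = (bed - 1) % MINUTES_PER_DAY
    tib = (arise - bed) % MINUTES_PER_DAY

    sol = _trunc_normal(rng, profile.baseline_sol * f, profile.sol_sd)
    waso = _trunc_normal(rng, profile.baseline_waso * f, profile.waso_sd)
    twak = _trunc_normal(rng, profile.baseline_twak * f, profile.twak_sd)
    total_wake = sol + waso + twak
    if total_wake >= tib:  # rare: keep the night physically possible
        scale = 0.9 * tib / total_wake
        sol, waso, twak = sol * scale, waso * scale, twak * scale
    twak_int = min(int(round(twak)), max(tib - 1, 0))
    sol = round(sol, 1)
    waso = round(waso, 1)
    if sol + waso + twak_int > tib:  # rounding pushed past the bound
        waso = max(round(tib - twak_int - sol, 1), 0.0)
        if sol + waso + twak_int > tib:
            sol = max(round(tib - twak_int - waso, 1), 0.0)
    final_wake = (arise - twak_int) % MINUTES_PER_DAY
    quality = int(np.clip(round(rng.normal(profile.quality_mean, profile.quality_sd)),
                          1, 10))
    return DiaryEntry(
        date=date,
        bed_time=bed,
        try_sleep_time=(bed + 10) % MINUTES_PER_DAY,
        sol=float(sol),
        n_awakenings=int(rng.poisson(profile.mean_awakenings)),
        waso=float(waso),
        final_wake_time=final_wake,
        arising_time=arise,
        quality=quality,
        used_medication=bool(rng.random() < profile.medication_prob),
    )


def simulate_diary_week(
    profile: SleeperProfile,
    rng: np.random.Generator,
    *,
    start: _date = _date(2015, 9, 1),
    days: int = 7,
    prescription: Optional[int] = None,
    week: int = 0,
    compliance: Optional[float] = None,
) -> list[DiaryEntry]:
    """A (possibly incomplete) batch of consecutive diary nights."""
    p = profile.diary_compliance if compliance is None else compliance
    entries = []
    for d in range(days):
        filled = rng.random() < p
        night = simulate_night(
            profile, prescription, rng, date=start + timedelta(days=d), week=week
        )
        if filled:
            entries.append(night)
    return entries


def run_participant(
    profile: SleeperProfile,
    seed: int,
    *,
    weeks: int = 7,
    start: _date = _date(2015, 9, 7),
    finish_conversation_prob: float = 0.9,
    restriction_response: str = "accept",
) -> tuple[eng.ProgramState, list[dict]]:
    """Drive one synthetic participant through the full coaching program.

    Diaries are filled with the profile's compliance, relaxation exercises
    arrive at the profile's weekly rate, and queued conversations are
    finished the next day with probability ``finish_conversation_prob``
    (the restriction introduction is answered with
    ``restriction_response``).  Returns the final engine state and the full
    event log; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    state = eng.new_program(start)
    events: list[dict] = []
    relax_daily = profile.relaxation_rate / 7.0
    restriction_week = 0
    while state.status == "active":
        today = state.today
        todays_entries = []
        if rng.random() < profile.diary_compliance:
            prescription = state.restriction.agreed_tib
            night = simulate_night(
                profile, prescription, rng,
                date=today, week=restriction_week,
            )
            todays_entries.append(night)
        actions: list[dict] = []
        n_relax = rng.poisson(relax_daily)
        for _ in range(int(n_relax)):
            actions.append({"type": "relaxation",
                            "duration": int(rng.integers(1, 17))})
        for conv in state.unfinished_conversations():
            if rng.random() < finish_conversation_prob:
                if conv.kind == "restriction_introduction":
                    outcome = {"response": restriction_response}
                elif conv.kind == "weekly_evaluation":
                    outcome = {"adherent": True}
                else:
                    outcome = {}
                actions.append({"type": "finish_conversation", "id": conv.id,
                                "outcome": outcome})
            break  # one conversation at a time
        state, evs = eng.advance_day(state, todays_entries, actions)
        events.extend(evs)
        if state.restriction.status == rc.RestrictionStatus.AGREED:
            restriction_week = max(restriction_week, state.day_index // 7)
        if state.day_index >= weeks * 7:
            break
    return state, events


# ---------------------------------------------------------------------------
# two-arm trial datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative spec for one trial outcome.

    ``d_between`` is the standardized between-group change-score effect
    (waitlist change minus app change over the pooled change-score SD);
    ``time_effect`` is the raw waitlist pre-to-post shift; ``rho`` the
    pre-post correlation induced by the participant random intercept.
    """

    name: str
    baseline_mean: float
    baseline_sd: float
    d_between: float
    time_effect: float = 0.0
    rho: float = 0.5
    followup_extra: float = 0.0  # app-arm shift from post to follow-up

    @property
    def sigma_u(self) -> float:
        return self.baseline_sd * np.sqrt(self.rho)

    @property
    def sigma_e(self) -> float:
        return self.baseline_sd * np.sqrt(1.0 - self.rho)

    @property
    def interaction_raw(self) -> float:
        """Raw time-by-condition coefficient implied by ``d_between``."""
        return self.d_between * np.sqrt(2.0) * self.sigma_e


# Baseline means/SDs pooled over the two arms of the reference cohort; the
# between-group d values are the configured truths the pipeline should
# recover.  Lower is better for all questionnaire scales, higher is better
# for sleep efficiency and total sleep time.
DEFAULT_OUTCOMES: tuple[OutcomeSpec, ...] = (
    OutcomeSpec("ISI", 16.4, 3.2, -0.66, time_effect=-3.2),
    OutcomeSpec("PSQI", 10.8, 2.8, -0.77, time_effect=-0.9),
    OutcomeSpec("DBAS16", 5.25, 1.3, -0.15, time_effect=-0.4),
    OutcomeSpec("CESD", 15.75, 5.9, -0.94, time_effect=0.5),
    OutcomeSpec("HADS", 5.85, 3.05, -0.75, time_effect=0.6),
    OutcomeSpec("sleep_efficiency", 77.3, 7.75, 0.71, time_effect=1.3),
    OutcomeSpec("tib", 503.0, 45.0, -0.55, time_effect=13.0),
    OutcomeSpec("tst", 389.5, 50.5, 0.24, time_effect=15.0),
    OutcomeSpec("sol", 32.0, 20.5, -0.45, time_effect=-1.0),
    OutcomeSpec("waso", 44.5, 31.0, -0.70, time_effect=0.0),
    OutcomeSpec("twak", 36.0, 21.0, -0.26, time_effect=0.0),
    OutcomeSpec("awakenings", 2.08, 1.07, -0.38, time_effect=-0.08),
)


@dataclass(frozen=True)
class TrialDataset:
    """Long-format two-arm trial outcomes plus per-participant covariates.

    ``data`` columns: participant, condition ("app"/"waitlist"), time
    ("pre"/"post"/"followup"), outcome, value.  The waitlist arm has no
    follow-up rows (the waitlist receives the intervention after posttest).
    """

    data: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl_followup = self.data[
            (self.data["condition"] == "waitlist") & (self.data["time"] == "followup")
        ]
        if len(wl_followup):
            raise ValueError("waitlist arm cannot have follow-up rows")

    def wide(self, outcome: str) -> pd.DataFrame:
        """Participant-per-row pre/post(/followup) table for one outcome."""
        sub = self.data[self.data["outcome"] == outcome]
        wide = sub.pivot_table(
            index="participant", columns="time", values="value",
            aggfunc="first", dropna=False,
        ).reset_index()
        wide.columns.name = None
        cond = sub[["participant", "condition"]].drop_duplicates()
        return wide.merge(cond, on="participant")

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(pd.util.hash_pandas_object(self.data, index=False).values.tobytes())
        h.update(
            pd.util.hash_pandas_object(self.covariates, index=False).values.tobytes()
        )
        return h.hexdigest()


def _missing_probability(
    base_rate: float, z_covs: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """MAR missingness: logistic in standardized covariates around a base rate."""
    base_logit = np.log(base_rate / (1.0 - base_rate)) if 0 < base_rate < 1 else -np.inf
    logit = base_logit + z_covs @ weights
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_trial(
    n_app: int,
    n_wl: int,
    outcomes: Sequence[OutcomeSpec] = DEFAULT_OUTCOMES,
    *,
    missingness: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    followup: bool = True,
) -> TrialDataset:
    """Generate a two-arm pre/post(/follow-up) trial dataset.

    ``missingness`` maps ``{"post_app": rate, "post_wl": rate, "followup":
    rate}``; omit (or pass ``None``) for complete data.  Posttest
    missingness is MAR: conditional on age, baseline sleep quality and
    terminal wakefulness in the app arm, and on the number of awakenings in
    the waitlist arm, mirroring the dropout structure the covariate
    adjustment is meant to absorb.  A single seed fans out to
    per-participant substreams, so adding a participant does not perturb the
    draws of the others.
    """
    if n_app < 1 or n_wl < 1:
        raise ValueError("need at least one participant per arm")
    n = n_app + n_wl
    root = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    part_seeds = root.spawn(n)

    condition = np.array(["app"] * n_app + ["waitlist"] * n_wl)
    age = np.clip(cov_rng.normal(39.66, 13.44, size=n), 18, 80)
    female = cov_rng.random(n) < 0.623
    base_quality = np.clip(cov_rng.normal(2.95, 0.47, size=n), 1, 5)
    base_twak = np.maximum(cov_rng.normal(36.0, 21.0, size=n), 0.0)
    base_awak = cov_rng.poisson(2.0, size=n)

    covariates = pd.DataFrame(
        {
            "participant": np.arange(n),
            "condition": condition,
            "age": age,
            "sex": np.where(female, "F", "M"),
            "baseline_quality": base_quality,
            "baseline_twak": base_twak,
            "baseline_awakenings": base_awak,
        }
    )

    records: list[tuple] = []
    is_app = (condition == "app").astype(float)
    for i in range(n):
        rng = np.random.default_rng(part_seeds[i])
        for spec in outcomes:
            u = rng.normal(0.0, spec.sigma_u)
            pre = spec.baseline_mean + u + rng.normal(0.0, spec.sigma_e)
            post = (
                spec.baseline_mean
                + spec.time_effect
                + spec.interaction_raw * is_app[i]
                + u
                + rng.normal(0.0, spec.sigma_e)
            )
            records.append((i, condition[i], "pre", spec.name, pre))
            records.append((i, condition[i], "post", spec.name, post))
            if followup and condition[i] == "app":
                fu = post + spec.followup_extra + rng.normal(0.0, spec.sigma_e * 0.5)
                records.append((i, condition[i], "followup", spec.name, fu))

    data = pd.DataFrame(
        records, columns=["participant", "condition", "time", "outcome", "value"]
    )

    if missingness:
        miss_rng = np.random.default_rng(root.spawn(n + 1)[-1])
        z = lambda x: (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)  # noqa: E731
        z_app = np.column_stack([z(age), z(base_quality), z(base_twak)])
        z_wl = np.column_stack([z(base_awak.astype(float))])
        p_miss = np.zeros(n)
        app_mask = condition == "app"
        if "post_app" in missingness:
            p_miss[app_mask] = _missing_probability(
                missingness["post_app"], z_app[app_mask], np.array([0.4, 0.4, 0.4])
            )
        if "post_wl" in missingness:
            p_miss[~app_mask] = _missing_probability(
                missingness["post_wl"], z_wl[~app_mask], np.array([0.4])
            )
        drop_post = miss_rng.random(n) < p_miss
        fu_rate = missingness.get("followup", 0.0)
        drop_fu = miss_rng.random(n) < fu_rate
        post_mask = (data["time"] == "post") & data["participant"].map(
            dict(enumerate(drop_post))
        )
        fu_mask = (data["time"] == "followup") & (
            data["participant"].map(dict(enumerate(drop_fu))) | post_mask.groupby(
                data["participant"]
            ).transform("any")
        )
        data.loc[post_mask | fu_mask, "value"] = np.nan

    truth = {spec.name: {"d_between": spec.d_between,
                         "time_effect": spec.time_effect,
                         "interaction_raw": float(spec.interaction_raw)}
             for spec in outcomes}
    return TrialDataset(data=data, covariates=covariates, truth=truth)
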