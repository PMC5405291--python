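"""Modified sleep-restriction coaching: eligibility, prescription, titration.

Sleep restriction consolidates sleep by limiting the prescribed time in bed
(TIB) and then titrating it weekly against achieved sleep efficiency (SE).
This variant is *negotiable*: the coach proposes an ideal TIB and a maximum
TIB, and the participant may accept the ideal, bargain upward to at most the
maximum, or decline the exercise entirely.

Prescription rules (derived from the first diary week's averages):

* the participant is eligible only with >= 6 filled diaries and mean SE < 85%;
* ideal TIB  = mean total sleep time, never below the 5-hour floor (300 min);
* maximum TIB = mean TIB − 60 min, clamped up to the ideal when the window
  would otherwise collapse.

Weekly titration: SE > 85% earns 15 min extra in bed; SE < 85% tightens by
15 min only when the participant actually adhered to the current
prescription (otherwise it is left unchanged); SE exactly 85% changes
nothing.  The prescription never drops below 300 minutes.

Safety: sleeping under 5 hours on average across 5 reported nights triggers
a sleepiness warning; a second full 5-night window still under 5 hours
escalates to a GP referral and stops the exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as _date
from enum import Enum
from typing import Optional, Sequence

from .diary import DiaryEntry, WeeklySummary

__all__ = [
    "TIB_FLOOR",
    "ELIGIBILITY_MIN_DIARIES",
    "SE_THRESHOLD",
    "TITRATION_STEP",
    "SAFETY_TST_THRESHOLD",
    "SAFETY_WINDOW_NIGHTS",
    "RestrictionStatus",
    "EligibilityVerdict",
    "RestrictionProposal",
    "RestrictionState",
    "NegotiationResult",
    "SafetyWarning",
    "check_eligibility",
    "compute_proposal",
    "negotiate",
    "weekly_titration",
    "safety_monitor",
]

TIB_FLOOR = 300  # "the advised time in bed is never <5 hours"
ELIGIBILITY_MIN_DIARIES = 6
SE_THRESHOLD = 85.0  # percent; strict on both sides
TITRATION_STEP = 15  # minutes per weekly adjustment
SAFETY_TST_THRESHOLD = 300  # mean TST below this triggers warnings
SAFETY_WINDOW_NIGHTS = 5


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


class RestrictionStatus(str, Enum):
    NOT_STARTED = "not_started"
    PROPOSED = "proposed"
    AGREED = "agreed"
    DECLINED = "declined"
    STOPPED_SAFETY = "stopped_safety"


@dataclass(frozen=True)
class EligibilityVerdict:
    eligible: bool
    reason: str

    def __bool__(self) -> bool:  # allows `if verdict:`
        return self.eligible


@dataclass(frozen=True)
class RestrictionProposal:
    """An ideal/maximum time-in-bed window derived from a diary week."""

    ideal_tib: int
    max_tib: int
    basis: WeeklySummary

    def __post_init__(self) -> None:
        if not TIB_FLOOR <= self.ideal_tib <= self.max_tib:
            raise ValueError(
                f"invalid proposal window: ideal {self.ideal_tib}, max {self.max_tib}"
            )


@dataclass(frozen=True)
class TitrationRecord:
    week: int
    se: float
    decision: str  # "extend" | "restrict" | "hold"
    new_tib: int


@dataclass(frozen=True)
class SafetyWarning:
    level: int  # 1 = sleepiness warning, 2 = GP referral + stop
    code: str
    text_key: str
    mean_tst: float


@dataclass(frozen=True)
class RestrictionState:
    """Current position in the sleep-restriction exercise (immutable)."""

    status: RestrictionStatus = RestrictionStatus.NOT_STARTED
    agreed_tib: Optional[int] = None
    week_index: int = 0
    titration_history: tuple[TitrationRecord, ...] = ()
    warning_level: int = 0
    last_warning_date: Optional[_date] = None
    proposal: Optional[RestrictionProposal] = None

    def __post_init__(self) -> None:
        if (self.agreed_tib is not None) != (self.status == RestrictionStatus.AGREED):
            raise ValueError("agreed_tib must be present iff status is 'agreed'")
        if self.agreed_tib is not None and self.agreed_tib < TIB_FLOOR:
            raise ValueError(f"agreed_tib below the {TIB_FLOOR}-minute floor")
        if self.warning_level not in (0, 1, 2):
            raise ValueError("warning_level must be 0, 1 or 2")

    # serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "status": self.status.value,
            "agreed_tib": self.agreed_tib,
            "week_index": self.week_index,
            "titration_history": [
                [r.week, r.se, r.decision, r.new_tib] for r in self.titration_history
            ],
            "warning_level": self.warning_level,
            "last_warning_date": (
                self.last_warning_date.isoformat() if self.last_warning_date else None
            ),
            "proposal": (
                {
                    "ideal_tib": self.proposal.ideal_tib,
                    "max_tib": self.proposal.max_tib,
                    "basis_n": self.proposal.basis.n_entries,
                    "basis_mean_tib": self.proposal.basis.mean_tib,
                    "basis_mean_tst": self.proposal.basis.mean_tst,
                    "basis_mean_se": self.proposal.basis.mean_se,
                }
                if self.proposal
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RestrictionState":
        proposal = None
        if d.get("proposal"):
            p = d["proposal"]
            proposal = RestrictionProposal(
                ideal_tib=p["ideal_tib"],
                max_tib=p["max_tib"],
                basis=WeeklySummary(
                    n_entries=p["basis_n"],
                    mean_tib=p["basis_mean_tib"],
                    mean_tst=p["basis_mean_tst"],
                    mean_se=p["basis_mean_se"],
                ),
            )
        return cls(
            status=RestrictionStatus(d["status"]),
            agreed_tib=d["agreed_tib"],
            week_index=d["week_index"],
            titration_history=tuple(
                TitrationRecord(week=w, se=se, decision=dec, new_tib=t)
                for w, se, dec, t in d.get("titration_history", [])
            ),
            warning_level=d.get("warning_level", 0),
            last_warning_date=(
                _date.fromisoformat(d["last_warning_date"])
                if d.get("last_warning_date")
                else None
            ),
            proposal=proposal,
        )


@dataclass(frozen=True)
class NegotiationResult:
    state: RestrictionState
    accepted: bool
    counter_offer: Optional[int] = None
    message: str = ""


def check_eligibility(summary: WeeklySummary) -> EligibilityVerdict:
    """Eligibility for sleep restriction after the first diary week.

    Requires >= 6 filled diaries and mean sleep efficiency strictly below 85%.
    """
    if summary.n_entries < ELIGIBILITY_MIN_DIARIES:
        return EligibilityVerdict(
            False,
            f"only {summary.n_entries} diaries filled "
            f"(need >= {ELIGIBILITY_MIN_DIARIES}); introduction postponed",
        )
    if not summary.mean_se < SE_THRESHOLD:
        return EligibilityVerdict(
            False,
            f"mean sleep efficiency {summary.mean_se:.1f}% is not below "
            f"{SE_THRESHOLD:.0f}%",
        )
    return EligibilityVerdict(True, "eligible")


def compute_proposal(summary: WeeklySummary) -> RestrictionProposal:
    """Ideal and maximum time in bed from the past week's diary averages.

    ideal = mean TST floored at 300 min; maximum = mean TIB − 60 min, clamped
    up to the ideal so the negotiation window never inverts.  Whole minutes,
    half-up rounding.
    """
    if not summary.mean_tib > 0:
        raise ValueError(f"mean_tib must be positive, got {summary.mean_tib}")
    ideal = max(_round_half_up(summary.mean_tst), TIB_FLOOR)
    max_tib = max(_round_half_up(summary.mean_tib) - 60, ideal)
    return RestrictionProposal(ideal_tib=ideal, max_tib=max_tib, basis=summary)


def negotiate(
    proposal: RestrictionProposal,
    request: int | str,
) -> NegotiationResult:
    """Resolve the participant's answer to a restriction proposal.

    ``request`` is ``"accept"``, ``"opt_out"``, or a requested TIB in minutes.
    Accepting takes the ideal; a request within (ideal, max] is granted; a
    request above the maximum is answered with a counter-offer at the maximum
    (not an error); a request below the ideal is refused — negotiation is
    upward only.
    """
    if request == "accept":
        state = RestrictionState(
            status=RestrictionStatus.AGREED,
            agreed_tib=proposal.ideal_tib,
            proposal=proposal,
        )
        return NegotiationResult(state, True, message="ideal time in bed accepted")
    if request == "opt_out":
        state = RestrictionState(status=RestrictionStatus.DECLINED, proposal=proposal)
        return NegotiationResult(state, False, message="sleep restriction declined")
    minutes = int(request)
    if minutes < proposal.ideal_tib:
        state = RestrictionState(status=RestrictionStatus.PROPOSED, proposal=proposal)
        return NegotiationResult(
            state,
            False,
            message=(
                f"negotiation is upward only: requested {minutes} is below "
                f"the ideal {proposal.ideal_tib}"
            ),
        )
    if minutes > proposal.max_tib:
        state = RestrictionState(status=RestrictionStatus.PROPOSED, proposal=proposal)
        return NegotiationResult(
            state,
            False,
            counter_offer=proposal.max_tib,
            message=(
                f"requested {minutes} exceeds the maximum; "
                f"counter-offer: {proposal.max_tib} minutes"
            ),
        )
    state = RestrictionState(
        status=RestrictionStatus.AGREED, agreed_tib=minutes, proposal=proposal
    )
    return NegotiationResult(state, True, message=f"agreed on {minutes} minutes in bed")


def weekly_titration(
    state: RestrictionState, weekly_se: float, adherent: bool
) -> RestrictionState:
    """Adjust the agreed time in bed after a week of restriction.

    SE > 85%: +15 min.  SE < 85% and adherent: −15 min (never below 300).
    SE < 85% without adherence, or SE exactly 85%: unchanged.  The decision
    is appended to the titration history.
    """
    if state.status != RestrictionStatus.AGREED or state.agreed_tib is None:
        raise ValueError(f"titration requires an agreed restriction, not {state.status}")
    tib = state.agreed_tib
    if weekly_se > SE_THRESHOLD:
        decision, new_tib = "extend", tib + TITRATION_STEP
    elif weekly_se < SE_THRESHOLD and adherent:
        decision, new_tib = "restrict", max(tib - TITRATION_STEP, TIB_FLOOR)
    else:
        decision, new_tib = "hold", tib
    record = TitrationRecord(
        week=state.week_index + 1, se=weekly_se, decision=decision, new_tib=new_tib
    )
    return replace(
        state,
        agreed_tib=new_tib,
        week_index=state.week_index + 1,
        titration_history=state.titration_history + (record,),
    )


def safety_monitor(
    entries: Sequence[DiaryEntry], state: RestrictionState
) -> tuple[RestrictionState, list[SafetyWarning]]:
    """Short-sleep safety check over the trailing 5 reported nights.

    If at least 5 nights are reported and their mean total sleep time is
    strictly below 300 minutes, a first offence raises the sleepiness
    warning (level 1).  A later window of 5 *fresh* nights, all after the
    first warning, escalates to level 2: GP referral and automatic stop of
    the restriction exercise.  A recovered window resets nothing that was
    already warned.
    """
    entries = sorted(entries, key=lambda e: e.date)
    if len(entries) < SAFETY_WINDOW_NIGHTS:
        return state, []
    window = entries[-SAFETY_WINDOW_NIGHTS:]
    mean_tst = sum(e.tst for e in window) / SAFETY_WINDOW_NIGHTS
    if not mean_tst < SAFETY_TST_THRESHOLD:
        return state, []
    warnings: list[SafetyWarning] = []
    if state.warning_level == 0:
        new = replace(state, warning_level=1, last_warning_date=window[-1].date)
        warnings.append(
            SafetyWarning(
                level=1,
                code="SHORT_SLEEP_WARNING",
                text_key="warning.sleepiness",
                mean_tst=mean_tst,
            )
        )
        return new, warnings
    if state.warning_level == 1:
        fresh = state.last_warning_date is None or all(
            e.date > state.last_warning_date for e in window
        )
        if fresh:
            status = state.status
            agreed = state.agreed_tib
            if status == RestrictionStatus.AGREED:
                status = RestrictionStatus.STOPPED_SAFETY
                agreed = None
            new = replace(
                state,
                warning_level=2,
                last_warning_date=window[-1].date,
                status=status,
                agreed_tib=agreed,
            )
            warnings.append(
                SafetyWarning(
                    level=2,
                    code="SHORT_SLEEP_STOP",
                    text_key="warning.gp_referral",
                    mean_tst=mean_tst,
                )
            )
            return new, warnings
    return state, []
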