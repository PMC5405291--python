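"""Protocol state machine for the 6-7 week automated coaching program.

The engine is a deterministic pure fold over a dated event stream: each call
to :func:`advance_day` consumes one calendar day's diary entries and
participant actions and returns a new :class:`ProgramState` plus the list of
emitted events.  No wall clock is read; the caller injects all dates, so a
given stream always reproduces the same final state and event log, and a
state serialized to JSON mid-stream resumes identically.

Protocol shape:

* week 1 is the baseline diary week; the relaxation exercise is introduced
  on day 1 and its adherence is checked once, 4 days later (a conversation
  starts if it was done fewer than 3 times);
* after day 7, once at least 6 diaries exist, the sleep-restriction
  introduction conversation is queued (postponed day by day until the count
  is met); its negotiated outcome feeds :mod:`sleepcare.restriction`;
* every further full diary week queues an evaluation conversation whose
  outcome drives the weekly titration;
* unfinished conversations get one reminder per day at noon;
* the base program lasts 42 days, extended by up to 7 postponement days.

Only one conversation may be open at a time, and a new one can be opened
only after the previous one is finished.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date as _date, datetime, time, timedelta
from typing import Any, Iterable, Optional, Sequence

from . import restriction as rc
from .diary import (
    DiaryEntry,
    entries_from_json,
    entries_to_json,
    summarize_window,
)

__all__ = [
    "BASE_PROGRAM_DAYS",
    "MAX_PROGRAM_DAYS",
    "Conversation",
    "ProgramState",
    "ConversationGatingError",
    "new_program",
    "advance_day",
    "open_conversation",
    "finish_conversation",
    "relaxation_adherence_check",
    "reminders",
]

BASE_PROGRAM_DAYS = 42
MAX_PROGRAM_DAYS = 49
RELAXATION_MIN_DURATION = 1
RELAXATION_MAX_DURATION = 16
RELAXATION_WINDOW_DAYS = 4
RELAXATION_MIN_COUNT = 3
NOON = time(12, 0)


class ConversationGatingError(RuntimeError):
    """A conversation was opened while another one is still unfinished."""


@dataclass(frozen=True)
class Conversation:
    """A typed conversation stub: trigger id plus slots for structured answers."""

    id: str
    kind: str  # welcome | restriction_introduction | weekly_evaluation | ...
    scheduled: str  # ISO date the conversation was queued
    opened: bool = False
    finished: bool = False
    payload: dict = field(default_factory=dict)
    outcome: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "kind": self.kind,
            "scheduled": self.scheduled,
            "opened": self.opened,
            "finished": self.finished,
            "payload": self.payload,
            "outcome": self.outcome,
        }


@dataclass(frozen=True)
class ProgramState:
    """Per-participant protocol position (immutable; JSON round-trippable)."""

    start_date: _date
    day_index: int = 0  # days already processed
    status: str = "active"  # active | finished
    entries: tuple[DiaryEntry, ...] = ()
    relaxation_log: tuple[tuple[str, int], ...] = ()  # (ISO date, minutes)
    conversations: tuple[Conversation, ...] = ()
    restriction: rc.RestrictionState = field(default_factory=rc.RestrictionState)
    relaxation_intro_date: Optional[_date] = None
    relaxation_check_done: bool = False
    restriction_intro_queued: bool = False
    postponement_days: int = 0
    last_reminder_date: Optional[_date] = None
    next_conversation_serial: int = 0

    # -- convenience -------------------------------------------------------

    @property
    def today(self) -> _date:
        """The next calendar day the engine will process."""
        return self.start_date + timedelta(days=self.day_index)

    @property
    def program_length(self) -> int:
        return BASE_PROGRAM_DAYS + min(self.postponement_days, 7)

    @property
    def diary_dates(self) -> set[_date]:
        return {e.date for e in self.entries}

    def open_conversations(self) -> list[Conversation]:
        return [c for c in self.conversations if c.opened and not c.finished]

    def unfinished_conversations(self) -> list[Conversation]:
        return [c for c in self.conversations if not c.finished]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "start_date": self.start_date.isoformat(),
            "day_index": self.day_index,
            "status": self.status,
            "entries": entries_to_json(self.entries),
            "relaxation_log": [list(r) for r in self.relaxation_log],
            "conversations": [c.to_dict() for c in self.conversations],
            "restriction": self.restriction.to_dict(),
            "relaxation_intro_date": (
                self.relaxation_intro_date.isoformat()
                if self.relaxation_intro_date
                else None
            ),
            "relaxation_check_done": self.relaxation_check_done,
            "restriction_intro_queued": self.restriction_intro_queued,
            "postponement_days": self.postponement_days,
            "last_reminder_date": (
                self.last_reminder_date.isoformat() if self.last_reminder_date else None
            ),
            "next_conversation_serial": self.next_conversation_serial,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ProgramState":
        return cls(
            start_date=_date.fromisoformat(d["start_date"]),
            day_index=d["day_index"],
            status=d["status"],
            entries=tuple(entries_from_json(d["entries"])),
            relaxation_log=tuple((r[0], r[1]) for r in d["relaxation_log"]),
            conversations=tuple(
                Conversation(
                    id=c["id"],
                    kind=c["kind"],
                    scheduled=c["scheduled"],
                    opened=c["opened"],
                    finished=c["finished"],
                    payload=c["payload"],
                    outcome=c["outcome"],
                )
                for c in d["conversations"]
            ),
            restriction=rc.RestrictionState.from_dict(d["restriction"]),
            relaxation_intro_date=(
                _date.fromisoformat(d["relaxation_intro_date"])
                if d["relaxation_intro_date"]
                else None
            ),
            relaxation_check_done=d["relaxation_check_done"],
            restriction_intro_queued=d["restriction_intro_queued"],
            postponement_days=d["postponement_days"],
            last_reminder_date=(
                _date.fromisoformat(d["last_reminder_date"])
                if d["last_reminder_date"]
                else None
            ),
            next_conversation_serial=d["next_conversation_serial"],
        )

    @classmethod
    def from_json(cls, text: str) -> "ProgramState":
        return cls.from_dict(json.loads(text))


def new_program(start_date: _date) -> ProgramState:
    """A fresh program: day 0, relaxation introduced on the first day."""
    return ProgramState(start_date=start_date, relaxation_intro_date=start_date)


def _event(date: _date, code: str, **payload: Any) -> dict:
    return {"date": date.isoformat(), "event_code": code, "payload": payload}


def _queue(state: ProgramState, kind: str, date: _date, payload: dict) -> ProgramState:
    conv = Conversation(
        id=f"{kind}-{state.next_conversation_serial}",
        kind=kind,
        scheduled=date.isoformat(),
        payload=payload,
    )
    return replace(
        state,
        conversations=state.conversations + (conv,),
        next_conversation_serial=state.next_conversation_serial + 1,
    )


def relaxation_adherence_check(
    relaxation_log: Sequence[tuple[str, int]],
    introduction_date: _date,
    today: _date,
) -> bool:
    """True iff the low-adherence conversation should fire today.

    Fires exactly on day ``introduction_date + 4`` when fewer than 3
    exercises were done within the 4-day window after the introduction.
    """
    if today != introduction_date + timedelta(days=RELAXATION_WINDOW_DAYS):
        return False
    window_end = introduction_date + timedelta(days=RELAXATION_WINDOW_DAYS)
    count = sum(
        1
        for iso, _dur in relaxation_log
        if introduction_date <= _date.fromisoformat(iso) <= window_end
    )
    return count < RELAXATION_MIN_COUNT


def advance_day(
    state: ProgramState,
    todays_entries: Iterable[DiaryEntry] = (),
    todays_actions: Iterable[dict] = (),
    *,
    date: Optional[_date] = None,
) -> tuple[ProgramState, list[dict]]:
    """Process one calendar day; returns the new state and emitted events.

    ``todays_actions`` are participant actions as dicts:
    ``{"type": "relaxation", "duration": minutes}``,
    ``{"type": "open_conversation", "id": ...}``,
    ``{"type": "finish_conversation", "id": ..., "outcome": {...}}``.
    Dates must advance monotonically one day at a time.
    """
    if state.status == "finished":
        return state, []
    today = state.today
    if date is not None and date != today:
        raise ValueError(f"out-of-order date: expected {today}, got {date}")
    events: list[dict] = []

    # diary entries for the previous night(s)
    for entry in todays_entries:
        entry.validate(today=today)
        if entry.date in state.diary_dates:
            continue  # one report per night
        state = replace(state, entries=state.entries + (entry,))
        events.append(_event(today, "diary_logged", night=entry.date.isoformat()))

    # participant actions
    for action in todays_actions:
        kind = action.get("type")
        if kind == "relaxation":
            duration = int(action.get("duration", 0))
            if not RELAXATION_MIN_DURATION <= duration <= RELAXATION_MAX_DURATION:
                events.append(
                    _event(today, "relaxation_rejected", duration=duration)
                )
                continue
            state = replace(
                state,
                relaxation_log=state.relaxation_log + ((today.isoformat(), duration),),
            )
            events.append(_event(today, "relaxation_done", duration=duration))
        elif kind == "open_conversation":
            try:
                state = open_conversation(state, action["id"])
                events.append(_event(today, "conversation_opened", id=action["id"]))
            except (ConversationGatingError, KeyError, ValueError) as exc:
                events.append(
                    _event(today, "conversation_refused", id=action.get("id"),
                           reason=str(exc))
                )
        elif kind == "finish_conversation":
            state, fin_events = finish_conversation(
                state, action["id"], action.get("outcome") or {}, today=today
            )
            events.extend(fin_events)
        else:
            events.append(_event(today, "unknown_action", action=kind))

    day_number = state.day_index + 1  # 1-based day just lived through

    # relaxation adherence trigger, once, 4 days after introduction
    if (
        not state.relaxation_check_done
        and state.relaxation_intro_date is not None
        and today == state.relaxation_intro_date + timedelta(days=RELAXATION_WINDOW_DAYS)
    ):
        state = replace(state, relaxation_check_done=True)
        if relaxation_adherence_check(
            state.relaxation_log, state.relaxation_intro_date, today
        ):
            state = _queue(state, "relaxation_adherence", today, {})
            events.append(_event(today, "relaxation_adherence_conversation"))

    # restriction introduction after the baseline week
    if (
        day_number >= 7
        and not state.restriction_intro_queued
        and state.restriction.status == rc.RestrictionStatus.NOT_STARTED
    ):
        n_diaries = len(state.entries)
        if n_diaries >= rc.ELIGIBILITY_MIN_DIARIES:
            summary = summarize_window(state.entries, window_days=7, end_date=today)
            if summary.n_entries < rc.ELIGIBILITY_MIN_DIARIES:
                # enough diaries overall but not within the trailing week:
                # use all entries so far as the basis week
                summary = summarize_window(
                    state.entries, window_days=day_number, end_date=today
                )
            verdict = rc.check_eligibility(summary)
            state = replace(state, restriction_intro_queued=True)
            if verdict.eligible:
                proposal = rc.compute_proposal(summary)
                state = _queue(
                    state,
                    "restriction_introduction",
                    today,
                    {"ideal_tib": proposal.ideal_tib, "max_tib": proposal.max_tib,
                     "mean_se": summary.mean_se, "mean_tib": summary.mean_tib,
                     "mean_tst": summary.mean_tst, "n_entries": summary.n_entries},
                )
                events.append(
                    _event(today, "restriction_introduction",
                           ideal_tib=proposal.ideal_tib, max_tib=proposal.max_tib)
                )
            else:
                events.append(
                    _event(today, "restriction_not_indicated", reason=verdict.reason)
                )
        else:
            state = replace(state, postponement_days=state.postponement_days + 1)
            if day_number == 7:
                events.append(
                    _event(today, "restriction_postponed",
                           n_diaries=n_diaries,
                           needed=rc.ELIGIBILITY_MIN_DIARIES)
                )

    # weekly evaluation while restriction is running
    if (
        state.restriction.status == rc.RestrictionStatus.AGREED
        and day_number % 7 == 0
        and day_number >= 14
    ):
        summary = summarize_window(state.entries, window_days=7, end_date=today)
        state = _queue(
            state,
            "weekly_evaluation",
            today,
            {"mean_se": summary.mean_se, "n_entries": summary.n_entries},
        )
        events.append(
            _event(today, "weekly_evaluation", mean_se=summary.mean_se,
                   n_entries=summary.n_entries)
        )

    # short-sleep safety monitor
    new_restriction, warnings = rc.safety_monitor(state.entries, state.restriction)
    if warnings:
        state = replace(state, restriction=new_restriction)
        for w in warnings:
            events.append(
                _event(today, w.code, level=w.level, text_key=w.text_key,
                       mean_tst=w.mean_tst)
            )

    state = replace(state, day_index=state.day_index + 1)

    if state.day_index >= state.program_length:
        state = replace(state, status="finished")
        events.append(_event(today, "program_finished", days=state.day_index))
    return state, events


def open_conversation(state: ProgramState, conversation_id: str) -> ProgramState:
    """Open a queued conversation; refuses while another one is open."""
    if state.open_conversations():
        open_id = state.open_conversations()[0].id
        raise ConversationGatingError(
            f"conversation {open_id} is still unfinished; finish it first"
        )
    convs = list(state.conversations)
    for i, c in enumerate(convs):
        if c.id == conversation_id:
            if c.finished:
                raise ValueError(f"conversation {conversation_id} already finished")
            convs[i] = replace(c, opened=True)
            return replace(state, conversations=tuple(convs))
    raise KeyError(conversation_id)


def finish_conversation(
    state: ProgramState,
    conversation_id: str,
    outcome: dict,
    *,
    today: Optional[_date] = None,
) -> tuple[ProgramState, list[dict]]:
    """Close a conversation and apply its structured outcome to the state.

    A ``restriction_introduction`` outcome ``{"response": "accept" | minutes
    | "opt_out"}`` runs the negotiation; a ``weekly_evaluation`` outcome
    ``{"adherent": bool}`` runs the weekly titration with the SE recorded in
    the conversation payload.
    """
    if today is None:
        today = state.today
    events: list[dict] = []
    convs = list(state.conversations)
    for i, c in enumerate(convs):
        if c.id != conversation_id:
            continue
        if c.finished:
            raise ValueError(f"conversation {conversation_id} already finished")
        convs[i] = replace(c, opened=True, finished=True, outcome=dict(outcome))
        state = replace(state, conversations=tuple(convs))
        if c.kind == "restriction_introduction":
            proposal = rc.RestrictionProposal(
                ideal_tib=c.payload["ideal_tib"],
                max_tib=c.payload["max_tib"],
                basis=summarize_window(state.entries, window_days=7, end_date=today),
            )
            result = rc.negotiate(proposal, outcome.get("response", "accept"))
            state = replace(state, restriction=result.state)
            events.append(
                _event(today, "negotiation_result",
                       accepted=result.accepted,
                       agreed_tib=result.state.agreed_tib,
                       counter_offer=result.counter_offer,
                       message=result.message)
            )
        elif c.kind == "weekly_evaluation":
            if state.restriction.status == rc.RestrictionStatus.AGREED:
                new_r = rc.weekly_titration(
                    state.restriction,
                    c.payload.get("mean_se", float("nan")),
                    bool(outcome.get("adherent", True)),
                )
                state = replace(state, restriction=new_r)
                events.append(
                    _event(today, "titration",
                           decision=new_r.titration_history[-1].decision,
                           new_tib=new_r.agreed_tib)
                )
        events.append(_event(today, "conversation_finished", id=conversation_id))
        return state, events
    raise KeyError(conversation_id)


def reminders(
    state: ProgramState, now: datetime
) -> tuple[ProgramState, list[dict]]:
    """Noon reminders for unfinished conversations; idempotent within a day.

    Returns the updated state (remembering the last reminded day) and one
    notification per unfinished conversation if ``now`` is at or past noon
    and no reminder was sent today.
    """
    if now.time() < NOON:
        return state, []
    if state.last_reminder_date == now.date():
        return state, []
    pending = state.unfinished_conversations()
    if not pending:
        return state, []
    state = replace(state, last_reminder_date=now.date())
    notes = [
        _event(now.date(), "reminder", conversation_id=c.id, kind=c.kind)
        for c in pending
    ]
    return state, notes
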