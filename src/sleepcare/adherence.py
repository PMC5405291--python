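"""Treatment-adherence components and adequate-dose flags.

Adherence to the program is measured by four objectively logged components:
diaries filled, relaxation exercises performed, conversations completed, and
the mean absolute deviation between the actual and the agreed-upon time in
bed during restriction nights.  A component counts as an *adequate dose*
under strict thresholds: >35 diaries, >35 relaxation exercises, >90%
conversation completion, and a mean restriction deviation <60 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from typing import Mapping, Optional, Sequence

from .diary import DiaryEntry
from .engine import ProgramState

__all__ = [
    "DIARIES_ADEQUATE_MIN",
    "RELAXATIONS_ADEQUATE_MIN",
    "CONVERSATIONS_ADEQUATE_MIN",
    "DEVIATION_ADEQUATE_MAX",
    "DeviationSummary",
    "AdherenceReport",
    "restriction_deviation",
    "adequacy",
    "report_from_state",
]

DIARIES_ADEQUATE_MIN = 35  # adequate iff strictly more
RELAXATIONS_ADEQUATE_MIN = 35
CONVERSATIONS_ADEQUATE_MIN = 90.0  # percent, strictly more
DEVIATION_ADEQUATE_MAX = 60.0  # minutes, strictly less


@dataclass(frozen=True)
class DeviationSummary:
    """Mean |actual − agreed| TIB, with per-direction means for calibration."""

    mean_abs: float
    n_nights: int
    mean_overstay: Optional[float]  # nights with actual > agreed
    mean_understay: Optional[float]  # nights with actual < agreed
    n_overstay: int
    n_understay: int


@dataclass(frozen=True)
class AdherenceReport:
    n_diaries: int
    n_relaxations: int
    conversation_completion: float  # percent of scheduled conversations finished
    restriction_deviation: Optional[float]  # mean minutes; None if never agreed
    adequate: dict

    def to_dict(self) -> dict:
        return {
            "n_diaries": self.n_diaries,
            "n_relaxations": self.n_relaxations,
            "conversation_completion": self.conversation_completion,
            "restriction_deviation": self.restriction_deviation,
            "adequate": dict(self.adequate),
        }


def restriction_deviation(
    entries: Sequence[DiaryEntry],
    agreed_tib_by_date: Mapping[_date, int],
) -> DeviationSummary | None:
    """Average nightly deviation from the agreed time in bed.

    Only nights with an active agreement contribute.  Returns ``None`` when
    no restriction night exists (absence, not zero).
    """
    devs: list[float] = []
    over: list[float] = []
    under: list[float] = []
    for e in entries:
        agreed = agreed_tib_by_date.get(e.date)
        if agreed is None:
            continue
        diff = e.tib - agreed
        devs.append(abs(diff))
        if diff > 0:
            over.append(diff)
        elif diff < 0:
            under.append(-diff)
    if not devs:
        return None
    return DeviationSummary(
        mean_abs=sum(devs) / len(devs),
        n_nights=len(devs),
        mean_overstay=sum(over) / len(over) if over else None,
        mean_understay=sum(under) / len(under) if under else None,
        n_overstay=len(over),
        n_understay=len(under),
    )


def adequacy(
    n_diaries: int,
    n_relaxations: int,
    conversation_completion: float,
    restriction_deviation: Optional[float],
) -> AdherenceReport:
    """Apply the adequate-dose thresholds (all strict, as printed).

    36 diaries is adequate, 35 is not; completion 90.1% is adequate, 90.0%
    is not; deviation 59.9 min is adherent, 60.0 is not.  The restriction
    flag is ``None`` when the exercise was never agreed.
    """
    if not 0.0 <= conversation_completion <= 100.0:
        raise ValueError("conversation_completion must be a percent in [0, 100]")
    if restriction_deviation is not None and restriction_deviation < 0:
        raise ValueError("restriction_deviation must be >= 0")
    flags = {
        "diaries": n_diaries > DIARIES_ADEQUATE_MIN,
        "relaxations": n_relaxations > RELAXATIONS_ADEQUATE_MIN,
        "conversations": conversation_completion > CONVERSATIONS_ADEQUATE_MIN,
        "restriction": (
            restriction_deviation < DEVIATION_ADEQUATE_MAX
            if restriction_deviation is not None
            else None
        ),
    }
    return AdherenceReport(
        n_diaries=n_diaries,
        n_relaxations=n_relaxations,
        conversation_completion=conversation_completion,
        restriction_deviation=restriction_deviation,
        adequate=flags,
    )


def report_from_state(
    state: ProgramState,
    agreed_tib_by_date: Optional[Mapping[_date, int]] = None,
) -> AdherenceReport:
    """Adherence report for a full program run.

    ``agreed_tib_by_date`` maps each restriction night to the prescription
    active that night; when omitted, a constant prescription equal to the
    final agreed TIB is assumed for nights after the agreement.
    """
    n_diaries = len(state.entries)
    n_relax = len(state.relaxation_log)
    scheduled = len(state.conversations)
    finished = sum(1 for c in state.conversations if c.finished)
    completion = 100.0 * finished / scheduled if scheduled else 100.0
    deviation = None
    if agreed_tib_by_date:
        summary = restriction_deviation(state.entries, agreed_tib_by_date)
        deviation = summary.mean_abs if summary else None
    elif state.restriction.agreed_tib is not None:
        agreed = state.restriction.agreed_tib
        mapping = {e.date: agreed for e in state.entries}
        summary = restriction_deviation(state.entries, mapping)
        deviation = summary.mean_abs if summary else None
    return adequacy(n_diaries, n_relax, completion, deviation)
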