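"""Consensus-sleep-diary records and derived nightly sleep metrics.

One :class:`DiaryEntry` is one morning's report about the previous night:
raw clock times (stored as minutes-of-day, 0-1439), wakefulness latencies in
minutes, a 1-10 quality rating and a medication flag.  From the raw record
the standard diary metrics are derived:

* time in bed      TIB  = arising time − bed time (crossing midnight if needed)
* terminal wake    TWAK = arising time − final-awakening time
* total sleep time TST  = TIB − SOL − WASO − TWAK
* sleep efficiency SE   = 100 · TST / TIB   (percent)

Entries whose reported wakefulness exceeds the time spent in bed describe an
impossible night and are rejected at validation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date as _date, timedelta
from math import isfinite
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DiaryEntry",
    "NightMetrics",
    "WeeklySummary",
    "DiaryValidationError",
    "parse_clock",
    "format_clock",
    "time_in_bed",
    "terminal_wakefulness",
    "total_sleep_time",
    "sleep_efficiency",
    "night_metrics",
    "summarize_window",
    "read_diary_csv",
    "write_diary_csv",
    "entries_to_json",
    "entries_from_json",
]

MINUTES_PER_DAY = 1440


class DiaryValidationError(ValueError):
    """A diary entry (or file row) violates the diary's consistency rules."""


def parse_clock(text: str) -> int:
    """Parse ``HH:MM`` into minutes-of-day (0-1439)."""
    try:
        hh, mm = text.strip().split(":")
        minutes = int(hh) * 60 + int(mm)
    except (ValueError, AttributeError) as exc:
        raise DiaryValidationError(f"unparseable clock time: {text!r}") from exc
    if not 0 <= minutes < MINUTES_PER_DAY:
        raise DiaryValidationError(f"clock time out of range: {text!r}")
    return minutes


def format_clock(minutes: int) -> str:
    """Render minutes-of-day as ``HH:MM``."""
    minutes = int(minutes) % MINUTES_PER_DAY
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def time_in_bed(bed_time: int, arising_time: int) -> int:
    """Minutes between going to bed and finally arising.

    Both arguments are minutes-of-day.  A night crosses midnight when the
    arising time is at or before the bed time, in which case 24 h is added.
    Equal clock times are rejected: a zero-length night cannot be told apart
    from a full 24 h in bed.
    """
    _check_clock(bed_time, "bed_time")
    _check_clock(arising_time, "arising_time")
    if bed_time == arising_time:
        raise DiaryValidationError(
            "bed time equals arising time: zero-length night is unresolvable"
        )
    delta = (arising_time - bed_time) % MINUTES_PER_DAY
    return delta


def terminal_wakefulness(final_wake_time: int, arising_time: int) -> int:
    """Minutes between the final awakening and getting out of bed (may be 0)."""
    _check_clock(final_wake_time, "final_wake_time")
    _check_clock(arising_time, "arising_time")
    return (arising_time - final_wake_time) % MINUTES_PER_DAY


def total_sleep_time(tib: float, sol: float, waso: float, twak: float) -> float:
    """TST = TIB − SOL − WASO − TWAK; negative results are impossible nights."""
    for name, v in (("tib", tib), ("sol", sol), ("waso", waso), ("twak", twak)):
        if not isfinite(v) or v < 0:
            raise DiaryValidationError(f"{name} must be finite and >= 0, got {v}")
    tst = tib - sol - waso - twak
    if tst < 0:
        raise DiaryValidationError(
            f"impossible night: SOL {sol} + WASO {waso} + TWAK {twak} "
            f"exceeds time in bed {tib}"
        )
    return tst


def sleep_efficiency(tst: float, tib: float) -> float:
    """Sleep efficiency in percent: 100 · TST / TIB."""
    if tib <= 0:
        raise DiaryValidationError(f"time in bed must be positive, got {tib}")
    if not 0 <= tst <= tib:
        raise DiaryValidationError(f"total sleep time {tst} outside [0, {tib}]")
    return 100.0 * tst / tib


def _check_clock(value: int, name: str) -> None:
    if not 0 <= value < MINUTES_PER_DAY:
        raise DiaryValidationError(f"{name} must be in [0, 1439], got {value}")


@dataclass(frozen=True)
class NightMetrics:
    """Derived metrics for one night (minutes; se in percent)."""

    tib: float
    twak: float
    tst: float
    se: float


@dataclass(frozen=True)
class DiaryEntry:
    """One night's consensus sleep diary record.

    ``date`` is the calendar date of the morning of report.  Clock times are
    minutes-of-day; durations are minutes.
    """

    date: _date
    bed_time: int
    try_sleep_time: int
    sol: float
    n_awakenings: int
    waso: float
    final_wake_time: int
    arising_time: int
    quality: int
    used_medication: bool = False

    def __post_init__(self) -> None:
        for name in ("bed_time", "try_sleep_time", "final_wake_time", "arising_time"):
            _check_clock(getattr(self, name), name)
        if not isfinite(self.sol) or self.sol < 0:
            raise DiaryValidationError(f"sol must be finite and >= 0, got {self.sol}")
        if not isfinite(self.waso) or self.waso < 0:
            raise DiaryValidationError(f"waso must be finite and >= 0, got {self.waso}")
        if self.n_awakenings < 0:
            raise DiaryValidationError("n_awakenings must be >= 0")
        if not 1 <= self.quality <= 10:
            raise DiaryValidationError(
                f"quality must be an integer 1-10, got {self.quality}"
            )
        # tst computation raises for impossible nights
        self.metrics()

    def validate(self, today: _date | None = None) -> None:
        """Re-run consistency checks; reject future-dated entries.

        The diary can only be filled out for the previous night, so an entry
        dated after the engine clock ``today`` is invalid.
        """
        if today is not None and self.date > today:
            raise DiaryValidationError(
                f"entry dated {self.date} is in the future relative to {today}"
            )

    # -- derived metrics ---------------------------------------------------

    @property
    def tib(self) -> int:
        return time_in_bed(self.bed_time, self.arising_time)

    @property
    def twak(self) -> int:
        return terminal_wakefulness(self.final_wake_time, self.arising_time)

    @property
    def tst(self) -> float:
        return total_sleep_time(self.tib, self.sol, self.waso, self.twak)

    @property
    def se(self) -> float:
        return sleep_efficiency(self.tst, self.tib)

    def metrics(self) -> NightMetrics:
        tib = self.tib
        twak = self.twak
        tst = total_sleep_time(tib, self.sol, self.waso, twak)
        return NightMetrics(tib=tib, twak=twak, tst=tst, se=sleep_efficiency(tst, tib))


def night_metrics(entry: DiaryEntry) -> NightMetrics:
    """Derived metrics for one entry (functional alias of ``entry.metrics()``)."""
    return entry.metrics()


@dataclass(frozen=True)
class WeeklySummary:
    """Unweighted means of nightly metrics over a trailing window.

    ``mean_se`` is the mean of the nightly efficiency ratios, matching how
    the coach reports "weekly sleep efficiency averages"; aggregate-ratio
    averaging (total TST / total TIB) is available via ``summarize_window``'s
    ``se_mode`` option.  All means are ``nan`` when ``n_entries`` is 0.
    """

    n_entries: int
    mean_tib: float = float("nan")
    mean_tst: float = float("nan")
    mean_sol: float = float("nan")
    mean_waso: float = float("nan")
    mean_twak: float = float("nan")
    mean_se: float = float("nan")
    mean_quality: float = float("nan")
    mean_awakenings: float = float("nan")


def summarize_window(
    entries: Sequence[DiaryEntry],
    window_days: int = 7,
    *,
    end_date: _date | None = None,
    se_mode: str = "per_night",
) -> WeeklySummary:
    """Aggregate diary entries inside a trailing calendar window.

    Parameters
    ----------
    entries
        Validated diary entries (any order; missing nights simply absent).
    window_days
        Length of the trailing window in days (>= 1).
    end_date
        Last date included; defaults to the latest entry date.
    se_mode
        ``"per_night"`` (default) averages the nightly SE percentages;
        ``"aggregate"`` computes 100 · ΣTST / ΣTIB over the window.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if se_mode not in ("per_night", "aggregate"):
        raise ValueError(f"unknown se_mode: {se_mode!r}")
    if end_date is None:
        if not entries:
            return WeeklySummary(n_entries=0)
        end_date = max(e.date for e in entries)
    start = end_date - timedelta(days=window_days - 1)
    inside = [e for e in entries if start <= e.date <= end_date]
    if not inside:
        return WeeklySummary(n_entries=0)
    metrics = [e.metrics() for e in inside]
    n = len(inside)
    mean = lambda xs: sum(xs) / n  # noqa: E731
    if se_mode == "per_night":
        mean_se = mean([m.se for m in metrics])
    else:
        mean_se = 100.0 * sum(m.tst for m in metrics) / sum(m.tib for m in metrics)
    return WeeklySummary(
        n_entries=n,
        mean_tib=mean([m.tib for m in metrics]),
        mean_tst=mean([m.tst for m in metrics]),
        mean_sol=mean([e.sol for e in inside]),
        mean_waso=mean([e.waso for e in inside]),
        mean_twak=mean([m.twak for m in metrics]),
        mean_se=mean_se,
        mean_quality=mean([e.quality for e in inside]),
        mean_awakenings=mean([e.n_awakenings for e in inside]),
    )


# -- I/O -------------------------------------------------------------------

CSV_COLUMNS = [
    "date",
    "bed_time",
    "try_sleep_time",
    "sol",
    "n_awakenings",
    "waso",
    "final_wake_time",
    "arising_time",
    "quality",
    "used_medication",
]


def _entry_to_row(e: DiaryEntry) -> dict[str, str]:
    return {
        "date": e.date.isoformat(),
        "bed_time": format_clock(e.bed_time),
        "try_sleep_time": format_clock(e.try_sleep_time),
        "sol": _fmt_minutes(e.sol),
        "n_awakenings": str(e.n_awakenings),
        "waso": _fmt_minutes(e.waso),
        "final_wake_time": format_clock(e.final_wake_time),
        "arising_time": format_clock(e.arising_time),
        "quality": str(e.quality),
        "used_medication": "1" if e.used_medication else "0",
    }


def _fmt_minutes(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _entry_from_row(row: dict[str, str], lineno: int | None = None) -> DiaryEntry:
    where = f" (line {lineno})" if lineno is not None else ""
    try:
        return DiaryEntry(
            date=_date.fromisoformat(row["date"]),
            bed_time=parse_clock(row["bed_time"]),
            try_sleep_time=parse_clock(row["try_sleep_time"]),
            sol=float(row["sol"]),
            n_awakenings=int(row["n_awakenings"]),
            waso=float(row["waso"]),
            final_wake_time=parse_clock(row["final_wake_time"]),
            arising_time=parse_clock(row["arising_time"]),
            quality=int(row["quality"]),
            used_medication=row["used_medication"].strip() in ("1", "true", "True"),
        )
    except KeyError as exc:
        raise DiaryValidationError(f"missing required column {exc}{where}") from exc
    except DiaryValidationError as exc:
        raise DiaryValidationError(f"{exc}{where}") from exc
    except ValueError as exc:
        raise DiaryValidationError(f"malformed value{where}: {exc}") from exc


def read_diary_csv(path: str | Path, *, today: _date | None = None) -> list[DiaryEntry]:
    """Read diary entries from CSV; malformed rows raise with line numbers."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DiaryValidationError(
                f"missing required column(s): {', '.join(sorted(missing))}"
            )
        entries = []
        for lineno, row in enumerate(reader, start=2):
            entry = _entry_from_row(row, lineno)
            entry.validate(today=today)
            entries.append(entry)
    return entries


def write_diary_csv(entries: Iterable[DiaryEntry], path: str | Path) -> None:
    """Write diary entries to CSV with the canonical column schema."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for e in entries:
            writer.writerow(_entry_to_row(e))


def entries_to_json(entries: Iterable[DiaryEntry]) -> list[dict]:
    """JSON-serializable mirror of the CSV schema (for engine-state embedding)."""
    return [_entry_to_row(e) for e in entries]


def entries_from_json(records: Iterable[dict]) -> list[DiaryEntry]:
    return [_entry_from_row(dict(r)) for r in records]
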