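from __future__ import annotations

from datetime import date, timedelta

import pytest

from sleepcare.diary import DiaryEntry


def make_entry(
    day: date,
    tib: int = 480,
    sol: float = 20,
    waso: float = 30,
    twak: float = 10,
    *,
    arising: int = 420,  # 07:00
    quality: int = 6,
    n_awakenings: int = 2,
    used_medication: bool = False,
) -> DiaryEntry:
    """Build a valid diary night with the requested derived components."""
    bed = (arising - tib) % 1440
    final_wake = (arising - int(twak)) % 1440
    return DiaryEntry(
        date=day,
        bed_time=bed,
        try_sleep_time=(bed + 5) % 1440,
        sol=sol,
        n_awakenings=n_awakenings,
        waso=waso,
        final_wake_time=final_wake,
        arising_time=arising,
        quality=quality,
        used_medication=used_medication,
    )


@pytest.fixture
def entry_builder():
    return make_entry


@pytest.fixture
def week_of_entries():
    """Seven identical nights: TIB 480, TST 408, SE 85.0."""
    start = date(2015, 9, 1)
    return [
        make_entry(start + timedelta(days=i), tib=480, sol=30, waso=32, twak=10)
        for i in range(7)
    ]
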