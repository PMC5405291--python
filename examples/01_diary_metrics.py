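"""Compute nightly and weekly sleep metrics from consensus-diary records.

Builds one week of diary nights, derives TIB/TST/sleep efficiency per night
and summarizes the trailing week the way the coach does before proposing
sleep restriction.
"""

from datetime import date, timedelta

from sleepcare.diary import DiaryEntry, summarize_window

# A week of nights: to bed 23:00, arising 07:26 (8 h 26 min in bed), with
# the wakefulness pattern of a mildly insomniac sleeper.
entries = [
    DiaryEntry(
        date=date(2015, 9, 1) + timedelta(days=i),
        bed_time=23 * 60,
        try_sleep_time=23 * 60 + 10,
        sol=33,
        n_awakenings=2,
        waso=45,
        final_wake_time=6 * 60 + 51,  # 06:51, i.e. 35 min before arising
        arising_time=7 * 60 + 26,
        quality=5,
        used_medication=False,
    )
    for i in range(7)
]

night = entries[0].metrics()
print(f"one night: TIB {night.tib} min, TWAK {night.twak} min, "
      f"TST {night.tst:.0f} min, SE {night.se:.1f}%")

week = summarize_window(entries, window_days=7)
print(f"week of {week.n_entries} diaries: mean TIB {week.mean_tib:.0f} min, "
      f"mean TST {week.mean_tst:.0f} min, mean SE {week.mean_se:.1f}%")

# TST is definitional: TIB − SOL − WASO − TWAK.  A sleep efficiency below
# 85% over >= 6 diaries is what makes this sleeper eligible for restriction.
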