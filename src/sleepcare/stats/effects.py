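"""Change-score effect sizes, outcome-scale checks and clinical classification.

Between-group Cohen d follows the change-score convention: the waitlist
mean change minus the app mean change, divided by the pooled standard
deviation of the change scores, where change = pre − post.  On a
"lower is better" scale (e.g. insomnia severity) an app advantage therefore
comes out negative; on a "higher is better" scale (sleep efficiency) it
comes out positive.  Within-group d divides (mean pre − mean post) by the
SD pooled over the pre and post distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SCALE_RANGES",
    "EffectSizeResult",
    "validate_score",
    "pooled_sd",
    "cohen_d_between",
    "cohen_d_within",
    "cohen_d_from_summary",
    "classify_change",
]

# admissible score ranges per questionnaire
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "ISI": (0, 28),
    "PSQI": (0, 21),
    "DBAS16": (0, 10),
    "HADS": (0, 21),
    "CESD": (0, 60),
}

ISI_MEANINGFUL_CHANGE = 8  # pre − post >= 8 is clinically meaningful
ISI_REMISSION_MAX = 7  # post <= 7 counts as remitted


def validate_score(scale: str, value: float) -> float:
    """Check a questionnaire score against its admissible range."""
    try:
        lo, hi = SCALE_RANGES[scale]
    except KeyError:
        raise KeyError(f"unknown scale {scale!r}; known: {sorted(SCALE_RANGES)}")
    if not lo <= value <= hi:
        raise ValueError(f"{scale} score {value} outside [{lo}, {hi}]")
    return value


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    ci95: Optional[tuple[float, float]]
    sd_pooled: float
    n1: Optional[int] = None
    n2: Optional[int] = None


def pooled_sd(a: Sequence[float], b: Sequence[float]) -> float:
    """SD pooled over two samples with (n−1) weights."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 values per sample")
    v = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return float(np.sqrt(v))


def _d_ci(d: float, n1: int, n2: int) -> tuple[float, float]:
    se = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2 - 2)))
    return (float(d - 1.96 * se), float(d + 1.96 * se))


def cohen_d_between(
    change_wl: Sequence[float], change_app: Sequence[float]
) -> EffectSizeResult:
    """d = (mean change waitlist − mean change app) / pooled change-score SD."""
    change_wl = np.asarray(change_wl, dtype=float)
    change_app = np.asarray(change_app, dtype=float)
    sd = pooled_sd(change_wl, change_app)
    if sd == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((change_wl.mean() - change_app.mean()) / sd)
    return EffectSizeResult(
        d=d,
        ci95=_d_ci(d, len(change_wl), len(change_app)),
        sd_pooled=sd,
        n1=len(change_wl),
        n2=len(change_app),
    )


def cohen_d_within(pre: Sequence[float], post: Sequence[float]) -> EffectSizeResult:
    """d = (mean pre − mean post) / SD pooled over the pre and post scores."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    sd = pooled_sd(pre, post)
    if sd == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((pre.mean() - post.mean()) / sd)
    return EffectSizeResult(
        d=d, ci95=_d_ci(d, len(pre), len(post)), sd_pooled=sd,
        n1=len(pre), n2=len(post),
    )


def cohen_d_from_summary(
    mean_pre: float, sd_pre: float, mean_post: float, sd_post: float,
    n_pre: Optional[int] = None, n_post: Optional[int] = None,
) -> EffectSizeResult:
    """Within-group d from summary statistics only.

    With equal (or unspecified) group sizes the pooled SD reduces to
    ``sqrt((sd_pre² + sd_post²)/2)``.
    """
    if n_pre is None or n_post is None or n_pre == n_post:
        sd = float(np.sqrt((sd_pre**2 + sd_post**2) / 2.0))
        ci = None
        if n_pre is not None:
            d0 = (mean_pre - mean_post) / sd
            ci = _d_ci(d0, n_pre, n_pre)
    else:
        v = ((n_pre - 1) * sd_pre**2 + (n_post - 1) * sd_post**2) / (
            n_pre + n_post - 2
        )
        sd = float(np.sqrt(v))
        ci = None
    if sd == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((mean_pre - mean_post) / sd)
    if ci is None and n_pre is not None and n_post is not None:
        ci = _d_ci(d, n_pre, n_post)
    return EffectSizeResult(d=d, ci95=ci, sd_pooled=sd, n1=n_pre, n2=n_post)


def classify_change(pre_isi: float, post_isi: float) -> dict:
    """Clinically meaningful change (ΔISI >= 8) and remission (post <= 7)."""
    validate_score("ISI", pre_isi)
    validate_score("ISI", post_isi)
    return {
        "meaningful_change": (pre_isi - post_isi) >= ISI_MEANINGFUL_CHANGE,
        "remitted": post_isi <= ISI_REMISSION_MAX,
    }
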