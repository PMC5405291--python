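"""Pearson chi-square tests for r x c contingency tables.

The statistic is the classical Pearson chi-square on observed vs expected
counts, *without* Yates continuity correction — this is the dialect that
reproduces standard trial reports' printed values on 2x2 tables — with
df = (r−1)(c−1).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2_contingency

__all__ = ["pearson_chi2"]


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Parameters
    ----------
    table
        r x c array of non-negative counts; no row or column may sum to 0.

    Returns
    -------
    (chi_square, df, p_value)
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    res = chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
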