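"""GRS-threshold enrichment analysis.

For a cutoff t, compare the HTG:control composition of the high-score
subgroup (GRS >= t) against the whole sample:

    relative_ratio = (a/b) / (A/B)

where a, b count HTG and control participants with GRS >= t and A, B are the
group totals.  A ratio of 1 means the subgroup mirrors the full sample; the
published headline is a 2.54-fold HTG enrichment at GRS >= 12.  Each cutoff
is accompanied by a 2x2 partition chi-square test — (GRS >= t vs < t) x
(HTG vs control) — reported with and without Yates continuity correction.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence

import numpy as np
from pydantic import BaseModel
from scipy import stats

from .errors import ContractError, DegenerateTableError
from .scoring import ScoreVector


class CutoffResult(BaseModel):
    """Counts and statistics at one GRS threshold.

    ``relative_ratio`` is null when the ratio is infinite (b = 0 < a) or
    undefined (a = b = 0); ``ratio_flag`` disambiguates.  Chi-square fields
    are null when the partition table has a zero margin.
    """

    threshold: float
    a: int  # HTG with GRS >= threshold
    b: int  # control with GRS >= threshold
    A: int  # total HTG
    B: int  # total control
    relative_ratio: Optional[float] = None
    ratio_flag: str = "ok"  # ok | infinite | undefined
    chi2_uncorrected: Optional[float] = None
    p_uncorrected: Optional[float] = None
    chi2_yates: Optional[float] = None
    p_yates: Optional[float] = None


def relative_ratio(a: int, b: int, A: int, B: int) -> float:
    """(a/b) / (A/B): enrichment of HTG over control above a score cutoff.

    Sentinels: returns ``math.inf`` when b = 0 with a > 0 and ``math.nan``
    when a = b = 0 (see :class:`CutoffResult` for the flagged form).
    """
    if A <= 0 or B <= 0:
        raise ContractError(f"group totals must be positive: A={A}, B={B}")
    if a < 0 or b < 0:
        raise ContractError("counts must be non-negative")
    if a > A or b > B:
        raise ContractError(f"subgroup exceeds total: a={a}>A={A} or b={b}>B={B}")
    if b == 0:
        return math.inf if a > 0 else math.nan
    return (a / b) / (A / B)


def _ratio_flag(a: int, b: int) -> str:
    if b == 0:
        return "infinite" if a > 0 else "undefined"
    return "ok"


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test (1 df) on a 2x2 count table.

    ``yates`` applies the continuity correction.  Both margins must be
    positive; a zero margin raises :class:`DegenerateTableError`.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ContractError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ContractError("counts must be non-negative")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise DegenerateTableError("2x2 table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(stat), float(p)


def cutoff_result(
    threshold: float, a: int, b: int, A: int, B: int
) -> CutoffResult:
    """Assemble a :class:`CutoffResult`, attaching both chi-square variants.

    The partition table is [[a, A-a], [b, B-b]] (rows HTG/control, columns
    GRS >= t / < t).
    """
    rr = relative_ratio(a, b, A, B)
    flag = _ratio_flag(a, b)
    res = CutoffResult(
        threshold=threshold,
        a=a,
        b=b,
        A=A,
        B=B,
        relative_ratio=rr if math.isfinite(rr) else None,
        ratio_flag=flag,
    )
    table = [[a, A - a], [b, B - b]]
    try:
        res.chi2_uncorrected, res.p_uncorrected = chi_square_2x2(table, yates=False)
        res.chi2_yates, res.p_yates = chi_square_2x2(table, yates=True)
    except DegenerateTableError:
        pass
    return res


def cutoff_scan(
    scores: ScoreVector,
    groups: Sequence[str],
    thresholds: Optional[Iterable[float]] = None,
) -> List[CutoffResult]:
    """One :class:`CutoffResult` per threshold (default: integers 0..max GRS).

    ``groups`` must be aligned with ``scores.participant_ids`` and contain
    both "HTG" and "control" labels; other labels are ignored.
    """
    g = np.asarray(groups, dtype=object)
    s = np.asarray(scores.scores, dtype=float)
    if len(g) != len(s):
        raise ContractError("groups not aligned to scores")
    htg = s[g == "HTG"]
    ctl = s[g == "control"]
    if len(htg) == 0 or len(ctl) == 0:
        raise ContractError("scan requires both HTG and control rows")
    if thresholds is None:
        thresholds = range(0, int(np.nanmax(s)) + 1)
    A, B = len(htg), len(ctl)
    out = []
    for t in thresholds:
        a = int((htg >= t).sum())
        b = int((ctl >= t).sum())
        out.append(cutoff_result(float(t), a, b, A, B))
    return out


def plot_cutoff_scan(results: Sequence[CutoffResult], ax=None):
    """Relative ratio vs threshold (enrichment-curve analogue); returns Axes."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 3.5))
    xs = [r.threshold for r in results if r.ratio_flag == "ok"]
    ys = [r.relative_ratio for r in results if r.ratio_flag == "ok"]
    ax.plot(xs, ys, marker="o")
    ax.axhline(1.0, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("GRS cutoff (risk alleles)")
    ax.set_ylabel("relative ratio HTG:control")
    return ax
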