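"""Scoring and descriptive statistics for the four-item Gaming Disorder Test.

The GDT is four Likert items (1 = never .. 5 = very often); the total ranges
4..20.  A respondent is classified as at risk of gaming disorder when every
item is answered 4 or 5, and at the scale floor when every item is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupStats",
    "score_gdt",
    "classify_at_risk",
    "at_floor",
    "cronbach_alpha",
    "two_sample_t",
    "pooled_mean",
    "descriptives",
]


@dataclass(frozen=True)
class GroupStats:
    """Summary triple for one subgroup (sample SD, n-1 denominator)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _validate_items(items: np.ndarray) -> np.ndarray:
    items = np.asarray(items)
    if not np.issubdtype(items.dtype, np.integer):
        as_int = np.asarray(items, dtype=float)
        if not np.all(as_int == np.rint(as_int)):
            raise ValueError("GDT items must be integers")
        items = as_int.astype(int)
    if items.shape[-1] != 4:
        raise ValueError("GDT has exactly 4 items")
    if ((items < 1) | (items > 5)).any():
        raise ValueError("GDT items must lie in 1..5")
    return items


def score_gdt(items) -> np.ndarray | int:
    """Sum of the four items; integer in [4, 20]."""
    arr = _validate_items(items)
    total = arr.sum(axis=-1)
    return int(total) if np.ndim(total) == 0 else total


def classify_at_risk(items) -> np.ndarray | bool:
    """True iff every item is 4 or 5."""
    arr = _validate_items(items)
    out = (arr >= 4).all(axis=-1)
    return bool(out) if np.ndim(out) == 0 else out


def at_floor(items) -> np.ndarray | bool:
    """True iff every item is 1 (the minimal attainable response pattern)."""
    arr = _validate_items(items)
    out = (arr == 1).all(axis=-1)
    return bool(out) if np.ndim(out) == 0 else out


def cronbach_alpha(item_matrix) -> float:
    """Internal consistency: alpha = k/(k-1) * (1 - sum(var_item)/var_total)."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def two_sample_t(
    stats_a: GroupStats, stats_b: GroupStats, variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; returns (t, df, two-sided p).

    ``student`` pools variances (df = nA + nB - 2); ``welch`` uses the
    Welch-Satterthwaite approximation.
    """
    equal_var = {"student": True, "welch": False}[variant]
    t, p = stats.ttest_ind_from_stats(
        stats_a.mean, stats_a.sd, stats_a.n, stats_b.mean, stats_b.sd, stats_b.n,
        equal_var=equal_var,
    )
    if equal_var:
        df = float(stats_a.n + stats_b.n - 2)
    else:
        va, vb = stats_a.sd**2 / stats_a.n, stats_b.sd**2 / stats_b.n
        df = (va + vb) ** 2 / (va**2 / (stats_a.n - 1) + vb**2 / (stats_b.n - 1))
    return float(t), float(df), float(p)


def pooled_mean(groups: Iterable[GroupStats]) -> float:
    """n-weighted combination of subgroup means."""
    groups = list(groups)
    if not groups:
        raise ValueError("need at least one group")
    n_total = sum(g.n for g in groups)
    return sum(g.n * g.mean for g in groups) / n_total


def descriptives(clean_df) -> dict:
    """Overall and by-gender GDT descriptives from a clean dataset.

    Expects columns gdt_1..gdt_4 and gender; reports mean, sample SD,
    Cronbach alpha, floor share, and at-risk share.
    """
    items = clean_df[[f"gdt_{i}" for i in range(1, 5)]].to_numpy()
    totals = score_gdt(items)
    out: dict = {
        "n": int(len(clean_df)),
        "gdt_mean": float(np.mean(totals)),
        "gdt_sd": float(np.std(totals, ddof=1)),
        "cronbach_alpha": cronbach_alpha(items),
        "floor_share": float(np.mean(at_floor(items))),
        "at_risk_share": float(np.mean(classify_at_risk(items))),
        "by_gender": {},
    }
    for g, sub in clean_df.groupby("gender"):
        sub_items = sub[[f"gdt_{i}" for i in range(1, 5)]].to_numpy()
        sub_tot = score_gdt(sub_items)
        if len(sub) >= 2:
            out["by_gender"][g] = {
                "n": int(len(sub)),
                "mean": float(np.mean(sub_tot)),
                "sd": float(np.std(sub_tot, ddof=1)),
            }
    if {"male", "female"} <= set(out["by_gender"]):
        a = GroupStats(**out["by_gender"]["male"])
        b = GroupStats(**out["by_gender"]["female"])
        t, df, p = two_sample_t(a, b)
        out["gender_t"] = {"t": t, "df": df, "p": p}
    return out
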