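"""Trial exclusion rules and category-wise exclusion accounting.

Four exclusion criteria are applied to the analyzed (non-practice) trials,
in a fixed precedence so that every excluded trial is counted in exactly
one category:

1. ``ke`` — kinematic error (action initiated with the wrong hand),
2. ``me`` — movement error (wrong or inaccurate end point),
3. ``rt_out_of_range`` — reaction time faster than ``rt_min_ms`` or slower
   than ``rt_max_ms`` (bounds exclusive; boundary values are retained),
4. ``mt_too_slow`` — movement time above ``mt_max_ms``, evaluated only for
   movements with a transport phase.

Error trials (KE, ME) are analyzed separately — by kinematic-error rates
and conditional accuracy functions — and removed from the chronometric
analyses of RT and MT.  Percentages are computed against all analyzed
trials, pooled over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .trials import TRANSPORT_MOVEMENTS

__all__ = [
    "CATEGORIES",
    "ExclusionCriteria",
    "ExclusionReport",
    "apply_exclusions",
    "exclusion_summary",
]

#: Exclusion categories in precedence order.
CATEGORIES = ("ke", "me", "rt_out_of_range", "mt_too_slow")


@dataclass(frozen=True)
class ExclusionCriteria:
    """Absolute cutoffs for trial exclusion (milliseconds)."""

    rt_min_ms: float = 100.0
    rt_max_ms: float = 2000.0
    mt_max_ms: float = 1200.0
    exclude_ke_from_rt: bool = True
    exclude_me_from_rt: bool = True

    def __post_init__(self):
        if not self.rt_min_ms < self.rt_max_ms:
            raise ValueError("rt_min_ms must be below rt_max_ms")
        if self.mt_max_ms <= 0:
            raise ValueError("mt_max_ms must be positive")


@dataclass
class ExclusionReport:
    """Counts and percentages of excluded trials, one category per trial."""

    n_total: int
    per_category: dict[str, tuple[int, float]] = field(default_factory=dict)

    @property
    def total_excluded(self) -> tuple[int, float]:
        count = sum(c for c, _ in self.per_category.values())
        pct = 100.0 * count / self.n_total if self.n_total else 0.0
        return count, pct


def apply_exclusions(table: pd.DataFrame,
                     criteria: ExclusionCriteria = ExclusionCriteria(),
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove trials matching any exclusion criterion.

    Returns the clean table (row order preserved) and an
    :class:`ExclusionReport` whose categories are mutually exclusive under
    the fixed precedence ke -> me -> rt_out_of_range -> mt_too_slow.
    Idempotent: applied to its own output it excludes nothing.
    """
    n = len(table)
    report = ExclusionReport(n_total=n)
    if n == 0:
        for cat in CATEGORIES:
            report.per_category[cat] = (0, 0.0)
        return table.copy(), report

    masks = {
        "ke": table["ke"].astype(bool) if criteria.exclude_ke_from_rt
        else pd.Series(False, index=table.index),
        "me": table["me"].astype(bool) if criteria.exclude_me_from_rt
        else pd.Series(False, index=table.index),
        "rt_out_of_range": (table["rt_ms"] < criteria.rt_min_ms)
        | (table["rt_ms"] > criteria.rt_max_ms),
        "mt_too_slow": table["movement"].isin(TRANSPORT_MOVEMENTS)
        & table["mt_ms"].notna() & (table["mt_ms"] > criteria.mt_max_ms),
    }
    taken = pd.Series(False, index=table.index)
    for cat in CATEGORIES:
        hit = masks[cat] & ~taken
        report.per_category[cat] = (int(hit.sum()), 100.0 * hit.sum() / n)
        taken |= hit
    return table.loc[~taken].copy(), report


def exclusion_summary(report: ExclusionReport, decimals: int = 2) -> pd.DataFrame:
    """Tabulate an exclusion report with rounded percentages plus a total row.

    The total percentage is computed from the raw counts (then rounded), so
    it equals the sum of the category percentages up to rounding.
    """
    rows = [
        {"category": cat, "count": cnt, "percentage": round(pct, decimals)}
        for cat, (cnt, pct) in report.per_category.items()
    ]
    tot_cnt, tot_pct = report.total_excluded
    rows.append({"category": "total", "count": tot_cnt,
                 "percentage": round(tot_pct, decimals)})
    return pd.DataFrame(rows, columns=["category", "count", "percentage"])
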