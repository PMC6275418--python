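"""Within-subject inference: repeated-measures ANOVA, contrasts, effect sizes.

All inference operates on subject x cell means (one observation per
subject per cell of a fully crossed within-subject design), the standard
summary-statistics approach that yields error degrees of freedom
``df2 = (n_subjects - 1) * df1``.  With all factors at two levels —
the designs supported here — sphericity holds trivially and no
correction is applied.

Effect size is partial eta squared,
``eta_p^2 = SS_effect / (SS_effect + SS_error) = F*df1 / (F*df1 + df2)``.

Kinematic-error rates are typically right-skewed; :func:`sqrt_transform`
applies the square-root transform to subject-level proportions before
they enter an ANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTable",
    "ContrastResult",
    "cell_means",
    "sqrt_transform",
    "rm_anova",
    "partial_eta_sq",
    "planned_contrast",
    "bonferroni",
]

#: Alias: rm_anova returns a plain DataFrame with these columns.
ANOVA_COLUMNS = ["effect", "F", "df1", "df2", "p", "eta_p2", "degenerate"]
AnovaTable = pd.DataFrame


@dataclass
class ContrastResult:
    """A planned paired comparison of weighted cell means across subjects."""

    estimate: float
    t: float
    df: int
    p: float
    family_size: int = 1
    adjusted_p: float | None = None
    degenerate: bool = False


def cell_means(table: pd.DataFrame, factors: list[str] | tuple[str, ...],
               response: str = "rt_ms", subject: str = "subject_id",
               ) -> pd.DataFrame:
    """One mean per subject per design cell.

    ``response`` may be any numeric column, or ``"ke_rate"`` / ``"me_rate"``
    for the proportion of flagged trials.  Every subject must contribute to
    every cell of the crossed design; a missing cell raises, naming the
    subject and cell (no imputation).
    """
    factors = list(factors)
    df = table.copy()
    if response in ("ke_rate", "me_rate"):
        df["_resp"] = df[response[:2]].astype(bool).astype(float)
    else:
        df["_resp"] = pd.to_numeric(df[response])
    means = (df.groupby([subject, *factors], sort=True, observed=True)["_resp"]
             .mean().rename(response).reset_index())
    subjects = means[subject].unique()
    cells = [tuple(levels) for levels in itertools.product(
        *[sorted(means[f].unique()) for f in factors])]
    have = set(map(tuple, means[[subject, *factors]].itertuples(index=False)))
    missing = [(s, c) for s in subjects for c in cells if (s, *c) not in have]
    if missing:
        desc = "; ".join(f"subject {s}: cell {c}" for s, c in missing[:10])
        raise ValueError(f"incomplete design, missing {len(missing)} "
                         f"subject x cell mean(s): {desc}")
    return means


def sqrt_transform(rate):
    """Square root of a proportion in [0, 1] (variance-stabilizing, monotone)."""
    arr = np.asarray(rate, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("rates must lie in [0, 1]")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(rate) or arr.ndim == 0 else out


def _effect_label(factors: tuple[str, ...]) -> str:
    return ":".join(factors)


def rm_anova(data: pd.DataFrame, dv: str, within: list[str] | tuple[str, ...],
             subject: str = "subject_id") -> AnovaTable:
    """Fully within-subject factorial ANOVA on subject x cell means.

    Sums of squares are computed by the balanced-design decomposition:
    for each effect, the cell-mean array is averaged over the factors not
    in the effect, mean-centered along each involved factor, and split
    into its across-subject mean (effect SS) and per-subject residual
    (the effect-by-subject error SS).  ``F = MS_effect / MS_error`` with
    ``df1 = prod(levels - 1)`` and ``df2 = (n - 1) * df1``.

    Degenerate cells are flagged rather than left to numeric noise: a
    zero error SS with a nonzero effect SS yields ``F = inf`` with
    ``degenerate=True``; a zero effect SS yields ``F = 0, p = 1``.

    Returns a DataFrame with columns ``effect, F, df1, df2, p, eta_p2,
    degenerate``; ``eta_p2`` is ``SS_effect / (SS_effect + SS_error)``.
    """
    within = list(within)
    if not within:
        raise ValueError("at least one within-subject factor is required")
    levels = {f: sorted(data[f].unique()) for f in within}
    for f, lv in levels.items():
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")

    pivot = data.pivot_table(index=subject, columns=within, values=dv,
                             aggfunc="mean", observed=True)
    full = pd.MultiIndex.from_product([levels[f] for f in within],
                                      names=within) if len(within) > 1 \
        else pd.Index(levels[within[0]], name=within[0])
    pivot = pivot.reindex(columns=full)
    if pivot.isna().any().any():
        missing = [(s, c) for s in pivot.index for c in pivot.columns
                   if pd.isna(pivot.loc[s, c])]
        raise ValueError(f"incomplete subject x cell grid: {missing[:10]}")
    n = len(pivot)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    shape = (n, *[len(levels[f]) for f in within])
    Y = pivot.to_numpy().reshape(shape)
    scale = max(1.0, float(np.abs(Y).max()) ** 2)
    tiny = 1e-10 * scale

    rows = []
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), k):
            keep_axes = tuple(c + 1 for c in combo)
            drop_axes = tuple(ax for ax in range(1, len(within) + 1)
                              if ax not in keep_axes)
            Z = Y.mean(axis=drop_axes) if drop_axes else Y.copy()
            for ax in range(1, Z.ndim):
                Z = Z - Z.mean(axis=ax, keepdims=True)
            M = Z.mean(axis=0)
            mult = float(np.prod([shape[ax] for ax in drop_axes])) if drop_axes else 1.0
            ss_eff = n * mult * float((M ** 2).sum())
            ss_err = mult * float(((Z - M) ** 2).sum())
            df1 = int(np.prod([len(levels[within[c]]) - 1 for c in combo]))
            df2 = (n - 1) * df1
            degenerate = False
            if ss_eff <= tiny:
                F, p = 0.0, 1.0
            elif ss_err <= tiny:
                F, p, degenerate = math.inf, 0.0, True
            else:
                F = (ss_eff / df1) / (ss_err / df2)
                p = float(stats.f.sf(F, df1, df2))
            eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            rows.append({"effect": _effect_label(tuple(within[c] for c in combo)),
                         "F": F, "df1": df1, "df2": df2, "p": p,
                         "eta_p2": eta, "degenerate": degenerate})
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def partial_eta_sq(F, df1, df2):
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    F = np.asarray(F, dtype=float)
    df1 = np.asarray(df1, dtype=float)
    df2 = np.asarray(df2, dtype=float)
    if np.any(F < 0) or np.any(df1 < 1) or np.any(df2 < 1):
        raise ValueError("require F >= 0 and df1, df2 >= 1")
    out = (F * df1) / (F * df1 + df2)
    return float(out) if out.ndim == 0 else out


def planned_contrast(means: pd.DataFrame, weights: dict,
                     dv: str, within: list[str] | tuple[str, ...],
                     subject: str = "subject_id") -> ContrastResult:
    """Paired contrast of weighted cell means across subjects.

    ``weights`` maps cell keys (a level, or a tuple of levels in ``within``
    order) to contrast weights summing to zero.  The per-subject score
    ``sum_c w_c * mean_c`` is tested against zero with a one-sample
    (paired) t test; the estimate is in the units of the response.

    With zero between-subject variance the t statistic is undefined: a
    uniformly zero score gives ``p = 1``; a constant nonzero score is
    flagged ``degenerate`` with an undefined p.
    """
    within = list(within)
    wsum = sum(weights.values())
    if abs(wsum) > 1e-12:
        raise ValueError(f"contrast weights must sum to 0 (got {wsum})")
    pivot = means.pivot_table(index=subject, columns=within, values=dv,
                              aggfunc="mean", observed=True)
    scores = np.zeros(len(pivot))
    for key, w in weights.items():
        if not isinstance(key, tuple):
            key = (key,)
        col = key if len(within) > 1 else key[0]
        if col not in pivot.columns:
            raise KeyError(f"cell {key} not present in the design")
        cell = pivot[col].to_numpy(dtype=float)
        if np.isnan(cell).any():
            raise ValueError(f"cell {key} missing for some subject(s)")
        scores = scores + w * cell
    n = len(scores)
    estimate = float(scores.mean())
    sd = float(scores.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        if estimate == 0.0:
            return ContrastResult(estimate=0.0, t=0.0, df=n - 1, p=1.0)
        return ContrastResult(estimate=estimate, t=math.inf, df=n - 1,
                              p=math.nan, degenerate=True)
    t = estimate / (sd / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return ContrastResult(estimate=estimate, t=float(t), df=n - 1, p=p)


def bonferroni(p_values, family_size: int | None = None):
    """Bonferroni adjustment: ``min(1, p * family_size)`` per p value."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    if m < p.size:
        raise ValueError("family_size must be >= the number of p values")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out
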