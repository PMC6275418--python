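"""Distributional analysis of the Simon effect: delta-plots and CAFs.

The Simon effect is the reaction-time cost of an irrelevant stimulus
location that conflicts with the responding side: mean incongruent RT
minus mean congruent RT.  Beyond the mean effect, the activation-
suppression account makes predictions about how the effect evolves across
the RT distribution, which this module estimates with two standard
chronometric tools:

* **Delta-plots** — per subject, correct-trial RTs of each congruence
  level are rank ordered and divided into ``n_bins`` quantile bins
  (quartiles by default).  The effect in bin *b* is the difference of the
  incongruent and congruent bin means, plotted against the midpoint of
  the two bin means.  The slope of the final segment (Q3-Q4) indexes the
  build-up of selective response suppression: the more negative, the more
  effective the late suppression.  Bin statistics are averaged over
  subjects (Vincentizing).

* **Conditional accuracy functions (CAF)** — all incongruent trials,
  including kinematic errors (KE), are binned by RT per subject; the
  accuracy of each bin is the proportion of non-KE trials.  A dip in the
  fastest bins is the signature of impulsive "fast errors" driven by the
  automatic location-based response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExclusionCriteria

__all__ = [
    "BinAssignment",
    "DeltaPlot",
    "SlopeResult",
    "CAF",
    "bin_quartiles",
    "simon_summary",
    "delta_plot",
    "segment_slope",
    "conditional_accuracy",
    "select_caf_trials",
]

logger = logging.getLogger("simondelta")

DEFAULT_CELLS = ("selection_mode", "movement")


@dataclass
class BinAssignment:
    """Partition of one subject x condition cell into RT quantile bins."""

    n_bins: int
    bin_of_trial: pd.Series  # index: trial labels, values: bin 1..n_bins
    bin_counts: list[int]


@dataclass
class DeltaPlot:
    """Per-subject and group delta-plot points.

    ``per_subject`` columns: subject_id, cell columns, bin, rt_congruent,
    rt_incongruent, delta_ms (incongruent - congruent) and x_ms (midpoint
    of the two bin means).  ``group`` holds the across-subject mean and
    standard error of delta and x per bin.
    """

    n_bins: int
    cell_cols: tuple[str, ...]
    per_subject: pd.DataFrame
    group: pd.DataFrame


@dataclass
class SlopeResult:
    """Segment slopes of a delta-plot, per subject and aggregated."""

    i: int
    j: int
    per_subject: pd.DataFrame  # subject_id, cells, slope
    group: pd.DataFrame  # cells, slope_mean, slope_se, slope_of_group_means, n


@dataclass
class CAF:
    """Conditional accuracy function over incongruent trials (incl. KE)."""

    n_bins: int
    cell_cols: tuple[str, ...]
    per_subject: pd.DataFrame  # subject_id, cells, bin, accuracy, n_trials
    group: pd.DataFrame  # cells, bin, accuracy_mean, accuracy_se, n_subjects


def bin_quartiles(cell: pd.DataFrame, n_bins: int = 4) -> BinAssignment:
    """Assign the trials of one subject x condition cell to RT quantile bins.

    Trials are sorted stably by ``(rt_ms, trial_index)`` — ties broken by
    trial order, for determinism — and the trial at sorted position ``i``
    (0-based, ``n`` trials) goes to bin ``floor(i * n_bins / n) + 1``.
    Bin counts therefore differ by at most one.

    Parameters
    ----------
    cell
        DataFrame with columns ``rt_ms`` and ``trial_index``; the index
        labels identify trials.
    n_bins
        Number of quantile bins (>= 2); quartiles by default.
    """
    n = len(cell)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < n_bins:
        raise ValueError(
            f"cannot form {n_bins} bins from {n} trials "
            f"(cell index {cell.index.tolist()})")
    order = np.lexsort((cell["trial_index"].to_numpy(),
                        cell["rt_ms"].to_numpy()))
    bins = np.empty(n, dtype=int)
    bins[order] = np.arange(n) * n_bins // n + 1
    assignment = pd.Series(bins, index=cell.index, name="bin")
    counts = [int((bins == b).sum()) for b in range(1, n_bins + 1)]
    return BinAssignment(n_bins=n_bins, bin_of_trial=assignment,
                         bin_counts=counts)


def _two_stage_mean(df: pd.DataFrame, value: str = "rt_ms") -> tuple[float, int]:
    """Mean over trials within subject, then unweighted over subjects."""
    per_subject = df.groupby("subject_id", sort=True)[value].mean()
    return float(per_subject.mean()), int(per_subject.size)


def simon_summary(clean: pd.DataFrame,
                  grouping: tuple[str, ...] | list[str] | None = None,
                  ) -> pd.DataFrame:
    """Mean RT per congruence level and the Simon effect, per cell.

    Means are taken over trials within each subject first, then unweighted
    over subjects, so every subject contributes equally.  A subject
    missing either congruence level in a cell is dropped from that cell
    with a logged warning; a cell left without subjects has an undefined
    (NaN) effect.

    Returns a DataFrame with the grouping columns plus
    ``mean_rt_congruent``, ``mean_rt_incongruent``, ``effect_ms``
    (incongruent - congruent) and ``n_subjects``.
    """
    grouping = list(grouping) if grouping else []
    rows = []
    for key, cell in _iter_cells(clean, grouping):
        wide = (cell.groupby(["subject_id", "congruence"])["rt_ms"].mean()
                .unstack("congruence"))
        for level in ("congruent", "incongruent"):
            if level not in wide.columns:
                wide[level] = np.nan
        incomplete = wide["congruent"].isna() | wide["incongruent"].isna()
        if incomplete.any():
            logger.warning("simon_summary: dropped subject(s) %s from cell %s "
                           "(missing a congruence level)",
                           list(wide.index[incomplete]), key or "overall")
        wide = wide.loc[~incomplete]
        con = float(wide["congruent"].mean()) if len(wide) else np.nan
        inc = float(wide["incongruent"].mean()) if len(wide) else np.nan
        rows.append({**dict(zip(grouping, key)),
                     "mean_rt_congruent": con,
                     "mean_rt_incongruent": inc,
                     "effect_ms": inc - con,
                     "n_subjects": len(wide)})
    return pd.DataFrame(rows)


def _iter_cells(df: pd.DataFrame, cols: list[str]):
    if not cols:
        yield (), df
        return
    for key, sub in df.groupby(cols, sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        yield key, sub


def _se(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return np.nan
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def delta_plot(clean: pd.DataFrame, n_bins: int = 4,
               cell_cols: tuple[str, ...] | list[str] = DEFAULT_CELLS,
               scope: str = "per_subject") -> DeltaPlot:
    """Construct delta-plots from correct trials (KE/ME already excluded).

    Bins are built per subject, separately within each congruence level of
    each cell, so that subject-level bin means, deltas and slopes exist
    for repeated-measures inference.  With ``scope="pooled"``, bins are
    instead built on the trials of all subjects pooled (the group frame is
    then the only output) — provided for comparison with pooled-binning
    conventions.

    Subjects with fewer than ``n_bins`` trials in either congruence level
    of a cell are dropped from that cell with a logged warning.
    """
    cell_cols = tuple(c for c in cell_cols if c in clean.columns)
    if scope not in ("per_subject", "pooled"):
        raise ValueError("scope must be 'per_subject' or 'pooled'")

    if scope == "pooled":
        rows = []
        for key, cell in _iter_cells(clean, list(cell_cols)):
            means = {}
            ok = True
            for level in ("congruent", "incongruent"):
                sub = cell[cell["congruence"] == level]
                if len(sub) < n_bins:
                    logger.warning("delta_plot(pooled): cell %s lacks %s trials",
                                   key, level)
                    ok = False
                    break
                ba = bin_quartiles(sub, n_bins)
                means[level] = sub["rt_ms"].groupby(ba.bin_of_trial).mean()
            if not ok:
                continue
            for b in range(1, n_bins + 1):
                con, inc = means["congruent"][b], means["incongruent"][b]
                rows.append({**dict(zip(cell_cols, key)), "bin": b,
                             "x_mean": (con + inc) / 2.0, "x_se": np.nan,
                             "delta_mean": inc - con, "delta_se": np.nan,
                             "n_subjects": clean["subject_id"].nunique()})
        group = pd.DataFrame(rows)
        per_subject = pd.DataFrame(
            columns=["subject_id", *cell_cols, "bin", "rt_congruent",
                     "rt_incongruent", "delta_ms", "x_ms"])
        return DeltaPlot(n_bins, cell_cols, per_subject, group)

    ps_rows = []
    for key, cell in _iter_cells(clean, list(cell_cols)):
        for subject, sub in cell.groupby("subject_id", sort=True):
            bin_means = {}
            ok = True
            for level in ("congruent", "incongruent"):
                trials = sub[sub["congruence"] == level]
                if len(trials) < n_bins:
                    logger.warning(
                        "delta_plot: subject %s dropped from cell %s "
                        "(%d %s trials < %d bins)",
                        subject, key or "overall", len(trials), level, n_bins)
                    ok = False
                    break
                ba = bin_quartiles(trials, n_bins)
                bin_means[level] = trials["rt_ms"].groupby(ba.bin_of_trial).mean()
            if not ok:
                continue
            for b in range(1, n_bins + 1):
                con = float(bin_means["congruent"][b])
                inc = float(bin_means["incongruent"][b])
                ps_rows.append({"subject_id": subject,
                                **dict(zip(cell_cols, key)), "bin": b,
                                "rt_congruent": con, "rt_incongruent": inc,
                                "delta_ms": inc - con,
                                "x_ms": (con + inc) / 2.0})
    per_subject = pd.DataFrame(
        ps_rows, columns=["subject_id", *cell_cols, "bin", "rt_congruent",
                          "rt_incongruent", "delta_ms", "x_ms"])
    g_rows = []
    if len(per_subject):
        for key, sub in _iter_cells(per_subject, [*cell_cols, "bin"]):
            *cell_key, b = key
            g_rows.append({**dict(zip(cell_cols, cell_key)), "bin": b,
                           "x_mean": float(sub["x_ms"].mean()),
                           "x_se": _se(sub["x_ms"].to_numpy()),
                           "delta_mean": float(sub["delta_ms"].mean()),
                           "delta_se": _se(sub["delta_ms"].to_numpy()),
                           "n_subjects": len(sub)})
    group = pd.DataFrame(
        g_rows, columns=[*cell_cols, "bin", "x_mean", "x_se", "delta_mean",
                         "delta_se", "n_subjects"])
    return DeltaPlot(n_bins, cell_cols, per_subject, group)


def segment_slope(dp: DeltaPlot, i: int = 3, j: int = 4) -> SlopeResult:
    """Slope of the delta-plot segment connecting bins ``i`` and ``j``.

    ``slope = (delta(j) - delta(i)) / (x(j) - x(i))`` per subject
    (dimensionless, ms/ms).  The group frame reports the mean of the
    per-subject slopes (primary) and, for comparison, the slope of the
    group-mean delta points.  Subjects with ``x(i) == x(j)`` are excluded
    with a logged warning.
    """
    if not (1 <= i < j <= dp.n_bins):
        raise ValueError(f"need 1 <= i < j <= n_bins, got i={i}, j={j}")
    cells = list(dp.cell_cols)
    ps_rows = []
    for key, sub in _iter_cells(dp.per_subject, ["subject_id", *cells]):
        subject, *cell_key = key
        pts = sub.set_index("bin")
        if i not in pts.index or j not in pts.index:
            continue
        dx = float(pts.loc[j, "x_ms"] - pts.loc[i, "x_ms"])
        if dx == 0.0:
            logger.warning("segment_slope: subject %s cell %s has x(%d)==x(%d); "
                           "slope undefined, subject excluded",
                           subject, tuple(cell_key), i, j)
            continue
        slope = float(pts.loc[j, "delta_ms"] - pts.loc[i, "delta_ms"]) / dx
        ps_rows.append({"subject_id": subject,
                        **dict(zip(cells, cell_key)), "slope": slope})
    per_subject = pd.DataFrame(ps_rows, columns=["subject_id", *cells, "slope"])

    g_rows = []
    for key, sub in _iter_cells(per_subject, cells):
        gm = np.nan
        if len(dp.group):
            gcell = dp.group
            for col, val in zip(cells, key):
                gcell = gcell[gcell[col] == val]
            gpts = gcell.set_index("bin")
            if i in gpts.index and j in gpts.index:
                gdx = float(gpts.loc[j, "x_mean"] - gpts.loc[i, "x_mean"])
                if gdx != 0.0:
                    gm = float(gpts.loc[j, "delta_mean"]
                               - gpts.loc[i, "delta_mean"]) / gdx
        g_rows.append({**dict(zip(cells, key)),
                       "slope_mean": float(sub["slope"].mean()),
                       "slope_se": _se(sub["slope"].to_numpy()),
                       "slope_of_group_means": gm,
                       "n_subjects": len(sub)})
    group = pd.DataFrame(
        g_rows, columns=[*cells, "slope_mean", "slope_se",
                         "slope_of_group_means", "n_subjects"])
    return SlopeResult(i=i, j=j, per_subject=per_subject, group=group)


def select_caf_trials(table: pd.DataFrame,
                      criteria: ExclusionCriteria = ExclusionCriteria(),
                      ) -> pd.DataFrame:
    """Incongruent trials entering the CAF: correct and KE trials pooled.

    Movement errors and RT-range outliers are removed (the CAF accuracy
    contrasts correct initiation against kinematic errors only), but KE
    trials are retained — they are the quantity of interest.
    """
    keep = ((table["congruence"] == "incongruent")
            & ~table["me"].astype(bool)
            & (table["rt_ms"] >= criteria.rt_min_ms)
            & (table["rt_ms"] <= criteria.rt_max_ms))
    return table.loc[keep].copy()


def conditional_accuracy(incongruent: pd.DataFrame, n_bins: int = 4,
                         cell_cols: tuple[str, ...] | list[str] = DEFAULT_CELLS,
                         ) -> CAF:
    """Conditional accuracy function per subject and cell.

    ``incongruent`` must contain the incongruent trials of the analyzed
    conditions with the ``ke`` flag set (see :func:`select_caf_trials`).
    Bins are built per subject on all incongruent RTs; the accuracy of bin
    *b* is ``correct / (correct + KE)`` within the bin.  Subjects with
    fewer than ``n_bins`` incongruent trials in a cell are dropped with a
    logged warning.
    """
    if len(incongruent) == 0:
        raise ValueError("no incongruent trials supplied")
    if (incongruent["congruence"] != "incongruent").any():
        raise ValueError("conditional_accuracy expects incongruent trials only")
    cell_cols = tuple(c for c in cell_cols if c in incongruent.columns)
    ps_rows = []
    for key, cell in _iter_cells(incongruent, list(cell_cols)):
        for subject, sub in cell.groupby("subject_id", sort=True):
            if len(sub) < n_bins:
                logger.warning("conditional_accuracy: subject %s dropped from "
                               "cell %s (%d trials < %d bins)",
                               subject, key or "overall", len(sub), n_bins)
                continue
            ba = bin_quartiles(sub, n_bins)
            ke = sub["ke"].astype(bool).groupby(ba.bin_of_trial)
            for b, grp in ke:
                ps_rows.append({"subject_id": subject,
                                **dict(zip(cell_cols, key)), "bin": int(b),
                                "accuracy": 1.0 - float(grp.mean()),
                                "n_trials": int(grp.size)})
    per_subject = pd.DataFrame(
        ps_rows, columns=["subject_id", *cell_cols, "bin", "accuracy",
                          "n_trials"])
    g_rows = []
    for key, sub in _iter_cells(per_subject, [*cell_cols, "bin"]):
        *cell_key, b = key
        g_rows.append({**dict(zip(cell_cols, cell_key)), "bin": b,
                       "accuracy_mean": float(sub["accuracy"].mean()),
                       "accuracy_se": _se(sub["accuracy"].to_numpy()),
                       "n_subjects": len(sub)})
    group = pd.DataFrame(
        g_rows, columns=[*cell_cols, "bin", "accuracy_mean", "accuracy_se",
                         "n_subjects"])
    return CAF(n_bins=n_bins, cell_cols=cell_cols, per_subject=per_subject,
               group=group)
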