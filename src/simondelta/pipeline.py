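"""End-to-end runs: simulate/load -> exclude -> distributional -> inference.

One :class:`RunConfig` drives a full analysis.  The output directory
receives tidy CSVs for every stage (exclusions, Simon summaries,
delta-plot points, segment slopes, CAFs, ANOVA tables, contrasts),
delta-plot and CAF figures, a run log, and a manifest recording the
config and seed so a rerun is numerically identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import __version__
from .distributional import (
    conditional_accuracy,
    delta_plot,
    segment_slope,
    select_caf_trials,
    simon_summary,
)
from .inferential import bonferroni, cell_means, planned_contrast, rm_anova, sqrt_transform
from .preprocess import ExclusionCriteria, apply_exclusions, exclusion_summary
from .simulate import PRESET_NAMES, preset, simulate_experiment
from .trials import read_trials, validate_trials, write_trials

__all__ = ["RunConfig", "run_pipeline", "render_figures"]

logger = logging.getLogger("simondelta")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a trial CSV) or ``preset_name`` (a
    generator regime) must be set.
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    preset_name: str | None = None
    criteria: ExclusionCriteria = ExclusionCriteria()
    n_bins: int = 4
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self):
        if (self.input_path is None) == (self.preset_name is None):
            raise ValueError("set exactly one of input_path or preset_name")
        if self.preset_name is not None and self.preset_name not in PRESET_NAMES:
            raise ValueError(f"unknown preset {self.preset_name!r}")


def _factors_for(table: pd.DataFrame) -> list[str]:
    """Within-subject design columns that actually vary in this table."""
    return [c for c in ("selection_mode", "movement")
            if table[c].nunique() > 1]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict of the in-memory results (tables keyed by the CSV
    names written to ``out_dir``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {}
    try:
        if config.preset_name is not None:
            gen = preset(config.preset_name, seed=config.seed)
            table, truth = simulate_experiment(gen)
            write_trials(table, out / "trials.csv")
            with open(out / "truth.yaml", "w") as fh:
                yaml.safe_dump(truth, fh, sort_keys=True)
        else:
            table, parse_report = read_trials(config.input_path)
            if not parse_report.ok:
                raise ValueError(f"input table has {len(parse_report.problems)} "
                                 f"parse problem(s): {parse_report.problems[:5]}")
        if len(table) == 0:
            raise ValueError("input table contains no trials")
        vreport = validate_trials(table)
        if not vreport.ok:
            raise ValueError(f"input table violates trial invariants: "
                             f"{vreport.problems[:5]}")

        clean, excl = apply_exclusions(table, config.criteria)
        results["exclusions.csv"] = exclusion_summary(excl)

        factors = _factors_for(table)
        results["simon_summary.csv"] = simon_summary(clean, grouping=factors)
        results["simon_overall.csv"] = simon_summary(clean)

        dp = delta_plot(clean, n_bins=config.n_bins)
        results["deltaplot_subject.csv"] = dp.per_subject
        results["deltaplot_group.csv"] = dp.group
        slopes = segment_slope(dp, config.n_bins - 1, config.n_bins)
        results["slopes_subject.csv"] = slopes.per_subject
        results["slopes_group.csv"] = slopes.group

        caf = conditional_accuracy(select_caf_trials(table, config.criteria),
                                   n_bins=config.n_bins)
        results["caf_subject.csv"] = caf.per_subject
        results["caf_group.csv"] = caf.group

        # Inference layer: mean RT, sqrt-transformed KE rate, Q3-Q4 slope,
        # and the fast-bin (Q1 vs Q2) CAF comparison with Bonferroni
        # adjustment, each on subject x cell means.
        anovas = {}
        if factors:
            rt_means = cell_means(clean, [*factors, "congruence"], "rt_ms")
            anovas["anova_rt.csv"] = rm_anova(rt_means, "rt_ms",
                                              [*factors, "congruence"])
            ke_means = cell_means(table, [*factors, "congruence"], "ke_rate")
            ke_means["sqrt_ke_rate"] = sqrt_transform(
                ke_means["ke_rate"].to_numpy())
            anovas["anova_ke.csv"] = rm_anova(ke_means, "sqrt_ke_rate",
                                              [*factors, "congruence"])
            try:
                anovas["anova_slope.csv"] = rm_anova(
                    slopes.per_subject, "slope", factors)
            except ValueError as err:
                logger.warning("slope ANOVA skipped: %s", err)
        fast = caf.per_subject[caf.per_subject["bin"].isin([1, 2])].copy()
        fast["bin"] = fast["bin"].astype(str)
        try:
            anovas["anova_caf.csv"] = rm_anova(fast, "accuracy",
                                               [*factors, "bin"])
        except ValueError as err:
            logger.warning("CAF ANOVA skipped: %s", err)
        results.update(anovas)

        contrast_rows = []
        try:
            c12 = planned_contrast(fast, {"1": 1.0, "2": -1.0},
                                   "accuracy", ["bin"])
            contrast_rows.append({
                "contrast": "caf_q1_minus_q2", "estimate": c12.estimate,
                "t": c12.t, "df": c12.df, "p": c12.p,
                "adjusted_p": bonferroni(c12.p, 2) if c12.p == c12.p else None,
                "family_size": 2, "degenerate": c12.degenerate})
        except (ValueError, KeyError) as err:
            logger.warning("CAF Q1-Q2 contrast skipped: %s", err)
        results["contrasts.csv"] = pd.DataFrame(
            contrast_rows, columns=["contrast", "estimate", "t", "df", "p",
                                    "adjusted_p", "family_size", "degenerate"])

        for name, frame in results.items():
            frame.to_csv(out / name, index=False)

        if config.make_figures:
            render_figures(results, out)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_bins": config.n_bins,
            "preset": config.preset_name,
            "input_path": str(config.input_path) if config.input_path else None,
            "criteria": dataclasses.asdict(config.criteria),
            "outputs": {
                name: hashlib.sha256(
                    (out / name).read_bytes()).hexdigest()
                for name in sorted(results)
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest"] = manifest
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()


def render_figures(results: dict, out_dir: str | Path) -> list[Path]:
    """Delta-plot and CAF figures with standard-error bars.

    One series per movement (and selection mode, if present), bins on the
    x-axis; error bars are suppressed when only one subject contributed.
    Missing tables are skipped with a warning.
    """
    out = Path(out_dir)
    made: list[Path] = []
    specs = [
        ("deltaplot_group.csv", "x_mean", "delta_mean", "delta_se",
         "Simon effect (ms)", "mean RT (ms)", "deltaplot.png"),
        ("caf_group.csv", "bin", "accuracy_mean", "accuracy_se",
         "accuracy", "RT bin", "caf.png"),
    ]
    for name, xcol, ycol, secol, ylabel, xlabel, fname in specs:
        frame = results.get(name)
        if frame is None or len(frame) == 0:
            logger.warning("render_figures: table %s missing or empty; skipped",
                           name)
            continue
        series_cols = [c for c in ("selection_mode", "movement")
                       if c in frame.columns and frame[c].nunique() >= 1]
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = frame.groupby(series_cols, observed=True) if series_cols \
            else [((), frame)]
        for key, sub in groups:
            if not isinstance(key, tuple):
                key = (key,)
            label = " ".join(str(k) for k in key) or "all"
            sub = sub.sort_values("bin")
            err = sub[secol] if sub["n_subjects"].min() > 1 else None
            ax.errorbar(sub[xcol], sub[ycol], yerr=err, marker="o",
                        capsize=3, label=label)
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    return made
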