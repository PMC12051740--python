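"""Group-comparison statistics and the summary report over features.

Normal-vs-cancer comparisons use the unpaired two-tailed Welch t-test
(Satterthwaite degrees of freedom); within-line comparisons across days
use one-way ANOVA followed by a post-hoc procedure (Tukey HSD by default,
Bonferroni-adjusted pairwise Welch tests as an alternative).  Error bars
throughout are the standard error of the mean (SD/sqrt(n)).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import MechSpheroidError, UndefinedStatisticError

log = logging.getLogger("mechspheroid")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Unpaired two-tailed Welch's t-test.

    Requires n >= 2 per sample and nonzero variance in at least one.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise MechSpheroidError("Welch test needs n >= 2 in each sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise UndefinedStatisticError(
            "Welch test undefined: both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_adjusted


def one_way_anova_posthoc(groups, method: str = "tukey") -> AnovaResult:
    """One-way ANOVA across >= 3 groups with pairwise post-hoc p-values.

    ``groups`` is a sequence of samples (or a dict name -> sample).
    ``method`` is 'tukey' (Tukey HSD) or 'bonferroni' (pairwise Welch
    tests with Bonferroni adjustment).
    """
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[n], dtype=float).ravel() for n in names]
    else:
        samples = [np.asarray(g, dtype=float).ravel() for g in groups]
        names = list(range(len(samples)))
    if len(samples) < 3:
        raise MechSpheroidError("ANOVA post-hoc requires >= 3 groups")
    for name, s in zip(names, samples):
        if s.size < 2:
            raise MechSpheroidError(f"group {name!r} has fewer than 2 values")
    if all(s.var(ddof=1) == 0 for s in samples):
        raise UndefinedStatisticError("all groups degenerate (zero variance)")

    F, p = stats.f_oneway(*samples)
    pairs = list(itertools.combinations(range(len(samples)), 2))
    if method == "tukey":
        tukey = stats.tukey_hsd(*samples)
        rows = [{"group_a": names[i], "group_b": names[j],
                 "p_adjusted": float(tukey.pvalue[i, j])} for i, j in pairs]
    elif method == "bonferroni":
        m = len(pairs)
        rows = []
        for i, j in pairs:
            raw = welch_t_test(samples[i], samples[j]).p
            rows.append({"group_a": names[i], "group_b": names[j],
                         "p_adjusted": min(1.0, raw * m)})
    else:
        raise MechSpheroidError(f"unknown post-hoc method {method!r}")
    return AnovaResult(F=float(F), p=float(p), pairwise=pd.DataFrame(rows))


def group_summary(values) -> dict:
    """n, mean and SEM (SD/sqrt(n), sample SD) of one group."""
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n == 0:
        raise MechSpheroidError("empty group")
    sem = float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return {"n": n, "mean": float(x.mean()), "sem": sem}


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_WHOLE_METRICS = ["mean_shift", "sd_shift", "skewness"]
_ZONE_METRICS = {"core": ["core_mean", "core_sd", "core_skew"],
                 "periphery": ["peri_mean", "peri_sd", "peri_skew"]}


def build_report(features: pd.DataFrame, out_dir=None,
                 posthoc: str = "tukey") -> dict:
    """Per-day, per-line, per-zone summary of the mechanical features.

    Returns a dict with three tables:

    * ``summary`` — mean +/- SEM of each metric per (line, day, zone);
    * ``welch``   — normal-vs-cancer Welch p-value per (day, metric);
    * ``anova``   — across-day ANOVA within each line per metric (omitted
      with a log message when only one day is present).

    If ``out_dir`` is given, tables are written as CSV and a Figure-3-style
    panel plot as PNG.
    """
    if features.empty:
        raise MechSpheroidError("empty features table")
    label_col = "label" if "label" in features.columns else "line"
    days = sorted(features["day"].unique())
    lines = sorted(features[label_col].unique())

    summary_rows, welch_rows, anova_rows = [], [], []
    metric_zone = ([(m, "whole") for m in _WHOLE_METRICS]
                   + [(m, zone) for zone, ms in _ZONE_METRICS.items()
                      for m in ms])
    for metric, zone in metric_zone:
        if metric not in features.columns:
            log.warning("metric %s missing from features; skipped", metric)
            continue
        for day in days:
            by_line = {}
            for line in lines:
                vals = features.loc[(features["day"] == day)
                                    & (features[label_col] == line), metric]
                if vals.empty:
                    log.warning("group (%s, day %s) missing; omitted", line, day)
                    continue
                s = group_summary(vals)
                by_line[line] = vals.to_numpy(dtype=float)
                summary_rows.append({"line": line, "day": day, "zone": zone,
                                     "metric": metric, **s})
            if {"normal", "cancer"} <= set(by_line):
                res = welch_t_test(by_line["normal"], by_line["cancer"])
                welch_rows.append({"day": day, "zone": zone, "metric": metric,
                                   "t": res.t, "df": res.df, "p": res.p})
        # across-day ANOVA within each line
        for line in lines:
            groups = {d: features.loc[(features["day"] == d)
                                      & (features[label_col] == line), metric]
                      .to_numpy(dtype=float) for d in days}
            groups = {d: g for d, g in groups.items() if g.size >= 2}
            if len(groups) < 3:
                log.info("ANOVA skipped for %s/%s: fewer than 3 day groups",
                         line, metric)
                continue
            res = one_way_anova_posthoc(groups, method=posthoc)
            anova_rows.append({"line": line, "zone": zone, "metric": metric,
                               "F": res.F, "p": res.p})

    report = {"summary": pd.DataFrame(summary_rows),
              "welch": pd.DataFrame(welch_rows),
              "anova": pd.DataFrame(anova_rows)}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in report.items():
            table.to_csv(out_dir / f"{name}.csv", index=False)
        _plot_panels(report["summary"], out_dir / "figure_panels.png")
    return report


def _plot_panels(summary: pd.DataFrame, path: Path) -> None:
    """Six-panel mean +/- SEM plot (whole / core / periphery x metric)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [("mean_shift", "Mean shift (GHz)"),
               ("sd_shift", "SD of shift (GHz)"),
               ("skewness", "Skewness")]
    zonal = [("core_mean", "peri_mean", "Zonal mean (GHz)"),
             ("core_sd", "peri_sd", "Zonal SD (GHz)"),
             ("core_skew", "peri_skew", "Zonal skewness")]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    colors = {"normal": "tab:blue", "cancer": "tab:red"}
    for ax, (metric, title) in zip(axes[0], metrics):
        sub = summary[summary["metric"] == metric]
        for line, grp in sub.groupby("line"):
            grp = grp.sort_values("day")
            ax.errorbar(grp["day"], grp["mean"], yerr=grp["sem"],
                        marker="o", capsize=3, label=line,
                        color=colors.get(line))
        ax.set_xlabel("Day")
        ax.set_title(title)
        ax.legend(fontsize=8)
    for ax, (core_m, peri_m, title) in zip(axes[1], zonal):
        for metric, style in ((core_m, "-"), (peri_m, "--")):
            sub = summary[summary["metric"] == metric]
            for line, grp in sub.groupby("line"):
                grp = grp.sort_values("day")
                ax.errorbar(grp["day"], grp["mean"], yerr=grp["sem"],
                            marker="o", capsize=3, linestyle=style,
                            label=f"{line} {'core' if metric == core_m else 'periphery'}",
                            color=colors.get(line))
        ax.set_xlabel("Day")
        ax.set_title(title)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
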