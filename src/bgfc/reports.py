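"""Machine-readable twins of the study's report tables.

* table1: Pearson correlations of local basal-ganglia z-FC and fatigue
  measures (FSS pooled row; FC rows per task x group), with BH-FDR flags
  (one family per table, q < 0.10).
* table2: local FC group contrasts (HC vs MS) per task x pair, pooled t,
  df, two-sided p and |Cohen's d|.
* table3-5: block-1 vs block-4 global FC paired contrasts for the split
  groups (table3: HC intrinsic, table4: MS intrinsic, table5: MS
  extrinsic).

A JSON summary carries the 2x2 mixed ANOVA on reaction time and the one
global-FC group contrast reported with fractional df (Welch, flagged in
metadata).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behaviour import filter_rt_outliers
from .connectivity import BG_PAIRS
from .stats import (
    DegenerateVarianceError,
    apply_fdr,
    mixed_anova_2x2,
    paired_t,
    two_sample_t_from_data,
)

__all__ = ["GroupStatsReport", "subject_measures", "build_report"]

TASK_LABEL = {"T2": "Intrinsic alertness", "T3": "Extrinsic alertness"}
SEED_LABEL = {"Caudate": "Caudate", "Putamen": "Putamen", "Pallidum": "Pallidum",
              "BG-average": "Average"}
COND_LABEL = {"handgrip_only": "Handgrip only", "mental_imagery_first": "Mental imagery first"}


@dataclass
class GroupStatsReport:
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables.items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2, default=float))


def subject_measures(fc: pd.DataFrame, behaviour: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: FSS, grand RT/force per alertness task, and
    whole-task local z-FC per pair (columns ``fc_<task>_<pair>``)."""
    alert = behaviour[behaviour["task"].isin(("T2", "T3"))]
    per = alert.groupby(["subject", "task"]).agg(
        rt=("mean_rt_ms", "mean"), force=("mean_peak_force", "mean")
    ).unstack("task")
    meta = behaviour.drop_duplicates("subject").set_index("subject")
    out = pd.DataFrame({
        "group": meta["group"],
        "condition": meta["condition"],
        "fss": meta["fss"],
        "rt_t2": per[("rt", "T2")],
        "rt_t3": per[("rt", "T3")],
        "force_t2": per[("force", "T2")],
        "force_t3": per[("force", "T3")],
    })
    if fc is not None and len(fc):
        whole = fc[fc["block"].isna()] if "block" in fc else fc
        for task in ("T2", "T3"):
            sel = whole[whole["task"] == task].set_index("subject")
            for pair in BG_PAIRS:
                col = f"local_{pair}"
                if col in sel:
                    out[f"fc_{task}_{pair}"] = sel[col]
    return out.reset_index()


def _table1(measures: pd.DataFrame, q: float) -> pd.DataFrame:
    from scipy import stats as sps

    bcols = ("fss", "rt_t2", "rt_t3", "force_t2", "force_t3")
    col_label = {"fss": "FSS", "rt_t2": "T2 RT", "rt_t3": "T3 RT",
                 "force_t2": "T2 Force", "force_t3": "T3 Force"}
    cells = []
    # pooled behaviour-behaviour row
    for y in bcols[1:]:
        sub = measures[["fss", y]].dropna()
        r, p = sps.pearsonr(sub["fss"], sub[y])
        cells.append(("", "", "FSS", col_label[y], float(r), float(p), len(sub)))
    # per task x group FC rows
    for task in ("T2", "T3"):
        for group in ("HC", "MS"):
            frame = measures[measures["group"] == group]
            for pair in BG_PAIRS:
                x = f"fc_{task}_{pair}"
                if x not in measures:
                    continue
                for y in bcols:
                    sub = frame[[x, y]].dropna()
                    r, p = sps.pearsonr(sub[x], sub[y])
                    cells.append((TASK_LABEL[task], group, pair, col_label[y],
                                  float(r), float(p), len(sub)))
    frame = pd.DataFrame(cells, columns=["task", "group", "variable_x", "variable_y",
                                         "r", "p", "n"])
    from .stats import bh_fdr

    frame["fdr_significant"] = bh_fdr(frame["p"].to_numpy(), q)
    return frame


def _table2(measures: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for task in ("T2", "T3"):
        for pair in BG_PAIRS:
            col = f"fc_{task}_{pair}"
            if col not in measures:
                continue
            hc = measures.loc[measures["group"] == "HC", col].dropna()
            ms = measures.loc[measures["group"] == "MS", col].dropna()
            res = two_sample_t_from_data(hc, ms)
            rows.append((TASK_LABEL[task], pair, hc.mean(), hc.std(ddof=1),
                         ms.mean(), ms.std(ddof=1), res.t, res.df, res.p, abs(res.d)))
    return pd.DataFrame(rows, columns=["task", "connectivity", "hc_mean", "hc_sd",
                                       "ms_mean", "ms_sd", "t", "df", "p", "cohens_d"])


def _block_table(fc: pd.DataFrame, group: str, task: str) -> pd.DataFrame:
    rows = []
    sel = fc[(fc["group"] == group) & (fc["task"] == task)]
    for condition in ("handgrip_only", "mental_imagery_first"):
        csel = sel[sel["condition"] == condition]
        b1 = csel[csel["block"] == 1].set_index("subject")
        b4 = csel[csel["block"] == 4].set_index("subject")
        common = b1.index.intersection(b4.index)
        for seed in ("Caudate", "Putamen", "Pallidum", "BG-average"):
            col = f"global_{seed}"
            if col not in csel or not len(common):
                continue
            x1 = b1.loc[common, col].astype(float)
            x4 = b4.loc[common, col].astype(float)
            try:
                res = paired_t(x1.to_numpy(), x4.to_numpy())
                t, df, p = res.t, res.df, res.p
            except DegenerateVarianceError:
                t, df, p = np.inf, len(common) - 1, 0.0
            rows.append((COND_LABEL[condition], SEED_LABEL[seed],
                         x1.mean(), x1.std(ddof=1), x4.mean(), x4.std(ddof=1), t, df, p))
    return pd.DataFrame(rows, columns=["condition", "connectivity", "block1_mean",
                                       "block1_sd", "block4_mean", "block4_sd",
                                       "t", "df", "p"])


def build_report(
    fc: pd.DataFrame,
    behaviour: pd.DataFrame,
    q: float = 0.10,
    filter_outliers: bool = True,
) -> GroupStatsReport:
    """Assemble the full group-statistics report.

    ``fc`` holds one row per subject x task (whole-task, ``block`` NaN)
    plus rows per block for the block-wise global statistics; columns
    ``local_<pair>`` / ``global_<seed>``. ``behaviour`` is the tidy
    cohort behaviour table. RT outlier filtering (+/- 2 SD) is applied
    before any statistic unless disabled.
    """
    report = GroupStatsReport()
    if filter_outliers:
        behaviour, _removed, screen = filter_rt_outliers(behaviour)
        retained = set(behaviour["subject"])
        if fc is not None and len(fc):
            fc = fc[fc["subject"].isin(retained)]
        report.tables["outlier_screen"] = screen
        report.summary["n_retained"] = {
            g: int(screen.loc[(screen["group"] == g) & ~screen["removed"], "subject"].nunique())
            for g in ("HC", "MS")
        }
    measures = subject_measures(fc, behaviour)
    report.tables["table1_correlations"] = _table1(measures, q)
    report.tables["table2_local_fc"] = _table2(measures)
    if fc is not None and "block" in fc and fc["block"].notna().any():
        report.tables["table3_global_fc_hc_intrinsic"] = _block_table(fc, "HC", "T2")
        report.tables["table4_global_fc_ms_intrinsic"] = _block_table(fc, "MS", "T2")
        report.tables["table5_global_fc_ms_extrinsic"] = _block_table(fc, "MS", "T3")
    # 2x2 mixed ANOVA on grand alertness RT
    rt_long = measures.melt(
        id_vars=["subject", "group"], value_vars=["rt_t2", "rt_t3"],
        var_name="task", value_name="rt",
    ).dropna()
    if rt_long["subject"].nunique() >= 4:
        anova = mixed_anova_2x2(rt_long, dv="rt")
        report.summary["rt_mixed_anova"] = anova.as_dict()
    # the one global-FC group contrast reported with fractional df: Welch
    if fc is not None and len(fc):
        whole = fc[fc["block"].isna()] if "block" in fc else fc
        sel = whole[whole["task"] == "T3"]
        if "global_Putamen" in sel:
            hc = sel.loc[sel["group"] == "HC", "global_Putamen"].dropna()
            ms = sel.loc[sel["group"] == "MS", "global_Putamen"].dropna()
            if len(hc) > 1 and len(ms) > 1:
                res = two_sample_t_from_data(hc, ms, welch=True)
                report.summary["global_putamen_extrinsic_contrast"] = {
                    "t": res.t, "df": res.df, "p": res.p, "welch": True,
                }
    report.summary["fdr_q"] = q
    return report
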