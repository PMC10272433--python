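"""Behavioural fatigue measures: reaction times, grip force, screening.

Cognitive fatigue is operationalised as the increase in mean reaction time
(RT) from block 1 to block 4 of an alertness task; physical fatigue as the
decrease in average peak grip force (high-force level) over the same
blocks. RT is the latency from white-square onset to grip onset; a grip
preceding its stimulus is an anticipation and is excluded from block
means.

Cohort-level behaviour travels as a tidy table with one row per
(subject, task, block):

``subject  group  condition  task  block  mean_rt_ms  mean_peak_force
force_low  force_medium  fss  hads_anx  hads_dep``

where ``mean_peak_force`` is the analysed high-force level and group is
"HC" or "MS". The sensorimotor task (T1) is self-paced, so its rows carry
no RT.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectBehaviour",
    "FatigueMeasures",
    "trial_rt",
    "block_mean_rt",
    "block_force",
    "subject_grand_rt",
    "filter_rt_outliers",
    "screen_inclusion",
    "fatigue_measures",
]

FSS_RANGE = (9, 63)      # 9-item total score
HADS_RANGE = (0, 21)     # per subscale
HADS_EXCLUSION = 12      # excluded if either subscale is strictly above
FSS_CUTOFF = 36          # MS included iff >= 36; HC excluded iff >= 36

ALERTNESS_TASKS = ("T2", "T3")
BLOCKS = (1, 2, 3, 4)


@dataclass(frozen=True)
class SubjectBehaviour:
    """Per-subject behavioural record.

    ``rt_ms`` maps (task, block) -> mean RT for the alertness tasks;
    ``force`` maps (task, block, level) -> mean peak force with level in
    {"low", "medium", "high"}.
    """

    subject_id: str
    group: str
    condition: str
    rt_ms: dict
    force: dict
    fss_total: float
    hads_anxiety: float
    hads_depression: float

    def __post_init__(self) -> None:
        if self.group not in ("HC", "MS"):
            raise ValueError(f"group must be HC or MS, got {self.group!r}")
        if self.condition not in ("handgrip_only", "mental_imagery_first"):
            raise ValueError(f"unknown condition {self.condition!r}")
        for task in ALERTNESS_TASKS:
            for block in BLOCKS:
                rt = self.rt_ms.get((task, block))
                if rt is None:
                    raise ValueError(f"missing RT for {task} block {block}")
                if rt <= 0:
                    raise ValueError(f"non-positive RT for {task} block {block}")
        if not (FSS_RANGE[0] <= self.fss_total <= FSS_RANGE[1]):
            raise ValueError(f"FSS total {self.fss_total} outside {FSS_RANGE}")
        for name, v in (("anxiety", self.hads_anxiety), ("depression", self.hads_depression)):
            if not (HADS_RANGE[0] <= v <= HADS_RANGE[1]):
                raise ValueError(f"HADS {name} {v} outside {HADS_RANGE}")


@dataclass(frozen=True)
class FatigueMeasures:
    """Block-4-minus-block-1 RT delta and block-1-minus-block-4 force delta."""

    cognitive_fatigue: dict = field(default_factory=dict)  # task -> RT(b4) - RT(b1)
    physical_fatigue: dict = field(default_factory=dict)   # task -> F(b1) - F(b4), high level


def trial_rt(grip_onset_ms: float, stimulus_onset_ms: float) -> float | None:
    """Single-trial RT; None flags an invalid (anticipatory) trial."""
    rt = grip_onset_ms - stimulus_onset_ms
    if rt < 0:
        return None
    return float(rt)


def block_mean_rt(grip_onsets_ms, stimulus_onsets_ms) -> float:
    """Mean RT over the valid trials of one block."""
    rts = [trial_rt(g, s) for g, s in zip(grip_onsets_ms, stimulus_onsets_ms)]
    valid = [r for r in rts if r is not None]
    if not valid:
        raise ValueError("no valid trials in block")
    return float(np.mean(valid))


def block_force(peak_forces) -> float:
    """Average peak force over the trials of one block."""
    forces = np.asarray(list(peak_forces), dtype=float)
    if forces.size == 0:
        raise ValueError("no force peaks in block")
    return float(forces.mean())


def subject_grand_rt(table: pd.DataFrame) -> pd.Series:
    """Grand-mean RT per subject, pooled over the T2+T3 blocks."""
    alert = table[table["task"].isin(ALERTNESS_TASKS)]
    return alert.groupby("subject")["mean_rt_ms"].mean()


def filter_rt_outliers(
    table: pd.DataFrame, k_sd: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Remove subjects whose grand-mean RT is an outlier within their group.

    A subject is removed iff its pooled T2+T3 grand-mean RT lies strictly
    outside group_mean +/- k_sd * group_SD, with the group statistics
    computed once, before any removal (single pass, per diagnostic group).

    Returns ``(retained, removed, report)`` where retained/removed are row
    subsets of ``table`` and report has one row per subject with columns
    subject, group, mean_rt, group_mean, group_sd, z, removed.
    """
    grand = subject_grand_rt(table)
    groups = table.drop_duplicates("subject").set_index("subject")["group"]
    if grand.empty:
        raise ValueError("behaviour table has no alertness-task RT rows")
    rows = []
    for group, subjects in groups.groupby(groups):
        ids = [s for s in subjects.index if s in grand.index]
        if len(ids) < 3:
            raise ValueError(f"need >= 3 subjects per group, {group} has {len(ids)}")
        vals = grand.loc[ids]
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        for s in ids:
            if sd == 0:
                z = 0.0
                removed = False  # degenerate SD: nothing can exceed the bound
            else:
                z = (float(grand[s]) - mean) / sd
                removed = abs(z) > k_sd
            rows.append((s, group, float(grand[s]), mean, sd, z, removed))
    report = pd.DataFrame(
        rows, columns=["subject", "group", "mean_rt", "group_mean", "group_sd", "z", "removed"]
    )
    removed_ids = set(report.loc[report["removed"], "subject"])
    retained = table[~table["subject"].isin(removed_ids)].copy()
    removed = table[table["subject"].isin(removed_ids)].copy()
    return retained, removed, report


def screen_inclusion(
    group: str,
    fss_total: float,
    hads_anxiety: float,
    hads_depression: float,
) -> tuple[bool, str]:
    """Study inclusion decision: (include, reason).

    MS participants are included iff FSS >= 36; HC are excluded iff
    FSS >= 36; either group is excluded if a HADS subscale exceeds 12
    (mental-health comorbidity).
    """
    if hads_anxiety > HADS_EXCLUSION or hads_depression > HADS_EXCLUSION:
        return False, "mental-health comorbidity (HADS subscale > 12)"
    if group == "MS":
        if fss_total >= FSS_CUTOFF:
            return True, "included"
        return False, f"MS with FSS {fss_total} < {FSS_CUTOFF}"
    if group == "HC":
        if fss_total < FSS_CUTOFF:
            return True, "included"
        return False, f"HC with FSS {fss_total} >= {FSS_CUTOFF}"
    raise ValueError(f"unknown group {group!r}")


def fatigue_measures(subject: SubjectBehaviour | pd.DataFrame) -> FatigueMeasures:
    """Cognitive (RT block4 - block1) and physical (high force block1 - block4)
    fatigue deltas for the two alertness tasks."""
    if isinstance(subject, SubjectBehaviour):
        rt = {t: (subject.rt_ms[(t, 1)], subject.rt_ms[(t, 4)]) for t in ALERTNESS_TASKS}
        force = {
            t: (subject.force[(t, 1, "high")], subject.force[(t, 4, "high")])
            for t in ALERTNESS_TASKS
        }
    else:
        rt, force = {}, {}
        for t in ALERTNESS_TASKS:
            sel = subject[subject["task"] == t].set_index("block")
            rt[t] = (float(sel.loc[1, "mean_rt_ms"]), float(sel.loc[4, "mean_rt_ms"]))
            force[t] = (
                float(sel.loc[1, "mean_peak_force"]),
                float(sel.loc[4, "mean_peak_force"]),
            )
    cognitive = {t: rt[t][1] - rt[t][0] for t in ALERTNESS_TASKS}
    physical = {t: force[t][0] - force[t][1] for t in ALERTNESS_TASKS}
    return FatigueMeasures(cognitive, physical)
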