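"""Cohort persistence: TSV dialects for time series, confounds, behaviour.

A cohort directory contains::

    schedule.tsv                       task, block, onset_s, duration_s
    behaviour.tsv                      tidy behaviour table
    <subject>_timeseries.tsv           T x 116, header = AAL region names
    <subject>_confounds.tsv            wm, csf, motion1..motion6
    cohort.json                        tr_seconds, subject ids, groups

NIfTI fixtures (optional) live alongside as ``<subject>_bold.nii.gz`` /
``<subject>_labels.nii.gz`` / tissue masks.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .behaviour import SubjectBehaviour
from .cohort import SyntheticSubject, behaviour_table
from .containers import ConfoundSet, RoiTimeSeriesSet
from .schedule import ParadigmSchedule

__all__ = ["write_cohort", "read_cohort", "read_behaviour_table"]


def write_cohort(
    subjects: list[SyntheticSubject],
    out_dir: str | Path,
    schedule: ParadigmSchedule | None = None,
    tr_seconds: float | None = None,
    write_timeseries: bool = True,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    behaviour_table(subjects).to_csv(out / "behaviour.tsv", sep="\t", index=False)
    meta = {"subjects": []}
    for s in subjects:
        meta["subjects"].append(
            {"id": s.subject_id, "group": s.group, "condition": s.condition}
        )
        if write_timeseries and s.roi_timeseries is not None:
            s.roi_timeseries.to_frame().to_csv(
                out / f"{s.subject_id}_timeseries.tsv", sep="\t", index=False
            )
            if tr_seconds is None:
                tr_seconds = s.roi_timeseries.tr_seconds
        if write_timeseries and s.confounds is not None:
            s.confounds.to_frame().to_csv(
                out / f"{s.subject_id}_confounds.tsv", sep="\t", index=False
            )
    if schedule is not None:
        schedule.to_tsv(out / "schedule.tsv")
    meta["tr_seconds"] = tr_seconds
    (out / "cohort.json").write_text(json.dumps(meta, indent=2))
    return out


def read_behaviour_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _behaviour_from_rows(rows: pd.DataFrame) -> SubjectBehaviour:
    first = rows.iloc[0]
    rt_ms, force = {}, {}
    for r in rows.itertuples():
        key = (r.task, int(r.block))
        if pd.notna(r.mean_rt_ms):
            rt_ms[key] = float(r.mean_rt_ms)
        force[key + ("high",)] = float(r.mean_peak_force)
        force[key + ("low",)] = float(r.force_low)
        force[key + ("medium",)] = float(r.force_medium)
    return SubjectBehaviour(
        subject_id=str(first.subject),
        group=str(first.group),
        condition=str(first.condition),
        rt_ms=rt_ms,
        force=force,
        fss_total=float(first.fss),
        hads_anxiety=float(first.hads_anx),
        hads_depression=float(first.hads_dep),
    )


def read_cohort(in_dir: str | Path, load_timeseries: bool = True) -> tuple[list[SyntheticSubject], ParadigmSchedule | None]:
    """Read a cohort directory back into subjects (+ schedule if present)."""
    src = Path(in_dir)
    meta = json.loads((src / "cohort.json").read_text())
    tr = meta.get("tr_seconds") or 0.906
    behaviour = read_behaviour_table(src / "behaviour.tsv")
    schedule = None
    if (src / "schedule.tsv").exists():
        schedule = ParadigmSchedule.from_tsv(src / "schedule.tsv")
    subjects = []
    for entry in meta["subjects"]:
        sid = entry["id"]
        rows = behaviour[behaviour["subject"] == sid]
        beh = _behaviour_from_rows(rows)
        ts = conf = None
        ts_path = src / f"{sid}_timeseries.tsv"
        if load_timeseries and ts_path.exists():
            ts = RoiTimeSeriesSet.from_frame(pd.read_csv(ts_path, sep="\t"), tr)
            conf_path = src / f"{sid}_confounds.tsv"
            if conf_path.exists():
                conf = ConfoundSet.from_frame(pd.read_csv(conf_path, sep="\t"))
        subjects.append(
            SyntheticSubject(sid, entry["group"], entry["condition"], beh, ts, conf)
        )
    return subjects, schedule
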