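"""End-to-end orchestration: synthesise or ingest, clean, segment,
connect, merge behaviour, and emit the group-statistics report.

All randomness flows from one root seed through named per-subject
substreams, so runs are deterministic given (config, seed) and a subject's
data do not depend on cohort size. A manifest records the configuration
hash, seed, package versions and per-stage row counts.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import load_aal116
from .cleaning import CleaningConfig, clean_roi_timeseries
from .cohort import CohortSpec, SyntheticSubject, behaviour_table, generate_cohort
from .connectivity import BG_PAIRS, BG_SEEDS, correlation_matrix, fisher_z, global_bg_fc, local_bg_fc
from .reports import GroupStatsReport, build_report
from .schedule import ParadigmSchedule, segment_by_task, segment_single_block

__all__ = ["RunConfig", "run_pipeline", "subject_fc_row", "compute_fc_table"]

log = logging.getLogger("bgfc")


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage name and subject id."""

    def __init__(self, stage: str, subject: str | None, cause: Exception):
        super().__init__(f"stage {stage!r}" + (f" subject {subject}" if subject else "") + f": {cause}")
        self.stage = stage
        self.subject = subject
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    mode: str = "synthetic"              # synthetic | tsv | nifti
    in_dir: str | None = None            # cohort dir (tsv mode)
    out_dir: str = "bgfc_out"
    seed: int = 42
    n_hc: int | None = None
    n_ms: int | None = None
    tasks: tuple[str, ...] = ("T2", "T3")
    blocks: tuple[int, ...] = (1, 4)
    fdr_q: float = 0.10
    hrf_lag_seconds: float = 0.0
    min_block_volumes: int = 30
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    write_matrices: bool = False
    write_cohort_tsv: bool = False
    spec_overrides: dict | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.mode not in ("synthetic", "tsv", "nifti"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "tsv" and not self.in_dir:
            raise ValueError("tsv mode requires in_dir")

    def config_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, (Path, CleaningConfig)) else v)
            for k, v in sorted(self.__dict__.items())
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def subject_fc_row(
    subject: SyntheticSubject,
    schedule: ParadigmSchedule,
    cfg: RunConfig,
    matrices_out: Path | None = None,
) -> list[dict]:
    """Whole-task and block-wise FC statistics for one subject."""
    names = load_aal116().names
    ts = subject.roi_timeseries
    if ts is None:
        raise ValueError(f"subject {subject.subject_id} has no time series")
    confounds = subject.confounds
    if confounds is None:
        raise ValueError(f"subject {subject.subject_id} has no confounds")
    cleaned = clean_roi_timeseries(ts, confounds, cfg.cleaning)
    rows = []
    for task in cfg.tasks:
        seg = segment_by_task(cleaned.data, schedule, task, ts.tr_seconds, cfg.hrf_lag_seconds)
        z = fisher_z(correlation_matrix(seg, names, task=task))
        row = {
            "subject": subject.subject_id, "group": subject.group,
            "condition": subject.condition, "task": task, "block": np.nan,
        }
        for pair in BG_PAIRS:
            row[f"local_{pair}"] = local_bg_fc(z, pair)
        for seed in BG_SEEDS:
            row[f"global_{seed}"] = global_bg_fc(z, seed)
        rows.append(row)
        if matrices_out is not None:
            z.to_tsv(matrices_out / f"{subject.subject_id}_{task}_fisher_z.tsv")
        for block in cfg.blocks:
            bseg = segment_single_block(
                cleaned.data, schedule, task, block, ts.tr_seconds,
                cfg.hrf_lag_seconds, min_volumes=cfg.min_block_volumes,
            )
            zb = fisher_z(correlation_matrix(bseg, names, task=task, block=block))
            brow = {
                "subject": subject.subject_id, "group": subject.group,
                "condition": subject.condition, "task": task, "block": block,
            }
            for pair in BG_PAIRS:
                brow[f"local_{pair}"] = local_bg_fc(zb, pair)
            for seed in BG_SEEDS:
                brow[f"global_{seed}"] = global_bg_fc(zb, seed)
            rows.append(brow)
            if matrices_out is not None:
                zb.to_tsv(matrices_out / f"{subject.subject_id}_{task}_b{block}_fisher_z.tsv")
    return rows


def compute_fc_table(
    subjects: list[SyntheticSubject],
    schedule: ParadigmSchedule,
    cfg: RunConfig,
    matrices_out: Path | None = None,
) -> pd.DataFrame:
    rows = []
    for s in subjects:
        try:
            rows.extend(subject_fc_row(s, schedule, cfg, matrices_out))
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise StageError("connectivity", s.subject_id, exc) from exc
        log.info("stage=connectivity subject=%s rows=%d", s.subject_id, len(rows))
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> GroupStatsReport:
    """Execute the configured run and persist all artefacts under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.mode == "synthetic":
        try:
            spec = CohortSpec.default(
                n_hc=cfg.n_hc, n_ms=cfg.n_ms, seed=cfg.seed, overrides=cfg.spec_overrides
            )
            subjects = generate_cohort(spec, seed=cfg.seed)
            schedule = spec.schedule
        except Exception as exc:
            raise StageError("synthesis", None, exc) from exc
        if cfg.write_cohort_tsv:
            from .io import write_cohort

            write_cohort(subjects, out / "cohort", schedule, spec.tr_seconds)
    elif cfg.mode == "tsv":
        from .io import read_cohort

        try:
            subjects, schedule = read_cohort(cfg.in_dir)
        except Exception as exc:
            raise StageError("ingest", None, exc) from exc
        if schedule is None:
            from .schedule import default_schedule

            schedule = default_schedule()
    else:
        raise NotImplementedError(
            "nifti mode: extract ROI series with bgfc.imaging, write a TSV cohort, "
            "then run in tsv mode"
        )
    matrices_out = None
    if cfg.write_matrices:
        matrices_out = out / "matrices"
        matrices_out.mkdir(exist_ok=True)
    fc = compute_fc_table(subjects, schedule, cfg, matrices_out)
    behaviour = behaviour_table(subjects)
    try:
        report = build_report(fc, behaviour, q=cfg.fdr_q)
    except Exception as exc:
        raise StageError("group_stats", None, exc) from exc
    fc.to_csv(out / "fc_stats.tsv", sep="\t", index=False)
    behaviour.to_csv(out / "behaviour.tsv", sep="\t", index=False)
    report.write(out / "report")
    import bgfc

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "bgfc": bgfc.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "rows": {"fc_stats": len(fc), "behaviour": len(behaviour)},
        "n_subjects": len(subjects),
        "tables": sorted(report.tables),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %d subjects, outputs in %s", len(subjects), out)
    return report
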