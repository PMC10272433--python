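# bgfc — basal-ganglia functional connectivity and fatigue

`bgfc` is a tested, reusable implementation of a task-fMRI functional
connectivity (FC) analysis of fatigue in multiple sclerosis (MS): from
ROI-parcellated BOLD time series (or small volumetric inputs) and
behavioural logs to local/global basal-ganglia FC statistics, behavioural
fatigue measures, and group-statistics report tables. Because the original
scanner data cannot be shared, the package ships a **calibrated
synthetic-cohort generator** that reproduces the statistical structure the
analysis assumes, so every stage of the pipeline is testable end to end.

It is intended for neuroimaging researchers who want to reuse, audit or
extend the analysis: methods developers probing how local basal-ganglia
coupling statistics behave under cleaning and segmentation choices, and
students learning block-design FC pipelines.

## The analysis

Participants (MS patients with fatigue, FSS ≥ 36, and healthy controls)
perform an alertness–motor paradigm of three interleaved tasks —
sensorimotor (T1), intrinsic alertness (T2), extrinsic alertness (T3) —
each in four blocks over a ~15-min scan (TR = 0.906 s). Per subject:

1. **Cleaning** — ROI mean series from the AAL-116 parcellation are
   residualised on white-matter, CSF and six motion signals (least
   squares), then bandpass filtered at 0.01–0.08 Hz (4th-order
   Butterworth, zero-phase).
2. **Segmentation** — cleaned series are split by task-block timings and
   concatenated per task.
3. **Connectivity** — Pearson correlation over the concatenated segment
   gives a 116×116 weighted matrix; the Fisher transform
   z = ½·ln((1+r)/(1−r)) is applied element-wise.
4. **Basal-ganglia statistics** — local FC of a named pair
   (Caudate–Putamen, Caudate–Pallidum, Putamen–Pallidum) is the mean z
   over the four cross edges between the two bilateral structures; global
   FC of a seed (a bilateral structure, or all six regions) is the mean z
   to the 110 non-basal-ganglia regions.
5. **Behaviour** — reaction time (RT) is grip onset minus stimulus onset;
   cognitive fatigue is RT(block 4) − RT(block 1), physical fatigue is
   high-grip force(block 1) − force(block 4); subjects whose grand-mean RT
   lies beyond ±2 SD of their group are removed (single pass).
6. **Group statistics** — pooled-variance t-tests with Cohen's d, paired
   t-tests for block contrasts, a 2×2 mixed ANOVA (diagnosis × task) with
   partial η², Pearson correlation tables, and Benjamini–Hochberg FDR at
   q < 0.10.

## Worked example

```python
from bgfc import CohortSpec, generate_cohort, behaviour_table, filter_rt_outliers
from bgfc.stats import TwoGroupSummary, two_sample_t

# the default fixture: 40 HC + 40 MS with planted RT outliers (4 HC, 3 MS)
spec = CohortSpec.default(seed=42)
subjects = generate_cohort(spec, seed=42, include_imaging=False)
retained, removed, screen = filter_rt_outliers(behaviour_table(subjects))
kept = screen.loc[~screen.removed].groupby("group").subject.nunique()
print(f"retained after +/-2 SD RT filter: HC={kept['HC']}, MS={kept['MS']}")

# a group contrast from printed-style summaries (means, SDs, group sizes)
res = two_sample_t(TwoGroupSummary(36, 37, 1.18, 1.05, 0.21, 0.23))
print(f"extrinsic putamen-pallidum contrast: t({res.df:.0f}) = {res.t:.2f}, "
      f"p = {res.p:.3f}, d = {abs(res.d):.2f}")
```

prints

```
retained after +/-2 SD RT filter: HC=36, MS=37
extrinsic putamen-pallidum contrast: t(71) = 2.52, p = 0.014, d = 0.59
```

The filter keeps 36 controls and 37 patients (the planted outliers are
removed, nobody else), and the pooled-variance contrast of the two group
summaries gives a medium effect (d ≈ 0.59) on 71 degrees of freedom.

With imaging, a small cohort runs through the full pipeline in under a
minute:

```python
from bgfc.pipeline import RunConfig, compute_fc_table

spec = CohortSpec.default(n_hc=12, n_ms=12, seed=42)
subjects = generate_cohort(spec, seed=42)   # pilot-calibrated BOLD synthesis
fc = compute_fc_table(subjects, spec.schedule, RunConfig(blocks=(), tasks=("T2",)))
print(fc.groupby("group")["local_Putamen-Pallidum"].agg(["mean", "std"]).round(2))
```

```
       mean   std
group
HC     1.15  0.22
MS     1.11  0.18
```

i.e. the intrinsic-task putamen–pallidum coupling of simulated controls
sits near its calibration target of 1.21 (Fisher z) with between-subject
SD ≈ 0.21, and the MS group is calibrated lower (1.05); at n = 12 per
group the group means are still noisy — the recovery tests use n = 200.

The command line mirrors the library: `bgfc synth | clean | connect |
behaviour | report | all` (and the `synth-cohort` alias), e.g.

```bash
bgfc all --out run1 --seed 42          # full synthetic run + report tables
synth-cohort --seed 7 --out cohort7    # cohort TSVs only
```

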