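# Methods

This note documents the models and numerical choices behind `bgfc`: what
the pipeline computes, what the synthetic cohort emulates (and does not),
and where genuinely open design questions were settled.

## Pipeline model

**Parcellation.** The AAL atlas with 116 regions, shipped as a packaged
label table in atlas order with the original sparse label values. ROI
signals are arithmetic voxel means within a label. Volumetric inputs are
assumed already in atlas space; a strict grid-equality check (shape and,
where available, affine) replaces resampling, and an ROI without voxels
or a label value absent from the table is an error naming the region.

**Cleaning.** Each ROI column is residualised on an intercept plus eight
confounds (WM mean, CSF mean, six motion parameters) by least squares;
all-zero confound columns are treated as absent, and genuine collinearity
is an error naming the columns. Regression at ROI level is equivalent to
the voxel-level formulation because both regression and ROI averaging are
linear and the confounds are shared across voxels. Filtering is a
4th-order Butterworth bandpass at 0.01–0.08 Hz (the printed band read as
Hz, the field convention), applied forward–backward (`filtfilt`) so the
output is zero-phase, with a linear detrend first (on by default) to
avoid ramp leakage. Order is fixed: regression, detrend, filter — then
segmentation. Whether filtering should precede or follow segmentation is
not determined by the study description; filtering the full-length series
is the standard choice and is what the calibration assumes.

**Segmentation.** Task blocks map to half-open volume ranges
`[floor((onset+lag)/TR), floor((onset+lag+duration)/TR))` with 0-based
indices; the haemodynamic lag is configurable and defaults to 0 (no lag
compensation is imposed). A block shorter than one TR is an error.
Block-wise FC (block-1 vs block-4 contrasts) enforces a configurable
floor of 30 volumes per block for correlation stability.

**Connectivity.** Pearson correlation over the concatenated within-task
samples; Fisher z applied element-wise with r clipped to ±(1−1e−7) and a
zero diagonal. Averaging happens on the z scale (z first, then mean):
local-coupling values above 1 are only reachable there. Local FC of a
named pair averages the four cross-structure edges (L–L, L–R, R–L, R–R);
within-structure homotopic edges belong to no named pair and are
excluded. Global FC averages seed-to-target edges over the 110 non-BG
regions (220 edges for a bilateral seed, 660 for the six-region average).
Negative weights are used as-is; no thresholding.

**Behaviour.** RT is grip onset minus stimulus onset; anticipations
(negative RT) are excluded from block means. Force is summarised directly
as the per-block average peak (no raw grip-waveform model — only the
block summary is analysed). The outlier statistic is the subject's
grand-mean RT pooled over the T2+T3 blocks; removal is a single pass with
group statistics computed before any removal, strictly-outside-±2-SD,
per diagnostic group. The FSS is represented as the 9-item total (9–63)
so the 36 cut-off is meaningful. Screening: MS included iff FSS ≥ 36, HC
excluded iff FSS ≥ 36, either group excluded if a HADS subscale exceeds
12.

**Group statistics.** Pooled-variance (Student) t by default —
group contrasts are reported on df = n1+n2−2 — with Welch available by
flag and used for the one global-FC contrast conventionally reported with
fractional df (flagged in the report metadata). Cohen's d uses the pooled
SD; tables show |d|, machine output keeps the sign. The 2×2 mixed ANOVA
(between: diagnosis; within: task) is computed by `pingouin.mixed_anova`
and verified in the tests against an explicit sums-of-squares
decomposition; partial η² is SS_effect/(SS_effect+SS_error-of-stratum).
All p values are two-sided. BH-FDR runs at q = 0.10 with one family per
report table.

## Synthetic cohort

The generator is a generative twin of the analysis assumptions, not a
biophysical simulator: no haemodynamic response model, no vascular or
scanner artefacts, no lesions, no spatial structure beyond the
parcellation. Passing tests therefore demonstrate that the *pipeline*
recovers known statistical structure, not that it would behave
identically on scanner data.

**Signal model.** Per task state, ROI samples follow a factor model
chosen to make the implied 116×116 correlation matrix hit the calibrated
targets while being positive-definite *by construction* (a naive pairwise
assembly of the target matrix is indefinite in the required jitter
range): two cortical modes carry the cortico-cortical baseline
(r_cc = 0.35, a realistic task-state mean without global-signal
regression) and the seed-to-cortex coupling, with the caudate loading
mostly on one mode and putamen/pallidum on the other — this is what lets
weak caudate–putamen coupling (z ≈ 0.25) coexist with strong
seed-to-cortex coupling (z ≈ 0.38) for all three structures; three
correlated structure factors carry homotopic coupling (r_h = 0.95) and
the named-pair targets; independent residuals complete unit variance.
All latent series are band-limited to the analysis passband before the
state-dependent mixing, so the cleaning filter is nearly an identity on
signal; confound mixtures (20% of signal SD), broadband white noise
(20%), a linear drift and random-walk motion are added on top and removed
by cleaning. Block-level modulation of FC within a task is not generated;
the block-wise report tables are produced but their paired contrasts are
null by construction.

**Calibration targets.** Group-level mean Fisher-z values and SDs for the
three local pairs per task and group, and per-structure global levels,
ship in `bgfc/data/calibration.yaml` together with the behavioural
calibration. Cells without a reported value (sensorimotor-task coupling,
extrinsic-task global levels for controls, block-2/3 force means, the RT
block trajectories of the condition subgroups) carry realistic defaults
consistent with the reported block-1/block-4 patterns; each is a fixed
default, not a fitted quantity.

**Pilot self-calibration.** Sample correlations of finite filtered
segments are biased (state-boundary smearing, residual broadband noise)
and noisy (effective sample size ≈ 2·bandwidth·segment-length ≈ 40 for a
four-block task, i.e. measurement SD ≈ 0.16–0.21 on the z scale). The
generator therefore runs pilot subjects through the *actual* cleaning/
segmentation/connectivity pipeline: round 1 (384 pilots, fixed targets)
estimates each statistic's bias and measurement-noise SD; targets are
offset by the bias with a damped slope of 0.85; round 2 (768 pilots, with
subject jitter) removes the residual bias and measures the realised
moments of the six behaviour-linked FC statistics. The printed
between-subject SD is decomposed as target-jitter² + measurement-noise²;
jitter is truncated at ±3 SD. For the caudate pairs the printed SD sits
at the measurement-noise floor, so their jitter SD is floored at 0.02 and
their realised between-subject SD slightly exceeds the printed value.
Calibration is seeded from the spec's own seed and cached per spec
content, so replicate cohorts share one deterministic calibration.

**Behaviour.** Block-mean RTs and forces are generated directly at the
summary level: per (group, condition, task, block) means plus a subject
random effect (RT SD 65 ms, force SD 3.0) and block noise (20 ms, 0.3).
Low/medium force levels are fixed fractions of high. FSS is Normal per
group (HC 23±6, MS 50±6) clipped to the instrument range; HADS subscales
are Normal(6, 2.5) clipped to 0–21. The pooled FSS–RT correlation target
is converted to a within-group latent correlation in closed form,
accounting for the between-group mean gaps and all noise terms. The
FC–behaviour correlations are realised by drawing the behavioural latents
*conditionally on each subject's realised post-pipeline FC statistics*
(standardised with the pilot moments), which hits the targets without
attenuation corrections; the conditioning matrix uses a covariance
decomposed into a pooled-pilot measurement part plus the analytically
known jitter part. Remaining limitation: estimation noise in that 6×6
inversion leaves a small systematic residual (of order 0.01) on the
realised FC–behaviour correlations, and the caudate-pair correlations
realise attenuated because their jitter SD is floored.

**Outlier planting.** Chosen subjects (split across condition arms so the
retained sample reproduces the 19/17 and 19/18 arm sizes) get their
grand-mean RT moved to group-mean ± c·SD, alternating sides, with c
increased from 3.5 until the ±2 SD filter — with statistics recomputed
after planting — flags exactly the planted set; infeasible placements
(e.g. one outlier in a group of six, where the maximum attainable |z| is
(n−1)/√n ≈ 2.04) raise an error.

**Schedule.** Block durations, trial counts and rests are not fixed by
the study description beyond a ~15-min scan; the default schedule uses
twelve 80-volume blocks with 5-volume rests and a 10-volume lead-in
(1025 volumes ≈ 15.5 min at TR 0.906 s), with a fixed pseudorandomised
task order.

## Numerical choices

- Zero-phase filtering uses `filtfilt` with odd-reflection padding
  (padlen 27); series must exceed three padding lengths.
- Linear detrend is closed-form (projection on [1, t]).
- Cleaning is exactly linear in exact arithmetic; IIR round-off limits
  the verifiable linearity to ~1e−8 absolute on unit-scale data.
- Fisher z clips r at ±(1−1e−7); correlation matrices are symmetrised
  (r+rᵀ)/2 and clipped to [−1, 1] before storage.
- Degenerate inputs raise typed errors: zero-variance ROI series (named),
  rank-deficient confound designs (named columns), zero pooled variance
  with unequal means (overflow), empty masks/ROIs, empty block ranges.
- The structure-factor correlation matrix and the conditional-residual
  covariance are eigenvalue-floored at 1e−8 when jitter pushes them
  marginally indefinite; pair-factor correlations are clipped to ±0.95.
- All randomness flows through `numpy.random.SeedSequence` substreams
  keyed by (seed, group, subject index), so a subject's data are
  independent of cohort size and runs are bit-reproducible.

## Problem sizes

The recovery tests and the acceptance script use 200 subjects per group
for FC-mean recovery and 200 replicate cohorts (n = 73 pooled, n = 37 MS)
for the correlation targets, with tolerances of three Monte-Carlo
standard errors of the estimate in question; pilot rounds use 384 and 768
subjects. These sizes make the Monte-Carlo error a fraction of each
tolerance while keeping a full run in the minutes range on one CPU.
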