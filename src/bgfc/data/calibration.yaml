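# Default calibration of the synthetic cohort.
#
# FC coupling targets are group-level mean Fisher-z values with
# between-subject SDs; behavioural targets are group (and condition)
# level summaries plus the correlation structure linking subjective
# fatigue (FSS), reaction time, grip force and basal-ganglia coupling.
# Where the study reports no value for a cell (T1 coupling, HC extrinsic
# global FC, block-2/3 force means, within-block RT trajectories for the
# condition subgroups), realistic defaults consistent with the reported
# block-1/block-4 patterns are used; see docs/methods.md.

coupling:
  # (group, task, pair) -> mean Fisher z and between-subject SD
  local:
    HC:
      T2: {Caudate-Putamen: {z: 0.25, sd: 0.15}, Caudate-Pallidum: {z: 0.28, sd: 0.14}, Putamen-Pallidum: {z: 1.21, sd: 0.21}}
      T3: {Caudate-Putamen: {z: 0.29, sd: 0.19}, Caudate-Pallidum: {z: 0.27, sd: 0.17}, Putamen-Pallidum: {z: 1.18, sd: 0.21}}
      T1: {Caudate-Putamen: {z: 0.25, sd: 0.15}, Caudate-Pallidum: {z: 0.28, sd: 0.14}, Putamen-Pallidum: {z: 1.21, sd: 0.21}}
    MS:
      T2: {Caudate-Putamen: {z: 0.30, sd: 0.23}, Caudate-Pallidum: {z: 0.30, sd: 0.21}, Putamen-Pallidum: {z: 1.05, sd: 0.21}}
      T3: {Caudate-Putamen: {z: 0.29, sd: 0.17}, Caudate-Pallidum: {z: 0.30, sd: 0.17}, Putamen-Pallidum: {z: 1.05, sd: 0.23}}
      T1: {Caudate-Putamen: {z: 0.30, sd: 0.23}, Caudate-Pallidum: {z: 0.30, sd: 0.21}, Putamen-Pallidum: {z: 1.05, sd: 0.21}}
  # (group, task, structure) -> mean Fisher z of seed-to-cortex FC
  global:
    HC:
      T2: {Caudate: 0.38, Putamen: 0.38, Pallidum: 0.38}
      T3: {Caudate: 0.38, Putamen: 0.38, Pallidum: 0.38}
      T1: {Caudate: 0.38, Putamen: 0.38, Pallidum: 0.38}
    MS:
      T2: {Caudate: 0.41, Putamen: 0.41, Pallidum: 0.40}
      T3: {Caudate: 0.44, Putamen: 0.40, Pallidum: 0.41}
      T1: {Caudate: 0.41, Putamen: 0.41, Pallidum: 0.40}
  # free structural parameters of the signal model (r scale)
  cortex_cortex_r: 0.35
  homotopic_r: 0.95
  rest_local_z: {Caudate-Putamen: 0.20, Caudate-Pallidum: 0.20, Putamen-Pallidum: 0.50}

# correlations between local basal-ganglia z-FC and behavioural measures,
# per group; columns are (fss, rt_t2, rt_t3, force_t2, force_t3)
fc_behaviour:
  HC:
    T2:
      Caudate-Putamen: [-0.22, -0.19, -0.16, -0.08, -0.06]
      Caudate-Pallidum: [-0.24, -0.21, -0.18, -0.10, -0.07]
      Putamen-Pallidum: [-0.36, -0.38, -0.20, -0.12, -0.08]
    T3:
      Caudate-Putamen: [-0.19, -0.18, -0.13, -0.07, -0.02]
      Caudate-Pallidum: [-0.21, -0.20, -0.14, -0.09, -0.02]
      Putamen-Pallidum: [-0.28, -0.25, -0.18, -0.06, -0.05]
  MS:
    T2:
      Caudate-Putamen: [-0.23, -0.21, -0.18, -0.11, -0.08]
      Caudate-Pallidum: [-0.24, -0.22, -0.19, -0.13, -0.10]
      Putamen-Pallidum: [-0.38, -0.42, -0.30, -0.20, -0.16]
    T3:
      Caudate-Putamen: [-0.21, -0.18, -0.15, -0.09, -0.05]
      Caudate-Pallidum: [-0.22, -0.21, -0.17, -0.11, -0.06]
      Putamen-Pallidum: [-0.30, -0.29, -0.21, -0.13, -0.09]

behaviour:
  # pooled (both groups combined) correlations of FSS with task behaviour
  pooled_corr: {fss_rt_t2: 0.476, fss_rt_t3: 0.38, fss_force_t2: -0.20, fss_force_t3: -0.10}
  # free within-subject correlation structure
  free_corr: {rt_t2_rt_t3: 0.55, force_t2_force_t3: 0.65, rt_force: -0.10,
              fc_within_task: 0.50, fc_across_task: 0.40}
  fss: {HC: {mean: 23.0, sd: 6.0}, MS: {mean: 50.0, sd: 6.0}}
  hads: {mean: 6.0, sd: 2.5}
  rt_subject_sd_ms: 65.0
  rt_block_noise_sd_ms: 20.0
  force_subject_sd: 3.0
  force_block_noise_sd: 0.3
  force_level_fractions: {low: 0.333, medium: 0.667}
  # per (group, condition, task) block-mean RT (ms), blocks 1..4
  rt_block_means_ms:
    HC:
      handgrip_only: {T2: [380, 390, 400, 420], T3: [355, 357, 358, 360]}
      mental_imagery_first: {T2: [385, 385, 386, 387], T3: [357, 358, 357, 359]}
    MS:
      handgrip_only: {T2: [440, 452, 462, 478], T3: [408, 412, 415, 420]}
      mental_imagery_first: {T2: [448, 452, 455, 459], T3: [410, 418, 426, 438]}
  # per (group, condition, task) block-mean high peak force, blocks 1 and 4
  # transcribed; blocks 2-3 interpolated linearly
  force_block_means_high:
    HC:
      handgrip_only: {T2: [11.01, 10.95], T3: [11.90, 11.01]}
      mental_imagery_first: {T2: [11.65, 10.95], T3: [11.58, 11.02]}
    MS:
      handgrip_only: {T2: [9.83, 9.31], T3: [10.68, 9.76]}
      mental_imagery_first: {T2: [7.30, 6.85], T3: [6.71, 6.05]}

cohort:
  n_hc: 40
  n_ms: 40
  # condition counts [handgrip_only, mental_imagery_first] at n=40;
  # planted RT outliers per group split the same way, so the retained
  # sample reproduces the 19/17 (HC) and 19/18 (MS) condition split
  condition_split: {HC: [21, 19], MS: [21, 19]}
  rt_outliers: {HC: 4, MS: 3}
  outlier_condition_split: {HC: [2, 2], MS: [2, 1]}

noise:
  confound_mix_sd: 0.20      # fraction of unit signal SD per region
  white_noise_sd: 0.20
  drift_sd: 0.30
  motion_step_sd: 0.05

calibration_pilot:
  n_round1: 384    # fixed-target pilots (bias + measurement-noise SD)
  n_round2: 768    # jittered pilots (residual bias + realised moments)
  damped_slope: 0.85
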