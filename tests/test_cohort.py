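import numpy as np
import pandas as pd
import pytest

from bgfc.behaviour import filter_rt_outliers, subject_grand_rt
from bgfc.cohort import (
    CohortSpec,
    behaviour_table,
    calibrate_pipeline,
    generate_cohort,
    plant_rt_outliers,
)
from bgfc.pipeline import RunConfig, compute_fc_table

from conftest import TINY_PILOT


def test_spec_validation_rejects_infeasible_coupling():
    with pytest.raises(ValueError, match="rejected"):
        CohortSpec.default(overrides={
            "coupling": {"local": {"HC": {"T2": {"Putamen-Pallidum": {"z": 3.5, "sd": 0.5}}}}}
        })
    with pytest.raises(ValueError, match="negative"):
        CohortSpec.default(overrides={
            "coupling": {"local": {"HC": {"T2": {"Putamen-Pallidum": {"z": 1.0, "sd": -0.1}}}}}
        })
    with pytest.raises(ValueError, match="at least 2"):
        CohortSpec.default(n_hc=1)


def test_same_seed_is_bit_identical(small_spec):
    a = generate_cohort(small_spec, seed=11)
    b = generate_cohort(small_spec, seed=11)
    for sa, sb in zip(a, b):
        assert sa.subject_id == sb.subject_id
        np.testing.assert_array_equal(sa.roi_timeseries.data, sb.roi_timeseries.data)
        np.testing.assert_array_equal(sa.confounds.motion, sb.confounds.motion)
        assert sa.behaviour == sb.behaviour


def test_different_seeds_differ(small_spec, small_cohort):
    other = generate_cohort(small_spec, seed=12)
    assert not np.array_equal(
        other[0].roi_timeseries.data, small_cohort[0].roi_timeseries.data
    )


def test_cohort_composition(small_cohort):
    groups = [s.group for s in small_cohort]
    assert groups.count("HC") == 4 and groups.count("MS") == 4
    table = behaviour_table(small_cohort)
    # one record per subject x task x block
    assert len(table) == 8 * 3 * 4
    t1 = table[table["task"] == "T1"]
    assert t1["mean_rt_ms"].isna().all()  # self-paced control task has no RT
    assert table[table["task"] != "T1"]["mean_rt_ms"].notna().all()


def test_null_coupling_gives_null_local_fc():
    zero_local = {p: {"z": 0.0, "sd": 0.0} for p in
                  ("Caudate-Putamen", "Caudate-Pallidum", "Putamen-Pallidum")}
    zero_global = {s: 0.0 for s in ("Caudate", "Putamen", "Pallidum")}
    overrides = {
        "coupling": {
            "local": {g: {t: zero_local for t in ("T1", "T2", "T3")} for g in ("HC", "MS")},
            "global": {g: {t: zero_global for t in ("T1", "T2", "T3")} for g in ("HC", "MS")},
            "rest_local_z": {p: 0.0 for p in zero_local},
        },
        "calibration_pilot": {"n_round1": 48, "n_round2": 48},
    }
    spec = CohortSpec.default(n_hc=200, n_ms=2, seed=5, rt_outliers={"HC": 0, "MS": 0},
                              overrides=overrides)
    subs = generate_cohort(spec, seed=5, groups=("HC",))
    fc = compute_fc_table(subs, spec.schedule, RunConfig(blocks=(), tasks=("T2",)))
    grand = fc["local_Putamen-Pallidum"].mean()
    assert -0.05 <= grand <= 0.05


class TestPlantOutliers:
    def test_zero_outliers_leaves_table_unchanged(self, small_cohort):
        table = behaviour_table(small_cohort)
        planted = plant_rt_outliers(table, 0, seed=1)
        pd.testing.assert_frame_equal(planted, table)

    def test_planted_counts_and_bruteforce_z(self):
        spec = CohortSpec.default(seed=42)  # default 40+40 with 4 HC / 3 MS outliers
        subs = generate_cohort(spec, seed=42, include_imaging=False)
        table = behaviour_table(subs)
        grand = subject_grand_rt(table)
        groups = table.drop_duplicates("subject").set_index("subject")["group"]
        for group, expected_removed in (("HC", 4), ("MS", 3)):
            ids = groups[groups == group].index
            vals = grand.loc[ids]
            z = (vals - vals.mean()) / vals.std(ddof=1)
            assert (z.abs() > 2).sum() == expected_removed

    def test_default_fixture_retains_37_ms_and_36_hc(self):
        spec = CohortSpec.default(seed=42)
        subs = generate_cohort(spec, seed=42, include_imaging=False)
        _, _, report = filter_rt_outliers(behaviour_table(subs))
        kept = report.loc[~report["removed"]].groupby("group")["subject"].nunique()
        assert kept["MS"] == 37
        assert kept["HC"] == 36
        # retained condition split matches the recruitment of the two arms
        retained = behaviour_table(subs)
        retained = retained[retained["subject"].isin(
            report.loc[~report["removed"], "subject"])]
        split = retained.drop_duplicates("subject").groupby(
            ["group", "condition"]).size()
        assert split["HC", "handgrip_only"] == 19
        assert split["HC", "mental_imagery_first"] == 17
        assert split["MS", "handgrip_only"] == 19
        assert split["MS", "mental_imagery_first"] == 18

    def test_infeasible_planting_errors(self, small_cohort):
        table = behaviour_table(small_cohort)
        with pytest.raises(ValueError, match="cannot plant"):
            plant_rt_outliers(table, {"HC": 4, "MS": 0}, seed=1)


def test_behaviour_only_mode_has_no_imaging(small_spec):
    subs = generate_cohort(small_spec, seed=3, include_imaging=False)
    assert all(s.roi_timeseries is None for s in subs)
    assert all(s.behaviour is not None for s in subs)


def test_calibration_is_deterministic_and_cached(small_spec):
    a = calibrate_pipeline(small_spec, ("HC",))
    b = calibrate_pipeline(small_spec, ("HC",))
    assert a is b  # cached by spec content
    np.testing.assert_array_equal(a.q_mu["HC"], b.q_mu["HC"])


def test_fss_and_hads_within_instrument_ranges(small_cohort):
    for s in small_cohort:
        assert 9 <= s.behaviour.fss_total <= 63
        assert 0 <= s.behaviour.hads_anxiety <= 21
        assert 0 <= s.behaviour.hads_depression <= 21


def test_roi_series_match_schedule_length(small_spec, small_cohort):
    from bgfc.schedule import n_volumes_for

    expected = n_volumes_for(small_spec.schedule, small_spec.tr_seconds)
    for s in small_cohort:
        assert s.roi_timeseries.n_volumes == expected
        assert s.roi_timeseries.n_regions == 116
        assert s.confounds.n_volumes == expected
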