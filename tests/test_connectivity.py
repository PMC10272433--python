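import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgfc.atlas import BG_REGIONS, load_aal116
from bgfc.connectivity import (
    BG_PAIRS,
    BG_SEEDS,
    FCMatrix,
    correlation_matrix,
    fisher_z,
    global_bg_fc,
    local_bg_fc,
)

NAMES = load_aal116().names
BG_IDX = {n: NAMES.index(n) for n in BG_REGIONS}


def _z_matrix(values):
    return FCMatrix(values, "fisher_z", NAMES)


def _random_z(rng):
    m = rng.standard_normal((116, 116)) * 0.3
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return _z_matrix(m)


def test_identical_and_negated_columns():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(40)
    data = np.column_stack([x, x, -(x - x.mean()), rng.standard_normal(40)])
    m = correlation_matrix(data, ("a", "b", "c", "d"))
    assert m.values[0, 1] == pytest.approx(1.0)
    assert m.values[0, 2] == pytest.approx(-1.0)


def test_matrix_matches_pairwise_pearson_oracle(rng):
    data = rng.standard_normal((40, 5))
    m = correlation_matrix(data, tuple("abcde"))
    for i in range(5):
        for j in range(5):
            x, y = data[:, i], data[:, j]
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
            assert m.values[i, j] == pytest.approx(r, abs=1e-12)


def test_zero_variance_column_error_names_region(rng):
    data = rng.standard_normal((30, 3))
    data[:, 1] = 7.0
    with pytest.raises(ValueError, match="b"):
        correlation_matrix(data, ("a", "b", "c"))


def test_fisher_z_values():
    r = np.zeros((3, 3))
    r[0, 1] = r[1, 0] = 0.8365
    np.fill_diagonal(r, 1.0)
    z = fisher_z(FCMatrix(r, "pearson_r", ("a", "b", "c")))
    expected = 0.5 * math.log((1 + 0.8365) / (1 - 0.8365))
    assert z.values[0, 1] == pytest.approx(expected, abs=1e-12)
    assert round(z.values[0, 1], 3) == 1.209
    assert z.values[0, 2] == 0.0
    assert np.all(np.diag(z.values) == 0.0)


def test_fisher_z_requires_r_scale(rng):
    with pytest.raises(ValueError, match="pearson_r"):
        fisher_z(_random_z(rng))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=-0.999, max_value=0.999))
def test_fisher_z_antisymmetry(r):
    m = np.array([[1.0, r], [r, 1.0]])
    mp = np.array([[1.0, -r], [-r, 1.0]])
    z = fisher_z(FCMatrix(m, "pearson_r", ("a", "b"))).values[0, 1]
    zn = fisher_z(FCMatrix(mp, "pearson_r", ("a", "b"))).values[0, 1]
    assert zn == pytest.approx(-z, abs=1e-12)


def test_local_fc_constant_matrix():
    vals = np.full((116, 116), 0.7)
    np.fill_diagonal(vals, 0.0)
    m = _z_matrix(vals)
    for pair in BG_PAIRS:
        assert local_bg_fc(m, pair) == pytest.approx(0.7)


def test_local_fc_hand_mean_of_four_edges():
    vals = np.zeros((116, 116))
    edges = {
        ("Putamen_L", "Pallidum_L"): 1.0,
        ("Putamen_L", "Pallidum_R"): 1.2,
        ("Putamen_R", "Pallidum_L"): 1.1,
        ("Putamen_R", "Pallidum_R"): 1.3,
    }
    for (a, b), v in edges.items():
        vals[BG_IDX[a], BG_IDX[b]] = vals[BG_IDX[b], BG_IDX[a]] = v
    assert local_bg_fc(_z_matrix(vals), "Putamen-Pallidum") == pytest.approx(1.15)


def test_local_fc_excludes_homotopic_edges():
    vals = np.zeros((116, 116))
    # only within-structure edges set: every named pair must ignore them
    for s in ("Caudate", "Putamen", "Pallidum"):
        i, j = BG_IDX[f"{s}_L"], BG_IDX[f"{s}_R"]
        vals[i, j] = vals[j, i] = 9.0
    m = _z_matrix(vals)
    for pair in BG_PAIRS:
        assert local_bg_fc(m, pair) == 0.0


def test_global_fc_counts_110_target_regions(rng):
    m = _random_z(rng)
    bg = set(BG_IDX.values())
    others = [i for i in range(116) if i not in bg]
    assert len(others) == 116 - 6 == 110
    # edge-loop oracle for every seed
    for seed in BG_SEEDS:
        if seed == "BG-average":
            seed_idx = sorted(bg)
        else:
            seed_idx = [BG_IDX[f"{seed}_L"], BG_IDX[f"{seed}_R"]]
        acc = [m.values[i, j] for i in seed_idx for j in others]
        assert len(acc) == len(seed_idx) * 110
        assert global_bg_fc(m, seed) == pytest.approx(np.mean(acc), abs=1e-12)


def test_global_fc_constant_off_diagonal():
    vals = np.full((116, 116), 0.4)
    np.fill_diagonal(vals, 0.0)
    m = _z_matrix(vals)
    for seed in BG_SEEDS:
        assert global_bg_fc(m, seed) == pytest.approx(0.4)


def test_global_fc_invariant_to_permuting_non_seed_regions(rng):
    m = _random_z(rng)
    before = {seed: global_bg_fc(m, seed) for seed in BG_SEEDS}
    bg = sorted(BG_IDX.values())
    others = np.array([i for i in range(116) if i not in bg])
    perm = np.arange(116)
    perm[others] = others[rng.permutation(len(others))]
    permuted = FCMatrix(
        m.values[np.ix_(perm, perm)],
        "fisher_z",
        tuple(NAMES[i] for i in perm),
    )
    for seed in BG_SEEDS:
        assert global_bg_fc(permuted, seed) == pytest.approx(before[seed], abs=1e-12)


def test_bg_statistics_are_linear_in_the_matrix(rng):
    m = _random_z(rng)
    scaled = _z_matrix(2.5 * m.values)
    for pair in BG_PAIRS:
        assert local_bg_fc(scaled, pair) == pytest.approx(2.5 * local_bg_fc(m, pair))
    for seed in BG_SEEDS:
        assert global_bg_fc(scaled, seed) == pytest.approx(2.5 * global_bg_fc(m, seed))


def test_unknown_pair_and_seed_names():
    m = _z_matrix(np.zeros((116, 116)))
    with pytest.raises(KeyError):
        local_bg_fc(m, "Putamen-Thalamus")
    with pytest.raises(KeyError):
        global_bg_fc(m, "Thalamus")


def test_fc_matrix_rejects_asymmetry():
    vals = np.zeros((3, 3))
    vals[0, 1] = 0.2
    with pytest.raises(ValueError, match="symmetric"):
        FCMatrix(vals, "fisher_z", ("a", "b", "c"))


def test_fc_matrix_tsv_roundtrip(tmp_path, rng):
    m = _random_z(rng)
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    back = FCMatrix.from_tsv(path, "fisher_z")
    np.testing.assert_allclose(back.values, m.values, atol=1e-12)
    assert back.region_names == m.region_names
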