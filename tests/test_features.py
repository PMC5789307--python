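"""The 14 per-epoch movement metrics and the labelled feature matrix."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_epoch, naive_features, random_epoch
from lamegait.features import (
    FEATURE_NAMES,
    EpochFeatureExtractor,
    build_feature_matrix,
    compute_features,
    read_feature_matrix,
    write_feature_matrix,
)


def test_constant_unit_x_closed_forms():
    ep = make_epoch(np.column_stack([np.ones(120), np.zeros(120), np.zeros(120)]))
    f = compute_features(ep)
    assert f["Ax"] == 1.0 and f["Ay"] == 0.0 and f["Az"] == 0.0
    assert f["MV"] == 0.0
    assert f["SMA"] == 1.0
    assert f["AI"] == 1.0
    assert f["Entropy"] == pytest.approx(2.0 * math.log(2.0), abs=1e-15)
    assert f["Energy"] == 1.0
    assert f["MaxX"] == f["MinX"] == 1.0
    assert f["MaxY"] == f["MinY"] == 0.0


def test_all_zero_epoch_gives_all_zero_features():
    f = compute_features(make_epoch(np.zeros((50, 3))))
    assert all(v == 0.0 for v in f.values())


def test_four_sample_epoch_matches_frozen_hand_computed_table():
    samples = np.zeros((4, 3))
    samples[:, 0] = [0.1, -0.2, 0.3, 0.0]
    f = compute_features(make_epoch(samples))
    expected = {
        "Ax": 0.05, "Ay": 0.0, "Az": 0.0,
        "MV": 0.275, "SMA": 0.15, "AI": 0.15,
        "Entropy": 0.06684997513528201, "Energy": 0.00245,
        "MaxX": 0.3, "MaxY": 0.0, "MaxZ": 0.0,
        "MinX": -0.2, "MinY": 0.0, "MinZ": 0.0,
    }
    for name in FEATURE_NAMES:
        assert f[name] == pytest.approx(expected[name], abs=1e-12), name
    # and the naive per-sample oracle agrees with the same table
    nf = naive_features(samples)
    for name in FEATURE_NAMES:
        assert nf[name] == pytest.approx(expected[name], abs=1e-12), name


def test_vectorized_agrees_with_naive_oracle_on_random_epochs(rng):
    for _ in range(200):
        ep = random_epoch(rng, n=int(rng.integers(2, 121)),
                          scale=float(rng.uniform(0.1, 2.0)))
        f = compute_features(ep)
        nf = naive_features(ep.samples)
        for name in FEATURE_NAMES:
            assert f[name] == pytest.approx(nf[name], abs=1e-10), name


@given(c=st.floats(-0.5, 0.5), seed=st.integers(0, 100))
def test_shift_property_against_naive_oracle(c, seed):
    rng = np.random.default_rng(seed)
    s = rng.normal(0, 0.3, size=(30, 3))
    shifted = s.copy()
    shifted[:, 0] += c
    f0 = compute_features(make_epoch(s))
    f1 = compute_features(make_epoch(shifted))
    assert f1["Ax"] == pytest.approx(f0["Ax"] + c, abs=1e-12)
    assert f1["MaxX"] == pytest.approx(f0["MaxX"] + c, abs=1e-12)
    assert f1["MinX"] == pytest.approx(f0["MinX"] + c, abs=1e-12)
    assert f1["MV"] == pytest.approx(f0["MV"], abs=1e-12)
    nf1 = naive_features(shifted)
    for name in ("SMA", "AI", "Entropy", "Energy"):
        assert f1[name] == pytest.approx(nf1[name], abs=1e-10)


@given(s_factor=st.floats(0.1, 5.0), seed=st.integers(0, 100))
def test_scale_property_for_linear_features(s_factor, seed):
    rng = np.random.default_rng(seed)
    samples = rng.normal(0, 0.3, size=(30, 3))
    f0 = compute_features(make_epoch(samples))
    f1 = compute_features(make_epoch(samples * s_factor))
    for name in ("MV", "SMA", "AI"):
        assert f1[name] == pytest.approx(s_factor * f0[name], rel=1e-10)


def test_extrema_bound_the_mean(rng):
    f = compute_features(random_epoch(rng))
    for axis in "XYZ":
        assert f[f"Min{axis}"] <= f[f"A{axis.lower()}"] <= f[f"Max{axis}"]
    assert f["MV"] >= 0 and f["SMA"] >= 0 and f["AI"] >= 0 and f["Energy"] >= 0


def test_single_sample_epoch_rejected():
    with pytest.raises(ValueError, match="2 samples"):
        compute_features(make_epoch(np.ones((1, 3))))


def test_non_finite_input_rejected():
    s = np.ones((10, 3))
    s[3, 1] = np.nan
    with pytest.raises(ValueError, match="finite"):
        compute_features(make_epoch(s))


def test_entropy_guard_warns_or_rejects():
    s = np.full((10, 3), -1.0)  # 1 + Ts = -2
    with pytest.warns(RuntimeWarning, match="entropy"):
        f = compute_features(make_epoch(s))
    assert f["Entropy"] == pytest.approx(-2.0 * math.log(2.0))
    with pytest.raises(ValueError, match="entropy"):
        compute_features(make_epoch(s), entropy_guard="reject")


class TestFeatureMatrix:
    def epochs(self, rng, behaviours, deployment="ear"):
        out = []
        for i, b in enumerate(behaviours):
            out.append(random_epoch(rng, behaviour=b, animal_id="a1",
                                    deployment=deployment, start_time=10.0 * i))
        return out

    def test_row_per_epoch_stable_order(self, rng):
        eps = self.epochs(rng, ["sound_grazing", "sound_walking", "lame_walking"])
        m = build_feature_matrix(eps)
        assert len(m) == 3
        assert m["behaviour"].tolist() == ["sound_grazing", "sound_walking",
                                           "lame_walking"]
        assert list(m.columns[:14]) == list(FEATURE_NAMES)

    def test_analysis_class_filters(self, rng):
        eps = self.epochs(rng, ["sound_grazing", "lame_grazing", "lame_standing",
                                "lame_lying", "lame_walking"])
        m1 = build_feature_matrix(eps, analysis="I")
        assert sorted(m1["behaviour"]) == ["lame_grazing", "lame_walking",
                                           "sound_grazing"]
        m2 = build_feature_matrix(eps, analysis="II")
        assert sorted(m2["behaviour"]) == ["lame_walking", "sound_grazing"]
        assert len(eps) - len(m2) == 3

    def test_mixed_deployments_rejected(self, rng):
        eps = (self.epochs(rng, ["sound_grazing"], deployment="ear")
               + self.epochs(rng, ["sound_walking"], deployment="leg"))
        with pytest.raises(ValueError, match="deployment"):
            build_feature_matrix(eps)

    def test_csv_round_trip_to_12_significant_digits(self, rng, tmp_path):
        m = build_feature_matrix(self.epochs(rng, ["sound_grazing",
                                                   "lame_walking"]))
        path = tmp_path / "features.csv"
        write_feature_matrix(m, path)
        back = read_feature_matrix(path)
        for name in FEATURE_NAMES:
            np.testing.assert_allclose(back[name], m[name], rtol=1e-12)

    def test_transformer_wrapper_matches_function(self, rng):
        eps = self.epochs(rng, ["sound_grazing", "lame_walking"])
        direct = build_feature_matrix(eps)
        via = EpochFeatureExtractor().fit_transform(eps)
        assert via.equals(direct)
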