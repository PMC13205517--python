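"""Surrogate Synchrony: segmentation, lagged Z, surrogates, effect sizes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import facesync as fs
from facesync.errors import ContractError, SurrogateError
from facesync.susy import SusyConfig, _aggregate


def _cfg(**kw):
    base = dict(segment_seconds=5.0, maxlag_seconds=0.0, rate=1.0,
                n_surrogates=10, seed=0)
    base.update(kw)
    return SusyConfig(**base)


# ---------------------------------------------------------------------------
# Lag axis and segmentation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "maxlag_s, rate",
    [(0.0, 1.0), (3.0, 5.0), (2.0, 4.7), (1.0, 1.0), (0.5, 30.0)],
)
def test_lag_axis_has_2_round_lf_plus_1_entries(maxlag_s, rate):
    cfg = SusyConfig(segment_seconds=20.0, maxlag_seconds=maxlag_s,
                     rate=rate, seed=0)
    expected = 2 * int(round(maxlag_s * rate)) + 1
    assert len(cfg.lags) == expected
    rng = np.random.default_rng(1)
    T = int(60 * rate)
    dz = fs.lagged_segment_z(rng.normal(size=T), rng.normal(size=T), cfg)
    assert dz.z.shape == (T // cfg.segment_samples, expected)


def test_trailing_partial_segment_is_dropped():
    cfg = _cfg()
    rng = np.random.default_rng(2)
    dz = fs.lagged_segment_z(rng.normal(size=23), rng.normal(size=23), cfg)
    assert dz.z.shape[0] == 4  # 23 // 5


def test_segment_times_are_closed_sample_intervals():
    cfg = _cfg(rate=1.0)
    rng = np.random.default_rng(3)
    dz = fs.lagged_segment_z(rng.normal(size=20), rng.normal(size=20), cfg)
    np.testing.assert_array_equal(
        dz.segment_times, [[0, 4], [5, 9], [10, 14], [15, 19]]
    )


# ---------------------------------------------------------------------------
# Correlation values
# ---------------------------------------------------------------------------

def test_identical_series_hit_the_fisher_z_clip():
    x = np.random.default_rng(4).normal(size=20)
    dz = fs.lagged_segment_z(x, x.copy(), _cfg())
    np.testing.assert_allclose(dz.z, np.arctanh(1 - 1e-7))


def test_sign_inverted_series_give_negative_z():
    x = np.random.default_rng(5).normal(size=20)
    dz = fs.lagged_segment_z(x, -x, _cfg())
    np.testing.assert_allclose(dz.z, np.arctanh(-(1 - 1e-7)))


def test_z_symmetric_under_series_swap_at_lag_zero():
    rng = np.random.default_rng(6)
    a, b = rng.normal(size=25), rng.normal(size=25)
    za = fs.lagged_segment_z(a, b, _cfg())
    zb = fs.lagged_segment_z(b, a, _cfg())
    np.testing.assert_allclose(za.z, zb.z, atol=1e-12)


def test_zero_variance_segment_yields_z_zero():
    a = np.concatenate([np.full(5, 2.0), np.random.default_rng(7).normal(size=5)])
    b = np.random.default_rng(8).normal(size=10)
    dz = fs.lagged_segment_z(a, b, _cfg())
    assert dz.z[0, 0] == 0.0
    assert dz.z[1, 0] != 0.0


def test_lagged_z_matches_shifted_pearson():
    # at lag tau, a[t] is paired with b[t + tau] over the segment overlap
    rng = np.random.default_rng(9)
    a, b = rng.normal(size=10), rng.normal(size=10)
    cfg = _cfg(segment_seconds=10.0, maxlag_seconds=2.0)
    dz = fs.lagged_segment_z(a, b, cfg)
    for li, tau in enumerate(range(-2, 3)):
        if tau >= 0:
            r = np.corrcoef(a[: 10 - tau], b[tau:])[0, 1]
        else:
            r = np.corrcoef(a[-tau:], b[: 10 + tau])[0, 1]
        assert dz.z[0, li] == pytest.approx(np.arctanh(r), abs=1e-10)


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------

def test_surrogate_config_rejects_lag_not_shorter_than_segment():
    with pytest.raises(ContractError):
        SusyConfig(segment_seconds=5.0, maxlag_seconds=5.0, rate=1.0)


def test_too_short_series_raises_surrogate_error():
    x = np.arange(8.0)
    with pytest.raises(SurrogateError):
        fs.circular_surrogates(x, x, _cfg())  # needs >= 10 samples


def test_surrogates_deterministic_under_seed():
    rng = np.random.default_rng(10)
    a, b = rng.normal(size=40), rng.normal(size=40)
    s1 = fs.circular_surrogates(a, b, _cfg(seed=42))
    s2 = fs.circular_surrogates(a, b, _cfg(seed=42))
    np.testing.assert_array_equal(s1, s2)
    s3 = fs.circular_surrogates(a, b, _cfg(seed=43))
    assert not np.array_equal(s1, s3)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_rotation_preserves_value_multiset(seed):
    rng = np.random.default_rng(seed)
    b = rng.normal(size=37)
    offset = int(rng.integers(1, 37))
    rotated = np.roll(b, offset)
    assert np.array_equal(np.sort(rotated), np.sort(b))


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------

def test_effect_size_arithmetic():
    real = np.full((2, 1), 1.5)                       # aggregate 1.5
    surr = np.stack([np.full((2, 1), 0.0), np.full((2, 1), 1.0)])
    # replicate aggregates [0, 1]: mean 0.5, SD (ddof=1) = sqrt(0.5)
    es = fs.effect_size(real, surr)
    assert es == pytest.approx((1.5 - 0.5) / np.sqrt(0.5))


def test_effect_size_zero_when_real_matches_null_mean():
    surr = np.stack([np.full((3, 1), -1.0), np.full((3, 1), 1.0)])
    assert fs.effect_size(np.zeros((3, 1)), surr) == pytest.approx(0.0)


def test_effect_size_undefined_for_degenerate_null():
    surr = np.stack([np.zeros((3, 1))] * 4)
    with pytest.raises(ContractError):
        fs.effect_size(np.ones((3, 1)), surr)


def test_absolute_mean_aggregate():
    z = np.array([[[-1.0, 1.0], [0.5, -0.5]]])
    assert _aggregate(z, "absolute-mean")[0] == pytest.approx(0.75)
    assert _aggregate(z, "signed-mean")[0] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Group runs, summaries, window pooling
# ---------------------------------------------------------------------------

def test_susy_group_enumerates_all_dyads():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(5, 30))
    res = fs.susy_group(X, "", _cfg(n_surrogates=5))
    assert len(res.dyads) == 10  # C(5, 2)
    assert set(res.dyads) == set(res.real) == set(res.surrogate)


def test_susy_group_deterministic_under_seed():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(3, 40))
    r1 = fs.susy_group(X, "", _cfg(seed=7, n_surrogates=5))
    r2 = fs.susy_group(X, "", _cfg(seed=7, n_surrogates=5))
    for d in r1.dyads:
        np.testing.assert_array_equal(r1.surrogate[d], r2.surrogate[d])
        assert r1.es_per_dyad[d] == r2.es_per_dyad[d]


def test_susy_group_accepts_recording_set_channel(processed_set):
    cfg = SusyConfig(segment_seconds=3.0, rate=1.0, n_surrogates=5, seed=1)
    res = fs.susy_group(processed_set, "head_movement", cfg)
    assert len(res.dyads) == 3
    res_emo = fs.susy_group(
        processed_set, "happiness",
        SusyConfig(segment_seconds=3.0, rate=5.0, n_surrogates=5, seed=1),
    )
    assert len(res_emo.dyads) == 3


def test_summary_levels(susy_sim_result):
    res, _ = susy_sim_result
    dyads = fs.susy_summarise(res, "dyad")
    assert len(dyads) == 435
    seg = fs.susy_summarise(res, "segment")
    assert len(seg) == 24  # 120 samples / 5 per segment
    grand = fs.susy_summarise(res, "grand")
    assert grand["z_real_mean"].iloc[0] == pytest.approx(dyads["z_real_mean"].mean())


def test_pooled_window_segment_selection(susy_sim_result):
    res, _ = susy_sim_result
    seg_times = res.real[res.dyads[0]].segment_times
    from facesync.susy import _window_segment_mask

    within = _window_segment_mask(seg_times, (70.0, 80.0), "within")
    intersect = _window_segment_mask(seg_times, (70.0, 80.0), "intersect")
    assert within.sum() == 2       # [70,74] and [75,79]
    assert intersect.sum() == 3    # plus [80,84]
    assert np.all(intersect[within])


def test_window_with_no_segments_raises(susy_sim_result):
    res, _ = susy_sim_result
    with pytest.raises(ContractError):
        fs.pooled_window_z(res, (70.0, 71.0), "within")


def test_real_vs_surrogate_pair_count(susy_sim_result):
    res, _ = susy_sim_result
    t, df, p = fs.real_vs_surrogate_test(res, (70.0, 80.0))
    # 435 dyads x 3 intersecting segments x 1 lag - 1
    assert df == 435 * 3 - 1
    assert t > 0 and p < 1e-6
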