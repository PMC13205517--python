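"""Screening, resampling, alignment, head movement and scalarisation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import facesync as fs
from facesync.errors import AlignmentError, ContractError
from facesync.preprocess import (
    Recording, RecordingSet, head_movement_series, interocular_distance_px,
    missingness_fraction,
)
from facesync.template import NOSE_TIP, face_template
from facesync.trace_io import RawRecording, RawTraceRecord


def _raw(timestamps, valid_mask, pid="P1"):
    lm = face_template().points
    records = [
        RawTraceRecord(float(t), pid, {}, lm.copy() if ok else None, None)
        for t, ok in zip(timestamps, valid_mask)
    ]
    return RawRecording(participant_id=pid, group_values={}, records=records)


def _recording(landmarks, rate=5.0):
    T = landmarks.shape[0]
    return Recording(time=np.arange(T) / rate, landmarks=landmarks, rate=rate)


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def test_missingness_fraction_worked_example():
    # span 10 s at 5 Hz -> 50 expected frames; 40 valid -> 0.2 missing
    ts = np.linspace(0.0, 10.0, 41)
    mask = np.ones(41, bool)
    mask[5] = False
    raw = _raw(ts, mask)
    assert missingness_fraction(raw, 5.0) == pytest.approx(1.0 - 40 / 50)


def test_missingness_fraction_clamped_to_unit_interval():
    # more valid frames than expected (oversampled) -> clamp at 0
    ts = np.linspace(0.0, 1.0, 21)  # 20 Hz actual vs 5 Hz expected
    raw = _raw(ts, np.ones(21, bool))
    assert missingness_fraction(raw, 5.0) == 0.0


def test_missingness_threshold_is_strict():
    # span 8 s at 5 Hz -> exactly 40 expected frames; 20 valid -> 0.5 missing.
    # Exactly at the threshold -> kept; strictly above -> excluded.
    ts = np.linspace(0.0, 8.0, 20)
    at = _raw(ts, np.ones(20, bool))
    assert missingness_fraction(at, 5.0) == 0.5
    cfg = fs.PreprocConfig(max_missing_fraction=0.5, target_rate=5.0)
    kept, excluded = fs.filter_by_missingness([at], cfg)
    assert kept == [at] and not excluded
    cfg2 = fs.PreprocConfig(max_missing_fraction=0.4999, target_rate=5.0)
    kept2, excluded2 = fs.filter_by_missingness([at], cfg2)
    assert not kept2 and excluded2[0][0] is at


# ---------------------------------------------------------------------------
# Resampling and alignment
# ---------------------------------------------------------------------------

def test_resample_recovers_linear_trajectory():
    # landmarks moving linearly in time are interpolated exactly
    rng = np.random.default_rng(3)
    ts = np.sort(rng.uniform(0.0, 10.0, 80))
    ts[0], ts[-1] = 0.0, 10.0
    base = face_template().points
    vel = rng.normal(0, 1.0, size=(68, 2))
    records = [
        RawTraceRecord(float(t), "P1", {}, base + vel * t, None) for t in ts
    ]
    raw = RawRecording("P1", {}, records)
    rec = fs.resample_to_grid(raw, fs.PreprocConfig(target_rate=5.0))
    expected = base[None] + vel[None] * rec.time[:, None, None]
    np.testing.assert_allclose(rec.landmarks, expected, atol=1e-9)
    assert rec.time[0] == 0.0
    np.testing.assert_allclose(np.diff(rec.time), 0.2)


def test_resample_grid_stays_inside_valid_span():
    ts = np.array([0.3, 0.9, 1.7, 2.5, 3.1])
    raw = _raw(ts, np.ones(5, bool))
    rec = fs.resample_to_grid(raw, fs.PreprocConfig(target_rate=5.0))
    assert rec.time[0] == pytest.approx(0.3)
    assert rec.time[-1] <= 3.1 + 1e-12


def test_align_common_overlap_uses_phase_aligned_grid():
    base = face_template().points
    r1 = Recording(time=0.3 + np.arange(50) * 0.2,
                   landmarks=np.tile(base, (50, 1, 1)), rate=5.0)
    r2 = Recording(time=1.1 + np.arange(55) * 0.2,
                   landmarks=np.tile(base, (55, 1, 1)), rate=5.0)
    out = fs.align_group([r1, r2], fs.PreprocConfig(target_rate=5.0))
    # overlap [1.1, 10.1]; phase-aligned grid points k/5 in that span
    assert out.time[0] == pytest.approx(1.2)
    assert out.time[-1] == pytest.approx(10.0)
    assert len(out.time) == 45
    # every grid point is an integer multiple of the step
    np.testing.assert_allclose(out.time * 5.0, np.round(out.time * 5.0), atol=1e-9)


def test_align_fixed_duration_gives_relative_axis():
    base = face_template().points
    recs = [
        Recording(time=off + np.arange(60) * 0.2,
                  landmarks=np.tile(base, (60, 1, 1)), rate=5.0)
        for off in (0.0, 3.7)
    ]
    cfg = fs.PreprocConfig(trim_policy="fixed-duration", fixed_duration_seconds=8.0)
    out = fs.align_group(recs, cfg)
    assert len(out.time) == 41
    assert out.time[0] == 0.0 and out.time[-1] == pytest.approx(8.0)


def test_align_disjoint_spans_raises():
    base = face_template().points
    r1 = Recording(time=np.arange(10) * 0.2, landmarks=np.tile(base, (10, 1, 1)), rate=5.0)
    r2 = Recording(time=5.0 + np.arange(10) * 0.2, landmarks=np.tile(base, (10, 1, 1)), rate=5.0)
    with pytest.raises(AlignmentError):
        fs.align_group([r1, r2], fs.PreprocConfig())


# ---------------------------------------------------------------------------
# Head movement
# ---------------------------------------------------------------------------

def test_head_movement_one_interocular_distance_is_6_3_cm():
    # nose tip travels exactly one IOD (63 px) of path within the first second
    base = face_template().points
    lm = np.tile(base, (11, 1, 1))
    lm[1:6, NOSE_TIP - 1, 0] += 12.6 * np.arange(1, 6)
    lm[6:, NOSE_TIP - 1, 0] += 63.0
    rec = _recording(lm, rate=5.0)
    hm = head_movement_series(rec, fs.PreprocConfig(target_rate=5.0))
    assert abs(hm[0] - 6.3) < 1e-12
    assert abs(hm[1]) < 1e-12


def test_head_movement_stationary_face_is_zero():
    lm = np.tile(face_template().points, (16, 1, 1))
    rec = _recording(lm, rate=5.0)
    hm = head_movement_series(rec, fs.PreprocConfig())
    np.testing.assert_array_equal(hm, 0.0)


def test_head_movement_invariant_to_camera_zoom():
    # scaling all pixel coordinates rescales IOD and displacement alike
    rng = np.random.default_rng(5)
    lm = np.tile(face_template().points, (26, 1, 1))
    lm[:, NOSE_TIP - 1, :] += np.cumsum(rng.normal(0, 2.0, size=(26, 2)), axis=0)
    cfg = fs.PreprocConfig(target_rate=5.0)
    hm1 = head_movement_series(_recording(lm), cfg)
    hm2 = head_movement_series(_recording(lm * 3.5), cfg)
    np.testing.assert_allclose(hm1, hm2, rtol=1e-12)


def test_interocular_distance_of_template_is_63_px():
    rec = _recording(np.tile(face_template().points, (6, 1, 1)))
    assert interocular_distance_px(rec) == pytest.approx(63.0, abs=1e-9)


def test_head_movement_mean_stat_divides_by_frames_per_second():
    lm = np.tile(face_template().points, (11, 1, 1))
    lm[:, NOSE_TIP - 1, 0] += 2.0 * np.arange(11)  # constant 2 px per frame
    rec = _recording(lm, rate=5.0)
    hm_sum = head_movement_series(rec, fs.PreprocConfig(head_movement_stat="sum"))
    hm_mean = head_movement_series(rec, fs.PreprocConfig(head_movement_stat="mean"))
    np.testing.assert_allclose(hm_sum, 5.0 * hm_mean, rtol=1e-12)


def test_movement_summary_levels(processed_set):
    per_part = fs.movement_summary(processed_set, "participant")
    assert len(per_part) == processed_set.n_subjects
    hand_mean = float(np.mean(processed_set.recordings[0].head_movement))
    assert per_part["mean"].iloc[0] == pytest.approx(hand_mean)
    per_sec = fs.movement_summary(processed_set, "per-second")
    assert len(per_sec) == len(processed_set.recordings[0].head_movement)
    cond = fs.movement_summary(processed_set, "condition")
    assert cond["mean"].iloc[0] == pytest.approx(per_part["mean"].mean())


# ---------------------------------------------------------------------------
# Scalarisation
# ---------------------------------------------------------------------------

def test_vector_norm_is_distance_from_mean_position():
    # a landmark alternating ±(3, 4) px around its mean is always 5 px away
    lm = np.tile(face_template().points, (10, 1, 1))
    lm[::2, 0, :] += np.array([3.0, 4.0])
    lm[1::2, 0, :] -= np.array([3.0, 4.0])
    rs = RecordingSet([_recording(lm), _recording(lm.copy())])
    feats = fs.scalarize(rs, "vector_norm")
    np.testing.assert_allclose(feats.data[:, 0, :], 5.0, rtol=1e-12)


def test_motion_amplitude_first_sample_zero_and_steps():
    lm = np.tile(face_template().points, (6, 1, 1))
    lm[:, 2, 0] += np.array([0.0, 1.0, 3.0, 3.0, 7.0, 7.0])
    rs = RecordingSet([_recording(lm), _recording(lm.copy())])
    feats = fs.scalarize(rs, "motion_amplitude")
    np.testing.assert_allclose(
        feats.data[0, 2, :], [0.0, 1.0, 2.0, 0.0, 4.0, 0.0], atol=1e-12
    )


@settings(max_examples=25, deadline=None)
@given(
    dx=st.floats(-500, 500, allow_nan=False),
    dy=st.floats(-500, 500, allow_nan=False),
)
def test_scalarisations_invariant_to_rigid_translation(dx, dy):
    rng = np.random.default_rng(9)
    lm = np.tile(face_template().points, (12, 1, 1)) + rng.normal(0, 1, (12, 68, 2))
    shifted = lm + np.array([dx, dy])
    for mode in ("vector_norm", "motion_amplitude"):
        a = fs.scalarize(RecordingSet([_recording(lm), _recording(lm)]), mode)
        b = fs.scalarize(RecordingSet([_recording(shifted), _recording(shifted)]), mode)
        np.testing.assert_allclose(a.data, b.data, atol=1e-8)


def test_scalarize_unknown_mode_rejected(processed_set):
    with pytest.raises(ContractError):
        fs.scalarize(processed_set, "pca")


def test_preprocess_group_end_to_end(processed_set):
    assert processed_set.n_subjects == 3
    assert processed_set.rate == 5.0
    for rec in processed_set.recordings:
        assert rec.landmarks.shape == (len(processed_set.time), 68, 2)
        assert rec.head_movement is not None
        np.testing.assert_allclose(np.diff(rec.time), 0.2)
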