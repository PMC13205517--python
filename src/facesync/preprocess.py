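"""Preprocessing of raw landmark recordings.

Webcam landmark capture is irregularly sampled with dropped frames, so before
any synchrony analysis each recording is (1) screened by its fraction of
missing frames, (2) linearly interpolated onto a uniform time grid, and
(3) trimmed so all recordings in a group share the same grid. Head movement
is quantified as per-second "nose energy" — the summed frame-to-frame path
length of the nose tip (landmark #34) — converted from pixels to centimetres
via the inter-ocular distance (6.3 cm adult average). Landmark X/Y
trajectories are compressed to one scalar series per landmark either as the
distance from the landmark's mean-centred position (vector norm,

    r(t) = sqrt(x'(t)^2 + y'(t)^2),   x', y' mean-centred over the recording)

or as frame-to-frame motion amplitude

    d(t) = sqrt((x_t - x_{t-1})^2 + (y_t - y_{t-1})^2),   d(0) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ContractError, InputError, ScalingError
from .template import region_indices, NOSE_TIP
from .trace_io import EMOTIONS, RawRecording

logger = logging.getLogger(__name__)

SCALARISATION_MODES = ("vector_norm", "motion_amplitude")


@dataclass
class PreprocConfig:
    """User-settable preprocessing parameters.

    max_missing_fraction: recordings whose missing-frame fraction strictly
        exceeds this are excluded (default 0.5).
    target_rate: uniform grid rate in Hz (default 5, Trace's mean rate).
    trim_policy: "common-overlap" trims all recordings to the intersection of
        their spans on a shared phase-aligned grid; "fixed-duration" truncates
        each recording to ``fixed_duration_seconds`` from its own start.
    iod_cm: physical inter-ocular distance used for pixel→cm scaling.
    head_movement_stat: "sum" (per-second path length, i.e. nose energy) or
        "mean" (mean per-frame displacement within the second).
    """

    max_missing_fraction: float = 0.5
    target_rate: float = 5.0
    interpolation: str = "linear"
    trim_policy: str = "common-overlap"
    fixed_duration_seconds: Optional[float] = None
    iod_cm: float = 6.3
    head_movement_stat: str = "sum"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ContractError("max_missing_fraction must lie in [0, 1]")
        if self.target_rate <= 0:
            raise ContractError("target_rate must be positive")
        if self.interpolation != "linear":
            raise ContractError("only linear interpolation is supported")
        if self.trim_policy not in ("common-overlap", "fixed-duration"):
            raise ContractError("trim_policy must be common-overlap or fixed-duration")
        if self.trim_policy == "fixed-duration" and not self.fixed_duration_seconds:
            raise ContractError("fixed-duration policy requires fixed_duration_seconds")


@dataclass
class Recording:
    """One participant's uniform-grid landmark time series."""

    time: np.ndarray                     # (T,) seconds, constant step 1/rate
    landmarks: np.ndarray                # (T, 68, 2) pixels
    rate: float
    emotion_scores: Optional[np.ndarray] = None  # (T, 7), EMOTIONS order
    head_movement: Optional[np.ndarray] = None   # (seconds,) cm/s
    metadata: dict = field(default_factory=dict)

    @property
    def participant_id(self):
        return self.metadata.get("participant_id")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class RecordingSet:
    """Aligned recordings sharing one time grid."""

    recordings: list[Recording]

    def __post_init__(self) -> None:
        lengths = {len(r.time) for r in self.recordings}
        rates = {r.rate for r in self.recordings}
        if len(lengths) > 1 or len(rates) > 1:
            raise ContractError("recordings in a set must share grid length and rate")

    @property
    def rate(self) -> float:
        return self.recordings[0].rate

    @property
    def time(self) -> np.ndarray:
        return self.recordings[0].time

    @property
    def n_subjects(self) -> int:
        return len(self.recordings)

    def channel(self, name: str) -> np.ndarray:
        """Per-subject 1-D series for a named channel (N × len)."""
        from .errors import ChannelNameError

        if name == "head_movement":
            series = [r.head_movement for r in self.recordings]
            if any(s is None for s in series):
                raise ChannelNameError("head movement has not been computed")
            return np.stack(series)
        if name in EMOTIONS:
            idx = EMOTIONS.index(name)
            if any(r.emotion_scores is None for r in self.recordings):
                raise ChannelNameError(f"emotion channel {name!r} not present")
            return np.stack([r.emotion_scores[:, idx] for r in self.recordings])
        raise ChannelNameError(
            f"unknown channel {name!r}; available: head_movement, {', '.join(EMOTIONS)}"
        )


@dataclass
class FeatureMatrix:
    """Subjects × features × time tensor of scalarised landmark signals."""

    data: np.ndarray                     # (N, D, T)
    feature_labels: list                 # landmark ids (1-based) or names
    subject_ids: list
    rate: float
    mode: str

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# Missingness screening
# ---------------------------------------------------------------------------

def missingness_fraction(raw: RawRecording, expected_rate: float) -> float:
    """Fraction of expected frames without valid landmarks, clamped to [0, 1].

    Expected frames = (t_last − t_first) × expected_rate; rows present in the
    file but with missing/malformed landmarks count as missing.
    """
    ts = raw.timestamps
    if len(ts) < 2 or ts.max() == ts.min():
        raise ContractError("recording duration undefined (fewer than 2 timestamps)")
    expected = (ts.max() - ts.min()) * expected_rate
    frac = 1.0 - raw.n_valid / expected
    return float(np.clip(frac, 0.0, 1.0))


def filter_by_missingness(
    raws: Sequence[RawRecording], config: PreprocConfig
) -> tuple[list[RawRecording], list[tuple[RawRecording, float]]]:
    """Split recordings into (kept, excluded-with-fraction) by the threshold.

    Exclusion is strict: a recording is excluded iff its missingness fraction
    exceeds ``max_missing_fraction``.
    """
    kept, excluded = [], []
    for raw in raws:
        frac = missingness_fraction(raw, config.target_rate)
        if frac > config.max_missing_fraction:
            excluded.append((raw, frac))
            logger.info(
                "excluding %s (missingness %.3f > %.3f)",
                raw.participant_id, frac, config.max_missing_fraction,
            )
        else:
            kept.append(raw)
    return kept, excluded


# ---------------------------------------------------------------------------
# Resampling and alignment
# ---------------------------------------------------------------------------

def resample_to_grid(raw: RawRecording, config: PreprocConfig) -> Recording:
    """Linearly interpolate a raw recording onto a uniform grid.

    The grid spans [first valid timestamp, last valid timestamp] at
    ``target_rate``; interior gaps are bridged linearly and there is no
    extrapolation beyond the valid span.
    """
    valid = [r for r in raw.records if r.landmarks is not None]
    if len(valid) < 2:
        raise InputError("fewer than 2 frames with valid landmarks; cannot resample")
    t = np.array([r.timestamp for r in valid])
    order = np.argsort(t, kind="stable")
    t = t[order]
    coords = np.stack([valid[i].landmarks for i in order]).reshape(len(valid), 136)
    # collapse duplicate timestamps (keep first occurrence)
    uniq, first_idx = np.unique(t, return_index=True)
    t, coords = uniq, coords[first_idx]

    step = 1.0 / config.target_rate
    n = int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    grid = t[0] + np.arange(n) * step
    out = np.empty((n, 136))
    for j in range(136):
        out[:, j] = np.interp(grid, t, coords[:, j])

    emotions = None
    emo_records = [r for r in raw.records if r.emotion_scores is not None]
    if emo_records:
        te = np.array([r.timestamp for r in emo_records])
        eo = np.argsort(te, kind="stable")
        te = te[eo]
        ev = np.array(
            [[emo_records[i].emotion_scores.get(e, np.nan) for e in EMOTIONS] for i in eo]
        )
        keep = ~np.any(np.isnan(ev), axis=1)
        if keep.sum() >= 2:
            tu, iu = np.unique(te[keep], return_index=True)
            evk = ev[keep][iu]
            emotions = np.column_stack(
                [np.interp(grid, tu, evk[:, j]) for j in range(len(EMOTIONS))]
            )

    return Recording(
        time=grid,
        landmarks=out.reshape(n, 68, 2),
        rate=config.target_rate,
        emotion_scores=emotions,
        metadata={
            "participant_id": raw.participant_id,
            "group_values": dict(raw.group_values),
            "settings": asdict(config),
        },
    )


def align_group(recordings: Sequence[Recording], config: PreprocConfig) -> RecordingSet:
    """Trim resampled recordings onto a shared grid.

    common-overlap: all recordings are re-gridded onto the phase-aligned grid
    (points at integer multiples of 1/rate) covering [max start, min end].
    fixed-duration: each recording is truncated to the stated duration from
    its own start and given a relative (0-based) time axis.
    """
    recs = list(recordings)
    if len(recs) < 2:
        raise ContractError("alignment requires at least 2 recordings")
    rates = {r.rate for r in recs}
    if len(rates) > 1:
        raise ContractError("recordings must share a sampling rate")
    rate = recs[0].rate
    step = 1.0 / rate

    if config.trim_policy == "fixed-duration":
        n = int(round(config.fixed_duration_seconds * rate)) + 1
        short = [r.participant_id for r in recs if len(r.time) < n]
        if short:
            raise AlignmentError(f"recordings shorter than fixed duration: {short}")
        out = []
        for r in recs:
            out.append(
                Recording(
                    time=np.arange(n) * step,
                    landmarks=r.landmarks[:n],
                    rate=rate,
                    emotion_scores=None if r.emotion_scores is None else r.emotion_scores[:n],
                    metadata=r.metadata,
                )
            )
        return RecordingSet(out)

    start = max(r.time[0] for r in recs)
    end = min(r.time[-1] for r in recs)
    if end <= start:
        spans = [(r.participant_id, float(r.time[0]), float(r.time[-1])) for r in recs]
        raise AlignmentError(f"recordings have no common temporal overlap: {spans}")
    k0 = int(np.ceil(start * rate - 1e-9))
    k1 = int(np.floor(end * rate + 1e-9))
    grid = np.arange(k0, k1 + 1) * step
    out = []
    for r in recs:
        T = len(grid)
        lm = np.column_stack(
            [np.interp(grid, r.time, r.landmarks.reshape(len(r.time), 136)[:, j]) for j in range(136)]
        ).reshape(T, 68, 2)
        emo = None
        if r.emotion_scores is not None:
            emo = np.column_stack(
                [np.interp(grid, r.time, r.emotion_scores[:, j]) for j in range(r.emotion_scores.shape[1])]
            )
        out.append(Recording(time=grid, landmarks=lm, rate=rate, emotion_scores=emo, metadata=r.metadata))
    return RecordingSet(out)


# ---------------------------------------------------------------------------
# Head movement
# ---------------------------------------------------------------------------

def interocular_distance_px(recording: Recording) -> float:
    """Median over frames of the distance between the two eye centroids."""
    right = recording.landmarks[:, region_indices("right_eye"), :].mean(axis=1)
    left = recording.landmarks[:, region_indices("left_eye"), :].mean(axis=1)
    iod = float(np.median(np.linalg.norm(left - right, axis=1)))
    if not np.isfinite(iod) or iod <= 0:
        raise ScalingError(f"degenerate inter-ocular distance: {iod}")
    return iod


def head_movement_series(recording: Recording, config: PreprocConfig) -> np.ndarray:
    """Per-second head movement (cm/s) from nose-tip path length.

    For each 1-s bin the frame-to-frame Euclidean displacements of landmark
    #34 are summed (or averaged, per ``head_movement_stat``) and scaled from
    pixels to centimetres by iod_cm / IOD-in-pixels.
    """
    per_bin = int(round(recording.rate))
    T = len(recording.time)
    if per_bin < 1 or T - 1 < per_bin:
        raise ContractError("recording must span at least one full second")
    nose = recording.landmarks[:, NOSE_TIP - 1, :]
    disp = np.linalg.norm(np.diff(nose, axis=0), axis=1)  # (T-1,)
    n_bins = (T - 1) // per_bin
    binned = disp[: n_bins * per_bin].reshape(n_bins, per_bin)
    agg = binned.mean(axis=1) if config.head_movement_stat == "mean" else binned.sum(axis=1)
    scale = config.iod_cm / interocular_distance_px(recording)
    return agg * scale


def compute_head_movement(recording_set: RecordingSet, config: PreprocConfig) -> RecordingSet:
    """Fill ``head_movement`` on every recording in the set (in place)."""
    for rec in recording_set.recordings:
        rec.head_movement = head_movement_series(rec, config)
    return recording_set


def movement_summary(recording_set: RecordingSet, level: str = "participant") -> pd.DataFrame:
    """Mean and standard error of head movement at an aggregation level.

    Levels: ``per-second`` (group mean/SE per 1-s bin), ``participant``
    (whole-recording mean per participant), ``whole-recording`` (alias of
    participant), ``condition`` (mean/SE over participants' means, grouped by
    their group values).
    """
    recs = recording_set.recordings
    if any(r.head_movement is None for r in recs):
        raise ContractError("head movement has not been computed")
    if level == "per-second":
        hm = np.stack([r.head_movement for r in recs])
        n = hm.shape[0]
        return pd.DataFrame(
            {
                "second": np.arange(hm.shape[1]),
                "mean": hm.mean(axis=0),
                "se": hm.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(hm.shape[1]),
            }
        )
    per_part = pd.DataFrame(
        {
            "participant": [r.participant_id for r in recs],
            "condition": [str(tuple(sorted(r.metadata.get("group_values", {}).items()))) for r in recs],
            "mean": [float(np.mean(r.head_movement)) for r in recs],
            "se": [
                float(np.std(r.head_movement, ddof=1) / np.sqrt(len(r.head_movement)))
                if len(r.head_movement) > 1 else 0.0
                for r in recs
            ],
        }
    )
    if level in ("participant", "whole-recording"):
        return per_part
    if level == "condition":
        def _se(x):
            return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
        g = per_part.groupby("condition")["mean"]
        return g.agg(mean="mean", se=_se).reset_index()
    raise ContractError(f"unknown aggregation level {level!r}")


# ---------------------------------------------------------------------------
# Scalarisation
# ---------------------------------------------------------------------------

def scalarize(recording_set: RecordingSet, mode: str = "vector_norm") -> FeatureMatrix:
    """Compress each landmark's X/Y trajectory into one scalar series.

    vector_norm: distance from the landmark's mean-centred position (the mean
    is taken over the full recording). motion_amplitude: frame-to-frame
    displacement, first sample 0.
    """
    if mode not in SCALARISATION_MODES:
        raise ContractError(f"mode must be one of {SCALARISATION_MODES}")
    recs = recording_set.recordings
    N, T = len(recs), len(recording_set.time)
    data = np.empty((N, 68, T))
    for i, rec in enumerate(recs):
        xy = rec.landmarks  # (T, 68, 2)
        if mode == "vector_norm":
            centred = xy - xy.mean(axis=0, keepdims=True)
            data[i] = np.linalg.norm(centred, axis=2).T
        else:
            d = np.linalg.norm(np.diff(xy, axis=0), axis=2)  # (T-1, 68)
            data[i] = np.vstack([np.zeros((1, 68)), d]).T
    return FeatureMatrix(
        data=data,
        feature_labels=list(range(1, 69)),
        subject_ids=[r.participant_id for r in recs],
        rate=recording_set.rate,
        mode=mode,
    )


def preprocess_group(raws: Sequence[RawRecording], config: PreprocConfig) -> RecordingSet:
    """Full preprocessing chain: screen → resample → align → head movement."""
    kept, _ = filter_by_missingness(raws, config)
    if len(kept) < 2:
        raise InputError("fewer than 2 recordings survive missingness screening")
    resampled = [resample_to_grid(r, config) for r in kept]
    aligned = align_group(resampled, config)
    return compute_head_movement(aligned, config)
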