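"""Reading and writing Trace-dialect CSV landmark recordings.

Trace exports one CSV row per captured webcam frame: a timestamp, a
participant identifier, optional grouping columns (condition, stimulus, ...),
a landmark cell holding the 68 X/Y pairs as JSON, and seven emotion
classification score columns. Sampling is irregular (~5 Hz mean) and rows may
be missing or malformed; parsing is total — bad landmark cells become missing
values and are logged, never raised.

Processed (uniform-grid) recordings round-trip through a documented CSV
layout: a ``time`` column, 136 stacked coordinate columns ``x1, y1, ...,
x68, y68`` and a ``HeadMovement`` column, plus a JSON manifest sidecar that
carries participant/group metadata, the per-second head-movement series and
the preprocessing settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, InputError

logger = logging.getLogger(__name__)

#: Canonical emotion names in fixed order.
EMOTIONS = ("happiness", "sadness", "fear", "anger", "disgust", "surprise", "neutral")

#: Default Trace column names for the emotion classification scores.
DEFAULT_EMOTION_COLUMNS = {
    "happiness": "happyDetection",
    "sadness": "sadDetection",
    "fear": "fearfulDetection",
    "anger": "angryDetection",
    "disgust": "disgustedDetection",
    "surprise": "surprisedDetection",
    "neutral": "neutralDetection",
}


@dataclass
class ColumnMap:
    """Mapping from Trace CSV column names to their roles.

    Trace's exact column names vary across versions, so every name is
    user-configurable; the defaults match the visible headers of a typical
    Pavlovia export.
    """

    participant_column: str = "participant"
    timestamp_column: str = "timestamp"
    landmark_column: str = "landmarks"
    grouping_columns: list[str] = field(default_factory=list)
    emotion_columns: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EMOTION_COLUMNS)
    )
    timestamp_unit: str = "auto"  # "auto" | "s" | "ms"

    def __post_init__(self) -> None:
        names = [self.participant_column, self.timestamp_column, self.landmark_column]
        names += list(self.grouping_columns)
        if len(set(names)) != len(names):
            raise ConfigurationError("mapped column names must be distinct")
        if self.timestamp_unit not in ("auto", "s", "ms"):
            raise ConfigurationError("timestamp_unit must be 'auto', 's' or 'ms'")


@dataclass
class RawTraceRecord:
    """One captured frame from a Trace CSV."""

    timestamp: float
    participant_id: str
    group_values: dict[str, str]
    landmarks: Optional[np.ndarray]  # (68, 2) or None when missing/malformed
    emotion_scores: Optional[dict[str, float]]


@dataclass
class RawRecording:
    """Time-ordered frames for one participant × grouping combination."""

    participant_id: str
    group_values: dict[str, str]
    records: list[RawTraceRecord]
    parse_log: dict[str, int] = field(default_factory=dict)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([r.timestamp for r in self.records])

    @property
    def n_valid(self) -> int:
        return sum(r.landmarks is not None for r in self.records)


def parse_landmark_cell(text: object) -> Optional[np.ndarray]:
    """Parse a landmark cell into a (68, 2) array, or ``None`` when malformed.

    Accepts either a flat 136-number array ordered x1, y1, x2, y2, ..., x68,
    y68 or a nested array of 68 two-element [x, y] arrays. Never raises:
    anything else (truncated JSON, wrong cardinality, non-numeric entries)
    returns ``None`` with a logged reason.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    try:
        obj = json.loads(text) if isinstance(text, str) else text
    except (json.JSONDecodeError, TypeError) as exc:
        logger.debug("unparseable landmark cell: %s", exc)
        return None
    try:
        arr = np.asarray(obj, dtype=float)
    except (ValueError, TypeError) as exc:
        logger.debug("non-numeric landmark cell: %s", exc)
        return None
    if arr.shape == (136,):
        arr = arr.reshape(68, 2)
    if arr.shape != (68, 2) or not np.all(np.isfinite(arr)):
        logger.debug("landmark cell with shape %s rejected", arr.shape)
        return None
    return arr


def _detect_unit_scale(timestamps: np.ndarray, unit: str) -> float:
    """Seconds-per-unit scale; 'auto' treats median gaps > 10 as milliseconds."""
    if unit == "s":
        return 1.0
    if unit == "ms":
        return 1e-3
    if len(timestamps) >= 2:
        gaps = np.diff(np.sort(timestamps))
        gaps = gaps[gaps > 0]
        if gaps.size and np.median(gaps) > 10.0:
            return 1e-3
    return 1.0


def read_trace_folder(path: str | Path, column_map: ColumnMap | None = None) -> list[RawRecording]:
    """Read every Trace CSV under ``path`` into raw recordings.

    Returns one :class:`RawRecording` per (file × participant × grouping
    combination), rows sorted by timestamp. Rows whose landmark cell fails to
    parse are retained with ``landmarks=None`` so they still count toward
    missingness downstream; per-recording counts are kept in ``parse_log``.
    """
    cm = column_map or ColumnMap()
    folder = Path(path)
    if not folder.is_dir():
        raise InputError(f"not a directory: {folder}")
    csv_files = sorted(folder.glob("*.csv"))
    if not csv_files:
        raise InputError(f"no CSV files found in {folder}")

    recordings: list[RawRecording] = []
    for csv_path in csv_files:
        df = pd.read_csv(csv_path)
        for col in (cm.participant_column, cm.timestamp_column):
            if col not in df.columns:
                raise ConfigurationError(
                    f"{csv_path.name}: missing mandatory column {col!r}"
                )
        if cm.landmark_column not in df.columns:
            raise ConfigurationError(
                f"{csv_path.name}: missing landmark column {cm.landmark_column!r}"
            )
        group_cols = [g for g in cm.grouping_columns if g in df.columns]
        scale = _detect_unit_scale(
            pd.to_numeric(df[cm.timestamp_column], errors="coerce").to_numpy(),
            cm.timestamp_unit,
        )
        emo_cols = {e: c for e, c in cm.emotion_columns.items() if c in df.columns}
        keys = [cm.participant_column] + group_cols
        for key_vals, sub in df.groupby(keys, dropna=False, sort=True):
            if not isinstance(key_vals, tuple):
                key_vals = (key_vals,)
            participant = str(key_vals[0])
            group_values = {g: str(v) for g, v in zip(group_cols, key_vals[1:])}
            sub = sub.sort_values(cm.timestamp_column, kind="stable")
            records: list[RawTraceRecord] = []
            n_missing = n_bad = 0
            for _, row in sub.iterrows():
                ts = float(row[cm.timestamp_column]) * scale
                cell = row[cm.landmark_column]
                lm = parse_landmark_cell(cell)
                if lm is None:
                    if isinstance(cell, str) and cell.strip():
                        n_bad += 1
                    else:
                        n_missing += 1
                emotions = None
                if emo_cols:
                    emotions = {}
                    for emo, col in emo_cols.items():
                        v = row[col]
                        emotions[emo] = float(v) if pd.notna(v) else np.nan
                records.append(
                    RawTraceRecord(ts, participant, group_values, lm, emotions)
                )
            recordings.append(
                RawRecording(
                    participant_id=participant,
                    group_values=group_values,
                    records=records,
                    parse_log={
                        "file": str(csv_path.name),
                        "rows": len(records),
                        "missing_landmarks": n_missing,
                        "bad_landmarks": n_bad,
                    },
                )
            )
            if n_bad or n_missing:
                logger.info(
                    "%s / %s: %d rows, %d missing, %d malformed landmark cells",
                    csv_path.name, participant, len(records), n_missing, n_bad,
                )
    return recordings


def group_records(recordings: Sequence, keys: Sequence[str]) -> dict[tuple, list]:
    """Partition recordings by the ordered tuple of grouping-key values.

    Recordings lacking a key value land in an ``('ungrouped:<key>',)`` group
    (logged) so the partition stays exhaustive and disjoint.
    """
    groups: dict[tuple, list] = {}
    for rec in recordings:
        gv = rec.group_values if hasattr(rec, "group_values") else rec.metadata["group_values"]
        missing = [k for k in keys if k not in gv]
        if missing:
            label = (f"ungrouped:{missing[0]}",)
            logger.info("recording %s lacks grouping key %r", rec.participant_id, missing[0])
        else:
            label = tuple(gv[k] for k in keys)
        groups.setdefault(label, []).append(rec)
    return groups


# ---------------------------------------------------------------------------
# Processed round trip
# ---------------------------------------------------------------------------

def _coordinate_columns() -> list[str]:
    cols = []
    for i in range(1, 69):
        cols += [f"x{i}", f"y{i}"]
    return cols


def write_processed(recording_set, path: str | Path) -> None:
    """Write an aligned recording set as per-recording CSVs plus a manifest.

    Each data file has columns ``time, x1, y1, ..., x68, y68, HeadMovement``
    (head movement is the per-second value repeated for each sample within
    the second), followed by any emotion channels. ``manifest.json`` carries
    the exact per-second head-movement series, metadata and settings so the
    round trip is lossless.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"rate": recording_set.rate, "recordings": []}
    for idx, rec in enumerate(recording_set.recordings):
        fname = f"recording_{idx:03d}.csv"
        T = len(rec.time)
        data = {"time": rec.time}
        flat = rec.landmarks.reshape(T, 136)
        for j, col in enumerate(_coordinate_columns()):
            data[col] = flat[:, j]
        hm = rec.head_movement
        if hm is not None and len(hm):
            bins = np.minimum((np.arange(T) // max(int(round(rec.rate)), 1)), len(hm) - 1)
            data["HeadMovement"] = hm[bins]
        else:
            data["HeadMovement"] = np.full(T, np.nan)
        if rec.emotion_scores is not None:
            for j, emo in enumerate(EMOTIONS):
                data[emo] = rec.emotion_scores[:, j]
        # %.17g + round_trip reader make the numeric round trip bit-exact
        pd.DataFrame(data).to_csv(out / fname, index=False, float_format="%.17g")
        manifest["recordings"].append(
            {
                "file": fname,
                "participant_id": rec.metadata.get("participant_id"),
                "group_values": rec.metadata.get("group_values", {}),
                "settings": rec.metadata.get("settings", {}),
                "head_movement": None if hm is None else [float(v) for v in hm],
                "has_emotions": rec.emotion_scores is not None,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_processed(path: str | Path):
    """Read back a processed recording set written by :func:`write_processed`."""
    from .preprocess import Recording, RecordingSet  # local import avoids a cycle

    folder = Path(path)
    manifest_path = folder / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json in {folder}")
    manifest = json.loads(manifest_path.read_text())
    recordings = []
    for entry in manifest["recordings"]:
        df = pd.read_csv(folder / entry["file"], float_precision="round_trip")
        time = df["time"].to_numpy()
        lms = df[_coordinate_columns()].to_numpy().reshape(len(df), 68, 2)
        emotions = None
        if entry.get("has_emotions"):
            emotions = df[list(EMOTIONS)].to_numpy()
        hm = entry.get("head_movement")
        recordings.append(
            Recording(
                time=time,
                landmarks=lms,
                emotion_scores=emotions,
                head_movement=None if hm is None else np.asarray(hm, dtype=float),
                rate=manifest["rate"],
                metadata={
                    "participant_id": entry.get("participant_id"),
                    "group_values": entry.get("group_values", {}),
                    "settings": entry.get("settings", {}),
                },
            )
        )
    if not recordings:
        raise ContractError("processed set is empty")
    return RecordingSet(recordings=recordings)
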