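"""Synthetic-data generators for the two built-in simulation studies and for
raw Trace-dialect CSV fixtures.

Two study designs are generated:

* Head-movement synchrony (SUSY) study: 30 subjects, 120 s at 1 Hz; each
  subject is unit-SD white Gaussian noise, except inside a 70-80 s window
  where the signal is the convex mix alpha * template + (1 - alpha) * noise
  (alpha = 0.7) with a shared 0.5 Hz sine template. At 1 Hz sampling the
  0.5 Hz sine sits exactly at the Nyquist frequency, so the sampled template
  is determined entirely by its phase (phase 0 samples to all zeros); the
  default phase is pi/2, giving the alternating +/-1 sequence.

* Landmark (CorrCA) study: 30 subjects, 60 s at 5 Hz on the canonical
  68-landmark face template, with per-subject Gaussian spatial offsets
  (sigma = 5 px), white temporal noise, and region-localised oscillatory
  signals injected for participant subsets in stated windows (mouth for
  subjects 1-15 during 20-22 s; left eye for subjects 16-25 during 30-32 s),
  each subject's copy circularly phase-shifted by -2..+2 frames and amplitude
  scaled in [0.8, 1.2].

All generators are bit-reproducible under their seed and return truth labels
marking exactly which samples/subjects carry injected synchrony.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InputError
from .template import FaceTemplate, face_template
from .trace_io import DEFAULT_EMOTION_COLUMNS, EMOTIONS

__all__ = [
    "SusySimSpec", "CorrcaSimSpec", "SyncEvent",
    "simulate_head_movement_study", "simulate_landmark_study",
    "simulate_raw_trace_csv", "face_template", "REGION_SIGNALS",
]


def _default_template(t: np.ndarray, phase: float) -> np.ndarray:
    return np.sin(2 * np.pi * 0.5 * t + phase)


@dataclass
class SusySimSpec:
    """Parameters of the simulated head-movement synchrony study."""

    n_subjects: int = 30
    duration: float = 120.0       # seconds
    rate: float = 1.0             # Hz
    sync_window: tuple[float, float] = (70.0, 80.0)
    alpha: float = 0.7
    template_phase: float = math.pi / 2
    template: Optional[Callable[[np.ndarray], np.ndarray]] = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ContractError("alpha must lie in [0, 1]")
        lo, hi = self.sync_window
        if not (0.0 <= lo < hi <= self.duration):
            raise ContractError("sync_window must lie within the recording")


def simulate_head_movement_study(spec: SusySimSpec) -> tuple[np.ndarray, dict]:
    """Simulate the single-channel synchrony study.

    Returns (X, truth): X is (n_subjects, T) with T = duration * rate; truth
    holds the sample times, the boolean window mask (closed interval) and the
    sampled template.
    """
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.duration * spec.rate))
    t = np.arange(T) / spec.rate
    tmpl_fn = spec.template or (lambda tt: _default_template(tt, spec.template_phase))
    template = tmpl_fn(t)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_subjects, T))
    lo, hi = spec.sync_window
    mask = (t >= lo) & (t <= hi)
    X[:, mask] = spec.alpha * template[mask] + (1.0 - spec.alpha) * X[:, mask]
    truth = {
        "time": t,
        "window_mask": mask,
        "template": template,
        "sync_window": spec.sync_window,
    }
    return X, truth


#: Region-specific oscillatory signals, argument t in seconds.
REGION_SIGNALS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mouth": lambda t: np.sin(t) + 0.5 * np.sin(2 * t),
    "left_eye": lambda t: np.cos(2 * t) + 0.2 * np.cos(4 * t),
    "right_eye": lambda t: np.sin(1.5 * t) + 0.3 * np.sin(3 * t),
    "jawline": lambda t: 0.5 + 0.5 * np.sin(0.8 * t),
    "nose": lambda t: np.sin(3 * t) + 0.2 * np.sin(6 * t),
}


@dataclass
class SyncEvent:
    """One injected synchrony event: a region, a subject subset, a window."""

    region: str
    subjects: tuple[int, ...]        # 1-based participant numbers
    window: tuple[float, float]      # seconds, half-open [t0, t1)

    def signal(self) -> Callable[[np.ndarray], np.ndarray]:
        return REGION_SIGNALS[self.region]


def _default_events() -> list[SyncEvent]:
    return [
        SyncEvent("mouth", tuple(range(1, 16)), (20.0, 22.0)),
        SyncEvent("left_eye", tuple(range(16, 26)), (30.0, 32.0)),
    ]


@dataclass
class CorrcaSimSpec:
    """Parameters of the simulated landmark synchrony study."""

    n_subjects: int = 30
    duration: float = 60.0
    rate: float = 5.0
    offset_sd: float = 5.0           # per-subject spatial offset SD (px)
    noise_sd: float = 0.5            # temporal white noise SD (px)
    events: list[SyncEvent] = field(default_factory=_default_events)
    max_phase_shift: int = 2         # frames
    amplitude_range: tuple[float, float] = (0.8, 1.2)
    inject_axes: tuple[int, ...] = (0, 1)   # add signal to x and/or y
    seed: int = 0

    def __post_init__(self) -> None:
        used: set[str] = set()
        for ev in self.events:
            if ev.region in used:
                raise ContractError(f"overlapping event regions: {ev.region}")
            used.add(ev.region)
            lo, hi = ev.window
            if not (0.0 <= lo < hi <= self.duration):
                raise ContractError(f"event window {ev.window} outside recording")


def simulate_landmark_study(
    spec: CorrcaSimSpec, template: FaceTemplate | None = None
) -> tuple[np.ndarray, dict]:
    """Simulate the multi-landmark synchrony study.

    Returns (data, truth): data is (N, 68, 2, T); truth records, per event,
    the injected frame indices, 0-based subject indices and 0-based landmark
    indices.
    """
    tpl = template or face_template()
    rng = np.random.default_rng(spec.seed)
    N = spec.n_subjects
    T = int(round(spec.duration * spec.rate))
    t = np.arange(T) / spec.rate

    offsets = rng.normal(0.0, spec.offset_sd, size=(N, 68, 2))
    noise = rng.normal(0.0, spec.noise_sd, size=(N, 68, 2, T))
    data = tpl.points[None, :, :, None] + offsets[..., None] + noise

    truth_events = []
    for ev in spec.events:
        frames = np.nonzero((t >= ev.window[0]) & (t < ev.window[1]))[0]
        lm_idx = tpl.regions[ev.region]
        sig = ev.signal()(t[frames])
        subj_idx = [s - 1 for s in ev.subjects]
        for s in subj_idx:
            shift = int(rng.integers(-spec.max_phase_shift, spec.max_phase_shift + 1))
            amp = float(rng.uniform(*spec.amplitude_range))
            s_sig = amp * np.roll(sig, shift)
            for ax in spec.inject_axes:
                data[s, lm_idx[:, None], ax, frames[None, :]] += s_sig[None, :]
        truth_events.append(
            {
                "region": ev.region,
                "window": ev.window,
                "frames": frames,
                "subjects": subj_idx,
                "landmarks": lm_idx,
            }
        )
    truth = {"time": t, "events": truth_events, "template": tpl}
    return data, truth


# ---------------------------------------------------------------------------
# Raw Trace-dialect CSV fixtures
# ---------------------------------------------------------------------------

def simulate_raw_trace_csv(
    n_subjects: int = 4,
    duration: float = 60.0,
    mean_rate: float = 5.0,
    drop_fraction: float = 0.2,
    jitter: float = 0.02,
    seed: int = 0,
    out_path: str | Path = ".",
    condition: str = "A",
    landmark_format: str = "nested",     # "nested" | "flat"
) -> Path:
    """Write a Trace-dialect CSV fixture plus a ground-truth manifest.

    Each participant's face is the canonical template plus a fixed offset and
    a slow sinusoidal whole-face drift (so linear interpolation can recover
    it accurately). Timestamps are jittered around a mean_rate grid;
    ``drop_fraction`` of the interior rows is removed at random. Returns the
    fixture directory.
    """
    if mean_rate <= 0:
        raise ContractError("mean_rate must be positive")
    if not 0.0 <= drop_fraction < 1.0:
        raise ContractError("drop_fraction must lie in [0, 1)")
    out = Path(out_path)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}") from exc

    rng = np.random.default_rng(seed)
    tpl = face_template()
    rows = []
    manifest: dict = {
        "seed": seed, "duration": duration, "mean_rate": mean_rate,
        "drop_fraction": drop_fraction, "condition": condition, "subjects": {},
    }
    n_frames = int(round(duration * mean_rate)) + 1
    for p in range(n_subjects):
        pid = f"P{p + 1:02d}"
        offset = rng.normal(0.0, 10.0, size=2)
        amp = float(rng.uniform(2.0, 5.0))
        freq = float(rng.uniform(0.05, 0.15))
        ts = np.arange(n_frames) / mean_rate
        if jitter > 0:
            ts = ts + rng.uniform(-jitter, jitter, size=n_frames)
            ts[0] = max(ts[0], 0.0)
            ts = np.sort(ts)
        keep = np.ones(n_frames, bool)
        n_drop = int(round(drop_fraction * n_frames))
        if n_drop:
            interior = np.arange(1, n_frames - 1)
            keep[rng.choice(interior, size=min(n_drop, len(interior)), replace=False)] = False
        emotions_base = rng.uniform(0.05, 0.3, size=len(EMOTIONS))
        for fi in np.nonzero(keep)[0]:
            t = ts[fi]
            drift = amp * np.array([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
            pts = tpl.points + offset + drift
            if landmark_format == "flat":
                cell = json.dumps([round(v, 4) for v in pts.ravel()])
            else:
                cell = json.dumps([[round(x, 4), round(y, 4)] for x, y in pts])
            emo = np.clip(emotions_base + 0.1 * np.sin(2 * np.pi * 0.1 * t + np.arange(len(EMOTIONS))), 0, 1)
            row = {
                "participant": pid,
                "condition": condition,
                "timestamp": round(float(t), 5),
                "landmarks": cell,
            }
            row.update(
                {DEFAULT_EMOTION_COLUMNS[e]: round(float(v), 5) for e, v in zip(EMOTIONS, emo)}
            )
            rows.append(row)
        manifest["subjects"][pid] = {
            "offset": offset.tolist(),
            "drift_amplitude": amp,
            "drift_frequency": freq,
            "n_rows_written": int(keep.sum()),
            "n_rows_total": n_frames,
        }
    pd.DataFrame(rows).to_csv(out / "trace_data.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=1))
    return out
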