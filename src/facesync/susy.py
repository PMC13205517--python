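"""Surrogate Synchrony (SUSY) for single-channel dyadic time series.

The two series of a dyad are cut into consecutive non-overlapping segments
(default 5 s). Within each segment one series is shifted against the other by
every integer lag up to ±L samples (L = round(maxlag_seconds × rate), so the
lag axis has 2·L + 1 entries) and the Pearson correlation of the overlapping
portions is Fisher-Z transformed (z = atanh r). A null distribution is built
by circularly rotating one series by a random whole-series offset — rotation
preserves the series' value multiset (hence mean and SD) exactly while
destroying its temporal alignment — and recomputing the same segment × lag
Z array. Synchrony strength per dyad is the Cohen's-d-like effect size

    ES = (mu_real − mu_surrogate) / sigma_surrogate,

where mu/sigma are taken over the per-replicate aggregated Z values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, SurrogateError
from .preprocess import FeatureMatrix, RecordingSet

logger = logging.getLogger(__name__)

AGGREGATES = ("signed-mean", "absolute-mean")


@dataclass
class SusyConfig:
    segment_seconds: float = 5.0
    maxlag_seconds: float = 0.0
    rate: float = 1.0
    n_surrogates: int = 100
    aggregate: str = "signed-mean"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.aggregate not in AGGREGATES:
            raise ContractError(f"aggregate must be one of {AGGREGATES}")
        if self.n_surrogates < 1:
            raise ContractError("n_surrogates must be >= 1")
        if self.segment_samples < 3:
            raise ContractError("segments must contain at least 3 samples")
        if self.maxlag_samples >= self.segment_samples:
            raise ContractError("maximum lag must be shorter than a segment")

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_seconds * self.rate))

    @property
    def maxlag_samples(self) -> int:
        return int(round(self.maxlag_seconds * self.rate))

    @property
    def lags(self) -> np.ndarray:
        L = self.maxlag_samples
        return np.arange(-L, L + 1)


@dataclass
class DyadZ:
    """Fisher-Z values for one dyad: segments × lags."""

    dyad: tuple
    z: np.ndarray                 # (S, 2L+1)
    lags: np.ndarray              # (2L+1,) in samples
    segment_times: np.ndarray     # (S, 2) closed [first, last] sample times


@dataclass
class SusyResult:
    dyads: list
    real: dict                    # dyad -> DyadZ
    surrogate: dict               # dyad -> (n_surrogates, S, 2L+1)
    es_per_dyad: dict             # dyad -> float
    config: SusyConfig
    channel: str = ""
    dyad_conditions: dict = field(default_factory=dict)


def _segment_lag_z(a: np.ndarray, B: np.ndarray, cfg: SusyConfig) -> np.ndarray:
    """Fisher-Z of segmented lagged Pearson correlations, vectorised.

    a: (T,) reference series; B: (M, T) one or many partner series (surrogate
    replicates share this path with the real computation). Returns
    (M, S, 2L+1). For lag tau, a[t] is correlated with b[t + tau] over the
    within-segment overlap, each portion mean-centred over that overlap;
    zero-variance overlaps yield z = 0.
    """
    n = cfg.segment_samples
    L = cfg.maxlag_samples
    T = a.shape[-1]
    S = T // n
    if S < 1:
        raise ContractError("series shorter than one segment")
    A = a[: S * n].reshape(S, n)
    Bs = B[:, : S * n].reshape(B.shape[0], S, n)
    out = np.empty((B.shape[0], S, 2 * L + 1))
    for li, tau in enumerate(range(-L, L + 1)):
        if tau >= 0:
            x = A[:, : n - tau]            # (S, m)
            y = Bs[:, :, tau:]             # (M, S, m)
        else:
            x = A[:, -tau:]
            y = Bs[:, :, : n + tau]
        xc = x - x.mean(axis=-1, keepdims=True)
        yc = y - y.mean(axis=-1, keepdims=True)
        num = np.einsum("sm,gsm->gs", xc, yc)
        den = np.sqrt(np.einsum("sm,sm->s", xc, xc)[None, :] * np.einsum("gsm,gsm->gs", yc, yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
        out[:, :, li] = np.arctanh(r)
    return out


def _segment_times(T: int, cfg: SusyConfig, t0: float = 0.0) -> np.ndarray:
    n = cfg.segment_samples
    S = T // n
    starts = t0 + np.arange(S) * n / cfg.rate
    ends = starts + (n - 1) / cfg.rate
    return np.column_stack([starts, ends])


def lagged_segment_z(a: np.ndarray, b: np.ndarray, config: SusyConfig) -> DyadZ:
    """Segment × lag Fisher-Z matrix for one dyad (trailing partial segment dropped)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("series must be 1-D and of equal length")
    z = _segment_lag_z(a, b[None, :], config)[0]
    return DyadZ(
        dyad=(0, 1),
        z=z,
        lags=config.lags,
        segment_times=_segment_times(len(a), config),
    )


def circular_surrogates(
    a: np.ndarray,
    b: np.ndarray,
    config: SusyConfig,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Surrogate Z arrays from random circular rotations of ``b``.

    Offsets are drawn uniformly from [segment samples, T − segment samples] so
    every rotation moves the series by at least one full segment. Returns
    (n_surrogates, S, 2L+1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("series must be 1-D and of equal length")
    T = len(b)
    n = config.segment_samples
    if T - n < n:
        raise SurrogateError(
            f"series of {T} samples too short for a legal rotation (needs >= {2 * n})"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    offsets = rng.integers(n, T - n + 1, size=config.n_surrogates)
    rotated = np.stack([np.roll(b, int(off)) for off in offsets])
    return _segment_lag_z(a, rotated, config)


def _aggregate(z: np.ndarray, how: str) -> np.ndarray:
    """Aggregate over the trailing (segments, lags) axes."""
    vals = np.abs(z) if how == "absolute-mean" else z
    return vals.mean(axis=(-2, -1))


def effect_size(real_z: np.ndarray, surrogate_z: np.ndarray, aggregate: str = "signed-mean") -> float:
    """Cohen's-d-like ES = (mu_real − mu_surrogate) / sigma_surrogate.

    ``real_z``: (S, 2L+1); ``surrogate_z``: (M, S, 2L+1). Each replicate is
    aggregated over segments × lags first; mu/sigma are over replicates.
    """
    mu_real = float(_aggregate(real_z[None], aggregate)[0])
    surr = _aggregate(surrogate_z, aggregate)
    sd = float(np.std(surr, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ContractError("surrogate SD is zero; effect size undefined")
    return (mu_real - float(surr.mean())) / sd


def susy_group(
    data: RecordingSet | FeatureMatrix | np.ndarray,
    channel: str,
    config: SusyConfig,
) -> SusyResult:
    """Run SUSY over all C(N, 2) dyads of a group on one named channel.

    ``data`` may be a RecordingSet (channel = "head_movement" or an emotion
    name), a FeatureMatrix (channel = a feature label) or a plain (N, T)
    array (channel ignored). Deterministic under ``config.seed``.
    """
    if isinstance(data, RecordingSet):
        series = data.channel(channel)
        ids = [r.participant_id for r in data.recordings]
        conds = [tuple(sorted(r.metadata.get("group_values", {}).items())) for r in data.recordings]
    elif isinstance(data, FeatureMatrix):
        from .errors import ChannelNameError

        if channel not in data.feature_labels:
            raise ChannelNameError(
                f"unknown feature {channel!r}; available: {data.feature_labels}"
            )
        series = data.data[:, data.feature_labels.index(channel), :]
        ids = list(data.subject_ids)
        conds = [()] * len(ids)
    else:
        series = np.asarray(data, float)
        ids = list(range(series.shape[0]))
        conds = [()] * len(ids)
    N = series.shape[0]
    if N < 2:
        raise ContractError("SUSY needs at least 2 subjects")

    rng = np.random.default_rng(config.seed)
    seg_times = _segment_times(series.shape[1], config)
    real: dict = {}
    surrogate: dict = {}
    es: dict = {}
    dyads = []
    dyad_conditions = {}
    for i, j in combinations(range(N), 2):
        dyad = (ids[i], ids[j])
        dyads.append(dyad)
        z = _segment_lag_z(series[i], series[j][None, :], config)[0]
        real[dyad] = DyadZ(dyad=dyad, z=z, lags=config.lags, segment_times=seg_times)
        surrogate[dyad] = circular_surrogates(series[i], series[j], config, rng)
        es[dyad] = effect_size(z, surrogate[dyad], config.aggregate)
        dyad_conditions[dyad] = (conds[i], conds[j])
    return SusyResult(
        dyads=dyads, real=real, surrogate=surrogate, es_per_dyad=es,
        config=config, channel=channel, dyad_conditions=dyad_conditions,
    )


def susy_summarise(result: SusyResult, level: str = "dyad") -> pd.DataFrame:
    """Means/SEs of real and surrogate Z (and ES) at a given aggregation level.

    Levels: dyad, segment (indexed by segment midpoint time), condition,
    grand.
    """
    cfg = result.config

    def _se(x):
        x = np.asarray(x, float)
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0

    if level == "dyad":
        rows = []
        for d in result.dyads:
            rz = result.real[d].z
            sz = result.surrogate[d]
            rows.append(
                {
                    "dyad": d,
                    "z_real_mean": float(_aggregate(rz[None], cfg.aggregate)[0]),
                    "z_surrogate_mean": float(_aggregate(sz, cfg.aggregate).mean()),
                    "es": result.es_per_dyad[d],
                }
            )
        return pd.DataFrame(rows)
    if level == "segment":
        any_dyad = result.dyads[0]
        seg_times = result.real[any_dyad].segment_times
        rz = np.stack([result.real[d].z for d in result.dyads])        # (D, S, L)
        sz = np.stack([result.surrogate[d].mean(axis=0) for d in result.dyads])
        rows = []
        for s in range(rz.shape[1]):
            rows.append(
                {
                    "segment": s,
                    "midpoint_s": float(seg_times[s].mean()),
                    "z_real_mean": float(rz[:, s, :].mean()),
                    "z_real_se": _se(rz[:, s, :].ravel()),
                    "z_surrogate_mean": float(sz[:, s, :].mean()),
                    "z_surrogate_se": _se(sz[:, s, :].ravel()),
                }
            )
        return pd.DataFrame(rows)
    if level == "condition":
        dyad_df = susy_summarise(result, "dyad")
        dyad_df["condition"] = [
            str(result.dyad_conditions.get(d, ())) for d in dyad_df["dyad"]
        ]
        return (
            dyad_df.groupby("condition")
            .agg(
                z_real_mean=("z_real_mean", "mean"),
                z_surrogate_mean=("z_surrogate_mean", "mean"),
                es_mean=("es", "mean"),
                es_se=("es", _se),
            )
            .reset_index()
        )
    if level == "grand":
        dyad_df = susy_summarise(result, "dyad")
        return pd.DataFrame(
            [
                {
                    "z_real_mean": dyad_df["z_real_mean"].mean(),
                    "z_surrogate_mean": dyad_df["z_surrogate_mean"].mean(),
                    "es_mean": dyad_df["es"].mean(),
                    "es_se": _se(dyad_df["es"].to_numpy()),
                }
            ]
        )
    raise ContractError(f"unknown summary level {level!r}")


# ---------------------------------------------------------------------------
# Window-based comparisons
# ---------------------------------------------------------------------------

def _window_segment_mask(seg_times: np.ndarray, window: tuple[float, float], mode: str) -> np.ndarray:
    lo, hi = window
    if mode == "intersect":
        return (seg_times[:, 1] >= lo) & (seg_times[:, 0] <= hi)
    if mode == "within":
        return (seg_times[:, 0] >= lo) & (seg_times[:, 1] <= hi)
    raise ContractError("mode must be 'intersect' or 'within'")


def pooled_window_z(
    result: SusyResult, window: tuple[float, float], mode: str = "within"
) -> tuple[float, float]:
    """(mean real Z, mean surrogate Z) pooled over dyads × window segments × lags.

    ``mode='within'`` pools segments fully inside the closed window (the
    segments the synchrony event spans); ``mode='intersect'`` pools every
    segment whose closed time span touches the closed window.
    """
    seg_times = result.real[result.dyads[0]].segment_times
    mask = _window_segment_mask(seg_times, window, mode)
    if not mask.any():
        raise ContractError(f"no segments selected by window {window}")
    rz = np.concatenate([result.real[d].z[mask].ravel() for d in result.dyads])
    sz = np.concatenate(
        [result.surrogate[d].mean(axis=0)[mask].ravel() for d in result.dyads]
    )
    return float(rz.mean()), float(sz.mean())


def real_vs_surrogate_test(
    result: SusyResult, window: tuple[float, float]
) -> tuple[float, int, float]:
    """Paired t-test of real vs surrogate Z inside a time window.

    Pairs one real Z with the replicate-mean surrogate Z for every (dyad,
    segment, lag) whose closed segment interval intersects the closed window;
    df = pair count − 1.
    """
    seg_times = result.real[result.dyads[0]].segment_times
    mask = _window_segment_mask(seg_times, window, "intersect")
    if not mask.any():
        raise ContractError(f"no segments intersect window {window}")
    rz = np.concatenate([result.real[d].z[mask].ravel() for d in result.dyads])
    sz = np.concatenate(
        [result.surrogate[d].mean(axis=0)[mask].ravel() for d in result.dyads]
    )
    t, p = stats.ttest_rel(rz, sz)
    return float(t), int(rz.size - 1), float(p)
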