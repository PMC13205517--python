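"""Plot-ready exports and condition-level statistics.

All figures have a CSV data twin: the facial-topography export joins each
component's 68 forward-model loadings to the canonical template coordinates,
the windowed-ISC trace and SUSY curves are written as long-format tables, and
condition-level comparison of component-1 ISC values uses a standard one-way
ANOVA. Rendering (matplotlib) is optional and never required by analyses.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .corrca import CorrCAResult
from .errors import ContractError
from .template import FaceTemplate, face_template


def topoplot_frame(result: CorrCAResult, template: FaceTemplate | None = None) -> pd.DataFrame:
    """Long table (landmark, x, y, component, loading) of forward-model loadings.

    Requires a 68-feature fit (one forward-model row per landmark); a
    136-channel X/Y fit is rejected explicitly rather than silently reshaped.
    """
    if result.A.shape[0] != 68:
        raise ContractError(
            f"forward model has {result.A.shape[0]} rows; facial topography "
            "requires exactly 68 (one per landmark) — scalarise the X/Y data first"
        )
    tpl = template or face_template()
    K = result.A.shape[1]
    frames = []
    for k in range(K):
        frames.append(
            pd.DataFrame(
                {
                    "landmark": np.arange(1, 69),
                    "x": tpl.points[:, 0],
                    "y": tpl.points[:, 1],
                    "component": k + 1,
                    "loading": result.A[:, k],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if not np.all(np.isfinite(out["loading"])):
        raise ContractError("non-finite forward-model loadings")
    return out


def export_topoplot_data(
    result: CorrCAResult,
    out_dir: str | Path,
    template: FaceTemplate | None = None,
    render: bool = False,
) -> list[Path]:
    """Write one 68-row loading CSV per component (plus optional PNGs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = topoplot_frame(result, template)
    paths = []
    for k, sub in frame.groupby("component"):
        p = out / f"topoplot_component_{k}.csv"
        sub.to_csv(p, index=False)
        paths.append(p)
        if render:
            _render_topoplot(sub, out / f"topoplot_component_{k}.png")
    return paths


def _render_topoplot(frame: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(frame["x"], frame["y"], c=frame["loading"], cmap="coolwarm", s=40)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    fig.colorbar(sc, ax=ax, label="loading")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def condition_anova(per_condition_isc: dict, component: int = 1) -> tuple[float, int, int, float]:
    """One-way ANOVA on per-subject component ISC values grouped by condition.

    ``per_condition_isc`` maps condition label to either a 1-D array of
    component ISC values or an (N, K) subject-ISC table from which the stated
    component (1-based) is taken. Returns (F, df1, df2, p).
    """
    groups = []
    for label, vals in per_condition_isc.items():
        arr = np.asarray(vals, float)
        if arr.ndim == 2:
            arr = arr[:, component - 1]
        if arr.size < 2:
            raise ContractError(f"condition {label!r} has fewer than 2 values")
        groups.append(arr)
    if len(groups) < 2:
        raise ContractError("ANOVA needs at least 2 conditions")
    if all(np.ptp(g) == 0 for g in groups) and len({float(g[0]) for g in groups}) == 1:
        raise ContractError("degenerate ANOVA: all values identical in every group")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(f), df1, df2, float(p)


def windowed_isc_frame(result: CorrCAResult) -> pd.DataFrame:
    """Long-format (component, time_s, isc) table of the windowed ISC trace."""
    if result.windowed_isc is None:
        raise ContractError("result has no windowed ISC trace")
    K, n = result.windowed_isc.shape
    return pd.DataFrame(
        {
            "component": np.repeat(np.arange(1, K + 1), n),
            "time_s": np.tile(result.window_times, K),
            "isc": result.windowed_isc.ravel(),
        }
    )


def susy_long_frame(result) -> pd.DataFrame:
    """Long-format SUSY table: dyad, segment, lag, z_real, z_surrogate_mean, es."""
    rows = []
    for d in result.dyads:
        dz = result.real[d]
        surr_mean = result.surrogate[d].mean(axis=0)
        for s in range(dz.z.shape[0]):
            for li, lag in enumerate(dz.lags):
                rows.append(
                    {
                        "dyad": f"{d[0]}|{d[1]}",
                        "segment": s,
                        "segment_mid_s": float(dz.segment_times[s].mean()),
                        "lag": int(lag),
                        "z_real": dz.z[s, li],
                        "z_surrogate_mean": surr_mean[s, li],
                        "es": result.es_per_dyad[d],
                    }
                )
    return pd.DataFrame(rows)
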