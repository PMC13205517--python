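"""Correlated Component Analysis (CorrCA) for multi-subject feature tensors.

CorrCA finds projections w of an N-subject, D-feature signal that maximise
correlation across subjects, by solving the generalised eigenvalue problem

    R_B W = R_W(gamma) W Lambda,

where R_W = sum_i R_ii is the pooled within-subject covariance, R_B =
sum_{i != j} R_ij the pooled (symmetrised) between-subject covariance, and
R_W(gamma) = (1 − gamma) R_W + gamma (tr R_W / D) I is a shrinkage-stabilised
within covariance (gamma in [0, 1], default 0.1). Shrinkage regularises the
eigenvectors only; synchrony strength is always measured on the actual
covariances: the reported eigenvalue for component k is the unshrunk
generalised Rayleigh quotient lambda_k = (w_k' R_B w_k)/(w_k' R_W w_k), and
the component ISC is rho_k = lambda_k / (N − 1), which the Cauchy–Schwarz
inequality bounds by |rho_k| <= 1 for every input. (The eigenvalues of the
shrunk problem itself are kept as ``gev_eigenvalues``.)

Per-subject contributions, a sliding-window ISC trace projected through the
global W, the forward model A = R_W W (W' R_W W)^{-1} mapping components back
to landmark space, and reconstruction X_hat = A W' X are also provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ContractError, NumericIntegrityError
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

GAMMA_GRID = (0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class CorrCAConfig:
    gamma: float = 0.1
    window_seconds: float = 3.0
    window_step_seconds: float = 1.0
    n_components: Optional[int] = None   # None = all D
    normalize_windowed: bool = True
    subject_isc_variant: str = "pooled"  # "pooled" | "individual"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ContractError("gamma must lie in [0, 1]")


@dataclass
class CovarianceSet:
    R_w: np.ndarray               # (D, D) pooled within-subject covariance
    R_b: np.ndarray               # (D, D) pooled between-subject covariance
    R_w_i: np.ndarray             # (N, D, D)
    R_b_i: np.ndarray             # (N, D, D)
    n_subjects: int
    n_features: int
    n_samples: int


@dataclass
class CorrCAResult:
    W: np.ndarray                     # (D, K)
    eigenvalues: np.ndarray           # (K,) unshrunk Rayleigh quotients
    gev_eigenvalues: np.ndarray       # (K,) shrunk-problem eigenvalues
    rho: np.ndarray                   # (K,) component ISC
    subject_isc: np.ndarray           # (N, K)
    A: np.ndarray                     # (D, K) forward model
    gamma: float
    n_subjects: int
    covariances: CovarianceSet
    windowed_isc: Optional[np.ndarray] = None      # (K, n_windows)
    window_times: Optional[np.ndarray] = None      # (n_windows,) centre seconds
    subject_ids: list = field(default_factory=list)
    feature_labels: list = field(default_factory=list)


def _as_tensor(X) -> tuple[np.ndarray, list, list, Optional[float]]:
    if isinstance(X, FeatureMatrix):
        return np.asarray(X.data, float), list(X.subject_ids), list(X.feature_labels), X.rate
    arr = np.asarray(X, float)
    if arr.ndim != 3:
        raise ContractError("expected an (N, D, T) tensor or FeatureMatrix")
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1])), None


def estimate_covariances(X) -> CovarianceSet:
    """Pooled and per-subject within/between covariances (1/(T−1) normalised).

    Subject series are mean-centred over time; R_ij = X_i X_j' / (T−1);
    R_w,i = R_ii; R_b,i = sum_{j != i} (R_ij + R_ji)/2; pooled matrices are
    the sums over subjects.
    """
    data, _, _, _ = _as_tensor(X)
    N, D, T = data.shape
    if N < 2:
        raise ContractError("covariance estimation needs at least 2 subjects")
    if T < 2:
        raise ContractError("covariance estimation needs at least 2 samples")
    if T < D:
        warnings.warn(
            f"T={T} < D={D}: covariance estimates will be rank-deficient",
            stacklevel=2,
        )
    Xc = data - data.mean(axis=2, keepdims=True)
    denom = T - 1
    R_w_i = np.einsum("idt,iet->ide", Xc, Xc) / denom
    S = Xc.sum(axis=0)                       # (D, T)
    total = S @ S.T / denom
    cross_i = np.einsum("idt,et->ide", Xc, S) / denom - R_w_i  # X_i (S − X_i)'
    R_b_i = 0.5 * (cross_i + np.transpose(cross_i, (0, 2, 1)))
    R_w = R_w_i.sum(axis=0)
    R_b = R_b_i.sum(axis=0)
    # exact identity: sum_i R_b,i = S S' − sum_i R_ii, symmetrised
    np.testing.assert_allclose(R_b, 0.5 * (total + total.T) - R_w, atol=1e-8 * max(1.0, abs(total).max()))
    R_w = 0.5 * (R_w + R_w.T)
    R_b = 0.5 * (R_b + R_b.T)
    return CovarianceSet(R_w=R_w, R_b=R_b, R_w_i=R_w_i, R_b_i=R_b_i,
                         n_subjects=N, n_features=D, n_samples=T)


def shrink(R_w: np.ndarray, gamma: float) -> np.ndarray:
    """Convex combination of R_w with its isotropic target (tr R_w / D) I."""
    D = R_w.shape[0]
    return (1.0 - gamma) * R_w + gamma * (np.trace(R_w) / D) * np.eye(D)


def component_isc(eigenvalues: np.ndarray | float, n_subjects: int) -> np.ndarray:
    """rho_k = lambda_k / (N − 1); errors if the |rho| <= 1 bound is violated."""
    if n_subjects < 2:
        raise ContractError("component ISC needs at least 2 subjects")
    rho = np.asarray(eigenvalues, float) / (n_subjects - 1)
    if np.any(np.abs(rho) > 1 + 1e-8):
        raise NumericIntegrityError(
            f"component ISC bound violated: max |rho| = {np.abs(rho).max():.6g}"
        )
    return rho


def subject_isc(W: np.ndarray, cov: CovarianceSet, variant: str = "pooled") -> np.ndarray:
    """Per-subject ISC contributions, (N, K).

    Default ("pooled", the printed form of the per-subject equation with the
    pooled within covariance in the denominator, scaled by N/(N−1)): the mean
    over subjects equals rho_k exactly. "individual" uses each subject's own
    within covariance in the denominator.
    """
    N = cov.n_subjects
    num = np.einsum("dk,ide,ek->ik", W, cov.R_b_i, W)    # (N, K)
    if variant == "pooled":
        den = np.einsum("dk,de,ek->k", W, cov.R_w, W)    # (K,)
        return N * num / ((N - 1) * den[None, :])
    if variant == "individual":
        den_i = np.einsum("dk,ide,ek->ik", W, cov.R_w_i, W)
        return num / ((N - 1) * den_i)
    raise ContractError("variant must be 'pooled' or 'individual'")


def corrca_fit(X, config: CorrCAConfig | None = None) -> CorrCAResult:
    """Fit CorrCA: shrunk generalised eigendecomposition + ISC + forward model.

    Components are ordered by descending eigenvalue; each eigenvector is
    normalised so w' R_w(gamma) w = 1 and sign-fixed so its largest-magnitude
    forward-model loading is positive (eigenvectors are only defined up to
    ±1).
    """
    cfg = config or CorrCAConfig()
    data, subject_ids, feature_labels, rate = _as_tensor(X)
    N, D, T = data.shape
    cov = estimate_covariances(data)
    K = cfg.n_components or D
    if K > D:
        raise ContractError(f"n_components={K} exceeds feature count {D}")
    Rwg = shrink(cov.R_w, cfg.gamma)
    if not (np.all(np.isfinite(Rwg)) and np.all(np.isfinite(cov.R_b))):
        raise NumericIntegrityError("non-finite covariance estimates")
    gev_vals, vecs = linalg.eigh(cov.R_b, Rwg)
    order = np.argsort(gev_vals)[::-1][:K]
    gev_vals = gev_vals[order]
    W = vecs[:, order]
    # eigh already yields w' Rwg w = 1; re-normalise defensively
    scale = np.sqrt(np.einsum("dk,de,ek->k", W, Rwg, W))
    W = W / scale[None, :]

    # forward model from the unshrunk within covariance
    G = W.T @ cov.R_w @ W
    try:
        A = cov.R_w @ W @ linalg.inv(G)
    except linalg.LinAlgError as exc:
        raise NumericIntegrityError(
            "W' R_w W is singular; increase gamma or reduce n_components"
        ) from exc
    # sign convention: largest-|loading| of each forward-model column positive
    for k in range(K):
        j = int(np.argmax(np.abs(A[:, k])))
        if A[j, k] < 0:
            A[:, k] = -A[:, k]
            W[:, k] = -W[:, k]

    quot_num = np.einsum("dk,de,ek->k", W, cov.R_b, W)
    quot_den = np.einsum("dk,de,ek->k", W, cov.R_w, W)
    eigenvalues = quot_num / quot_den
    rho = component_isc(eigenvalues, N)
    s_isc = subject_isc(W, cov, cfg.subject_isc_variant)

    result = CorrCAResult(
        W=W, eigenvalues=eigenvalues, gev_eigenvalues=gev_vals, rho=rho,
        subject_isc=s_isc, A=A, gamma=cfg.gamma, n_subjects=N,
        covariances=cov, subject_ids=subject_ids, feature_labels=feature_labels,
    )
    if rate is not None:
        win = int(round(cfg.window_seconds * rate))
        if 2 <= win <= T:
            result.windowed_isc, result.window_times = windowed_isc(X, result, cfg)
    return result


def windowed_isc(X, result: CorrCAResult, config: CorrCAConfig | None = None):
    """Sliding-window ISC trace projected through the global W.

    Covariances are re-estimated (per-window mean-centred) inside each window
    and projected through the eigenvectors of the full fit — never refit per
    window, so component identity is preserved across time. Default output is
    scaled by 1/(N−1) for comparability with rho; ``normalize_windowed=False``
    gives the raw quotient.
    """
    cfg = config or CorrCAConfig(gamma=result.gamma)
    data, _, _, rate = _as_tensor(X)
    N, D, T = data.shape
    if rate is None:
        raise ContractError("windowed ISC needs a FeatureMatrix with a sampling rate")
    win = int(round(cfg.window_seconds * rate))
    step = max(int(round(cfg.window_step_seconds * rate)), 1)
    if win > T:
        raise ContractError("window longer than the recording")
    if win < 2:
        raise ContractError("window must contain at least 2 samples")
    W = result.W
    starts = np.arange(0, T - win + 1, step)
    K = W.shape[1]
    trace = np.full((K, len(starts)), np.nan)
    centres = np.empty(len(starts))
    for wi, s in enumerate(starts):
        seg = data[:, :, s : s + win]
        Y = np.einsum("dk,idt->ikt", W, seg)            # (N, K, win)
        Yc = Y - Y.mean(axis=2, keepdims=True)
        num_w = np.einsum("ikt,ikt->k", Yc, Yc) / (win - 1)          # w'R_w(t)w
        Ssum = Yc.sum(axis=0)                                        # (K, win)
        tot = np.einsum("kt,kt->k", Ssum, Ssum) / (win - 1)
        num_b = tot - num_w                                          # w'R_b(t)w
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(num_w > 0, num_b / np.where(num_w > 0, num_w, 1.0), np.nan)
        trace[:, wi] = ratio / (N - 1) if cfg.normalize_windowed else ratio
        centres[wi] = (s + (win - 1) / 2) / rate
    return trace, centres


def reconstruct(A: np.ndarray, W: np.ndarray, X) -> np.ndarray:
    """X_hat = A W' X per subject, on mean-centred data (N, D, T)."""
    data, _, _, _ = _as_tensor(X)
    Xc = data - data.mean(axis=2, keepdims=True)
    return np.einsum("dk,ke,iet->idt", A, W.T, Xc)


def gamma_sweep(
    X, gammas: Sequence[float] = GAMMA_GRID, config: CorrCAConfig | None = None
) -> pd.DataFrame:
    """Refit CorrCA at each gamma; long table of component-1 ISC per group.

    ``X`` may be one tensor/FeatureMatrix or a mapping of group label to
    tensors. The returned frame has columns (group, gamma, rho_1,
    subject_isc_mean, subject_isc_se); groups' rank order per gamma supports
    the stability summary.
    """
    base = config or CorrCAConfig()
    groups = X if isinstance(X, dict) else {"all": X}
    rows = []
    for label, tensor in groups.items():
        for g in gammas:
            cfg = CorrCAConfig(
                gamma=float(g),
                window_seconds=base.window_seconds,
                window_step_seconds=base.window_step_seconds,
                n_components=base.n_components,
                normalize_windowed=base.normalize_windowed,
                subject_isc_variant=base.subject_isc_variant,
            )
            res = corrca_fit(tensor, cfg)
            s1 = res.subject_isc[:, 0]
            rows.append(
                {
                    "group": label,
                    "gamma": float(g),
                    "rho_1": float(res.rho[0]),
                    "subject_isc_mean": float(s1.mean()),
                    "subject_isc_se": float(s1.std(ddof=1) / np.sqrt(len(s1)))
                    if len(s1) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def rank_order_stability(sweep: pd.DataFrame) -> bool:
    """True when the groups' rho_1 rank order is identical at every gamma."""
    orders = {
        g: tuple(sub.sort_values("rho_1", ascending=False)["group"])
        for g, sub in sweep.groupby("gamma")
    }
    return len(set(orders.values())) == 1
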