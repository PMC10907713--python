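"""Low-dimensional latent dynamics: PCA manifolds and CCA alignment.

For each trial the beta-filtered movement-window activity (movement onset
to onset + 600 ms) is reduced to its three leading principal components
("neural modes"), and two sets of latent trajectories (e.g. derived from
ground-truth vs reconstructed signals) are aligned with canonical
correlation analysis computed explicitly via QR decompositions and an SVD
of Q_A^T Q_B.  Canonical correlations are sorted descending and equal the
per-mode Pearson correlation of the aligned trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .metrics import pearson_similarity

__all__ = [
    "LatentTrajectory",
    "CCAResult",
    "extract_window",
    "fit_pca_manifold",
    "align_cca",
    "temporal_correlation",
    "session_latents",
]

N_MODES = 3
WINDOW_S = 0.6
#: sliding-window length (samples) for "instantaneous" correlation
TEMPORAL_WINDOW = 101
#: display threshold for a strong instantaneous correlation
STRONG_CORRELATION = 0.4


@dataclass(frozen=True)
class LatentTrajectory:
    """Top-``n_modes`` PCA scores of one windowed trial."""

    modes: np.ndarray  # (n_modes, T') scores
    loadings: np.ndarray  # (n_channels, n_modes), orthonormal columns
    variance_explained: np.ndarray  # fraction per mode, non-increasing


@dataclass(frozen=True)
class CCAResult:
    transform_a: np.ndarray  # (k, k)
    transform_b: np.ndarray
    canonical_correlations: np.ndarray  # (k,), sorted descending
    aligned_a: np.ndarray  # (k, T')
    aligned_b: np.ndarray


def extract_window(
    trial: np.ndarray,
    fs: float,
    onset: int,
    band: tuple[float, float] = (12.5, 30.0),
) -> np.ndarray:
    """Beta-filtered (n_channels, T') matrix from onset to onset + 600 ms."""
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    t_win = int(round(WINDOW_S * fs))
    if onset < 0 or onset + t_win > trial.shape[-1]:
        raise ValidationError(
            f"window [{onset}, {onset + t_win}) overflows trial of length {trial.shape[-1]}"
        )
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trial, axis=-1)
    return filtered[:, onset : onset + t_win]


def fit_pca_manifold(d: np.ndarray, n_modes: int = N_MODES) -> LatentTrajectory:
    """Top principal components of a channels x time data matrix.

    Rows are centered internally; loadings are the leading eigenvectors of
    the channel covariance, scores are their projections, and
    variance_explained is the fraction of total variance per mode.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    n = d.shape[0]
    if n < n_modes:
        raise ValidationError(f"need at least {n_modes} channels, got {n}")
    centered = d - d.mean(axis=1, keepdims=True)
    # SVD of the centered data is numerically preferable to eigh(cov)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    var = (s[:n_modes] ** 2 / total) if total > 0 else np.zeros(n_modes)
    loadings = u[:, :n_modes]
    return LatentTrajectory(
        modes=loadings.T @ centered,
        loadings=loadings,
        variance_explained=np.asarray(var, dtype=float),
    )


def align_cca(p_a: np.ndarray, p_b: np.ndarray) -> CCAResult:
    """Canonical correlation alignment of two (k, T') latent trajectories.

    Both trajectories are row-centered, QR-decomposed (P^T = Q R), the SVD
    Q_A^T Q_B = U S V^T is formed, and the transforms T_A = R_A^-1 U,
    T_B = R_B^-1 V map the trajectories into maximally correlated pairs.
    The canonical correlations (diagonal of S) come out sorted descending.
    """
    p_a = np.atleast_2d(np.asarray(p_a, dtype=float))
    p_b = np.atleast_2d(np.asarray(p_b, dtype=float))
    if p_a.shape != p_b.shape:
        raise ValidationError("latent trajectories must share shape")
    k, t_len = p_a.shape
    if t_len <= k:
        raise ValidationError(f"need more than {k} time samples, got {t_len}")
    a = (p_a - p_a.mean(axis=1, keepdims=True)).T  # (T', k)
    b = (p_b - p_b.mean(axis=1, keepdims=True)).T
    for name, mat in (("A", a), ("B", b)):
        if np.linalg.matrix_rank(mat) < k:
            raise ValidationError(f"trajectory {name} is rank deficient (rank < {k})")
    q_a, r_a = np.linalg.qr(a)
    q_b, r_b = np.linalg.qr(b)
    u, s, vt = np.linalg.svd(q_a.T @ q_b)
    t_a = np.linalg.solve(r_a, u)
    t_b = np.linalg.solve(r_b, vt.T)
    aligned_a = (a @ t_a).T
    aligned_b = (b @ t_b).T
    return CCAResult(
        transform_a=t_a,
        transform_b=t_b,
        canonical_correlations=np.clip(s, 0.0, 1.0),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
    )


def temporal_correlation(
    aligned_a: np.ndarray,
    aligned_b: np.ndarray,
    window_samples: int = TEMPORAL_WINDOW,
) -> np.ndarray:
    """Sliding-window Pearson correlation per mode; NaN marks constant windows.

    Returns (k, T' - window + 1); samples above ``STRONG_CORRELATION`` count
    as strongly correlated in downstream summaries.
    """
    if window_samples < 3 or window_samples % 2 == 0:
        raise ValidationError("window_samples must be odd and >= 3")
    a = np.atleast_2d(np.asarray(aligned_a, dtype=float))
    b = np.atleast_2d(np.asarray(aligned_b, dtype=float))
    if a.shape != b.shape or a.shape[1] < window_samples:
        raise ValidationError("trajectories must share shape and be longer than the window")
    k, t_len = a.shape
    n_out = t_len - window_samples + 1
    out = np.full((k, n_out), np.nan)
    for mode in range(k):
        for i in range(n_out):
            xa = a[mode, i : i + window_samples]
            xb = b[mode, i : i + window_samples]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                continue  # undefined on a constant window
            out[mode, i] = pearson_similarity(xa, xb)
    return out


def _sign_align(loadings: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-mode sign flips making loadings agree with a reference (PCA signs are arbitrary)."""
    signs = np.sign(np.sum(loadings * reference, axis=0))
    signs[signs == 0] = 1.0
    return signs


def session_latents(
    signals: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    band: tuple[float, float] = (12.5, 30.0),
    n_modes: int = N_MODES,
) -> list[LatentTrajectory]:
    """Trial-wise PCA latents for a (n_trials, n_ch, T) array.

    PCA is fit per trial; loadings are sign-aligned across trials against
    the session-mean loading so per-trial scores can be averaged.
    """
    signals = np.asarray(signals, dtype=float)
    trajs = [
        fit_pca_manifold(extract_window(signals[k], fs, int(onsets[k]), band), n_modes)
        for k in range(signals.shape[0])
    ]
    mean_loading = np.mean([t.loadings for t in trajs], axis=0)
    aligned = []
    for t in trajs:
        signs = _sign_align(t.loadings, mean_loading)
        aligned.append(
            LatentTrajectory(
                modes=t.modes * signs[:, None],
                loadings=t.loadings * signs[None, :],
                variance_explained=t.variance_explained,
            )
        )
    return aligned
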