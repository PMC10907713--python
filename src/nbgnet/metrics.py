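"""Scale-dependent error, similarity, and phase-synchrony metrics.

Implements the evaluation suite used to compare predicted and ground-truth
signals: root-mean-square error, Pearson similarity, and a beta-band phase
suite built on the analytic (Hilbert) signal — phase-locking value (PLV),
phase of phase-locking, instantaneous phase synchrony IPS(t) = 1 -
sin(|dphi|/2) with phases in degrees, the phase synchrony index PSI (the
fraction of time IPS exceeds the 45-degree-equivalent threshold), and the
(PSI, PLV) synchrony-zone classification with both thresholds at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError

__all__ = [
    "IPS_THRESHOLD",
    "PhaseSeries",
    "SyncReport",
    "rmse",
    "pearson_similarity",
    "analytic_signal",
    "plv",
    "ips",
    "psi",
    "synchrony_zone",
    "sync_report",
    "evaluate_session",
]

#: IPS value at a 45-degree phase difference: 1 - sin(22.5 deg).  The PSI
#: counts samples strictly above this threshold (0.62 to two decimals).
IPS_THRESHOLD = 1.0 - np.sin(np.deg2rad(22.5))

#: fraction of samples at each end flagged as Hilbert edge transients
EDGE_FRACTION = 0.05


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous amplitude and phase of a band-limited signal.

    ``phase`` is in degrees wrapped to (-180, 180]; ``edge_mask`` is True on
    the first/last 5% of samples where the Hilbert transform is unreliable.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    edge_mask: np.ndarray


@dataclass(frozen=True)
class SyncReport:
    plv: float
    phase_of_locking: float  # degrees
    ips_series: np.ndarray
    psi: float
    zone: str


def rmse(y_gt: np.ndarray, y_pre: np.ndarray) -> float:
    """Square root of the mean squared error between two equal-length series."""
    y_gt = np.asarray(y_gt, dtype=float).ravel()
    y_pre = np.asarray(y_pre, dtype=float).ravel()
    if y_gt.shape != y_pre.shape or y_gt.size < 1:
        raise ValidationError(f"series lengths differ: {y_gt.shape} vs {y_pre.shape}")
    return float(np.sqrt(np.mean((y_gt - y_pre) ** 2)))


def pearson_similarity(y_gt: np.ndarray, y_pre: np.ndarray) -> float:
    """Pearson correlation coefficient via the computational formula.

    rho = (S_xy - S_x S_y / T) / sqrt((S_xx - S_x^2/T)(S_yy - S_y^2/T)).
    Symmetric, and invariant to positive affine rescaling of either series.
    """
    x = np.asarray(y_gt, dtype=float).ravel()
    y = np.asarray(y_pre, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError(f"series lengths differ: {x.shape} vs {y.shape}")
    t = x.size
    sxx = np.sum(x * x) - np.sum(x) ** 2 / t
    syy = np.sum(y * y) - np.sum(y) ** 2 / t
    scale = np.sqrt(sxx * syy)
    if not scale > 0:
        raise ValidationError("correlation undefined: at least one series has zero variance")
    return float((np.sum(x * y) - np.sum(x) * np.sum(y) / t) / scale)


def analytic_signal(s: np.ndarray, band: tuple[float, float], fs: float) -> PhaseSeries:
    """Band-pass filter then Hilbert-transform a real signal.

    The band-pass is a zero-phase 4th-order Butterworth (applied
    forward-backward) so the extracted phase carries no filter delay.  The
    analytic signal is built in the frequency domain (negative frequencies
    zeroed, positive doubled); amplitude = |z|, phase = arg(z) in degrees.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValidationError(f"band {band} outside (0, Nyquist={fs / 2})")
    s = np.asarray(s, dtype=float)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, s, axis=-1)
    z = sps.hilbert(filtered, axis=-1)
    n = s.shape[-1]
    edge = int(np.ceil(EDGE_FRACTION * n))
    mask = np.zeros(n, dtype=bool)
    mask[:edge] = True
    if edge > 0:
        mask[-edge:] = True
    return PhaseSeries(amplitude=np.abs(z), phase=np.rad2deg(np.angle(z)), edge_mask=mask)


def _wrap_deg(phi: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to (-180, 180]."""
    return -((-np.asarray(phi, dtype=float) + 180.0) % 360.0 - 180.0)


def plv(phi1: np.ndarray, phi2: np.ndarray) -> tuple[float, float]:
    """Phase-locking value and phase of phase-locking (degrees).

    PLV = |mean over time of exp(j dphi)| in [0, 1]; the phase of
    phase-locking is the argument of the same complex mean.
    """
    phi1 = np.asarray(phi1, dtype=float).ravel()
    phi2 = np.asarray(phi2, dtype=float).ravel()
    if phi1.shape != phi2.shape:
        raise ValidationError("phase series lengths differ")
    phasor = np.exp(1j * np.deg2rad(phi1 - phi2))
    mean = phasor.mean()
    return float(np.abs(mean)), float(np.rad2deg(np.angle(mean)))


def ips(phi1: np.ndarray, phi2: np.ndarray) -> np.ndarray:
    """Instantaneous phase synchrony 1 - sin(|dphi|/2), phases in degrees.

    The difference is wrapped to [0, 180] degrees first, so the result is 1
    at zero phase difference, 0 at antiphase, and monotone in between.
    """
    dphi = np.abs(_wrap_deg(np.asarray(phi1, dtype=float) - np.asarray(phi2, dtype=float)))
    return 1.0 - np.sin(np.deg2rad(dphi / 2.0))


def psi(ips_series: np.ndarray, edge_mask: np.ndarray | None = None) -> float:
    """Fraction of (unmasked) time with IPS above the 45-degree threshold."""
    x = np.asarray(ips_series, dtype=float).ravel()
    if edge_mask is not None:
        x = x[~np.asarray(edge_mask, dtype=bool).ravel()]
    if x.size == 0:
        raise ValidationError("no samples left after masking")
    return float(np.mean(x > IPS_THRESHOLD))


def synchrony_zone(psi_value: float, plv_value: float) -> str:
    """Classify (PSI, PLV) with both thresholds at 0.5.

    Both low -> "poor"; both high -> "perfect"; mixed -> "medium".
    """
    hi_psi, hi_plv = psi_value >= 0.5, plv_value >= 0.5
    if hi_psi and hi_plv:
        return "perfect"
    if not hi_psi and not hi_plv:
        return "poor"
    return "medium"


def sync_report(
    y_gt: np.ndarray, y_pre: np.ndarray, band: tuple[float, float], fs: float
) -> SyncReport:
    """Full phase-synchrony report for one ground-truth/prediction pair."""
    pa = analytic_signal(y_gt, band, fs)
    pb = analytic_signal(y_pre, band, fs)
    keep = ~pa.edge_mask
    plv_value, phase_lock = plv(pa.phase[..., keep], pb.phase[..., keep])
    series = ips(pa.phase, pb.phase)
    psi_value = psi(series, pa.edge_mask)
    return SyncReport(
        plv=plv_value,
        phase_of_locking=phase_lock,
        ips_series=series,
        psi=psi_value,
        zone=synchrony_zone(psi_value, plv_value),
    )


def evaluate_session(
    truth: np.ndarray,
    pred: np.ndarray,
    fs: float,
    band: tuple[float, float] = (12.5, 30.0),
    trial_ids: np.ndarray | None = None,
):
    """Per trial x channel metric table for (n_trials, n_ch, T) arrays.

    Returns a pandas DataFrame with columns trial_id, channel, rmse,
    pearson, plv, phase_of_locking_deg, psi, zone.
    """
    import pandas as pd

    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape or truth.ndim != 3:
        raise ValidationError("truth and pred must be identical (n_trials, n_ch, T) arrays")
    rows = []
    ids = trial_ids if trial_ids is not None else np.arange(truth.shape[0])
    for k in range(truth.shape[0]):
        for ch in range(truth.shape[1]):
            rep = sync_report(truth[k, ch], pred[k, ch], band, fs)
            rows.append(
                {
                    "trial_id": int(ids[k]),
                    "channel": ch,
                    "rmse": rmse(truth[k, ch], pred[k, ch]),
                    "pearson": pearson_similarity(truth[k, ch], pred[k, ch]),
                    "plv": rep.plv,
                    "phase_of_locking_deg": rep.phase_of_locking,
                    "psi": rep.psi,
                    "zone": rep.zone,
                }
            )
    return pd.DataFrame(rows)
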