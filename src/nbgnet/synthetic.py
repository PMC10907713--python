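"""Synthetic center-out-task sessions with a known cross-scale transfer.

Generates paired fine-scale ("LFP" role) and coarse-scale ("screw ECoG"
role) multichannel trials that mimic the structure of motor-cortical
recordings during a center-out joystick task: beta-band (12.5-30 Hz)
oscillations riding on 1/f background noise, with movement-locked,
cosine-tuned amplitude modulation across 8 equiprobable targets.  The
coarse channels are the fine channels passed through a known discrete
state-space transfer (the tissue-impedance template), optionally through
a saturating nonlinearity, plus measurement noise — so every downstream
stage (network training, phase metrics, latent alignment, decoding) can
be validated against ground truth without any real recordings.

What this emulates, and what it does not: the generator reproduces the
task statistics (8 uniform targets, movement-onset-locked modulation),
the spectral signature (movement-band beta over pink background), and a
physically-motivated cross-scale coupling.  It does not attempt
biophysical cortical network simulation, eye-movement or kinematic
signals, or the spatial correlation structure of real electrode arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import UnstableTransferError, ValidationError
from .statespace import (
    DiscreteStateSpace,
    TissueCircuitParams,
    assemble_transfer,
    circuit_to_statespace,
    discretize,
    simulate_statespace,
)

__all__ = [
    "TrialLabel",
    "ChannelInfo",
    "RecordingSession",
    "SimConfig",
    "tuning_profile",
    "default_transfer",
    "simulate_session",
]

N_TARGETS = 8
#: duration of the movement-execution analysis window (s)
MOVEMENT_WINDOW_S = 0.6
#: beta amplitude at rest relative to the movement-window level
REST_LEVEL = 0.4
#: 1/f background amplitude relative to the beta carrier scale
PINK_LEVEL = 0.3
#: number of shared latent beta sources mixed into the fine channels
N_LATENT_SOURCES = 3
#: reference amplitude of the beta carrier (V); LFP-scale signals
BASE_AMPLITUDE_V = 1e-4

_REGIONS = ("M1", "PMd", "PMv", "SMA", "S1", "PFC", "FEF", "PPC")


@dataclass(frozen=True)
class TrialLabel:
    """Per-trial task annotation: which of the 8 targets, and when movement began."""

    target_direction: int  # 1..8, equally spaced around the circle
    movement_onset: int  # sample index
    trial_id: int


@dataclass(frozen=True)
class ChannelInfo:
    name: str
    role: str  # "fine" or "coarse"
    region: str


@dataclass
class RecordingSession:
    """Paired fine/coarse channelxtime trials with labels; the universal I/O unit."""

    fine: np.ndarray  # (n_trials, n_fine, T) volts
    coarse: np.ndarray  # (n_trials, n_coarse, T) volts
    fs: float
    labels: list[TrialLabel]
    channel_meta: list[ChannelInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fine = np.asarray(self.fine, dtype=float)
        self.coarse = np.asarray(self.coarse, dtype=float)
        if self.fine.ndim != 3 or self.coarse.ndim != 3:
            raise ValidationError("fine and coarse must be (n_trials, n_channels, T) arrays")
        if self.fine.shape[0] != self.coarse.shape[0] or self.fine.shape[2] != self.coarse.shape[2]:
            raise ValidationError("fine and coarse must share trial count and trial length")
        if self.fine.shape[1] < self.coarse.shape[1] or self.coarse.shape[1] < 1:
            raise ValidationError("need n_fine >= n_coarse >= 1")
        if len(self.labels) != self.fine.shape[0]:
            raise ValidationError("one TrialLabel per trial required")
        if not (np.all(np.isfinite(self.fine)) and np.all(np.isfinite(self.coarse))):
            raise ValidationError("signals must be finite")

    @property
    def n_trials(self) -> int:
        return self.fine.shape[0]

    @property
    def n_fine(self) -> int:
        return self.fine.shape[1]

    @property
    def n_coarse(self) -> int:
        return self.coarse.shape[1]

    @property
    def n_samples(self) -> int:
        return self.fine.shape[2]

    def targets(self) -> np.ndarray:
        return np.array([lab.target_direction for lab in self.labels])

    def onsets(self) -> np.ndarray:
        return np.array([lab.movement_onset for lab in self.labels])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic session.

    Defaults mirror a reduced-channel recording layout (16 fine / 8 coarse
    channels) at 1 kHz with 160 trials of 1.6 s, which keeps every
    downstream analysis exercised at desk scale.
    """

    n_fine: int = 16
    n_coarse: int = 8
    n_trials: int = 160
    fs: float = 1000.0
    trial_length: float = 1.6
    beta_band: tuple[float, float] = (12.5, 30.0)
    modulation_depth: float = 0.5
    noise_sd: float = 2e-6
    nonlinearity_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.beta_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValidationError(f"beta_band {self.beta_band} must lie within (0, fs/2)")
        if self.n_trials < N_TARGETS:
            raise ValidationError("need at least 8 trials (one per target)")
        if self.n_fine < self.n_coarse or self.n_coarse < 1:
            raise ValidationError("need n_fine >= n_coarse >= 1")
        if self.trial_length * self.fs < (MOVEMENT_WINDOW_S + 0.1) * self.fs:
            raise ValidationError("trial too short to contain the movement window")
        if self.noise_sd < 0 or self.modulation_depth < 0:
            raise ValidationError("noise_sd and modulation_depth must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length * self.fs))


def tuning_profile(
    target_direction: int, preferred_direction: float, modulation_depth: float = 0.5
) -> float:
    """Cosine tuning gain 1 + depth*cos(theta_target - preferred).

    ``target_direction`` is 1..8 (targets equally spaced on the circle,
    target 1 at angle 0); ``preferred_direction`` is in radians.  The gain is
    bounded in [1-depth, 1+depth] and averages 1 over the 8 targets.
    """
    theta = 2.0 * np.pi * (target_direction - 1) / N_TARGETS
    return 1.0 + modulation_depth * np.cos(theta - preferred_direction)


def default_transfer(
    n_fine: int = 16,
    n_coarse: int = 8,
    fs: float = 1000.0,
    seed: int = 0,
    feedthrough_gain: float = 0.1,
    circuit: TissueCircuitParams | None = None,
) -> DiscreteStateSpace:
    """Ground-truth cross-scale transfer: tissue circuit blocks + random mixing.

    One 3-state tissue-impedance block per coarse channel, driven by a random
    weighted sum of the fine channels, Euler-discretized at the sampling
    rate.  ``feedthrough_gain`` sets the instantaneous volume-conduction
    component of D (which also makes the linear inverse well posed).
    """
    rng = np.random.default_rng(seed)
    mixing = rng.normal(size=(n_coarse, n_fine)) / np.sqrt(n_fine)
    block = circuit_to_statespace(circuit or TissueCircuitParams())
    model = assemble_transfer(block, mixing, feedthrough_gain=feedthrough_gain)
    return discretize(model, 1.0 / fs, scheme="euler")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """1/f-power background via spectral shaping of white noise, unit RMS."""
    white = rng.normal(size=shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    out = np.fft.irfft(spec, n=shape[-1], axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    return out / np.maximum(rms, 1e-30)


def _ramp_window(t_len: int, onset: int, length: int, edge: int) -> np.ndarray:
    """0->1->0 envelope over [onset, onset+length) with raised-cosine edges."""
    w = np.zeros(t_len)
    hi = min(onset + length, t_len)
    w[onset:hi] = 1.0
    e = min(edge, length // 2, hi - onset)
    if e > 0:
        up = 0.5 * (1.0 - np.cos(np.pi * np.arange(e) / e))
        w[onset : onset + e] = up
        w[hi - e : hi] = up[::-1]
    return w


def simulate_session(config: SimConfig, transfer: DiscreteStateSpace) -> RecordingSession:
    """Generate one paired session driven through the given ground-truth transfer.

    The fine channels are a random mixture of 3 shared band-limited beta
    sources whose amplitude is cosine-tuned to the trial's target during the
    600 ms movement window, plus 1/f background and white measurement noise.
    The coarse channels are the transfer output, optionally distorted by a
    normalized tanh saturation, plus independent white noise.  The same
    config (including seed) always yields a bit-identical session.
    """
    if transfer.n_inputs != config.n_fine or transfer.n_outputs != config.n_coarse:
        raise ValidationError(
            f"transfer is {transfer.n_inputs}->{transfer.n_outputs} channels but config "
            f"asks for {config.n_fine}->{config.n_coarse}"
        )
    if not transfer.stable:
        raise UnstableTransferError(
            f"transfer spectral radius {transfer.spectral_radius:.6g} >= 1; "
            "simulation would diverge"
        )
    rng = np.random.default_rng(config.seed)
    t_len = config.n_samples
    fs = config.fs
    win = int(round(MOVEMENT_WINDOW_S * fs))
    edge = int(round(0.05 * fs))

    # session-level structure: mixing of latent sources, per-channel tuning
    mix = rng.normal(size=(config.n_fine, N_LATENT_SOURCES)) / np.sqrt(N_LATENT_SOURCES)
    preferred = rng.uniform(0.0, 2.0 * np.pi, size=config.n_fine)

    sos = sps.butter(4, config.beta_band, btype="bandpass", fs=fs, output="sos")

    # movement onset must leave room for the 600 ms window
    onset_lo = int(round(0.25 * t_len))
    onset_hi = max(onset_lo + 1, t_len - win - edge)
    targets = rng.integers(1, N_TARGETS + 1, size=config.n_trials)
    onsets = rng.integers(onset_lo, onset_hi, size=config.n_trials)

    fine = np.empty((config.n_trials, config.n_fine, t_len))
    labels: list[TrialLabel] = []
    for k in range(config.n_trials):
        target, onset = int(targets[k]), int(onsets[k])
        labels.append(TrialLabel(target_direction=target, movement_onset=onset, trial_id=k))
        latents = sps.sosfiltfilt(sos, rng.normal(size=(N_LATENT_SOURCES, t_len)), axis=-1)
        latents /= np.maximum(np.sqrt(np.mean(latents**2, axis=-1, keepdims=True)), 1e-30)
        carrier = mix @ latents  # (n_fine, T)
        gains = np.array(
            [tuning_profile(target, preferred[ch], config.modulation_depth) for ch in range(config.n_fine)]
        )
        w = _ramp_window(t_len, onset, win, edge)
        envelope = REST_LEVEL + (gains[:, None] - REST_LEVEL) * w[None, :]
        trial = BASE_AMPLITUDE_V * carrier * envelope
        trial += BASE_AMPLITUDE_V * PINK_LEVEL * _pink_noise(rng, (config.n_fine, t_len), fs)
        if config.noise_sd > 0:
            trial += rng.normal(scale=config.noise_sd, size=(config.n_fine, t_len))
        fine[k] = trial

    coarse = np.empty((config.n_trials, config.n_coarse, t_len))
    for k in range(config.n_trials):
        coarse[k] = simulate_statespace(transfer, fine[k])
    if config.nonlinearity_gain > 0:
        g = config.nonlinearity_gain
        scale = float(np.sqrt(np.mean(coarse**2)))
        if scale > 0:
            coarse = (scale / g) * np.tanh(g * coarse / scale)
    if config.noise_sd > 0:
        coarse = coarse + rng.normal(scale=config.noise_sd, size=coarse.shape)

    meta = [
        ChannelInfo(name=f"lfp{ch:02d}", role="fine", region=_REGIONS[ch % len(_REGIONS)])
        for ch in range(config.n_fine)
    ] + [
        ChannelInfo(name=f"ecog{ch:02d}", role="coarse", region=_REGIONS[ch % len(_REGIONS)])
        for ch in range(config.n_coarse)
    ]
    return RecordingSession(fine=fine, coarse=coarse, fs=fs, labels=labels, channel_meta=meta)
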