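"""The bond-graph recurrent network (NBGNet).

The network implements the causal form of the third-order tissue dynamics
with the unknown constitutive relations replaced by small MLPs: per output
block b (one block per predicted channel, three latent states each), three
state-update MLPs f_{b,k}(q_b, u) give the Euler increment of each latent
state and one readout MLP g_b(q_b, u) gives the output sample:

    q[t+1] = q[t] + dt * f(q[t], u[t]),    y[t] = g(q[t], u[t]).

Each MLP has 7 hidden units; the time step equals the sampling interval.
With identity activations and suitably embedded weights the network is
exactly an Euler-discretized linear state-space model, which is the oracle
used to validate the implementation.  Training minimizes mean-squared
error with Adam, a 9:1 train/validation split, and rotation of the
training trial every 20 updates.  Effective connectivity is read out from
the trained parameters as the input-to-output sensitivity Jacobian
averaged over trials and time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._training import TrainConfig, TrainHistory, fit_recurrent, normalization_stats
from .errors import DivergenceError, ValidationError
from .statespace import DiscreteStateSpace
from .synthetic import RecordingSession

__all__ = [
    "NBGNetArch",
    "NBGNetParams",
    "TrainConfig",
    "EffectiveConnectivity",
    "init_nbgnet",
    "nbgnet_step",
    "nbgnet_rollout",
    "train_nbgnet",
    "predict",
    "predict_session",
    "effective_connectivity",
    "embed_linear",
]

_WEIGHT_FIELDS = ("w1f", "b1f", "w2f", "b2f", "w1g", "b1g", "w2g", "b2g")


@dataclass(frozen=True)
class NBGNetArch:
    n_in: int
    n_out: int
    dt: float
    states_per_block: int = 3
    mlp_hidden: int = 7
    activation: str = "tanh"  # "tanh" or "identity"

    def __post_init__(self) -> None:
        if self.mlp_hidden < 1 or self.states_per_block < 1:
            raise ValidationError("mlp_hidden and states_per_block must be >= 1")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.activation not in ("tanh", "identity"):
            raise ValidationError(f"unknown activation {self.activation!r}")

    @property
    def mlp_input_dim(self) -> int:
        return self.states_per_block + self.n_in

    @property
    def n_states(self) -> int:
        return self.states_per_block * self.n_out

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_in": self.n_in,
                "n_out": self.n_out,
                "dt": self.dt,
                "states_per_block": self.states_per_block,
                "mlp_hidden": self.mlp_hidden,
                "activation": self.activation,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NBGNetArch":
        return cls(**json.loads(text))


@dataclass
class NBGNetParams:
    """Structured weights plus the signal normalization learned at training time."""

    arch: NBGNetArch
    w1f: np.ndarray  # (nb, ns, H, d)
    b1f: np.ndarray  # (nb, ns, H)
    w2f: np.ndarray  # (nb, ns, H)
    b2f: np.ndarray  # (nb, ns)
    w1g: np.ndarray  # (nb, H, d)
    b1g: np.ndarray  # (nb, H)
    w2g: np.ndarray  # (nb, H)
    b2g: np.ndarray  # (nb,)
    in_mean: np.ndarray | None = None
    in_std: np.ndarray | None = None
    out_mean: np.ndarray | None = None
    out_std: np.ndarray | None = None

    def weights(self) -> tuple[np.ndarray, ...]:
        return tuple(getattr(self, f) for f in _WEIGHT_FIELDS)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights()])

    def from_vector(self, vec: np.ndarray) -> None:
        offset = 0
        for name in _WEIGHT_FIELDS:
            w = getattr(self, name)
            w[...] = vec[offset : offset + w.size].reshape(w.shape)
            offset += w.size
        if offset != vec.size:
            raise ValidationError(f"vector length {vec.size} does not match parameter count {offset}")

    def copy(self) -> "NBGNetParams":
        return NBGNetParams(
            arch=self.arch,
            **{f: getattr(self, f).copy() for f in _WEIGHT_FIELDS},
            in_mean=None if self.in_mean is None else self.in_mean.copy(),
            in_std=None if self.in_std is None else self.in_std.copy(),
            out_mean=None if self.out_mean is None else self.out_mean.copy(),
            out_std=None if self.out_std is None else self.out_std.copy(),
        )


@dataclass(frozen=True)
class EffectiveConnectivity:
    """Signed source->target influence strengths.

    ``w[j, i]`` is the trial- and time-averaged sensitivity of output
    channel i to input channel j; positive = excitatory, negative =
    inhibitory.  ``per_group`` holds the same matrix restricted to trials of
    one target direction.
    """

    w: np.ndarray  # (n_in, n_out)
    per_group: dict = field(default_factory=dict)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_nbgnet(arch: NBGNetArch, seed: int = 0) -> NBGNetParams:
    """Glorot-uniform weights (zero biases), deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    nb, ns, d, nh = arch.n_out, arch.states_per_block, arch.mlp_input_dim, arch.mlp_hidden
    return NBGNetParams(
        arch=arch,
        w1f=_glorot(rng, d, nh, (nb, ns, nh, d)),
        b1f=np.zeros((nb, ns, nh)),
        w2f=_glorot(rng, nh, 1, (nb, ns, nh)),
        b2f=np.zeros((nb, ns)),
        w1g=_glorot(rng, d, nh, (nb, nh, d)),
        b1g=np.zeros((nb, nh)),
        w2g=_glorot(rng, nh, 1, (nb, nh)),
        b2g=np.zeros(nb),
    )


def _act_flag(arch: NBGNetArch) -> int:
    return 1 if arch.activation == "tanh" else 0


def nbgnet_step(
    params: NBGNetParams, q: np.ndarray, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One causal step: y_t from (q_t, u_t), and q_{t+1} = q_t + dt f(q_t, u_t)."""
    arch = params.arch
    q = np.asarray(q, dtype=float).reshape(arch.n_out, arch.states_per_block)
    u = np.asarray(u, dtype=float).reshape(arch.n_in)
    y, q_traj, _, _ = K.nbg_rollout(
        *params.weights(), np.ascontiguousarray(u[:, None]), q, arch.dt, _act_flag(arch)
    )
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(q_traj))):
        raise DivergenceError("non-finite state or output in nbgnet_step")
    return y[:, 0], q_traj[1]


def nbgnet_rollout(
    params: NBGNetParams, u: np.ndarray, q0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run the whole trial forward (no lookahead).  Returns (Y (p,T), Q (n,T))."""
    arch = params.arch
    u = np.ascontiguousarray(np.atleast_2d(np.asarray(u, dtype=float)))
    if u.shape[0] != arch.n_in:
        raise ValidationError(f"input has {u.shape[0]} channels, arch expects {arch.n_in}")
    if not np.all(np.isfinite(u)):
        raise ValidationError("input contains non-finite values")
    q_init = (
        np.zeros((arch.n_out, arch.states_per_block))
        if q0 is None
        else np.asarray(q0, dtype=float).reshape(arch.n_out, arch.states_per_block)
    )
    y, q_traj, _, _ = K.nbg_rollout(*params.weights(), u, q_init, arch.dt, _act_flag(arch))
    if not np.all(np.isfinite(y)):
        bad = int(np.argmax(~np.all(np.isfinite(y), axis=0)))
        raise DivergenceError(f"rollout diverged at step {bad}")
    q_flat = q_traj[:-1].reshape(u.shape[1], arch.n_states).T
    return y, q_flat


class _NBGModel:
    """Trainer adapter: MSE loss and BPTT gradient on one (normalized) trial."""

    def __init__(self, params: NBGNetParams):
        self.params = params
        self.burnin = 0  # samples excluded from the loss (windowed training)

    def _forward(self, u: np.ndarray):
        arch = self.params.arch
        q0 = np.zeros((arch.n_out, arch.states_per_block))
        return K.nbg_rollout(*self.params.weights(), u, q0, arch.dt, _act_flag(arch))

    def loss(self, u: np.ndarray, y_target: np.ndarray) -> float:
        y, _, _, _ = self._forward(u)
        return float(np.mean((y - y_target) ** 2))

    def loss_and_grad(self, u, y_target, rng):
        arch = self.params.arch
        y, q, hf, hg = self._forward(u)
        err = y - y_target
        if self.burnin > 0:
            err[:, : self.burnin] = 0.0
        n_counted = err.shape[0] * (err.shape[1] - self.burnin)
        loss = float(np.sum(err**2) / n_counted)
        dy = (2.0 / n_counted) * err
        grads = K.nbg_bptt(
            *self.params.weights(), u, q, hf, hg, dy, arch.dt, _act_flag(arch)
        )
        return loss, np.concatenate([g.ravel() for g in grads])

    def get_vector(self) -> np.ndarray:
        return self.params.to_vector()

    def set_vector(self, vec: np.ndarray) -> None:
        self.params.from_vector(vec)


def train_nbgnet(
    params: NBGNetParams,
    session: RecordingSession,
    direction: str = "forward",
    cfg: TrainConfig | None = None,
) -> tuple[NBGNetParams, TrainHistory]:
    """Fit the network on a session; forward maps fine->coarse, inverse coarse->fine.

    Signals are z-scored per channel with training-split statistics before
    optimization (the saturating MLPs need O(1) inputs); the normalization is
    stored on the returned parameters so :func:`predict` works in volts.
    Returns the best-validation parameters and the training history.
    """
    cfg = cfg or TrainConfig()
    if direction == "forward":
        u_all, y_all = session.fine, session.coarse
    elif direction == "inverse":
        u_all, y_all = session.coarse, session.fine
    else:
        raise ValidationError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    arch = params.arch
    if u_all.shape[1] != arch.n_in or y_all.shape[1] != arch.n_out:
        raise ValidationError(
            f"session is {u_all.shape[1]}->{y_all.shape[1]} channels, arch expects "
            f"{arch.n_in}->{arch.n_out}"
        )
    work = params.copy()
    # the same seed drives the split here and in fit_recurrent, so the
    # normalization is computed on exactly the training trials
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(u_all.shape[0])
    n_val = max(1, int(round(cfg.val_fraction * u_all.shape[0])))
    train_idx = perm[n_val:]
    in_mean, in_std = normalization_stats(u_all, train_idx)
    out_mean, out_std = normalization_stats(y_all, train_idx)
    u_norm = (u_all - in_mean[None, :, None]) / in_std[None, :, None]
    y_norm = (y_all - out_mean[None, :, None]) / out_std[None, :, None]
    model = _NBGModel(work)
    history = fit_recurrent(model, u_norm, y_norm, cfg)
    work.in_mean, work.in_std = in_mean, in_std
    work.out_mean, work.out_std = out_mean, out_std
    return work, history


def predict(params: NBGNetParams, u: np.ndarray) -> np.ndarray:
    """Rollout in physical units, applying the stored normalization if any."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if params.in_mean is not None:
        u = (u - params.in_mean[:, None]) / params.in_std[:, None]
    y, _ = nbgnet_rollout(params, u)
    if params.out_mean is not None:
        y = y * params.out_std[:, None] + params.out_mean[:, None]
    return y


def predict_session(params: NBGNetParams, inputs: np.ndarray) -> np.ndarray:
    """Apply :func:`predict` to every trial of an (n_trials, ch, T) array."""
    inputs = np.asarray(inputs, dtype=float)
    return np.stack([predict(params, inputs[k]) for k in range(inputs.shape[0])])


def _instantaneous_jacobian(params: NBGNetParams, u: np.ndarray) -> np.ndarray:
    """Mean over time of d y_i,t / d u_j,t along the rollout trajectory (analytic)."""
    arch = params.arch
    u = np.ascontiguousarray(np.atleast_2d(np.asarray(u, dtype=float)))
    q0 = np.zeros((arch.n_out, arch.states_per_block))
    _, _, _, hg = K.nbg_rollout(*params.weights(), u, q0, arch.dt, _act_flag(arch))
    dact = 1.0 - hg**2 if arch.activation == "tanh" else np.ones_like(hg)
    w1g_u = params.w1g[:, :, arch.states_per_block :]  # (nb, H, n_in)
    # J[t, j, b] = sum_h w2g[b,h] * dact[t,b,h] * w1g_u[b,h,j]
    jac = np.einsum("bh,tbh,bhj->tjb", params.w2g, dact, w1g_u)
    return jac.mean(axis=0)  # (n_in, n_out)


def _fd_jacobian(params: NBGNetParams, u: np.ndarray, eps: float = 1e-5, stride: int = 50) -> np.ndarray:
    """Central-finite-difference check of the instantaneous sensitivity."""
    arch = params.arch
    u = np.atleast_2d(np.asarray(u, dtype=float))
    _, q_flat = nbgnet_rollout(params, u)
    t_idx = np.arange(0, u.shape[1], stride)
    acc = np.zeros((arch.n_in, arch.n_out))
    for t in t_idx:
        q = q_flat[:, t].reshape(arch.n_out, arch.states_per_block)
        for j in range(arch.n_in):
            up = u[:, t].copy()
            um = u[:, t].copy()
            up[j] += eps
            um[j] -= eps
            yp, _ = nbgnet_step(params, q, up)
            ym, _ = nbgnet_step(params, q, um)
            acc[j] += (yp - ym) / (2 * eps)
    return acc / t_idx.size


def effective_connectivity(
    params: NBGNetParams,
    trials: list[np.ndarray] | np.ndarray,
    group_by: np.ndarray | None = None,
    method: str = "analytic",
) -> EffectiveConnectivity:
    """Input-to-output sensitivity averaged over trials (and optionally per target).

    ``method='analytic'`` differentiates the readout MLP exactly along the
    rollout trajectory; ``'fd'`` uses central finite differences on a time
    subgrid (slow; used to cross-check the analytic path).
    """
    fn = {"analytic": _instantaneous_jacobian, "fd": _fd_jacobian}.get(method)
    if fn is None:
        raise ValidationError(f"unknown method {method!r}")
    mats = np.stack([fn(params, np.asarray(tr, dtype=float)) for tr in trials])
    per_group: dict = {}
    if group_by is not None:
        group_by = np.asarray(group_by)
        for g in np.unique(group_by):
            per_group[int(g)] = mats[group_by == g].mean(axis=0)
    return EffectiveConnectivity(w=mats.mean(axis=0), per_group=per_group)


def state_jacobian(params: NBGNetParams, u: np.ndarray) -> np.ndarray:
    """Latent-to-latent variant: mean d q_{t+1} / d q_t within each block.

    Returns (n_out, ns, ns) block-diagonal sensitivities (blocks are
    independent by construction).
    """
    arch = params.arch
    u = np.ascontiguousarray(np.atleast_2d(np.asarray(u, dtype=float)))
    ns = arch.states_per_block
    q0 = np.zeros((arch.n_out, ns))
    _, _, hf, _ = K.nbg_rollout(*params.weights(), u, q0, arch.dt, _act_flag(arch))
    dact = 1.0 - hf**2 if arch.activation == "tanh" else np.ones_like(hf)
    w1f_q = params.w1f[:, :, :, :ns]  # (nb, ns, H, ns)
    jac = np.einsum("bkh,tbkh,bkhj->tbkj", params.w2f, dact, w1f_q)
    eye = np.eye(ns)[None, :, :]
    return eye + arch.dt * jac.mean(axis=0)


def embed_linear(
    arch: NBGNetArch, dss: DiscreteStateSpace, scale: float = 1.0
) -> NBGNetParams:
    """Weights that make the network reproduce an Euler-discretized linear model.

    ``dss`` must be block-structured to match the architecture: one
    ``states_per_block`` block per output, Euler scheme.  With identity
    activation the embedding is exact; with tanh it is exact only in the
    small-signal limit and ``scale`` shrinks the first layer (and grows the
    second) to keep hidden pre-activations in the linear range.
    """
    nb, ns, m = arch.n_out, arch.states_per_block, arch.n_in
    if dss.n_states != nb * ns or dss.n_inputs != m or dss.n_outputs != nb:
        raise ValidationError(
            f"state-space ({dss.n_states} states, {dss.n_inputs}->{dss.n_outputs}) does not "
            f"match architecture ({nb * ns} states, {m}->{nb})"
        )
    params = init_nbgnet(arch, seed=0)
    for w in params.weights():
        w[...] = 0.0
    dt = arch.dt
    for b in range(nb):
        sl = slice(b * ns, (b + 1) * ns)
        a_blk = (dss.ad[sl, sl] - np.eye(ns)) / dt
        b_blk = dss.bd[sl, :] / dt
        for k in range(ns):
            coeffs = np.concatenate([a_blk[k], b_blk[k]])  # (ns + m,)
            params.w1f[b, k, 0, :] = coeffs * scale
            params.w2f[b, k, 0] = 1.0 / scale
        coeffs_g = np.concatenate([dss.cd[b, sl], dss.dd[b, :]])
        params.w1g[b, 0, :] = coeffs_g * scale
        params.w2g[b, 0] = 1.0 / scale
    return params
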