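"""Shared training driver for the recurrent models.

Implements the common optimization contract: mean-squared-error loss,
Adam updates, a 9:1 train/validation split, rotation to a freshly drawn
training trial every ``rotation_period`` parameter updates (the
over-fitting guard), early stopping on validation loss, and return of the
best-validation parameters.  Both the bond-graph network and the GRU
baseline train through this driver so their comparison is like for like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .errors import ValidationError

__all__ = ["TrainConfig", "SequenceModel", "fit_recurrent", "normalization_stats"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3  # starting learning rate
    #: cosine-anneal the learning rate to lr/30 over max_updates
    #: ("constant" disables the schedule)
    lr_schedule: str = "cosine"
    rotation_period: int = 20  # updates between training-trial swaps
    val_fraction: float = 0.1  # 9:1 train:validation split
    max_updates: int = 20000
    patience: int = 50  # rotations without validation improvement
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    #: at most this many validation trials are scored at each rotation
    #: (keeps the early-stopping check cheap on large sessions)
    val_eval_cap: int = 8
    #: global-norm gradient clip; stabilizes the unsaturated (identity
    #: activation) recurrence, inert once training is in a good basin
    grad_clip: float | None = 10.0
    #: if set, each update backpropagates through a random contiguous
    #: sub-window of this many samples instead of the whole trial (the
    #: recurrent state is re-zeroed at the window start); raises the update
    #: rate on long trials at the cost of a short initial-state transient
    window_samples: int | None = None
    #: when windowing, the first this-many samples of each window are run
    #: but excluded from the loss (the re-zeroed state needs to settle)
    window_burnin: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValidationError("val_fraction must be in (0, 1)")
        if self.max_updates < 1 or self.rotation_period < 1:
            raise ValidationError("max_updates and rotation_period must be >= 1")


class SequenceModel(Protocol):
    """What the trainer needs: loss/gradient on one trial, flat parameter access."""

    def loss_and_grad(self, u: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> tuple[float, np.ndarray]: ...

    def loss(self, u: np.ndarray, y: np.ndarray) -> float: ...

    def get_vector(self) -> np.ndarray: ...

    def set_vector(self, vec: np.ndarray) -> None: ...


def normalization_stats(arrays: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and std over the selected trials of (n_trials, ch, T)."""
    sel = arrays[idx]
    mean = sel.mean(axis=(0, 2))
    std = sel.std(axis=(0, 2))
    std = np.where(std > 0, std, 1.0)
    return mean, std


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)  # (update, loss)
    val_loss: list = field(default_factory=list)  # (update, loss)
    best_val: float = np.inf
    best_update: int = 0
    n_updates: int = 0
    early_stopped: bool = False
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None


def fit_recurrent(
    model: SequenceModel,
    u_trials: np.ndarray,
    y_trials: np.ndarray,
    cfg: TrainConfig,
) -> TrainHistory:
    """Train ``model`` on (n_trials, ch, T) input/target arrays.

    The data are assumed already normalized by the caller.  Returns the
    history; the model is left holding the best-validation parameters.
    """
    n = u_trials.shape[0]
    if n < 10:
        raise ValidationError(f"need at least 10 trials to honor the 9:1 split, got {n}")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    val_eval = val_idx[: cfg.val_eval_cap]

    def val_loss() -> float:
        return float(np.mean([model.loss(u_trials[i], y_trials[i]) for i in val_eval]))

    hist = TrainHistory(train_idx=train_idx, val_idx=val_idx)
    v0 = val_loss()
    hist.val_loss.append((0, v0))
    hist.best_val = v0
    best_vec = model.get_vector().copy()

    vec = model.get_vector()
    m_adam = np.zeros_like(vec)
    v_adam = np.zeros_like(vec)
    bad_rotations = 0
    trial = int(rng.choice(train_idx))
    for step in range(1, cfg.max_updates + 1):
        if step > 1 and (step - 1) % cfg.rotation_period == 0:
            trial = int(rng.choice(train_idx))
            vl = val_loss()
            hist.val_loss.append((step - 1, vl))
            if vl < hist.best_val:
                hist.best_val = vl
                hist.best_update = step - 1
                best_vec = model.get_vector().copy()
                bad_rotations = 0
            else:
                bad_rotations += 1
                if bad_rotations > cfg.patience:
                    hist.early_stopped = True
                    break
        u_t, y_t = u_trials[trial], y_trials[trial]
        model.burnin = 0
        if cfg.window_samples is not None and u_t.shape[-1] > cfg.window_samples:
            start = int(rng.integers(0, u_t.shape[-1] - cfg.window_samples + 1))
            u_t = u_t[..., start : start + cfg.window_samples]
            y_t = y_t[..., start : start + cfg.window_samples]
            if start > 0:  # a mid-trial window starts from a re-zeroed state
                model.burnin = min(cfg.window_burnin, cfg.window_samples // 2)
        loss, grad = model.loss_and_grad(u_t, y_t, rng)
        hist.train_loss.append((step, loss))
        hist.n_updates = step
        if not np.isfinite(loss) or not np.all(np.isfinite(grad)):
            # a diverged rollout: skip the update, fall back to the best state
            model.set_vector(best_vec.copy())
            continue
        if cfg.grad_clip is not None:
            gnorm = float(np.linalg.norm(grad))
            if gnorm > cfg.grad_clip:
                grad = grad * (cfg.grad_clip / gnorm)
        m_adam = cfg.beta1 * m_adam + (1 - cfg.beta1) * grad
        v_adam = cfg.beta2 * v_adam + (1 - cfg.beta2) * grad**2
        mhat = m_adam / (1 - cfg.beta1**step)
        vhat = v_adam / (1 - cfg.beta2**step)
        if cfg.lr_schedule == "cosine":
            lr_min = cfg.lr / 30.0
            lr = lr_min + 0.5 * (cfg.lr - lr_min) * (1 + np.cos(np.pi * step / cfg.max_updates))
        else:
            lr = cfg.lr
        vec = model.get_vector() - lr * mhat / (np.sqrt(vhat) + cfg.eps)
        model.set_vector(vec)

    vl = val_loss()
    hist.val_loss.append((hist.n_updates, vl))
    if vl < hist.best_val:
        hist.best_val = vl
        hist.best_update = hist.n_updates
    else:
        model.set_vector(best_vec)
    return hist
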