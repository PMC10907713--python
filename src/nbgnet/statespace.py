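"""Linear state-space skeleton of the cross-scale transfer.

The biological medium between a depth (fine-scale, LFP-role) electrode and a
skull-screw (coarse-scale, ECoG-role) electrode is modeled as a lumped
electrical circuit: the cortex as a series resistance, the dura as a
resistance and capacitance in parallel, the skull as a compact-bone /
spongy-bone / compact-bone ladder whose trabecular conduction path and
cavity capacitance shunt the signal, and an electrode-tissue interface
capacitance at the measurement node.  Kirchhoff analysis of that circuit
yields a third-order linear ODE per measurement path, written here in
state-space form

    x' = A x + B u,    y = C x + D u

with the three capacitor voltages as states.  This linear model is the
analytic template that the recurrent network nonlinearizes, the source of
the algebraic inverse model, and the oracle for linear equivalence tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .errors import SingularMatrixError, ValidationError

__all__ = [
    "TissueCircuitParams",
    "StateSpaceModel",
    "DiscreteStateSpace",
    "circuit_to_statespace",
    "assemble_transfer",
    "invert_statespace",
    "invert_discrete",
    "discretize",
    "simulate_statespace",
]


@dataclass(frozen=True)
class TissueCircuitParams:
    """Lumped impedances of the tissue path, all SI units.

    ``r_cortex``: effective resistance of the cortical grey matter (ohm).
    ``r_dura``/``c_dura``: dura mater modeled as R and C in parallel.
    ``r_compact1``/``r_compact2``: the two compact bone layers.
    ``r_trabecular``/``c_spongy``: trabecular conduction path and cavity
    capacitance of the spongy bone layer (shunt branch).
    ``c_interface``: electrode-tissue interface capacitance at the
    measurement node.
    """

    r_cortex: float = 1.0e3
    r_dura: float = 5.0e3
    c_dura: float = 1.0e-6
    r_compact1: float = 2.0e4
    r_compact2: float = 2.0e4
    r_trabecular: float = 1.0e4
    c_spongy: float = 5.0e-7
    c_interface: float = 1.0e-7

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValidationError(f"circuit parameter {name} must be positive, got {value!r}")


@dataclass(frozen=True)
class StateSpaceModel:
    """Continuous-time linear system x' = Ax + Bu, y = Cx + Du."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    state_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a, b, c, d = (np.atleast_2d(np.asarray(m, dtype=float)) for m in (self.a, self.b, self.c, self.d))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "d", d)
        n, m, p = a.shape[0], b.shape[1], c.shape[0]
        if a.shape != (n, n) or b.shape != (n, m) or c.shape != (p, n) or d.shape != (p, m):
            raise ValidationError(
                f"inconsistent state-space dimensions: A{a.shape} B{b.shape} C{c.shape} D{d.shape}"
            )

    @property
    def n_states(self) -> int:
        return self.a.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.b.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.c.shape[0]

    def dc_gain(self) -> np.ndarray:
        """Static gain D - C A^-1 B (A must be invertible, i.e. no pure integrators)."""
        return self.d - self.c @ np.linalg.solve(self.a, self.b)

    def frequency_response(self, omega: float) -> np.ndarray:
        """Transfer matrix C (jwI - A)^-1 B + D at angular frequency ``omega``."""
        n = self.n_states
        return self.c @ np.linalg.solve(1j * omega * np.eye(n) - self.a, self.b) + self.d


@dataclass(frozen=True)
class DiscreteStateSpace:
    """Discrete-time linear system x[t+1] = Ad x[t] + Bd u[t], y[t] = Cd x[t] + Dd u[t]."""

    ad: np.ndarray
    bd: np.ndarray
    cd: np.ndarray
    dd: np.ndarray
    dt: float
    scheme: str = "euler"
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.scheme not in ("euler", "zoh"):
            raise ValidationError(f"unknown discretization scheme {self.scheme!r}")
        ad, bd, cd, dd = (np.atleast_2d(np.asarray(m, dtype=float)) for m in (self.ad, self.bd, self.cd, self.dd))
        object.__setattr__(self, "ad", ad)
        object.__setattr__(self, "bd", bd)
        object.__setattr__(self, "cd", cd)
        object.__setattr__(self, "dd", dd)

    @property
    def n_states(self) -> int:
        return self.ad.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.bd.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.cd.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.ad)))) if self.n_states else 0.0

    @property
    def stable(self) -> bool:
        return self.spectral_radius < 1.0


def circuit_to_statespace(params: TissueCircuitParams) -> StateSpaceModel:
    """Kirchhoff node equations of the tissue ladder as a 3-state model.

    Circuit (source u = fine-scale potential, y = coarse-scale measurement)::

        u --R_cortex-- (R_dura || C_dura) --R_compact1-- node_s --R_compact2-- node_m
                                                           |                     |
                                                   R_trab || C_spongy        C_interface
                                                           |                     |
                                                          ref                   ref

    States are the three capacitor voltages x1 = V(C_dura) (series element),
    x2 = V(C_spongy) (spongy-bone node), x3 = V(C_interface) (measurement
    node); the output is x3.  The network is passive RC, so A is Hurwitz for
    any positive parameters.
    """
    p = params
    g = 1.0 / (p.r_cortex + p.r_compact1)  # series conductance up to the spongy node
    a = np.array(
        [
            [-(g + 1.0 / p.r_dura) / p.c_dura, -g / p.c_dura, 0.0],
            [-g / p.c_spongy, -(g + 1.0 / p.r_trabecular + 1.0 / p.r_compact2) / p.c_spongy, 1.0 / (p.r_compact2 * p.c_spongy)],
            [0.0, 1.0 / (p.r_compact2 * p.c_interface), -1.0 / (p.r_compact2 * p.c_interface)],
        ]
    )
    b = np.array([[g / p.c_dura], [g / p.c_spongy], [0.0]])
    c = np.array([[0.0, 0.0, 1.0]])
    d = np.zeros((1, 1))
    return StateSpaceModel(a, b, c, d, state_labels=("C_dura", "C_spongy", "C_interface"))


def assemble_transfer(
    block: StateSpaceModel,
    mixing: np.ndarray,
    feedthrough_gain: float = 0.0,
) -> StateSpaceModel:
    """Assemble a multi-channel transfer from a single-path tissue block.

    One independent copy of ``block`` (3 states for the tissue template) is
    allocated per coarse output channel; channel ``i`` is driven by the
    weighted sum of all fine inputs with weights ``mixing[i, :]``.  The total
    state dimension is ``block.n_states * n_coarse``.  ``feedthrough_gain``
    adds an instantaneous volume-conduction term ``feedthrough_gain * mixing``
    to D, modeling the capacitive/resistive direct coupling between sites
    that acts faster than one sample.
    """
    w = np.atleast_2d(np.asarray(mixing, dtype=float))
    if block.n_inputs != 1 or block.n_outputs != 1:
        raise ValidationError("assemble_transfer expects a single-input single-output block")
    n_coarse, n_fine = w.shape
    nb = block.n_states
    a = np.kron(np.eye(n_coarse), block.a)
    b = np.zeros((nb * n_coarse, n_fine))
    c = np.zeros((n_coarse, nb * n_coarse))
    for i in range(n_coarse):
        b[i * nb : (i + 1) * nb, :] = block.b @ w[i : i + 1, :]
        c[i, i * nb : (i + 1) * nb] = block.c[0]
    d = float(block.d[0, 0]) * w + feedthrough_gain * w
    labels = tuple(f"{lab}[{i}]" for i in range(n_coarse) for lab in (block.state_labels or ("x",) * nb))
    return StateSpaceModel(a, b, c, d, state_labels=labels)


def invert_statespace(model: StateSpaceModel, regularize: bool = True) -> StateSpaceModel:
    """Algebraic inverse of a state-space model.

    For invertible square D the inverse realization is
    ``(A - B D^-1 C,  B D^-1,  -D^-1 C,  D^-1)``; composing forward then
    inverse reproduces the input exactly in continuous time.  For singular or
    non-square D the inversion is ill-posed; with ``regularize`` a Tikhonov
    pseudo-inverse ``D+ = (D^T D + eps I)^-1 D^T`` with ``eps = 1e-8 ||D||^2``
    (spectral norm) is used instead.
    """
    d = model.d
    svals = np.linalg.svd(d, compute_uv=False)
    smin = float(svals.min()) if svals.size else 0.0
    smax = float(svals.max()) if svals.size else 0.0
    square = d.shape[0] == d.shape[1]
    if square and smin > 1e-12 * max(smax, 1.0):
        d_inv = np.linalg.solve(d, np.eye(d.shape[0]))
    elif regularize:
        if smax == 0.0:
            raise SingularMatrixError(
                "D is identically zero (smallest singular value 0.0); the direct-feedthrough "
                "inverse does not exist and regularization cannot recover it"
            )
        eps = 1e-8 * smax**2
        d_inv = np.linalg.solve(d.T @ d + eps * np.eye(d.shape[1]), d.T)
    else:
        raise SingularMatrixError(
            f"D is singular (smallest singular value {smin:.3e}) and regularization is disabled"
        )
    a_inv = model.a - model.b @ d_inv @ model.c
    b_inv = model.b @ d_inv
    c_inv = -d_inv @ model.c
    return StateSpaceModel(a_inv, b_inv, c_inv, d_inv, state_labels=model.state_labels)


def invert_discrete(model: DiscreteStateSpace, regularize: bool = True) -> DiscreteStateSpace:
    """Exact discrete-time inverse: feed y back in, read u out.

    Uses the same algebra as :func:`invert_statespace`; for discrete systems
    the composition forward-then-inverse is exact sample by sample (no
    discretization error), because u[t] = Dd^-1 (y[t] - Cd x[t]) recovers the
    input algebraically at every step.
    """
    inv = invert_statespace(
        StateSpaceModel(model.ad, model.bd, model.cd, model.dd), regularize=regularize
    )
    return DiscreteStateSpace(inv.a, inv.b, inv.c, inv.d, dt=model.dt, scheme=model.scheme)


def discretize(model: StateSpaceModel, dt: float, scheme: str = "euler") -> DiscreteStateSpace:
    """Discretize with forward Euler (the scheme the recurrent network embodies) or ZOH."""
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    notes: tuple[str, ...] = ()
    if scheme == "euler":
        ad = np.eye(model.n_states) + dt * model.a
        bd = dt * model.b
        radius = float(np.max(np.abs(np.linalg.eigvals(ad)))) if model.n_states else 0.0
        if radius >= 1.0:
            msg = f"euler discretization is unstable at dt={dt:g} (spectral radius {radius:.6g} >= 1)"
            notes = (msg,)
            warnings.warn(msg, stacklevel=2)
    elif scheme == "zoh":
        n, m = model.n_states, model.n_inputs
        aug = np.zeros((n + m, n + m))
        aug[:n, :n] = model.a * dt
        aug[:n, n:] = model.b * dt
        e = expm(aug)
        ad, bd = e[:n, :n], e[:n, n:]
    else:
        raise ValidationError(f"unknown discretization scheme {scheme!r}")
    return DiscreteStateSpace(ad, bd, model.c.copy(), model.d.copy(), dt=dt, scheme=scheme, warnings=notes)


def simulate_statespace(
    model: DiscreteStateSpace, u: np.ndarray, x0: np.ndarray | None = None
) -> np.ndarray:
    """Run the exact recursion x[t+1] = Ad x + Bd u, y[t] = Cd x + Dd u.

    ``u`` has shape (n_inputs, T); returns y of shape (n_outputs, T).
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[0] != model.n_inputs:
        raise ValidationError(f"input has {u.shape[0]} rows, model expects {model.n_inputs}")
    if not np.all(np.isfinite(u)):
        raise ValidationError("input contains non-finite values")
    n, t_len = model.n_states, u.shape[1]
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).reshape(n)
    y = np.empty((model.n_outputs, t_len))
    ad, bd, cd, dd = model.ad, model.bd, model.cd, model.dd
    for t in range(t_len):
        y[:, t] = cd @ x + dd @ u[:, t]
        x = ad @ x + bd @ u[:, t]
    return y
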