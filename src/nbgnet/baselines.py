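"""Comparison methods: four-shell sphere head model and GRU baseline.

The sphere head model is the purely electrophysiology-based alternative: a
radial current dipole inside a four-layered spherical volume conductor
(brain, CSF, skull, scalp) whose potential is a Legendre series with
per-harmonic coefficients fixed by the interface boundary conditions
(continuity of the potential and of the radial current density, and zero
radial current at the scalp surface).  A lead field F maps dipole moments
to electrode potentials, Y = F X; the inverse mapping is the minimum-norm
pseudo-inverse X = F^T (F F^T)^-1 Y; and cross-modality translation is the
two-step composition: invert to dipole moments from one electrode set,
re-project to the other.

The GRU recurrent network is the purely data-driven alternative: two GRU
layers (64 and 32 units), two tanh dense layers (32 and 16 nodes for the
forward direction, 32 and 128 for the inverse), and a linear output,
trained with the same optimizer, split, loss and stopping contract as the
bond-graph network, plus L2 weight decay and dropout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from ._training import TrainConfig, TrainHistory, fit_recurrent, normalization_stats
from .errors import ValidationError
from .synthetic import RecordingSession

__all__ = [
    "SphereHeadParams",
    "RadialDipole",
    "LeadField",
    "sphere_potential",
    "build_lead_field",
    "minnorm_inverse",
    "two_step_map",
    "default_dipole_grid",
    "default_electrode_geometry",
    "sphere_map_session",
    "GRUArch",
    "GRUParams",
    "init_gru",
    "predict_gru",
    "train_gru_baseline",
]

# --------------------------------------------------------------------------
# sphere head model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereHeadParams:
    """Radii (mm) and conductivities (S/m) of the four concentric layers.

    Defaults: brain 27.88 mm / 0.33 S/m, CSF 28.24 / 1.65, skull 30.00 /
    0.00825, scalp 31.76 / 0.33.
    """

    radii_mm: tuple[float, float, float, float] = (27.88, 28.24, 30.00, 31.76)
    sigma: tuple[float, float, float, float] = (0.33, 1.65, 0.00825, 0.33)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_mm, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if r.shape != (4,) or s.shape != (4,):
            raise ValidationError("need exactly 4 layers")
        if not np.all(np.diff(r) > 0):
            raise ValidationError("radii must be strictly increasing")
        if not np.all(s > 0):
            raise ValidationError("conductivities must be positive")


@dataclass(frozen=True)
class RadialDipole:
    """Radial current dipole at radius ``r_z_mm`` (inside the brain layer)."""

    r_z_mm: float
    moment: float = 1.0  # A*m

    def __post_init__(self) -> None:
        if self.r_z_mm <= 0:
            raise ValidationError("dipole radius must be positive")


@dataclass(frozen=True)
class LeadField:
    f: np.ndarray  # (n_r, n_d), volts per unit moment
    electrodes: np.ndarray  # (n_r, 3) mm
    dipoles: np.ndarray  # (n_d, 3) mm, radial dipole positions


def _shell_coefficients(head: SphereHeadParams, r_z_mm: float, n_terms: int) -> np.ndarray:
    """Solve the per-harmonic 7x7 boundary-condition system.

    Returns an (n_terms, 7) array of [A1, A2, B2, A3, B3, A4, B4] for
    n = 1..n_terms.  The shell-1 inhomogeneous source part (r_z/r)^{n+1}
    has fixed unit coefficient and enters the right-hand side.
    """
    r1, r2, r3, r4 = (x * 1e-3 for x in head.radii_mm)  # to meters
    s1, s2, s3, s4 = head.sigma
    rz = r_z_mm * 1e-3
    if not rz < r1:
        raise ValidationError(f"dipole radius {r_z_mm} mm must be inside the brain layer")
    out = np.empty((n_terms, 7))
    for i, n in enumerate(range(1, n_terms + 1)):
        np1 = n + 1
        # potential and radial-derivative templates in shell s at radius r:
        #   A_s (r/r_s)^n  +  B_s (r_s/r)^{n+1}
        #   d/dr: A_s n r^{n-1}/r_s^n  -  B_s np1 r_s^{n+1} / r^{n+2}
        mat = np.zeros((7, 7))
        rhs = np.zeros(7)
        src_phi_r1 = (rz / r1) ** np1
        src_dphi_r1 = -np1 / r1 * (rz / r1) ** np1
        # continuity of potential at r1: A1 + src = A2 (r1/r2)^n + B2 (r2/r1)^{n+1}
        mat[0, 0] = 1.0
        mat[0, 1] = -((r1 / r2) ** n)
        mat[0, 2] = -((r2 / r1) ** np1)
        rhs[0] = -src_phi_r1
        # continuity of sigma dPhi/dr at r1
        mat[1, 0] = s1 * n / r1
        mat[1, 1] = -s2 * n / r1 * (r1 / r2) ** n
        mat[1, 2] = s2 * np1 / r1 * (r2 / r1) ** np1
        rhs[1] = -s1 * src_dphi_r1
        # interface r2 between shells 2 and 3
        mat[2, 1] = 1.0
        mat[2, 2] = 1.0
        mat[2, 3] = -((r2 / r3) ** n)
        mat[2, 4] = -((r3 / r2) ** np1)
        mat[3, 1] = s2 * n / r2
        mat[3, 2] = -s2 * np1 / r2
        mat[3, 3] = -s3 * n / r2 * (r2 / r3) ** n
        mat[3, 4] = s3 * np1 / r2 * (r3 / r2) ** np1
        # interface r3 between shells 3 and 4
        mat[4, 3] = 1.0
        mat[4, 4] = 1.0
        mat[4, 5] = -((r3 / r4) ** n)
        mat[4, 6] = -((r4 / r3) ** np1)
        mat[5, 3] = s3 * n / r3
        mat[5, 4] = -s3 * np1 / r3
        mat[5, 5] = -s4 * n / r3 * (r3 / r4) ** n
        mat[5, 6] = s4 * np1 / r3 * (r4 / r3) ** np1
        # outer Neumann condition at r4: dPhi4/dr = 0
        mat[6, 5] = n / r4
        mat[6, 6] = -np1 / r4
        out[i] = np.linalg.solve(mat, rhs)
    return out


def _shell_of(head: SphereHeadParams, r_mm: float) -> int:
    r = np.asarray(head.radii_mm)
    if r_mm > r[3] * (1 + 1e-12):
        raise ValidationError(f"evaluation radius {r_mm} mm is outside the scalp ({r[3]} mm)")
    return int(np.searchsorted(r, r_mm * (1 - 1e-12)))  # 0..3


def _series_eval(
    head: SphereHeadParams,
    coeffs: np.ndarray,
    rz_mm: float,
    moment: float,
    r_mm: np.ndarray,
    cos_theta: np.ndarray,
    n_terms: int,
    tail_tol: float = 1e-10,
) -> np.ndarray:
    """Evaluate the truncated Legendre series at points (r, theta) (vectorized)."""
    radii = np.asarray(head.radii_mm, dtype=float) * 1e-3
    rz = rz_mm * 1e-3
    r = np.asarray(r_mm, dtype=float) * 1e-3
    x = np.asarray(cos_theta, dtype=float)
    shells = np.array([_shell_of(head, float(rv)) for rv in np.atleast_1d(r_mm)])
    if np.any((shells == 0) & (r < rz * (1 - 1e-12))):
        raise ValidationError("evaluation point lies below the dipole radius")
    prefac = moment / (4.0 * np.pi * head.sigma[0] * rz)
    # Legendre recurrence P_0 = 1, P_1 = x
    p_prev = np.ones_like(x)
    p_cur = x.copy()
    total = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        a_idx = {0: 0, 1: 1, 2: 3, 3: 5}
        term = np.empty_like(x)
        for s in (0, 1, 2, 3):
            m = shells == s
            if not np.any(m):
                continue
            rs = radii[s]
            a = coeffs[n - 1, a_idx[s]]
            if s == 0:
                radial = a * (r[m] / rs) ** n + (rz / r[m]) ** (n + 1)
            else:
                b = coeffs[n - 1, a_idx[s] + 1]
                radial = a * (r[m] / rs) ** n + b * (rs / r[m]) ** (n + 1)
            term[m] = radial
        contrib = term * n * p_cur
        total += contrib
        tail = np.max(np.abs(contrib))
        if tail < tail_tol * max(np.max(np.abs(total)), 1e-300):
            break
        # advance recurrence: P_{n+1}
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        p_prev, p_cur = p_cur, p_next
    return prefac * total


def sphere_potential(
    dipole: RadialDipole,
    point: tuple[float, float],
    head: SphereHeadParams | None = None,
    n_terms: int = 200,
) -> float:
    """Potential (V) of a radial unit dipole at (r_mm, theta_rad).

    ``point`` is (radius in mm, polar angle in radians between the
    measurement and dipole location vectors).  The series is truncated at
    ``n_terms`` or when the last term's relative contribution drops below
    1e-10.
    """
    head = head or SphereHeadParams()
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    r_mm, theta = point
    coeffs = _shell_coefficients(head, dipole.r_z_mm, n_terms)
    val = _series_eval(
        head,
        coeffs,
        dipole.r_z_mm,
        dipole.moment,
        np.array([r_mm]),
        np.array([np.cos(theta)]),
        n_terms,
    )
    return float(val[0])


def build_lead_field(
    dipole_positions: np.ndarray,
    electrode_positions: np.ndarray,
    head: SphereHeadParams | None = None,
    n_terms: int = 200,
) -> LeadField:
    """F[i, j] = potential at electrode i of a unit radial dipole at grid point j.

    Positions are (n, 3) arrays in mm with the head center at the origin;
    every dipole must lie inside the brain layer, every electrode at or
    inside the scalp radius (and above the dipole radius).
    """
    head = head or SphereHeadParams()
    dip = np.atleast_2d(np.asarray(dipole_positions, dtype=float))
    ele = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    r_dip = np.linalg.norm(dip, axis=1)
    r_ele = np.linalg.norm(ele, axis=1)
    if np.any(r_dip >= head.radii_mm[0]):
        raise ValidationError("all dipoles must be inside the brain layer")
    if np.any(r_ele > head.radii_mm[3] * (1 + 1e-12)):
        raise ValidationError("all electrodes must be at or inside the scalp radius")
    f = np.empty((ele.shape[0], dip.shape[0]))
    coeff_cache: dict[float, np.ndarray] = {}
    for j in range(dip.shape[0]):
        rz = float(r_dip[j])
        key = round(rz, 9)
        if key not in coeff_cache:
            coeff_cache[key] = _shell_coefficients(head, rz, n_terms)
        cos_theta = (ele @ dip[j]) / np.maximum(r_ele * rz, 1e-300)
        cos_theta = np.clip(cos_theta, -1.0, 1.0)
        f[:, j] = _series_eval(head, coeff_cache[key], rz, 1.0, r_ele, cos_theta, n_terms)
    return LeadField(f=f, electrodes=ele, dipoles=dip)


def minnorm_inverse(lead: LeadField | np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm solution X = F^T (F F^T)^-1 Y of the underdetermined system.

    ``y`` may be a vector (n_r,) or matrix (n_r, T).  If F F^T is
    rank-deficient a small ridge is added (with a warning).
    """
    f = lead.f if isinstance(lead, LeadField) else np.asarray(lead, dtype=float)
    y = np.asarray(y, dtype=float)
    gram = f @ f.T
    try:
        cond = np.linalg.cond(gram)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-10 * max(float(np.trace(gram)) / gram.shape[0], 1e-300)
        warnings.warn(
            f"F F^T is rank deficient (cond={cond:.3g}); adding ridge {ridge:.3g}",
            stacklevel=2,
        )
        gram = gram + ridge * np.eye(gram.shape[0])
    return f.T @ np.linalg.solve(gram, y)


def two_step_map(lead_in: LeadField, lead_out: LeadField, y_in: np.ndarray) -> np.ndarray:
    """Cross-modality mapping: invert to dipole moments, re-project to the other set.

    Requires both lead fields to share the dipole grid; applied per time
    sample (``y_in`` is (n_in,) or (n_in, T)).
    """
    if lead_in.f.shape[1] != lead_out.f.shape[1]:
        raise ValidationError("lead fields must share the dipole grid")
    return lead_out.f @ minnorm_inverse(lead_in, y_in)


def _fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniformly spaced unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def default_dipole_grid(
    head: SphereHeadParams | None = None,
    shell_fractions: tuple[float, ...] = (0.4, 0.55, 0.7, 0.85),
    n_directions: int = 900,
) -> np.ndarray:
    """Radial-dipole grid: concentric shells x Fibonacci directions (default 3600)."""
    head = head or SphereHeadParams()
    r1 = head.radii_mm[0]
    dirs = _fibonacci_directions(n_directions)
    return np.vstack([frac * r1 * dirs for frac in shell_fractions])


def default_electrode_geometry(
    n_fine: int, n_coarse: int, head: SphereHeadParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic electrode placement mirroring depth vs skull-screw recordings.

    Fine electrodes sit inside the brain layer at 0.9 r1 (above the dipole
    grid); coarse electrodes sit at the skull radius r3.
    """
    head = head or SphereHeadParams()
    fine = 0.9 * head.radii_mm[0] * _fibonacci_directions(n_fine)
    coarse = head.radii_mm[2] * _fibonacci_directions(n_coarse)
    return fine, coarse


def sphere_map_session(
    inputs: np.ndarray,
    direction: str = "forward",
    head: SphereHeadParams | None = None,
    dipole_grid: np.ndarray | None = None,
    n_terms: int = 200,
    n_fine: int | None = None,
    n_coarse: int | None = None,
) -> np.ndarray:
    """Two-step sphere mapping of an (n_trials, ch, T) array between modalities.

    ``forward`` maps fine (depth) -> coarse (skull); ``inverse`` the other
    way.  Uses the default synthetic electrode geometry.
    """
    inputs = np.asarray(inputs, dtype=float)
    head = head or SphereHeadParams()
    grid = dipole_grid if dipole_grid is not None else default_dipole_grid(head)
    if direction == "forward":
        nf = n_fine or inputs.shape[1]
        nc = n_coarse or max(1, nf // 2)
        fine, coarse = default_electrode_geometry(nf, nc, head)
        src, dst = fine, coarse
    elif direction == "inverse":
        nc = n_coarse or inputs.shape[1]
        nf = n_fine or 2 * nc
        fine, coarse = default_electrode_geometry(nf, nc, head)
        src, dst = coarse, fine
    else:
        raise ValidationError("direction must be 'forward' or 'inverse'")
    lead_src = build_lead_field(grid, src, head, n_terms)
    lead_dst = build_lead_field(grid, dst, head, n_terms)
    out = np.stack([two_step_map(lead_src, lead_dst, inputs[k]) for k in range(inputs.shape[0])])
    return out


# --------------------------------------------------------------------------
# GRU baseline
# --------------------------------------------------------------------------

_GRU_FIELDS = ("wz", "uz", "bz", "wr", "ur", "br", "wn", "un", "bn")


@dataclass(frozen=True)
class GRUArch:
    n_in: int
    n_out: int
    gru_units: tuple[int, int] = (64, 32)
    dense_units: tuple[int, int] = (32, 16)  # (32, 128) for the inverse direction
    dropout: float = 0.2
    l2: float = 1e-4

    @classmethod
    def for_direction(cls, n_in: int, n_out: int, direction: str) -> "GRUArch":
        dense = (32, 16) if direction == "forward" else (32, 128)
        return cls(n_in=n_in, n_out=n_out, dense_units=dense)


@dataclass
class GRUParams:
    arch: GRUArch
    layer1: dict = field(default_factory=dict)  # nine arrays per GRU layer
    layer2: dict = field(default_factory=dict)
    dense: dict = field(default_factory=dict)  # w1, c1, w2, c2, wo, co
    in_mean: np.ndarray | None = None
    in_std: np.ndarray | None = None
    out_mean: np.ndarray | None = None
    out_std: np.ndarray | None = None

    def _arrays(self) -> list[np.ndarray]:
        return (
            [self.layer1[k] for k in _GRU_FIELDS]
            + [self.layer2[k] for k in _GRU_FIELDS]
            + [self.dense[k] for k in ("w1", "c1", "w2", "c2", "wo", "co")]
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self._arrays()])

    def from_vector(self, vec: np.ndarray) -> None:
        offset = 0
        for a in self._arrays():
            a[...] = vec[offset : offset + a.size].reshape(a.shape)
            offset += a.size

    def copy(self) -> "GRUParams":
        return GRUParams(
            arch=self.arch,
            layer1={k: v.copy() for k, v in self.layer1.items()},
            layer2={k: v.copy() for k, v in self.layer2.items()},
            dense={k: v.copy() for k, v in self.dense.items()},
            in_mean=None if self.in_mean is None else self.in_mean.copy(),
            in_std=None if self.in_std is None else self.in_std.copy(),
            out_mean=None if self.out_mean is None else self.out_mean.copy(),
            out_std=None if self.out_std is None else self.out_std.copy(),
        )


def _gru_layer_init(rng: np.random.Generator, n_in: int, units: int) -> dict:
    def g(fi, fo, shape):
        lim = np.sqrt(6.0 / (fi + fo))
        return rng.uniform(-lim, lim, size=shape)

    return {
        "wz": g(n_in, units, (units, n_in)),
        "uz": g(units, units, (units, units)),
        "bz": np.zeros(units),
        "wr": g(n_in, units, (units, n_in)),
        "ur": g(units, units, (units, units)),
        "br": np.zeros(units),
        "wn": g(n_in, units, (units, n_in)),
        "un": g(units, units, (units, units)),
        "bn": np.zeros(units),
    }


def init_gru(arch: GRUArch, seed: int = 0) -> GRUParams:
    rng = np.random.default_rng(seed)
    g1, g2 = arch.gru_units
    d1, d2 = arch.dense_units

    def g(fi, fo, shape):
        lim = np.sqrt(6.0 / (fi + fo))
        return rng.uniform(-lim, lim, size=shape)

    return GRUParams(
        arch=arch,
        layer1=_gru_layer_init(rng, arch.n_in, g1),
        layer2=_gru_layer_init(rng, g1, g2),
        dense={
            "w1": g(g2, d1, (d1, g2)),
            "c1": np.zeros(d1),
            "w2": g(d1, d2, (d2, d1)),
            "c2": np.zeros(d2),
            "wo": g(d2, arch.n_out, (arch.n_out, d2)),
            "co": np.zeros(arch.n_out),
        },
    )


def _gru_forward(params: GRUParams, u: np.ndarray, mask1=None, mask2=None):
    l1, l2, dn = params.layer1, params.layer2, params.dense
    u = np.ascontiguousarray(u)
    h1, *c1 = K.gru_layer_forward(*[l1[k] for k in _GRU_FIELDS], u)
    h1d = h1 if mask1 is None else h1 * mask1
    h2, *c2 = K.gru_layer_forward(*[l2[k] for k in _GRU_FIELDS], np.ascontiguousarray(h1d))
    h2d = h2 if mask2 is None else h2 * mask2
    y, a1, a2 = K.dense_forward(
        dn["w1"], dn["c1"], dn["w2"], dn["c2"], dn["wo"], dn["co"], np.ascontiguousarray(h2d)
    )
    return y, (u, h1, h1d, c1, h2, h2d, c2, a1, a2)


class _GRUModel:
    def __init__(self, params: GRUParams):
        self.params = params
        self.burnin = 0  # samples excluded from the loss (windowed training)

    def loss(self, u: np.ndarray, y_target: np.ndarray) -> float:
        y, _ = _gru_forward(self.params, u)
        return float(np.mean((y - y_target) ** 2))

    def loss_and_grad(self, u, y_target, rng):
        p = self.params
        drop = p.arch.dropout
        g1, g2 = p.arch.gru_units
        if drop > 0:
            # variational (per-sequence) inverted dropout on the layer outputs
            mask1 = (rng.random((g1, 1)) >= drop) / (1.0 - drop)
            mask2 = (rng.random((g2, 1)) >= drop) / (1.0 - drop)
        else:
            mask1 = mask2 = None
        y, cache = _gru_forward(p, u, mask1, mask2)
        u_c, h1, h1d, c1, h2, h2d, c2, a1, a2 = cache
        err = y - y_target
        if self.burnin > 0:
            err[:, : self.burnin] = 0.0
        n_counted = err.shape[0] * (err.shape[1] - self.burnin)
        loss = float(np.sum(err**2) / n_counted)
        dy = (2.0 / n_counted) * err
        dn = p.dense
        dh2d, gw1, gc1, gw2, gc2, gwo, gco = K.dense_backward(
            dn["w1"], dn["c1"], dn["w2"], dn["c2"], dn["wo"], dn["co"],
            np.ascontiguousarray(h2d), a1, a2, dy,
        )
        dh2 = dh2d if mask2 is None else dh2d * mask2
        l2p = p.layer2
        dh1d, *gl2 = K.gru_layer_backward(
            *[l2p[k] for k in _GRU_FIELDS], np.ascontiguousarray(h1d), h2, *c2,
            np.ascontiguousarray(dh2),
        )
        dh1 = dh1d if mask1 is None else dh1d * mask1
        l1p = p.layer1
        _, *gl1 = K.gru_layer_backward(
            *[l1p[k] for k in _GRU_FIELDS], u_c, h1, *c1, np.ascontiguousarray(dh1)
        )
        grads = list(gl1) + list(gl2) + [gw1, gc1, gw2, gc2, gwo, gco]
        # L2 weight decay on weight matrices (biases exempt), added to the loss gradient
        lam = p.arch.l2
        if lam > 0:
            arrays = self.params._arrays()
            for i, (a, g) in enumerate(zip(arrays, grads)):
                if a.ndim == 2:
                    grads[i] = g + 2.0 * lam * a
        return loss, np.concatenate([g.ravel() for g in grads])

    def get_vector(self) -> np.ndarray:
        return self.params.to_vector()

    def set_vector(self, vec: np.ndarray) -> None:
        self.params.from_vector(vec)


def predict_gru(params: GRUParams, u: np.ndarray) -> np.ndarray:
    """Evaluate the GRU on one (n_in, T) trial in physical units (no dropout)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if params.in_mean is not None:
        u = (u - params.in_mean[:, None]) / params.in_std[:, None]
    y, _ = _gru_forward(params, u)
    if params.out_mean is not None:
        y = y * params.out_std[:, None] + params.out_mean[:, None]
    return y


def predict_gru_session(params: GRUParams, inputs: np.ndarray) -> np.ndarray:
    inputs = np.asarray(inputs, dtype=float)
    return np.stack([predict_gru(params, inputs[k]) for k in range(inputs.shape[0])])


def train_gru_baseline(
    session: RecordingSession,
    direction: str = "forward",
    cfg: TrainConfig | None = None,
    arch: GRUArch | None = None,
) -> tuple[GRUParams, TrainHistory]:
    """Train the GRU under the same contract as the bond-graph network."""
    cfg = cfg or TrainConfig()
    if direction == "forward":
        u_all, y_all = session.fine, session.coarse
    elif direction == "inverse":
        u_all, y_all = session.coarse, session.fine
    else:
        raise ValidationError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    arch = arch or GRUArch.for_direction(u_all.shape[1], y_all.shape[1], direction)
    params = init_gru(arch, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(u_all.shape[0])
    n_val = max(1, int(round(cfg.val_fraction * u_all.shape[0])))
    train_idx = perm[n_val:]
    in_mean, in_std = normalization_stats(u_all, train_idx)
    out_mean, out_std = normalization_stats(y_all, train_idx)
    u_norm = (u_all - in_mean[None, :, None]) / in_std[None, :, None]
    y_norm = (y_all - out_mean[None, :, None]) / out_std[None, :, None]
    history = fit_recurrent(_GRUModel(params), u_norm, y_norm, cfg)
    params.in_mean, params.in_std = in_mean, in_std
    params.out_mean, params.out_std = out_mean, out_std
    return params, history
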