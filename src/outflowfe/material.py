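"""Single-term shear-relaxation constitutive model.

The shear relaxation modulus is

    G(t) = Ginf + (G0 - Ginf) * exp(-beta * t)

and the deviatoric stress follows the hereditary integral of the deviatoric
strain rate under an incrementally objective (Jaumann) rotation.  The bulk
response is elastic, with the bulk modulus derived from ``G0`` and a
volumetric Poisson ratio (``nu_vol``); this closure mirrors the common
explicit-solver viscoelastic material (elastic bulk + relaxing shear).

Symmetric tensors are stored in 6-component Voigt order
``[xx, yy, zz, xy, yz, zx]``.  Stress-like quantities carry tensor shear
components; strain increments passed to :func:`update_stress` are full 3x3
tensors (tensor shear, not engineering shear).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ViscoelasticParams",
    "StressState",
    "relaxation_modulus",
    "jaumann_rotate",
    "update_stress",
    "voigt_to_tensor",
    "tensor_to_voigt",
    "stress_update_coefficients",
]

VOIGT_IJ = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0))


@dataclass(frozen=True)
class ViscoelasticParams:
    """Parameter triple (G0, Ginf, beta) plus the volumetric closure.

    Moduli are in MPa, ``beta`` in 1/s, ``nu_vol`` dimensionless.
    """

    g0: float
    ginf: float
    beta: float
    nu_vol: float = 0.495

    def __post_init__(self):
        if not (self.ginf > 0.0):
            raise ValueError(f"Ginf must be positive, got {self.ginf}")
        if self.g0 < self.ginf:
            raise ValueError(
                f"G0 must be >= Ginf, got G0={self.g0}, Ginf={self.ginf}"
            )
        if not (self.beta > 0.0):
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (0.0 <= self.nu_vol < 0.5):
            raise ValueError(f"nu_vol must lie in [0, 0.5), got {self.nu_vol}")

    @classmethod
    def elastic(cls, g: float, nu: float = 0.495, beta: float = 1.0) -> "ViscoelasticParams":
        """Degenerate (rate-independent) parameter set with G0 = Ginf = g."""
        return cls(g0=g, ginf=g, beta=beta, nu_vol=nu)

    @classmethod
    def from_youngs(cls, e: float, nu: float = 0.495, beta: float = 1.0) -> "ViscoelasticParams":
        g = e / (2.0 * (1.0 + nu))
        return cls.elastic(g, nu=nu, beta=beta)

    @property
    def bulk_modulus(self) -> float:
        """K = 2 G0 (1 + nu) / (3 (1 - 2 nu))."""
        return 2.0 * self.g0 * (1.0 + self.nu_vol) / (3.0 * (1.0 - 2.0 * self.nu_vol))

    @property
    def youngs_instantaneous(self) -> float:
        """E = 2 G0 (1 + nu) — the short-time uniaxial modulus."""
        return 2.0 * self.g0 * (1.0 + self.nu_vol)

    def relaxation_modulus(self, t) -> float:
        return relaxation_modulus(self, t)


@dataclass
class StressState:
    """Stress plus deviatoric memory variable at one material point."""

    sigma: np.ndarray = field(default_factory=lambda: np.zeros(6))
    h: np.ndarray = field(default_factory=lambda: np.zeros(6))
    t: float = 0.0

    def copy(self) -> "StressState":
        return StressState(self.sigma.copy(), self.h.copy(), self.t)


def relaxation_modulus(params: ViscoelasticParams, t):
    """Evaluate G(t) = Ginf + (G0 - Ginf) exp(-beta t) for t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("relaxation modulus requires t >= 0")
    out = params.ginf + (params.g0 - params.ginf) * np.exp(-params.beta * t)
    return float(out) if out.ndim == 0 else out


def voigt_to_tensor(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return np.array(
        [
            [v[0], v[3], v[5]],
            [v[3], v[1], v[4]],
            [v[5], v[4], v[2]],
        ]
    )


def tensor_to_voigt(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return np.array([a[0, 0], a[1, 1], a[2, 2], a[0, 1], a[1, 2], a[2, 0]])


def _deviatoric(a: np.ndarray) -> np.ndarray:
    return a - np.trace(a) / 3.0 * np.eye(3)


def jaumann_rotate(sigma, d_omega, tol: float = 1.0e-8) -> np.ndarray:
    """Incremental Jaumann rotation of a Voigt stress by a spin increment.

    ``d_omega`` is the 3x3 skew-symmetric incremental spin tensor.  The
    update adds the commutator ``W s - s W`` to the stress, which matches the
    exact rotation ``R s R^T`` to second order in the spin magnitude.  The
    sign convention is fixed by that oracle (a positive spin about z rotates
    a uniaxial x-stress toward xy shear).
    """
    w = np.asarray(d_omega, dtype=float)
    if w.shape != (3, 3):
        raise ValueError("spin increment must be a 3x3 tensor")
    sym = 0.5 * (w + w.T)
    scale = max(1.0, float(np.abs(w).max()))
    if np.abs(sym).max() > tol * scale:
        raise ValueError("spin increment is not skew-symmetric")
    s = voigt_to_tensor(sigma)
    s_new = s + w @ s - s @ w
    return tensor_to_voigt(0.5 * (s_new + s_new.T))


def _rotate_orthogonal(v6, d_omega):
    """Rotate a Voigt tensor by the orthogonal (Cayley) operator of the spin.

    Agrees with the linearized Jaumann update to second order but is exactly
    orthogonal, so stress invariants are conserved to round-off under pure
    spin sequences.
    """
    w = np.asarray(d_omega, dtype=float)
    th = np.array([w[2, 1], w[0, 2], w[1, 0]])
    s = np.array(
        [
            [0.0, -th[2], th[1]],
            [th[2], 0.0, -th[0]],
            [-th[1], th[0], 0.0],
        ]
    )
    r = np.eye(3) + (s + 0.5 * (s @ s)) / (1.0 + 0.25 * float(th @ th))
    return tensor_to_voigt(r @ voigt_to_tensor(v6) @ r.T)


def stress_update_coefficients(params: ViscoelasticParams, dt: float):
    """Coefficients of the exponential-integrator stress recursion.

    Returns ``(decay, ramp, g_eff, k)`` where ``decay = exp(-beta dt)``,
    ``ramp = (1 - decay)/(beta dt)`` (exact for piecewise-constant strain
    rate), ``g_eff = Ginf + (G0 - Ginf) ramp`` is the per-step effective
    shear modulus and ``k`` the elastic bulk modulus.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    x = params.beta * dt
    decay = math.exp(-x)
    if x < 1.0e-8:
        ramp = 1.0 - 0.5 * x
    else:
        ramp = (1.0 - decay) / x
    g_eff = params.ginf + (params.g0 - params.ginf) * ramp
    return decay, ramp, g_eff, params.bulk_modulus


def update_stress(
    state: StressState,
    d_eps,
    d_omega,
    dt: float,
    params: ViscoelasticParams,
) -> StressState:
    """Advance one material point by a strain/spin increment over ``dt``.

    Steps: (1) rotate ``sigma`` and the memory variable ``h`` by the spin
    increment, (2) split the strain increment into deviatoric and volumetric
    parts, (3) update ``h`` by the exponential recursion and add the
    equilibrium deviatoric increment ``2 Ginf dE'``, (4) add the elastic
    volumetric increment ``K tr(dE) I``.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    d_eps = np.asarray(d_eps, dtype=float)
    if d_eps.shape == (6,):
        d_eps = voigt_to_tensor(d_eps)
    if d_omega is None:
        d_omega = np.zeros((3, 3))

    sym = 0.5 * (np.asarray(d_omega) + np.asarray(d_omega).T)
    if np.abs(sym).max() > 1e-8 * max(1.0, float(np.abs(d_omega).max())):
        raise ValueError("spin increment is not skew-symmetric")
    sigma = _rotate_orthogonal(state.sigma, d_omega)
    h = _rotate_orthogonal(state.h, d_omega)

    decay, ramp, _, k = stress_update_coefficients(params, dt)
    de_dev = tensor_to_voigt(_deviatoric(d_eps))
    tr = float(np.trace(d_eps))

    h_new = decay * h + (params.g0 - params.ginf) * ramp * 2.0 * de_dev
    sigma_new = sigma + 2.0 * params.ginf * de_dev + (h_new - h)
    sigma_new[:3] += k * tr

    return StressState(sigma=sigma_new, h=h_new, t=state.t + dt)
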