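"""Jeffery-orbit rotation dynamics for oblate bodies in simple shear.

A rigid oblate spheroid (semi-axes a > b, aspect ratio ``e = a/b``)
suspended in steady viscous shear flow tumbles in the flow-gradient plane.
Its in-plane rotation angle phi, measured against dimensionless time
``gamma_t`` (physical time times the shear rate), obeys the classical
Jeffery angular-speed equation

    dphi/d(gamma_t) = 1/2 (Lambda cos 2phi + 1),

where ``Lambda = (e^2 - 1)/(e^2 + 1)`` measures the departure from a
sphere.  Two empirical corrections are provided on top of it:

* the inertial two-harmonic correction (``+ beta1 sin 2phi +
  beta2 sin 4phi``), accounting for weak fluid/particle inertia; and
* the learned three-parameter correction

      dphi/dt = 1/2 (Lambda cos 2phi + 1 + kappa0) (1 + lambda0 +
                lambda1 sin 2phi),

  whose parameters capture fluid-object coupling (kappa0) and coarse- and
  fine-grained deviations from a perfect oblate (lambda0, lambda1).  At
  ``kappa0 = lambda0 = lambda1 = 0`` it reduces exactly to the classical
  equation, and at ``kappa0 = lambda0 = 0`` it contains the inertial
  correction via ``beta1 = lambda1/2``, ``beta2 = lambda1 Lambda/4``.

The module also provides the exact closed-form angle solution of the
classical equation, a fixed-step RK4 trajectory integrator, and the
quadrature flip period (time for phi to advance by pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.integrate import quad

__all__ = [
    "OblateGeometry",
    "EquationParams",
    "RotationState",
    "FlowCondition",
    "InvalidGeometryError",
    "DegenerateOrbitError",
    "shape_constant",
    "joe_speed",
    "mjoe_speed",
    "ljoe_speed",
    "ljoe_speed_expanded",
    "ljoe_param_gradients",
    "closed_form_angle",
    "integrate_orbit",
    "flip_period",
    "PLATELET",
]


class InvalidGeometryError(ValueError):
    """Raised for geometries that cannot describe an oblate spheroid."""


class DegenerateOrbitError(ValueError):
    """Raised when the angular speed is not strictly positive, so the
    body would cease tumbling and no flip period exists."""


class ConfigurationError(ValueError):
    """Raised for invalid numerical configuration (steps, durations...)."""


@dataclass(frozen=True)
class OblateGeometry:
    """Oblate spheroid geometry.

    Parameters
    ----------
    semi_major : float
        Semi-major axis a in micrometres.
    semi_minor : float
        Semi-minor axis b in micrometres.
    """

    semi_major: float = 2.0
    semi_minor: float = 0.5

    def __post_init__(self):
        if not (self.semi_major > 0 and self.semi_minor > 0):
            raise InvalidGeometryError(
                f"semi-axes must be positive, got a={self.semi_major}, "
                f"b={self.semi_minor}"
            )

    @property
    def aspect_ratio(self) -> float:
        """e = a/b (dimensionless)."""
        return self.semi_major / self.semi_minor

    @property
    def shape_constant(self) -> float:
        """Lambda = (e^2 - 1)/(e^2 + 1)."""
        return shape_constant(self)

    @classmethod
    def from_aspect_ratio(cls, e: float) -> "OblateGeometry":
        if not e > 0:
            raise InvalidGeometryError(f"aspect ratio must be positive, got {e}")
        return cls(semi_major=e, semi_minor=1.0)


#: Default quiescent-platelet geometry: 2 um semi-major, 0.5 um semi-minor.
PLATELET = OblateGeometry(semi_major=2.0, semi_minor=0.5)


@dataclass(frozen=True)
class EquationParams:
    """Dimensionless correction parameters of the learned equation.

    ``kappa0`` couples the body to the surrounding fluid, ``lambda0`` and
    ``lambda1`` absorb coarse- and fine-grained deviations from a perfect
    oblate, and ``phase_offset`` (phi0, radians) rectifies a constant
    misalignment of the measured rotation angle.  ``beta1``/``beta2`` are
    the two-harmonic inertial-correction coefficients; they are only used
    by :func:`mjoe_speed`.

    All-zero parameters reproduce the classical Jeffery equation exactly.
    """

    kappa0: float = 0.0
    lambda0: float = 0.0
    lambda1: float = 0.0
    phase_offset: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.kappa0, self.lambda0, self.lambda1, self.phase_offset]
        )

    def mjoe_equivalent(self) -> "EquationParams":
        """The contained inertial-correction parameterization:
        beta1 = lambda1/2, beta2 = lambda1*Lambda/4 requires the geometry,
        so this returns betas for a given lambda1 lazily via
        :func:`mjoe_betas_from_lambda1` instead.  Kept for symmetry."""
        raise NotImplementedError("use mjoe_betas_from_lambda1(lambda1, geometry)")


def mjoe_betas_from_lambda1(lambda1: float, geometry: OblateGeometry) -> EquationParams:
    """Inertial-correction parameters contained in the learned equation at
    kappa0 = lambda0 = 0: beta1 = lambda1/2, beta2 = lambda1*Lambda/4."""
    lam = shape_constant(geometry)
    return EquationParams(beta1=lambda1 / 2.0, beta2=lambda1 * lam / 4.0)


@dataclass(frozen=True)
class RotationState:
    """One sample of the tumbling motion: dimensionless time ``gamma_t``,
    rotation angle ``phi`` (radians) and angular speed dphi/d(gamma_t)."""

    time: float
    angle: float
    angular_speed: float


@dataclass(frozen=True)
class FlowCondition:
    """Flow shear stress (dyne/cm^2) and body-rigidity regime label."""

    shear_stress: float = 100.0
    label: str = "rigid"

    #: shear stresses exercised in the reference study
    PRESETS = (50.0, 100.0, 200.0, 300.0)

    def __post_init__(self):
        if self.shear_stress <= 0:
            raise ConfigurationError(
                f"shear stress must be positive, got {self.shear_stress}"
            )
        if self.label not in ("rigid", "deformable"):
            raise ConfigurationError(
                f"body regime must be 'rigid' or 'deformable', got {self.label!r}"
            )


# ---------------------------------------------------------------------------
# speed equations
# ---------------------------------------------------------------------------

def shape_constant(geometry: OblateGeometry) -> float:
    """Lambda = (e^2 - 1)/(e^2 + 1) = (a^2 - b^2)/(a^2 + b^2).

    Zero for a sphere; approaches 1 monotonically as e grows.
    """
    e = geometry.aspect_ratio
    if not e > 0:
        raise InvalidGeometryError(f"aspect ratio must be positive, got {e}")
    return (e * e - 1.0) / (e * e + 1.0)


def joe_speed(angle, geometry: OblateGeometry):
    """Classical Jeffery angular speed 1/2 (Lambda cos 2phi + 1).

    Strictly positive for 0 <= Lambda < 1 and pi-periodic in phi.
    Accepts scalars or arrays.
    """
    lam = shape_constant(geometry)
    angle = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(angle)):
        raise ValueError("angle must be finite")
    return 0.5 * (lam * np.cos(2.0 * angle) + 1.0)


def mjoe_speed(angle, geometry: OblateGeometry, params: EquationParams):
    """Inertia-corrected speed: Jeffery + beta1 sin 2phi + beta2 sin 4phi."""
    angle = np.asarray(angle, dtype=float)
    return (
        joe_speed(angle, geometry)
        + params.beta1 * np.sin(2.0 * angle)
        + params.beta2 * np.sin(4.0 * angle)
    )


def ljoe_speed(angle, geometry: OblateGeometry, params: EquationParams):
    """Learned angular speed (factored form).

    ``1/2 (Lambda cos 2psi + 1 + kappa0)(1 + lambda0 + lambda1 sin 2psi)``
    with ``psi = phi - phi0`` when a phase offset is set.
    """
    lam = shape_constant(geometry)
    psi = np.asarray(angle, dtype=float) - params.phase_offset
    if not np.all(np.isfinite(psi)):
        raise ValueError("angle must be finite")
    a = 0.5 * (lam * np.cos(2.0 * psi) + 1.0 + params.kappa0)
    b = 1.0 + params.lambda0 + params.lambda1 * np.sin(2.0 * psi)
    return a * b


def ljoe_speed_expanded(angle, geometry: OblateGeometry, params: EquationParams):
    """Learned speed in the expanded five-term form (algebraically equal to
    the factored form; kept for identity checks and inspection)::

        1/2 (Lambda cos 2psi + 1)
        + 1/2 lambda1 (1 + kappa0) sin 2psi
        + 1/2 lambda0 Lambda cos 2psi
        + 1/4 lambda1 Lambda sin 4psi
        + 1/2 (lambda0 + kappa0 + lambda0 kappa0)
    """
    lam = shape_constant(geometry)
    psi = np.asarray(angle, dtype=float) - params.phase_offset
    k0, l0, l1 = params.kappa0, params.lambda0, params.lambda1
    return (
        0.5 * (lam * np.cos(2.0 * psi) + 1.0)
        + 0.5 * l1 * (1.0 + k0) * np.sin(2.0 * psi)
        + 0.5 * l0 * lam * np.cos(2.0 * psi)
        + 0.25 * l1 * lam * np.sin(4.0 * psi)
        + 0.5 * (l0 + k0 + l0 * k0)
    )


def ljoe_param_gradients(angle, geometry: OblateGeometry, params: EquationParams):
    """Analytic partial derivatives of the learned speed.

    Returns ``(d/dkappa0, d/dlambda0, d/dlambda1, d/dphi0)``, each shaped
    like ``angle``.  Used for gradient-based parameter estimation.
    """
    lam = shape_constant(geometry)
    psi = np.asarray(angle, dtype=float) - params.phase_offset
    c2, s2 = np.cos(2.0 * psi), np.sin(2.0 * psi)
    a = 0.5 * (lam * c2 + 1.0 + params.kappa0)
    b = 1.0 + params.lambda0 + params.lambda1 * s2
    d_kappa0 = 0.5 * b
    d_lambda0 = a
    d_lambda1 = a * s2
    # d/dphi0 = -d/dpsi (A B)
    d_phi0 = lam * s2 * b - 2.0 * a * params.lambda1 * c2
    return d_kappa0, d_lambda0, d_lambda1, d_phi0


# ---------------------------------------------------------------------------
# closed form, integration, period
# ---------------------------------------------------------------------------

def closed_form_angle(time, geometry: OblateGeometry):
    """Exact, branch-continued solution of the classical speed equation
    with phi(0) = 0:  tan(phi) = e tan(e gamma_t / (e^2 + 1)).

    The arctangent branch is continued cumulatively so the returned angle
    is continuous and strictly increasing (not folded to [-pi/2, pi/2)).
    """
    e = geometry.aspect_ratio
    t = np.asarray(time, dtype=float)
    omega = e / (e * e + 1.0)
    x = omega * t
    # each half-turn of x advances phi by pi
    n = np.floor((x + np.pi / 2.0) / np.pi)
    phi = np.arctan(e * np.tan(x - n * np.pi)) + n * np.pi
    return phi if phi.shape else float(phi)


def _instantaneous_params(params, t: float) -> EquationParams:
    """Resolve possibly time-dependent parameters at time t."""
    if callable(params):
        return params(t)
    return params


def integrate_orbit(
    params: EquationParams,
    geometry: OblateGeometry,
    initial_angle: float = 0.0,
    t_end: float = 30.0,
    step: float = 1e-3,
) -> list[RotationState]:
    """Integrate the learned-equation ODE with classical fixed-step RK4.

    ``params`` may be a callable ``t -> EquationParams`` for drifting
    parameters; it is then held constant within each step (evaluated at
    the step start).  Returns the trajectory on the uniform grid
    ``0, step, ..., ~t_end``; the first state is the initial condition.
    """
    if step <= 0 or t_end <= 0:
        raise ConfigurationError(
            f"step and duration must be positive, got step={step}, t_end={t_end}"
        )
    n_steps = int(round(t_end / step))
    times = np.arange(n_steps + 1) * step
    angles = np.empty(n_steps + 1)
    angles[0] = initial_angle
    phi = float(initial_angle)
    for i in range(n_steps):
        t = times[i]
        p = _instantaneous_params(params, t)
        f = lambda a: float(ljoe_speed(a, geometry, p))  # noqa: E731
        k1 = f(phi)
        k2 = f(phi + 0.5 * step * k1)
        k3 = f(phi + 0.5 * step * k2)
        k4 = f(phi + step * k3)
        phi = phi + (step / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        angles[i + 1] = phi
    param_at = [_instantaneous_params(params, t) for t in times] if callable(params) \
        else [params] * (n_steps + 1)
    speeds = np.array(
        [float(ljoe_speed(a, geometry, p)) for a, p in zip(angles, param_at)]
    )
    return [
        RotationState(time=float(t), angle=float(a), angular_speed=float(s))
        for t, a, s in zip(times, angles, speeds)
    ]


def trajectory_arrays(trajectory: Iterable[RotationState]):
    """Convenience: (times, angles, speeds) arrays from a trajectory."""
    ts = np.array([s.time for s in trajectory])
    phis = np.array([s.angle for s in trajectory])
    dots = np.array([s.angular_speed for s in trajectory])
    return ts, phis, dots


def flip_period(params: EquationParams, geometry: OblateGeometry) -> float:
    """Dimensionless time for the angle to advance by pi.

    Computed as the quadrature ``T = int_0^pi dphi / phi_dot(phi)``.  The
    speed must be strictly positive over [0, pi); otherwise the body would
    stall and no period exists.
    """
    grid = np.linspace(0.0, np.pi, 721)
    speeds = ljoe_speed(grid + params.phase_offset, geometry, params)
    if np.min(speeds) <= 0.0:
        raise DegenerateOrbitError(
            "angular speed is not strictly positive over a half turn; "
            "the body would cease tumbling"
        )
    integrand = lambda phi: 1.0 / float(  # noqa: E731
        ljoe_speed(phi + params.phase_offset, geometry, params)
    )
    value, _ = quad(integrand, 0.0, np.pi, limit=200)
    return value


def jeffery_period(geometry: OblateGeometry) -> float:
    """Analytic classical flip period pi (e + 1/e)."""
    e = geometry.aspect_ratio
    return math.pi * (e + 1.0 / e)
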