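"""Synthetic ground-truth generator standing in for particle-based
multiscale simulations of a tumbling cell.

The generator integrates the learned-equation dynamics with (optionally)
slowly drifting parameters and then contaminates the clean trajectory the
way coarse-grained simulation output is contaminated:

* *surface quiver* — a deterministic high-frequency sinusoid on the angle,
  emulating the membrane quivering of a deformable body (period much
  shorter than the flip period; absent for rigid bodies);
* *measurement noise* — i.i.d. Gaussian noise on the angle; the measured
  angular speed is the analytic speed evaluated at the noisy angle plus
  independent Gaussian noise, so the downstream differentiation path stays
  independently testable.

Every series carries its own seeded generator; the same seed reproduces
the series bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .dynamics import (
    ConfigurationError,
    EquationParams,
    FlowCondition,
    OblateGeometry,
    PLATELET,
    integrate_orbit,
    ljoe_speed,
    trajectory_arrays,
)

__all__ = [
    "ScenarioSpec",
    "GroundTruthSeries",
    "generate_ground_truth",
    "stream",
    "default_rigid_scenario",
    "default_deformable_scenario",
]

#: Default learned-parameter values used by the deformable test scenario:
#: fluid-coupling around 0.5, coarse deviation around -0.4, a small
#: fine-grained correction.  These are generator fixtures for testing the
#: recovery pipeline, not measurements of real platelets.
DEFORMABLE_PARAMS = EquationParams(kappa0=0.5, lambda0=-0.4, lambda1=0.1)
RIGID_PARAMS = EquationParams(kappa0=0.5, lambda0=-0.1, lambda1=0.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic ground-truth experiment."""

    flow: FlowCondition = field(default_factory=FlowCondition)
    geometry: OblateGeometry = PLATELET
    true_params: EquationParams = field(default_factory=EquationParams)
    measurement_noise_sd: float = 0.0  # radians, on the angle
    quiver_amplitude: float = 0.0  # radians; deformable bodies only
    quiver_period: float = 0.2  # dimensionless time, << flip period
    drift_rate: EquationParams = field(default_factory=EquationParams)
    duration: float = 30.0  # dimensionless time
    sample_interval: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.sample_interval <= 0:
            raise ConfigurationError("sample_interval must be positive")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.quiver_period <= 0:
            raise ConfigurationError("quiver_period must be positive")
        if self.measurement_noise_sd < 0 or self.quiver_amplitude < 0:
            raise ConfigurationError("noise amplitudes must be non-negative")
        if self.flow.label == "rigid" and self.quiver_amplitude != 0.0:
            raise ConfigurationError(
                "rigid bodies do not quiver; set quiver_amplitude=0"
            )

    def params_at(self, t: float) -> EquationParams:
        """Instantaneous parameters true_params + drift_rate * t."""
        d = self.drift_rate
        p = self.true_params
        return EquationParams(
            kappa0=p.kappa0 + d.kappa0 * t,
            lambda0=p.lambda0 + d.lambda0 * t,
            lambda1=p.lambda1 + d.lambda1 * t,
            phase_offset=p.phase_offset + d.phase_offset * t,
        )


@dataclass(frozen=True)
class GroundTruthSeries:
    """Raw (noisy) samples plus the matching noise-free reference on the
    identical time grid."""

    samples: pd.DataFrame  # columns gamma_t, phi, phi_dot
    clean_reference: pd.DataFrame  # same columns, same grid
    scenario: ScenarioSpec

    def __len__(self) -> int:
        return len(self.samples)

    def metadata(self) -> dict:
        s = self.scenario
        return {
            "shear_stress_dyne_cm2": s.flow.shear_stress,
            "body_type": s.flow.label,
            "aspect_ratio": s.geometry.aspect_ratio,
            "seed": s.seed,
            "sample_interval": s.sample_interval,
        }


def default_rigid_scenario(**overrides) -> ScenarioSpec:
    base = dict(
        flow=FlowCondition(shear_stress=100.0, label="rigid"),
        true_params=RIGID_PARAMS,
        quiver_amplitude=0.0,
    )
    base.update(overrides)
    return ScenarioSpec(**base)


def default_deformable_scenario(**overrides) -> ScenarioSpec:
    base = dict(
        flow=FlowCondition(shear_stress=100.0, label="deformable"),
        true_params=DEFORMABLE_PARAMS,
        quiver_amplitude=0.02,
        measurement_noise_sd=0.01,
    )
    base.update(overrides)
    return ScenarioSpec(**base)


def generate_ground_truth(scenario: ScenarioSpec) -> GroundTruthSeries:
    """Generate one noisy streaming series with its clean reference.

    The clean reference is the RK4 integration of the (possibly drifting)
    true parameters sampled on the scenario grid; the raw series adds the
    quiver sinusoid (phase drawn once per series) and measurement noise to
    the angle, and reports the analytic speed at the noisy angle plus
    independent noise.
    """
    rng = np.random.default_rng(scenario.seed)
    has_drift = any(
        getattr(scenario.drift_rate, f) != 0.0
        for f in ("kappa0", "lambda0", "lambda1", "phase_offset")
    )
    params = scenario.params_at if has_drift else scenario.true_params
    traj = integrate_orbit(
        params,
        scenario.geometry,
        initial_angle=0.0,
        t_end=scenario.duration,
        step=scenario.sample_interval,
    )
    times, angles, speeds = trajectory_arrays(traj)
    clean = pd.DataFrame({"gamma_t": times, "phi": angles, "phi_dot": speeds})

    quiver_phase = rng.uniform(0.0, 2.0 * np.pi)
    quiver = scenario.quiver_amplitude * np.sin(
        2.0 * np.pi * times / scenario.quiver_period + quiver_phase
    )
    angle_noise = rng.normal(0.0, scenario.measurement_noise_sd, size=times.shape) \
        if scenario.measurement_noise_sd > 0 else np.zeros_like(times)
    noisy_phi = angles + quiver + angle_noise

    params_per_t = (
        [scenario.params_at(t) for t in times] if has_drift
        else [scenario.true_params] * len(times)
    )
    noisy_dot = np.array(
        [float(ljoe_speed(a, scenario.geometry, p))
         for a, p in zip(noisy_phi, params_per_t)]
    )
    if scenario.measurement_noise_sd > 0:
        noisy_dot = noisy_dot + rng.normal(
            0.0, scenario.measurement_noise_sd, size=times.shape
        )
    raw = pd.DataFrame({"gamma_t": times, "phi": noisy_phi, "phi_dot": noisy_dot})
    return GroundTruthSeries(samples=raw, clean_reference=clean, scenario=scenario)


def stream(series: GroundTruthSeries, chunk: int) -> Iterator[pd.DataFrame]:
    """Iterate over the raw samples in order, ``chunk`` rows at a time.

    Chunks never overlap, their concatenation is the full series, and the
    final chunk may be short.
    """
    if chunk < 1:
        raise ConfigurationError(f"chunk size must be >= 1, got {chunk}")
    frame = series.samples
    for start in range(0, len(frame), chunk):
        yield frame.iloc[start : start + chunk]
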