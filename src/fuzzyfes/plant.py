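"""Knee-extension-against-gravity plant.

The shank hangs at 0 degrees and is driven toward extension by quadriceps
torque recruited through surface stimulation.  Two stages:

* **activation**: a one-pole lag from stimulus pulse width (us) to active
  knee torque, ``dT_a/dt = (G * pw - T_a) / tau``, advanced with its exact
  exponential update;
* **shank dynamics**: a nonlinear second-order rotational balance
  ``J * dd(theta) = T_a - m*g*l*sin(theta) - B*d(theta) - K*(theta - theta_r)``
  integrated with fixed-step classical Runge-Kutta (RK4), with hard stops at
  0 and 90 degrees (velocity zeroed against the stop).

``K`` models the passive elastic moment of the knee with resting angle
``theta_r``; in spastic or contractured limbs this passive stiffness can
dominate the gravitational moment, and the shipped defaults live in that
regime (see docs/methods.md for the calibration).  Parameter values are
package defaults, not published constants.

Between controller samples the pulse width is held (zero-order hold) and
the two stages advance on a 1 ms inner step using Strang splitting
(half-activation / dynamics / half-activation), which keeps the coupling
error at second order so that halving the inner step moves a 5 s trajectory
by far less than 0.01 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Tuple

__all__ = [
    "PlantParams",
    "PlantState",
    "default_plant_params",
    "activation_step",
    "dynamics_step",
    "KneePlant",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class PlantParams:
    """Physical parameters of the activation stage and shank dynamics.

    Defaults are calibrated so that the shipped controller tables hold their
    three target angles; they are package constants, not measured data.
    """

    inertia: float = 1.2              # J, kg m^2 (effective, about the knee)
    gravity_moment: float = 0.9716    # m*g*l, N m
    damping: float = 4.6              # B, N m s / rad
    stiffness: float = 2.5789         # K, N m / rad (passive elastic moment)
    rest_angle_deg: float = 5.577     # resting angle of the elastic moment
    torque_gain: float = 0.01         # G, N m per us of pulse width
    activation_tau: float = 0.35      # tau, s (torque recruitment lag)

    def __post_init__(self) -> None:
        if self.inertia <= 0 or self.activation_tau <= 0:
            raise ValueError("inertia and activation_tau must be positive")
        if min(self.damping, self.stiffness, self.torque_gain) < 0:
            raise ValueError("damping, stiffness and torque gain must be >= 0")

    @property
    def rest_angle_rad(self) -> float:
        return self.rest_angle_deg * _DEG


def default_plant_params() -> PlantParams:
    return PlantParams()


@dataclass(frozen=True)
class PlantState:
    """Knee angle (deg, 0 = hanging), angular velocity (deg/s), torque (N m)."""

    angle_deg: float = 0.0
    velocity_deg_s: float = 0.0
    torque: float = 0.0


def activation_step(torque: float, pulse_width_us: float,
                    params: PlantParams, dt: float) -> float:
    """Exact one-pole update of the active torque over ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = params.torque_gain * pulse_width_us
    return target + (torque - target) * math.exp(-dt / params.activation_tau)


def _accel(theta: float, omega: float, torque: float, p: PlantParams) -> float:
    """Angular acceleration (rad/s^2) from the moment balance."""
    return (torque
            - p.gravity_moment * math.sin(theta)
            - p.damping * omega
            - p.stiffness * (theta - p.rest_angle_rad)) / p.inertia


def dynamics_step(state: PlantState, torque: float, params: PlantParams,
                  dt: float) -> PlantState:
    """One fixed-step RK4 advance of the shank dynamics with ``torque`` held.

    ``dt`` is the inner integration step and should stay at or below 1 ms.
    Hard stops clamp the angle to [0, 90] degrees and zero the velocity
    against the stop.  Non-finite states are rejected.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    th = state.angle_deg * _DEG
    om = state.velocity_deg_s * _DEG
    if not (math.isfinite(th) and math.isfinite(om) and math.isfinite(torque)):
        raise ValueError("non-finite plant state")

    k1t, k1o = om, _accel(th, om, torque, params)
    k2t = om + 0.5 * dt * k1o
    k2o = _accel(th + 0.5 * dt * k1t, k2t, torque, params)
    k3t = om + 0.5 * dt * k2o
    k3o = _accel(th + 0.5 * dt * k2t, k3t, torque, params)
    k4t = om + dt * k3o
    k4o = _accel(th + dt * k3t, k4t, torque, params)
    th += dt / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t)
    om += dt / 6.0 * (k1o + 2 * k2o + 2 * k3o + k4o)

    if th <= 0.0:
        th = 0.0
        om = max(om, 0.0)
    elif th >= math.pi / 2:
        th = math.pi / 2
        om = min(om, 0.0)
    return PlantState(angle_deg=th / _DEG, velocity_deg_s=om / _DEG,
                      torque=state.torque)


@dataclass
class KneePlant:
    """Stateful plant advancing activation and dynamics on an inner step."""

    params: PlantParams
    state: PlantState = PlantState()
    dt: float = 1e-3

    def step(self, pulse_width_us: float, duration: float,
             record: Optional[Callable[[float, PlantState], None]] = None,
             t0: float = 0.0) -> PlantState:
        """Advance ``duration`` seconds with the pulse width held constant.

        ``record(t, state)`` is invoked after every inner step.  Strang
        splitting: the activation lag advances half a step on either side of
        the RK4 dynamics advance.
        """
        n = max(1, round(duration / self.dt))
        h = duration / n
        torque = self.state.torque
        st = self.state
        for i in range(n):
            mid = activation_step(torque, pulse_width_us, self.params, h / 2)
            st = dynamics_step(st, mid, self.params, h)
            torque = activation_step(mid, pulse_width_us, self.params, h / 2)
            st = replace(st, torque=torque)
            if record is not None:
                record(t0 + (i + 1) * h, st)
        self.state = st
        return st

    def reset(self, state: PlantState = PlantState()) -> None:
        self.state = state
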