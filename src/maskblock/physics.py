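"""Closed-form ballistic kinematics of a droplet under gravity and Stokes drag.

A droplet of radius ``r`` ejected with speed ``v0`` at angle ``theta0`` from
the horizontal experiences gravity and a linear (Stokes) drag force
``-6*pi*eta*r*v``.  The motion then has a closed-form solution governed by the
relaxation time ``tau = 2*rho*r**2 / (9*eta)``: the horizontal velocity decays
exponentially, so the horizontal displacement is bounded by
``tau * v0 * cos(theta0)``, while the vertical velocity relaxes toward the
terminal settling speed ``v_T = tau * g``.

Everything here is strictly planar (x toward the screen, y vertical) and SI.
Scalar, user-facing wrappers operate on :class:`Droplet`; the vectorised
`*_arrays` helpers are the workhorses used by the Monte-Carlo simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FluidEnvironment",
    "Droplet",
    "StalledFlightError",
    "relaxation_time",
    "terminal_velocity",
    "max_horizontal_range",
    "trajectory_height",
    "flight_state_at",
    "droplet_volume",
]


class StalledFlightError(ValueError):
    """Raised when a droplet's drag-limited range ends before the requested x."""


@dataclass(frozen=True)
class FluidEnvironment:
    """Ambient constants for droplet flight.

    Defaults are dynamic viscosity of air at 30 C, density of water at 30 C
    and standard gravity.
    """

    air_viscosity: float = 18.73e-6  # Pa s
    liquid_density: float = 995.7  # kg/m^3
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        for name in ("air_viscosity", "liquid_density", "gravity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Droplet:
    """Kinematic state of a single droplet.

    Parameters
    ----------
    radius : float
        Droplet radius in metres, strictly positive.
    x, y : float
        Position in metres (x horizontal toward the screen, y vertical).
    speed : float
        Velocity magnitude in m/s, non-negative.
    angle : float
        Velocity direction in radians from the horizontal.
    """

    radius: float
    x: float = 0.0
    y: float = 0.0
    speed: float = 0.0
    angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be strictly positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")

    @property
    def volume(self) -> float:
        """Spherical volume (4/3) pi r^3 in m^3, always derived from radius."""
        return droplet_volume(self.radius)


def droplet_volume(radius):
    """Volume of a spherical droplet, (4/3) pi r^3.  Accepts arrays."""
    return (4.0 / 3.0) * np.pi * np.asarray(radius) ** 3 if np.ndim(radius) else (4.0 / 3.0) * math.pi * radius**3


def relaxation_time(radius, env: FluidEnvironment = FluidEnvironment()):
    """Stokes relaxation time tau = 2 rho r^2 / (9 eta), in seconds.

    The timescale over which a droplet of radius ``radius`` forgets its
    initial velocity and approaches terminal settling.  Accepts a scalar or
    array radius; scales quadratically with radius.
    """
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be strictly positive")
    tau = 2.0 * env.liquid_density * r**2 / (9.0 * env.air_viscosity)
    return float(tau) if np.ndim(radius) == 0 else tau


def terminal_velocity(radius, env: FluidEnvironment = FluidEnvironment()):
    """Terminal settling speed v_T = tau(r) g = 2 rho r^2 g / (9 eta), m/s."""
    return relaxation_time(radius, env) * env.gravity


def max_horizontal_range(droplet: Droplet, env: FluidEnvironment = FluidEnvironment()) -> float:
    """Supremum of horizontal displacement: tau * v0 * cos(theta0).

    Under Stokes drag the horizontal velocity decays as exp(-t/tau), so the
    horizontal coordinate approaches but never reaches x0 + tau v0 cos(theta0).
    Droplets whose range is shorter than the distance to a target plane stall
    (physically: they slow to settling speed and fall) before reaching it.
    """
    if math.cos(droplet.angle) <= 0 or abs(droplet.angle) >= math.pi / 2:
        raise ValueError("angle must satisfy |angle| < pi/2 (cos(angle) > 0)")
    tau = relaxation_time(droplet.radius, env)
    return tau * droplet.speed * math.cos(droplet.angle)


def trajectory_height(x: float, droplet: Droplet, env: FluidEnvironment = FluidEnvironment()) -> float:
    """Vertical position y(x) of the droplet when it crosses horizontal x.

    Implements the closed-form drag trajectory

        y(x) = y0 + (tan(theta0) + tau g / (v0 cos(theta0))) (x - x0)
                  + tau^2 g ln(1 - (x - x0) / (tau v0 cos(theta0)))

    valid for x0 <= x < x0 + max_horizontal_range (strict: the log argument
    must stay positive).

    Raises
    ------
    StalledFlightError
        If the droplet stalls (drag-limited range ends) before reaching x.
    ValueError
        If x < x0 or the droplet is not moving forward.
    """
    if droplet.speed <= 0:
        raise ValueError("droplet speed must be positive for a trajectory")
    dx = x - droplet.x
    if dx < 0:
        raise ValueError("x must be at or beyond the droplet's current position")
    xmax = max_horizontal_range(droplet, env)
    if dx >= xmax and dx > 0:
        raise StalledFlightError(
            f"droplet stalls {xmax:.6g} m after x0={droplet.x:.6g} m, before reaching x={x:.6g} m"
        )
    tau = relaxation_time(droplet.radius, env)
    g = env.gravity
    vcos = droplet.speed * math.cos(droplet.angle)
    s = dx / (tau * vcos)
    return droplet.y + (math.tan(droplet.angle) + tau * g / vcos) * dx + tau**2 * g * math.log1p(-s)


def flight_state_at(x: float, droplet: Droplet, env: FluidEnvironment = FluidEnvironment()) -> Droplet:
    """Droplet state (position and velocity) when it reaches horizontal x.

    The velocity components follow from the same drag solution: the
    horizontal component decays linearly in the fraction of range consumed,
    ``vx = v0 cos(theta0) (1 - s)`` with ``s = (x - x0)/(tau v0 cos(theta0))``,
    and the vertical component at the corresponding elapsed time
    ``t = -tau ln(1 - s)`` is ``vy = (v0 sin(theta0) + tau g)(1 - s) - tau g``.

    Chaining two flights (x0 -> x1 -> x2) agrees with one flight (x0 -> x2)
    to floating precision.  Preconditions and errors as
    :func:`trajectory_height`.
    """
    if x == droplet.x:
        return droplet
    y = trajectory_height(x, droplet, env)
    tau = relaxation_time(droplet.radius, env)
    g = env.gravity
    vcos = droplet.speed * math.cos(droplet.angle)
    s = (x - droplet.x) / (tau * vcos)
    vx = vcos * (1.0 - s)
    vy = (droplet.speed * math.sin(droplet.angle) + tau * g) * (1.0 - s) - tau * g
    return replace(droplet, x=x, y=y, speed=math.hypot(vx, vy), angle=math.atan2(vy, vx))


# ---------------------------------------------------------------------------
# Vectorised core used by the Monte-Carlo simulator.
# ---------------------------------------------------------------------------

def flight_arrays(radius, y0, speed, angle, dx, env: FluidEnvironment):
    """Vectorised flight over a horizontal distance ``dx``.

    Parameters are broadcastable arrays; ``speed`` must be positive where a
    result is wanted.  Returns ``(reached, y, vx, vy)``: a boolean mask of
    droplets whose drag-limited range strictly exceeds ``dx`` (the others are
    stalled, with NaN kinematics), and the vertical position and velocity
    components at arrival for those that do.
    """
    radius = np.asarray(radius, dtype=float)
    y0, speed, angle, dx = np.broadcast_arrays(
        np.asarray(y0, float), np.asarray(speed, float), np.asarray(angle, float), np.asarray(dx, float)
    )
    tau = 2.0 * env.liquid_density * radius**2 / (9.0 * env.air_viscosity)
    g = env.gravity
    vcos = speed * np.cos(angle)
    with np.errstate(divide="ignore", invalid="ignore"):
        xmax = tau * vcos
        reached = dx < xmax
        s = np.where(reached, dx / xmax, np.nan)
        y = y0 + (np.tan(angle) + tau * g / vcos) * dx + tau**2 * g * np.log1p(-s)
        vx = vcos * (1.0 - s)
        vy = (speed * np.sin(angle) + tau * g) * (1.0 - s) - tau * g
    return reached, y, vx, vy
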