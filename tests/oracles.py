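"""Independent numerical oracles used by the test suite.

The drag-flight oracle integrates the equations of motion

    m dv/dt = m g_vec - 6 pi eta r v_vec,      m = (4/3) pi r^3 rho,

directly with an adaptive Runge-Kutta integrator and never touches the
package's closed-form solution, so agreement between the two is a genuine
cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp


def integrate_flight(
    radius: float,
    speed: float,
    angle: float,
    x_target: float,
    air_viscosity: float = 18.73e-6,
    liquid_density: float = 995.7,
    gravity: float = 9.81,
    x0: float = 0.0,
    y0: float = 0.0,
):
    """State (y, vx, vy) when the droplet's horizontal coordinate reaches x_target.

    Integrates Newton's equations with Stokes drag from (x0, y0).  Raises if
    the droplet never reaches x_target within a generous time horizon.
    """
    mass = (4.0 / 3.0) * math.pi * radius**3 * liquid_density
    k = 6.0 * math.pi * air_viscosity * radius  # drag coefficient, N s/m

    def rhs(t, state):
        x, y, vx, vy = state
        return [vx, vy, -k * vx / mass, -gravity - k * vy / mass]

    def crossed(t, state):
        return state[0] - x_target

    crossed.terminal = True
    crossed.direction = 1

    v0 = [speed * math.cos(angle), speed * math.sin(angle)]
    tau = mass / k
    sol = solve_ivp(
        rhs,
        (0.0, 200.0 * tau + 10.0),
        [x0, y0, v0[0], v0[1]],
        events=crossed,
        rtol=1e-11,
        atol=1e-14,
        max_step=tau / 4.0,
    )
    if sol.t_events[0].size == 0:
        raise RuntimeError("droplet never reached the target plane in the ODE oracle")
    state = sol.y_events[0][0]
    return float(state[1]), float(state[2]), float(state[3])


def terminal_speed_from_rest(radius, air_viscosity=18.73e-6, liquid_density=995.7, gravity=9.81):
    """Asymptotic vertical settling speed of a droplet released from rest."""
    mass = (4.0 / 3.0) * math.pi * radius**3 * liquid_density
    k = 6.0 * math.pi * air_viscosity * radius
    tau = mass / k

    def rhs(t, state):
        return [-gravity - k * state[0] / mass]

    sol = solve_ivp(rhs, (0.0, 40.0 * tau), [0.0], rtol=1e-11, atol=1e-14)
    return -float(sol.y[0, -1])


def truncated_lognormal_mean(mean: float, sd: float, lower: float) -> float:
    """Mean of a moment-matched lognormal truncated below at ``lower``, by quadrature."""
    from scipy import integrate, stats

    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    dist = stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(math.log(mean) - sigma2 / 2.0))
    tail = 1.0 - dist.cdf(lower)
    num, _ = integrate.quad(lambda x: x * dist.pdf(x), lower, np.inf, limit=200)
    return num / tail
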