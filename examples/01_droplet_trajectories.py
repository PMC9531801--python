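"""Flight of single droplets under gravity and Stokes drag.

Computes, for a few droplet sizes launched horizontally at 3 m/s, the
relaxation time, terminal settling speed, and the maximum horizontal
distance drag allows — showing why only large droplets behave ballistically
over a 19 cm face-to-face distance.
"""

from maskblock import (
    Droplet,
    FluidEnvironment,
    StalledFlightError,
    max_horizontal_range,
    relaxation_time,
    terminal_velocity,
    trajectory_height,
)

env = FluidEnvironment()  # air at 30 C, water droplets
print(f"{'diameter':>10} {'tau [ms]':>10} {'v_T [m/s]':>10} {'range [cm]':>11} {'y at 19 cm':>11}")
for diameter_um in (7, 54, 100, 146, 300, 600):
    r = diameter_um * 1e-6 / 2
    d = Droplet(radius=r, y=0.10, speed=3.0, angle=0.0)
    tau = relaxation_time(r, env)
    try:
        y = f"{100 * trajectory_height(0.19, d, env):.1f} cm"
    except StalledFlightError:
        y = "stalls"
    print(
        f"{diameter_um:>7} um {1e3 * tau:>10.3f} {terminal_velocity(r, env):>10.4f}"
        f" {100 * max_horizontal_range(d, env):>11.2f} {y:>11}"
    )

print(
    "\nOnly droplets wider than ~150 um can cross the 19 cm gap before drag"
    "\nstops them; a 7 um droplet travels under a millimetre: it is an"
    "\naerosol, outside this ballistic model."
)
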