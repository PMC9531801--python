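"""Monte-Carlo blocking of a spray by a cloth at different positions.

Emits 100 000 droplets (mean diameter 54 um, launch 3 m/s, +-10 degrees),
places one cloth with tunneling probability p = 0.04 and deceleration
factor f = 0.56 at four planes between nozzle and screen, and reports the
Simulated Ballistic Blocking Capacity (SBBC) at each — the percentage of
droplet volume kept away from the centre of the receptor screen.
"""

from maskblock import Barrier, EmissionModel, ExperimentGeometry, expected_sbbc, sbbc, simulate_experiment

model = EmissionModel(seed=1)  # 100 000 droplets
geometry = ExperimentGeometry()  # nozzle -> screen distance 19 cm

free = simulate_experiment(model, geometry)
print("barrier-free run, droplet fates:", free.counts_by_fate())

print(f"\n{'cloth position':>16} {'SBBC (MC)':>10} {'SBBC (exact)':>13}")
for d_cm in (1.5, 6.8, 12.2, 17.5):
    barrier = Barrier(d_cm / 100, tunneling_probability=0.04, deceleration_factor=0.56)
    run = simulate_experiment(model, geometry, barrier)
    print(
        f"{d_cm:>13.1f} cm {sbbc(run, free):>9.2f}% {expected_sbbc(model, geometry, barrier):>12.2f}%"
    )

print(
    "\nSBBC falls as the cloth moves from the nozzle toward the screen:"
    "\nthe same cloth protects better as source control than as wearer"
    "\nprotection.  The exact column is the variance-free expected-volume"
    "\nestimator; the MC column applies per-droplet Bernoulli transmission."
)
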