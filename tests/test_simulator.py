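"""Monte-Carlo transport: sampling laws, barrier model, fates and SBBC."""

import math

import numpy as np
import pytest

from maskblock import (
    Barrier,
    Droplet,
    EmissionModel,
    ExperimentGeometry,
    FluidEnvironment,
    barrier_interaction,
    expected_sbbc,
    max_horizontal_range,
    sample_droplets,
    sbbc,
    simulate_experiment,
)
from maskblock.simulator import FATES, ImpactRecord, ImpactSet

from oracles import truncated_lognormal_mean


class TestSampling:
    def test_zero_count_gives_empty_list(self):
        assert sample_droplets(EmissionModel(count=0)) == []

    def test_same_seed_identical_samples(self):
        a = sample_droplets(EmissionModel(count=500, seed=7))
        b = sample_droplets(EmissionModel(count=500, seed=7))
        assert a == b

    def test_different_seed_differs(self):
        a = sample_droplets(EmissionModel(count=500, seed=7))
        b = sample_droplets(EmissionModel(count=500, seed=8))
        assert a != b

    def test_angles_within_bounds(self):
        drops = sample_droplets(EmissionModel(count=2000, seed=1))
        angles = np.array([d.angle for d in drops])
        assert angles.min() >= -math.radians(10.0)
        assert angles.max() <= math.radians(10.0)
        # uniform law: mean near centre, spread near the uniform SD
        assert abs(angles.mean()) < 3 * math.radians(20) / math.sqrt(12 * 2000)

    def test_truncated_lognormal_mean_matches_quadrature(self):
        model = EmissionModel(count=100_000, seed=3)
        drops = sample_droplets(model)
        diam_um = np.array([2 * d.radius * 1e6 for d in drops])
        assert diam_um.min() >= model.min_diameter_um
        target = truncated_lognormal_mean(54.0, 52.3, 7.0)
        se = diam_um.std(ddof=1) / math.sqrt(diam_um.size)
        assert abs(diam_um.mean() - target) < 3 * se

    def test_empirical_list_resampled(self):
        model = EmissionModel(count=300, seed=0, diameters_um=[20.0, 40.0, 80.0])
        drops = sample_droplets(model)
        assert {round(2 * d.radius * 1e6, 9) for d in drops} <= {20.0, 40.0, 80.0}

    def test_empty_empirical_list_rejected(self):
        with pytest.raises(ValueError):
            EmissionModel(diameters_um=[])

    def test_speed_and_origin(self):
        d = sample_droplets(EmissionModel(count=1, seed=0))[0]
        assert d.speed == 3.0 and (d.x, d.y) == (0.0, 0.0)


class TestBarrierInteraction:
    def test_opaque_barrier_always_blocks(self, rng):
        b = Barrier(0.1, tunneling_probability=0.0, deceleration_factor=0.5)
        d = Droplet(radius=50e-6, speed=3.0)
        assert all(barrier_interaction(d, b, rng) is None for _ in range(100))

    def test_transparent_barrier_is_identity(self, rng):
        b = Barrier(0.1, tunneling_probability=1.0, deceleration_factor=1.0)
        d = Droplet(radius=50e-6, x=0.1, y=0.08, speed=2.0, angle=-0.05)
        assert barrier_interaction(d, b, rng) == d

    def test_deceleration_scales_speed_only(self, rng):
        b = Barrier(0.1, tunneling_probability=1.0, deceleration_factor=0.56)
        d = Droplet(radius=50e-6, speed=2.0, angle=0.1)
        out = barrier_interaction(d, b, rng)
        assert out.speed == pytest.approx(2.0 * 0.56) and out.angle == d.angle and out.radius == d.radius

    def test_pass_fraction_matches_binomial(self, rng):
        b = Barrier(0.1, tunneling_probability=0.5, deceleration_factor=1.0)
        d = Droplet(radius=50e-6, speed=3.0)
        n = 20_000
        passed = sum(barrier_interaction(d, b, rng) is not None for _ in range(n))
        assert abs(passed / n - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Barrier(0.1, tunneling_probability=1.5, deceleration_factor=0.5)
        with pytest.raises(ValueError):
            Barrier(0.1, tunneling_probability=0.5, deceleration_factor=-0.1)


class TestSimulateExperiment:
    def test_opaque_barrier_leaves_no_impacts(self, small_emission, geometry):
        b = Barrier(0.175, 0.0, 0.5)
        res = simulate_experiment(small_emission, geometry, b)
        counts = res.counts_by_fate()
        assert counts["hit_roi"] == 0 and counts["hit_screen"] == 0

    def test_transparent_barrier_matches_free_run(self, small_emission, geometry):
        free = simulate_experiment(small_emission, geometry, None)
        transparent = simulate_experiment(small_emission, geometry, Barrier(0.1, 1.0, 1.0))
        assert (free.fate == transparent.fate).all()
        mask = np.isin(free.fate, ("hit_roi", "hit_screen"))
        np.testing.assert_allclose(transparent.y[mask], free.y[mask], rtol=0, atol=1e-10)

    def test_determinism(self, small_emission, geometry):
        b = Barrier(0.1, 0.3, 0.7)
        a = simulate_experiment(small_emission, geometry, b)
        c = simulate_experiment(small_emission, geometry, b)
        np.testing.assert_array_equal(a.radius, c.radius)
        np.testing.assert_array_equal(a.y, c.y)
        assert (a.fate == c.fate).all()

    def test_fates_partition_population(self, small_emission, geometry):
        res = simulate_experiment(small_emission, geometry, Barrier(0.1, 0.3, 0.7))
        counts = res.counts_by_fate()
        assert sum(counts.values()) == small_emission.count
        assert set(np.unique(res.fate)) <= set(FATES)

    def test_volume_conserved_across_fates(self, small_emission, geometry):
        res = simulate_experiment(small_emission, geometry, Barrier(0.1, 0.3, 0.7))
        total = sum(res.volume_by_fate().values())
        assert total == pytest.approx(res.volume.sum(), rel=1e-12)

    def test_stalled_iff_range_short_of_screen(self, geometry, env):
        # per-droplet closed-form oracle for the free configuration
        model = EmissionModel(count=5000, seed=9)
        res = simulate_experiment(model, geometry, None)
        for drop, fate in zip(sample_droplets(model), res.fate):
            short = max_horizontal_range(drop, env) <= geometry.screen_distance
            if short:
                assert fate == "stalled"
            else:
                assert fate != "stalled"

    def test_barrier_must_sit_before_screen(self, small_emission, geometry):
        with pytest.raises(ValueError):
            simulate_experiment(small_emission, geometry, Barrier(0.25, 0.5, 0.5))

    def test_two_barriers_block_more_than_one(self, geometry):
        model = EmissionModel(count=50_000, seed=5)
        free = simulate_experiment(model, geometry, None)
        one = simulate_experiment(model, geometry, Barrier(0.175, 0.3, 0.7))
        both = simulate_experiment(
            model, geometry, [Barrier(0.015, 0.3, 0.7), Barrier(0.175, 0.3, 0.7)]
        )
        assert sbbc(both, free) >= sbbc(one, free)


class TestSBBC:
    def test_total_blocking_gives_100(self, small_emission, geometry):
        free = simulate_experiment(small_emission, geometry, None)
        blocked = simulate_experiment(small_emission, geometry, Barrier(0.1, 0.0, 0.5))
        assert sbbc(blocked, free) == 100.0

    def test_identical_runs_give_0(self, small_emission, geometry):
        free = simulate_experiment(small_emission, geometry, None)
        assert sbbc(free, free) == 0.0

    def test_zero_reference_volume_rejected(self, geometry):
        model = EmissionModel(count=10, seed=0, diameters_um=[10.0])  # all stall
        free = simulate_experiment(model, geometry, None)
        with pytest.raises(ValueError):
            sbbc(free, free)

    def test_stochastic_sbbc_monotone_in_p_under_crn(self, geometry):
        # nested pass sets under common uniforms make this exact, not statistical
        model = EmissionModel(count=50_000, seed=21)
        free = simulate_experiment(model, geometry, None)
        values = [
            sbbc(simulate_experiment(model, geometry, Barrier(0.1, p, 0.56)), free)
            for p in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert values[0] == 100.0
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_expected_sbbc_exactly_affine_in_p(self, geometry):
        model = EmissionModel(count=50_000, seed=21)
        ps = np.array([0.0, 0.25, 0.5, 1.0])
        vals = np.array([expected_sbbc(model, geometry, Barrier(0.1, p, 0.56)) for p in ps])
        assert vals[0] == 100.0
        slope = (vals[-1] - vals[0]) / (ps[-1] - ps[0])
        residual = np.max(np.abs(vals - (100.0 + slope * ps)))
        assert residual < 1e-9

    def test_expected_sbbc_monotone_in_f(self, geometry):
        model = EmissionModel(count=50_000, seed=22)
        vals = [expected_sbbc(model, geometry, Barrier(0.1, 0.5, f)) for f in np.linspace(0.1, 1.0, 7)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_expected_sbbc_decreases_with_barrier_distance(self, geometry):
        # source control beats wearer protection: a cloth near the nozzle
        # blocks more than the same cloth near the screen
        model = EmissionModel(count=50_000, seed=23)
        dists = [0.015, 0.0683, 0.1217, 0.175]
        vals = [expected_sbbc(model, geometry, Barrier(d, 0.04, 0.56)) for d in dists]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] > vals[-1]

    def test_stochastic_matches_expected_estimator(self, geometry):
        model = EmissionModel(count=100_000, seed=24)
        b = Barrier(0.1, 0.3, 0.7)
        free = simulate_experiment(model, geometry, None)
        stoch = sbbc(simulate_experiment(model, geometry, b), free)
        exact = expected_sbbc(model, geometry, b)
        assert stoch == pytest.approx(exact, abs=3.0)  # Monte-Carlo scatter


class TestContainers:
    def test_unknown_fate_rejected(self):
        with pytest.raises(ValueError):
            ImpactRecord(radius=1e-5, y=0.1, speed=1.0, volume=1e-15, fate="vanished")

    def test_records_roundtrip(self, geometry):
        res = simulate_experiment(EmissionModel(count=50, seed=0), geometry, None)
        records = res.records()
        assert len(records) == 50
        assert all(r.fate in FATES for r in records)

    def test_dataframe_columns(self, geometry):
        res = simulate_experiment(EmissionModel(count=10, seed=0), geometry, None)
        assert list(res.to_dataframe().columns) == ["radius_m", "y_m", "speed_m_s", "volume_m3", "fate"]

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            ExperimentGeometry(nozzle_height=0.3)  # above the screen extent
        with pytest.raises(ValueError):
            ExperimentGeometry(roi_half_height=0.15)  # band sticks out
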