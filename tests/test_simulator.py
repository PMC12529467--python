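"""Fire regime, spread, fire effects, dispersal, establishment, growth."""

import numpy as np
import pytest
from scipy import ndimage

from fxsim.grid import GridSpec
from fxsim.landscape import generate_climate
from fxsim.scenarios import FxScenario, reference_scenario
from fxsim.simulator import (
    FireEvent,
    RegimeParams,
    _dispersal_kernel,
    apply_fire_effects,
    calibrate_regime,
    disperse_seeds,
    draw_fire_events,
    establish,
    grow_and_graduate,
    run_simulation,
    spread_fire,
)

NO_WIND = {"wind_dir": 0.0, "wind_speed": 0.0}


def flat_state(small_state):
    """Uniform, fully stockable, fully fueled landscape for spread oracles."""
    state = small_state.copy()
    state.stockable[:] = 1
    state.elevation[:] = 2300.0
    state.time_since_fire[:] = 1000.0
    state.stand_age[:] = 150.0
    for name in state.mature_density:
        state.mature_density[name][:] = 0.0
    state.mature_density["lodgepole_nonserotinous"][:] = 200.0
    return state


class TestFireRegime:
    def test_poisson_mean_of_large_fire_counts(self):
        regime = RegimeParams(lambda_small=0.0, lambda_large_0=0.2, aridity_coef=0.4)
        aridity = 2.0
        lam = regime.lambda_large(aridity)
        rng = np.random.default_rng(0)
        counts = [len(draw_fire_events(2050, aridity, regime, rng)) for _ in range(10_000)]
        se = np.sqrt(lam / 10_000)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_zero_rates_give_empty_list(self):
        regime = RegimeParams(lambda_small=0.0, lambda_large_0=0.0, aridity_coef=0.0)
        rng = np.random.default_rng(1)
        assert draw_fire_events(2030, 5.0, regime, rng) == []

    def test_size_classes_respect_400_ha_boundary(self):
        regime = RegimeParams(lambda_small=3.0, lambda_large_0=3.0, aridity_coef=0.0)
        rng = np.random.default_rng(2)
        events = []
        for _ in range(200):
            events.extend(draw_fire_events(2030, 0.0, regime, rng))
        for ev in events:
            if ev.klass == "large":
                assert ev.size_cap >= 400
            else:
                assert ev.size_cap < 400

    def test_calibration_hits_both_anchors(self):
        """Expected burn equals 1.7 % of stockable at the reference aridity and
        3.4x that at the peak aridity (the hot-dry/warm-wet contrast)."""
        regime = calibrate_regime(9000.0, aridity_ref=1.0, aridity_peak=4.5)
        ref = regime.expected_burn(1.0)
        assert ref == pytest.approx(0.017 * 9000.0, rel=1e-9)
        assert regime.expected_burn(4.5) / ref == pytest.approx(3.4, rel=1e-9)

    def test_event_size_cap_must_be_positive(self):
        with pytest.raises(ValueError):
            FireEvent(2030, (0, 0), 0.0)


class TestSpreadFire:
    def test_fx_ring_blocks_all_spread(self, small_state):
        state = flat_state(small_state)
        fx = np.zeros(state.grid.shape, dtype=np.uint8)
        fx[19:22, 19:22] = 1
        fx[20, 20] = 0
        scen = FxScenario(mask=fx, kind="nlm", amount=0.1, configuration="dispersed")
        event = FireEvent(2030, (20, 20), 500.0)
        bm = spread_fire(state, event, scen, NO_WIND, np.random.default_rng(0), p_base=1.0)
        assert bm.burned.sum() == 1
        assert bm.burned[20, 20] == 1

    def test_size_cap_is_a_hard_bound(self, small_state):
        state = flat_state(small_state)
        scen = reference_scenario(state.grid)
        for seed in range(5):
            event = FireEvent(2030, (20, 20), 100.0)
            bm = spread_fire(state, event, scen, NO_WIND, np.random.default_rng(seed), p_base=1.0)
            assert bm.burned.sum() <= 100

    def test_certain_spread_fills_connected_component(self, small_state):
        """With p = 1, no wind, flat terrain, uniform fuel and no cap the burn
        equals the flood fill of the ignition's stockable component."""
        state = flat_state(small_state)
        rng = np.random.default_rng(3)
        state.stockable = (rng.random(state.grid.shape) < 0.55).astype(np.uint8)
        state.stockable[15, 15] = 1
        scen = reference_scenario(state.grid)
        event = FireEvent(2030, (15, 15), 1e9)
        bm = spread_fire(state, event, scen, NO_WIND, np.random.default_rng(0), p_base=1.0)
        labels, _ = ndimage.label(state.stockable, structure=np.ones((3, 3)))
        component = labels == labels[15, 15]
        np.testing.assert_array_equal(bm.burned.astype(bool), component)

    def test_ignition_inside_fx_rejected(self, small_state):
        state = flat_state(small_state)
        fx = np.zeros(state.grid.shape, dtype=np.uint8)
        fx[10, 10] = 1
        scen = FxScenario(mask=fx, kind="nlm", amount=0.1, configuration="dispersed")
        with pytest.raises(ValueError, match="Fx"):
            spread_fire(state, FireEvent(2030, (10, 10), 50.0), scen, NO_WIND, np.random.default_rng(0))

    def test_severity_positive_only_where_burned(self, small_state):
        state = flat_state(small_state)
        scen = reference_scenario(state.grid)
        bm = spread_fire(state, FireEvent(2030, (20, 20), 50.0), scen, NO_WIND, np.random.default_rng(4))
        assert np.all(bm.severity[bm.burned == 0] == 0)
        assert np.all(bm.severity[bm.burned == 1] > 0)


class TestFireEffects:
    def make_burnmap(self, state, severity=1.0):
        burned = np.zeros(state.grid.shape, dtype=np.uint8)
        burned[5, 5] = 1
        sev = np.zeros(state.grid.shape, dtype=np.float32)
        sev[5, 5] = severity
        fid = burned.astype(np.int32)
        from fxsim.simulator import BurnMap

        return BurnMap(year=2030, burned=burned, severity=sev, fire_id=fid)

    def test_avoider_killed_at_full_severity(self, small_state):
        state = small_state.copy()
        state.mature_density["subalpine_fir"][5, 5] = 100.0
        state, _ = apply_fire_effects(state, self.make_burnmap(state, 1.0))
        assert state.mature_density["subalpine_fir"][5, 5] == 0.0

    def test_immature_serotinous_stand_releases_nothing(self, small_state):
        """Immaturity risk: a young serotinous stand loses its canopy bank."""
        state = small_state.copy()
        state.stand_age[5, 5] = 10.0  # below maturity_age 20
        state.canopy_seed_bank["lodgepole_serotinous"][5, 5] = 1e5
        state, released = apply_fire_effects(state, self.make_burnmap(state, 1.0))
        assert released["lodgepole_serotinous"][5, 5] == 0.0
        assert state.canopy_seed_bank["lodgepole_serotinous"][5, 5] == 0.0

    def test_mature_serotinous_stand_releases_bank(self, small_state):
        state = small_state.copy()
        state.stand_age[5, 5] = 80.0
        state.canopy_seed_bank["lodgepole_serotinous"][5, 5] = 1e5
        _, released = apply_fire_effects(state, self.make_burnmap(state, 1.0))
        assert released["lodgepole_serotinous"][5, 5] == 1e5

    def test_resister_survival_increases_with_stand_age(self, small_state):
        surviving = {}
        for age in (0.0, 500.0):
            state = small_state.copy()
            state.stand_age[5, 5] = age
            state.mature_density["douglas_fir"][5, 5] = 100.0
            state, _ = apply_fire_effects(state, self.make_burnmap(state, 1.0))
            surviving[age] = state.mature_density["douglas_fir"][5, 5]
        assert surviving[500.0] > surviving[0.0] > 0.0

    def test_stand_replacing_resets_clocks(self, small_state):
        state = small_state.copy()
        state.stand_age[5, 5] = 200.0
        state.time_since_fire[5, 5] = 200.0
        state, _ = apply_fire_effects(state, self.make_burnmap(state, 0.9))
        assert state.stand_age[5, 5] == 0.0
        assert state.time_since_fire[5, 5] == 0.0


class TestDispersal:
    def test_kernel_normalized_to_one(self):
        for scale in (30.0, 60.0, 100.0):
            k = _dispersal_kernel(scale, 100.0)
            assert k.sum() == pytest.approx(1.0, abs=1e-12)

    def test_point_source_conserves_total(self, small_state, species):
        """An interior point source's seed rain sums to the source strength."""
        state = small_state.copy()
        sp = species["douglas_fir"]
        for name in state.mature_density:
            state.mature_density[name][:] = 0.0
        state.stand_age[:] = 100.0
        state.mature_density["douglas_fir"][20, 20] = 50.0
        rain = disperse_seeds(state, sp, year=2031)  # non-mast year
        total_source = 50.0 * sp.fecundity
        assert rain.sum() == pytest.approx(total_source, rel=1e-6)

    def test_seed_rain_declines_with_distance(self, small_state, species):
        state = small_state.copy()
        sp = species["engelmann_spruce"]
        for name in state.mature_density:
            state.mature_density[name][:] = 0.0
        state.stand_age[:] = 100.0
        state.mature_density["engelmann_spruce"][20, 20] = 100.0
        rain = disperse_seeds(state, sp, year=2031)
        d1 = rain[20, 21]  # 100 m = ~1.25 kernel scales
        d2 = rain[20, 22]  # 200 m
        assert d2 < d1

    def test_uniform_field_gives_uniform_interior_rain(self, small_state, species):
        state = small_state.copy()
        sp = species["subalpine_fir"]
        for name in state.mature_density:
            state.mature_density[name][:] = 0.0
        state.stand_age[:] = 100.0
        state.mature_density["subalpine_fir"][:] = 80.0
        rain = disperse_seeds(state, sp, year=2031)
        interior = rain[5:-5, 5:-5]
        assert np.ptp(interior) / interior.mean() < 1e-6

    def test_serotinous_annual_dispersal_rejected(self, small_state, species):
        with pytest.raises(ValueError, match="serotinous"):
            disperse_seeds(small_state, species["lodgepole_serotinous"])


class TestEstablishment:
    def test_far_outside_thermal_envelope_no_establishment(self, small_state, species):
        sp = species["subalpine_fir"]
        state = small_state.copy()
        state.elevation[:] = 2300.0  # no lapse adjustment
        rain = np.full(state.grid.shape, 1000.0)
        temp = sp.establishment_T_opt + 10 * sp.establishment_T_width
        new = establish(rain, state, temp, 0.0, sp, np.random.default_rng(0), noise_sd=0.0)
        assert new.max() < 1e-6 * 1000.0

    def test_zero_seed_rain_means_zero_cohorts(self, small_state, species):
        new = establish(
            np.zeros(small_state.grid.shape), small_state, 13.0, 0.0,
            species["douglas_fir"], np.random.default_rng(0),
        )
        assert np.all(new == 0)

    def test_spruce_establishment_declines_faster_with_warming_than_fir(self, small_state, species):
        """Spruce's narrower envelope and higher drought sensitivity make its
        establishment fall off faster as summers warm."""
        state = small_state.copy()
        state.elevation[:] = 2300.0
        state.time_since_fire[:] = 1.0  # recent burn, full light
        rain = np.full(state.grid.shape, 1000.0)

        def ratio(sp):
            cool = establish(rain, state, 11.0, 0.0, sp, np.random.default_rng(0), noise_sd=0.0).mean()
            hot = establish(rain, state, 17.0, 3.0, sp, np.random.default_rng(0), noise_sd=0.0).mean()
            return hot / cool

        assert ratio(species["engelmann_spruce"]) < ratio(species["subalpine_fir"])

    def test_no_establishment_off_stockable(self, small_state, species):
        rain = np.full(small_state.grid.shape, 1000.0)
        new = establish(rain, small_state, 13.0, 0.0, species["douglas_fir"], np.random.default_rng(0))
        assert np.all(new[small_state.stockable == 0] == 0)

    def test_establishment_bounded_by_seed_rain(self, small_state, species):
        rain = np.full(small_state.grid.shape, 500.0)
        new = establish(rain, small_state, 13.0, 0.0, species["douglas_fir"], np.random.default_rng(1))
        assert float(new.sum()) <= float(rain.sum())


class TestGrowAndGraduate:
    def test_cohort_graduates_at_four_meters(self, small_state):
        state = small_state.copy()
        layer = state.cohorts["douglas_fir"]  # growth 0.30
        layer.density[:] = 0.0
        layer.density[8, 8] = 1000.0
        layer.height[8, 8] = 3.8
        before = state.mature_density["douglas_fir"][8, 8]
        grow_and_graduate(state)
        assert layer.density[8, 8] == 0.0
        assert state.mature_density["douglas_fir"][8, 8] > before

    def test_faster_species_wins_cell(self, small_state):
        state = small_state.copy()
        for name in state.cohorts:
            state.cohorts[name].density[:] = 0.0
        fast, slow = state.cohorts["douglas_fir"], state.cohorts["engelmann_spruce"]
        fast.density[8, 8] = slow.density[8, 8] = 500.0
        fast.height[8, 8] = slow.height[8, 8] = 3.8
        spruce_before = state.mature_density["engelmann_spruce"][8, 8]
        grow_and_graduate(state)
        assert state.mature_density["douglas_fir"][8, 8] > 0
        assert slow.density[8, 8] == 0.0  # loser removed
        assert state.mature_density["engelmann_spruce"][8, 8] == spruce_before

    def test_empty_cohorts_leave_state_unchanged(self, small_state):
        state = small_state.copy()
        for name in state.cohorts:
            state.cohorts[name].density[:] = 0.0
            state.cohorts[name].height[:] = 0.0
            state.cohorts[name].age[:] = 0.0
        dens_before = {k: v.copy() for k, v in state.mature_density.items()}
        grow_and_graduate(state)
        for k in dens_before:
            np.testing.assert_array_equal(state.mature_density[k], dens_before[k])


class TestRunSimulation:
    @pytest.fixture(scope="class")
    def regime(self):
        return calibrate_regime(1440.0, aridity_ref=1.0, aridity_peak=4.5)

    @pytest.fixture(scope="class")
    def climate(self):
        return generate_climate("hot-dry", seed=5)

    def test_total_exclusion_burns_nothing(self, small_state, climate, regime):
        fx = FxScenario(
            mask=small_state.stockable.copy(), kind="nlm", amount=1.0, configuration="n/a"
        )
        out = run_simulation(small_state, climate, fx, regime, fire_seed=1, regen_seed=2)
        assert np.all(out.area_burned == 0)

    def test_deterministic_given_seeds(self, small_state, climate, regime):
        a = run_simulation(small_state, climate, reference_scenario(small_state.grid), regime, fire_seed=3, regen_seed=4)
        b = run_simulation(small_state, climate, reference_scenario(small_state.grid), regime, fire_seed=3, regen_seed=4)
        np.testing.assert_array_equal(a.area_burned, b.area_burned)
        np.testing.assert_array_equal(a.fire_id_maps, b.fire_id_maps)
        for sp in a.cohort_density:
            np.testing.assert_array_equal(a.cohort_density[sp], b.cohort_density[sp])

    def test_regen_seed_does_not_change_fire_history(self, small_state, climate, regime):
        fx = reference_scenario(small_state.grid)
        a = run_simulation(small_state, climate, fx, regime, fire_seed=3, regen_seed=4)
        b = run_simulation(small_state, climate, fx, regime, fire_seed=3, regen_seed=99)
        np.testing.assert_array_equal(a.fire_id_maps, b.fire_id_maps)
        np.testing.assert_array_equal(a.area_burned, b.area_burned)

    def test_burned_never_intersects_fx_and_area_accounting_exact(self, small_state, climate, regime):
        from fxsim.scenarios import nlm_scenario

        fx = nlm_scenario(small_state, 0.3, "dispersed", nlm_seed=8)
        out = run_simulation(small_state, climate, fx, regime, fire_seed=6, regen_seed=7)
        assert int((out.fire_id_maps[:, fx.mask == 1] > 0).sum()) == 0
        for yi in range(len(out.years)):
            burned_cells = int((out.fire_id_maps[yi] > 0).sum())
            assert out.area_burned[yi] == burned_cells * out.cell_area_ha

    def test_avoider_regen_declines_with_distance_serotinous_does_not(self, species, regime):
        """In a landscape burned except one mature source patch, 5-yr avoider
        regeneration declines with distance from the patch while serotinous
        lodgepole regeneration (in-situ release) shows no such decline."""
        from fxsim.landscape import generate_landscape

        state = generate_landscape(GridSpec(60, 60), species, seed=2)
        state.stockable[:] = 1
        state.elevation[:] = 2300.0
        state.stand_age[:] = 100.0
        state.time_since_fire[:] = 100.0
        for name in state.mature_density:
            state.mature_density[name][:] = 0.0
            state.cohorts[name].density[:] = 0.0
        # Mature mixed source column at the west edge.
        state.mature_density["engelmann_spruce"][:, :3] = 150.0
        state.mature_density["lodgepole_serotinous"][:, 3:] = 150.0
        state.canopy_seed_bank["lodgepole_serotinous"][:, 3:] = 1e5

        burned = np.zeros(state.grid.shape, dtype=np.uint8)
        burned[:, 3:] = 1
        sev = burned.astype(np.float32)
        from fxsim.simulator import BurnMap

        bm = BurnMap(year=2021, burned=burned, severity=sev, fire_id=burned.astype(np.int32))
        state, released = apply_fire_effects(state, bm)

        rng = np.random.default_rng(0)
        spruce = species["engelmann_spruce"]
        sero = species["lodgepole_serotinous"]
        spruce_total = np.zeros(state.grid.shape)
        for year in range(2021, 2026):
            rain = disperse_seeds(state, spruce, year=year)
            spruce_total += establish(rain, state, 10.0, 0.0, spruce, rng, noise_sd=0.0)
        sero_regen = establish(released["lodgepole_serotinous"], state, 13.0, 0.0, sero, rng, noise_sd=0.0)

        # Distance bins within the spruce kernel's 400-m truncation radius.
        cols = np.arange(3, 7)
        spruce_profile = np.array([spruce_total[:, c].mean() for c in cols])
        assert np.all(np.diff(spruce_profile) < 0)
        sero_profile = np.array([sero_regen[:, c].mean() for c in np.arange(3, 15)])
        assert np.ptp(sero_profile) / sero_profile.mean() < 0.01
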