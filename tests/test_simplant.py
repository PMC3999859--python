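"""Virtual plant: column dynamics, analyzer, faults, reservoir, response surface."""

import itertools

import numpy as np
import pytest

from flowrig import (
    AnalyzerModel,
    ColumnBed,
    Fault,
    FeedStream,
    HydrationPlant,
    HydrogenationUnit,
    PlantError,
    PressureModel,
    Reservoir,
    analyzer_readout,
    inject_fault,
    mean_residence_time,
    step_column,
)
from flowrig.simplant import sustained_conversion_window


def run_to_steady(bed, feed, minutes, dt_s=10.0):
    t = 0.0
    while t < minutes * 60.0:
        bed.step(feed, dt_s)
        t += dt_s
    return bed


class TestColumnStep:
    def test_dehydrated_bed_passes_nitrile_unconverted(self, dry_feed):
        bed = ColumnBed(water_capacity=0.0)
        run_to_steady(bed, dry_feed, minutes=80)
        out = bed.outlet()
        assert out["nitrile"] == pytest.approx(dry_feed.nitrile, rel=1e-3)
        assert out["amide"] == pytest.approx(0.0, abs=1e-9)

    def test_excess_water_gives_quantitative_conversion(self, bed, aqueous_feed):
        run_to_steady(bed, aqueous_feed, minutes=80)
        out = bed.outlet()
        assert out["amide"] == pytest.approx(aqueous_feed.nitrile, rel=1e-3)
        assert out["nitrile"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_flow_leaves_bed_unchanged(self, bed, aqueous_feed):
        run_to_steady(bed, aqueous_feed, minutes=30)
        before = (bed.nitrile.copy(), bed.amide.copy(), bed.bound_water)
        step_column(bed, FeedStream(0.0, 0.06, 0.6), 10.0)
        assert np.allclose(bed.nitrile, before[0])
        assert np.allclose(bed.amide, before[1])
        assert bed.bound_water == pytest.approx(before[2])

    def test_unstable_step_rejected(self, bed, aqueous_feed):
        # transfer per step must stay below one tank volume: V/N = 0.1 mL
        with pytest.raises(PlantError):
            bed.step(aqueous_feed, dt_s=61.0)

    def test_mass_balance_closes_under_varied_feeds(self, bed):
        rng = np.random.default_rng(7)
        for _ in range(300):
            feed = FeedStream(float(rng.uniform(0, 0.3)),
                              float(rng.uniform(0, 0.1)),
                              float(rng.uniform(0, 0.3)))
            bed.step(feed, dt_s=10.0)
        fed = bed.fed["nitrile"]
        held = bed.holdup()
        out = bed.effluent
        total = out["nitrile"] + out["amide"] + held["nitrile"] + held["amide"]
        assert total == pytest.approx(fed, rel=1e-6)

    def test_water_ledger_stays_within_bounds(self, bed):
        rng = np.random.default_rng(11)
        w0 = bed.water_capacity
        for _ in range(300):
            feed = FeedStream(float(rng.uniform(0, 0.3)),
                              float(rng.uniform(0, 0.1)),
                              float(rng.uniform(0, 0.2)))
            bed.step(feed, dt_s=10.0)
            assert -1e-12 <= bed.bound_water <= w0 + 1e-12
        supplied = bed.fed["water"] + w0
        amide_formed = bed.effluent["amide"] + bed.holdup()["amide"]
        assert amide_formed <= supplied + 1e-9

    def test_dry_feed_conversion_non_increasing_after_onset(self, bed, dry_feed):
        conversions = []
        t = 0.0
        while t < 5 * 3600:
            bed.step(dry_feed, 20.0)
            t += 20.0
            conversions.append(bed.outlet()["amide"])
        peak = int(np.argmax(conversions))
        tail = np.array(conversions[peak:])
        assert np.all(np.diff(tail) <= 1e-12)


class TestResidenceTime:
    def test_two_ml_bed_at_point_one_gives_twenty_minutes(self, bed):
        assert mean_residence_time(bed, 0.1) == pytest.approx(20.0, rel=0.01)

    def test_scales_inversely_with_flow(self, bed):
        assert mean_residence_time(bed, 0.2) == pytest.approx(10.0, rel=0.01)

    @pytest.mark.parametrize("n_tanks", [1, 5, 50])
    def test_first_moment_independent_of_tank_count(self, n_tanks):
        bed = ColumnBed(void_volume=2.0, n_tanks=n_tanks)
        assert mean_residence_time(bed, 0.1) == pytest.approx(20.0, rel=0.01)

    def test_zero_flow_undefined(self, bed):
        with pytest.raises(PlantError):
            mean_residence_time(bed, 0.0)


class TestDispersion:
    @staticmethod
    def _rise_width_cv(n_tanks: int) -> float:
        """10-90% rise of the step response, in column volumes."""
        bed = ColumnBed(void_volume=2.0, n_tanks=n_tanks, water_capacity=0.0)
        feed = FeedStream(0.1, nitrile=0.06)
        t, t10, t90 = 0.0, None, None
        while t < 6 * 3600:
            bed.step(feed, 10.0)
            t += 10.0
            c = bed.outlet()["nitrile"]
            if t10 is None and c >= 0.1 * feed.nitrile:
                t10 = t
            if t90 is None and c >= 0.9 * feed.nitrile:
                t90 = t
                break
        cv_seconds = 60.0 * bed.void_volume / feed.flow_rate
        return (t90 - t10) / cv_seconds

    def test_front_spans_about_one_column_volume_at_default_n(self):
        width = self._rise_width_cv(20)
        assert 0.3 < width < 1.5

    def test_front_sharpens_with_more_tanks(self):
        assert self._rise_width_cv(80) < self._rise_width_cv(10)


class TestBreakthrough:
    def test_dry_feed_sustains_conversion_for_three_hours(self, bed, dry_feed):
        rise, fall = sustained_conversion_window(bed, dry_feed, dt_s=10.0)
        assert (fall - rise) / 3600.0 == pytest.approx(3.0, rel=0.05)

    def test_elution_lag_is_about_one_column_volume(self, bed, dry_feed):
        rise, _ = sustained_conversion_window(bed, dry_feed, dt_s=10.0)
        cv_s = 60.0 * bed.void_volume / dry_feed.flow_rate
        assert rise == pytest.approx(cv_s, rel=0.35)


class TestAnalyzer:
    def test_zero_concentrations_read_baseline(self, bed):
        channels = analyzer_readout(bed)
        assert channels["absorbance_1685"] == 0.0
        assert channels["absorbance_2245"] == 0.0

    def test_full_conversion_lights_amide_channel_only(self, bed, aqueous_feed):
        run_to_steady(bed, aqueous_feed, minutes=80)
        channels = analyzer_readout(bed)
        assert channels["absorbance_1685"] > 0.25
        assert channels["absorbance_2245"] == pytest.approx(0.0, abs=1e-6)

    def test_noise_free_channel_is_linear_in_concentration(self):
        model = AnalyzerModel(amide_factor=10.0)
        a1 = model.readout({"amide": 0.03, "nitrile": 0.0})["absorbance_1685"]
        a2 = model.readout({"amide": 0.06, "nitrile": 0.0})["absorbance_1685"]
        assert a2 == pytest.approx(2.0 * a1)

    def test_noise_is_seed_reproducible(self):
        r1 = AnalyzerModel(noise_sigma=0.01, rng=np.random.default_rng(5)).readout(
            {"amide": 0.03, "nitrile": 0.0})
        r2 = AnalyzerModel(noise_sigma=0.01, rng=np.random.default_rng(5)).readout(
            {"amide": 0.03, "nitrile": 0.0})
        assert r1 == r2


class TestPressureFaults:
    def test_no_schedule_keeps_nominal_pressure(self):
        pm = PressureModel()
        assert pm.reading(0.0) == pm.reading(9999.0) == pm.nominal

    def test_bubble_collapses_below_low_alarm_and_suspends_flow(self):
        plant = HydrationPlant(ColumnBed(), FeedStream(0.1, 0.06, 0.6))
        inject_fault(plant, [{"time_s": 5400.0, "fault_type": "bubble_loss"}])
        assert plant.pressure.reading(5400.0) < plant.pressure.low_alarm
        assert plant.pressure.flow_suspended(5400.0)
        assert plant.effective_feed(5400.0).flow_rate == 0.0
        assert not plant.pressure.flow_suspended(5399.0)

    def test_re_prime_restores_nominal_next_reading(self):
        pm = PressureModel()
        pm.schedule([Fault(100.0, "bubble_loss")])
        assert pm.reading(200.0) == pm.bubble_pressure
        pm.re_prime(250.0)
        assert pm.reading(249.0) == pm.bubble_pressure
        assert pm.reading(250.0) == pm.nominal

    def test_over_pressure_reads_above_high_alarm(self):
        pm = PressureModel()
        pm.schedule([Fault(10.0, "over_pressure", duration_s=60.0)])
        assert pm.reading(30.0) > pm.high_alarm
        assert pm.reading(80.0) == pm.nominal

    def test_overlapping_faults_rejected(self):
        pm = PressureModel()
        with pytest.raises(PlantError):
            pm.schedule([Fault(0.0, "bubble_loss", 100.0),
                         Fault(50.0, "over_pressure", 100.0)])


class TestReservoir:
    def test_net_inflow_arithmetic(self):
        res = Reservoir(capacity=50.0, volume=5.0)
        res.inflow_rate, res.outflow_rate = 0.2, 0.1
        res.step(600.0)  # 10 min
        assert res.volume == pytest.approx(6.0)

    def test_overflow_caps_volume_and_raises_event(self):
        res = Reservoir(capacity=50.0, volume=49.9)
        res.inflow_rate = 1.0
        events = res.step(60.0)
        assert "overflow_risk" in events
        assert res.volume == 50.0

    def test_balanced_rates_hold_level(self):
        res = Reservoir(capacity=50.0, volume=20.0)
        res.amide_mmol = 1.0
        res.inflow_rate = res.outflow_rate = 0.15
        for _ in range(100):
            res.step(30.0)
        assert res.volume == pytest.approx(20.0)

    def test_low_level_crossing_emits_event(self):
        res = Reservoir(capacity=50.0, volume=2.5, low_mark=2.0)
        res.outflow_rate = 0.1
        seen = []
        for _ in range(10):
            seen += res.step(60.0)
        assert "low_level" in seen


class TestHydrogenationSurface:
    CORNERS = list(itertools.product((40.0, 100.0), ("20bar", "full"), (0.1, 0.2)))

    def test_flat_surface_is_constant(self):
        unit = HydrogenationUnit(
            conv_coeffs={"intercept": 0.5, "T": 0.0, "H": 0.0, "Q": 0.0},
            frac4_coeffs={"intercept": 0.0, "T": 0.0, "H": 0.0, "Q": 0.0},
            other_fraction=0.0,
        )
        for corner in self.CORNERS:
            assert unit.response(*corner)[0] == pytest.approx(0.5)

    def test_best_corner_is_hot_full_hydrogen_slow(self):
        unit = HydrogenationUnit()
        best = max(self.CORNERS, key=lambda c: unit.response(*c)[0])
        assert best == (100.0, "full", 0.1)

    def test_hydrogen_mode_outweighs_temperature(self):
        unit = HydrogenationUnit()
        base = unit.response(40.0, "20bar", 0.2)[0]
        dh = abs(unit.response(40.0, "full", 0.2)[0] - base)
        dt = abs(unit.response(100.0, "20bar", 0.2)[0] - base)
        assert dh > dt

    def test_hot_and_slow_minimises_tetrahydro_fraction(self):
        unit = HydrogenationUnit()
        f4 = {c: unit.response(*c)[2] for c in self.CORNERS}
        assert min(f4, key=f4.get) == (100.0, "full", 0.1)

    def test_fractions_are_proper(self):
        unit = HydrogenationUnit()
        for corner in self.CORNERS:
            conv, f1, f4, fo = unit.response(*corner)
            assert 0.0 <= conv <= 1.0
            assert all(f >= 0 for f in (f1, f4, fo))
            assert f1 + f4 + fo == pytest.approx(conv)

    def test_off_grid_settings_rejected(self):
        unit = HydrogenationUnit()
        with pytest.raises(PlantError):
            unit.response(95.0, "full", 0.1)
        with pytest.raises(PlantError):
            unit.response(100.0, "30bar", 0.1)


class TestScaleUp:
    @staticmethod
    def _steady_output(flow: float) -> float:
        """Steady molar output (mmol/min) of the scaled 10 mm column."""
        bed = ColumnBed(void_volume=4.0, water_capacity=2.16)
        feed = FeedStream(flow, nitrile=0.06, water=0.6)
        run_to_steady(bed, feed, minutes=6 * 60, dt_s=20.0)
        return flow * bed.outlet()["amide"]

    def test_doubling_flow_doubles_molar_output(self):
        ratio = self._steady_output(0.2) / self._steady_output(0.1)
        assert ratio == pytest.approx(2.0, rel=0.01)
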