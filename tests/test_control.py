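"""Control engine: rule evaluation, delays, ledger, alerts, determinism."""

import pytest

from flowrig import (
    COLLECT,
    ColumnBed,
    CollectionLedger,
    ControlError,
    FeedStream,
    HydrationConfig,
    HydrationPlant,
    MonitorRule,
    Notifier,
    RuleEvaluator,
    SequenceProgram,
    build_hydration_rig,
    dispatch_alert,
    ledger_summary,
    notifier,
    resolve_column_volume_delay,
    run_monitored_hydration,
    run_sequence,
)

BUBBLE_AT_90MIN = [
    {"time_s": 5400.0, "fault_type": "bubble_loss"},
    {"time_s": 5760.0, "fault_type": "re_prime"},
]


class TestRuleEvaluation:
    def test_immediate_rule_flips_same_tick(self):
        rule = MonitorRule("abs", "IR1", "absorbance_1685", "above", threshold=0.3)
        ev = RuleEvaluator([rule])
        assert not ev.evaluate({("IR1", "absorbance_1685"): 0.1}, 0.0).collect_ok
        assert ev.evaluate({("IR1", "absorbance_1685"): 0.31}, 1.0).collect_ok
        assert not ev.evaluate({("IR1", "absorbance_1685"): 0.3}, 2.0).collect_ok

    def test_delayed_rule_blocks_for_full_resume_delay(self):
        rule = MonitorRule("p", "PS1", "pressure", "within", low=2.0, high=15.0,
                           response="delayed", resume_delay_s=1200.0)
        ev = RuleEvaluator([rule])
        key = ("PS1", "pressure")
        assert ev.evaluate({key: 8.0}, 0.0).collect_ok
        assert not ev.evaluate({key: 0.5}, 1.0).collect_ok  # violated
        recovery_t = 2.0
        assert not ev.evaluate({key: 8.0}, recovery_t).collect_ok  # recovering
        # still blocked strictly inside the delay window
        assert not ev.evaluate({key: 8.0}, recovery_t + 1199.0).collect_ok
        state = ev.evaluate({key: 8.0}, recovery_t + 1200.0)
        assert state.collect_ok  # exactly resume_delay after recovery

    def test_collect_ok_tracks_absorbance_when_nothing_else_violates(self):
        rules = [
            MonitorRule("abs", "IR1", "absorbance_1685", "above", threshold=0.3),
            MonitorRule("p", "PS1", "pressure", "within", low=2.0, high=15.0,
                        response="delayed", resume_delay_s=600.0),
        ]
        ev = RuleEvaluator(rules)
        for t, absorb, expect in [(0, 0.0, False), (1, 0.4, True), (2, 0.2, False)]:
            state = ev.evaluate(
                {("IR1", "absorbance_1685"): absorb, ("PS1", "pressure"): 8.0}, t)
            assert state.collect_ok is expect

    def test_safety_immediate_violation_always_blocks(self):
        """collect_ok may never be true while an immediate rule is violated."""
        rules = [
            MonitorRule("abs", "IR1", "absorbance_1685", "above", threshold=0.3),
            MonitorRule("p", "PS1", "pressure", "within", low=2.0, high=15.0,
                        response="delayed", resume_delay_s=60.0),
        ]
        ev = RuleEvaluator(rules)
        import numpy as np
        rng = np.random.default_rng(3)
        for t in range(500):
            absorb = float(rng.uniform(0, 0.6))
            pressure = float(rng.choice([8.0, 8.0, 8.0, 0.5]))
            state = ev.evaluate(
                {("IR1", "absorbance_1685"): absorb, ("PS1", "pressure"): pressure},
                float(t))
            if absorb <= 0.3:
                assert not state.collect_ok

    def test_missing_reading_errors(self):
        rule = MonitorRule("abs", "IR1", "absorbance_1685", "above", threshold=0.3)
        with pytest.raises(ControlError):
            RuleEvaluator([rule]).evaluate({}, 0.0)

    def test_malformed_rules_rejected_at_construction(self):
        with pytest.raises(ControlError):
            MonitorRule("bad", "X", "y", "within", low=5.0, high=2.0)
        with pytest.raises(ControlError):
            MonitorRule("bad", "X", "y", "above", threshold=float("inf"))


class TestColumnVolumeDelay:
    def test_two_ml_at_point_one(self):
        assert resolve_column_volume_delay(ColumnBed(void_volume=2.0), 0.1) == 1200.0

    def test_halves_with_doubled_flow(self):
        assert resolve_column_volume_delay(ColumnBed(void_volume=2.0), 0.2) == 600.0

    def test_degenerate_zero_volume(self):
        bed = ColumnBed(void_volume=1.0)
        bed.void_volume = 0.0
        assert resolve_column_volume_delay(bed, 0.1) == 0.0

    def test_zero_flow_errors(self):
        with pytest.raises(ControlError):
            resolve_column_volume_delay(ColumnBed(), 0.0)


class TestLedger:
    def test_fractions_and_window_count(self):
        led = CollectionLedger()
        led.record(0.0, 1.0, {"volume": 1.0, "amide": 0.1}, collecting=False)
        led.record(1.0, 1.0, {"volume": 1.0, "amide": 0.1}, collecting=True)
        led.record(2.0, 1.0, {"volume": 1.0, "amide": 0.1}, collecting=True)
        led.record(3.0, 1.0, {"volume": 1.0, "amide": 0.1}, collecting=False)
        led.record(4.0, 1.0, {"volume": 1.0, "amide": 0.1}, collecting=True)
        s = ledger_summary(led)
        assert s["collected_fraction"] == pytest.approx(0.6)
        assert s["waste_fraction"] == pytest.approx(0.4)
        assert s["window_count"] == 2

    def test_empty_ledger_has_undefined_fractions(self):
        with pytest.raises(ControlError):
            ledger_summary(CollectionLedger())

    def test_never_opened_valve_collects_nothing(self):
        led = CollectionLedger()
        for t in range(5):
            led.record(float(t), 1.0, {"volume": 1.0}, collecting=False)
        assert ledger_summary(led)["collected_fraction"] == 0.0


class TestAlerts:
    def test_single_message_via_notifier(self):
        from flowrig.devices import Notifier as NotifierDevice
        n = NotifierDevice(notifier("N1"))
        msg = dispatch_alert(n, {"severity": "critical", "device": "PS1",
                                 "parameter": "pressure", "text": "lost pressure",
                                 "t": 42.0})
        assert msg["severity"] == "critical" and msg["timestamp"] == 42.0
        assert n.messages == [msg]

    def test_persistent_fault_alerts_once(self):
        cfg = HydrationConfig(duration_s=3 * 3600, dt_s=2.0,
                              fault_schedule=BUBBLE_AT_90MIN)
        report = run_monitored_hydration(cfg, seed=0)
        assert report.summary["alerts"] == 1

    def test_distinct_fault_kinds_alert_separately(self):
        cfg = HydrationConfig(
            duration_s=2 * 3600, dt_s=2.0,
            fault_schedule=[
                {"time_s": 1800.0, "fault_type": "bubble_loss", "duration_s": 300.0},
                {"time_s": 3600.0, "fault_type": "over_pressure", "duration_s": 300.0},
            ])
        report = run_monitored_hydration(cfg, seed=0)
        assert report.summary["alerts"] == 2


class TestRunSequence:
    def test_fault_free_run_has_single_collect_transition(self):
        cfg = HydrationConfig(duration_s=2 * 3600, dt_s=2.0)
        rig, plant, program = build_hydration_rig(cfg, seed=0)
        result = run_sequence(program, plant, rig, dt_s=cfg.dt_s,
                              horizon_s=cfg.duration_s + 10)
        switches = [e for e in result.events
                    if e.get("type") == "valve_switch" and e["to"] == COLLECT]
        assert len(switches) == 1
        assert result.ledger.window_count == 1

    def test_bubble_interrupts_collection_and_resumes_after_delay(self):
        cfg = HydrationConfig(duration_s=3 * 3600, dt_s=2.0,
                              fault_schedule=BUBBLE_AT_90MIN)
        report = run_monitored_hydration(cfg, seed=0)
        assert report.summary["window_count"] == 2
        w1, w2 = report.run_result.ledger.windows
        # collection resumes no earlier than re-prime + one column volume
        delay = 60.0 * cfg.void_volume / cfg.flow_rate
        assert w2[0] >= 5760.0 + delay

    def test_empty_program_produces_no_events_or_effluent(self):
        cfg = HydrationConfig(dt_s=2.0)
        rig, plant, _ = build_hydration_rig(cfg, seed=0)
        result = run_sequence(SequenceProgram(steps=[]), plant, rig)
        assert result.events == []
        assert result.ledger.collected_volume == 0.0
        assert result.ledger.wasted_volume == 0.0

    def test_program_referencing_unknown_device_rejected(self):
        from flowrig import SetParameter, Wait
        cfg = HydrationConfig(dt_s=2.0)
        rig, plant, _ = build_hydration_rig(cfg, seed=0)
        bad = SequenceProgram(steps=[SetParameter("NOPE", "flow_rate", 1.0), Wait(10)])
        with pytest.raises(ControlError):
            run_sequence(bad, plant, rig)


class TestDeterminism:
    def test_identical_runs_give_byte_identical_event_logs(self):
        cfg = HydrationConfig(duration_s=2 * 3600, dt_s=2.0,
                              analyzer_noise=0.005,
                              fault_schedule=BUBBLE_AT_90MIN)
        a = run_monitored_hydration(cfg, seed=123)
        cfg2 = HydrationConfig(duration_s=2 * 3600, dt_s=2.0,
                               analyzer_noise=0.005,
                               fault_schedule=BUBBLE_AT_90MIN)
        b = run_monitored_hydration(cfg2, seed=123)
        assert a.events_jsonl().encode() == b.events_jsonl().encode()

    def test_different_seed_changes_noisy_telemetry(self):
        cfg = HydrationConfig(duration_s=1800, dt_s=2.0, analyzer_noise=0.01)
        a = run_monitored_hydration(cfg, seed=1)
        cfg2 = HydrationConfig(duration_s=1800, dt_s=2.0, analyzer_noise=0.01)
        b = run_monitored_hydration(cfg2, seed=2)
        va = [r.value for r in a.run_result.telemetry if r.parameter == "absorbance_1685"]
        vb = [r.value for r in b.run_result.telemetry if r.parameter == "absorbance_1685"]
        assert va != vb
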