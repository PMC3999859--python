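"""End-to-end process scenarios.

Three ready-to-run campaigns tie the layers together:

* :func:`run_monitored_hydration` -- the monitored packed-bed hydration:
  product is collected only while the inline IR absorbance, the system
  pressure and the bed temperature are all stable; pressure faults divert
  effluent to waste, raise one alert each, and collection resumes only a
  full column volume after recovery.
* :func:`run_doe_campaign` -- the automated two-level factorial
  hydrogenation campaign: randomised replicated runs executed through a
  multi-position sampling valve, responses computed from (simulated or
  supplied) NMR integral rows, effects estimated and ranked.
* :func:`run_two_step` -- the reservoir-coupled semi-continuous two-step
  process: the hydration step fills a buffer reservoir (gated on the IR
  threshold), the hydrogenation step draws from it at its own rate, and a
  stop-at-full / restart-at-low hysteresis on step 1 yields the periodic
  fill-drain cycle that lets two unmatched flow rates coexist.

Every scenario returns a :class:`CampaignReport` with the event log, the
collection ledger, summary numbers and any invariant violations observed
during the run (there should be none).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .clock import SimClock
from .control import (
    ONE_COLUMN_VOLUME,
    CollectionLedger,
    ControlError,
    Monitor,
    MonitorRule,
    RunResult,
    SequenceProgram,
    SetParameter,
    Wait,
    ledger_summary,
    run_sequence,
)
from .devices import (
    COLLECT,
    WASTE,
    Notifier,
    Rig,
    binary_valve,
    camera,
    column_heater,
    ir_analyzer,
    multiposition_valve,
    notifier,
    pressure_sensor,
    pump,
    temperature_sensor,
)
from .doe import (
    Factor,
    FactorialDesign,
    compute_responses,
    effects_frame,
    estimate_effects,
    full_factorial,
    rank_factors,
)
from .simplant import (
    AnalyzerModel,
    ColumnBed,
    FeedStream,
    HydrationPlant,
    HydrogenationUnit,
    PlantError,
    PressureModel,
    Reservoir,
    inject_fault,
)


@dataclass
class CampaignReport:
    """Uniform result container for all scenarios."""

    scenario: str
    summary: dict[str, Any] = field(default_factory=dict)
    events: list[dict[str, Any]] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    run_result: RunResult | None = None
    invariant_violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.invariant_violations

    def to_json(self) -> str:
        payload = {
            "scenario": self.scenario,
            "summary": self.summary,
            "invariant_violations": self.invariant_violations,
            "n_events": len(self.events),
        }
        return json.dumps(payload, indent=2, sort_keys=False, default=float)

    def events_jsonl(self) -> str:
        return "\n".join(json.dumps(e, sort_keys=False, default=float) for e in self.events) + "\n"


# ---------------------------------------------------------------------------
# Monitored hydration (scenario 1)
# ---------------------------------------------------------------------------

@dataclass
class HydrationConfig:
    """Configuration for the monitored hydration run.

    Defaults describe the 100 x 6.6 mm bed (2.0 mL void, 2.5 g catalyst)
    fed with 0.06 M nitrile at 0.1 mL/min and heated to 100 degC.  With
    ``feed_water`` = 0 the catalyst's bound-water budget depletes and the
    run shows breakthrough after ~3 h of sustained conversion; an aqueous
    feed sustains conversion indefinitely.
    """

    void_volume: float = 2.0
    n_tanks: int = 20
    water_capacity: float = 1.08
    temperature: float = 100.0
    flow_rate: float = 0.1  # mL/min
    feed_nitrile: float = 0.06  # mmol/mL
    feed_water: float = 0.6  # mmol/mL; 0 for the dry-feed experiment
    duration_s: float = 3 * 3600.0
    dt_s: float = 1.0
    absorbance_threshold: float | None = None  # None -> 50% of plateau
    temperature_band: float = 2.0  # +/- degC
    analyzer_noise: float = 0.0
    fault_schedule: Sequence[dict[str, Any]] = ()
    pressure: dict[str, float] = field(default_factory=dict)


def build_hydration_rig(
    config: HydrationConfig, seed: int | None = None
) -> tuple[Rig, HydrationPlant, SequenceProgram]:
    """Assemble rig, plant and program for the monitored hydration."""
    clock = SimClock(tick=config.dt_s)
    rig = Rig(clock)
    rig.register(pump("P1", max_flow=10.0))
    rig.register(binary_valve("V1"))
    rig.register(column_heater("H1"))
    rig.register(ir_analyzer("IR1"))
    rig.register(pressure_sensor("PS1"))
    rig.register(temperature_sensor("TS1"))
    rig.register(notifier("N1"))

    bed = ColumnBed(
        void_volume=config.void_volume,
        n_tanks=config.n_tanks,
        water_capacity=config.water_capacity,
        temperature=config.temperature,
    )
    feed = FeedStream(config.flow_rate, config.feed_nitrile, config.feed_water)
    rng = np.random.default_rng(seed)
    analyzer = AnalyzerModel(noise_sigma=config.analyzer_noise, rng=rng)
    plant = HydrationPlant(bed, feed, PressureModel(**config.pressure), analyzer)
    if config.fault_schedule:
        inject_fault(plant, list(config.fault_schedule))

    rig["PS1"].bind("pressure", lambda: plant.pressure.reading(clock.now))
    rig["TS1"].bind("temperature", lambda: rig["H1"].values.get("temperature", bed.temperature))
    rig["IR1"].bind("absorbance_1685", lambda: plant.ir()["absorbance_1685"])
    rig["IR1"].bind("absorbance_2245", lambda: plant.ir()["absorbance_2245"])

    threshold = config.absorbance_threshold
    if threshold is None:
        # half of the full-conversion plateau signal
        threshold = 0.5 * analyzer.amide_factor * config.feed_nitrile
    pm = plant.pressure
    rules = (
        MonitorRule("absorbance", "IR1", "absorbance_1685", "above", threshold=threshold,
                    response="immediate"),
        MonitorRule("pressure", "PS1", "pressure", "within",
                    low=pm.low_alarm, high=pm.high_alarm, response="delayed",
                    resume_delay_s=ONE_COLUMN_VOLUME, alert_severity="critical"),
        MonitorRule("temperature", "TS1", "temperature", "within",
                    low=config.temperature - config.temperature_band,
                    high=config.temperature + config.temperature_band,
                    response="delayed", resume_delay_s=ONE_COLUMN_VOLUME),
    )
    program = SequenceProgram(
        steps=[
            SetParameter("H1", "temperature", config.temperature),
            SetParameter("P1", "flow_rate", config.flow_rate),
            Monitor(rules),
            Wait(config.duration_s),
        ],
        collect_valve="V1",
        notifier="N1",
    )
    return rig, plant, program


def run_monitored_hydration(
    config: HydrationConfig | None = None, seed: int | None = None
) -> CampaignReport:
    """Execute the monitored hydration scenario end to end."""
    config = config or HydrationConfig()
    rig, plant, program = build_hydration_rig(config, seed)
    result = run_sequence(program, plant, rig, dt_s=config.dt_s,
                          horizon_s=config.duration_s + 60.0)
    violations: list[str] = []
    mb = plant.mass_balance_error()
    if mb > 1e-6:
        violations.append(f"mass balance error {mb:.3e} exceeds 1e-6")
    led = result.ledger
    pumped = plant.column.effluent["volume"]
    if abs((led.collected_volume + led.wasted_volume) - pumped) > 1e-6:
        violations.append("collected + wasted != pumped effluent")

    summary: dict[str, Any] = {
        "status": result.status,
        "final_time_h": result.final_time_s / 3600.0,
        "collected_volume_ml": led.collected_volume,
        "collected_amide_mmol": led.collected_amide,
        "window_count": led.window_count,
        "alerts": len(result.alerts),
        "mass_balance_error": mb,
    }
    if led.collected_volume + led.wasted_volume > 0:
        summary.update(ledger_summary(led))
    return CampaignReport(
        scenario="monitored_hydration",
        summary=summary,
        events=result.events,
        run_result=result,
        invariant_violations=violations,
    )


# ---------------------------------------------------------------------------
# Factorial hydrogenation campaign (scenario 2)
# ---------------------------------------------------------------------------

@dataclass
class DoeConfig:
    """Configuration of the automated factorial campaign.

    The default design is the three-factor, two-level, duplicated campaign:
    temperature 40/100 degC (10 degC grid), hydrogen mode 20 bar / full, flow
    0.1/0.2 mL/min -- 16 runs through a 9-port sampling valve, so two
    batches.  Each run holds its settings for ``steady_cv`` column volumes
    of the hydrogenation cartridge before sampling.
    """

    replicates: int = 2
    ports: int = 9
    steady_cv: float = 3.0
    cartridge_volume: float = 2.0  # mL dead volume of the hydrogenation unit
    response_noise: float = 0.0  # sigma on the simulated NMR integrals
    unit: HydrogenationUnit = field(default_factory=HydrogenationUnit)
    # reservoir feeding (optional): pause iterations while the buffer is low
    reservoir_fed: bool = False
    reservoir_capacity: float = 50.0
    reservoir_initial: float = 20.0
    reservoir_inflow: float = 0.05  # mL/min from the upstream step
    reservoir_low: float = 2.0


def default_factors(config: DoeConfig) -> list[Factor]:
    t_lo, t_hi = config.unit.temp_levels
    q_lo, q_hi = config.unit.flow_levels
    return [
        Factor("T", t_lo, t_hi),
        Factor("H", "20bar", "full"),
        Factor("Q", q_lo, q_hi),
    ]


def run_doe_campaign(
    config: DoeConfig | None = None,
    seed: int | None = None,
    integrals: pd.DataFrame | None = None,
) -> CampaignReport:
    """Execute the factorial campaign against the simulated hydrogenation unit.

    If ``integrals`` is given (columns run_id, I1, I2, I4, Ix) those rows are
    used as the measured NMR table instead of simulating the unit.  Returns
    effects tables and rankings for all four responses.
    """
    config = config or DoeConfig()
    factors = default_factors(config)
    if not factors:
        raise ControlError("empty design")
    design = full_factorial(factors, config.replicates, seed=seed, ports=config.ports)

    clock = SimClock()
    rig = Rig(clock)
    rig.register(pump("P2", max_flow=5.0))
    rig.register(
        column_heater("HC1", grid=config.unit.temp_grid)
    )
    rig.register(multiposition_valve("V2", ports=config.ports))
    rig.register(notifier("N2"))

    rng = np.random.default_rng(seed)
    events: list[dict[str, Any]] = []
    given = None
    if integrals is not None:
        given = {int(r.run_id): (r.I1, r.I2, r.I4, r.Ix) for r in integrals.itertuples()}

    reservoir = None
    if config.reservoir_fed:
        reservoir = Reservoir(config.reservoir_capacity, config.reservoir_initial,
                              low_mark=config.reservoir_low)
        reservoir.inflow_rate = config.reservoir_inflow

    for run in design.in_execution_order():
        t_set = rig.set_parameter("HC1", "temperature", run.settings["T"])
        q_set = rig.set_parameter("P2", "flow_rate", run.settings["Q"])
        settle_s = 60.0 * config.steady_cv * config.cartridge_volume / q_set

        if reservoir is not None:
            needed = q_set * settle_s / 60.0
            paused = 0.0
            while reservoir.volume < max(needed, reservoir.low_mark) and paused < 48 * 3600:
                reservoir.outflow_rate = 0.0
                reservoir.step(60.0)
                clock.advance(60.0)
                paused += 60.0
            if paused:
                events.append({"t": clock.now, "type": "iteration_pause",
                               "run_id": run.run_id, "paused_s": paused})
            reservoir.outflow_rate = q_set
            remaining = settle_s
            while remaining > 0:
                step = min(60.0, remaining)
                reservoir.step(step)
                clock.advance(step)
                remaining -= step
        else:
            clock.advance(settle_s)

        rig.switch_valve("V2", run.port)
        events.append({"t": clock.now, "type": "sample", "run_id": run.run_id,
                       "batch": run.batch, "port": run.port})
        if given is not None:
            i1, i2, i4, ix = given[run.run_id]
        else:
            i1, i2, i4, ix = config.unit.nmr_integrals(
                run.settings["T"], run.settings["H"], run.settings["Q"],
                noise_sigma=config.response_noise, rng=rng,
            )
        design.attach_response(run.run_id, compute_responses(i1, i2, i4, ix).to_dict())
        design.attach_response(run.run_id, {"I1": i1, "I2": i2, "I4": i4, "Ix": ix})

    tables: dict[str, pd.DataFrame] = {"design": design.to_frame()}
    rankings: dict[str, list[str]] = {}
    for resp in ("conversion", "yield_1", "impurity_4", "impurity_x"):
        est = estimate_effects(design, resp)
        tables[f"effects_{resp}"] = effects_frame(est)
        rankings[resp] = rank_factors(est)

    violations: list[str] = []
    expected_runs = config.replicates * 2 ** len(factors)
    if design.n_runs != expected_runs:
        violations.append(f"run count {design.n_runs} != {expected_runs}")

    summary: dict[str, Any] = {
        "n_runs": design.n_runs,
        "n_batches": design.n_batches,
        "rankings": rankings,
        "pauses": sum(1 for e in events if e["type"] == "iteration_pause"),
        "total_time_h": clock.now / 3600.0,
    }
    return CampaignReport(
        scenario="doe_campaign",
        summary=summary,
        events=events,
        tables=tables,
        invariant_violations=violations,
    )


# ---------------------------------------------------------------------------
# Reservoir-coupled two-step process (scenario 3)
# ---------------------------------------------------------------------------

VALID_PHASES = ("startup", "filling", "both_running", "step1_stopped",
                "draining", "finished")


@dataclass
class TwoStepState:
    """Live state of the coupled process."""

    phase: str = "startup"
    level_ml: float = 0.0
    step1_on: bool = True
    step2_on: bool = False
    step2_started: bool = False  # latched once the start level is first hit


@dataclass
class TwoStepConfig:
    """Configuration of the reservoir-coupled two-step run.

    Step 1 (hydration) feeds the reservoir at ``step1_flow`` once the IR
    threshold is crossed; step 2 (hydrogenation) withdraws at
    ``step2_flow``.  Step 2 starts once the level first reaches
    ``start_level`` and pauses below ``low_level``; step 1 stops when the
    reservoir is full and restarts when the level falls to
    ``restart_level``.  ``feed_volume`` (mL) bounds the total step-1 feed;
    ``None`` runs until ``horizon_s`` or ``stop_after_restarts``.
    """

    # step 1: the scaled 10 mm column (5 g catalyst, doubled water budget)
    void_volume: float = 4.0
    n_tanks: int = 20
    water_capacity: float = 2.16
    step1_flow: float = 0.2  # mL/min
    feed_nitrile: float = 0.06
    feed_water: float = 0.6
    # step 2
    step2_flow: float = 0.1  # mL/min
    unit: HydrogenationUnit = field(default_factory=HydrogenationUnit)
    step2_temperature: float = 100.0
    step2_h2_mode: str = "full"
    # reservoir
    capacity: float = 50.0
    start_level: float = 10.0
    low_level: float = 2.0
    restart_level: float = 2.0
    # execution
    dt_s: float = 2.0
    horizon_s: float = 48 * 3600.0
    feed_volume: float | None = None
    stop_after_restarts: int | None = None
    absorbance_threshold: float | None = None

    def validate(self) -> None:
        if not 0 <= self.start_level < self.capacity:
            raise ControlError("start level must lie inside [0, capacity)")
        if self.restart_level >= self.capacity:
            raise ControlError("restart level must be below capacity")
        if self.low_level >= self.start_level:
            raise ControlError("pause level must be below the start level")


def run_two_step(config: TwoStepConfig | None = None, seed: int | None = None) -> CampaignReport:
    """Execute the semi-continuous two-step process.

    Returns cycle statistics (fill time, drain time, period between step-1
    restarts) alongside the event log, ledger and invariant check results.
    """
    config = config or TwoStepConfig()
    config.validate()

    clock = SimClock(tick=config.dt_s)
    rig = Rig(clock)
    rig.register(pump("P1"))
    rig.register(pump("P2"))
    rig.register(binary_valve("V1"))
    rig.register(multiposition_valve("V2"))
    rig.register(column_heater("H1"))
    rig.register(ir_analyzer("IR1"))
    rig.register(camera("C1"))
    rig.register(notifier("N1"))

    bed = ColumnBed(config.void_volume, config.n_tanks, config.water_capacity)
    feed = FeedStream(config.step1_flow, config.feed_nitrile, config.feed_water)
    analyzer = AnalyzerModel()
    plant = HydrationPlant(bed, feed, analyzer=analyzer)
    reservoir = Reservoir(config.capacity, 0.0, low_mark=config.low_level)
    threshold = config.absorbance_threshold
    if threshold is None:
        threshold = 0.5 * analyzer.amide_factor * config.feed_nitrile

    state = TwoStepState()
    events: list[dict[str, Any]] = []
    violations: list[str] = []
    ledger = CollectionLedger()
    conv2 = (
        config.unit.response(
            config.step2_temperature, config.step2_h2_mode, config.step2_flow
        )[0]
        if config.step2_flow > 0
        else 0.0
    )

    wasted_amide = 0.0
    product_mmol = 0.0
    restart_times: list[float] = []
    stop_times: list[float] = []
    feed_left = config.feed_volume
    t = 0.0
    dt = config.dt_s

    def log(kind: str, **extra: Any) -> None:
        events.append({"t": t, "type": kind, **extra})

    while t < config.horizon_s and state.phase != "finished":
        # -- step 1: column feed gated by the on/off state and feed stock
        feed_exhausted = feed_left is not None and feed_left <= 1e-12
        run1 = state.step1_on and not feed_exhausted
        active_feed = feed if run1 else FeedStream(0.0, feed.nitrile, feed.water)
        slug = plant.step(t, dt) if active_feed.flow_rate > 0 else {
            "volume": 0.0, "nitrile": 0.0, "amide": 0.0, "water": 0.0}
        if run1 and feed_left is not None:
            feed_left -= slug["volume"]

        # -- routing: to reservoir once the IR threshold is crossed
        ir_now = plant.ir()["absorbance_1685"]
        to_reservoir = ir_now > threshold
        if to_reservoir and state.phase == "startup":
            state.phase = "filling"
            log("reservoir_fill_start")
        ledger.record(t, dt, slug, collecting=to_reservoir)
        if not to_reservoir:
            wasted_amide += slug["amide"]

        # -- reservoir + step 2 withdrawal
        reservoir.inflow_rate = (slug["volume"] / dt) * 60.0 if to_reservoir else 0.0
        reservoir.outflow_rate = config.step2_flow if state.step2_on else 0.0
        taken_before = reservoir.withdrawn["amide"]
        res_events = reservoir.step(dt, inflow_amide=slug["amide"] if to_reservoir else 0.0)
        product_mmol += (reservoir.withdrawn["amide"] - taken_before) * conv2
        for name in res_events:
            log(name, level_ml=reservoir.volume)
        state.level_ml = reservoir.volume
        t = clock.advance(dt)

        # -- state machine transitions (evaluated every tick)
        lvl = reservoir.volume
        if not state.step2_started and lvl >= config.start_level:
            state.step2_started = True
            state.step2_on = True
            state.phase = "both_running"
            log("step2_start", level_ml=lvl)
        elif state.step2_started:
            want2 = lvl > config.low_level or (state.step1_on and not feed_exhausted)
            if state.step2_on and not want2:
                state.step2_on = False
                log("step2_pause", level_ml=lvl)
            elif not state.step2_on and want2 and lvl > config.low_level:
                state.step2_on = True
                log("step2_resume", level_ml=lvl)

        if state.step1_on and lvl >= config.capacity - 1e-9:
            state.step1_on = False
            state.phase = "draining"
            stop_times.append(t)
            log("step1_stop", level_ml=lvl)
        elif not state.step1_on and lvl <= config.restart_level and not feed_exhausted:
            state.step1_on = True
            state.phase = "both_running" if state.step2_started else "filling"
            restart_times.append(t)
            log("step1_restart", level_ml=lvl)
            if (config.stop_after_restarts is not None
                    and len(restart_times) >= config.stop_after_restarts):
                break

        if feed_exhausted and lvl <= max(config.low_level, 1e-9) and state.step2_started:
            state.phase = "finished"
            state.step1_on = False
            state.step2_on = False
            log("finished", level_ml=lvl)

        if feed_exhausted and not state.step2_started:
            # degenerate: nothing will ever start step 2
            log("watchdog_stall", level_ml=lvl)
            break
        no_drain = (not state.step2_on) or config.step2_flow <= 0
        if not state.step1_on and no_drain and state.phase != "finished":
            # stalled: reservoir full but nothing draining it
            log("watchdog_stall", level_ml=lvl)
            break

        # -- per-tick invariant assertions (model check)
        if state.step2_on and not state.step2_started:
            violations.append(f"t={t}: step2 on before start level reached")
        if state.step1_on and lvl >= config.capacity - 1e-9:
            violations.append(f"t={t}: step1 on at full reservoir")
        if state.phase == "finished" and (state.step1_on or lvl > config.low_level + 1e-9):
            violations.append(f"t={t}: finished with step1 on or level high")

    # -- conservation: amide out of step 1 = waste + reservoir + withdrawn
    out_amide = plant.column.effluent["amide"]
    acc = wasted_amide + reservoir.amide_mmol + reservoir.withdrawn["amide"]
    if out_amide > 0 and abs(out_amide - acc) / out_amide > 1e-6:
        violations.append(
            f"amide conservation: step1 out {out_amide:.6f} != accounted {acc:.6f}"
        )

    periods = [b - a for a, b in zip(restart_times, restart_times[1:])]
    fill_times = [s - r for r, s in zip(restart_times, stop_times[1:])]
    drain_times = [r - s for s, r in zip(stop_times, restart_times)]
    summary: dict[str, Any] = {
        "final_time_h": t / 3600.0,
        "phase": state.phase,
        "level_ml": reservoir.volume,
        "restarts": len(restart_times),
        "cycle_period_h": periods[0] / 3600.0 if periods else None,
        "fill_time_h": fill_times[0] / 3600.0 if fill_times else None,
        "drain_time_h": drain_times[0] / 3600.0 if drain_times else None,
        "product_mmol": product_mmol,
        "intermediate_collected_mmol": ledger.collected_amide,
        "stalled": any(e["type"] == "watchdog_stall" for e in events),
    }
    return CampaignReport(
        scenario="two_step",
        summary=summary,
        events=events,
        invariant_violations=violations,
    )
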