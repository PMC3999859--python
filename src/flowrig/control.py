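"""Scripted control engine.

The engine executes a :class:`SequenceProgram` against a simulated plant and
rig on a shared virtual clock: device setpoints, timed waits, condition
waits, and parallel monitor branches evaluated every tick in deterministic
registration order.

Monitoring follows the process-analytical-technology pattern: effluent is
collected only while *all* monitored parameters are stable.  Two response
classes exist:

* **immediate** rules (the inline IR absorbance) flip the collect gate the
  same tick their predicate changes -- the absorbance reflects the current
  reactor output, so no settling margin is needed;
* **delayed** rules (pressure, temperature) keep blocking collection for a
  resume delay after their predicate recovers, because a transient could
  have compromised material still inside the column.  The conventional
  delay is one column volume, resolved as V/Q at the current flow.

Alerts are dispatched to a notifier device once per distinct fault onset
(no repeat spam while a fault persists).  All valve switches, alerts and
rule transitions are logged as JSON-serialisable events with stable field
order, so identical program + plant + seed reproduces a byte-identical
event log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

from .clock import SimClock
from .devices import COLLECT, WASTE, Notifier, Reading, Rig
from .simplant import ColumnBed, HydrationPlant, PlantError

ONE_COLUMN_VOLUME = "one_column_volume"


class ControlError(Exception):
    """Program validation or execution error."""


# ---------------------------------------------------------------------------
# Monitor rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonitorRule:
    """A predicate on one telemetry parameter plus its response class.

    ``predicate`` is one of ``above`` (value strictly greater than
    ``threshold`` is satisfied), ``below`` (strictly less), or ``within``
    (``low <= value <= high``).  ``response`` is ``immediate`` or
    ``delayed``; delayed rules need a ``resume_delay_s`` (seconds, or the
    symbolic :data:`ONE_COLUMN_VOLUME` resolved against the column at the
    current flow).  ``alert_severity`` set to a string makes violations
    dispatch a notifier message.
    """

    name: str
    device: str
    parameter: str
    predicate: str  # above | below | within
    threshold: float | None = None
    low: float | None = None
    high: float | None = None
    response: str = "immediate"
    resume_delay_s: float | str = 0.0
    alert_severity: str | None = None

    def __post_init__(self) -> None:
        if self.predicate not in ("above", "below", "within"):
            raise ControlError(f"unknown predicate {self.predicate!r}")
        if self.predicate == "within":
            if self.low is None or self.high is None or not (self.low < self.high):
                raise ControlError(f"rule {self.name!r}: within-band needs low < high")
        elif self.threshold is None or not math.isfinite(self.threshold):
            raise ControlError(f"rule {self.name!r}: finite threshold required")
        if self.response not in ("immediate", "delayed"):
            raise ControlError(f"unknown response class {self.response!r}")
        if self.response == "delayed" and not (
            self.resume_delay_s == ONE_COLUMN_VOLUME
            or (isinstance(self.resume_delay_s, (int, float)) and self.resume_delay_s >= 0)
        ):
            raise ControlError(f"rule {self.name!r}: unresolvable resume delay")

    def satisfied(self, value: float) -> bool:
        if self.predicate == "above":
            return value > self.threshold  # type: ignore[operator]
        if self.predicate == "below":
            return value < self.threshold  # type: ignore[operator]
        return self.low <= value <= self.high  # type: ignore[operator]


def resolve_column_volume_delay(bed: ColumnBed, flow_rate: float) -> float:
    """Seconds for one column volume to pass at ``flow_rate``: 60*V/Q."""
    if flow_rate <= 0:
        raise ControlError("cannot resolve a column-volume delay at zero flow")
    return 60.0 * bed.void_volume / flow_rate


@dataclass
class RuleStatus:
    """Per-rule state: satisfied, violated, or recovering until ``resume_at``."""

    state: str = "satisfied"  # satisfied | violated | recovering
    resume_at: float = 0.0


@dataclass
class StabilityState:
    """Snapshot of all rule statuses; collection is gated on all-satisfied."""

    statuses: dict[str, RuleStatus] = field(default_factory=dict)

    @property
    def collect_ok(self) -> bool:
        return all(s.state == "satisfied" for s in self.statuses.values())


class RuleEvaluator:
    """Stateful tick-by-tick evaluation of a set of monitor rules.

    Immediate rules track their predicate directly.  A delayed rule becomes
    ``violated`` the tick its predicate fails; when the predicate recovers it
    enters ``recovering`` and only returns to ``satisfied`` once the resume
    delay has fully elapsed, guaranteeing
    (resume time - recovery time) >= resume_delay in simulated time.
    """

    def __init__(
        self,
        rules: Sequence[MonitorRule],
        resolve_delay: Callable[[MonitorRule], float] | None = None,
    ):
        names = [r.name for r in rules]
        if len(names) != len(set(names)):
            raise ControlError("duplicate rule names")
        self.rules = list(rules)
        self._resolve = resolve_delay
        self.state = StabilityState(
            {r.name: RuleStatus() for r in self.rules}
        )
        self.transitions: list[dict[str, Any]] = []

    def _delay_of(self, rule: MonitorRule) -> float:
        if isinstance(rule.resume_delay_s, (int, float)):
            return float(rule.resume_delay_s)
        if self._resolve is None:
            raise ControlError(
                f"rule {rule.name!r} uses a symbolic delay but no resolver is attached"
            )
        return float(self._resolve(rule))

    def evaluate(self, readings: dict[tuple[str, str], float], t: float) -> StabilityState:
        """Update all rule statuses from the latest readings at time ``t``."""
        for rule in self.rules:
            key = (rule.device, rule.parameter)
            if key not in readings:
                raise ControlError(
                    f"rule {rule.name!r} references parameter {key} with no reading"
                )
            ok = rule.satisfied(readings[key])
            status = self.state.statuses[rule.name]
            prev = status.state
            if rule.response == "immediate":
                status.state = "satisfied" if ok else "violated"
            else:
                if not ok:
                    status.state = "violated"
                elif prev == "violated":
                    status.state = "recovering"
                    status.resume_at = t + self._delay_of(rule)
                if status.state == "recovering" and t >= status.resume_at:
                    status.state = "satisfied"
            if status.state != prev:
                self.transitions.append(
                    {"t": t, "type": "rule", "rule": rule.name,
                     "from": prev, "to": status.state}
                )
        return self.state


def evaluate_rules(
    rules: Sequence[MonitorRule],
    readings: Iterable[Reading],
    t: float,
    evaluator: RuleEvaluator | None = None,
) -> StabilityState:
    """One-shot rule evaluation over a batch of readings.

    Convenience wrapper: builds (or reuses) a :class:`RuleEvaluator`, feeds
    it the latest value per (device, parameter) and returns the resulting
    :class:`StabilityState`.
    """
    latest: dict[tuple[str, str], float] = {}
    for r in readings:
        latest[(r.device_id, r.parameter)] = r.value
    ev = evaluator or RuleEvaluator(rules)
    return ev.evaluate(latest, t)


# ---------------------------------------------------------------------------
# Alerts
# ---------------------------------------------------------------------------

class AlertDispatcher:
    """Deduplicating alert channel: one message per distinct fault onset."""

    def __init__(self, notifier: Notifier):
        self.notifier = notifier
        self._active: set[str] = set()
        self.dispatched: list[dict[str, Any]] = []

    def update(self, key: str, violated: bool, severity: str,
               device: str, parameter: str, text: str, t: float) -> dict[str, Any] | None:
        """Report the current violation state of ``key``; alert on onset only."""
        if violated and key not in self._active:
            self._active.add(key)
            msg = self.notifier.notify(severity, device, parameter, text, t)
            self.dispatched.append(msg)
            return msg
        if not violated:
            self._active.discard(key)
        return None


def dispatch_alert(notifier: Notifier, event: dict[str, Any]) -> dict[str, Any]:
    """Send a single alert message through the notifier device."""
    return notifier.notify(
        severity=event.get("severity", "warning"),
        device=event.get("device", ""),
        parameter=event.get("parameter", ""),
        text=event.get("text", ""),
        timestamp=event.get("t", 0.0),
    )


# ---------------------------------------------------------------------------
# Collection ledger
# ---------------------------------------------------------------------------

class CollectionLedger:
    """Accounting of effluent routed to product versus waste.

    Tracks cumulative volumes (mL) and moles of product (mmol) on each route
    plus the list of contiguous collect windows (start_s, end_s).
    """

    def __init__(self) -> None:
        self.collected_volume = 0.0
        self.wasted_volume = 0.0
        self.collected_amide = 0.0
        self.wasted_amide = 0.0
        self.windows: list[list[float]] = []
        self._open = False

    def record(self, t: float, dt_s: float, slug: dict[str, float], collecting: bool) -> None:
        """Route one effluent slug; extend or close the current window."""
        if collecting:
            self.collected_volume += slug.get("volume", 0.0)
            self.collected_amide += slug.get("amide", 0.0)
            if not self._open:
                self.windows.append([t, t + dt_s])
                self._open = True
            else:
                self.windows[-1][1] = t + dt_s
        else:
            self.wasted_volume += slug.get("volume", 0.0)
            self.wasted_amide += slug.get("amide", 0.0)
            self._open = False

    @property
    def window_count(self) -> int:
        return len(self.windows)


def ledger_summary(ledger: CollectionLedger) -> dict[str, float]:
    """Collected/wasted fractions of total pumped output plus window count."""
    total = ledger.collected_volume + ledger.wasted_volume
    if total <= 0:
        raise ControlError("no volume pumped; fractions undefined")
    return {
        "collected_fraction": ledger.collected_volume / total,
        "waste_fraction": ledger.wasted_volume / total,
        "window_count": ledger.window_count,
    }


# ---------------------------------------------------------------------------
# Sequence programs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetParameter:
    device: str
    parameter: str
    value: Any


@dataclass(frozen=True)
class SwitchValve:
    device: str
    position: Any


@dataclass(frozen=True)
class Wait:
    duration_s: float


@dataclass(frozen=True)
class WaitUntil:
    """Block until a telemetry predicate holds (checked every tick)."""

    device: str
    parameter: str
    predicate: str  # above | below
    threshold: float


@dataclass(frozen=True)
class Monitor:
    """Spawn parallel monitor branches: rules active until the program ends."""

    rules: tuple[MonitorRule, ...]


Step = SetParameter | SwitchValve | Wait | WaitUntil | Monitor


@dataclass
class SequenceProgram:
    """Ordered control steps plus the product valve the monitors drive."""

    steps: list[Step] = field(default_factory=list)
    collect_valve: str | None = None
    notifier: str | None = None

    def validate(self, rig: Rig) -> None:
        """Fail fast if any step or rule references an unregistered device."""
        for step in self.steps:
            for dev in _devices_of(step):
                if dev not in rig.devices:
                    raise ControlError(f"program references unknown device {dev!r}")
            if isinstance(step, Monitor):
                for rule in step.rules:
                    if rule.device not in rig.devices:
                        raise ControlError(
                            f"rule {rule.name!r} references unknown device {rule.device!r}"
                        )
                    rig[rule.device].spec(rule.parameter)
        for dev in (self.collect_valve, self.notifier):
            if dev is not None and dev not in rig.devices:
                raise ControlError(f"program references unknown device {dev!r}")


def _devices_of(step: Step) -> list[str]:
    if isinstance(step, (SetParameter, SwitchValve)):
        return [step.device]
    if isinstance(step, WaitUntil):
        return [step.device]
    return []


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of one program execution."""

    status: str  # completed | aborted
    ledger: CollectionLedger
    events: list[dict[str, Any]]
    telemetry: list[Reading]
    alerts: list[dict[str, Any]]
    final_time_s: float

    def events_jsonl(self) -> str:
        """Event log as JSON lines with stable field order."""
        return "\n".join(json.dumps(e, sort_keys=False) for e in self.events) + "\n"


def run_sequence(
    program: SequenceProgram,
    plant: HydrationPlant,
    rig: Rig,
    dt_s: float = 1.0,
    horizon_s: float = 24 * 3600.0,
    watchdog_s: float | None = None,
) -> RunResult:
    """Execute ``program`` against ``plant`` and ``rig`` on the shared clock.

    Every tick: the plant advances, sensors are polled, active monitor rules
    are evaluated in registration order, the product valve follows the
    collect gate, the effluent slug is routed per the valve position that was
    in force at the *start* of the tick (switches take effect on the next
    step), and alerts fire once per fault onset.

    ``wait_until`` steps that exceed ``watchdog_s`` (default: the horizon)
    abort the run with status ``"aborted"`` and a ``watchdog_abort`` event
    rather than dead-locking.
    """
    program.validate(rig)
    clock = rig.clock
    events: list[dict[str, Any]] = []
    ledger = CollectionLedger()
    evaluator: RuleEvaluator | None = None
    dispatcher = (
        AlertDispatcher(rig[program.notifier])  # type: ignore[arg-type]
        if program.notifier
        else None
    )
    watchdog = watchdog_s if watchdog_s is not None else horizon_s

    def resolve(rule: MonitorRule) -> float:
        return resolve_column_volume_delay(plant.column, plant.feed.flow_rate)

    step_iter = iter(program.steps)
    current: Step | None = next(step_iter, None)
    wait_deadline = 0.0
    wait_started = 0.0
    status = "completed"

    # Consume all instantaneous steps runnable at the current tick.
    def drain_instantaneous() -> None:
        nonlocal current, evaluator, wait_deadline, wait_started
        while current is not None:
            if isinstance(current, SetParameter):
                rig.set_parameter(current.device, current.parameter, current.value)
                events.append({"t": clock.now, "type": "set", "device": current.device,
                               "parameter": current.parameter, "value": current.value})
            elif isinstance(current, SwitchValve):
                ev = rig.switch_valve(current.device, current.position)
                events.append(ev)
            elif isinstance(current, Monitor):
                rules = list(evaluator.rules) if evaluator else []
                rules.extend(current.rules)
                evaluator = RuleEvaluator(rules, resolve_delay=resolve)
                events.append({"t": clock.now, "type": "monitor_spawn",
                               "rules": [r.name for r in current.rules]})
            elif isinstance(current, Wait):
                wait_deadline = clock.now + current.duration_s
                return
            elif isinstance(current, WaitUntil):
                wait_started = clock.now
                return
            current = next(step_iter, None)

    drain_instantaneous()
    prev_collect_ok: bool | None = None

    while current is not None and clock.now < horizon_s:
        valve_pos_at_tick_start = (
            rig[program.collect_valve].position if program.collect_valve else WASTE
        )
        slug = plant.step(clock.now, dt_s)
        clock.advance(dt_s)
        t = clock.now
        readings = rig.poll()
        latest = {(r.device_id, r.parameter): r.value for r in readings}

        if evaluator is not None:
            state = evaluator.evaluate(latest, t)
            events.extend(evaluator.transitions)
            evaluator.transitions.clear()
            # alerts on violation onsets
            if dispatcher is not None:
                for rule in evaluator.rules:
                    if rule.alert_severity is None:
                        continue
                    st = state.statuses[rule.name].state
                    msg = dispatcher.update(
                        key=rule.name,
                        violated=(st == "violated"),
                        severity=rule.alert_severity,
                        device=rule.device,
                        parameter=rule.parameter,
                        text=f"rule {rule.name} violated",
                        t=t,
                    )
                    if msg is not None:
                        events.append({"t": t, "type": "alert", "rule": rule.name,
                                       "severity": rule.alert_severity})
            # drive the product valve from the collect gate
            if program.collect_valve is not None:
                ok = state.collect_ok
                if ok != prev_collect_ok:
                    target = COLLECT if ok else WASTE
                    if rig[program.collect_valve].position != target:
                        events.append(rig.switch_valve(program.collect_valve, target))
                prev_collect_ok = ok

        ledger.record(t - dt_s, dt_s, slug, valve_pos_at_tick_start == COLLECT)

        # program progression
        if isinstance(current, Wait):
            if t >= wait_deadline - 1e-9:
                current = next(step_iter, None)
                drain_instantaneous()
        elif isinstance(current, WaitUntil):
            value = latest.get((current.device, current.parameter))
            met = value is not None and (
                value > current.threshold
                if current.predicate == "above"
                else value < current.threshold
            )
            if met:
                current = next(step_iter, None)
                drain_instantaneous()
            elif t - wait_started > watchdog:
                events.append({"t": t, "type": "watchdog_abort",
                               "waiting_on": f"{current.device}.{current.parameter}"})
                status = "aborted"
                break

    return RunResult(
        status=status,
        ledger=ledger,
        events=events,
        telemetry=rig.telemetry,
        alerts=dispatcher.dispatched if dispatcher else [],
        final_time_s=clock.now,
    )
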