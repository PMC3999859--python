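"""Device-class abstraction layer.

Every piece of apparatus on a rig -- pump, valve, heater, sensor, analyzer,
camera, notifier -- is described by a :class:`DeviceDescriptor` carrying one
:class:`ParameterSpec` per settable/readable parameter.  Simulated devices
and (hypothetical) hardware drivers are interchangeable behind this surface:
the control engine only ever calls :meth:`Rig.set_parameter`,
:meth:`Rig.poll` and :meth:`Rig.switch_valve`.

Setpoint semantics mirror real equipment: continuous parameters are clamped
to their declared range (as pumps do), discrete grids reject off-grid values
outright (a reactor whose column temperature is only settable in 10 degC
increments simply cannot express 95 degC), and every acknowledgement is
logged as a timestamped :class:`Reading` so the telemetry stream is a
complete record of what the rig was told and what it reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

from .clock import SimClock

DEVICE_CLASSES = frozenset(
    {"pump", "valve", "heater", "sensor", "analyzer", "camera", "notifier"}
)

#: Binary product valve positions.
COLLECT = "collect"
WASTE = "waste"


class RigError(Exception):
    """Base class for device-layer errors."""


class RegistrationError(RigError):
    """Duplicate or malformed device registration."""


class UnknownParameterError(RigError):
    """Parameter name not declared for the device."""


class GridValueError(RigError):
    """Requested value does not lie on a discrete parameter grid."""


class ValvePositionError(RigError):
    """Requested valve position is not available on the valve."""


@dataclass(frozen=True)
class ParameterSpec:
    """Declaration of one device parameter.

    ``kind`` is one of ``continuous`` (clamped to ``[minimum, maximum]``),
    ``discrete`` (value must lie exactly on ``grid``) or ``enumerated``
    (value must be a member of ``choices``).  Units are fixed here at
    registration; no runtime unit conversion is performed.
    """

    name: str
    units: str = ""
    kind: str = "continuous"
    minimum: float | None = None
    maximum: float | None = None
    grid: tuple[float, ...] = ()
    choices: tuple[Any, ...] = ()
    readable: bool = True
    settable: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete", "enumerated"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "continuous":
            if self.minimum is not None and self.maximum is not None:
                if not self.minimum < self.maximum:
                    raise ValueError("continuous range requires min < max")
        elif self.kind == "discrete":
            if not self.grid:
                raise ValueError("discrete grid must be non-empty")
            if list(self.grid) != sorted(self.grid):
                raise ValueError("discrete grid must be sorted")
        elif self.kind == "enumerated" and not self.choices:
            raise ValueError("enumerated parameter needs choices")

    def acknowledge(self, value: Any) -> Any:
        """Validate ``value``, returning the acknowledged (maybe clamped) value.

        Continuous values are clamped to the declared bounds; discrete values
        off the grid and enumerated values outside the choice set raise
        :class:`GridValueError` -- there is no silent rounding.
        """
        if self.kind == "continuous":
            v = float(value)
            if self.minimum is not None:
                v = max(v, self.minimum)
            if self.maximum is not None:
                v = min(v, self.maximum)
            return v
        if self.kind == "discrete":
            v = float(value)
            for g in self.grid:
                if abs(v - g) <= 1e-9:
                    return g
            raise GridValueError(
                f"{self.name}={value!r} is off the grid {list(self.grid)}"
            )
        if value not in self.choices:
            raise GridValueError(
                f"{self.name}={value!r} not in allowed set {list(self.choices)}"
            )
        return value


@dataclass(frozen=True)
class DeviceDescriptor:
    """Identity, class and parameter declarations of one device."""

    id: str
    device_class: str
    parameters: tuple[ParameterSpec, ...] = ()
    ports: int = 0  # multi-position valves only

    def __post_init__(self) -> None:
        if self.device_class not in DEVICE_CLASSES:
            raise ValueError(f"unknown device class {self.device_class!r}")
        names = [p.name for p in self.parameters]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate parameter names on device {self.id!r}")


@dataclass(frozen=True)
class Reading:
    """One timestamped telemetry sample: (device, parameter, value, units)."""

    device_id: str
    parameter: str
    timestamp: float  # simulated seconds
    value: float
    units: str = ""


class Device:
    """Runtime device instance: parameter values plus optional sensor bindings.

    A readable parameter may be *bound* to a zero-argument callable (usually a
    closure over the virtual plant); polling then samples that callable.
    Unbound parameters report the last value set.
    """

    def __init__(self, descriptor: DeviceDescriptor):
        self.descriptor = descriptor
        self._specs = {p.name: p for p in descriptor.parameters}
        self.values: dict[str, Any] = {}
        self._sources: dict[str, Callable[[], float]] = {}
        # Valve state
        if descriptor.device_class == "valve":
            self.position: Any = 1 if descriptor.ports else WASTE

    @property
    def id(self) -> str:
        return self.descriptor.id

    def spec(self, name: str) -> ParameterSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise UnknownParameterError(
                f"device {self.id!r} has no parameter {name!r}"
            ) from None

    def bind(self, name: str, source: Callable[[], float]) -> None:
        """Attach a simulated measurement source to a readable parameter."""
        self.spec(name)
        self._sources[name] = source

    def set(self, name: str, value: Any) -> Any:
        spec = self.spec(name)
        if not spec.settable:
            raise UnknownParameterError(f"{self.id}.{name} is read-only")
        ack = spec.acknowledge(value)
        self.values[name] = ack
        return ack

    def read(self, name: str) -> float:
        spec = self.spec(name)
        if name in self._sources:
            return float(self._sources[name]())
        return self.values.get(name, 0.0)

    def readable_parameters(self) -> list[str]:
        return [p.name for p in self.descriptor.parameters if p.readable]


class Notifier(Device):
    """Log-backed notifier standing in for an SMS gateway.

    Messages follow the schema {severity, device, parameter, text, timestamp}
    and are appended to an in-memory list (and optionally a text log file).
    """

    def __init__(self, descriptor: DeviceDescriptor, logfile: str | None = None):
        super().__init__(descriptor)
        self.messages: list[dict[str, Any]] = []
        self._logfile = logfile

    def notify(
        self,
        severity: str,
        device: str,
        parameter: str,
        text: str,
        timestamp: float,
    ) -> dict[str, Any]:
        msg = {
            "severity": severity,
            "device": device,
            "parameter": parameter,
            "text": text,
            "timestamp": timestamp,
        }
        self.messages.append(msg)
        if self._logfile:
            with open(self._logfile, "a", encoding="utf-8") as fh:
                fh.write(
                    f"{timestamp:.1f}\t{severity}\t{device}\t{parameter}\t{text}\n"
                )
        return msg


class Rig:
    """A registered collection of devices sharing one telemetry stream."""

    def __init__(self, clock: SimClock | None = None):
        self.clock = clock or SimClock()
        self.devices: dict[str, Device] = {}
        self.telemetry: list[Reading] = []
        self.events: list[dict[str, Any]] = []

    # -- registration ------------------------------------------------------
    def register(self, descriptor: DeviceDescriptor, **kwargs: Any) -> Device:
        if descriptor.id in self.devices:
            raise RegistrationError(f"device id {descriptor.id!r} already registered")
        cls = Notifier if descriptor.device_class == "notifier" else Device
        device = cls(descriptor, **kwargs)
        self.devices[descriptor.id] = device
        return device

    def __getitem__(self, device_id: str) -> Device:
        try:
            return self.devices[device_id]
        except KeyError:
            raise RigError(f"no device {device_id!r} on rig") from None

    def __len__(self) -> int:
        return len(self.devices)

    # -- setpoints ---------------------------------------------------------
    def set_parameter(self, device_id: str, name: str, value: Any) -> Any:
        """Set a parameter, log the acknowledgement, return it."""
        device = self[device_id]
        ack = device.set(name, value)
        units = device.spec(name).units
        if isinstance(ack, (int, float)):
            self.telemetry.append(
                Reading(device_id, name, self.clock.now, float(ack), units)
            )
        return ack

    # -- polling -----------------------------------------------------------
    def poll(self) -> list[Reading]:
        """Sample every readable parameter of every sensor/analyzer once.

        Returns one :class:`Reading` per readable parameter, stamped with the
        current simulated time, and appends them to the telemetry stream.
        """
        out: list[Reading] = []
        t = self.clock.now
        for device in self.devices.values():
            if device.descriptor.device_class not in ("sensor", "analyzer"):
                continue
            for name in device.readable_parameters():
                r = Reading(
                    device.id, name, t, device.read(name), device.spec(name).units
                )
                out.append(r)
        self.telemetry.extend(out)
        return out

    # -- valves ------------------------------------------------------------
    def switch_valve(self, valve_id: str, position: Any) -> dict[str, Any]:
        """Switch a valve; routing takes effect on the next simulation step.

        Switching to the current position is a logged no-op.  Binary valves
        accept ``"collect"``/``"waste"``; multi-position valves accept a port
        index in ``1..ports``.
        """
        valve = self[valve_id]
        if valve.descriptor.device_class != "valve":
            raise ValvePositionError(f"{valve_id!r} is not a valve")
        if valve.descriptor.ports:
            if not (isinstance(position, int) and 1 <= position <= valve.descriptor.ports):
                raise ValvePositionError(
                    f"port {position!r} outside 1..{valve.descriptor.ports}"
                )
        elif position not in (COLLECT, WASTE):
            raise ValvePositionError(f"binary valve position {position!r} invalid")
        event = {
            "t": self.clock.now,
            "type": "valve_switch",
            "device": valve_id,
            "from": valve.position,
            "to": position,
            "noop": position == valve.position,
        }
        valve.position = position
        self.events.append(event)
        return event

    # -- persistence -------------------------------------------------------
    def write_telemetry_csv(self, path: str) -> None:
        """Append-only CSV log: time_s, device, parameter, value, units."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "device", "parameter", "value", "units"])
            for r in self.telemetry:
                w.writerow([f"{r.timestamp:.3f}", r.device_id, r.parameter, r.value, r.units])


# -- spec-level operation aliases ------------------------------------------

def register_device(rig: Rig, descriptor: DeviceDescriptor, **kwargs: Any) -> Rig:
    """Register ``descriptor`` on ``rig`` and return the rig (fluent style)."""
    rig.register(descriptor, **kwargs)
    return rig


def set_parameter(rig: Rig, device_id: str, name: str, value: Any) -> Any:
    return rig.set_parameter(device_id, name, value)


def poll(rig: Rig) -> list[Reading]:
    return rig.poll()


def switch_valve(rig: Rig, valve_id: str, position: Any) -> dict[str, Any]:
    return rig.switch_valve(valve_id, position)


# -- convenience descriptor builders ---------------------------------------

def pump(pump_id: str, max_flow: float = 10.0) -> DeviceDescriptor:
    """Standard HPLC-style pump: continuous flow rate in mL/min, clamped."""
    return DeviceDescriptor(
        pump_id,
        "pump",
        (ParameterSpec("flow_rate", "mL/min", "continuous", 0.0, max_flow),),
    )


def binary_valve(valve_id: str) -> DeviceDescriptor:
    """Two-way product valve routing effluent to collect or waste."""
    return DeviceDescriptor(
        valve_id,
        "valve",
        (ParameterSpec("position", "", "enumerated", choices=(COLLECT, WASTE)),),
    )


def multiposition_valve(valve_id: str, ports: int = 9) -> DeviceDescriptor:
    """Sample-collection valve with ``ports`` numbered outlets."""
    return DeviceDescriptor(
        valve_id,
        "valve",
        (
            ParameterSpec(
                "position", "", "enumerated", choices=tuple(range(1, ports + 1))
            ),
        ),
        ports=ports,
    )


def column_heater(heater_id: str, grid: Iterable[float] = range(40, 110, 10)) -> DeviceDescriptor:
    """Heater whose setpoint lives on a 10 degC grid (no off-grid values)."""
    return DeviceDescriptor(
        heater_id,
        "heater",
        (ParameterSpec("temperature", "degC", "discrete", grid=tuple(float(g) for g in grid)),),
    )


def pressure_sensor(sensor_id: str) -> DeviceDescriptor:
    return DeviceDescriptor(
        sensor_id,
        "sensor",
        (ParameterSpec("pressure", "bar", "continuous", 0.0, 200.0, settable=False),),
    )


def temperature_sensor(sensor_id: str) -> DeviceDescriptor:
    return DeviceDescriptor(
        sensor_id,
        "sensor",
        (ParameterSpec("temperature", "degC", "continuous", -50.0, 400.0, settable=False),),
    )


def ir_analyzer(analyzer_id: str) -> DeviceDescriptor:
    """Inline IR flow cell reporting amide (1685 1/cm) and nitrile (2245 1/cm) bands."""
    return DeviceDescriptor(
        analyzer_id,
        "analyzer",
        (
            ParameterSpec("absorbance_1685", "AU", "continuous", settable=False),
            ParameterSpec("absorbance_2245", "AU", "continuous", settable=False),
        ),
    )


def camera(camera_id: str) -> DeviceDescriptor:
    return DeviceDescriptor(camera_id, "camera", ())


def notifier(notifier_id: str) -> DeviceDescriptor:
    return DeviceDescriptor(notifier_id, "notifier", ())
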