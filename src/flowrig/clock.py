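"""Virtual simulated clock.

All sequencing in the framework runs against a purely simulated clock: time
advances only when the engine steps it, so a 15-hour campaign executes in
seconds of wall time.  The ``accel`` knob exists for API symmetry with
hardware deployments (where it would throttle real sleeps); in simulation it
is ignored because no wall-clock waiting ever happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SimClock:
    """Monotone simulated clock, in seconds.

    Parameters
    ----------
    start : float
        Initial time in simulated seconds.
    tick : float
        Default step size in simulated seconds (1 s mirrors the once-a-second
        sensor interrogation cadence of the real rig).
    accel : float
        Acceleration factor relative to wall time.  Accepted for interface
        compatibility; purely-simulated runs never sleep.
    """

    start: float = 0.0
    tick: float = 1.0
    accel: float = float("inf")
    _now: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.tick <= 0:
            raise ValueError("tick must be positive")
        self._now = float(self.start)

    @property
    def now(self) -> float:
        """Current simulated time in seconds."""
        return self._now

    def advance(self, dt: float | None = None) -> float:
        """Advance the clock by ``dt`` seconds (default: one tick)."""
        step = self.tick if dt is None else float(dt)
        if step < 0:
            raise ValueError("cannot step the clock backwards")
        self._now += step
        return self._now
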