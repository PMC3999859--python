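"""Physics-lite virtual flow plant.

The simulator reproduces the handful of process dynamics the control logic
must cope with, and nothing more:

* **Dispersed plug flow** through a packed column, modelled as N ideal
  stirred tanks in series.  N controls front sharpness; the mean residence
  time is V/Q for any N, and breakthrough/elution fronts spread over about
  one column volume at the default N = 20.
* **Catalyst water-budget deactivation.**  Nitrile hydration to the amide is
  treated as instantaneous whenever water is available (free in the feed or
  bound on the catalyst).  On a dry feed the bed's bound-water reserve W is
  consumed stoichiometrically; when it runs out, conversion collapses --
  the breakthrough the monitoring system must detect.  An aqueous feed
  replenishes W up to its capacity W0.
* **Pressure faults.**  The system pressure sits at a nominal value unless a
  scheduled fault is active: an inlet air bubble collapses the reading below
  the low alarm and suspends column inflow until an explicit re-prime
  action; an over-pressure excursion pushes it above the high alarm.
* **A level reservoir** buffering two steps with unmatched flow rates.
* **A hydrogenation response surface**, linear in coded factors, standing in
  for the packed-cartridge hydrogenation reactor during factorial campaigns.

Units: volumes mL, flows mL/min, amounts mmol, concentrations mmol/mL (= M),
temperatures degC, pressures bar, time arguments in simulated seconds unless
a name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Sequence

import numpy as np


class PlantError(Exception):
    """Simulator configuration or stability error."""


# ---------------------------------------------------------------------------
# Feed and column
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeedStream:
    """Pumped inlet stream: flow rate and inlet concentrations.

    ``water`` is the *free* water concentration; 0 models a rigorously dry
    solvent feed.
    """

    flow_rate: float  # mL/min
    nitrile: float = 0.0  # mmol/mL
    water: float = 0.0  # mmol/mL

    def __post_init__(self) -> None:
        if self.flow_rate < 0 or self.nitrile < 0 or self.water < 0:
            raise PlantError("feed flow and concentrations must be non-negative")


class ColumnBed:
    """Packed catalyst bed as a cascade of N stirred tanks.

    Parameters
    ----------
    void_volume : float
        Interstitial (fluid) volume V of the bed in mL.  The 100 x 6.6 mm
        column holding 2.5 g of catalyst has V = 2.0 mL, giving the observed
        20 min residence time at 0.1 mL/min.
    n_tanks : int
        Number of tanks N in the dispersion cascade.  N = 20 reproduces a
        10-90% front rise of roughly one column volume.
    water_capacity : float
        Catalyst bound-water capacity W0 in mmol, spread uniformly across the
        tanks.  1.08 mmol for the 2.5 g bed makes a dry 0.06 M feed at
        0.1 mL/min deplete the bed after ~3 h; scales linearly with bed mass.
    temperature : float
        Bed temperature in degC.  At or above ``full_conversion_temp`` the
        hydration is quantitative; below it, conversion is scaled by
        ``low_temp_efficiency`` (a coarse nod to the fact that shorter
        residence/lower temperature gives partial conversion).
    """

    def __init__(
        self,
        void_volume: float = 2.0,
        n_tanks: int = 20,
        water_capacity: float = 1.08,
        temperature: float = 100.0,
        full_conversion_temp: float = 100.0,
        low_temp_efficiency: float = 0.5,
    ):
        if void_volume <= 0:
            raise PlantError("void volume must be positive")
        if n_tanks < 1:
            raise PlantError("need at least one tank")
        if water_capacity < 0:
            raise PlantError("water capacity must be non-negative")
        self.void_volume = float(void_volume)
        self.n_tanks = int(n_tanks)
        self.water_capacity = float(water_capacity)
        self.temperature = float(temperature)
        self.full_conversion_temp = float(full_conversion_temp)
        self.low_temp_efficiency = float(low_temp_efficiency)

        n = self.n_tanks
        self.tank_volume = self.void_volume / n
        # per-tank fluid-phase concentrations, mmol/mL
        self.nitrile = np.zeros(n)
        self.amide = np.zeros(n)
        self.water = np.zeros(n)
        # per-tank catalyst-bound water, mmol
        self.cat_water = np.full(n, self.water_capacity / n)
        # cumulative ledgers, mmol / mL
        self.fed = {"volume": 0.0, "nitrile": 0.0, "water": 0.0}
        self.effluent = {"volume": 0.0, "nitrile": 0.0, "amide": 0.0, "water": 0.0}

    # -- state inspection --------------------------------------------------
    @property
    def bound_water(self) -> float:
        """Total catalyst-bound water W remaining, mmol."""
        return float(self.cat_water.sum())

    def outlet(self) -> dict[str, float]:
        """Fluid-phase concentrations in the last tank (mmol/mL)."""
        return {
            "nitrile": float(self.nitrile[-1]),
            "amide": float(self.amide[-1]),
            "water": float(self.water[-1]),
        }

    def holdup(self) -> dict[str, float]:
        """Moles of each species held in the bed fluid phase (mmol)."""
        vt = self.tank_volume
        return {
            "nitrile": float(self.nitrile.sum() * vt),
            "amide": float(self.amide.sum() * vt),
            "water": float(self.water.sum() * vt),
        }

    def conversion(self) -> float:
        """Outlet conversion: amide / (amide + nitrile); 0 if both zero."""
        a, n = self.amide[-1], self.nitrile[-1]
        tot = a + n
        return float(a / tot) if tot > 0 else 0.0

    def stability_limit_s(self, flow_rate: float) -> float:
        """Largest stable step, seconds: transfer per step must stay < V/N."""
        if flow_rate <= 0:
            return math.inf
        return 60.0 * self.tank_volume / flow_rate

    # -- dynamics ----------------------------------------------------------
    def step(self, feed: FeedStream, dt_s: float) -> dict[str, float]:
        """Advance the cascade by ``dt_s`` simulated seconds.

        Explicit upwind transfer of ``Q*dt`` followed by reaction to
        equilibrium in each tank.  Returns the effluent slug leaving the
        column during the step: ``{"volume", "nitrile", "amide", "water"}``
        (mL and mmol).  Raises :class:`PlantError` if the step violates the
        stability criterion ``Q*dt < V/N``.
        """
        if dt_s <= 0:
            raise PlantError("dt must be positive")
        q = feed.flow_rate * dt_s / 60.0  # mL transferred this step
        vt = self.tank_volume
        if q >= vt:
            raise PlantError(
                f"step {dt_s} s unstable: transfer {q:.4g} mL >= tank volume {vt:.4g} mL"
            )

        out = {"volume": q, "nitrile": 0.0, "amide": 0.0, "water": 0.0}
        if q > 0.0:
            # effluent leaves from the last tank at pre-update concentration
            out["nitrile"] = q * float(self.nitrile[-1])
            out["amide"] = q * float(self.amide[-1])
            out["water"] = q * float(self.water[-1])
            frac = q / vt
            for arr, inlet in (
                (self.nitrile, feed.nitrile),
                (self.amide, 0.0),
                (self.water, feed.water),
            ):
                upstream = np.empty_like(arr)
                upstream[0] = inlet
                upstream[1:] = arr[:-1]
                arr += frac * (upstream - arr)
            self.fed["volume"] += q
            self.fed["nitrile"] += q * feed.nitrile
            self.fed["water"] += q * feed.water
            self.effluent["volume"] += out["volume"]
            self.effluent["nitrile"] += out["nitrile"]
            self.effluent["amide"] += out["amide"]
            self.effluent["water"] += out["water"]

        self._react()
        return out

    def _react(self) -> None:
        """Hydrate nitrile to amide 1:1 against free + bound water, per tank.

        Free water is consumed before bound water; leftover free water then
        replenishes the catalyst up to its per-tank capacity.
        """
        vt = self.tank_volume
        eff = (
            1.0
            if self.temperature >= self.full_conversion_temp
            else self.low_temp_efficiency
        )
        cap = self.water_capacity / self.n_tanks
        n_mmol = self.nitrile * vt
        w_free = self.water * vt
        avail = w_free + self.cat_water
        react = np.minimum(n_mmol * eff, avail)
        from_free = np.minimum(react, w_free)
        from_bound = react - from_free
        n_mmol -= react
        w_free -= from_free
        self.cat_water -= from_bound
        # replenish catalyst from excess free water
        refill = np.minimum(w_free, cap - self.cat_water)
        w_free -= refill
        self.cat_water += refill
        self.nitrile = n_mmol / vt
        self.amide += react / vt
        self.water = w_free / vt
        np.clip(self.cat_water, 0.0, cap, out=self.cat_water)


def step_column(bed: ColumnBed, feed: FeedStream, dt_s: float) -> ColumnBed:
    """Advance ``bed`` by one step (mutating) and return it."""
    bed.step(feed, dt_s)
    return bed


def mean_residence_time(bed: ColumnBed, flow_rate: float, dt_s: float | None = None) -> float:
    """Mean residence time in minutes: first moment of the tracer response.

    Simulates a unit tracer impulse through a cascade with the bed's geometry
    (V, N) at ``flow_rate`` and integrates the outlet response.  The first
    temporal moment of a tanks-in-series cascade equals V/Q regardless of N;
    this routine measures it rather than assuming it.
    """
    if flow_rate <= 0:
        raise PlantError("residence time undefined at zero flow")
    n = bed.n_tanks
    vt = bed.tank_volume
    if dt_s is None:
        dt_s = 0.2 * 60.0 * vt / flow_rate  # 20% of a tank turnover
    q = flow_rate * dt_s / 60.0
    frac = q / vt
    if frac >= 1.0:
        raise PlantError("tracer step unstable")
    c = np.zeros(n)
    c[0] = 1.0 / vt  # unit impulse in tank 1 at t = 0
    tau = bed.void_volume / flow_rate  # minutes
    horizon = int(math.ceil((tau * 60.0 / dt_s) * (5.0 + 40.0 / n)))
    mass = 0.0
    moment = 0.0
    for k in range(1, horizon + 1):
        out = q * c[-1]
        t = k * dt_s
        mass += out
        moment += out * t
        upstream = np.empty_like(c)
        upstream[0] = 0.0
        upstream[1:] = c[:-1]
        c += frac * (upstream - c)
    if mass <= 0:
        raise PlantError("tracer never eluted within the horizon")
    return (moment / mass) / 60.0  # minutes


def sustained_conversion_window(
    bed: ColumnBed,
    feed: FeedStream,
    dt_s: float = 10.0,
    horizon_s: float = 8 * 3600.0,
) -> tuple[float, float]:
    """(rise_s, fall_s): the sustained full-conversion plateau boundaries.

    Runs the bed on ``feed`` and returns the times at which the outlet amide
    concentration rises through and later falls back through 50% of the
    full-conversion plateau (the feed nitrile concentration).  The window
    ``fall - rise`` is the duration of sustained quantitative conversion;
    on a dry feed the fall marks catalytic breakthrough.  Raises
    :class:`PlantError` if either crossing never happens within the horizon.
    """
    if feed.nitrile <= 0:
        raise PlantError("feed must carry nitrile to define conversion")
    half = 0.5 * feed.nitrile
    rise = fall = None
    t = 0.0
    while t < horizon_s:
        bed.step(feed, dt_s)
        t += dt_s
        a = bed.amide[-1]
        if rise is None:
            if a >= half:
                rise = t
        elif a < half:
            fall = t
            break
    if rise is None or fall is None:
        raise PlantError("plateau crossings not observed within the horizon")
    return rise, fall


# ---------------------------------------------------------------------------
# Inline IR analyzer
# ---------------------------------------------------------------------------

@dataclass
class AnalyzerModel:
    """Two-channel IR readout of the column outlet.

    The 1685 1/cm channel tracks the amide carbonyl, the 2245 1/cm channel
    the nitrile stretch; each is the outlet concentration scaled by a
    response factor (AU per mmol/mL) plus optional Gaussian noise.
    """

    amide_factor: float = 10.0
    nitrile_factor: float = 10.0
    noise_sigma: float = 0.0
    rng: np.random.Generator | None = None

    def readout(self, outlet: dict[str, float]) -> dict[str, float]:
        a = self.amide_factor * outlet.get("amide", 0.0)
        n = self.nitrile_factor * outlet.get("nitrile", 0.0)
        if self.noise_sigma > 0:
            rng = self.rng if self.rng is not None else np.random.default_rng()
            a += rng.normal(0.0, self.noise_sigma)
            n += rng.normal(0.0, self.noise_sigma)
        return {"absorbance_1685": a, "absorbance_2245": n}


def analyzer_readout(
    bed: ColumnBed, analyzer: AnalyzerModel | None = None
) -> dict[str, float]:
    """IR channels for the bed's current outlet concentrations."""
    return (analyzer or AnalyzerModel()).readout(bed.outlet())


# ---------------------------------------------------------------------------
# Pressure and faults
# ---------------------------------------------------------------------------

FAULT_KINDS = ("bubble_loss", "over_pressure")


@dataclass(frozen=True)
class Fault:
    """One scheduled fault: onset time (s), kind, optional fixed duration.

    A ``bubble_loss`` with ``duration_s=None`` persists until an explicit
    re-prime action clears it, mirroring a pump that must be manually
    re-primed.
    """

    start_s: float
    kind: str
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in FAULT_KINDS:
            raise PlantError(f"unknown fault kind {self.kind!r}")

    def end_s(self) -> float:
        return math.inf if self.duration_s is None else self.start_s + self.duration_s


class PressureModel:
    """System pressure: nominal unless a scheduled fault is active.

    Defaults (nominal 8 bar, low alarm 2 bar, high alarm 15 bar) are
    conventions of this simulator, overridable in config.  A bubble collapses
    the reading to ``bubble_pressure`` (below the low alarm) and suspends
    column inflow; over-pressure pushes it to ``over_pressure_value``.
    """

    def __init__(
        self,
        nominal: float = 8.0,
        low_alarm: float = 2.0,
        high_alarm: float = 15.0,
        bubble_pressure: float = 0.5,
        over_pressure_value: float = 18.0,
    ):
        self.nominal = nominal
        self.low_alarm = low_alarm
        self.high_alarm = high_alarm
        self.bubble_pressure = bubble_pressure
        self.over_pressure_value = over_pressure_value
        self.faults: list[Fault] = []
        self.re_primes: list[float] = []  # operator re-prime action times

    def schedule(self, faults: Iterable[Fault]) -> None:
        """Add faults, rejecting overlapping windows on this sensor."""
        new = sorted([*self.faults, *faults], key=lambda f: f.start_s)
        for a, b in zip(new, new[1:]):
            if b.start_s < a.end_s():
                raise PlantError(
                    f"overlapping faults at t={a.start_s} and t={b.start_s}"
                )
        self.faults = new

    def re_prime(self, t: float) -> None:
        """Operator re-prime at time ``t``: ends any bubble active then.

        May be called ahead of time (a scheduled manual intervention) or
        live; pressure is restored from the next reading after ``t``.
        """
        self.re_primes.append(float(t))

    def _is_active(self, f: Fault, t: float) -> bool:
        if t < f.start_s:
            return False
        end = f.end_s()
        if f.kind == "bubble_loss":
            cleared = [rp for rp in self.re_primes if rp >= f.start_s]
            if cleared:
                end = min(end, min(cleared))
        return t < end

    def active_fault(self, t: float) -> Fault | None:
        for f in self.faults:
            if self._is_active(f, t):
                return f
        return None

    def reading(self, t: float) -> float:
        f = self.active_fault(t)
        if f is None:
            return self.nominal
        if f.kind == "bubble_loss":
            return self.bubble_pressure
        return self.over_pressure_value

    def flow_suspended(self, t: float) -> bool:
        f = self.active_fault(t)
        return f is not None and f.kind == "bubble_loss"


# ---------------------------------------------------------------------------
# Reservoir
# ---------------------------------------------------------------------------

class Reservoir:
    """Intermediate buffer vessel between two flow steps.

    Volume integrates (inflow - outflow) and is clamped to [0, capacity].
    Crossing the configured marks emits level events; an attempted overflow
    caps the volume and emits ``overflow_risk``.
    """

    def __init__(
        self,
        capacity: float = 50.0,
        volume: float = 0.0,
        high_mark: float | None = None,
        low_mark: float = 2.0,
    ):
        if not 0 <= volume <= capacity:
            raise PlantError("initial volume outside [0, capacity]")
        self.capacity = float(capacity)
        self.volume = float(volume)
        self.high_mark = float(high_mark) if high_mark is not None else 0.9 * capacity
        self.low_mark = float(low_mark)
        self.inflow_rate = 0.0  # mL/min
        self.outflow_rate = 0.0  # mL/min
        # moles of intermediate in the vessel, for end-to-end accounting
        self.amide_mmol = 0.0
        self.withdrawn = {"volume": 0.0, "amide": 0.0}

    def concentration(self) -> float:
        return self.amide_mmol / self.volume if self.volume > 0 else 0.0

    def step(
        self,
        dt_s: float,
        inflow_amide: float = 0.0,
    ) -> list[str]:
        """Advance the level by ``dt_s``; returns crossing events.

        ``inflow_amide`` is the mmol of intermediate carried by this step's
        inflow.  Withdrawal removes material at the vessel concentration.
        Events: ``high_level``, ``low_level``, ``overflow_risk``, ``empty``.
        """
        if dt_s <= 0:
            raise PlantError("dt must be positive")
        dt_min = dt_s / 60.0
        v0 = self.volume
        vin = self.inflow_rate * dt_min
        vout_req = self.outflow_rate * dt_min
        vout = min(vout_req, v0 + vin)  # cannot withdraw what is not there
        conc = self.amide_mmol / v0 if v0 > 0 else 0.0
        taken = min(vout * conc, self.amide_mmol)
        self.amide_mmol += inflow_amide - taken
        self.withdrawn["volume"] += vout
        self.withdrawn["amide"] += taken
        v1 = v0 + vin - vout
        events: list[str] = []
        if v1 > self.capacity:
            events.append("overflow_risk")
            v1 = self.capacity
        if v0 < self.high_mark <= v1:
            events.append("high_level")
        if v0 > self.low_mark >= v1:
            events.append("low_level")
        if v0 > 0.0 and v1 <= 1e-12:
            events.append("empty")
            v1 = 0.0
        self.volume = v1
        return events


def step_reservoir(reservoir: Reservoir, dt_s: float, inflow_amide: float = 0.0) -> tuple[Reservoir, list[str]]:
    """Advance ``reservoir`` (mutating); returns it with any level events."""
    events = reservoir.step(dt_s, inflow_amide)
    return reservoir, events


# ---------------------------------------------------------------------------
# Hydrogenation response surface
# ---------------------------------------------------------------------------

H2_MODES = ("20bar", "full")


@dataclass
class HydrogenationUnit:
    """Packed-cartridge hydrogenation reactor as a coded-factor surface.

    Factors and their physical levels (low / high -> coded -1 / +1):

    * temperature, degC, settable only on a 10 degC grid (40 / 100)
    * hydrogen mode, ``"20bar"`` / ``"full"`` (categorical, no bar scale)
    * flow rate, mL/min (0.1 / 0.2)

    Responses are linear in the coded factors with configurable
    coefficients.  The defaults encode the qualitative structure of the real
    reaction: hydrogen mode dominates conversion, while high temperature and
    low flow shrink the partially-reduced (tetrahydro) impurity fraction.
    Outputs are clamped to [0, 1] and the product fractions sum to at most
    the conversion.
    """

    temp_grid: tuple[float, ...] = tuple(float(t) for t in range(40, 110, 10))
    temp_levels: tuple[float, float] = (40.0, 100.0)
    flow_levels: tuple[float, float] = (0.1, 0.2)
    # conversion = b0 + bT*xT + bH*xH + bQ*xQ
    conv_coeffs: dict[str, float] = field(
        default_factory=lambda: {"intercept": 0.72, "T": 0.05, "H": 0.18, "Q": -0.03}
    )
    # tetrahydro intermediate fraction
    frac4_coeffs: dict[str, float] = field(
        default_factory=lambda: {"intercept": 0.08, "T": -0.035, "H": -0.01, "Q": 0.025}
    )
    other_fraction: float = 0.02

    def code(self, temperature: float, h2_mode: str, flow_rate: float) -> tuple[float, float, float]:
        """Map physical settings to coded (-1, +1) factor levels.

        Raises :class:`PlantError` for settings off the allowed grids.
        """
        if not any(abs(temperature - g) <= 1e-9 for g in self.temp_grid):
            raise PlantError(f"temperature {temperature} not on the 10 degC grid")
        if h2_mode not in H2_MODES:
            raise PlantError(f"hydrogen mode {h2_mode!r} not in {H2_MODES}")
        t_lo, t_hi = self.temp_levels
        q_lo, q_hi = self.flow_levels
        if not (min(q_lo, q_hi) - 1e-9 <= flow_rate <= max(q_lo, q_hi) + 1e-9):
            raise PlantError(f"flow {flow_rate} outside [{q_lo}, {q_hi}] mL/min")
        xt = (2.0 * temperature - (t_lo + t_hi)) / (t_hi - t_lo)
        xh = 1.0 if h2_mode == "full" else -1.0
        xq = (2.0 * flow_rate - (q_lo + q_hi)) / (q_hi - q_lo)
        return xt, xh, xq

    def response(
        self, temperature: float, h2_mode: str, flow_rate: float
    ) -> tuple[float, float, float, float]:
        """(conversion, fraction_1, fraction_4, fraction_other) at a setting."""
        xt, xh, xq = self.code(temperature, h2_mode, flow_rate)

        def surface(c: dict[str, float]) -> float:
            return c["intercept"] + c["T"] * xt + c["H"] * xh + c["Q"] * xq

        conv = min(1.0, max(0.0, surface(self.conv_coeffs)))
        f4 = min(conv, max(0.0, surface(self.frac4_coeffs)))
        fo = min(conv - f4, max(0.0, self.other_fraction))
        f1 = conv - f4 - fo
        return conv, f1, f4, fo

    def nmr_integrals(
        self,
        temperature: float,
        h2_mode: str,
        flow_rate: float,
        noise_sigma: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, float, float, float]:
        """Relative NMR integrals (I1, I2, I4, Ix) for a steady-state sample.

        I1 = fully-reduced product, I2 = residual starting amide,
        I4 = tetrahydro intermediate, Ix = unidentified byproduct; optional
        multiplicative-free Gaussian noise models integration error.
        """
        conv, f1, f4, fo = self.response(temperature, h2_mode, flow_rate)
        vals = np.array([f1, 1.0 - conv, f4, fo])
        if noise_sigma > 0:
            rng = rng if rng is not None else np.random.default_rng()
            vals = np.clip(vals + rng.normal(0.0, noise_sigma, 4), 0.0, None)
        return tuple(float(v) for v in vals)  # type: ignore[return-value]


def hydrogenation_response(
    unit: HydrogenationUnit, temperature: float, h2_mode: str, flow_rate: float
) -> tuple[float, float, float, float]:
    """Module-level alias for :meth:`HydrogenationUnit.response`."""
    return unit.response(temperature, h2_mode, flow_rate)


# ---------------------------------------------------------------------------
# Assembled plant
# ---------------------------------------------------------------------------

class HydrationPlant:
    """Column + feed + pressure + analyzer wired together for one step.

    ``step(t, dt_s)`` advances the column by one tick with the feed gated by
    any active bubble fault (inlet flow suspended) and records the effluent
    slug for routing by the control layer.
    """

    def __init__(
        self,
        column: ColumnBed,
        feed: FeedStream,
        pressure: PressureModel | None = None,
        analyzer: AnalyzerModel | None = None,
    ):
        self.column = column
        self.feed = feed
        self.pressure = pressure or PressureModel()
        self.analyzer = analyzer or AnalyzerModel()
        self.last_outlet: dict[str, float] = {
            "volume": 0.0, "nitrile": 0.0, "amide": 0.0, "water": 0.0
        }
        self.pumped_volume = 0.0

    def effective_feed(self, t: float) -> FeedStream:
        if self.pressure.flow_suspended(t) or self.feed.flow_rate == 0:
            return replace(self.feed, flow_rate=0.0)
        return self.feed

    def step(self, t: float, dt_s: float) -> dict[str, float]:
        feed = self.effective_feed(t)
        out = self.column.step(feed, dt_s)
        self.last_outlet = out
        self.pumped_volume += feed.flow_rate * dt_s / 60.0
        return out

    def ir(self) -> dict[str, float]:
        return self.analyzer.readout(self.column.outlet())

    def mass_balance_error(self) -> float:
        """Relative organic (nitrile + amide) imbalance: fed vs out + holdup."""
        fed = self.column.fed["nitrile"]
        held = self.column.holdup()
        out = self.column.effluent
        total = out["nitrile"] + out["amide"] + held["nitrile"] + held["amide"]
        if fed == 0:
            return abs(total)
        return abs(total - fed) / fed


def inject_fault(plant: HydrationPlant, schedule: Sequence[Fault | dict[str, Any]]) -> HydrationPlant:
    """Attach a fault schedule to the plant's pressure model.

    Accepts :class:`Fault` objects or dicts with keys ``start_s``/``time_s``,
    ``kind``/``fault_type`` and optional ``duration_s``.  Entries of kind
    ``re_prime`` schedule the corresponding operator action instead of a
    fault.  Overlapping faults raise :class:`PlantError`.
    """
    faults = []
    for item in schedule:
        if isinstance(item, Fault):
            faults.append(item)
            continue
        kind = str(item.get("kind", item.get("fault_type")))
        start = float(item.get("start_s", item.get("time_s")))
        if kind == "re_prime":
            plant.pressure.re_prime(start)
            continue
        faults.append(
            Fault(
                start_s=start,
                kind=kind,
                duration_s=(
                    float(item["duration_s"]) if item.get("duration_s") is not None else None
                ),
            )
        )
    plant.pressure.schedule(faults)
    return plant
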