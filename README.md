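# flowrig

A desk-testable automation framework for multi-device continuous-flow
chemistry.

Research-scale flow syntheses increasingly chain together equipment from
different vendors — pumps, packed-bed column reactors, hydrogenation units,
inline IR flow cells, switching valves, cameras — and the control problem is
less about any single instrument than about coordinating all of them:
collecting product only while every monitored parameter is stable, diverting
to waste and alerting the operator on a pressure fault, pausing one step
while a buffer reservoir refills, and grinding through the repetitive runs of
a factorial optimisation campaign overnight.

`flowrig` provides that coordination layer as an importable Python library,
and pairs it with a physics-lite **virtual flow plant** so every control
pathway — including the failure pathways — can be exercised and tested
entirely at a desk. The plant reproduces the dynamics of a two-step
nitrile-hydration / ring-hydrogenation process:

- **Dispersed plug flow** through a packed column as *N* tanks in series:
  the mean residence time is V/Q for any *N* (2.0 mL at 0.1 mL min⁻¹ → 20 min),
  and composition fronts spread over about one column volume.
- **Catalyst water-budget breakthrough**: hydration of the nitrile to the
  amide is water-limited. On a dry feed the bed's bound-water reserve W₀ is
  consumed stoichiometrically and conversion collapses after
  W₀ / (C_N · Q) of sustained operation (1.08 mmol at 0.06 M, 0.1 mL min⁻¹
  → 3 h); an aqueous feed sustains conversion indefinitely.
- **Pressure faults**: an inlet air bubble collapses the pressure reading
  below the low alarm and suspends flow until an explicit re-prime.
- **A 50 mL buffer reservoir** coupling two steps with unmatched flow rates,
  its level read by a camera watching a green float.
- **A hydrogenation response surface**, linear in coded factors, for
  factorial campaign machinery (effects, pooled standard errors, rankings).

## Worked example

`examples/fault_handling.py` runs the monitored hydration with an air
bubble injected at 1.5 h and the pump re-primed six minutes later:

```text
run status:        completed after 3.0 h
alerts dispatched: 1 (one per fault onset, no spam)
collect windows:   2 (fault splits collection in two)
collected:         13.4 mL (77% of pumped output)
product secured:   0.79 mmol amide
  window 0.33 -> 1.50 h
  window 1.93 -> 3.00 h
```

Collection starts at 0.33 h, when the amide front (one column volume plus
dispersion) crosses the IR threshold; the fault cuts it at exactly 1.5 h;
and it resumes at 1.93 h — re-prime at 1.6 h plus a one-column-volume delay
(V/Q = 20 min), because a pressure transient may have compromised material
still inside the bed. One SMS-style alert is logged at fault onset, none
while it persists.

Other examples, one per capability: `residence_time.py`, `breakthrough.py`,
`doe_campaign.py` (16-run duplicated 2³ campaign through a 9-port sampling
valve, hydrogen mode ranked most influential for conversion),
`two_step_cycle.py` (16 h reservoir fill–drain cycle), `level_sensing.py`
(float detection within its own radius despite clutter and noise).

A thin CLI mirrors the scenarios for shell use:

```bash
flowrig hydration --config cfg.yaml --faults faults.csv --seed 1 --out out/
flowrig doe --seed 1 --out out/
flowrig twostep --seed 1 --out out/
flowrig vision frame.ppm --calibration cal.csv
```

Each subcommand writes `report.json`, `events.jsonl` (byte-reproducible
under a fixed seed) and CSV tables, and exits non-zero if any run-time
invariant (mass balance, collect-gate safety, state-machine rules) was
violated.

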