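"""Automated two-level factorial hydrogenation campaign.

Generates the duplicated 2^3 design (temperature 40/100 degC, hydrogen mode
20 bar/full, flow 0.1/0.2 mL/min -> 16 runs), executes it against the
simulated hydrogenation unit through a 9-port sampling valve, computes the
four responses from the NMR integral rows and ranks the factor effects.
"""

from flowrig import DoeConfig, run_doe_campaign

report = run_doe_campaign(DoeConfig(), seed=0)

print(f"runs executed: {report.summary['n_runs']} "
      f"in {report.summary['n_batches']} valve batches")
print(f"campaign time: {report.summary['total_time_h']:.1f} h simulated\n")

print("conversion effects (effect = mean at +1 minus mean at -1):")
print(report.tables["effects_conversion"][["term", "estimate"]]
      .to_string(index=False))

print("\nfactor ranking per response (most influential first):")
for resp, order in report.summary["rankings"].items():
    print(f"  {resp:12s} {' > '.join(order[:3])}")

# Hydrogen mode (H) dominates conversion; the temperature x flow structure
# shows up in the impurity_4 ranking -- hot and slow removes the
# partially-reduced intermediate.
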