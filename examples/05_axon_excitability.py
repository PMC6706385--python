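"""Nerve-excitability test (NET) on the simulated myelinated axon.

Builds the control (wild-type channels, 30 pA pump) and IEM (mutant
channels, 15 pA pump) axon scenarios at 36 degC, runs the threshold-
tracking battery and prints the TROND-style indices side by side.
Takes ~10 s.
"""

from resurgentsim.axon import load_scenario, run_net_battery

indices = {}
for scenario in ("control", "iem"):
    axon = load_scenario(scenario, temperature_c=36.0)
    _, idx = run_net_battery(axon)
    indices[scenario] = idx.to_dict()
    print(f"{scenario}: resting potential {axon.resting_potential:.1f} mV, "
          f"1 ms threshold {idx.threshold_1ms_pa:.0f} pA")

print(f"\n{'index':32s} {'control':>10s} {'iem':>10s}")
for key in ("sdtc_ms", "rheobase_pa", "te_d_10_20", "te_h_90_100", "te_h_99",
            "refractoriness_pct", "superexcitability_pct", "subexcitability_pct",
            "relative_refractory_period_ms", "iv_minus_80", "iv_minus_100",
            "hyperpolarizing_iv_slope"):
    print(f"{key:32s} {indices['control'][key]:10.2f} {indices['iem'][key]:10.2f}")

print("\nthe IEM axon shows higher refractoriness, a longer strength-duration")
print("time constant and less hyperpolarizing threshold elevation - the")
print("preconditioning-dependent signature of mutant-channel dysfunction.")
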