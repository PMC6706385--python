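"""Activation/inactivation curves, Boltzmann fits and window current.

Simulates the I-V and steady-state inactivation protocols for the
wild-type channel at 25 degC, fits both gating curves with the signed-k
Boltzmann form, and evaluates the window-current product.
"""

import numpy as np

import resurgentsim as rs
from resurgentsim.analysis import inactivation_availability

scheme = rs.default_scheme()
wt = rs.wild_type_parameters()

traces = rs.run_battery(scheme, wt, rs.make_protocol("activation_iv"), 25.0,
                        keep_occupancy=False)
iv = rs.analyze_iv(traces)
sel = (iv.test_voltages >= -80) & (iv.test_voltages <= 40)
act = rs.fit_boltzmann(iv.test_voltages[sel], iv.normalized_conductance[sel],
                       form="activation")
print(f"activation:   Vh = {act.vh:6.1f} mV, k = {act.k:5.2f} mV  "
      f"(V_Na from I-V regression: {iv.v_na:.1f} mV)")

traces = rs.run_battery(scheme, wt, rs.make_protocol("inactivation"), 25.0,
                        keep_occupancy=False)
v, avail = inactivation_availability(traces)
inact = rs.fit_boltzmann(v, avail, form="inactivation")
print(f"inactivation: Vh = {inact.vh:6.1f} mV, k = {inact.k:5.2f} mV  "
      f"(negative k: availability falls with depolarization)")

win = rs.window_curve(act, inact)
print(f"\nwindow-current area: {win.area:.3f} (dimensionless x mV)")
for volt, val in sorted(win.spot_values.items(), reverse=True):
    print(f"  product at {volt:6.1f} mV: {val:.2e}")
print("the overlap of the two sigmoid curves is the steady Na+ conductance")
print("available at subthreshold potentials.")
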