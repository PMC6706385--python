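"""Evaluate single transition rates and assemble the gating generator.

Loads the wild-type Nav1.7 parameter set, evaluates a few rate laws at
different voltages and temperatures, builds the generator matrix Q at
the holding potential and prints the stationary occupancy.
"""

import numpy as np

import resurgentsim as rs

wt = rs.wild_type_parameters()
print("alpha(0 mV, 25 C)  =", rs.evaluate_rate(wt["alpha"], 0.0, 25.0), "1/ms")
print("alpha(25 mV, 35 C) =", round(rs.evaluate_rate(wt["alpha"], 25.0, 35.0), 1),
      "1/ms   (x e^(0.08*25) for voltage, x 2.1 for the 10 C warming)")
print("o2i2 Q10 ratio     =",
      rs.evaluate_rate(wt["o2i2"], -40.0, 35.0) / rs.evaluate_rate(wt["o2i2"], -40.0, 25.0),
      " (the WT resurgent-inactivation Q10; 3.3 in the IEM mutant)")

scheme = rs.default_scheme()
q = rs.build_generator(scheme, wt, -120.0, 25.0)
print("\ngenerator at -120 mV: shape", q.shape,
      "max |row sum| =", float(np.abs(q.sum(axis=1)).max()))

p = rs.stationary_distribution(q)
print("stationary occupancy at -120 mV (holding):")
for state, prob in zip(scheme.states, p):
    if prob > 1e-4:
        print(f"  {state:4s} {prob:.4f}")
print("conducting occupancy:", float(p[scheme.conducting_indices].sum()),
      " (the channel is shut at rest)")
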