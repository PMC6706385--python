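"""Recovery from inactivation and parameter recovery on synthetic data.

First simulates the paired-pulse recovery protocol at -80 mV for both
genotypes at 15 and 25 degC and fits the mono-exponential recovery time
constant.  Then demonstrates the synthetic-data module: noisy Boltzmann
samples from known parameters are refit 50 times to show the estimator
is unbiased.
"""

import numpy as np

import resurgentsim as rs
from resurgentsim.analysis import recovery_fractions
from resurgentsim.synth import NoiseModel, generate_curve_dataset

scheme = rs.default_scheme()
proto = rs.make_protocol("recovery", gaps=np.geomspace(0.3, 120.0, 14).tolist())

print("recovery from inactivation at -80 mV (mono-exponential tau):")
for genotype in ("wt", "iem"):
    params = rs.get_parameters(genotype)
    for t_c in (15.0, 25.0):
        traces = rs.run_battery(scheme, params, proto, t_c, keep_occupancy=False)
        gaps, fracs = recovery_fractions(traces)
        fit = rs.fit_recovery(gaps, np.clip(fracs, 0, 1.05),
                              recovery_voltage_mv=-80.0, temperature_c=t_c)
        print(f"  {params.label:3s} {t_c:4.0f} C: tau = {fit.tau_ms:7.1f} ms")
print("cooling slows recovery in both genotypes (tau at 15 C > tau at 25 C).")

print("\nsynthetic Boltzmann samples (Vh = -21.8 mV, k = 8.3 mV, sigma = 0.02):")
ds = generate_curve_dataset("boltzmann", {"vh": -21.8, "k": 8.3},
                            np.linspace(-90.0, 50.0, 29),
                            noise=NoiseModel(sigma=0.02, seed=0),
                            n_replicates=50)
x, reps = ds.data
vhs = [rs.fit_boltzmann(x, y, "activation").vh for y in reps]
print(f"  mean fitted Vh over 50 replicates: {np.mean(vhs):.2f} mV "
      f"(sd {np.std(vhs, ddof=1):.2f})")
print("the fit recovers the generating half-activation voltage without bias.")
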