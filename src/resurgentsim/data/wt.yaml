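# Wild-type Nav1.7 resurgent-gating rate laws.
# Each transition rate is k0 * exp(k1 * V) * q10 ** ((T - 25) / 10),
# with k0 in 1/ms at 0 mV and 25 degC, k1 in 1/mV.
label: WT
reference_temperature_c: 25.0
transitions:
  alpha: {k0: 100.0, k1: 0.08, q10: 2.1}
  beta: {k0: 0.55, k1: -0.01, q10: 2.1}
  gamma: {k0: 40.0, k1: 0.01, q10: 2.1}
  delta: {k0: 2.0, k1: -0.01, q10: 2.1}
  c_on: {k0: 0.1, k1: 0.0, q10: 3.2}
  c_off: {k0: 0.5, k1: 0.0, q10: 3.2}
  o_on: {k0: 2.5, k1: 0.0, q10: 3.2}
  o_off: {k0: 0.004, k1: 0.0, q10: 3.2}
  o1o2: {k0: 0.12, k1: 0.057, q10: 2.0}
  o2o1: {k0: 0.001, k1: -0.095, q10: 2.0}
  o2i2: {k0: 0.5, k1: 0.04, q10: 2.0}
  i2o2: {k0: 0.06, k1: -0.03, q10: 2.0}
  i1i2: {k0: 0.002, k1: 0.01, q10: 2.6}
  i2i1: {k0: 0.2, k1: -0.038, q10: 2.6}
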