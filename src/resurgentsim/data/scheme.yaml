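# Default resurgent-gating state topology (two-chain scheme).
#
# Closed states C1..C4 activate via alpha/beta with statistical
# multipliers and open through gamma/delta into O1.  A parallel
# inactivated chain IC1..IC4 -> I1 mirrors it, with activation scaled by
# the allosteric coupling factor a = (o_on*c_off/(c_on*o_off))**(1/8)
# ~= 2.7344 and deactivation by 1/a; vertical C_i <-> IC_i inactivation
# rates are c_on*a**(i-1) / c_off*a**-(i-1).  This choice makes every
# activation-inactivation cycle microscopically reversible; the
# resurgent loop O1-O2-I2-I1 is the only (deliberately) unbalanced
# cycle.  The conducting states are O1 and O2.
states:
- C1
- C2
- C3
- C4
- O1
- IC1
- IC2
- IC3
- IC4
- I1
- O2
- I2
conducting:
- O1
- O2
transitions:
- from: C1
  to: C2
  rate: alpha
  multiplier: 3.0
- from: C2
  to: C1
  rate: beta
  multiplier: 1.0
- from: IC1
  to: IC2
  rate: alpha
  multiplier: 8.203090585563158
- from: IC2
  to: IC1
  rate: beta
  multiplier: 0.3657158199959149
- from: C2
  to: C3
  rate: alpha
  multiplier: 2.0
- from: C3
  to: C2
  rate: beta
  multiplier: 2.0
- from: IC2
  to: IC3
  rate: alpha
  multiplier: 5.468727057042106
- from: IC3
  to: IC2
  rate: beta
  multiplier: 0.7314316399918298
- from: C3
  to: C4
  rate: alpha
  multiplier: 1.0
- from: C4
  to: C3
  rate: beta
  multiplier: 3.0
- from: IC3
  to: IC4
  rate: alpha
  multiplier: 2.734363528521053
- from: IC4
  to: IC3
  rate: beta
  multiplier: 1.0971474599877447
- from: C4
  to: O1
  rate: gamma
  multiplier: 1.0
- from: O1
  to: C4
  rate: delta
  multiplier: 1.0
- from: IC4
  to: I1
  rate: gamma
  multiplier: 2.734363528521053
- from: I1
  to: IC4
  rate: delta
  multiplier: 0.3657158199959149
- from: C1
  to: IC1
  rate: c_on
  multiplier: 1.0
- from: IC1
  to: C1
  rate: c_off
  multiplier: 1.0
- from: C2
  to: IC2
  rate: c_on
  multiplier: 2.734363528521053
- from: IC2
  to: C2
  rate: c_off
  multiplier: 0.3657158199959149
- from: C3
  to: IC3
  rate: c_on
  multiplier: 7.476743906106102
- from: IC3
  to: C3
  rate: c_off
  multiplier: 0.1337480609952844
- from: C4
  to: IC4
  rate: c_on
  multiplier: 20.444135848948562
- from: IC4
  to: C4
  rate: c_off
  multiplier: 0.04891378179975408
- from: O1
  to: I1
  rate: o_on
  multiplier: 1.0
- from: I1
  to: O1
  rate: o_off
  multiplier: 1.0
- from: O1
  to: O2
  rate: o1o2
  multiplier: 1.0
- from: O2
  to: O1
  rate: o2o1
  multiplier: 1.0
- from: O2
  to: I2
  rate: o2i2
  multiplier: 1.0
- from: I2
  to: O2
  rate: i2o2
  multiplier: 1.0
- from: I1
  to: I2
  rate: i1i2
  multiplier: 1.0
- from: I2
  to: I1
  rate: i2i1
  multiplier: 1.0
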