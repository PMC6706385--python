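# Methods

`resurgentsim` models how inherited-erythromelalgia (IEM) mutations of
the Nav1.7 sodium channel change the channel's behaviour with
temperature, and how that change surfaces in clinical nerve-excitability
measurements.  It has three layers: a Markov gating model of the
channel, a voltage-clamp protocol/analysis battery, and a
threshold-tracking myelinated-axon simulator.  A synthetic-data module
makes every fitting stage testable without recordings.

## Channel model

### Rate laws

Every transition of the gating scheme follows

    k(V, T) = k0 · exp(k1·V) · Q10^((T − 25 °C)/10)

with `k0` in 1/ms at 0 mV and 25 °C, `k1` in 1/mV and `Q10`
dimensionless.  The wild-type (WT) and IEM parameter sets ship as YAML
(`data/wt.yaml`, `data/iem.yaml`).  The two genotypes differ in the
activation/deactivation rates (`alpha` 100 → 500, `beta` 0.55 → 4 ms⁻¹),
in the rates of the resurgent loop (`o2i2` 0.5 → 0.3, `i2o2` 0.06 →
0.07, `i1i2` 0.002 → 0.001, `i2i1` 0.2 → 0.12 ms⁻¹) and — decisively —
in the temperature coefficient of the transitions around the resurgent
open state: Q10 ≈ 2 in WT versus 2.6–3.3 in IEM.  A Q10 change from 2 to
3 corresponds to an activation-energy change from 0.69 RT to 1.1 RT per
10 °C.

### State topology

The scheme (shipped as a YAML edge list, `data/scheme.yaml`; built
programmatically by `two_chain_scheme()`) has twelve states:

* a closed chain C1–C4 activating via `alpha`/`beta` with statistical
  multipliers 3/2/1, opening through `gamma`/`delta` into the open state
  O1;
* a parallel fast-inactivated chain IC1–IC4 ending in the
  open-inactivated state I1 (reached from O1 via `o_on`/`o_off`);
  vertical inactivation C_i ⇄ IC_i uses `c_on`·a^(i−1) forward and
  `c_off`·a^(1−i) backward, and the inactivated chain's activation steps
  are scaled by a (deactivation by 1/a);
* the resurgent loop: a second open state O2 reached from O1
  (`o1o2`/`o2o1`), its inactivated partner I2 (`o2i2`/`i2o2`), and the
  I1 ⇄ I2 bridge (`i1i2`/`i2i1`).

The allosteric coupling factor

    a = (o_on·c_off / (c_on·o_off))^(1/8) ≈ 2.734

is the unique choice that makes every activation–inactivation cycle of
the two-chain graph microscopically reversible.  This matters: with a
single aggregate inactivated state (the obvious compact reading of the
scheme; available as `single_inactivated_scheme()` for comparison) the
closed→open→inactivated→closed cycle is unbalanced by a factor of ~10⁴
at subthreshold voltages, which drives a standing circulation through
the open state — a steady open probability of ~0.17 at −40 mV, i.e. an
absurd window current that swamps every analysis.  The two-chain
construction confines the (physically intended) non-equilibrium
circulation to the resurgent loop O1–O2–I2–I1, which remains unbalanced
by design: resurgent gating is a driven cyclic process fed by the
depolarizing prepulse.

The number of closed states (4) and the placement of the coupling
factor are configuration data; a different transcription is a one-file
YAML change.

### Mechanistic picture

During a strong depolarization the channel activates, opens and
inactivates within a millisecond; O1→O2→I2 traffic loads the
resurgent-inactivated state I2.  On repolarization I2 drains partly
through O2 — the resurgent current, a transient reopening — and partly
through I1 into the silent recovery path.  Because the IEM mutant
carries a larger Q10 on the O2/I2 transitions, warming speeds the
wild-type's resurgent dissipation more than the mutant's: the simulated
mutant-over-WT ratio of peak resurgent/transient currents grows from
≈1.1 at 15 °C to ≈3.2 at 40 °C, the package's central reproduction of
the heat-enhanced mutant phenotype.

### Numerics

Occupancies evolve as dp/dt = p·Q(V, T).  On piecewise-constant command
segments the propagator is computed from a cached eigendecomposition of
Q per (V, T) — exact up to round-off; a scipy `expm` fallback handles
near-defective eigensystems (condition number > 1e10).  An independent
cross-check, `simulate_sweep_ode`, integrates the same generator with
LSODA at rtol 1e−10/atol 1e−12; the two routes agree to ≤ 1e−6 (in
practice ~1e−10) maximum occupancy error across the full protocol
battery, both genotypes, 15/25/40 °C.  Occupancy is monitored for
conservation (drift > 1e−6 aborts the sweep).  Currents are Ohmic,
I = gmax · p_open · (V − E_rev) with E_rev = +100 mV and gmax = 1 by
default (all reported quantities are ratios).  Stored traces sample at
0.01 ms (0.005 ms at ≥ 40 °C, where kinetics are ~2–3× faster).

## Voltage-clamp protocols

Protocols are data (holding potential, segment template, one varying
parameter) with these defaults: activation I–V (−160…+40 mV × 5 mV,
100 ms, hold −120 mV), steady-state inactivation (100 ms prepulse
−160…+20 mV × 10 mV, test +10 mV), resurgent (+40 mV × 10 ms prepulse,
repolarization −20…−60 mV × 10 mV for 100 ms), paired-pulse recovery
(+20 mV × 10 ms pulses, gap at −80 mV growing in 0.1 ms steps), and
prepulse-duration (+60 mV prepulse of growing duration, test −40 mV).
The 1.5 s inter-sweep interval is modelled as full re-equilibration at
holding — at −120 mV every relaxation time is far below 1.5 s.

## Analysis layer

* **I–V**: reversal potential V_Na from the x-intercept of the linear
  regression of peak current on voltage over +10…+40 mV; G_max is the
  slope; normalized conductance I_peak/((V − V_Na)·G_max).  Note the
  finite-range extrapolation overestimates the true reversal potential
  when peak open probability still grows across the regression range
  (by ~14 mV for the shipped model); the method is kept as defined.
* **Boltzmann fits**: the single signed-k form 1/(1+exp((V_h−V)/k)) for
  both curve types (negative k ⇒ descending availability curve).
  Initialization: V_h from the half-maximum crossing, |k| from the
  10–90% rise span divided by 4.4; bounds |V_h| ≤ 200 mV,
  0.1 ≤ |k| ≤ 50 mV.
* **Window current**: product of the two fitted sigmoids on a 0.1 mV
  grid over −120…+20 mV; trapezoidal area; spot values at −20/−40/−60/
  −80 mV.
* **Sustained/peak ratio**: mean current on 90–95 ms of a 100 ms pulse
  over the peak transient current.
* **Resurgent metrics**: per repolarization voltage — peak located after
  the prepulse end (skipping a 0.1 ms blank after the step to ignore
  the instantaneous tail), time-to-peak from prepulse end, decay τ from
  a mono-exponential (with floor) fitted from the peak to sweep end,
  and charge from **signed** current integrals (identical to rectified
  magnitude on clean simulations, but unbiased under additive noise).
  The transient reference is the peak inward current during the
  prepulse of the same simulated cell.  A battery-level summary uses
  the maximum peak ratio across repolarization voltages.
* **Decay–voltage regression**: 1/τ(V) = A·exp(k·V/25), fitted as a
  linear regression of ln(1/τ) on V/25.
* **Prepulse-duration decay**: R(t) = (1−f0)·exp(−t/τ) + f0 with
  f0 ∈ [0, 1]; flat data is flagged degenerate (τ unidentifiable).
* **Recovery**: offset-free 1 − exp(−t/τ) through the origin, one time
  constant.  Sub-3 ms gaps are contaminated by the deactivation tail of
  the conditioning pulse (τ_deact ≈ 0.14 ms at −80 mV) and the
  long-gap plateau equals the steady-state availability at the recovery
  voltage, so fitted τ values should be compared within a fixed gap
  grid.

All fits are deterministic, seed-free scipy least squares.

## Synthetic data

`generate_noisy_sweeps` emulates an n-cell experiment: one clean
simulation per protocol, then per-cell log-normal conductance jitter
(CV 10%, unit mean) and additive white Gaussian current noise with
σ = 0.02 × the battery's transient peak.  `generate_curve_dataset`
produces noisy Boltzmann/recovery/prepulse-decay samples clipped to the
physical range.  A single master seed spawns independent per-replicate
`numpy` generators, so identical seeds give identical datasets.  What
the generator does **not** emulate: leak and capacitive artifacts,
series-resistance error, filtering, TTX subtraction, or correlated
(1/f) noise — passing parameter-recovery tests therefore demonstrates
estimator correctness under the stated noise family, not robustness to
every laboratory artifact.

## Myelinated-axon model and NET battery

The axon is a Bostock-type two-compartment model — a node of Ranvier
coupled to the internodal axolemma through the Barrett–Barrett pathway —
with all parameters exposed in `AxonParameters` and the two scenario
YAMLs.  Units: mV, ms, nS, pF, pA.

* Node: transient Na (73% Hodgkin–Huxley m³h + **27% Markov resurgent
  model**, the share of Nav1.7 on peripheral axons), persistent Na,
  slow K, fast K, leak.  Internode: fast K, slow K, HCN, leak.  A
  constant outward pump current (30 pA control, 15 pA IEM — reduced
  perfusion) is split equally between the compartments.
* m/h use Schwarz–Reid–Bostock-style α/β rate functions referenced to
  20 °C; persistent Na, fast K, slow K and HCN use steady-state/τ
  forms.  Slow K has a voltage-dependent τ (fast during the spike,
  ~120 ms at rest) so a single conditioning spike leaves a long-lived
  K⁺ tail.  All HH gates share a global Q10 of 2.2; the Markov block
  uses its own per-transition Q10 laws.
* Integration at dt = 10⁻³ ms: semi-implicit Euler for the two coupled
  membrane potentials (2×2 linear solve per step), exponential Euler
  for the gates, and a precomputed matrix-exponential propagator table
  for the Markov occupancy (0.2 mV grid over −170…+80 mV, linearly
  interpolated).  The stepping core is numba-compiled.
* Free parameters (capacitances, conductances) were calibrated once so
  that the **control** scenario shows normal human sensory-axon
  excitability behaviour — resting potential ≈ −85 mV, TE_d(10–20 ms)
  ≈ +50%, superexcitability ≈ −10%, relative refractory period ≈ 5 ms,
  recovery-cycle threshold change ≈ 0 at 200 ms, positive
  hyperpolarizing I/V slope — **not** against the IEM-vs-control
  comparisons, which are left to emerge from the channel substitution
  and pump reduction.

Thresholds: bisection on stimulus amplitude to 0.5% relative tolerance;
the spike criterion is the nodal potential crossing 0 mV within 5 ms of
test onset (a single deterministic axon has a binary spike, replacing
the clinical 40%-of-maximal-response target).  If a conditioning
current alone fires the axon the threshold is reported as 0.

The NET battery (reduced TROND grid): strength–duration at widths
0.2–1.0 ms with Weiss-law regression of threshold charge on width
(slope = rheobase, intercept/slope = SDTC); threshold electrotonus at
±20/±40% of threshold for 100 ms, tracked at 10/15/20/90/95/99 ms;
current–threshold relation after 200 ms polarizing currents (+50…−100%)
with the test delivered during the final ms; recovery cycle after a
supramaximal (2×) conditioning stimulus at 14 interstimulus intervals
from 2 to 200 ms.  Refractoriness is read at 2.5 ms (3.2 ms below
30 °C, the cooled-limb convention); superexcitability is the most
negative threshold change; subexcitability the largest late positive
change after the superexcitable minimum; the hyperpolarizing I/V slope
is fitted over the three most hyperpolarized levels.

## Known limitations

* The channel-model topology is a reconstruction; the published rate
  table constrains it only partially.  Three directional observations
  cannot be reproduced from the printed rates under any topology tried:
  the growth of the WT-vs-mutant time-to-peak gap with warming (the
  mutant's uniformly larger Q10 shrinks the gap instead), the slower
  mutant recovery from inactivation at 15 °C (simulated recovery is
  rate-limited by genotype-shared or mutant-faster steps), and — as a
  downstream consequence — the reduction of axonal superexcitability in
  the IEM scenario.  The corresponding acceptance checks are asserted
  as stated and fail, documented in their docstrings.
* Simulated recovery at −80 mV is much slower than experimental values
  (hundreds of ms versus ~1–5 ms): the balanced two-chain scheme pins
  the open-inactivated state deep relative to the inactivated chain.
  Directional temperature comparisons (15 °C slower than 25 °C) hold.
* The axon model is a two-compartment reduction: no multi-node
  propagation, no C-fibres, no fitting to recorded patient traces.
* Single-channel stochastics, GHK permeation and ion accumulation are
  out of scope.
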