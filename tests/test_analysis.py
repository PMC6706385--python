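"""Curve-analysis layer: Boltzmann, I-V, window, resurgent, recovery fits."""

import numpy as np
import pytest

import resurgentsim as rs
from resurgentsim.analysis import (boltzmann, fit_boltzmann, analyze_iv,
                                   window_curve, sustained_ratio,
                                   resurgent_metrics,
                                   fit_decay_voltage_regression,
                                   fit_prepulse_decay, fit_recovery,
                                   ratio_to_wt, BoltzmannFit)
from resurgentsim.simulate import CurrentTrace, VoltageSegment

# gating-curve parameters (Vh, k) of the four genotypes at 25 degC
FIG_PARAMS = {
    "WT": {"act": (-21.8, 8.3), "inact": (-85.7, -12.5)},
    "I136V": {"act": (-27.5, 7.7), "inact": (-80.5, -12.8)},
    "I848T": {"act": (-32.6, 7.6), "inact": (-73.5, -12.5)},
    "V1316A": {"act": (-34.04, 8.7), "inact": (-77.1, -11.9)},
}


def synthetic_trace(t, current, segments=None, temperature=25.0):
    t = np.asarray(t, float)
    return CurrentTrace(
        time_ms=t, voltage_mv=np.zeros_like(t), current=np.asarray(current, float),
        temperature_c=temperature, dt_ms=float(t[1] - t[0]),
        segments=tuple(segments or [VoltageSegment(0.0, float(t[-1]))]),
    )


# --------------------------------------------------------------------- IV

def test_iv_exact_line_recovers_reversal():
    volts = np.arange(-20.0, 45.0, 5.0)
    g = 0.3
    peaks = g * (volts - 100.0)
    traces = []
    for v, p in zip(volts, peaks):
        t = np.arange(1, 11) * 0.1
        tr = synthetic_trace(t, np.full(10, p))
        tr.meta["sweep_value"] = v
        traces.append(tr)
    iv = analyze_iv(traces)
    assert iv.v_na == pytest.approx(100.0, abs=1e-9)
    assert iv.g_max == pytest.approx(g, rel=1e-9)


def test_iv_scale_equivariance(scheme, wt):
    traces = rs.run_battery(scheme, wt, rs.make_protocol("activation_iv"), 25.0,
                            keep_occupancy=False)
    iv1 = analyze_iv(traces)
    iv2 = analyze_iv([tr.copy_scaled(2.0) for tr in traces])
    assert iv2.g_max == pytest.approx(2.0 * iv1.g_max, rel=1e-9)
    np.testing.assert_allclose(iv2.normalized_conductance,
                               iv1.normalized_conductance, rtol=1e-9)
    # the +10..+40 mV linear extrapolation brackets the model's true
    # reversal potential from above (peak open probability still grows
    # with test voltage over the regression range, tilting the intercept)
    assert 100.0 <= iv1.v_na <= 120.0


# --------------------------------------------------------------- Boltzmann

def test_boltzmann_noiseless_self_recovery():
    v = np.arange(-120.0, 41.0, 5.0)
    for vh, k, form in [(-21.8, 8.3, "activation"), (-85.7, -12.5, "inactivation")]:
        fit = fit_boltzmann(v, boltzmann(v, vh, k), form)
        assert fit.vh == pytest.approx(vh, abs=0.01)
        assert fit.k == pytest.approx(k, abs=0.01)


def test_boltzmann_half_point_definition():
    v = np.arange(-100.0, 1.0, 4.0)
    fit = fit_boltzmann(v, boltzmann(v, -48.0, 6.0), "activation")
    assert fit(-48.0) == pytest.approx(0.5, abs=1e-6)
    assert fit.vh == pytest.approx(-48.0, abs=1e-6)


def test_boltzmann_monte_carlo_unbiased():
    """Seeded sigma=0.02 noise, 29 voltages, 100 replicates: mean Vh
    within 0.5 mV of truth."""
    vh, k = -21.8, 8.3
    v = np.linspace(-90.0, 50.0, 29)
    ds = rs.generate_curve_dataset("boltzmann", {"vh": vh, "k": k}, v,
                                   noise=rs.NoiseModel(sigma=0.02, seed=7),
                                   n_replicates=100)
    x, reps = ds.data
    fits = [fit_boltzmann(x, y, "activation").vh for y in reps]
    assert np.mean(fits) == pytest.approx(vh, abs=0.5)


def test_boltzmann_rejects_flat_and_short_data():
    v = np.arange(-50.0, 10.0, 10.0)
    with pytest.raises(ValueError):
        fit_boltzmann(v, np.full_like(v, 0.4), "activation")
    with pytest.raises(ValueError):
        fit_boltzmann(v[:4], boltzmann(v[:4], -20.0, 8.0), "activation")


# ------------------------------------------------------------------ window

def test_window_identity_factor():
    act = BoltzmannFit(vh=-21.8, k=8.3, form="activation")
    flat = BoltzmannFit(vh=-1e6, k=50.0, form="inactivation")  # ~1 everywhere
    win = window_curve(act, flat)
    np.testing.assert_allclose(win.product, act(win.voltages), atol=1e-6)


def test_window_spot_value_matches_direct_evaluation():
    p = FIG_PARAMS["WT"]
    act = BoltzmannFit(*p["act"], form="activation")
    inact = BoltzmannFit(*p["inact"], form="inactivation")
    win = window_curve(act, inact)
    # independent evaluation of both sigmoid factors at -80 mV
    expected = (1.0 / (1.0 + np.exp((-21.8 + 80.0) / 8.3))
                * 1.0 / (1.0 + np.exp((-85.7 + 80.0) / -12.5)))
    assert win.spot_values[-80.0] == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(3.5e-4, rel=0.02)
    assert win.area > 0


@pytest.mark.parametrize("mutant", ["I136V", "I848T", "V1316A"])
@pytest.mark.parametrize("voltage", [-20.0, -40.0, -60.0, -80.0])
def test_mutant_window_exceeds_wild_type(mutant, voltage):
    """Each mutant's gating-curve product exceeds WT at the four spot
    voltages (strict ordering)."""
    def spot(name):
        p = FIG_PARAMS[name]
        act = BoltzmannFit(*p["act"], form="activation")
        inact = BoltzmannFit(*p["inact"], form="inactivation")
        return window_curve(act, inact).spot_values[voltage]
    assert spot(mutant) > spot("WT")


# --------------------------------------------------------------- sustained

def test_sustained_ratio_constant_current_is_one():
    t = np.arange(1, 9701) * 0.01
    tr = synthetic_trace(t, np.full(t.size, -5.0))
    assert sustained_ratio(tr) == pytest.approx(1.0)


def test_sustained_ratio_exponential_closed_form():
    tau = 10.0
    t = np.arange(1, 10001) * 0.01
    tr = synthetic_trace(t, -np.exp(-t / tau))
    # closed-form mean of exp(-t/10) on [90, 95] over the peak at t->0
    expected = (tau / 5.0) * (np.exp(-9.0) - np.exp(-9.5))
    assert sustained_ratio(tr) == pytest.approx(expected, rel=5e-3)


@pytest.mark.parametrize("level", [10.0, 20.0, 30.0])
def test_simulated_iem_sustained_exceeds_wt(scheme, wt, iem, level):
    proto = rs.make_protocol("activation_iv", levels=[level])
    (wt_tr,) = rs.run_battery(scheme, wt, proto, 25.0, keep_occupancy=False)
    (iem_tr,) = rs.run_battery(scheme, iem, proto, 25.0, keep_occupancy=False)
    assert sustained_ratio(iem_tr) > sustained_ratio(wt_tr)


# --------------------------------------------------------------- resurgent

def test_resurgent_metrics_scale_invariant(wt_resurgent_25):
    m1 = resurgent_metrics(wt_resurgent_25)
    m2 = resurgent_metrics([tr.copy_scaled(3.0) for tr in wt_resurgent_25])
    np.testing.assert_allclose(m2.ratio_peak, m1.ratio_peak, rtol=1e-9)
    np.testing.assert_allclose(m2.decay_tau_ms, m1.decay_tau_ms, rtol=1e-6)
    np.testing.assert_allclose(m2.time_to_peak_ms, m1.time_to_peak_ms)


def test_resurgent_decay_tau_self_recovery():
    """A synthetic exact exponential decay after a delayed peak returns
    its own tau."""
    tau_true = 7.3
    t = np.arange(1, 11001) * 0.01
    rise = 1.0 - np.exp(-np.maximum(t - 10.0, 0.0) / 0.5)
    decay = np.exp(-np.maximum(t - 10.0, 0.0) / tau_true)
    current = -np.where(t <= 10.0, 0.5, rise * decay)
    tr = synthetic_trace(t, current,
                         segments=[VoltageSegment(40.0, 10.0),
                                   VoltageSegment(-40.0, 100.0)])
    tr.meta["sweep_value"] = -40.0
    m = resurgent_metrics([tr])
    assert m.decay_tau_ms[0] == pytest.approx(tau_true, rel=0.02)
    assert m.time_to_peak_ms[0] > 0


def test_wt_resurgent_ratio_calibration(wt_resurgent_25):
    """Simulated WT 25 degC peak resurgent/transient ratio lands within
    the +-50% calibration band around 0.071."""
    m = resurgent_metrics(wt_resurgent_25)
    assert 0.5 * 0.071 <= m.max_ratio <= 1.5 * 0.071


# ------------------------------------------------------- decay regression

def test_decay_regression_constant_tau():
    reg = fit_decay_voltage_regression([-20.0, -40.0, -60.0], [4.0, 4.0, 4.0])
    assert reg.k == pytest.approx(0.0, abs=1e-12)
    assert reg.a == pytest.approx(0.25, rel=1e-12)


def test_decay_regression_exact_recovery():
    a_true, k_true = 0.08, -0.6
    v = np.array([-20.0, -30.0, -40.0, -50.0, -60.0])
    tau = 1.0 / (a_true * np.exp(k_true * v / 25.0))
    reg = fit_decay_voltage_regression(v, tau)
    assert reg.a == pytest.approx(a_true, rel=1e-9)
    assert reg.k == pytest.approx(k_true, rel=1e-9)


def test_decay_regression_input_validation():
    with pytest.raises(ValueError):
        fit_decay_voltage_regression([-20.0, -40.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_decay_voltage_regression([-20.0, -40.0, -60.0], [1.0, -2.0, 3.0])


@pytest.mark.parametrize("temperature", [15.0, 25.0])
def test_simulated_iem_decay_slower_than_wt(scheme, wt, iem, temperature):
    """The mutant resurgent current decays more slowly (lower 1/tau) at
    every repolarization voltage at 15 and 25 degC."""
    def taus(par):
        traces = rs.run_battery(scheme, par, rs.make_protocol("resurgent"),
                                temperature, keep_occupancy=False)
        return resurgent_metrics(traces).decay_tau_ms
    assert (taus(iem) > taus(wt)).all()


# --------------------------------------------------- prepulse-duration fit

def test_prepulse_decay_noiseless_self_recovery():
    tau, f0 = 64.2, 0.4
    t = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0])
    y = (1 - f0) * np.exp(-t / tau) + f0
    fit = fit_prepulse_decay(t, y)
    assert fit.tau_ms == pytest.approx(tau, rel=1e-6)
    assert fit.f0 == pytest.approx(f0, abs=1e-8)


def test_prepulse_decay_flat_data_flagged():
    t = np.array([2.0, 5.0, 10.0, 20.0, 40.0])
    with pytest.warns(RuntimeWarning, match="flat"):
        fit = fit_prepulse_decay(t, np.full(5, 0.4))
    assert fit.degenerate
    assert fit.f0 == pytest.approx(0.4)
    assert np.isnan(fit.tau_ms)


def test_prepulse_decay_noisy_f0_recovery():
    tau, f0 = 64.2, 0.4
    t = np.geomspace(2.0, 320.0, 12)
    ds = rs.generate_curve_dataset("prepulse_decay", {"tau": tau, "f0": f0}, t,
                                   noise=rs.NoiseModel(sigma=0.02, seed=11),
                                   n_replicates=50)
    x, reps = ds.data
    f0s = [fit_prepulse_decay(x, y).f0 for y in reps]
    assert np.mean(f0s) == pytest.approx(f0, abs=0.05)


# ---------------------------------------------------------------- recovery

def test_recovery_fit_self_recovery():
    tau = 1.13
    t = np.arange(0.1, 10.0, 0.1)
    fit = fit_recovery(t, 1.0 - np.exp(-t / tau), recovery_voltage_mv=-80.0,
                       temperature_c=25.0)
    assert fit.tau_ms == pytest.approx(tau, rel=1e-9)
    assert fit.recovery_voltage_mv == -80.0


def test_recovery_fit_validates_fractions():
    t = np.arange(0.1, 2.0, 0.1)
    with pytest.raises(ValueError):
        fit_recovery(t, np.full(t.size, 1.5))


@pytest.mark.parametrize("genotype_fix", ["wt", "iem"])
def test_simulated_recovery_slower_when_cold(scheme, genotype_fix):
    """Recovery from inactivation at -80 mV is slower at 15 than 25 degC."""
    params = rs.get_parameters(genotype_fix)
    proto = rs.make_protocol("recovery", gaps=np.geomspace(0.3, 120.0, 14).tolist())
    taus = {}
    for t_c in (15.0, 25.0):
        traces = rs.run_battery(scheme, params, proto, t_c, keep_occupancy=False)
        g, f = rs.analysis.recovery_fractions(traces)
        taus[t_c] = fit_recovery(g, np.clip(f, 0, 1.05)).tau_ms
    assert taus[15.0] > taus[25.0]


# ------------------------------------------------------------- ratio to WT

@pytest.mark.parametrize("mut,wt_val,expected", [
    (0.12, 0.071, 1.69), (0.22, 0.05, 4.4), (0.13, 0.05, 2.6),
])
def test_ratio_to_wt_printed_examples(mut, wt_val, expected):
    assert ratio_to_wt(mut, wt_val) == pytest.approx(expected, abs=0.005)


def test_ratio_to_wt_identity_and_errors():
    assert ratio_to_wt(0.3, 0.3) == 1.0
    with pytest.raises(ZeroDivisionError):
        ratio_to_wt(0.1, 0.0)
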