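"""Kinetic analysis of voltage-clamp sweep families.

Implements the standard analysis battery for transient and resurgent
Na+ currents:

* I-V analysis with reversal-potential regression and conductance
  normalization,
* Boltzmann fits of activation/inactivation curves (single signed-k form
  ``1 / (1 + exp((Vh - V)/k))``, negative k giving descending curves),
* window-current product and area,
* sustained/peak current ratio,
* resurgent-current metrics (peak ratio, charge ratio, time to peak,
  decay tau) and the exponential voltage-dependence regression of the
  decay rate ``1/tau(V) = A * exp(k * V / 25)``,
* prepulse-duration decay ``R(t) = (1 - f0) exp(-t/tau) + f0``,
* mono-exponential recovery from inactivation ``1 - exp(-t/tau)``.

All fits are deterministic, seed-free least squares (scipy), with
documented initialization: Vh from the half-maximum crossing, k from the
10-90% rise span, tau from log-linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .simulate import CurrentTrace

__all__ = [
    "BoltzmannFit", "IVAnalysis", "WindowCurve", "ResurgentMetrics",
    "DecayVoltageRegression", "PrepulseDecayFit", "RecoveryFit",
    "boltzmann", "fit_boltzmann", "analyze_iv", "window_curve",
    "sustained_ratio", "resurgent_metrics", "fit_decay_voltage_regression",
    "fit_prepulse_decay", "fit_recovery", "ratio_to_wt",
    "peak_current", "recovery_fractions",
]

WINDOW_SPOT_VOLTAGES = (-20.0, -40.0, -60.0, -80.0)


def boltzmann(v, vh, k):
    """Signed-k Boltzmann sigmoid ``1 / (1 + exp((vh - v)/k))``."""
    return 1.0 / (1.0 + np.exp((vh - np.asarray(v, dtype=float)) / k))


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class BoltzmannFit:
    vh: float                      # half-maximal potential, mV
    k: float                       # slope factor, mV (signed)
    form: str                      # activation | inactivation
    residual_norm: float = np.nan
    vh_stderr: float = np.nan
    k_stderr: float = np.nan

    def __post_init__(self) -> None:
        if self.k == 0:
            raise ValueError("slope factor k must be nonzero")

    def __call__(self, v):
        return boltzmann(v, self.vh, self.k)


@dataclass(frozen=True)
class IVAnalysis:
    test_voltages: np.ndarray
    peak_currents: np.ndarray
    v_na: float                    # reversal potential from regression, mV
    g_max: float                   # regression slope (conductance scale)
    normalized_conductance: np.ndarray


@dataclass(frozen=True)
class WindowCurve:
    voltages: np.ndarray
    product: np.ndarray
    area: float                    # dimensionless * mV
    spot_values: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ResurgentMetrics:
    """Per-repolarization-voltage resurgent metrics for one battery."""
    voltages: np.ndarray
    peak_resurgent: np.ndarray           # magnitude of the resurgent peak
    ratio_peak: np.ndarray               # I_resurgent / I_transient
    ratio_charge: np.ndarray             # Q_resurgent / Q_transient
    time_to_peak_ms: np.ndarray          # from prepulse end to peak
    decay_tau_ms: np.ndarray
    transient_peak: float
    monotone: np.ndarray = None          # True where no delayed peak existed

    @property
    def max_ratio(self) -> float:
        """Largest peak ratio over repolarization voltages (summary value)."""
        return float(np.max(self.ratio_peak))

    def at_voltage(self, v: float) -> dict:
        i = int(np.argmin(np.abs(self.voltages - v)))
        return {
            "voltage": float(self.voltages[i]),
            "ratio_peak": float(self.ratio_peak[i]),
            "ratio_charge": float(self.ratio_charge[i]),
            "time_to_peak_ms": float(self.time_to_peak_ms[i]),
            "decay_tau_ms": float(self.decay_tau_ms[i]),
        }


@dataclass(frozen=True)
class DecayVoltageRegression:
    a: float                       # 1/ms
    k: float                       # dimensionless (per 25 mV)

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError("regression amplitude A must be positive")

    def inverse_tau(self, v):
        return self.a * np.exp(self.k * np.asarray(v, dtype=float) / 25.0)


@dataclass(frozen=True)
class PrepulseDecayFit:
    tau_ms: float
    f0: float                      # residual fraction at long prepulses
    degenerate: bool = False       # flat data: tau unidentifiable


@dataclass(frozen=True)
class RecoveryFit:
    tau_ms: float
    recovery_voltage_mv: float = np.nan
    temperature_c: float = np.nan

    def __call__(self, t):
        return 1.0 - np.exp(-np.asarray(t, dtype=float) / self.tau_ms)


# ---------------------------------------------------------------------------
# trace helpers

def peak_current(trace: CurrentTrace, t_start: float = 0.0,
                 t_end: float | None = None) -> float:
    """Most negative (inward) current in [t_start, t_end] ms."""
    t = trace.time_ms
    sel = (t >= t_start) if t_end is None else ((t >= t_start) & (t <= t_end))
    return float(trace.current[sel].min())


def analyze_iv(traces: list[CurrentTrace], fit_lo: float = 10.0,
               fit_hi: float = 40.0) -> IVAnalysis:
    """I-V analysis of an activation sweep family.

    The reversal potential ``V_Na`` is the x-intercept of the linear
    regression of peak current on test voltage over [+10, +40] mV, and
    ``G_max`` its slope.  Normalized conductance is
    ``I_peak / ((V - V_Na) * G_max)``.
    """
    volts = np.array([tr.meta["sweep_value"] for tr in traces], dtype=float)
    peaks = np.array([peak_current(tr) for tr in traces])
    sel = (volts >= fit_lo) & (volts <= fit_hi)
    if sel.sum() < 3:
        raise ValueError("need >=3 sweeps with test voltages in the regression range")
    reg = linregress(volts[sel], peaks[sel])
    if reg.slope <= 0:
        raise ValueError(f"degenerate I-V regression (slope {reg.slope:.3g} <= 0)")
    v_na = -reg.intercept / reg.slope
    g_max = reg.slope
    with np.errstate(divide="ignore", invalid="ignore"):
        g_norm = peaks / ((volts - v_na) * g_max)
    g_norm = np.where(np.isclose(volts, v_na), np.nan, g_norm)
    return IVAnalysis(test_voltages=volts, peak_currents=peaks,
                      v_na=float(v_na), g_max=float(g_max),
                      normalized_conductance=g_norm)


def inactivation_availability(traces: list[CurrentTrace]) -> tuple[np.ndarray, np.ndarray]:
    """(prepulse voltage, normalized test-pulse peak) from an inactivation battery."""
    volts = np.array([tr.meta["sweep_value"] for tr in traces], dtype=float)
    t0 = np.array([tr.segments[0].duration for tr in traces])
    peaks = np.array([abs(peak_current(tr, t_start=start)) for tr, start in zip(traces, t0)])
    return volts, peaks / peaks.max()


# ---------------------------------------------------------------------------
# Boltzmann / window

def fit_boltzmann(voltages, response, form: str = "activation") -> BoltzmannFit:
    """Least-squares Boltzmann fit with half-point/rise-span initialization.

    ``form`` only selects the sign of the initial slope guess; activation
    and inactivation share the single signed-k algebraic form.
    """
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(response, dtype=float)
    if v.size < 6:
        raise ValueError("need at least 6 points spanning the transition")
    if np.ptp(y) < 1e-6:
        raise ValueError("all-flat response: Boltzmann fit is unidentifiable")
    order = np.argsort(v)
    v, y = v[order], y[order]

    # initialization: Vh at the half-maximum crossing, |k| from 10-90% span
    half = 0.5 * (y.min() + y.max())
    vh0 = float(v[np.argmin(np.abs(y - half))])
    ascending = form == "activation"
    if ascending:
        lo = v[np.searchsorted(np.maximum.accumulate(y), 0.1 * y.max())]
        hi = v[min(np.searchsorted(np.maximum.accumulate(y), 0.9 * y.max()), v.size - 1)]
    else:
        rev = np.maximum.accumulate(y[::-1])
        lo = v[::-1][np.searchsorted(rev, 0.1 * y.max())]
        hi = v[::-1][min(np.searchsorted(rev, 0.9 * y.max()), v.size - 1)]
    span = abs(float(hi) - float(lo))
    k0 = max(span / 4.4, 0.5)  # 10-90% span of a Boltzmann is ~4.4 k
    if not ascending:
        k0 = -k0

    bounds = ([-200.0, -50.0], [200.0, 50.0])
    popt, pcov = curve_fit(boltzmann, v, y, p0=[vh0, k0], bounds=bounds,
                           maxfev=20000)
    vh, k = popt
    if abs(k) < 0.1:
        raise RuntimeError("Boltzmann fit collapsed to |k| < 0.1 mV")
    perr = np.sqrt(np.diag(pcov))
    resid = float(np.linalg.norm(y - boltzmann(v, vh, k)))
    return BoltzmannFit(vh=float(vh), k=float(k), form=form,
                        residual_norm=resid, vh_stderr=float(perr[0]),
                        k_stderr=float(perr[1]))


def window_curve(act: BoltzmannFit, inact: BoltzmannFit,
                 grid: np.ndarray | None = None) -> WindowCurve:
    """Product of activation and availability curves on a voltage grid.

    Area is trapezoidal over the grid (default -120..+20 mV, 0.1 mV step);
    spot values are reported at -20, -40, -60 and -80 mV.
    """
    if grid is None:
        grid = np.arange(-120.0, 20.0 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    prod = act(grid) * inact(grid)
    area = float(np.trapezoid(prod, grid))
    spots = {float(v): float(act(v) * inact(v)) for v in WINDOW_SPOT_VOLTAGES}
    return WindowCurve(voltages=grid, product=prod, area=area, spot_values=spots)


# ---------------------------------------------------------------------------
# sustained / resurgent

def sustained_ratio(trace: CurrentTrace, window=(90.0, 95.0)) -> float:
    """Mean current on [90, 95] ms of the pulse over the peak transient current."""
    t = trace.time_ms
    if t[-1] < window[1]:
        raise ValueError(f"sweep ends at {t[-1]:.1f} ms; needs >= {window[1]} ms")
    mag = np.abs(trace.current)
    peak = mag.max()
    if peak == 0:
        raise ZeroDivisionError("peak transient current is zero")
    sel = (t >= window[0]) & (t <= window[1])
    return float(mag[sel].mean() / peak)


def _fit_exp_decay(t: np.ndarray, y: np.ndarray) -> float:
    """Mono-exponential decay constant of y(t) ~ a*exp(-t/tau) (+ floor).

    Initialized by log-linear regression over the upper part of the decay.
    """
    y0 = y[0]
    floor = float(y.min())
    pos = y - floor + 1e-12 * max(y0, 1.0)
    sel = pos > 0.05 * pos[0]
    if sel.sum() >= 3:
        slope = linregress(t[sel], np.log(pos[sel])).slope
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0
    tau0 = min(max(tau0, 1e-3), 10 * (t[-1] - t[0]))

    def model(tt, a, tau, c):
        return a * np.exp(-(tt - t[0]) / tau) + c

    popt, _ = curve_fit(model, t, y, p0=[y0 - floor, tau0, floor],
                        maxfev=20000)
    return float(abs(popt[1]))


def resurgent_metrics(traces: list[CurrentTrace],
                      transient_peak: float | None = None,
                      blank_ms: float = 0.1) -> ResurgentMetrics:
    """Resurgent metrics per repolarization voltage.

    The resurgent peak is the largest-magnitude inward current after the
    end of the depolarizing prepulse (a short ``blank_ms`` after the step
    is skipped to ignore the instantaneous tail); time to peak runs from
    prepulse end.  Charge is the integrated current magnitude from
    prepulse end to sweep end.  ``transient_peak`` defaults to the peak
    inward current during the prepulse of the same simulated cell; the
    transient charge is integrated over the prepulse.
    """
    volts, pk, rp, rq, ttp, tau, mono = [], [], [], [], [], [], []
    for tr in traces:
        t = tr.time_ms
        pre_end = tr.segments[0].duration
        mag = np.abs(tr.current)
        pre = t <= pre_end
        post = t > pre_end + blank_ms
        i_trans = float(mag[pre].max()) if transient_peak is None else abs(transient_peak)
        if i_trans == 0:
            raise ZeroDivisionError("transient reference peak is zero")
        # signed integrals (inward currents negative): zero-mean noise
        # cancels instead of rectifying into a positive charge bias
        q_trans = float(np.trapezoid(-tr.current[pre], t[pre]))
        tt, yy = t[post], mag[post]
        ipk = int(np.argmax(yy))
        is_monotone = ipk == 0
        peak = float(yy[ipk])
        q_res = float(np.trapezoid(-tr.current[post], tt))
        decay_t, decay_y = tt[ipk:], yy[ipk:]
        tau_ms = _fit_exp_decay(decay_t, decay_y) if decay_y.size >= 5 else np.nan

        volts.append(tr.meta.get("sweep_value", tr.segments[1].level))
        pk.append(peak)
        rp.append(peak / i_trans)
        rq.append(q_res / q_trans if q_trans > 0 else np.nan)
        ttp.append(np.nan if is_monotone else float(tt[ipk] - pre_end))
        tau.append(tau_ms)
        mono.append(is_monotone)
        if is_monotone:
            warnings.warn(
                f"no delayed resurgent peak at {volts[-1]} mV (monotone decay)",
                RuntimeWarning,
            )
    order = np.argsort(volts)[::-1]  # most depolarized first
    arr = lambda x: np.asarray(x, dtype=float)[order]
    return ResurgentMetrics(
        voltages=arr(volts), peak_resurgent=arr(pk), ratio_peak=arr(rp),
        ratio_charge=arr(rq), time_to_peak_ms=arr(ttp), decay_tau_ms=arr(tau),
        transient_peak=float(i_trans),
        monotone=np.asarray(mono, dtype=bool)[order],
    )


def fit_decay_voltage_regression(voltages, taus) -> DecayVoltageRegression:
    """Fit ``1/tau(V) = A exp(k V / 25)`` by log-linear regression."""
    v = np.asarray(voltages, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 voltages")
    if np.any(tau <= 0):
        raise ValueError("decay time constants must be positive")
    reg = linregress(v / 25.0, np.log(1.0 / tau))
    return DecayVoltageRegression(a=float(np.exp(reg.intercept)),
                                  k=float(reg.slope))


# ---------------------------------------------------------------------------
# prepulse-duration decay / recovery

def fit_prepulse_decay(durations, amplitudes) -> PrepulseDecayFit:
    """Fit ``R(t) = (1 - f0) exp(-t/tau) + f0`` to normalized resurgent peaks."""
    t = np.asarray(durations, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 prepulse durations")
    if np.ptp(y) < 1e-3:
        warnings.warn("flat prepulse-decay data: tau unidentifiable", RuntimeWarning)
        return PrepulseDecayFit(tau_ms=np.nan, f0=float(np.clip(y.mean(), 0, 1)),
                                degenerate=True)
    f00 = float(np.clip(y[np.argmax(t)], 0.0, 1.0))
    pos = np.clip(y - f00, 1e-9, None)
    slope = linregress(t, np.log(pos)).slope
    tau0 = -1.0 / slope if slope < 0 else t.max() / 3.0
    tau0 = min(max(tau0, 1e-3), 100 * t.max())

    def model(tt, tau, f0):
        return (1.0 - f0) * np.exp(-tt / tau) + f0

    popt, _ = curve_fit(model, t, y, p0=[tau0, f00],
                        bounds=([1e-6, 0.0], [np.inf, 1.0]), maxfev=20000)
    return PrepulseDecayFit(tau_ms=float(popt[0]), f0=float(popt[1]))


def recovery_fractions(traces: list[CurrentTrace]) -> tuple[np.ndarray, np.ndarray]:
    """(gap ms, peak2/peak1) from a paired-pulse recovery battery."""
    gaps, fracs = [], []
    for tr in traces:
        d1 = tr.segments[0].duration
        gap = tr.segments[1].duration
        p1 = abs(peak_current(tr, 0.0, d1))
        p2 = abs(peak_current(tr, d1 + gap, d1 + gap + tr.segments[2].duration))
        gaps.append(gap)
        fracs.append(p2 / p1)
    order = np.argsort(gaps)
    return np.asarray(gaps)[order], np.asarray(fracs)[order]


def fit_recovery(gaps, fractions, recovery_voltage_mv: float = np.nan,
                 temperature_c: float = np.nan) -> RecoveryFit:
    """Fit the offset-free rising exponential ``1 - exp(-t/tau)``."""
    t = np.asarray(gaps, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 gap durations")
    if np.any(y < 0) or np.any(y > 1.05):
        raise ValueError("recovered fractions must lie in [0, 1.05]")
    miss = np.clip(1.0 - y, 1e-9, None)
    slope = linregress(t, np.log(miss)).slope
    tau0 = -1.0 / slope if slope < 0 else t.max() / 3.0
    tau0 = min(max(tau0, 1e-4), 100 * t.max())
    popt, _ = curve_fit(lambda tt, tau: 1.0 - np.exp(-tt / tau), t, y,
                        p0=[tau0], bounds=([1e-9], [np.inf]), maxfev=20000)
    return RecoveryFit(tau_ms=float(popt[0]),
                       recovery_voltage_mv=recovery_voltage_mv,
                       temperature_c=temperature_c)


def ratio_to_wt(mutant_ratio: float, wt_ratio: float) -> float:
    """Mutant-over-WT quotient of I_resurgent/I_transient at matched temperature."""
    if wt_ratio == 0:
        raise ZeroDivisionError("WT ratio is zero")
    if mutant_ratio < 0 or wt_ratio < 0:
        raise ValueError("ratios must be non-negative")
    return mutant_ratio / wt_ratio
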