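"""Threshold-tracking simulation of a human myelinated sensory axon.

A Bostock-type two-compartment model: a node of Ranvier coupled to the
internodal axolemma through the Barrett-Barrett pathway.  The node
carries transient Na+ (73% Hodgkin-Huxley m3h plus 27% of the Markov
resurgent-gating model, the fraction of Nav1.7 on peripheral axons),
persistent Na+, fast and slow K+ and leak; the internode carries fast
and slow K+, HCN (inward rectifier) and leak, plus a constant outward
electrogenic pump current.  Membrane potentials advance by a
semi-implicit Euler step at dt = 1e-3 ms; HH gates by exponential Euler;
the Markov occupancy by a precomputed matrix-exponential propagator
table over a fine voltage grid.

On top of the membrane model sits a threshold-tracking layer that
reproduces the nerve-excitability-test (NET) battery: strength-duration
(SDTC/rheobase via Weiss's law), threshold electrotonus (TE),
current-threshold (I/V) relationship and the recovery cycle (RC), with
TROND-style indices (refractoriness, superexcitability, subexcitability,
TE_h(90-100ms), IV_-80% ...).

Thresholds are found by bisection on stimulus amplitude to 0.5% relative
tolerance; the spike criterion is the nodal potential crossing 0 mV
within 5 ms of test-stimulus onset.  Units: mV, ms, nS, pF, pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from numba import njit
from scipy.linalg import expm

from .rates import ChannelParameterSet, get_parameters
from .scheme import GatingScheme, build_generator, default_scheme, stationary_distribution

__all__ = [
    "AxonParameters", "Axon", "NetIndices", "ThresholdProtocolResult",
    "build_axon", "find_threshold", "run_net_battery", "load_scenario",
]

# state-vector layout
_VN, _VI, _M, _H, _P, _SN, _NN, _SI, _NI, _Q = range(10)
_MK0 = 10  # first Markov state index

# parameter-vector layout
(_C_N, _C_I, _G_NAT, _FRAC_RES, _G_NAP, _G_KS_N, _G_KF_N, _G_LK_N,
 _G_KF_I, _G_KS_I, _G_H, _G_LK_I, _G_BB, _E_NA, _E_K, _E_LK, _E_H,
 _I_PUMP, _RS, _PUMP_NODE) = range(20)

SPIKE_THRESHOLD_MV = 0.0
SPIKE_WINDOW_MS = 5.0
BISECTION_RTOL = 0.005


@dataclass(frozen=True)
class AxonParameters:
    """Conductances (nS), capacitances (pF) and currents (pA) of the axon.

    ``resurgent_fraction`` is the share of the transient Na conductance
    carried by the Markov resurgent model (0.27 by default).  The pump
    current is outward; the two shipped scenarios use 30 pA (control) and
    15 pA (IEM, reflecting reduced local perfusion).
    """

    # node
    c_node_pf: float = 1.5
    g_na_transient: float = 650.0
    resurgent_fraction: float = 0.27
    g_na_persistent: float = 8.0
    g_k_slow_node: float = 12.0
    g_k_fast_node: float = 15.0
    g_leak_node: float = 2.0
    # internode (as seen through the myelin / Barrett-Barrett pathway)
    c_internode_pf: float = 500.0
    g_k_fast_internode: float = 8.0
    g_k_slow_internode: float = 6.0
    g_hcn: float = 5.0
    g_leak_internode: float = 4.0
    g_barrett_barrett: float = 30.0
    # reversal potentials (mV)
    e_na: float = 50.0
    e_k: float = -90.0
    e_leak: float = -85.0
    e_hcn: float = -50.0
    # pump & temperature
    pump_current_pa: float = 30.0
    pump_node_fraction: float = 0.5  # share of the pump current at the node
    temperature_c: float = 36.0
    hh_q10: float = 2.2          # global Q10 of the HH gates (rates at 20 degC)
    dt_ms: float = 1e-3
    channel: str = "wt"          # genotype tag of the Markov parameter set

    def __post_init__(self) -> None:
        for name in ("g_na_transient", "g_na_persistent", "g_k_slow_node",
                     "g_k_fast_node", "g_leak_node", "g_k_fast_internode",
                     "g_k_slow_internode", "g_hcn", "g_leak_internode",
                     "g_barrett_barrett"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.resurgent_fraction <= 1.0):
            raise ValueError("resurgent_fraction must lie in [0, 1]")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    def to_vector(self) -> np.ndarray:
        rs = self.hh_q10 ** ((self.temperature_c - 20.0) / 10.0)
        vec = np.zeros(20)
        vec[_C_N] = self.c_node_pf
        vec[_C_I] = self.c_internode_pf
        vec[_G_NAT] = self.g_na_transient
        vec[_FRAC_RES] = self.resurgent_fraction
        vec[_G_NAP] = self.g_na_persistent
        vec[_G_KS_N] = self.g_k_slow_node
        vec[_G_KF_N] = self.g_k_fast_node
        vec[_G_LK_N] = self.g_leak_node
        vec[_G_KF_I] = self.g_k_fast_internode
        vec[_G_KS_I] = self.g_k_slow_internode
        vec[_G_H] = self.g_hcn
        vec[_G_LK_I] = self.g_leak_internode
        vec[_G_BB] = self.g_barrett_barrett
        vec[_E_NA] = self.e_na
        vec[_E_K] = self.e_k
        vec[_E_LK] = self.e_leak
        vec[_E_H] = self.e_hcn
        vec[_I_PUMP] = self.pump_current_pa
        vec[_RS] = rs
        vec[_PUMP_NODE] = self.pump_node_fraction
        return vec

    def to_yaml(self, path=None) -> str:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AxonParameters":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        elif "\n" in str(source):
            doc = yaml.safe_load(str(source))
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls(**doc)


@dataclass(frozen=True)
class ThresholdProtocolResult:
    """Abscissa/threshold series from one NET protocol."""

    protocol: str
    abscissa: np.ndarray          # delay ms | ISI ms | current % | width ms
    values: np.ndarray            # threshold (pA) or threshold change (%)
    kind: str = "threshold_change_pct"

    def __post_init__(self) -> None:
        object.__setattr__(self, "abscissa", np.asarray(self.abscissa, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))


@dataclass(frozen=True)
class NetIndices:
    """TROND-style excitability indices of one scenario.

    Threshold-change sign conventions follow clinical reporting:
    depolarizing TE positive, hyperpolarizing TE negative,
    superexcitability negative, refractoriness/subexcitability positive.
    """

    rheobase_pa: float
    sdtc_ms: float
    te_d_10_20: float
    te_d_90_100: float
    te_h_10_20: float
    te_h_90_100: float
    te_h_99: float
    refractoriness_pct: float
    superexcitability_pct: float
    subexcitability_pct: float
    relative_refractory_period_ms: float
    iv_minus_80: float
    iv_minus_100: float
    hyperpolarizing_iv_slope: float
    resting_potential_mv: float
    threshold_1ms_pa: float

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# jitted membrane integrator

@njit(cache=True)
def _vtrap(x, y):
    # x / (1 - exp(-x/y)) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y * (1.0 + 0.5 * x / y)
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def _integrate(state, n_steps, dt, i_ext, pvec, mk_mats, vmin, dvinv,
               io1, io2):
    """Advance the axon ``n_steps`` of ``dt`` ms with constant nodal current.

    Mutates ``state`` in place; returns the maximum nodal potential seen.
    """
    rs = pvec[_RS]
    n_mk = state.size - _MK0
    n_grid = mk_mats.shape[0]
    p_tmp = np.empty(n_mk)
    vmax = state[_VN]
    for _ in range(n_steps):
        vn = state[_VN]
        vi = state[_VI]

        # --- HH gate kinetics (rates at 20 degC, scaled by rs) ---------
        am = 1.86 * _vtrap(vn + 18.4, 10.3)
        bm = 0.086 * _vtrap(-(vn + 22.7), 9.16)
        ah = 0.0336 * _vtrap(-(vn + 111.0), 11.0)
        bh = 2.3 / (1.0 + math.exp(-(vn + 28.8) / 13.4))

        p_inf = 1.0 / (1.0 + math.exp(-(vn + 55.0) / 7.0))
        tau_p = 5.0
        sn_inf = 1.0 / (1.0 + math.exp(-(vn + 52.0) / 8.0))
        tau_sn = 8.0 + 120.0 / (1.0 + math.exp((vn + 55.0) / 8.0))
        nn_inf = 1.0 / (1.0 + math.exp(-(vn + 65.0) / 10.0))
        tau_nn = 2.5
        si_inf = 1.0 / (1.0 + math.exp(-(vi + 52.0) / 8.0))
        tau_si = 8.0 + 120.0 / (1.0 + math.exp((vi + 55.0) / 8.0))
        ni_inf = 1.0 / (1.0 + math.exp(-(vi + 65.0) / 10.0))
        tau_ni = 2.5
        q_inf = 1.0 / (1.0 + math.exp((vi + 100.0) / 6.0))
        tau_q = 150.0

        km = (am + bm) * rs
        kh = (ah + bh) * rs
        state[_M] += (am * rs / km - state[_M]) * (1.0 - math.exp(-dt * km))
        state[_H] += (ah * rs / kh - state[_H]) * (1.0 - math.exp(-dt * kh))
        state[_P] += (p_inf - state[_P]) * (1.0 - math.exp(-dt * rs / tau_p))
        state[_SN] += (sn_inf - state[_SN]) * (1.0 - math.exp(-dt * rs / tau_sn))
        state[_NN] += (nn_inf - state[_NN]) * (1.0 - math.exp(-dt * rs / tau_nn))
        state[_SI] += (si_inf - state[_SI]) * (1.0 - math.exp(-dt * rs / tau_si))
        state[_NI] += (ni_inf - state[_NI]) * (1.0 - math.exp(-dt * rs / tau_ni))
        state[_Q] += (q_inf - state[_Q]) * (1.0 - math.exp(-dt * rs / tau_q))

        # --- Markov resurgent-channel occupancy ------------------------
        g = (vn - vmin) * dvinv
        if g < 0.0:
            g = 0.0
        elif g > n_grid - 1.001:
            g = n_grid - 1.001
        i0 = int(g)
        w = g - i0
        for j in range(n_mk):
            acc = 0.0
            for k in range(n_mk):
                acc += state[_MK0 + k] * ((1.0 - w) * mk_mats[i0, k, j]
                                          + w * mk_mats[i0 + 1, k, j])
            p_tmp[j] = acc
        tot = 0.0
        for j in range(n_mk):
            if p_tmp[j] < 0.0:
                p_tmp[j] = 0.0
            tot += p_tmp[j]
        for j in range(n_mk):
            state[_MK0 + j] = p_tmp[j] / tot
        po = state[_MK0 + io1] + state[_MK0 + io2]

        # --- membrane potentials (semi-implicit Euler) ------------------
        m3h = state[_M] ** 3 * state[_H]
        g_na_hh = pvec[_G_NAT] * (1.0 - pvec[_FRAC_RES]) * m3h
        g_na_mk = pvec[_G_NAT] * pvec[_FRAC_RES] * po
        g_nap = pvec[_G_NAP] * state[_P]
        g_kn = pvec[_G_KS_N] * state[_SN] + pvec[_G_KF_N] * state[_NN]
        gn = g_na_hh + g_na_mk + g_nap + g_kn + pvec[_G_LK_N]
        bn = ((g_na_hh + g_na_mk + g_nap) * pvec[_E_NA]
              + g_kn * pvec[_E_K] + pvec[_G_LK_N] * pvec[_E_LK] + i_ext
              - pvec[_I_PUMP] * pvec[_PUMP_NODE])

        g_ki = pvec[_G_KF_I] * state[_NI] + pvec[_G_KS_I] * state[_SI]
        g_h = pvec[_G_H] * state[_Q]
        gi = g_ki + g_h + pvec[_G_LK_I]
        bi = (g_ki * pvec[_E_K] + g_h * pvec[_E_H]
              + pvec[_G_LK_I] * pvec[_E_LK]
              - pvec[_I_PUMP] * (1.0 - pvec[_PUMP_NODE]))

        gbb = pvec[_G_BB]
        a11 = pvec[_C_N] / dt + gn + gbb
        a22 = pvec[_C_I] / dt + gi + gbb
        r1 = pvec[_C_N] / dt * vn + bn
        r2 = pvec[_C_I] / dt * vi + bi
        det = a11 * a22 - gbb * gbb
        vn_new = (r1 * a22 + gbb * r2) / det
        vi_new = (a11 * r2 + gbb * r1) / det
        state[_VN] = vn_new
        state[_VI] = vi_new
        if vn_new > vmax:
            vmax = vn_new
    return vmax


# ---------------------------------------------------------------------------
# axon model object

class Axon:
    """An integrable two-compartment axon bound to one Markov channel set."""

    def __init__(self, params: AxonParameters,
                 channel: ChannelParameterSet | None = None,
                 scheme: GatingScheme | None = None,
                 v_grid: tuple[float, float, float] = (-170.0, 80.0, 0.2)):
        self.params = params
        self.channel = channel if channel is not None else get_parameters(params.channel)
        self.scheme = scheme if scheme is not None else default_scheme()
        self._io1 = self.scheme.state_index("O1")
        self._io2 = self.scheme.state_index("O2")
        self.pvec = params.to_vector()
        self.dt = params.dt_ms
        vmin, vmax, dv = v_grid
        self._vmin = vmin
        self._dvinv = 1.0 / dv
        grid = np.arange(vmin, vmax + dv / 2, dv)
        n = self.scheme.n_states
        mats = np.empty((grid.size, n, n))
        for i, v in enumerate(grid):
            q = build_generator(self.scheme, self.channel, v, params.temperature_c)
            mats[i] = expm(q * self.dt)
        self._mk_mats = mats
        self.resting_state = self._find_resting_state()
        self.resting_potential = float(self.resting_state[_VN])
        if not (-95.0 <= self.resting_potential <= -55.0):
            raise RuntimeError(
                f"no physiological resting state: V_rest = "
                f"{self.resting_potential:.1f} mV outside [-95, -55]"
            )

    # -- state handling ------------------------------------------------

    def _initial_state(self, v0: float = -82.0) -> np.ndarray:
        st = np.zeros(_MK0 + self.scheme.n_states)
        st[_VN] = st[_VI] = v0
        st[_M] = st[_H] = st[_P] = st[_SN] = st[_NN] = 0.1
        st[_SI] = st[_NI] = st[_Q] = 0.1
        p0 = stationary_distribution(
            build_generator(self.scheme, self.channel, v0, self.params.temperature_c)
        )
        st[_MK0:] = p0
        return st

    def _find_resting_state(self) -> np.ndarray:
        st = self._initial_state()
        self.run(st, 500.0, 0.0)
        return st

    def run(self, state: np.ndarray, duration_ms: float, i_ext: float) -> float:
        """Advance ``state`` in place; returns the max nodal potential."""
        n = max(1, int(round(duration_ms / self.dt)))
        return _integrate(state, n, self.dt, float(i_ext), self.pvec,
                          self._mk_mats, self._vmin, self._dvinv,
                          self._io1, self._io2)

    def resting_drift(self, duration_ms: float = 500.0) -> float:
        """|dV_rest| over an extra relaxation run (stability diagnostic)."""
        st = self.resting_state.copy()
        v0 = st[_VN]
        self.run(st, duration_ms, 0.0)
        return abs(float(st[_VN]) - v0)

    # -- threshold tracking ---------------------------------------------

    def _spikes(self, state0: np.ndarray, width: float, amplitude: float,
                background: list[tuple[float, float]] | None) -> bool:
        """Does a width-ms pulse of given amplitude fire within 5 ms of onset?"""
        st = state0.copy()
        total = max(width, SPIKE_WINDOW_MS)
        sched = background if background else [(total, 0.0)]
        vmax = -1e9
        t = 0.0
        for dur, bg in sched:
            if t >= total:
                break
            dur = min(dur, total - t)
            # split the segment at the end of the test pulse
            if t < width:
                d1 = min(dur, width - t)
                vmax = max(vmax, self.run(st, d1, bg + amplitude))
                dur -= d1
                t += d1
            if dur > 0:
                vmax = max(vmax, self.run(st, dur, bg))
                t += dur
        return vmax >= SPIKE_THRESHOLD_MV

    def find_threshold(self, width_ms: float = 1.0,
                       state: np.ndarray | None = None,
                       background: list[tuple[float, float]] | None = None,
                       guess: float | None = None) -> float:
        """Bisection threshold (pA) of a ``width_ms`` test pulse.

        ``background`` is an optional piecewise-constant conditioning
        current [(duration ms, pA), ...] that continues during the test.
        Returns NaN (unexcitable) if no spike occurs at 100x the initial
        bracket.
        """
        if width_ms <= 0:
            raise ValueError("stimulus width must be positive")
        state0 = state if state is not None else self.resting_state
        if self._spikes(state0, width_ms, 0.0, background):
            return 0.0  # conditioning alone is suprathreshold
        hi = guess if guess is not None and np.isfinite(guess) and guess > 0 else 500.0
        hi0 = hi
        while not self._spikes(state0, width_ms, hi, background):
            hi *= 2.0
            if hi > 100.0 * hi0:
                return float("nan")
        lo = 0.0
        while (hi - lo) / hi > BISECTION_RTOL:
            mid = 0.5 * (lo + hi)
            if self._spikes(state0, width_ms, mid, background):
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)


def build_axon(params: AxonParameters,
               channel: ChannelParameterSet | None = None,
               scheme: GatingScheme | None = None) -> Axon:
    """Construct the membrane model and locate its resting state."""
    return Axon(params, channel=channel, scheme=scheme)


def find_threshold(axon: Axon, width_ms: float = 1.0, **kw) -> float:
    return axon.find_threshold(width_ms, **kw)


# ---------------------------------------------------------------------------
# NET battery

DEFAULT_SD_WIDTHS = (0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_TE_LEVELS = (0.4, 0.2, -0.2, -0.4)       # fractions of threshold
DEFAULT_TE_DELAYS = (10.0, 15.0, 20.0, 90.0, 95.0, 99.0)
DEFAULT_IV_LEVELS = (0.5, 0.3, 0.1, -0.1, -0.3, -0.5, -0.7, -0.8, -0.9, -1.0)
DEFAULT_RC_INTERVALS = (2.0, 2.5, 3.2, 4.0, 5.0, 6.3, 8.0, 10.0, 14.0,
                        20.0, 30.0, 50.0, 100.0, 200.0)
TE_CONDITIONING_MS = 100.0
IV_CONDITIONING_MS = 200.0


def _weiss_regression(widths, thresholds):
    """Weiss's law: threshold charge Q = rheobase * (width + SDTC)."""
    w = np.asarray(widths, float)
    thr = np.asarray(thresholds, float)
    charge = thr * w
    slope, intercept = np.polyfit(w, charge, 1)
    return float(slope), float(intercept / slope)  # rheobase, SDTC


def run_net_battery(
    axon: Axon,
    sd_widths=DEFAULT_SD_WIDTHS,
    te_levels=DEFAULT_TE_LEVELS,
    te_delays=DEFAULT_TE_DELAYS,
    iv_levels=DEFAULT_IV_LEVELS,
    rc_intervals=DEFAULT_RC_INTERVALS,
    refractoriness_interval: float | None = None,
) -> tuple[list[ThresholdProtocolResult], NetIndices]:
    """Run the NET battery and compute TROND-style indices.

    ``refractoriness_interval`` defaults to 2.5 ms at >=30 degC and
    3.2 ms below (the cooled convention).
    """
    if refractoriness_interval is None:
        refractoriness_interval = 2.5 if axon.params.temperature_c >= 30.0 else 3.2
    results: list[ThresholdProtocolResult] = []

    # --- strength-duration ---------------------------------------------
    sd_thr = []
    guess = None
    for w in sorted(sd_widths, reverse=True):  # longest first: best bracket
        thr = axon.find_threshold(w, guess=guess)
        guess = thr * 1.5 if np.isfinite(thr) else None
        sd_thr.append((w, thr))
    sd_thr.sort()
    widths = [w for w, _ in sd_thr]
    thr_w = [t for _, t in sd_thr]
    rheobase, sdtc = _weiss_regression(widths, thr_w)
    results.append(ThresholdProtocolResult("strength_duration", widths, thr_w,
                                           kind="threshold_pa"))
    i0 = thr_w[-1]  # unconditioned 1 ms threshold

    # --- threshold electrotonus ----------------------------------------
    te_series = {}
    for level in te_levels:
        bg = level * i0
        st = axon.resting_state.copy()
        t = 0.0
        changes = []
        for d in sorted(te_delays):
            axon.run(st, d - t, bg)
            t = d
            remaining = max(TE_CONDITIONING_MS - d, 0.0)
            background = [(remaining, bg), (1e9, 0.0)]
            thr = axon.find_threshold(1.0, state=st, background=background,
                                      guess=i0 * (1.0 - 0.8 * level))
            changes.append(100.0 * (i0 - thr) / i0)
        te_series[level] = (sorted(te_delays), changes)
        results.append(ThresholdProtocolResult(
            f"threshold_electrotonus_{int(level * 100):+d}",
            sorted(te_delays), changes))

    def te_window(level, lo, hi):
        d, c = te_series[level]
        sel = [ci for di, ci in zip(d, c) if lo <= di <= hi]
        return float(np.mean(sel)) if sel else float("nan")

    def te_at(level, delay):
        d, c = te_series[level]
        return float(np.interp(delay, d, c))

    # --- current-threshold (I/V) ---------------------------------------
    iv_changes = []
    for level in sorted(iv_levels, reverse=True):
        bg = level * i0
        st = axon.resting_state.copy()
        axon.run(st, IV_CONDITIONING_MS - 1.0, bg)
        background = [(1e9, bg)]  # polarizing current continues during test
        thr = axon.find_threshold(1.0, state=st, background=background,
                                  guess=i0 * max(1.0 - 1.2 * level, 0.2))
        iv_changes.append((level, 100.0 * (i0 - thr) / i0))
    iv_levels_sorted = [l for l, _ in iv_changes]
    iv_vals = [c for _, c in iv_changes]
    results.append(ThresholdProtocolResult(
        "current_threshold", [100 * l for l in iv_levels_sorted], iv_vals))
    iv_map = dict(iv_changes)
    # hyperpolarizing I/V slope: d(current)/d(threshold reduction), most
    # hyperpolarized three levels, both axes as fractions of threshold
    hyp = sorted(iv_changes)[:3]
    slope = np.polyfit([c / 100.0 for _, c in hyp], [l for l, _ in hyp], 1)[0]

    # --- recovery cycle -------------------------------------------------
    isis = sorted(set(list(rc_intervals) + [refractoriness_interval]))
    st = axon.resting_state.copy()
    axon.run(st, 1.0, 2.0 * i0)   # supramaximal 1 ms conditioning stimulus
    t = 1.0
    rc_changes = []
    for isi in isis:
        if isi > t:
            axon.run(st, isi - t, 0.0)
            t = isi
        snap = st.copy()
        thr = axon.find_threshold(1.0, state=snap, guess=2.0 * i0)
        change = (100.0 * (thr - i0) / i0) if np.isfinite(thr) else float("nan")
        rc_changes.append(change)
    results.append(ThresholdProtocolResult("recovery_cycle", isis, rc_changes))
    rc = np.asarray(rc_changes)
    isis_arr = np.asarray(isis)
    finite = np.isfinite(rc)
    refr = float(np.interp(refractoriness_interval, isis_arr[finite], rc[finite]))
    superex = float(np.nanmin(rc))
    # subexcitability: late positive peak after the superexcitable minimum
    i_min = int(np.nanargmin(rc))
    late = finite & (np.arange(rc.size) > i_min) & (isis_arr >= 10.0)
    subex = float(np.max(rc[late])) if late.any() else float("nan")
    # relative refractory period: first downward zero crossing
    rrp = float("nan")
    for a, b, ca, cb in zip(isis_arr[finite][:-1], isis_arr[finite][1:],
                            rc[finite][:-1], rc[finite][1:]):
        if ca > 0 >= cb:
            rrp = float(a + (b - a) * ca / (ca - cb))
            break

    indices = NetIndices(
        rheobase_pa=rheobase,
        sdtc_ms=sdtc,
        te_d_10_20=te_window(0.4, 10.0, 20.0),
        te_d_90_100=te_window(0.4, 90.0, 100.0),
        te_h_10_20=te_window(-0.4, 10.0, 20.0),
        te_h_90_100=te_window(-0.4, 90.0, 100.0),
        te_h_99=te_at(-0.4, 99.0),
        refractoriness_pct=refr,
        superexcitability_pct=superex,
        subexcitability_pct=subex,
        relative_refractory_period_ms=rrp,
        iv_minus_80=float(iv_map.get(-0.8, float("nan"))),
        iv_minus_100=float(iv_map.get(-1.0, float("nan"))),
        hyperpolarizing_iv_slope=float(slope),
        resting_potential_mv=axon.resting_potential,
        threshold_1ms_pa=float(i0),
    )
    return results, indices


# ---------------------------------------------------------------------------
# shipped scenarios

def load_scenario(name: str, temperature_c: float | None = None) -> Axon:
    """Build a shipped NET scenario: ``control`` (WT, pump 30 pA) or
    ``iem`` (IEM channels, pump 15 pA), optionally at a non-default
    temperature (36 degC baseline, 25 degC cooled)."""
    fname = {"control": "net_control.yaml", "iem": "net_iem.yaml"}.get(name)
    if fname is None:
        raise KeyError(f"unknown scenario {name!r}; expected 'control' or 'iem'")
    with resources.files("resurgentsim.data").joinpath(fname).open() as fh:
        params = AxonParameters.from_yaml(fh)
    if temperature_c is not None:
        params = replace(params, temperature_c=temperature_c)
    return build_axon(params)
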