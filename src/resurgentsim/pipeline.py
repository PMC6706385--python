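"""End-to-end studies: the temperature-sweep voltage-clamp battery and
the control-vs-IEM nerve-excitability comparison.

Both studies emit tidy long-format tables (genotype, temperature,
protocol, metric, value, units) for machine readability; ``pivot_table``
renders the classic genotype-by-temperature layout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import analysis
from .axon import load_scenario, run_net_battery
from .protocols import make_protocol, run_battery
from .rates import get_parameters
from .scheme import default_scheme

__all__ = ["StudyConfig", "run_temperature_sweep", "run_net_comparison",
           "pivot_table", "write_table"]

_VERSION = "0.1.0"


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the paper-shaped studies."""

    genotypes: tuple[str, ...] = ("wt", "iem")
    temperatures_c: tuple[float, ...] = (15.0, 25.0, 40.0)
    protocols: tuple[str, ...] = ("activation_iv", "inactivation", "resurgent",
                                  "recovery", "prepulse_duration")
    axon_scenarios: tuple[str, ...] = ("control", "iem")
    axon_temperatures_c: tuple[float, ...] = (36.0, 25.0)
    recovery_max_gap_ms: float = 30.0
    recovery_gap_step_ms: float = 0.3
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if len(self.genotypes) < 1:
            raise ValueError("need at least one genotype")
        for t in tuple(self.temperatures_c) + tuple(self.axon_temperatures_c):
            if not (0.0 <= t <= 50.0):
                raise ValueError(f"temperature {t} outside [0, 50] degC")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _rows(genotype, temperature, protocol, metrics: dict, units: dict):
    out = []
    for name, value in metrics.items():
        out.append({
            "genotype": genotype, "temperature_c": temperature,
            "protocol": protocol, "metric": name,
            "value": float(value) if value is not None else np.nan,
            "units": units.get(name, ""),
        })
    return out


def run_temperature_sweep(config: StudyConfig = StudyConfig()) -> pd.DataFrame:
    """Voltage-clamp battery over genotypes x temperatures.

    For each combination the activation, inactivation, resurgent,
    recovery and prepulse-duration protocols are simulated and analyzed;
    the result is a tidy metrics table including the mutant-over-WT
    resurgent ratio ("ratio of ratios") where both genotypes ran.
    """
    scheme = default_scheme()
    rows = []
    res_ratio: dict[tuple[str, float], float] = {}
    for genotype in config.genotypes:
        params = get_parameters(genotype)
        for t_c in config.temperatures_c:
            label = params.label
            if "activation_iv" in config.protocols:
                traces = run_battery(scheme, params,
                                     make_protocol("activation_iv"), t_c,
                                     keep_occupancy=False)
                iv = analysis.analyze_iv(traces)
                sel = (iv.test_voltages >= -80) & (iv.test_voltages <= 40)
                act = analysis.fit_boltzmann(iv.test_voltages[sel],
                                             iv.normalized_conductance[sel],
                                             form="activation")
                sus = np.mean([
                    analysis.sustained_ratio(tr) for tr in traces
                    if tr.meta["sweep_value"] in (10.0, 20.0, 30.0)
                ])
                rows += _rows(label, t_c, "activation_iv", {
                    "vh_activation": act.vh, "k_activation": act.k,
                    "v_na": iv.v_na, "sustained_peak_ratio": sus,
                }, {"vh_activation": "mV", "k_activation": "mV", "v_na": "mV"})
                act_fit = act
            if "inactivation" in config.protocols:
                traces = run_battery(scheme, params,
                                     make_protocol("inactivation"), t_c,
                                     keep_occupancy=False)
                v, avail = analysis.inactivation_availability(traces)
                inact = analysis.fit_boltzmann(v, avail, form="inactivation")
                rows += _rows(label, t_c, "inactivation", {
                    "vh_inactivation": inact.vh, "k_inactivation": inact.k,
                }, {"vh_inactivation": "mV", "k_inactivation": "mV"})
                if "activation_iv" in config.protocols:
                    win = analysis.window_curve(act_fit, inact)
                    rows += _rows(label, t_c, "window", {
                        "window_area": win.area,
                        **{f"window_at_{int(v)}mV": p
                           for v, p in win.spot_values.items()},
                    }, {"window_area": "mV"})
            if "resurgent" in config.protocols:
                traces = run_battery(scheme, params, make_protocol("resurgent"),
                                     t_c, keep_occupancy=False)
                met = analysis.resurgent_metrics(traces)
                reg = analysis.fit_decay_voltage_regression(
                    met.voltages, met.decay_tau_ms)
                at40 = met.at_voltage(-40.0)
                res_ratio[(genotype, t_c)] = met.max_ratio
                rows += _rows(label, t_c, "resurgent", {
                    "resurgent_transient_ratio": met.max_ratio,
                    "resurgent_ratio_-40mV": at40["ratio_peak"],
                    "time_to_peak_-40mV": at40["time_to_peak_ms"],
                    "decay_tau_-40mV": at40["decay_tau_ms"],
                    "decay_regression_A": reg.a, "decay_regression_k": reg.k,
                }, {"time_to_peak_-40mV": "ms", "decay_tau_-40mV": "ms",
                    "decay_regression_A": "1/ms"})
            if "recovery" in config.protocols:
                proto = make_protocol(
                    "recovery", max_gap=config.recovery_max_gap_ms,
                    gap_step=config.recovery_gap_step_ms)
                traces = run_battery(scheme, params, proto, t_c,
                                     keep_occupancy=False)
                gaps, fracs = analysis.recovery_fractions(traces)
                fit = analysis.fit_recovery(gaps, np.clip(fracs, 0, 1.05),
                                            recovery_voltage_mv=-80.0,
                                            temperature_c=t_c)
                rows += _rows(label, t_c, "recovery", {
                    "recovery_tau": fit.tau_ms,
                }, {"recovery_tau": "ms"})
            if "prepulse_duration" in config.protocols:
                traces = run_battery(scheme, params,
                                     make_protocol("prepulse_duration"), t_c,
                                     keep_occupancy=False)
                met = analysis.resurgent_metrics(traces)
                peaks = met.peak_resurgent / met.peak_resurgent.max()
                durs = np.array([tr.segments[0].duration for tr in traces])
                fit = analysis.fit_prepulse_decay(np.sort(durs),
                                                  peaks[np.argsort(durs)])
                rows += _rows(label, t_c, "prepulse_duration", {
                    "prepulse_decay_tau": fit.tau_ms,
                    "prepulse_residual_f0": fit.f0,
                }, {"prepulse_decay_tau": "ms"})
    # mutant-over-WT ratio of resurgent ratios, per temperature
    for t_c in config.temperatures_c:
        if ("wt", t_c) in res_ratio:
            for genotype in config.genotypes:
                if genotype == "wt" or (genotype, t_c) not in res_ratio:
                    continue
                rows += _rows(get_parameters(genotype).label, t_c, "resurgent", {
                    "ratio_to_wt": analysis.ratio_to_wt(
                        res_ratio[(genotype, t_c)], res_ratio[("wt", t_c)]),
                }, {})
    return pd.DataFrame(rows)


def run_net_comparison(config: StudyConfig = StudyConfig(),
                       **battery_kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NET battery for every scenario x temperature.

    Returns (index table, per-protocol curve table), both tidy.
    """
    if len(config.axon_scenarios) < 2:
        raise ValueError("need two axon scenarios to compare")
    idx_rows, curve_rows = [], []
    for scenario in config.axon_scenarios:
        for t_c in config.axon_temperatures_c:
            axon = load_scenario(scenario, temperature_c=t_c)
            protos, indices = run_net_battery(axon, **battery_kwargs)
            for name, value in indices.to_dict().items():
                idx_rows.append({"scenario": scenario, "temperature_c": t_c,
                                 "metric": name, "value": value})
            for pr in protos:
                for x, y in zip(pr.abscissa, pr.values):
                    curve_rows.append({
                        "scenario": scenario, "temperature_c": t_c,
                        "protocol": pr.protocol, "abscissa": float(x),
                        "value": float(y), "kind": pr.kind,
                    })
    return pd.DataFrame(idx_rows), pd.DataFrame(curve_rows)


def pivot_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Genotype-by-temperature pivot of a tidy metrics table."""
    return tidy.pivot_table(index="metric",
                            columns=[c for c in ("genotype", "scenario")
                                     if c in tidy.columns] + ["temperature_c"],
                            values="value")


def write_table(df: pd.DataFrame, path, config: StudyConfig | None = None) -> None:
    """CSV with a provenance header (config hash, package version)."""
    with open(path, "w") as fh:
        fh.write(f"# resurgentsim {_VERSION}\n")
        if config is not None:
            fh.write(f"# config_hash {config.hash()}\n")
        df.to_csv(fh, index=False)
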