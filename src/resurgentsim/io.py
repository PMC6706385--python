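"""Trace and metrics export: HDF5 sweep groups, flat CSV, tidy tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CurrentTrace, VoltageSegment

__all__ = ["write_traces_h5", "read_traces_h5", "traces_to_csv", "traces_to_frame"]


def write_traces_h5(path, traces: list[CurrentTrace]) -> None:
    """One HDF5 group per sweep with time, voltage, current, occupancy."""
    import h5py

    with h5py.File(path, "w") as fh:
        for idx, tr in enumerate(traces):
            g = fh.create_group(f"sweep_{idx:04d}")
            g.create_dataset("time_ms", data=tr.time_ms)
            g.create_dataset("voltage_mv", data=tr.voltage_mv)
            g.create_dataset("current", data=tr.current)
            if tr.occupancy is not None:
                g.create_dataset("occupancy", data=tr.occupancy)
            g.attrs["temperature_c"] = tr.temperature_c
            g.attrs["dt_ms"] = tr.dt_ms
            g.attrs["segment_levels"] = [s.level for s in tr.segments]
            g.attrs["segment_durations"] = [s.duration for s in tr.segments]
            for key, val in tr.meta.items():
                if isinstance(val, (int, float, str, np.floating, np.integer)):
                    g.attrs[f"meta_{key}"] = val


def read_traces_h5(path) -> list[CurrentTrace]:
    import h5py

    traces = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            segs = tuple(
                VoltageSegment(float(l), float(d))
                for l, d in zip(g.attrs["segment_levels"],
                                g.attrs["segment_durations"])
            )
            meta = {k[5:]: (v.item() if hasattr(v, "item") else v)
                    for k, v in g.attrs.items() if k.startswith("meta_")}
            traces.append(CurrentTrace(
                time_ms=g["time_ms"][:], voltage_mv=g["voltage_mv"][:],
                current=g["current"][:],
                temperature_c=float(g.attrs["temperature_c"]),
                dt_ms=float(g.attrs["dt_ms"]),
                occupancy=g["occupancy"][:] if "occupancy" in g else None,
                segments=segs, meta=meta,
            ))
    return traces


def traces_to_frame(traces: list[CurrentTrace]) -> pd.DataFrame:
    """Flat long-format frame (time_ms, voltage_mV, current, sweep_id)."""
    frames = []
    for idx, tr in enumerate(traces):
        frames.append(pd.DataFrame({
            "time_ms": tr.time_ms,
            "voltage_mV": tr.voltage_mv,
            "current": tr.current,
            "sweep_id": idx,
            "sweep_value": tr.meta.get("sweep_value", np.nan),
        }))
    return pd.concat(frames, ignore_index=True)


def traces_to_csv(path, traces: list[CurrentTrace]) -> None:
    traces_to_frame(traces).to_csv(path, index=False)
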