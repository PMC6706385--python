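"""Voltage-clamp protocol definitions and batch execution.

Each protocol is data: a holding potential, a per-sweep segment template,
and a single sweep-varying parameter (one segment's level or duration).
The shipped defaults follow the standard whole-cell battery for
resurgent-current work on Nav1.7:

* ``activation_iv``   - hold -120 mV, 100 ms steps from -160 to +40 mV in
  5 mV increments (41 sweeps).
* ``inactivation``    - 100 ms prepulse from -160 to +20 mV in 10 mV
  steps, then a +10 mV / 100 ms test pulse.
* ``resurgent``       - +40 mV / 10 ms prepulse, then repolarization to
  -20 ... -60 mV in 10 mV increments for 100 ms.
* ``recovery``        - paired +20 mV / 10 ms pulses separated by a
  growing gap at the recovery voltage (default -80 mV), gaps in 0.1 ms
  increments.
* ``prepulse_duration`` - +60 mV prepulse of growing duration, then a
  fixed repolarization test at -40 mV.

Sweeps are delivered every 1.5 s; at -120 mV holding every relaxation
time is far below that, so batteries model the inter-sweep interval as
full re-equilibration at holding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .rates import ChannelParameterSet
from .scheme import GatingScheme, stationary_distribution
from .simulate import (CurrentTrace, Propagator, VoltageSegment, default_dt,
                       simulate_sweep, REVERSAL_POTENTIAL_MV)

__all__ = ["SweepProtocol", "make_protocol", "run_battery", "PROTOCOL_KINDS"]

PROTOCOL_KINDS = (
    "activation_iv", "inactivation", "resurgent", "recovery", "prepulse_duration",
)


@dataclass(frozen=True)
class SweepProtocol:
    """A family of sweeps: fixed segment template + one varying parameter.

    ``vary_segment`` indexes into ``segments``; ``vary_attr`` is ``"level"``
    or ``"duration"``; ``vary_values`` holds one value per sweep.
    """

    name: str
    holding_mv: float
    segments: tuple[VoltageSegment, ...]
    vary_segment: int
    vary_attr: str
    vary_values: tuple[float, ...]
    interval_ms: float = 1500.0

    def __post_init__(self) -> None:
        if len(self.vary_values) < 1:
            raise ValueError("protocol needs at least one sweep")
        if self.vary_attr not in ("level", "duration"):
            raise ValueError(f"vary_attr must be level|duration, got {self.vary_attr}")
        if not (0 <= self.vary_segment < len(self.segments)):
            raise IndexError("vary_segment out of range")
        for v in self.vary_values:
            if self.vary_attr == "duration" and not (v > 0):
                raise ValueError("durations must be positive")
        for seg in self.segments:
            _ = seg  # constructed -> already validated

    @property
    def n_sweeps(self) -> int:
        return len(self.vary_values)

    def sweep_segments(self, value: float) -> tuple[VoltageSegment, ...]:
        """Concrete segment list for one value of the varying parameter."""
        segs = list(self.segments)
        segs[self.vary_segment] = replace(
            segs[self.vary_segment], **{self.vary_attr: float(value)}
        )
        return tuple(segs)

    # -- serialization -------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = {
            "name": self.name,
            "holding_mv": self.holding_mv,
            "segments": [{"level": s.level, "duration": s.duration}
                         for s in self.segments],
            "vary": {"segment": self.vary_segment, "attr": self.vary_attr,
                     "values": list(self.vary_values)},
            "interval_ms": self.interval_ms,
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SweepProtocol":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        elif "\n" in str(source):
            doc = yaml.safe_load(str(source))
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls(
            name=doc["name"],
            holding_mv=float(doc["holding_mv"]),
            segments=tuple(VoltageSegment(float(s["level"]), float(s["duration"]))
                           for s in doc["segments"]),
            vary_segment=int(doc["vary"]["segment"]),
            vary_attr=doc["vary"]["attr"],
            vary_values=tuple(float(v) for v in doc["vary"]["values"]),
            interval_ms=float(doc.get("interval_ms", 1500.0)),
        )


def _frange(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(start + k * step for k in range(n))


def make_protocol(kind: str, **overrides) -> SweepProtocol:
    """Build a named protocol with its shipped defaults.

    Overrides (all optional): ``holding``, ``interval``; per-kind knobs
    such as ``start``, ``stop``, ``increment``, ``test_level``,
    ``test_duration``, ``prepulse_level``, ``prepulse_duration``,
    ``levels``, ``gaps``, ``recovery_voltage``, ``max_gap``, ``gap_step``,
    ``durations``.
    """
    if kind not in PROTOCOL_KINDS:
        raise KeyError(f"unknown protocol kind {kind!r}; expected one of {PROTOCOL_KINDS}")
    holding = float(overrides.pop("holding", -120.0))
    interval = float(overrides.pop("interval", 1500.0))

    if kind == "activation_iv":
        start = float(overrides.pop("start", -160.0))
        stop = float(overrides.pop("stop", 40.0))
        inc = float(overrides.pop("increment", 5.0))
        dur = float(overrides.pop("test_duration", 100.0))
        values = overrides.pop("levels", None) or _frange(start, stop, inc)
        segments = (VoltageSegment(0.0, dur),)
        proto = SweepProtocol(kind, holding, segments, 0, "level",
                              tuple(values), interval)
    elif kind == "inactivation":
        start = float(overrides.pop("start", -160.0))
        stop = float(overrides.pop("stop", 20.0))
        inc = float(overrides.pop("increment", 10.0))
        pre_dur = float(overrides.pop("prepulse_duration", 100.0))
        test_level = float(overrides.pop("test_level", 10.0))
        test_dur = float(overrides.pop("test_duration", 100.0))
        values = overrides.pop("levels", None) or _frange(start, stop, inc)
        segments = (VoltageSegment(0.0, pre_dur),
                    VoltageSegment(test_level, test_dur))
        proto = SweepProtocol(kind, holding, segments, 0, "level",
                              tuple(values), interval)
    elif kind == "resurgent":
        pre_level = float(overrides.pop("prepulse_level", 40.0))
        pre_dur = float(overrides.pop("prepulse_duration", 10.0))
        repol_dur = float(overrides.pop("repolarization_duration", 100.0))
        values = overrides.pop("levels", None) or (-20.0, -30.0, -40.0, -50.0, -60.0)
        segments = (VoltageSegment(pre_level, pre_dur),
                    VoltageSegment(0.0, repol_dur))
        proto = SweepProtocol(kind, holding, segments, 1, "level",
                              tuple(values), interval)
    elif kind == "recovery":
        pulse_level = float(overrides.pop("pulse_level", 20.0))
        pulse_dur = float(overrides.pop("pulse_duration", 10.0))
        vr = float(overrides.pop("recovery_voltage", -80.0))
        max_gap = float(overrides.pop("max_gap", 100.0))
        gap_step = float(overrides.pop("gap_step", 0.1))
        gaps = overrides.pop("gaps", None) or _frange(gap_step, max_gap, gap_step)
        segments = (VoltageSegment(pulse_level, pulse_dur),
                    VoltageSegment(vr, 1.0),
                    VoltageSegment(pulse_level, pulse_dur))
        proto = SweepProtocol(kind, holding, segments, 1, "duration",
                              tuple(gaps), interval)
    else:  # prepulse_duration
        pre_level = float(overrides.pop("prepulse_level", 60.0))
        test_level = float(overrides.pop("test_level", -40.0))
        test_dur = float(overrides.pop("test_duration", 100.0))
        durations = overrides.pop(
            "durations", None
        ) or (2.0, 5.0, 10.0, 20.0, 40.0, 70.0, 110.0, 160.0, 220.0, 300.0)
        segments = (VoltageSegment(pre_level, 10.0),
                    VoltageSegment(test_level, test_dur))
        proto = SweepProtocol(kind, holding, segments, 0, "duration",
                              tuple(durations), interval)

    if overrides:
        raise TypeError(f"unknown overrides for {kind}: {sorted(overrides)}")
    return proto


def run_battery(
    scheme: GatingScheme,
    params: ChannelParameterSet,
    protocol: SweepProtocol,
    temperature_c: float,
    dt: float | None = None,
    gmax: float = 1.0,
    erev: float = REVERSAL_POTENTIAL_MV,
    keep_occupancy: bool = True,
) -> list[CurrentTrace]:
    """Run every sweep of a protocol; one CurrentTrace per sweep.

    Each sweep starts from the stationary distribution at the holding
    potential (the 1.5 s inter-sweep interval dwarfs every relaxation
    time at -120 mV, so full re-equilibration is assumed).
    """
    prop = Propagator(scheme, params)
    p_hold = stationary_distribution(
        prop.generator(protocol.holding_mv, temperature_c)
    )
    if dt is None:
        dt = default_dt(temperature_c)
    traces = []
    for value in protocol.vary_values:
        segs = protocol.sweep_segments(value)
        tr = simulate_sweep(
            scheme, params, segs, temperature_c, p0=p_hold, dt=dt,
            gmax=gmax, erev=erev, propagator=prop,
            keep_occupancy=keep_occupancy,
            meta={
                "protocol": protocol.name,
                "sweep_value": float(value),
                "vary_attr": protocol.vary_attr,
                "holding_mv": protocol.holding_mv,
                "genotype": params.label,
            },
        )
        traces.append(tr)
    return traces
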