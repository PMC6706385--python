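"""Seeded synthetic datasets for exercising every fitting stage.

Real recordings carry cell-to-cell variability and instrument noise that
the deterministic simulator does not.  This module emulates both:

* noisy current sweeps — additive Gaussian noise with standard deviation
  expressed as a fraction of the transient peak (default 0.02), plus a
  per-cell log-normal conductance jitter (CV 10%) standing in for cell
  size variation;
* noisy gating-curve samples — Boltzmann, recovery or prepulse-decay
  curves evaluated on a grid with Gaussian noise, clipped to the
  physical range.

A single master seed derives independent per-replicate streams, so an
identical seed always reproduces an identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import boltzmann
from .protocols import SweepProtocol, run_battery
from .rates import ChannelParameterSet
from .scheme import GatingScheme
from .simulate import CurrentTrace

__all__ = ["NoiseModel", "SyntheticDataset", "generate_noisy_sweeps",
           "generate_curve_dataset", "CURVE_KINDS"]

CURVE_KINDS = ("boltzmann", "recovery", "prepulse_decay")

#: Coefficient of variation of the per-cell conductance jitter.
GMAX_JITTER_CV = 0.10


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian current noise, as a fraction of the transient peak."""

    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    def spawn(self, n: int) -> list[np.random.Generator]:
        """n independent, deterministic per-replicate generators."""
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(child) for child in ss.spawn(n)]


@dataclass(frozen=True)
class SyntheticDataset:
    """Synthetic data plus the parameters that generated it."""

    kind: str
    data: object                       # list-of-cells traces, or (x, Y) arrays
    generating_parameters: dict
    provenance: dict = field(default_factory=dict)


def generate_noisy_sweeps(
    scheme: GatingScheme,
    params: ChannelParameterSet,
    protocol: SweepProtocol,
    temperature_c: float,
    noise: NoiseModel = NoiseModel(),
    n_cells: int = 5,
    dt: float | None = None,
    gmax: float = 1.0,
) -> SyntheticDataset:
    """Simulate a battery once, then emit ``n_cells`` noisy replicates.

    Each cell scales every sweep by one log-normal gmax factor (CV 10%)
    and adds white Gaussian current noise of ``sigma`` times the battery's
    transient peak magnitude.  ``sigma == 0`` with ``n_cells == 1``
    returns traces bitwise equal to the simulator output.
    """
    if n_cells < 1:
        raise ValueError("need n_cells >= 1")
    clean = run_battery(scheme, params, protocol, temperature_c, dt=dt,
                        gmax=gmax, keep_occupancy=False)
    peak = max(np.abs(tr.current).max() for tr in clean)
    rngs = noise.spawn(n_cells)
    # log-normal with unit mean: mu = -s^2/2
    s = np.sqrt(np.log(1.0 + GMAX_JITTER_CV ** 2))
    cells: list[list[CurrentTrace]] = []
    for rng in rngs:
        if noise.sigma == 0 and n_cells == 1:
            cells.append(list(clean))
            continue
        jitter = float(np.exp(rng.normal(-0.5 * s * s, s)))
        cell = []
        for tr in clean:
            eps = rng.normal(0.0, noise.sigma * peak, size=tr.current.size)
            cell.append(CurrentTrace(
                time_ms=tr.time_ms, voltage_mv=tr.voltage_mv,
                current=tr.current * jitter + eps,
                temperature_c=tr.temperature_c, dt_ms=tr.dt_ms,
                occupancy=None, segments=tr.segments,
                meta={**tr.meta, "cell_gmax_factor": jitter},
            ))
        cells.append(cell)
    return SyntheticDataset(
        kind="sweeps",
        data=cells,
        generating_parameters={
            "genotype": params.label, "gmax": gmax,
            "transitions": {n: params[n].to_dict() for n in params},
        },
        provenance={"protocol": protocol.name, "temperature_c": temperature_c,
                    "sigma": noise.sigma, "seed": noise.seed,
                    "n_cells": n_cells},
    )


def _curve_model(kind: str, params: dict):
    if kind == "boltzmann":
        return lambda x: boltzmann(x, params["vh"], params["k"]), (0.0, 1.0)
    if kind == "recovery":
        return lambda x: 1.0 - np.exp(-np.asarray(x, float) / params["tau"]), (0.0, 1.05)
    if kind == "prepulse_decay":
        f0, tau = params["f0"], params["tau"]
        return lambda x: (1.0 - f0) * np.exp(-np.asarray(x, float) / tau) + f0, (0.0, 1.0)
    raise KeyError(f"unknown curve kind {kind!r}; expected one of {CURVE_KINDS}")


def generate_curve_dataset(
    kind: str,
    generating_parameters: dict,
    x_grid,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 1,
    clip: bool = True,
) -> SyntheticDataset:
    """Noisy samples of a named curve family on a grid.

    Returns data ``(x, Y)`` with ``Y`` of shape (n_replicates, len(x)).
    Samples are ``model(x) + N(0, sigma)``, clipped to the curve's
    physical range unless ``clip=False``.
    """
    model, rng_range = _curve_model(kind, generating_parameters)
    x = np.asarray(x_grid, dtype=float)
    clean = model(x)
    rngs = noise.spawn(n_replicates)
    rows = []
    for rng in rngs:
        y = clean + rng.normal(0.0, noise.sigma, size=x.size)
        if clip:
            y = np.clip(y, *rng_range)
        rows.append(y)
    return SyntheticDataset(
        kind=kind,
        data=(x, np.vstack(rows)),
        generating_parameters=dict(generating_parameters),
        provenance={"sigma": noise.sigma, "seed": noise.seed,
                    "n_replicates": n_replicates, "clip": clip},
    )
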