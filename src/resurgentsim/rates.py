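"""Voltage- and temperature-dependent transition-rate laws for Nav1.7 gating.

Every transition of the gating scheme follows a single functional form

    k(V, T) = k0 * exp(k1 * V) * q10 ** ((T - t0) / 10)

where ``k0`` is the rate at 0 mV and the reference temperature ``t0``
(25 degC), ``k1`` is the voltage-dependence coefficient in 1/mV and
``q10`` the temperature coefficient.  Wild-type (WT) and inherited
erythromelalgia (IEM) mutant channels share this form and differ only in
a handful of coefficients, most importantly the Q10 of the transitions
between the resurgent open state O2 and its inactivated state I2
(~2 in WT versus ~3.3 in IEM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "RateLaw",
    "ChannelParameterSet",
    "TRANSITION_NAMES",
    "evaluate_rate",
    "wild_type_parameters",
    "iem_parameters",
]

#: Reference temperature (degC) at which k0 is specified.
REFERENCE_TEMPERATURE = 25.0

#: Canonical transition names of the resurgent-gating scheme.
TRANSITION_NAMES = (
    "alpha", "beta", "gamma", "delta",
    "c_on", "c_off", "o_on", "o_off",
    "o1o2", "o2o1", "o2i2", "i2o2",
    "i1i2", "i2i1",
)


@dataclass(frozen=True)
class RateLaw:
    """A single exponential-in-voltage, Q10-in-temperature rate law.

    Parameters
    ----------
    k0 : float
        Transition rate at 0 mV and the reference temperature (1/ms).
    k1 : float
        Voltage-dependence coefficient (1/mV).
    q10 : float
        Fold change of the rate per 10 degC increase.
    t0 : float
        Reference temperature in degC (25 by convention).
    """

    k0: float
    k1: float = 0.0
    q10: float = 1.0
    t0: float = REFERENCE_TEMPERATURE

    def __post_init__(self) -> None:
        if not (self.k0 > 0):
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if not (self.q10 > 0):
            raise ValueError(f"q10 must be positive, got {self.q10}")
        for name in ("k0", "k1", "q10", "t0"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def __call__(self, v: float, t: float = REFERENCE_TEMPERATURE) -> float:
        return evaluate_rate(self, v, t)

    def to_dict(self) -> dict:
        return {"k0": self.k0, "k1": self.k1, "q10": self.q10}


def evaluate_rate(law: RateLaw, v: float, t: float = REFERENCE_TEMPERATURE) -> float:
    """Evaluate ``k0 * exp(k1*V) * q10**((T-t0)/10)`` in 1/ms.

    Raises
    ------
    ValueError
        If ``v`` or ``t`` is non-finite.
    """
    if not np.all(np.isfinite(v)):
        raise ValueError(f"membrane potential must be finite, got {v}")
    if not np.all(np.isfinite(t)):
        raise ValueError(f"temperature must be finite, got {t}")
    return law.k0 * np.exp(law.k1 * v) * law.q10 ** ((t - law.t0) / 10.0)


@dataclass(frozen=True)
class ChannelParameterSet:
    """The full fourteen-transition parameterization of one genotype."""

    label: str
    laws: Mapping[str, RateLaw] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [n for n in TRANSITION_NAMES if n not in self.laws]
        if missing:
            raise ValueError(f"missing rate laws: {missing}")
        extra = [n for n in self.laws if n not in TRANSITION_NAMES]
        if extra:
            raise ValueError(f"unknown rate laws: {extra}")

    def __getitem__(self, name: str) -> RateLaw:
        return self.laws[name]

    def __iter__(self) -> Iterator[str]:
        return iter(TRANSITION_NAMES)

    def rate(self, name: str, v: float, t: float = REFERENCE_TEMPERATURE) -> float:
        return evaluate_rate(self.laws[name], v, t)

    def replace(self, **laws: RateLaw) -> "ChannelParameterSet":
        """Return a copy with some rate laws substituted (for what-if runs)."""
        merged = dict(self.laws)
        merged.update(laws)
        return ChannelParameterSet(label=self.label, laws=merged)

    # -- serialization -------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = {
            "label": self.label,
            "reference_temperature_c": REFERENCE_TEMPERATURE,
            "transitions": {n: self.laws[n].to_dict() for n in TRANSITION_NAMES},
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ChannelParameterSet":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" in text or text.strip().startswith("label:"):
                doc = yaml.safe_load(text)
            else:
                with open(text) as fh:
                    doc = yaml.safe_load(fh)
        t0 = float(doc.get("reference_temperature_c", REFERENCE_TEMPERATURE))
        laws = {
            name: RateLaw(k0=float(d["k0"]), k1=float(d.get("k1", 0.0)),
                          q10=float(d.get("q10", 1.0)), t0=t0)
            for name, d in doc["transitions"].items()
        }
        return cls(label=doc["label"], laws=laws)


def _load_preset(name: str) -> ChannelParameterSet:
    with resources.files("resurgentsim.data").joinpath(name).open() as fh:
        return ChannelParameterSet.from_yaml(fh)


def wild_type_parameters() -> ChannelParameterSet:
    """Wild-type Nav1.7 parameter set (shipped YAML)."""
    return _load_preset("wt.yaml")


def iem_parameters() -> ChannelParameterSet:
    """IEM-mutant Nav1.7 parameter set (shipped YAML)."""
    return _load_preset("iem.yaml")


def get_parameters(genotype: str) -> ChannelParameterSet:
    """Look up a shipped parameter set by genotype tag (``wt`` or ``iem``)."""
    key = genotype.strip().lower()
    if key in ("wt", "wild_type", "wildtype"):
        return wild_type_parameters()
    if key == "iem":
        return iem_parameters()
    raise KeyError(f"unknown genotype {genotype!r}; expected 'wt' or 'iem'")
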