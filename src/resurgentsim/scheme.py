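"""State topology of the resurgent-gating scheme and its generator matrix.

The gating scheme is a connected, reversible graph over closed (C1..C4),
open (O1, O2) and inactivated (I1, I2) states.  At a fixed membrane
potential and temperature the occupancy vector evolves as ``dp/dt = p Q``
where ``Q`` is the transition-rate (generator) matrix assembled here.

The topology is data, not code: it ships as a YAML edge list
(``data/scheme.yaml``) so a corrected transcription is a one-file change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy.linalg import expm, null_space

from .rates import ChannelParameterSet, TRANSITION_NAMES

__all__ = [
    "Transition",
    "GatingScheme",
    "OccupancyState",
    "default_scheme",
    "build_generator",
    "stationary_distribution",
]


@dataclass(frozen=True)
class Transition:
    """A directed edge of the scheme: ``frm -> to`` at ``multiplier * rate``."""

    frm: str
    to: str
    rate: str
    multiplier: float = 1.0


@dataclass(frozen=True)
class OccupancyState:
    """Probability vector over scheme states at one time point."""

    probabilities: np.ndarray
    time_ms: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancies must sum to 1, got {p.sum()!r}")


@dataclass(frozen=True)
class GatingScheme:
    """State list, directed transitions and the set of conducting states."""

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    conducting: frozenset[str]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.states)})
        if not self.conducting:
            raise ValueError("conducting-state set must be non-empty")
        unknown = {t.frm for t in self.transitions} | {t.to for t in self.transitions}
        unknown -= set(self.states)
        if unknown:
            raise ValueError(f"transitions reference unknown states: {sorted(unknown)}")
        if not self.conducting <= set(self.states):
            raise ValueError("conducting states must be scheme states")
        for t in self.transitions:
            if t.multiplier <= 0:
                raise ValueError(f"multiplier must be positive on {t}")
        edges = {(t.frm, t.to) for t in self.transitions}
        missing = [(a, b) for (a, b) in edges if (b, a) not in edges]
        if missing:
            raise ValueError(f"transitions without a reverse edge: {missing}")
        if not self._connected():
            raise ValueError("scheme graph is not connected")

    def _connected(self) -> bool:
        adj: dict[str, set[str]] = {s: set() for s in self.states}
        for t in self.transitions:
            adj[t.frm].add(t.to)
            adj[t.to].add(t.frm)
        seen = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == len(self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self._index[name]

    @property
    def conducting_indices(self) -> np.ndarray:
        return np.array(sorted(self._index[s] for s in self.conducting), dtype=int)

    # -- serialization -------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = {
            "states": list(self.states),
            "conducting": sorted(self.conducting),
            "transitions": [
                {"from": t.frm, "to": t.to, "rate": t.rate, "multiplier": t.multiplier}
                for t in self.transitions
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GatingScheme":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        elif "\n" in str(source):
            doc = yaml.safe_load(str(source))
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        transitions = tuple(
            Transition(frm=d["from"], to=d["to"], rate=d["rate"],
                       multiplier=float(d.get("multiplier", 1.0)))
            for d in doc["transitions"]
        )
        return cls(states=tuple(doc["states"]),
                   transitions=transitions,
                   conducting=frozenset(doc["conducting"]))


def coupling_factor(c_on: float = 0.1, c_off: float = 0.5,
                    o_on: float = 2.5, o_off: float = 0.004,
                    n_closed: int = 4) -> float:
    """Allosteric coupling factor ``a`` between activation and inactivation.

    Closed-state inactivation rates are scaled by ``a**(i-1)`` along the
    activation chain (and the inactivated chain's activation steps by
    ``a`` / deactivation by ``1/a``), with ``a`` chosen so that every
    activation-inactivation cycle of the two-chain scheme satisfies
    microscopic reversibility:

        a ** (2 * n_steps) = (o_on * c_off) / (c_on * o_off)

    where ``n_steps = n_closed`` counts the activation steps between the
    resting closed state and the open state (including the final
    gamma/delta opening step).
    """
    return float(((o_on * c_off) / (c_on * o_off)) ** (1.0 / (2 * n_closed)))


def two_chain_scheme(n_closed: int = 4, a: float | None = None) -> GatingScheme:
    """Resurgent-gating topology with a parallel inactivated chain.

    Closed states C1..Cn activate via alpha/beta (statistical multipliers)
    and open through gamma/delta into O1; an inactivated chain IC1..ICn
    mirrors the closed chain (activation scaled by ``a``, deactivation by
    ``1/a``) and terminates in the open-inactivated state I1, coupled to
    O1 via o_on/o_off and to each C_i via c_on*a**(i-1) / c_off*a**-(i-1).
    O1 <-> O2 (o1o2/o2o1), O2 <-> I2 (o2i2/i2o2) and I1 <-> I2
    (i1i2/i2i1) form the resurgent loop, which is the scheme's only
    thermodynamically unbalanced cycle (resurgent gating is a driven,
    cyclic process).
    """
    if a is None:
        a = coupling_factor(n_closed=n_closed)
    closed = [f"C{i}" for i in range(1, n_closed + 1)]
    inact = [f"IC{i}" for i in range(1, n_closed + 1)]
    states = tuple(closed + ["O1"] + inact + ["I1", "O2", "I2"])
    edges: list[Transition] = []
    for i in range(n_closed - 1):
        fwd = float(n_closed - 1 - i)
        bwd = float(i + 1)
        edges.append(Transition(closed[i], closed[i + 1], "alpha", fwd))
        edges.append(Transition(closed[i + 1], closed[i], "beta", bwd))
        edges.append(Transition(inact[i], inact[i + 1], "alpha", fwd * a))
        edges.append(Transition(inact[i + 1], inact[i], "beta", bwd / a))
    edges.append(Transition(closed[-1], "O1", "gamma", 1.0))
    edges.append(Transition("O1", closed[-1], "delta", 1.0))
    edges.append(Transition(inact[-1], "I1", "gamma", a))
    edges.append(Transition("I1", inact[-1], "delta", 1.0 / a))
    for i in range(n_closed):
        edges.append(Transition(closed[i], inact[i], "c_on", a ** i))
        edges.append(Transition(inact[i], closed[i], "c_off", a ** (-i)))
    edges.append(Transition("O1", "I1", "o_on", 1.0))
    edges.append(Transition("I1", "O1", "o_off", 1.0))
    edges.append(Transition("O1", "O2", "o1o2", 1.0))
    edges.append(Transition("O2", "O1", "o2o1", 1.0))
    edges.append(Transition("O2", "I2", "o2i2", 1.0))
    edges.append(Transition("I2", "O2", "i2o2", 1.0))
    edges.append(Transition("I1", "I2", "i1i2", 1.0))
    edges.append(Transition("I2", "I1", "i2i1", 1.0))
    return GatingScheme(states=states, transitions=tuple(edges),
                        conducting=frozenset({"O1", "O2"}))


def single_inactivated_scheme(attach: str = "C4") -> GatingScheme:
    """Eight-state variant with ONE aggregate fast-inactivated state I1.

    I1 couples to the closed chain at ``attach`` (c_on/c_off) and to O1
    (o_on/o_off).  This compact topology recovers fast from inactivation
    (exit directly through c_off) but its activation-inactivation cycle
    is strongly unbalanced, which sustains a circulating open-state flux
    (an exaggerated steady window current) at subthreshold potentials.
    Shipped for comparison; :func:`two_chain_scheme` is the default.
    """
    states = ("C1", "C2", "C3", "C4", "O1", "I1", "O2", "I2")
    e: list[Transition] = []
    for i, (f, b) in enumerate([(3.0, 1.0), (2.0, 2.0), (1.0, 3.0)]):
        e.append(Transition(f"C{i + 1}", f"C{i + 2}", "alpha", f))
        e.append(Transition(f"C{i + 2}", f"C{i + 1}", "beta", b))
    e += [Transition("C4", "O1", "gamma"), Transition("O1", "C4", "delta"),
          Transition(attach, "I1", "c_on"), Transition("I1", attach, "c_off"),
          Transition("O1", "I1", "o_on"), Transition("I1", "O1", "o_off"),
          Transition("O1", "O2", "o1o2"), Transition("O2", "O1", "o2o1"),
          Transition("O2", "I2", "o2i2"), Transition("I2", "O2", "i2o2"),
          Transition("I1", "I2", "i1i2"), Transition("I2", "I1", "i2i1")]
    return GatingScheme(states=states, transitions=tuple(e),
                        conducting=frozenset({"O1", "O2"}))


def default_scheme() -> GatingScheme:
    """The shipped twelve-state resurgent-gating topology."""
    with resources.files("resurgentsim.data").joinpath("scheme.yaml").open() as fh:
        return GatingScheme.from_yaml(fh)


def build_generator(scheme: GatingScheme, params: ChannelParameterSet,
                    v: float, t: float) -> np.ndarray:
    """Assemble the generator matrix Q(V, T) in 1/ms.

    ``Q[i, j]`` for ``i != j`` is the i->j transition rate (multiplier times
    the rate law evaluated at V, T); diagonal entries make each row sum to
    zero, so that ``dp/dt = p Q`` conserves probability.
    """
    for tr in scheme.transitions:
        if tr.rate not in params.laws:
            raise KeyError(
                f"transition {tr.frm}->{tr.to} needs rate law {tr.rate!r} "
                f"which is not in parameter set {params.label!r}"
            )
    n = scheme.n_states
    q = np.zeros((n, n))
    for tr in scheme.transitions:
        i, j = scheme.state_index(tr.frm), scheme.state_index(tr.to)
        q[i, j] += tr.multiplier * params.rate(tr.rate, v, t)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary occupancy p with ``p Q = 0`` and ``sum(p) = 1``.

    Solved from the null space of Q^T; if the null space is not
    one-dimensional (numerically defective generator) the function falls
    back to long-time propagation from the uniform distribution and warns.
    """
    q = np.asarray(q, dtype=float)
    ns = null_space(q.T, rcond=1e-10)
    if ns.shape[1] == 1:
        p = ns[:, 0]
        p = np.abs(p) / np.abs(p).sum()
    else:
        warnings.warn(
            "generator null space is not one-dimensional; "
            "falling back to long-time propagation", RuntimeWarning
        )
        # 10 s of propagation dwarfs every relaxation time of the scheme
        p = np.full(q.shape[0], 1.0 / q.shape[0]) @ expm(q * 1e4)
        p = np.clip(p, 0.0, None)
        p /= p.sum()
    resid = np.max(np.abs(p @ q))
    if resid > 1e-9:
        warnings.warn(f"stationary residual {resid:.2e} exceeds 1e-9", RuntimeWarning)
    return p


def cycle_imbalance(scheme: GatingScheme, params: ChannelParameterSet,
                    v: float = 0.0, t: float = 25.0) -> dict[tuple, float]:
    """Diagnostic: log-ratio of forward/backward rate products around cycles.

    The rate table is taken verbatim, so thermodynamic loop balance is not
    enforced; this reports the imbalance of each independent cycle of the
    graph (empty dict means all cycles balanced at this V, T).
    """
    import networkx as nx  # local import; diagnostics only

    g = nx.Graph()
    g.add_edges_from({tuple(sorted((tr.frm, tr.to))) for tr in scheme.transitions})
    rate = {(tr.frm, tr.to): tr.multiplier * params.rate(tr.rate, v, t)
            for tr in scheme.transitions}
    out = {}
    for cyc in nx.cycle_basis(g):
        loop = list(cyc) + [cyc[0]]
        lg = 0.0
        for a, b in zip(loop[:-1], loop[1:]):
            lg += np.log(rate[(a, b)]) - np.log(rate[(b, a)])
        if abs(lg) > 1e-9:
            out[tuple(loop)] = float(lg)
    return out
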