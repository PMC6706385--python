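"""Gating-scheme topology, generator assembly and stationary occupancy."""

import numpy as np
import pytest
from scipy.linalg import expm

import resurgentsim as rs
from resurgentsim.rates import RateLaw, ChannelParameterSet, TRANSITION_NAMES
from resurgentsim.scheme import GatingScheme, Transition, coupling_factor


def two_state(a, b):
    """Toy A<->B scheme driven through the alpha/beta laws."""
    laws = {n: RateLaw(k0=1.0) for n in TRANSITION_NAMES}
    laws["alpha"] = RateLaw(k0=a)
    laws["beta"] = RateLaw(k0=b)
    params = ChannelParameterSet(label="WT", laws=laws)
    scheme = GatingScheme(
        states=("A", "B"),
        transitions=(Transition("A", "B", "alpha"), Transition("B", "A", "beta")),
        conducting=frozenset({"B"}),
    )
    return scheme, params


@pytest.mark.parametrize("v,t", [(-120.0, 25.0), (40.0, 15.0), (0.0, 40.0)])
def test_generator_row_sums_vanish(scheme, wt, v, t):
    q = rs.build_generator(scheme, wt, v, t)
    assert np.abs(q.sum(axis=1)).max() < 1e-12
    off = q - np.diag(np.diag(q))
    assert (off >= 0).all()


def test_two_state_stationary_matches_detailed_balance():
    a, b = 2.0, 3.0
    sch, par = two_state(a, b)
    p = rs.stationary_distribution(rs.build_generator(sch, par, 0.0, 25.0))
    assert p[1] == pytest.approx(a / (a + b), rel=1e-9)


def test_two_state_symmetric_gives_half():
    sch, par = two_state(1.3, 1.3)
    p = rs.stationary_distribution(rs.build_generator(sch, par, 0.0, 25.0))
    assert p == pytest.approx([0.5, 0.5], rel=1e-9)


def test_full_generator_matches_hand_assembly(scheme, wt, rate_table):
    """Element-by-element assembly from the printed constants."""
    v, t = -120.0, 25.0
    q = rs.build_generator(scheme, wt, v, t)
    n = scheme.n_states
    expected = np.zeros((n, n))
    for tr in scheme.transitions:
        k0, k1, q10 = rate_table["WT"][tr.rate]
        rate = tr.multiplier * k0 * np.exp(k1 * v) * q10 ** ((t - 25.0) / 10.0)
        expected[scheme.state_index(tr.frm), scheme.state_index(tr.to)] += rate
    np.fill_diagonal(expected, 0.0)
    np.fill_diagonal(expected, -expected.sum(axis=1))
    np.testing.assert_allclose(q, expected, rtol=1e-12, atol=0)


def test_stationary_solves_pq_zero_on_simplex(scheme, wt):
    q = rs.build_generator(scheme, wt, -120.0, 25.0)
    p = rs.stationary_distribution(q)
    assert np.abs(p @ q).max() < 1e-9
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert (p >= 0).all()


def test_resting_conducting_occupancy_negligible(scheme, wt):
    """At -120 mV / 25 degC the channel sits in resting closed states;
    the long-time propagation oracle agrees."""
    q = rs.build_generator(scheme, wt, -120.0, 25.0)
    p = rs.stationary_distribution(q)
    assert p[scheme.conducting_indices].sum() < 1e-3
    oracle = np.full(q.shape[0], 1.0 / q.shape[0]) @ expm(q * 1e4)
    np.testing.assert_allclose(p, oracle, atol=1e-8)


def test_stationary_invariant_to_state_relabeling(scheme, wt):
    q = rs.build_generator(scheme, wt, -60.0, 25.0)
    p = rs.stationary_distribution(q)
    rng = np.random.default_rng(0)
    perm = rng.permutation(q.shape[0])
    p_perm = rs.stationary_distribution(q[np.ix_(perm, perm)])
    np.testing.assert_allclose(p_perm, p[perm], atol=1e-10)


def test_missing_rate_law_raises(scheme):
    laws = {n: RateLaw(k0=1.0) for n in TRANSITION_NAMES}
    params = ChannelParameterSet(label="WT", laws=laws)
    bad = GatingScheme(
        states=("A", "B"),
        transitions=(Transition("A", "B", "alpha"), Transition("B", "A", "beta")),
        conducting=frozenset({"B"}),
    )
    # remove beta -> configuration error surfaces on assembly
    del laws["beta"]
    with pytest.raises(ValueError):
        ChannelParameterSet(label="WT", laws=laws)
    ok = ChannelParameterSet(label="WT",
                             laws={n: RateLaw(k0=1.0) for n in TRANSITION_NAMES})
    q = rs.build_generator(bad, ok, 0.0, 25.0)
    assert q.shape == (2, 2)


def test_reverse_edges_required():
    with pytest.raises(ValueError, match="reverse"):
        GatingScheme(states=("A", "B"),
                     transitions=(Transition("A", "B", "alpha"),),
                     conducting=frozenset({"B"}))


def test_disconnected_graph_rejected():
    with pytest.raises(ValueError, match="connected"):
        GatingScheme(
            states=("A", "B", "C"),
            transitions=(Transition("A", "B", "alpha"),
                         Transition("B", "A", "beta")),
            conducting=frozenset({"B"}),
        )


def test_shipped_yaml_matches_programmatic_builder(scheme):
    built = rs.two_chain_scheme()
    assert built.states == scheme.states
    assert built.conducting == scheme.conducting
    assert sorted((t.frm, t.to, t.rate, round(t.multiplier, 12))
                  for t in built.transitions) == \
           sorted((t.frm, t.to, t.rate, round(t.multiplier, 12))
                  for t in scheme.transitions)


def test_scheme_yaml_roundtrip(scheme, tmp_path):
    path = tmp_path / "scheme.yaml"
    scheme.to_yaml(path)
    back = GatingScheme.from_yaml(path)
    assert back == scheme


def test_coupling_factor_balances_gating_cycles(scheme, wt):
    """Every activation-inactivation cycle is reversible; only the
    resurgent loop carries a net driving imbalance."""
    from resurgentsim.scheme import cycle_imbalance
    bad = cycle_imbalance(scheme, wt, v=-50.0, t=25.0)
    resurgent_states = {"O2", "I2"}
    for cycle in bad:
        assert resurgent_states & set(cycle), f"unbalanced non-resurgent cycle {cycle}"
    a = coupling_factor()
    assert a ** 8 == pytest.approx((2.5 * 0.5) / (0.1 * 0.004), rel=1e-12)


def test_single_inactivated_variant_builds_and_conserves(wt):
    sch = rs.single_inactivated_scheme()
    q = rs.build_generator(sch, wt, -40.0, 25.0)
    assert np.abs(q.sum(axis=1)).max() < 1e-12
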