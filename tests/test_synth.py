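"""Synthetic-data generation: determinism, zero-noise exactness, recovery."""

import numpy as np
import pytest
from scipy.stats import binomtest

import resurgentsim as rs
from resurgentsim.analysis import resurgent_metrics, fit_recovery, fit_boltzmann
from resurgentsim.synth import NoiseModel, generate_noisy_sweeps, generate_curve_dataset


def test_zero_noise_single_cell_is_bitwise_identical(scheme, wt):
    proto = rs.make_protocol("resurgent", levels=[-40.0])
    clean = rs.run_battery(scheme, wt, proto, 25.0, keep_occupancy=False)
    ds = generate_noisy_sweeps(scheme, wt, proto, 25.0,
                               noise=NoiseModel(sigma=0.0, seed=1), n_cells=1)
    np.testing.assert_array_equal(ds.data[0][0].current, clean[0].current)


def test_same_seed_reproduces_dataset(scheme, wt):
    proto = rs.make_protocol("resurgent", levels=[-40.0])
    kw = dict(noise=NoiseModel(sigma=0.02, seed=42), n_cells=3)
    a = generate_noisy_sweeps(scheme, wt, proto, 25.0, **kw)
    b = generate_noisy_sweeps(scheme, wt, proto, 25.0, **kw)
    for cell_a, cell_b in zip(a.data, b.data):
        for tr_a, tr_b in zip(cell_a, cell_b):
            np.testing.assert_array_equal(tr_a.current, tr_b.current)


def test_different_seeds_and_cells_differ(scheme, wt):
    proto = rs.make_protocol("resurgent", levels=[-40.0])
    a = generate_noisy_sweeps(scheme, wt, proto, 25.0,
                              noise=NoiseModel(sigma=0.02, seed=1), n_cells=2)
    b = generate_noisy_sweeps(scheme, wt, proto, 25.0,
                              noise=NoiseModel(sigma=0.02, seed=2), n_cells=2)
    assert not np.array_equal(a.data[0][0].current, b.data[0][0].current)
    assert not np.array_equal(a.data[0][0].current, a.data[1][0].current)


def test_generating_parameters_stored(scheme, iem):
    proto = rs.make_protocol("resurgent", levels=[-40.0])
    ds = generate_noisy_sweeps(scheme, iem, proto, 40.0, n_cells=1)
    assert ds.generating_parameters["genotype"] == "IEM"
    assert ds.provenance["temperature_c"] == 40.0
    assert ds.provenance["protocol"] == "resurgent"


def test_curve_dataset_zero_noise_exact():
    v = np.linspace(-90.0, 30.0, 25)
    ds = generate_curve_dataset("boltzmann", {"vh": -21.8, "k": 8.3}, v,
                                noise=NoiseModel(sigma=0.0, seed=0))
    x, reps = ds.data
    np.testing.assert_array_equal(reps[0], rs.analysis.boltzmann(v, -21.8, 8.3))


def test_recovery_curve_dataset_round_trips_through_fit():
    t = np.arange(0.2, 15.0, 0.2)
    ds = generate_curve_dataset("recovery", {"tau": 1.78}, t,
                                noise=NoiseModel(sigma=0.0, seed=0))
    x, reps = ds.data
    assert fit_recovery(x, reps[0]).tau_ms == pytest.approx(1.78, rel=1e-9)


def test_unknown_curve_kind_rejected():
    with pytest.raises(KeyError):
        generate_curve_dataset("sigmoid", {}, [0, 1, 2])


def test_boltzmann_empirical_se_matches_asymptotic():
    """Monte-Carlo spread of Vh across seeded replicates agrees with the
    least-squares standard error (factor-of-2 sanity band)."""
    v = np.linspace(-90.0, 50.0, 29)
    ds = generate_curve_dataset("boltzmann", {"vh": -21.8, "k": 8.3}, v,
                                noise=NoiseModel(sigma=0.02, seed=3),
                                n_replicates=100, clip=False)
    x, reps = ds.data
    fits = [fit_boltzmann(x, y, "activation") for y in reps]
    empirical = np.std([f.vh for f in fits], ddof=1)
    asymptotic = np.median([f.vh_stderr for f in fits])
    assert 0.5 < empirical / asymptotic < 2.0


def test_pipeline_noise_does_not_bias_resurgent_ratio(scheme, wt):
    """simulate -> add noise -> analyze is unbiased: across 20 seeds the
    signed deviations of the noisy resurgent ratio from the noiseless one
    pass a two-sided sign test at alpha = 0.05."""
    proto = rs.make_protocol("resurgent", levels=[-40.0])
    clean = rs.run_battery(scheme, wt, proto, 25.0, keep_occupancy=False)
    truth = resurgent_metrics(clean).ratio_charge[0]
    signs = []
    for seed in range(20):
        ds = generate_noisy_sweeps(scheme, wt, proto, 25.0,
                                   noise=NoiseModel(sigma=0.02, seed=seed),
                                   n_cells=1)
        noisy = resurgent_metrics(ds.data[0]).ratio_charge[0]
        signs.append(noisy > truth)
    k = sum(signs)
    assert binomtest(k, 20, 0.5).pvalue > 0.05
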