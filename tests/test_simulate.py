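import math

import numpy as np
import pytest

from ribotraffic.simulate import (
    FeatureNorms,
    NominalTimes,
    TrafficConfig,
    bottleneck_distance_analysis,
    charge_window_sums,
    feature_bottleneck,
    fit_abc,
    simulate_deterministic,
    simulate_stochastic,
)


def _times(t, gene_id="g"):
    n = len(t)
    ones = np.ones(n)
    nt = NominalTimes(gene_id, ones, ones, ones, (1.0, 0.0, 0.0))
    nt.t = np.asarray(t, dtype=float)
    return nt


def test_charge_window_sums():
    c = [1, -1, 0, 1, 1]
    # codon 1 has an empty upstream window; full window length 2
    assert list(charge_window_sums(c, tunnel_len=2)) == [0, 1, 0, -1, 1]
    assert charge_window_sums(c, tunnel_len=31)[0] == 0


def test_nominal_times_closed_forms():
    ones = np.ones(5)
    nt = NominalTimes("g", ones, ones, ones, (1.0, 0.0, 0.0))
    assert np.allclose(nt.t, 1.0)
    nt2 = NominalTimes("g", ones, ones, ones, (1.0, 0.3, 0.2))
    assert np.allclose(nt2.t, math.exp(0.5))


def test_feature_norms_guard():
    with pytest.raises(ValueError):
        FeatureNorms(1.0, 0.0, -5.0)


def test_deterministic_single_ribosome():
    t = np.array([1.0, 2.0, 0.5, 3.0, 1.0] * 4)
    cfg = TrafficConfig(footprint=3, init_interval=math.inf, termination_time=1.0)
    sim = simulate_deterministic(_times(t), cfg)
    assert np.array_equal(sim.dwell, t)
    assert sim.production_rate == pytest.approx(1.0 / (t.sum() + 1.0))


def test_deterministic_wide_spacing_no_delay():
    t = np.ones(20)
    cfg = TrafficConfig(footprint=3, init_interval=100.0)
    sim = simulate_deterministic(_times(t), cfg)
    assert np.allclose(sim.dwell, t)
    assert sim.production_rate == pytest.approx(0.01, rel=1e-6)


def test_deterministic_hand_traced_max_plus():
    """5-codon lattice, footprint 1, one slow codon, tight spacing: the
    dwell vector equals a hand-traced max-plus table ([1, 5, 5, 1, 1])."""
    t = np.array([1.0, 1.0, 5.0, 1.0, 1.0])
    cfg = TrafficConfig(footprint=1, init_interval=1.0, termination_time=1.0)
    sim = simulate_deterministic(_times(t), cfg)
    assert np.allclose(sim.dwell, [1.0, 5.0, 5.0, 1.0, 1.0])


def test_deterministic_interactions_only_delay():
    rng = np.random.default_rng(0)
    t = rng.uniform(0.5, 2.0, 30)
    cfg = TrafficConfig(footprint=3, init_interval=5.0)
    base = simulate_deterministic(_times(t), cfg)
    # traffic can only add waiting on top of the nominal times
    assert np.all(base.dwell >= t - 1e-12)
    # and slowing any codon never increases throughput
    for i in (0, 10, 29):
        t2 = t.copy()
        t2[i] += 1.0
        slower = simulate_deterministic(_times(t2), cfg)
        assert slower.production_rate <= base.production_rate + 1e-12


def test_stochastic_determinism_and_occupancy_bounds():
    rates = np.ones(50)
    cfg = TrafficConfig(footprint=13, lam=0.2, burn_in=2000, measure=20000, seed=7)
    a = simulate_stochastic(rates, cfg, "x")
    b = simulate_stochastic(rates, cfg, "x")
    assert np.array_equal(a.occupancy, b.occupancy)
    assert a.production_rate == b.production_rate
    assert np.all((a.occupancy >= 0) & (a.occupancy <= 1))


def test_stochastic_low_density_current():
    # open-boundary exclusion process with pointlike particles: the
    # low-density current is alpha * (1 - alpha)
    cfg = TrafficConfig(footprint=1, lam=0.1, burn_in=50_000, measure=300_000, seed=1)
    sim = simulate_stochastic(np.ones(200), cfg, "x")
    assert sim.production_rate == pytest.approx(0.09, abs=0.01)


def test_stochastic_maximal_current_phase():
    # at strong initiation the current saturates near the known 1/4 maximum
    cfg = TrafficConfig(footprint=1, lam=1.0, burn_in=50_000, measure=300_000, seed=2)
    sim = simulate_stochastic(np.ones(200), cfg, "x")
    assert 0.2 < sim.production_rate < 0.3


def test_stochastic_single_ribosome_limit():
    # lam -> 0: occupancy ~ lam * t_i, tiny and flat for uniform rates
    cfg = TrafficConfig(
        footprint=13, lam=1e-3, burn_in=20_000, measure=400_000, seed=3
    )
    sim = simulate_stochastic(np.ones(100), cfg, "x")
    assert sim.occupancy.mean() == pytest.approx(1e-3, rel=0.35)
    assert sim.occupancy.max() < 0.01


def test_stochastic_littles_law():
    # mean ribosome number = production rate x mean transit time
    rng = np.random.default_rng(4)
    rates = rng.uniform(0.5, 2.0, 80)
    cfg = TrafficConfig(footprint=13, lam=0.01, burn_in=50_000, measure=500_000, seed=4)
    sim = simulate_stochastic(rates, cfg, "x")
    transit = (1.0 / rates).sum()  # sparse regime: no queueing delays
    assert sim.mean_ribosomes == pytest.approx(
        sim.production_rate * transit, rel=0.15
    )


def test_deterministic_and_stochastic_densities_agree(small_synth):
    from scipy.stats import spearmanr

    nt = small_synth.truth["nominal_times"]["g0000"]
    det = simulate_deterministic(nt, TrafficConfig(init_interval=math.inf))
    mean_rate = float(np.mean(1.0 / nt.t))
    cfg = TrafficConfig(
        footprint=13, lam=0.002 * mean_rate, burn_in=50_000, measure=500_000, seed=5
    )
    sto = simulate_stochastic(nt, cfg)
    rho = spearmanr(det.density, sto.density).statistic
    assert rho > 0.9


def test_fit_abc_recovery(small_synth):
    spec_noiseless = {
        gid: nt.t for gid, nt in small_synth.truth["nominal_times"].items()
    }
    (a1, a2, a3), rho = fit_abc(
        small_synth.truth["nominal_times"], spec_noiseless, max_positions=None
    )
    assert (a1, a2, a3) == (1.0, 0.4, 0.2)
    assert rho == pytest.approx(1.0)


def test_fit_abc_ablated_generation(small_synth):
    times = small_synth.truth["nominal_times"]
    flat = {gid: nt.combined((1.0, 0.0, 0.0)) for gid, nt in times.items()}
    (a1, a2, a3), _ = fit_abc(times, flat, max_positions=None)
    assert a2 == 0.0 and a3 == 0.0


def test_feature_bottleneck():
    v = np.ones(60)
    v[19:29] = 0.1  # slow stretch at codons 20-29 (1-based)
    assert feature_bottleneck(v, window=10, direction="min") == 20
    assert feature_bottleneck(np.arange(60.0), window=10, direction="min") == 1
    with pytest.raises(ValueError):
        feature_bottleneck(np.ones(5), window=10)


def test_bottleneck_distance_analysis(small_synth):
    noiseless = {
        gid: nt.t for gid, nt in small_synth.truth["nominal_times"].items()
    }
    res = bottleneck_distance_analysis(noiseless, noiseless, seed=0)
    assert res["mean_real"] == 0.0
    # model-generated noisy densities: real distances beat the permuted null
    res2 = bottleneck_distance_analysis(
        noiseless, small_synth.densities, n_permutations=3, seed=0
    )
    assert res2["mean_real"] < res2["mean_null"]
    assert res2["ks_p"] < 0.05


def test_predict_density_profile_identical_genes(small_synth):
    from ribotraffic.simulate import predict_density_profile

    nt = small_synth.truth["nominal_times"]["g0000"]
    times = {"a": nt, "b": nt}
    cfg = TrafficConfig(init_interval=math.inf)
    prof, smoothed = predict_density_profile(times, cfg, "deterministic")
    # a genome of identical genes reproduces the single-gene prediction
    assert np.allclose(prof.mean, nt.t)
    assert (prof.count == 2).all()
    assert len(smoothed) == len(prof)
    assert not np.allclose(smoothed.mean, prof.mean)  # smoothing applied
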