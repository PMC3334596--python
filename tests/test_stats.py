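import numpy as np
import pytest

from oracles import ks_statistic_brute, residual_partial_spearman
from ribotraffic.stats import (
    empirical_p,
    fit_regressor,
    ks_test,
    partial_corr_1,
    partial_corr_2,
    partial_corr_matrix,
    spearman,
    split_half_validation,
)


def test_ks_test_basic():
    a = np.arange(10.0)
    d, p = ks_test(a, a)
    assert d == 0.0 and p == 1.0
    d, _ = ks_test(np.arange(5.0), np.arange(10.0, 15.0))
    assert d == 1.0  # fully separated supports
    with pytest.raises(ValueError):
        ks_test([1.0], [1.0, 2.0])


def test_ks_statistic_matches_ecdf_scan():
    rng = np.random.default_rng(3)
    for _ in range(25):
        a = rng.normal(size=rng.integers(2, 20))
        b = rng.normal(0.5, 1.2, size=rng.integers(2, 20))
        d, _ = ks_test(a, b)
        assert d == pytest.approx(ks_statistic_brute(a, b), abs=1e-12)


def test_ks_rank_invariance():
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=30), rng.normal(0.3, 1, size=40)
    d1, _ = ks_test(a, b)
    d2, _ = ks_test(np.exp(a), np.exp(b))  # strictly monotone transform
    assert d1 == pytest.approx(d2)


def test_spearman():
    x = np.array([1.0, 2, 3, 4, 5])
    assert spearman(x, x).coefficient == pytest.approx(1.0)
    assert spearman(x, -x).coefficient == pytest.approx(-1.0)
    assert spearman(x, x**2).coefficient == pytest.approx(1.0)  # monotone
    with pytest.raises(ValueError):
        spearman(x, np.ones(5))


def test_partial_corr_1():
    assert partial_corr_1(0.8, 0.5, 0.5) == pytest.approx(0.55 / 0.75)
    assert partial_corr_1(0.3, 0.0, 0.0) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        partial_corr_1(0.3, 1.0, 0.2)


def test_partial_corr_2_matches_matrix_inversion():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = 50
        x, y, z, w = rng.normal(size=(4, n))
        y = y + 0.5 * x + 0.3 * z
        rec = partial_corr_2(x, y, z, w).coefficient
        inv = partial_corr_matrix(x, y, [z, w])
        assert rec == pytest.approx(inv, abs=1e-10)


def test_partial_corr_2_matches_residual_method():
    rng = np.random.default_rng(8)
    n = 500
    z, w = rng.normal(size=(2, n))
    x = 0.6 * z + rng.normal(size=n)
    y = 0.4 * x + 0.5 * w + rng.normal(size=n)
    rec = partial_corr_2(x, y, z, w).coefficient
    res = residual_partial_spearman(x, y, [z, w])
    assert rec == pytest.approx(res, abs=0.05)


def test_partial_corr_2_identity_and_degenerate():
    rng = np.random.default_rng(9)
    x = rng.normal(size=40)
    z, w = rng.normal(size=(2, 40))
    assert partial_corr_2(x, x, z, w).coefficient == pytest.approx(1.0)
    with pytest.raises(ValueError):
        partial_corr_2(x, x.copy(), x, w)  # control equal to x: |r| = 1


def test_empirical_p():
    rng = np.random.default_rng(10)
    x = np.arange(50.0)
    y = x + rng.normal(0, 1, 50)
    z, w = rng.normal(size=(2, 50))
    p = empirical_p(x, y, [z, w], B=50, seed=1)
    assert p <= 0.05  # strong association survives permutation
    assert p == empirical_p(x, y, [z, w], B=50, seed=1)  # seeded
    # a statistic blind to the data is never beaten strictly: p = 1
    p_const = empirical_p(x, y, [z, w], stat=lambda *a: 0.0, B=20, seed=0)
    assert p_const == 1.0


def test_fit_regressor_exact_recovery():
    rng = np.random.default_rng(11)
    inv_tai = rng.uniform(1, 4, 100)
    fe = rng.uniform(-12, 0, 100)
    charge = rng.uniform(-2, 2, 100)
    target = 2.0 * inv_tai - 0.5 * fe + 3.0 * charge + 1.0
    fit = fit_regressor(inv_tai, fe, charge, target)
    assert fit.coefficients["inv_tai"] == pytest.approx(2.0, abs=1e-8)
    assert fit.coefficients["fe"] == pytest.approx(-0.5, abs=1e-8)
    assert fit.coefficients["charge"] == pytest.approx(3.0, abs=1e-8)
    assert fit.intercept == pytest.approx(1.0, abs=1e-8)
    assert fit.spearman_fit == pytest.approx(1.0)


def test_fit_regressor_residual_orthogonality_and_smoothing_flag():
    rng = np.random.default_rng(12)
    inv_tai, fe, charge = rng.normal(size=(3, 80))
    target = inv_tai - fe + rng.normal(size=80)
    fit_raw = fit_regressor(inv_tai, fe, charge, target, smooth=False)
    resid = target - fit_raw.fitted
    for feat in (inv_tai, fe, charge):
        assert abs(np.dot(resid, feat)) < 1e-8
    assert fit_raw.smoothing is None
    fit_sm = fit_regressor(inv_tai, fe, charge, target, smooth=True)
    assert fit_sm.smoothing == 5
    assert fit_sm.coefficients != fit_raw.coefficients


def test_fit_regressor_null_features():
    rng = np.random.default_rng(13)
    inv_tai, fe, charge = rng.normal(size=(3, 200))
    target = rng.normal(size=200)  # independent of the features
    fit = fit_regressor(inv_tai, fe, charge, target, smooth=False)
    assert abs(fit.spearman_fit) < 0.25
    assert all(p > 0.01 for p in fit.p_values.values())


def test_split_half_identical_model():
    genes = [f"g{i}" for i in range(10)]

    def fit(train):
        return lambda test: 0.7

    res = split_half_validation(genes, fit, repeats=5, seed=0)
    assert np.all(res.differences == 0)
    assert set(res.verdicts) == {"not significant"}
    assert res.empirical_p == 0.0
    res2 = split_half_validation(genes, fit, repeats=5, seed=0)
    assert np.array_equal(res.full, res2.full)


def test_split_half_full_beats_ablated(small_synth):
    """A regressor using all three determinants predicts held-out density
    profiles better than one blind to codon adaptiveness."""
    res = small_synth
    feats = {}
    for g in res.genome:
        nt = res.truth["nominal_times"][g.gene_id]
        feats[g.gene_id] = np.column_stack([nt.ntai, nt.nch, nt.nfe])

    def make_fitter(cols):
        def fit(train):
            X = np.vstack([feats[g][:, cols] for g in train])
            y = np.concatenate([res.densities[g] for g in train])
            good = ~np.isnan(y)
            X1 = np.column_stack([np.ones(good.sum()), X[good]])
            beta, *_ = np.linalg.lstsq(X1, np.log(y[good]), rcond=None)

            def evaluate(test):
                Xt = np.vstack([feats[g][:, cols] for g in test])
                yt = np.concatenate([res.densities[g] for g in test])
                good_t = ~np.isnan(yt)
                pred = np.column_stack(
                    [np.ones(good_t.sum()), Xt[good_t]]
                ) @ beta
                from scipy.stats import spearmanr

                return float(spearmanr(pred, yt[good_t]).statistic)

            return evaluate

        return fit

    out = split_half_validation(
        res.genome.gene_ids,
        make_fitter([0, 1, 2]),
        make_fitter([1, 2]),  # ablate the tRNA-adaptation feature
        repeats=10,
        seed=2,
    )
    assert np.mean(out.full - out.reduced > 0.004) >= 0.8
    assert out.empirical_p <= 0.2
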