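import numpy as np
import pytest

from oracles import brute_charge_scan, brute_fe_scan, brute_tai_scan
from ribotraffic.robustness import (
    ScanWeights,
    binned_control_profiles,
    charge_robustness,
    expected_windows_per_error,
    fe_robustness,
    robustness_profile,
    scan_gene,
    tai_robustness,
)
from ribotraffic.seq_core import CodingSequence, Genome, SENSE_CODONS
from ribotraffic.tai import CodonWeights


def _random_window_nt(rng, n=40):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _random_window_codons(rng, n=13):
    return [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]


def test_fe_scan_mutant_count_and_poly_c(toy_backend):
    """In a poly-C window only the 40 C->G mutants can pair (one G against
    a C); each gains exactly one pair, derived by hand."""
    res = fe_robustness("C" * 40, toy_backend)
    assert res.n_mutants == 120  # 40 x 3 substitutions
    assert res.structure_changing == 40
    assert res.structure_preserving == 80
    assert res.mean_abs_dfe == pytest.approx(40 / 120)
    assert res.mean_bp_distance == pytest.approx(40 / 120)


def test_fe_scan_wrong_length(toy_backend):
    with pytest.raises(ValueError):
        fe_robustness("ACGT", toy_backend)


@pytest.mark.parametrize("seed", range(8))
def test_fe_scan_matches_brute_force(toy_backend, seed):
    rng = np.random.default_rng(100 + seed)
    win = _random_window_nt(rng)
    got = fe_robustness(win, toy_backend)
    exp = brute_fe_scan(win, toy_backend)
    for key, val in exp.items():
        assert getattr(got, key) == pytest.approx(val, abs=0), key


def test_fe_scan_weighted_matches_brute_force(toy_backend):
    rng = np.random.default_rng(200)
    win = _random_window_nt(rng)
    sw = ScanWeights(2.0, (1.0, 0.1, 1.0))
    got = fe_robustness(win, toy_backend, sw)
    exp = brute_fe_scan(win, toy_backend, ts_tv=2.0, pos_w=(1.0, 0.1, 1.0))
    for key, val in exp.items():
        assert getattr(got, key) == pytest.approx(val), key


def test_charge_scan_gly_third_positions_neutral():
    # Gly is 4-fold degenerate and neutral: GGN third-position changes never
    # alter the charge
    win = ["GGA", "GGC", "GGG", "GGT"] * 3 + ["GGA"]
    res = charge_robustness(win)
    exp = brute_charge_scan(win)
    assert res.charge_changing == exp["changing"]
    # third-position substitutions contribute nothing to the changing count
    third_only = charge_robustness(win, ScanWeights(1.0, (0.0, 0.0, 1.0)))
    assert third_only.charge_changing == 0.0


def test_charge_scan_poly_lysine_matches_enumeration():
    win = ["AAA"] * 13
    res = charge_robustness(win)
    exp = brute_charge_scan(win)
    assert res.n_mutants == exp["n_mutants"]
    assert res.charge_changing == exp["changing"]
    assert res.mean_abs_dcharge == pytest.approx(exp["mean_abs"])


def test_charge_scan_second_position_weight_linearity():
    win = ["AAA"] * 13
    full = charge_robustness(win, ScanWeights(1.0, (0.0, 1.0, 0.0)))
    tenth = charge_robustness(win, ScanWeights(1.0, (0.0, 0.1, 0.0)))
    assert tenth.charge_changing == pytest.approx(0.1 * full.charge_changing)


def test_charge_scan_rejects_stop():
    with pytest.raises(ValueError):
        charge_robustness(["TAA"] + ["AAA"] * 12)


def test_tai_scan_uniform_weights_all_preserving():
    w = CodonWeights(W={}, w={c: 1.0 for c in SENSE_CODONS})
    win = ["GGT"] * 13
    res = tai_robustness(win, w)
    assert res.mean_abs_dw == 0.0
    assert res.tai_preserving == res.n_mutants


@pytest.mark.parametrize("seed", range(5))
def test_tai_scan_matches_brute_force(simple_weights, seed):
    rng = np.random.default_rng(300 + seed)
    win = _random_window_codons(rng)
    got = tai_robustness(win, simple_weights)
    exp = brute_tai_scan(win, simple_weights.w)
    assert got.n_mutants == exp["n_mutants"]
    assert got.mean_abs_dw == pytest.approx(exp["mean_abs"], abs=0)
    assert got.tai_preserving == exp["preserving"]


def test_tai_scan_ts_tv_doubles_transitions(simple_weights):
    rng = np.random.default_rng(301)
    win = _random_window_codons(rng)
    exp = brute_tai_scan(win, simple_weights.w, ts_tv=2.0)
    got = tai_robustness(win, simple_weights, ScanWeights(2.0))
    assert got.mean_abs_dw == pytest.approx(exp["mean_abs"])
    assert got.tai_preserving == exp["preserving"]


def test_robustness_profile_single_gene_identity(simple_weights):
    cds = "ATG" + "AAACCCGGTACTGAT" * 4
    gene = CodingSequence("g", cds)
    genome = Genome([gene])
    profs = robustness_profile(
        genome, "charge", scan_weights=None, max_positions=None
    )
    scans = scan_gene(gene, "charge")
    prof = profs["charge_changing"]
    assert np.allclose(prof.mean, [s.charge_changing for s in scans])
    # a genome of identical genes gives the same profile
    genome2 = Genome([CodingSequence("a", cds), CodingSequence("b", cds)])
    profs2 = robustness_profile(genome2, "charge", max_positions=None)
    assert np.allclose(profs2["charge_changing"].mean, prof.mean)


def test_binned_control_profiles(simple_weights):
    rng = np.random.default_rng(7)
    genes = [
        CodingSequence(
            f"g{i}",
            "ATG" + "".join(SENSE_CODONS[j] for j in rng.integers(0, 61, 25)),
        )
        for i in range(6)
    ]
    per_gene = {g.gene_id: scan_gene(g, "charge") for g in genes}
    window_vals = {
        gid: [s.mean_abs_dcharge for s in scans]
        for gid, scans in per_gene.items()
    }
    profs, bounds = binned_control_profiles(
        per_gene, window_vals, "charge_changing", n_bins=3, max_positions=None
    )
    assert len(profs) == 3 and len(bounds) == 4
    # bins partition all windows with sizes differing by at most 1
    n_total = sum(len(s) for s in per_gene.values())
    sizes = [int(p.count.sum()) if p is not None else 0 for p in profs]
    assert sum(sizes) == n_total
    assert max(sizes) - min(sizes) <= 1
    # degenerate values collapse to a single bin
    const_vals = {gid: [1.0] * len(s) for gid, s in per_gene.items()}
    profs1, _ = binned_control_profiles(
        per_gene, const_vals, "charge_changing", n_bins=3
    )
    assert len(profs1) == 1


def test_expected_windows_per_error():
    exact, shown = expected_windows_per_error(1e-4, 50)
    assert exact == pytest.approx(66.67, abs=0.01)
    assert shown == 67
    exact2, _ = expected_windows_per_error(1e-4, 100)
    assert exact2 == pytest.approx(exact / 2)
    with pytest.raises(ValueError):
        expected_windows_per_error(0.0, 50)
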