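"""Profile-profile scoring, decoy calibration, significance and FDR."""

import math

import numpy as np
import pytest

from orfan.msa_profiles import build_profile, shuffle_columns
from orfan.remote_homology import (Calibration, FdrEstimate, RemoteHit,
                                   calibrate, estimate_fdr,
                                   fdr_from_pass_rates, import_hhr_results,
                                   is_significant, profile_align, search_all,
                                   sigma_matrix)


def one_hot_profile(seq, cid="p"):
    return build_profile([seq], cluster_id=cid, pseudocount_weight=0)


# ---------------------------------------------------------------------------
# profile alignment

def test_self_alignment_of_one_hot_profile():
    p = one_hot_profile("ACDEFGHIKL")  # 10 distinct one-hot columns
    score = profile_align(p, p)
    assert score == pytest.approx(10 * math.log2(20), rel=1e-9)


def test_uniform_profile_scores_zero():
    uniform = build_profile(["A"], pseudocount_weight=1e12)  # ~background
    other = one_hot_profile("ACDEF")
    assert profile_align(uniform, other) == pytest.approx(0.0, abs=1e-3)


def test_profile_align_symmetry():
    rng = np.random.default_rng(5)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(10):
        a = one_hot_profile("".join(rng.choice(list(aa), size=12)), "a")
        b = one_hot_profile("".join(rng.choice(list(aa), size=15)), "b")
        assert profile_align(a, b) == pytest.approx(profile_align(b, a))


def brute_force_local(sigma, go=2.5, ge=0.5):
    """Exhaustive enumeration over all local alignment paths."""
    m, n = sigma.shape
    best = 0.0

    def gapcost(k):
        return 0.0 if k == 0 else go + (k - 1) * ge

    def rec(i, j, score):
        nonlocal best
        best = max(best, score)
        for a in range(1, m - i):
            for b in range(1, n - j):
                rec(i + a, j + b,
                    score - gapcost(a - 1) - gapcost(b - 1) + sigma[i + a, j + b])

    for i in range(m):
        for j in range(n):
            rec(i, j, sigma[i, j])
    return best


def test_profile_align_matches_path_enumeration():
    rng = np.random.default_rng(17)
    from orfan._align import local_profile_score
    for _ in range(30):
        sigma = rng.normal(0.5, 2.0, size=(rng.integers(3, 7),
                                           rng.integers(3, 7)))
        assert local_profile_score(sigma) == pytest.approx(
            brute_force_local(sigma), abs=1e-9)


# ---------------------------------------------------------------------------
# calibration

def _calibration_fixture(seed=0, n=200, shift=30.0):
    rng = np.random.default_rng(seed)
    decoy = rng.gumbel(10.0, 2.0, size=n)
    real = np.concatenate([rng.gumbel(10.0, 2.0, size=n // 2),
                           rng.normal(10.0 + shift, 3.0, size=n // 2)])
    return real, decoy


def test_calibrate_probability_monotone_in_score():
    real, decoy = _calibration_fixture()
    cal = calibrate(real, decoy, n_templates=50)
    grid = np.linspace(min(real.min(), decoy.min()),
                       max(real.max(), decoy.max()), 200)
    probs = [cal.probability(s) for s in grid]
    assert all(b >= a - 1e-9 for a, b in zip(probs, probs[1:]))
    assert probs[-1] > 90
    assert probs[0] < 10


def test_calibrate_decoys_equal_reals_gives_low_probability():
    rng = np.random.default_rng(1)
    decoy = rng.gumbel(10, 2, size=500)
    real = rng.gumbel(10, 2, size=500)
    cal = calibrate(real, decoy, n_templates=50)
    # density ratio ~1 everywhere: probabilities near zero
    assert max(cal.probability(s) for s in np.linspace(5, 20, 50)) < 35


def test_calibrate_needs_enough_decoys():
    with pytest.raises(ValueError):
        calibrate([1.0] * 100, [1.0] * 49, n_templates=10)


def test_calibrate_evalue_decreases_with_score():
    real, decoy = _calibration_fixture()
    cal = calibrate(real, decoy, n_templates=70)
    assert cal.evalue(10) > cal.evalue(20) > cal.evalue(40)
    # Gumbel tail: log E is linear in S with slope -lambda
    d1 = math.log(cal.evalue(20)) - math.log(cal.evalue(25))
    d2 = math.log(cal.evalue(25)) - math.log(cal.evalue(30))
    assert d1 == pytest.approx(d2)


# ---------------------------------------------------------------------------
# thresholds and significance

def test_significance_thresholds_inclusive():
    assert is_significant(80.0, 1.0)          # both exactly at threshold
    assert not is_significant(79.9, 0.001)
    assert not is_significant(85.0, 2.0)      # conjunction


def test_search_all_ranks_and_template_order_invariance():
    real, decoy = _calibration_fixture()
    cal = calibrate(real, decoy, n_templates=3)
    q = one_hot_profile("ACDEFGHIKLMNP", "q")
    t_same = one_hot_profile("ACDEFGHIKLMNP", "t1")
    t_other = one_hot_profile("WWWWYYYYWWWWY", "t2")
    res = search_all({"q": q}, {"t1": t_same, "t2": t_other}, cal)
    hits = res["q"]
    assert [h.rank for h in hits] == [1, 2]
    assert hits[0].template_id == "t1"
    probs = [h.probability for h in hits]
    assert probs == sorted(probs, reverse=True)
    res2 = search_all({"q": q}, {"t2": t_other, "t1": t_same}, cal)
    assert [h.template_id for h in res2["q"]] == [h.template_id for h in hits]
    assert search_all({"q": q}, {}, cal) == {"q": []}


# ---------------------------------------------------------------------------
# FDR

def _hit(prob, evalue=0.1):
    return RemoteHit("c", "t", 0.0, evalue, prob)


def test_estimate_fdr_reproduces_pass_rate_arithmetic():
    # 15.8% of real queries pass, 1.4% of decoys: FDR ~ 9%
    real = {f"r{i}": [_hit(95.0 if i < 158 else 10.0)] for i in range(1000)}
    decoy = {f"d{i}": [_hit(95.0 if i < 14 else 10.0)] for i in range(1000)}
    est = estimate_fdr(real, decoy)
    assert est.real_pass_rate == pytest.approx(0.158)
    assert est.decoy_pass_rate == pytest.approx(0.014)
    assert est.fdr == pytest.approx(0.0886, abs=1e-3)
    assert fdr_from_pass_rates(0.158, 0.014) == pytest.approx(0.0886, abs=1e-3)


def test_estimate_fdr_edge_cases():
    real = {"r": [_hit(95.0)]}
    assert estimate_fdr(real, {"d": [_hit(10.0)]}).fdr == 0.0
    assert estimate_fdr(real, real).fdr == pytest.approx(1.0)
    undefined = estimate_fdr({"r": [_hit(10.0)]}, {"d": [_hit(10.0)]})
    assert undefined.fdr is None


def test_raising_probability_threshold_never_raises_fdr():
    rng = np.random.default_rng(2)
    real = {f"r{i}": [_hit(p)] for i, p in
            enumerate(rng.uniform(0, 100, size=400))}
    decoy = {f"d{i}": [_hit(p)] for i, p in
             enumerate(rng.uniform(0, 60, size=400))}
    fdrs = []
    for thr in (50, 60, 70, 80, 90):
        est = estimate_fdr(real, decoy, probability_threshold=thr)
        if est.fdr is not None:
            fdrs.append(est.fdr)
    assert all(b <= a + 1e-12 for a, b in zip(fdrs, fdrs[1:]))


# ---------------------------------------------------------------------------
# HHR import

def test_import_hhr_results(tmp_path):
    (tmp_path / "cl1.hhr").write_text(
        " No Hit                             Prob E-value P-value  Score    SS"
        " Cols Query HMM  Template HMM\n"
        "  1 1abc_A peptidase domain        95.2  0.0001 1.0E-08   90.0   0.0"
        "   60    1-60      1-60 (100)\n"
        "  2 9zzz_Z something               79.9     0.5 1.0E-03   15.0   0.0"
        "   20    1-20      1-20 (80)\n")
    res = import_hhr_results(tmp_path, cluster_ids=["cl1", "cl_missing"])
    assert res["cl_missing"] == []
    h1, h2 = res["cl1"]
    assert h1.significant
    assert not h2.significant  # probability 79.9 < 80
    assert h1.template_id == "1abc_A"
    assert h1.probability == 95.2
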