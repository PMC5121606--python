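"""Diversity statistics against hand/closed-form oracles."""

from math import comb, factorial

import numpy as np
import pytest

from finesgs import (GenotypeTable, amova_chord, chord_distance_matrix,
                     fis_from_het, fst_between_cohorts, hwe_test,
                     locus_summaries, weir_cockerham_theta)
from finesgs.diversity import _amova_sigma2, _hwe_chi2


def table(calls, cohorts, loci=None):
    calls = np.asarray(calls)
    return GenotypeTable(
        ids=[f"i{k}" for k in range(len(calls))],
        cohorts=np.asarray(cohorts, dtype=object),
        loci=loci or [f"L{j + 1}" for j in range(calls.shape[1])],
        calls=calls,
    )


# ---------------------------------------------------------------------------
# locus summaries
# ---------------------------------------------------------------------------

def test_all_heterozygotes_give_negative_fis():
    g = table([[[1, 2]]] * 4 + [[[1, 1]], [[2, 2]]],
              ["a"] * 4 + ["b"] * 2)
    summ = {(s.cohort, s.locus): s for s in locus_summaries(g)}
    s = summ[("a", "L1")]
    assert s.H_O == 1.0
    assert s.F_IS < 0


def test_unbiased_expected_heterozygosity_hand_formula():
    """6 individuals, 3 alleles: H_E = (2n/(2n-1)) (1 - sum p^2)."""
    calls = [[[1, 1]], [[1, 2]], [[2, 3]], [[3, 3]], [[1, 3]], [[2, 2]]]
    g = table(calls + [[[1, 1]], [[1, 2]]], ["a"] * 6 + ["b"] * 2)
    s = [x for x in locus_summaries(g) if x.cohort == "a"][0]
    counts = np.array([4, 4, 4]) / 12.0     # alleles 1, 2, 3 each 4/12
    he_hand = (12 / 11) * (1 - np.sum(counts ** 2))
    assert s.H_E == pytest.approx(he_hand, abs=1e-12)
    assert s.F_IS == pytest.approx(1 - s.H_O / he_hand, abs=1e-12)


def test_fis_identity_matches_printed_precision():
    # H_O = 0.758 with H_O/H_E = 0.808 implies F_IS = 0.192
    he = 0.758 / 0.808
    assert round(fis_from_het(0.758, he), 3) == 0.192


def test_monomorphic_locus_flagged_not_raised():
    g = table([[[1, 1]], [[1, 1]], [[1, 1]], [[1, 1]]], ["a", "a", "b", "b"])
    for s in locus_summaries(g):
        assert s.F_IS is None
        assert s.H_E == 0.0


# ---------------------------------------------------------------------------
# HWE Monte-Carlo exact test
# ---------------------------------------------------------------------------

def test_hwe_p_high_at_exact_proportions():
    calls = [[[1, 1]]] * 4 + [[[1, 2]]] * 8 + [[[2, 2]]] * 4
    g = table(calls + [[[1, 2]]] * 2, ["a"] * 16 + ["b"] * 2)
    chi2, p = hwe_test(g, "L1", "a", n_perm=499)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p > 0.5


def test_hwe_detects_total_heterozygote_deficit():
    calls = [[[1, 1]]] * 10 + [[[2, 2]]] * 10
    g = table(calls + [[[1, 2]]] * 2, ["a"] * 20 + ["b"] * 2)
    _, p = hwe_test(g, "L1", "a", n_perm=999)
    assert p <= 0.01


def levene_het_distribution(n_a: int, n: int) -> dict[int, float]:
    """Exact null distribution of the heterozygote count (2 alleles).

    P(h) = n! / (nAA! h! nBB!) * 2^h * nA! nB! / (2n)! for the random pairing
    of the 2n allele copies into n diploids.
    """
    n_b = 2 * n - n_a
    probs = {}
    for h in range(min(n_a, n_b) + 1):
        if (n_a - h) % 2:
            continue
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        probs[h] = (factorial(n) / (factorial(naa) * factorial(h)
                                    * factorial(nbb))
                    * 2 ** h * factorial(n_a) * factorial(n_b)
                    / factorial(2 * n))
    return probs


def test_hwe_p_matches_levene_enumeration():
    """MC p on a 2-allele, n=5 toy agrees with the exact pairing distribution."""
    calls = [[[1, 1]], [[1, 2]], [[1, 2]], [[2, 2]], [[2, 2]]]   # h=2, nA=4
    g = table(calls + [[[1, 2]]] * 2, ["a"] * 5 + ["b"] * 2)
    dist = levene_het_distribution(4, 5)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def chi2_of(h):
        naa, nbb = (4 - h) // 2, (6 - h) // 2
        geno = np.array([[1, 1]] * naa + [[1, 2]] * h + [[2, 2]] * nbb)
        return _hwe_chi2(geno)

    obs = chi2_of(2)
    p_exact = sum(pr for h, pr in dist.items() if chi2_of(h) >= obs - 1e-12)
    n_perm = 4000
    _, p_mc = hwe_test(g, "L1", "a", n_perm=n_perm,
                       rng=np.random.default_rng(7))
    se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert abs(p_mc - p_exact) <= 3 * se + 1 / (n_perm + 1)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def wc_theta_literal(calls_by_pop: list[np.ndarray]) -> tuple[float, float]:
    """Literal scalar transcription of the Weir-Cockerham components."""
    r = len(calls_by_pop)
    alleles = sorted(set(int(a) for c in calls_by_pop for a in c.ravel()))
    n_i = [len(c) for c in calls_by_pop]
    nbar = sum(n_i) / r
    n_c = (r * nbar - sum(ni ** 2 for ni in n_i) / (r * nbar)) / (r - 1)
    a_sum = abc_sum = 0.0
    for al in alleles:
        p_i = [np.mean(c == al) for c in calls_by_pop]
        h_i = [np.mean((c[:, 0] == al) != (c[:, 1] == al))
               for c in calls_by_pop]
        pbar = sum(ni * pi for ni, pi in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2
                 for ni, pi in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n_i, h_i)) / (r * nbar)
        a = (nbar / n_c) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                  - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def test_wc_theta_matches_literal_transcription():
    rng = np.random.default_rng(3)
    calls = rng.integers(1, 4, size=(12, 3, 2))
    cohorts = ["a"] * 6 + ["b"] * 6
    g = table(calls, cohorts)
    theta, per_locus = weir_cockerham_theta(g)
    a_tot = abc_tot = 0.0
    for l in range(3):
        a, abc = wc_theta_literal([calls[:6, l, :], calls[6:, l, :]])
        assert per_locus[f"L{l + 1}"] == pytest.approx(a / abc, abs=1e-10)
        a_tot += a
        abc_tot += abc
    assert theta == pytest.approx(a_tot / abc_tot, abs=1e-10)


def test_fixed_cohorts_give_theta_one():
    calls = [[[1, 1]] * 3] * 10 + [[[2, 2]] * 3] * 10
    g = table(calls, ["a"] * 10 + ["b"] * 10)
    res = fst_between_cohorts(g, n_perm=500, rng=np.random.default_rng(1))
    assert res.fst == pytest.approx(1.0, abs=1e-12)
    assert res.fst_p <= 0.002


def test_null_cohorts_give_small_theta():
    rng = np.random.default_rng(4)
    calls = rng.integers(1, 11, size=(100, 5, 2))
    g = table(calls, ["a"] * 50 + ["b"] * 50)
    res = fst_between_cohorts(g, n_perm=99, rng=rng)
    assert abs(res.fst) < 0.02
    assert res.fst_p > 0.01


# ---------------------------------------------------------------------------
# chord-distance AMOVA
# ---------------------------------------------------------------------------

def test_identical_genotypes_have_zero_chord_distance():
    g = table([[[1, 2], [3, 3]], [[1, 2], [3, 3]], [[2, 2], [3, 4]],
               [[1, 1], [4, 4]]], ["a", "b", "a", "b"])
    D = chord_distance_matrix(g)
    assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert D[2, 3] > 0


def test_duplicated_cohorts_give_zero_among_component():
    rng = np.random.default_rng(5)
    block = rng.integers(1, 5, size=(8, 3, 2))
    calls = np.concatenate([block, block])
    g = table(calls, ["a"] * 8 + ["b"] * 8)
    res = amova_chord(g, n_perm=99, rng=rng)
    assert res.amova_sigma2 == 0.0
    assert res.amova_sigma2_raw <= 1e-12


def test_amova_components_match_gower_centering():
    """Among/within components equal a trace computation on the
    Gower-centered squared-distance matrix."""
    rng = np.random.default_rng(6)
    calls = rng.integers(1, 4, size=(6, 2, 2))
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    g = table(calls, labels)
    D2 = chord_distance_matrix(g) ** 2
    n = 6

    def gower_trace(M):
        m = M.shape[0]
        H = np.eye(m) - np.ones((m, m)) / m
        return np.trace(-0.5 * H @ M @ H)

    ss_total = gower_trace(D2)
    ss_within = sum(gower_trace(D2[np.ix_(np.where(labels == lab)[0],
                                          np.where(labels == lab)[0])])
                    for lab in ("a", "b"))
    ss_among = ss_total - ss_within
    ms_among = ss_among / 1
    ms_within = ss_within / 4
    n0 = (n - (9 + 9) / n) / 1
    sigma_oracle = (ms_among - ms_within) / n0
    s2, s2w = _amova_sigma2(D2, labels)
    assert s2 == pytest.approx(sigma_oracle, abs=1e-10)
    assert s2w == pytest.approx(ms_within, abs=1e-10)


def test_theta_invariant_to_individual_order():
    rng = np.random.default_rng(8)
    calls = rng.integers(1, 5, size=(20, 4, 2))
    cohorts = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
    g = table(calls, cohorts)
    perm = rng.permutation(20)
    g2 = g.subset(perm)
    assert weir_cockerham_theta(g)[0] == pytest.approx(
        weir_cockerham_theta(g2)[0], abs=1e-12)
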