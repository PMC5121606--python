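"""Per-locus diversity statistics and between-cohort differentiation tests.

Covers the classic descriptive table (allelic richness, missing-data
percentage, observed and unbiased expected heterozygosity, F_IS, Monte-Carlo
Hardy-Weinberg exact test per locus and cohort), Weir-Cockerham theta as the
F_ST estimator with a cohort-label permutation test, and a distance-based
AMOVA on individual-level chord distances.

The p-value convention throughout is (1 + hits) / (1 + permutations), so a
permutation test can never report exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MISSING, GenotypeTable

__all__ = [
    "LocusSummary",
    "DifferentiationResult",
    "locus_summaries",
    "fis_from_het",
    "hwe_test",
    "weir_cockerham_theta",
    "fst_between_cohorts",
    "chord_distance_matrix",
    "amova_chord",
]


# ---------------------------------------------------------------------------
# per-locus summaries
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    locus: str
    cohort: str
    allelic_richness: int
    pct_missing: float
    H_O: float
    H_E: float
    F_IS: float | None      # None when H_E == 0 (monomorphic)
    hwe_chi2: float | None = None
    hwe_p: float | None = None


def fis_from_het(H_O: float, H_E: float) -> float:
    """Inbreeding coefficient from observed/expected heterozygosity."""
    if H_E <= 0:
        raise ValueError("F_IS undefined for H_E <= 0")
    return 1.0 - H_O / H_E


def _locus_cohort_stats(calls: np.ndarray) -> tuple[int, float, float, float]:
    """(R_S, %missing, H_O, unbiased H_E) for one locus in one cohort."""
    miss = np.any(calls == MISSING, axis=1)
    scored = calls[~miss]
    n = len(scored)
    pct_missing = 100.0 * miss.mean()
    if n == 0:
        return 0, pct_missing, np.nan, np.nan
    alleles, counts = np.unique(scored.ravel(), return_counts=True)
    p = counts / (2 * n)
    H_O = float(np.mean(scored[:, 0] != scored[:, 1]))
    # Nei's unbiased expected heterozygosity
    H_E = float((2 * n / (2 * n - 1)) * (1.0 - np.sum(p ** 2)))
    return len(alleles), pct_missing, H_O, H_E


def locus_summaries(g: GenotypeTable, hwe_perm: int | None = None,
                    rng: np.random.Generator | None = None
                    ) -> list[LocusSummary]:
    """Table-style per-locus, per-cohort summaries.

    ``H_E`` is Nei's small-sample-corrected expected heterozygosity and
    ``F_IS = 1 - H_O/H_E``; missing calls are excluded per locus. Passing
    ``hwe_perm`` also runs the Monte-Carlo HWE test for every polymorphic
    locus x cohort.
    """
    rng = rng or np.random.default_rng(0)
    out: list[LocusSummary] = []
    for cohort in g.cohort_labels:
        sub = g.cohort_subset(cohort)
        if sub.n_individuals < 2:
            raise ValueError(f"cohort {cohort!r} has fewer than 2 individuals")
        for l, locus in enumerate(g.loci):
            rs, pm, ho, he = _locus_cohort_stats(sub.calls[:, l, :])
            fis = None if (not np.isfinite(he) or he <= 0) else 1.0 - ho / he
            chi2 = p = None
            if hwe_perm and rs >= 2:
                chi2, p = hwe_test(g, locus, cohort, hwe_perm, rng=rng)
            out.append(LocusSummary(locus=locus, cohort=cohort,
                                    allelic_richness=rs, pct_missing=pm,
                                    H_O=ho, H_E=he, F_IS=fis,
                                    hwe_chi2=chi2, hwe_p=p))
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo exact test
# ---------------------------------------------------------------------------

def _hwe_chi2(geno: np.ndarray) -> float:
    """Genotype-count chi2 against HW proportions; geno is (n, 2) sorted rows."""
    n = len(geno)
    alleles, counts = np.unique(geno.ravel(), return_counts=True)
    p = counts / (2 * n)
    idx = {a: i for i, a in enumerate(alleles)}
    A = len(alleles)
    obs = np.zeros((A, A))
    for a1, a2 in geno:
        i, j = sorted((idx[a1], idx[a2]))
        obs[i, j] += 1
    chi2 = 0.0
    for i in range(A):
        for j in range(i, A):
            e = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            if e > 0:
                chi2 += (obs[i, j] - e) ** 2 / e
    return chi2


def hwe_test(g: GenotypeTable, locus: str, cohort: str, n_perm: int = 999,
             rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Monte-Carlo exact test of Hardy-Weinberg equilibrium.

    The statistic is the genotype-count chi-square against HW expectations;
    the null is built by shuffling the 2n observed allele copies into random
    diploid genotypes ``n_perm`` times. Returns ``(chi2, p)``.
    """
    rng = rng or np.random.default_rng(0)
    sub = g.cohort_subset(cohort)
    l = g.loci.index(locus)
    calls = sub.calls[:, l, :]
    calls = calls[~np.any(calls == MISSING, axis=1)]
    if len(calls) == 0:
        raise ValueError(f"all individuals missing at locus {locus!r}")
    if len(np.unique(calls)) < 2:
        raise ValueError(f"locus {locus!r} monomorphic in cohort {cohort!r}")
    obs = _hwe_chi2(calls)
    pool = calls.ravel().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        if _hwe_chi2(pool.reshape(-1, 2)) >= obs:
            hits += 1
    return float(obs), (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationResult:
    fst: float | None = None
    fst_per_locus: dict[str, float] | None = None
    fst_p: float | None = None
    amova_sigma2: float | None = None
    amova_sigma2_raw: float | None = None
    amova_sigma2_within: float | None = None
    amova_p: float | None = None


def _wc_components(calls: np.ndarray, labels: np.ndarray
                   ) -> tuple[float, float]:
    """Summed Weir-Cockerham (a, a+b+c) over alleles for one locus."""
    groups = np.unique(labels)
    r = len(groups)
    per_pop = []
    for grp in groups:
        c = calls[labels == grp]
        c = c[~np.any(c == MISSING, axis=1)]
        if len(c) < 1:
            return 0.0, 0.0
        per_pop.append(c)
    alleles = np.unique(np.concatenate([c.ravel() for c in per_pop]))
    if len(alleles) < 2:
        return 0.0, 0.0
    n_i = np.array([len(c) for c in per_pop], dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0
    n_c = (r * nbar - np.sum(n_i ** 2) / (r * nbar)) / (r - 1)
    a_sum = abc_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean(c == al) for c in per_pop])
        h_i = np.array([np.mean((c[:, 0] == al) ^ (c[:, 1] == al))
                        for c in per_pop])
        pbar = np.sum(n_i * p_i) / (r * nbar)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        a = (nbar / n_c) * (s2 - (pbar * (1 - pbar)
                                  - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def weir_cockerham_theta(g: GenotypeTable, labels: np.ndarray | None = None
                         ) -> tuple[float, dict[str, float]]:
    """Multilocus and per-locus Weir-Cockerham theta between cohorts."""
    labels = g.cohorts.astype(str) if labels is None else np.asarray(labels)
    a_tot = abc_tot = 0.0
    per_locus: dict[str, float] = {}
    for l, locus in enumerate(g.loci):
        a, abc = _wc_components(g.calls[:, l, :], labels)
        per_locus[locus] = a / abc if abc != 0 else np.nan
        a_tot += a
        abc_tot += abc
    theta = a_tot / abc_tot if abc_tot != 0 else np.nan
    return float(theta), per_locus


def fst_between_cohorts(g: GenotypeTable, n_perm: int = 500,
                        rng: np.random.Generator | None = None
                        ) -> DifferentiationResult:
    """Weir-Cockerham theta between the two cohorts with a permutation test.

    The null shuffles cohort labels over individuals; the p-value is
    one-sided for F_ST > 0.
    """
    labels = g.cohorts.astype(str)
    if len(np.unique(labels)) != 2:
        raise ValueError("exactly 2 cohorts required")
    for lab in np.unique(labels):
        if np.sum(labels == lab) < 2:
            raise ValueError(f"cohort {lab!r} has fewer than 2 individuals")
    rng = rng or np.random.default_rng(0)
    theta, per_locus = weir_cockerham_theta(g, labels)
    hits = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        t, _ = weir_cockerham_theta(g, lab)
        if t >= theta:
            hits += 1
    return DifferentiationResult(fst=theta, fst_per_locus=per_locus,
                                 fst_p=(1 + hits) / (n_perm + 1))


# ---------------------------------------------------------------------------
# chord-distance AMOVA
# ---------------------------------------------------------------------------

def chord_distance_matrix(g: GenotypeTable) -> np.ndarray:
    """Individual-pair chord distances over shared non-missing loci.

    D_ij = sqrt(2 * (1 - (1/L_ij) sum_l sum_a sqrt(p_ila * p_jla))) with
    L_ij the number of loci scored in both individuals; pairs sharing no
    locus get NaN.
    """
    n = g.n_individuals
    cos_sum = np.zeros((n, n))
    shared = np.zeros((n, n))
    for l in range(g.n_loci):
        P, scored, _ = g.dosage(l)
        S = np.sqrt(P)
        cos_l = S @ S.T
        ok = np.outer(scored, scored)
        cos_sum += np.where(ok, cos_l, 0.0)
        shared += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cos = np.where(shared > 0, cos_sum / np.maximum(shared, 1), np.nan)
    D = np.sqrt(np.maximum(2.0 * (1.0 - mean_cos), 0.0))
    np.fill_diagonal(D, 0.0)
    return D


def _amova_sigma2(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) from squared distances and group labels."""
    n = len(labels)
    groups = np.unique(labels)
    g_n = np.array([np.sum(labels == grp) for grp in groups], dtype=float)
    iu = np.triu_indices(n, k=1)
    ss_total = np.sum(D2[iu]) / n
    ss_within = 0.0
    for grp, ng in zip(groups, g_n):
        idx = np.where(labels == grp)[0]
        sub = D2[np.ix_(idx, idx)]
        ss_within += np.sum(np.triu(sub, k=1)) / ng
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - np.sum(g_n ** 2) / n) / df_among
    return (ms_among - ms_within) / n0, ms_within


def amova_chord(g: GenotypeTable, n_perm: int = 999,
                rng: np.random.Generator | None = None
                ) -> DifferentiationResult:
    """AMOVA between cohorts on squared chord distances.

    Excoffier-style sums of squares partition the among- and within-cohort
    variance; significance comes from permuting cohort labels (one-sided for
    sigma2_among > 0). The reported component is clamped at zero with the raw
    value retained.
    """
    labels = g.cohorts.astype(str)
    if len(np.unique(labels)) != 2:
        raise ValueError("exactly 2 cohorts required")
    D = chord_distance_matrix(g)
    if np.isnan(D).any():
        import warnings
        warnings.warn("pairs sharing no scored locus excluded from AMOVA")
        D = np.where(np.isnan(D), np.nanmean(D), D)
    D2 = D ** 2
    rng = rng or np.random.default_rng(0)
    s2_raw, s2_within = _amova_sigma2(D2, labels)
    hits = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        s2p, _ = _amova_sigma2(D2, lab)
        if s2p >= s2_raw:
            hits += 1
    return DifferentiationResult(
        amova_sigma2=max(s2_raw, 0.0), amova_sigma2_raw=s2_raw,
        amova_sigma2_within=s2_within, amova_p=(1 + hits) / (n_perm + 1),
    )
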