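"""Bearing correlograms, sector restriction and Mantel permutation nulls."""

import itertools

import numpy as np
import pytest

from finesgs import (AnalysisConfig, GenotypeTable, SpatialFrame,
                     angular_distance, bearing_correlogram, bearing_transform,
                     kinship_matrix, pairwise_geometry, sector_sp,
                     sp_statistic)


def cfg(**kw):
    base = dict(n_perm_distogram=49, n_perm_mantel=99, n_bearing_angles=64,
                rng_seed=3)
    base.update(kw)
    return AnalysisConfig(**base)


def test_transform_aligned_and_perpendicular_pairs():
    D = np.array([[0.0, np.e], [np.e, 0.0]])
    A = np.array([[0.0, 30.0], [30.0, 0.0]])
    T_aligned = bearing_transform(D, A, theta=30.0)
    assert T_aligned[0, 1] == pytest.approx(1.0, abs=1e-12)
    T_perp = bearing_transform(D, A, theta=120.0)
    assert T_perp[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_transform_is_180_degree_periodic():
    rng = np.random.default_rng(0)
    D = rng.uniform(0.5, 5.0, (6, 6))
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0)
    A = rng.uniform(0, 180, (6, 6)) % 180
    A = np.triu(A) + np.triu(A, 1).T
    for theta in (0.0, 37.5, 90.0):
        assert np.allclose(bearing_transform(D, A, theta),
                           bearing_transform(D, A, theta + 180.0), atol=1e-10)


def small_table(n=5, seed=0, loci=4):
    rng = np.random.default_rng(seed)
    calls = rng.integers(1, 4, size=(n, loci, 2))
    g = GenotypeTable(ids=[f"i{k}" for k in range(n)],
                      cohorts=np.array(["a"] * n, dtype=object),
                      loci=[f"L{j}" for j in range(loci)], calls=calls)
    frame = SpatialFrame(list(g.ids), rng.uniform(0, 10, n),
                         rng.uniform(0, 10, n))
    return g, frame


def mantel_r_brute(F, T, idx):
    f = np.array([F[i, j] for i, j in idx])
    t = np.array([T[i, j] for i, j in idx])
    return np.corrcoef(f, t)[0, 1]


def test_mantel_r_and_exact_enumeration_p_on_five_points():
    """Observed r matches brute force; the exact permutation p over all 120
    relabelings agrees between the package route and an independent one."""
    g, frame = small_table(n=5, seed=1)
    kin = kinship_matrix(g)
    D, A = pairwise_geometry(frame)
    c = cfg(n_bearing_angles=8, n_perm_mantel=999)
    bc = bearing_correlogram(kin, (D, A), c)
    idx = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    for a_i, theta in enumerate(bc.angles):
        T = bearing_transform(D, A, theta)
        assert bc.r[a_i] == pytest.approx(mantel_r_brute(kin.values, T, idx),
                                          abs=1e-12)
    # exact two-sided p by exhaustive enumeration, both routes
    theta = float(bc.angles[0])
    T = bearing_transform(D, A, theta)
    r_obs = bc.r[0]
    null_brute, null_pkg = [], []
    for perm in itertools.permutations(range(5)):
        P = np.array(perm)
        null_brute.append(mantel_r_brute(kin.values[np.ix_(P, P)], T, idx))
        # package route: relabel the genotype table, rebuild kinship
        null_pkg.append(
            bearing_correlogram(kinship_matrix(g.subset(P)), (D, A),
                                cfg(n_bearing_angles=8, n_perm_mantel=1)).r[0])
    assert np.allclose(sorted(null_brute), sorted(null_pkg), atol=1e-10)

    def exact_p(null):
        null = np.asarray(null)
        hi = np.mean(null >= r_obs - 1e-12)
        lo = np.mean(null <= r_obs + 1e-12)
        return min(1.0, 2 * min(hi, lo))

    p_exact = exact_p(null_brute)
    # the package's sampled p converges on the exact one
    assert abs(bc.p[0] - p_exact) <= 3 * np.sqrt(p_exact * (1 - p_exact)
                                                 / c.n_perm_mantel) + 2e-3


def test_correlogram_is_periodic_in_bearing_origin(sim_small):
    """Adding 180 degrees to every bearing leaves the r profile unchanged."""
    kin = kinship_matrix(sim_small.genotypes)
    D, A = pairwise_geometry(sim_small.frame)
    c = cfg(n_perm_mantel=9)
    bc1 = bearing_correlogram(kin, (D, A), c, mode="within_2010")
    bc2 = bearing_correlogram(kin, (D, (A + 180.0)), c, mode="within_2010")
    assert np.allclose(bc1.r, bc2.r, atol=1e-10)


def test_angular_distance_wraps_half_circle():
    assert angular_distance(170.0, 5.0) == pytest.approx(15.0)
    assert angular_distance(90.0, 90.0) == 0.0
    assert angular_distance(0.0, 179.0) == pytest.approx(1.0)


def test_sector_halfwidth_90_equals_full_isotropic(sim_small):
    kin = kinship_matrix(sim_small.genotypes)
    geom = pairwise_geometry(sim_small.frame)
    c = cfg(sector_halfwidth=90.0)
    full = sp_statistic(kin, geom[0], "within_2010", c, n_perm=0)
    sect = sector_sp(kin, geom, 45.0, c, mode="within_2010", n_perm=0)
    assert sect.b_F == pytest.approx(full.b_F, abs=1e-12)
    assert sect.F_1 == pytest.approx(full.F_1, abs=1e-12)
    assert sect.Sp == pytest.approx(full.Sp, abs=1e-12)


def test_sector_pair_count_matches_brute_force(sim_small):
    kin = kinship_matrix(sim_small.genotypes)
    D, A = pairwise_geometry(sim_small.frame)
    c = cfg(sector_halfwidth=15.0)
    theta = 30.0
    res = sector_sp(kin, (D, A), theta, c, mode="within_2010", n_perm=0)
    coh = kin.cohorts.astype(str)
    count = 0
    n = kin.n_individuals
    for i in range(n):
        for j in range(i + 1, n):
            if coh[i] == coh[j] == "2010" and D[i, j] > 0:
                d = abs(A[i, j] - theta) % 180
                if min(d, 180 - d) <= 15.0:
                    count += 1
    assert res.n_pairs_regression == count


def test_permutation_profile_deterministic_given_seed(sim_small):
    kin = kinship_matrix(sim_small.genotypes)
    geom = pairwise_geometry(sim_small.frame)
    c = cfg(n_perm_mantel=49)
    bc1 = bearing_correlogram(kin, geom, c, mode="within_2010")
    bc2 = bearing_correlogram(kin, geom, c, mode="within_2010")
    assert np.array_equal(bc1.p, bc2.p)
    assert bc1.theta_s == bc2.theta_s
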