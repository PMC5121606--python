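"""Anisotropic spatial genetic structure via bearing correlograms.

For a fixed compass direction theta (degrees clockwise from the plot's
Y-axis), the distance matrix is transformed as

    T_ij(theta) = ln(d_ij) * cos^2(alpha_ij - theta)

where alpha_ij is the pair's bearing; a Mantel correlation between pairwise
kinship and T(theta), profiled over a grid of directions, yields the bearing
correlogram. Its minimum marks the direction of strongest kinship-distance
decay (theta_s) and its maximum the weakest (theta_w). Sp statistics can then
be re-estimated using only pairs whose bearing falls inside a sector around a
chosen direction. Everything is 180-degree periodic: bearings live on the
half-circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AnalysisConfig
from .isotropic import SpResult, cohort_permutations, pair_indices, sp_statistic
from .kinship import KinshipMatrix

__all__ = [
    "BearingCorrelogram",
    "bearing_transform",
    "bearing_correlogram",
    "angular_distance",
    "sector_sp",
]


def bearing_transform(distances: np.ndarray, bearings: np.ndarray,
                      theta: float) -> np.ndarray:
    """cos^2-weighted log-distance matrix for direction ``theta`` (degrees).

    Zero-distance entries yield -inf from the log and must be excluded by the
    caller's pair bookkeeping; the transform is 180-degree periodic in theta.
    """
    D = np.asarray(distances, float)
    A = np.asarray(bearings, float)
    with np.errstate(divide="ignore"):
        lnd = np.log(D)
    w = np.cos(np.radians(A - theta)) ** 2
    return lnd * w


@dataclass
class BearingCorrelogram:
    angles: np.ndarray    # degrees from Y in [0, 180)
    r: np.ndarray         # Mantel correlation per angle
    p: np.ndarray         # two-sided permutation p per angle
    theta_s: float        # angle of minimum r (strongest SGS)
    theta_w: float        # angle of maximum r (weakest SGS)

    @property
    def r_s(self) -> float:
        return float(self.r[np.argmin(self.r)])

    @property
    def r_w(self) -> float:
        return float(self.r[np.argmax(self.r)])


def _pearson_profile(f: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Correlation of one pair vector against each row of T (angles)."""
    fc = f - f.mean()
    Tc = T - T.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(fc ** 2) * np.sum(Tc ** 2, axis=1))
    return (Tc @ fc) / denom


def bearing_correlogram(k: KinshipMatrix, geom: tuple[np.ndarray, np.ndarray],
                        config: AnalysisConfig, mode: str = "all",
                        ) -> BearingCorrelogram:
    """Mantel bearing correlogram of kinship against directional log distance.

    ``geom`` is the (distance, bearing) matrix pair. For each of
    ``config.n_bearing_angles`` equidistant directions in [0, 180) the Mantel
    r is the Pearson correlation over off-diagonal pairs of F_ij versus
    T_ij(theta); significance comes from ``config.n_perm_mantel`` simultaneous
    row/column permutations of the kinship matrix (the same permutation draws
    are reused across angles so the p-value profile is coherent). Pairs at
    zero distance or with undefined kinship are excluded.
    """
    D, A = geom
    if k.n_individuals < 4:
        raise ValueError("bearing correlogram needs at least 4 individuals")
    i_idx, j_idx = pair_indices(k.cohorts, mode)
    d = D[i_idx, j_idx]
    f_all = k.values[i_idx, j_idx]
    keep = (d > 0) & ~np.isnan(f_all)
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    f = f_all[keep]
    if np.allclose(f, f[0]):
        raise ValueError("constant kinship matrix; Mantel r undefined")
    lnd = np.log(d[keep])
    alpha = A[i_idx, j_idx]

    angles = np.arange(config.n_bearing_angles) * (180.0 / config.n_bearing_angles)
    # (n_angles, n_pairs) transformed distances
    T = lnd[None, :] * np.cos(np.radians(alpha[None, :] - angles[:, None])) ** 2

    r = _pearson_profile(f, T)

    n_perm = config.n_perm_mantel
    perms = cohort_permutations(k.cohorts, n_perm, config.rng())
    Fp = k.values[perms[:, i_idx], perms[:, j_idx]]     # (n_perm, n_pairs)
    # permuted pair vectors may contain NaN only if kinship had missing pairs
    if np.isnan(Fp).any():
        Fp = np.where(np.isnan(Fp), np.nanmean(Fp, axis=1, keepdims=True), Fp)
    Fc = Fp - Fp.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(Fc ** 2, axis=1)[:, None]
                    * np.sum(Tc ** 2, axis=1)[None, :])
    null = (Fc @ Tc.T) / denom                           # (n_perm, n_angles)

    p_hi = (1 + np.sum(null >= r[None, :] - 1e-12, axis=0)) / (n_perm + 1)
    p_lo = (1 + np.sum(null <= r[None, :] + 1e-12, axis=0)) / (n_perm + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))

    return BearingCorrelogram(
        angles=angles, r=r, p=p,
        theta_s=float(angles[np.argmin(r)]),
        theta_w=float(angles[np.argmax(r)]),
    )


def angular_distance(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    """Distance between bearings on the 180-degree half-circle."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 180.0
    return np.minimum(d, 180.0 - d)


def sector_sp(k: KinshipMatrix, geom: tuple[np.ndarray, np.ndarray],
              theta: float, config: AnalysisConfig, mode: str = "all",
              n_perm: int | None = None) -> SpResult:
    """Sp statistic restricted to pairs oriented within a sector.

    Keeps pairs whose bearing lies within ``config.sector_halfwidth`` degrees
    of ``theta`` on the half-circle (a 30-degree sector by default) and
    delegates to the isotropic Sp machinery on that pair set; permutations
    are restricted to the same pairs.
    """
    D, A = geom
    i_idx, j_idx = pair_indices(k.cohorts, mode)
    in_sector = angular_distance(A[i_idx, j_idx], theta) <= config.sector_halfwidth
    if np.sum(in_sector) < 2:
        raise ValueError(f"fewer than 2 pairs within the sector around {theta} deg")
    return sp_statistic(k, D, mode, config,
                        pair_subset=(i_idx[in_sector], j_idx[in_sector]),
                        n_perm=n_perm)
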