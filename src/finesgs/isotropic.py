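"""Isotropic fine-scale spatial genetic structure.

Builds kinship-distance distograms (mean pairwise kinship F_D per distance
class with a permutation envelope), estimates the kinship-on-ln(distance)
regression slope b_F, the first-class mean kinship F_1 and the Sp statistic

    Sp = -b_F / (1 - F_1),

the standard intensity measure of isolation by distance (larger Sp = more
restricted gene dispersal). Standard errors come from jackknifing over loci
and significance from permuting the genotype-to-coordinate assignment within
cohorts, which preserves each cohort's spatial point pattern. Analyses run
within one cohort, or restricted to pairs of individuals from different
cohorts ("between" mode) to probe whether structure persists across
flowering years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import AnalysisConfig
from .kinship import KinshipMatrix

__all__ = [
    "Distogram",
    "SpResult",
    "distogram",
    "sp_statistic",
    "sp_from_components",
    "compare_cohorts",
]


# ---------------------------------------------------------------------------
# pair bookkeeping and permutation machinery
# ---------------------------------------------------------------------------

def pair_indices(cohorts: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair indices selected by analysis mode.

    ``mode`` is ``"all"``, ``"between"`` (strictly different cohorts) or
    ``"within_<label>"`` (both individuals from that cohort).
    """
    coh = np.asarray(cohorts).astype(str)
    n = len(coh)
    i, j = np.triu_indices(n, k=1)
    if mode == "all":
        keep = np.ones(len(i), dtype=bool)
    elif mode in ("between", "between_cohorts"):
        keep = coh[i] != coh[j]
    elif mode.startswith("within_"):
        label = mode[len("within_"):]
        if label not in set(coh):
            raise ValueError(f"cohort {label!r} not present")
        keep = (coh[i] == label) & (coh[j] == label)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return i[keep], j[keep]


def cohort_permutations(cohorts: np.ndarray, n_perm: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Random genotype-to-coordinate reassignments, shuffled within cohorts.

    Returns an (n_perm, n) array of index permutations; applying one row
    ``pi`` relabels kinship values as F[pi[i], pi[j]] while coordinates stay
    put, so each cohort keeps its spatial point pattern under the null.
    """
    coh = np.asarray(cohorts).astype(str)
    n = len(coh)
    perms = np.tile(np.arange(n), (n_perm, 1))
    for lab in np.unique(coh):
        idx = np.where(coh == lab)[0]
        sub = np.tile(idx, (n_perm, 1))
        # vectorized independent shuffles via random-key argsort
        keys = rng.random((n_perm, len(idx)))
        perms[:, idx] = np.take_along_axis(sub, np.argsort(keys, axis=1), axis=1)
    return perms


def _two_sided_p(null: np.ndarray, obs: float) -> float:
    # the 1e-12 slack keeps degenerate nulls (identical up to summation
    # order) from turning into coin flips
    n_perm = len(null)
    p_hi = (1 + np.sum(null >= obs - 1e-12)) / (n_perm + 1)
    p_lo = (1 + np.sum(null <= obs + 1e-12)) / (n_perm + 1)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


# ---------------------------------------------------------------------------
# distogram
# ---------------------------------------------------------------------------

@dataclass
class Distogram:
    """Mean kinship per distance class with a permutation null envelope."""

    class_edges: np.ndarray      # (C + 1,), contiguous from 0
    F_D: np.ndarray              # (C,), NaN where a class is empty
    n_pairs: np.ndarray          # (C,)
    envelope_lo: np.ndarray      # 2.5 percentile of the null per class
    envelope_hi: np.ndarray      # 97.5 percentile
    p_per_class: np.ndarray      # two-sided permutation p, NaN where empty
    mode: str


def distogram(k: KinshipMatrix, geom: np.ndarray, mode: str,
              config: AnalysisConfig) -> Distogram:
    """Distance-class distogram of mean pairwise kinship.

    ``geom`` is the pairwise distance matrix aligned to ``k``. The null per
    class is built by shuffling the genotype-to-coordinate assignment within
    cohorts ``config.n_perm_distogram`` times; p-values are two-sided and the
    envelope spans the central 95% of the null draws.
    """
    D = np.asarray(geom, float)
    if D.shape != k.values.shape:
        raise ValueError("distance matrix not aligned with kinship matrix")
    i_idx, j_idx = pair_indices(k.cohorts, mode)
    d = D[i_idx, j_idx]
    width = config.distance_class_width
    n_classes = max(1, int(np.ceil(d.max() / width)))
    edges = width * np.arange(n_classes + 1)
    cls = np.minimum((d / width).astype(int), n_classes - 1)

    F = k.values
    f_obs = F[i_idx, j_idx]
    valid = ~np.isnan(f_obs)
    counts = np.bincount(cls[valid], minlength=n_classes)
    sums = np.bincount(cls[valid], weights=f_obs[valid], minlength=n_classes)
    with np.errstate(invalid="ignore"):
        F_D = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    n_perm = config.n_perm_distogram
    perms = cohort_permutations(k.cohorts, n_perm, config.rng())
    null = np.empty((n_perm, n_classes))
    for b in range(n_perm):
        fp = F[perms[b, i_idx], perms[b, j_idx]]
        ok = ~np.isnan(fp)
        s = np.bincount(cls[ok], weights=fp[ok], minlength=n_classes)
        c = np.bincount(cls[ok], minlength=n_classes)
        null[b] = np.where(c > 0, s / np.maximum(c, 1), np.nan)

    p = np.full(n_classes, np.nan)
    lo = np.full(n_classes, np.nan)
    hi = np.full(n_classes, np.nan)
    for c in range(n_classes):
        col = null[:, c]
        col = col[~np.isnan(col)]
        if counts[c] == 0 or len(col) == 0 or np.isnan(F_D[c]):
            continue
        p[c] = _two_sided_p(col, F_D[c])
        lo[c], hi[c] = np.percentile(col, [2.5, 97.5])
    return Distogram(class_edges=edges, F_D=F_D, n_pairs=counts,
                     envelope_lo=lo, envelope_hi=hi, p_per_class=p, mode=mode)


# ---------------------------------------------------------------------------
# Sp statistic
# ---------------------------------------------------------------------------

@dataclass
class SpResult:
    """b_F, F_1 and Sp with jackknife-over-loci SEs and permutation p."""

    b_F: float
    F_1: float
    Sp: float
    se_bF: float | None
    se_F1: float | None
    se_Sp: float | None
    p_Sp: float | None
    distance_range_used: tuple[float, float]
    mode: str
    n_pairs_regression: int
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "b_F": self.b_F, "F_1": self.F_1, "Sp": self.Sp,
            "se_bF": self.se_bF, "se_F1": self.se_F1, "se_Sp": self.se_Sp,
            "p_Sp": self.p_Sp,
            "distance_range_used": list(self.distance_range_used),
            "mode": self.mode, "n_pairs_regression": self.n_pairs_regression,
            "converged": self.converged,
        }


def sp_from_components(b_F: float, F_1: float) -> float:
    """The Sp identity -b_F/(1 - F_1)."""
    return -b_F / (1.0 - F_1)


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = np.sum(xc * xc)
    if denom == 0:
        raise ValueError("all regression pairs at one distance; b_F undefined")
    return float(np.sum(xc * (y - y.mean())) / denom)


def _point_estimates(F: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray,
                     d: np.ndarray, lnd: np.ndarray, first_class: np.ndarray,
                     in_range: np.ndarray) -> tuple[float, float, float]:
    f = F[i_idx, j_idx]
    ok = ~np.isnan(f)
    F1 = float(np.mean(f[first_class & ok])) if np.any(first_class & ok) else np.nan
    reg = in_range & ok
    b = _slope(lnd[reg], f[reg])
    return b, F1, sp_from_components(b, F1)


def sp_statistic(k: KinshipMatrix, geom: np.ndarray, mode: str,
                 config: AnalysisConfig, density: float | None = None,
                 pair_subset: tuple[np.ndarray, np.ndarray] | None = None,
                 n_perm: int | None = None) -> SpResult:
    """Estimate b_F, F_1 and Sp for one analysis mode.

    b_F is the least-squares slope of pairwise kinship on ln(distance);
    zero-distance pairs enter the first distance class (hence F_1) but are
    excluded from the log regression. If an effective density (individuals
    per m^2) is supplied, the regression range is restricted iteratively to
    (sigma, 20 sigma) with sigma = sqrt(Nb / (4 pi density)) and
    Nb = (1 - F_1)/Sp, until sigma changes by <1% (20 iterations max;
    non-convergence falls back to the full range, flagged). Jackknife SEs
    require >=2 loci; the permutation p for Sp reuses the within-cohort
    genotype-relocation scheme.

    ``pair_subset`` (explicit pair index arrays) supports sector-restricted
    analyses; permutations then rebuild Sp on the same pair set.
    """
    D = np.asarray(geom, float)
    if pair_subset is not None:
        i_idx, j_idx = pair_subset
    else:
        i_idx, j_idx = pair_indices(k.cohorts, mode)
    d = D[i_idx, j_idx]
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    pos = d > 0
    with np.errstate(divide="ignore"):
        lnd = np.where(pos, np.log(np.maximum(d, 1e-300)), np.nan)
    first_class = d < config.distance_class_width
    full_range = (0.0, float(d.max()))

    F = k.values

    def estimates(d_lo: float, d_hi: float):
        in_range = pos & (d > d_lo) & (d <= d_hi)
        return _point_estimates(F, i_idx, j_idx, d, lnd, first_class, in_range), in_range

    (b, F1, Sp), in_range = estimates(*full_range)
    rng_used = full_range
    converged = True
    if density is not None:
        sigma_prev = None
        converged = False
        for _ in range(20):
            if Sp <= 0 or not np.isfinite(Sp):
                break
            Nb = (1.0 - F1) / Sp
            sigma = float(np.sqrt(Nb / (4.0 * np.pi * density)))
            if sigma_prev is not None and abs(sigma - sigma_prev) < 0.01 * sigma_prev:
                converged = True
                break
            sigma_prev = sigma
            lo, hi = sigma, 20.0 * sigma
            trial = pos & (d > lo) & (d <= hi)
            if trial.sum() < 3:
                break
            (b, F1, Sp), in_range = estimates(lo, hi)
            rng_used = (lo, hi)
        if not converged:
            (b, F1, Sp), in_range = estimates(*full_range)
            rng_used = full_range

    # jackknife over loci
    se_b = se_F1 = se_Sp = None
    L = k.n_loci
    if L >= 2:
        theta = np.empty((L, 3))
        for l in range(L):
            Fl = k.multilocus(drop_locus=l)
            theta[l] = _point_estimates(Fl, i_idx, j_idx, d, lnd,
                                        first_class, in_range)
        fac = (L - 1) / L
        se_b, se_F1, se_Sp = (
            float(np.sqrt(fac * np.sum((theta[:, c] - theta[:, c].mean()) ** 2)))
            for c in range(3)
        )

    p_Sp = None
    n_perm = config.n_perm_distogram if n_perm is None else n_perm
    if n_perm > 0:
        perms = cohort_permutations(k.cohorts, n_perm, config.rng())
        reg = in_range
        null = np.empty(n_perm)
        for bi in range(n_perm):
            fp = F[perms[bi, i_idx], perms[bi, j_idx]]
            ok = ~np.isnan(fp)
            f1p = np.mean(fp[first_class & ok]) if np.any(first_class & ok) else np.nan
            bp = _slope(lnd[reg & ok], fp[reg & ok])
            null[bi] = sp_from_components(bp, f1p)
        p_Sp = _two_sided_p(null, Sp)

    return SpResult(b_F=b, F_1=F1, Sp=Sp, se_bF=se_b, se_F1=se_F1,
                    se_Sp=se_Sp, p_Sp=p_Sp, distance_range_used=rng_used,
                    mode=mode, n_pairs_regression=int(np.sum(in_range)),
                    converged=converged)


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

def compare_cohorts(a: SpResult, b: SpResult, n_loci: int) -> dict[str, dict]:
    """t-tests of b_F, F_1 and Sp between two cohorts.

    Uses the jackknife-over-loci SEs: t = (theta_a - theta_b) /
    sqrt(se_a^2 + se_b^2), two-sided p on Student's t with n_loci - 1 df.
    """
    out: dict[str, dict] = {}
    for name, (xa, sa), (xb, sb) in (
        ("b_F", (a.b_F, a.se_bF), (b.b_F, b.se_bF)),
        ("F_1", (a.F_1, a.se_F1), (b.F_1, b.se_F1)),
        ("Sp", (a.Sp, a.se_Sp), (b.Sp, b.se_Sp)),
    ):
        if sa is None or sb is None:
            raise ValueError("both results must carry jackknife SEs")
        denom = np.sqrt(sa ** 2 + sb ** 2)
        if denom == 0:
            t = 0.0 if xa == xb else np.inf
        else:
            t = (xa - xb) / denom
        p = float(2.0 * stats.t.sf(abs(t), df=n_loci - 1)) if np.isfinite(t) else 0.0
        out[name] = {"t": float(t), "p": min(1.0, p)}
    return out
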