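"""Spatial principal component analysis of allele frequencies.

sPCA finds linear combinations of allele-frequency columns whose scores
jointly maximize variance and spatial autocorrelation (Moran's I) under an
inverse-distance connection network: eigenvectors of

    M = (1/S0) X^T W_sym X,   W_sym = (W + W^T)/2,  S0 = sum of W_sym,

where X is the column-centered individual x allele matrix. Each eigenvalue
equals var(score) x Moran's I(score) of its score vector, so positive
eigenvalues flag global structures (clines, patches of similar genotypes)
and negative ones local structures (neighbour contrasts). Significance of
global/local structure is assessed with a Moran-eigenvector-based statistic
under row permutations of X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MISSING, GenotypeTable, SpatialFrame, pairwise_geometry

__all__ = [
    "ConnectionNetwork",
    "SpcaResult",
    "build_network",
    "moran_i",
    "allele_frequency_matrix",
    "spca_fit",
    "global_local_test",
]


@dataclass
class ConnectionNetwork:
    """Inverse-distance spatial weights W_ij = 1/d_ij (zero diagonal)."""

    weights: np.ndarray
    style: str  # "raw" or "row"
    ids: list[str]

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def symmetric(self) -> np.ndarray:
        return 0.5 * (self.weights + self.weights.T)

    @property
    def s0(self) -> float:
        return float(self.symmetric().sum())


def build_network(frame: SpatialFrame, style: str = "raw") -> ConnectionNetwork:
    """Inverse-distance weights among all individuals.

    Co-located pairs (d = 0) get the weight of half the smallest nonzero
    distance, keeping weights finite. ``style="row"`` row-standardizes
    (each row sums to 1), the convention expected by the SAR module.
    """
    if style not in ("raw", "row"):
        raise ValueError(f"unknown style {style!r}")
    D, _ = pairwise_geometry(frame)
    off = D[np.triu_indices_from(D, k=1)]
    nz = off[off > 0]
    if len(nz) == 0:
        raise ValueError("all individuals co-located; network undefined")
    eps = 0.5 * nz.min()
    Dsafe = np.where(D > 0, D, eps)
    W = 1.0 / Dsafe
    np.fill_diagonal(W, 0.0)
    if style == "row":
        rs = W.sum(axis=1, keepdims=True)
        W = W / np.where(rs > 0, rs, 1.0)
    return ConnectionNetwork(weights=W, style=style, ids=list(frame.ids))


def moran_i(values: np.ndarray, net: ConnectionNetwork | np.ndarray,
            n_perm: int = 0, rng: np.random.Generator | None = None
            ) -> tuple[float, float | None]:
        # I = (n/S0) z'Wz / z'z with z centered; permutation p two-sided
    W = net.weights if isinstance(net, ConnectionNetwork) else np.asarray(net)
    z = np.asarray(values, float)
    z = z - z.mean()
    n = len(z)
    s0 = W.sum()
    denom = float(z @ z)
    if denom == 0 or s0 == 0:
        raise ValueError("constant input or empty network; Moran's I undefined")
    I = float((n / s0) * (z @ W @ z) / denom)
    p = None
    if n_perm > 0:
        rng = rng or np.random.default_rng(0)
        null = np.empty(n_perm)
        zp = z.copy()
        for b in range(n_perm):
            rng.shuffle(zp)
            null[b] = (n / s0) * (zp @ W @ zp) / denom
        p_hi = (1 + np.sum(null >= I)) / (n_perm + 1)
        p_lo = (1 + np.sum(null <= I)) / (n_perm + 1)
        p = float(min(1.0, 2 * min(p_hi, p_lo)))
    return I, p


def allele_frequency_matrix(g: GenotypeTable, center: bool = True
                            ) -> tuple[np.ndarray, list[str]]:
    """Individual x allele matrix of within-individual frequencies.

    One column per allele per locus with entries 0, 1/2 or 1; missing calls
    are imputed with the column mean (an imputation used only here, never in
    kinship estimation); monomorphic columns are dropped.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for l, locus in enumerate(g.loci):
        P, scored, alleles = g.dosage(l)
        if len(alleles) == 0 or not scored.any():
            raise ValueError(f"locus {locus!r} has no scored individuals")
        mean = P[scored].mean(axis=0)
        Pfull = np.where(scored[:, None], P, mean[None, :])
        for a_i, a in enumerate(alleles):
            col = Pfull[:, a_i]
            if np.ptp(col) == 0:
                continue  # monomorphic column carries no signal
            cols.append(col)
            names.append(f"{locus}.{a}")
    if not cols:
        raise ValueError("no polymorphic allele columns")
    X = np.column_stack(cols)
    if center:
        X = X - X.mean(axis=0)
    return X, names


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray      # sorted descending, signed
    scores: np.ndarray           # individuals x components
    loadings: np.ndarray         # allele columns x components
    column_names: list[str]
    cohort: str | None = None

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.eigenvalues > 0))


def spca_fit(g: GenotypeTable, net: ConnectionNetwork,
             cohort: str | None = None) -> SpcaResult:
    """Fit the sPCA for one cohort (or the full table if ``cohort`` is None).

    The network must be aligned to the analyzed individuals. Eigenvalues are
    returned in decreasing signed order; by construction eigenvalue k equals
    var(score_k) x Moran's I(score_k).
    """
    sub = g if cohort is None else g.cohort_subset(cohort)
    if sub.n_individuals < 3:
        raise ValueError("sPCA needs at least 3 individuals")
    if net.n != sub.n_individuals or net.ids != sub.ids:
        raise ValueError("network not aligned with the analyzed individuals")
    X, names = allele_frequency_matrix(sub)
    Wsym = net.symmetric()
    s0 = Wsym.sum()
    if s0 == 0:
        M = np.zeros((X.shape[1], X.shape[1]))
    else:
        M = X.T @ Wsym @ X / s0
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scores = X @ vecs
    return SpcaResult(eigenvalues=vals, scores=scores, loadings=vecs,
                      column_names=names, cohort=cohort)


def _moran_eigenvectors(Wsym: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered Moran eigenvectors (MEMs) and their Moran's I values."""
    n = Wsym.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    vals, vecs = np.linalg.eigh(H @ Wsym @ H)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # drop the trivial constant vector (eigenvalue ~ 0 and no variance)
    keep = np.abs(vecs - vecs.mean(axis=0, keepdims=True)).max(axis=0) > 1e-10
    vecs, vals = vecs[:, keep], vals[keep]
    s0 = Wsym.sum()
    I = np.array([(n / s0) * (u @ Wsym @ u) / (u @ u) for u in vecs.T])
    return vecs, I


def _gl_statistic(X: np.ndarray, U: np.ndarray, order: np.ndarray,
                  window: int) -> float:
    Xc = X - X.mean(axis=0)
    Xn = Xc / np.sqrt(np.sum(Xc ** 2, axis=0))
    # U columns are orthonormal and centered; correlation = normalized dot
    Un = U / np.sqrt(np.sum(U ** 2, axis=0))
    R2 = (Xn.T @ Un) ** 2          # (columns, MEMs)
    t = R2.mean(axis=0)[order]
    if window <= 1 or len(t) < window:
        return float(t.max())
    sliding = np.convolve(t, np.ones(window) / window, mode="valid")
    return float(sliding.max())


def global_local_test(g: GenotypeTable, net: ConnectionNetwork,
                      cohort: str | None = None, which: str = "global",
                      n_perm: int = 999, window: int = 3,
                      rng: np.random.Generator | None = None
                      ) -> tuple[float, float]:
    """Permutation test for global or local spatial genetic structure.

    Computes Moran eigenvectors of the (double-centered) symmetrized network,
    scores every allele column by its squared correlation with each
    eigenvector, orders eigenvectors by decreasing (global) or increasing
    (local) Moran's I and takes the maximum of a width-``window`` sliding
    mean of those scores, max(t). The null distribution comes from permuting
    the rows of the allele-frequency matrix. Returns ``(max_t, p)``.
    """
    if which not in ("global", "local"):
        raise ValueError(f"which must be 'global' or 'local', got {which!r}")
    sub = g if cohort is None else g.cohort_subset(cohort)
    if sub.n_individuals < 4:
        raise ValueError("global/local test needs at least 4 individuals")
    if net.n != sub.n_individuals or net.ids != sub.ids:
        raise ValueError("network not aligned with the analyzed individuals")
    X, _ = allele_frequency_matrix(sub)
    U, I = _moran_eigenvectors(net.symmetric())
    # split the Moran spectrum at the null expectation E[I] = -1/(n-1):
    # eigenvectors above it carry global (positive-autocorrelation) signal,
    # those below it local (neighbour-contrast) signal
    i0 = -1.0 / (sub.n_individuals - 1)
    if which == "global":
        subset = np.where(I >= i0)[0]
        order = subset[np.argsort(I[subset])[::-1]]
    else:
        subset = np.where(I < i0)[0]
        order = subset[np.argsort(I[subset])]
    if len(order) == 0:
        raise ValueError(f"no Moran eigenvectors on the {which} side")
    obs = _gl_statistic(X, U, order, window)
    rng = rng or np.random.default_rng(0)
    n = X.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _gl_statistic(X[perm], U, order, window) >= obs:
            hits += 1
    return obs, (1 + hits) / (n_perm + 1)
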