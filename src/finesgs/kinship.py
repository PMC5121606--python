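"""Pairwise Loiselle/Nason kinship coefficients.

The kinship coefficient F_ij measures the correlation of allele frequencies
between two individuals relative to reference (sample) allele frequencies.
Per locus l with alleles a,

    F_ij,l = sum_a [ (p_ila - p_la)(p_jla - p_la) + p_la(1 - p_la)/(N_l - 1) ]
             / sum_a p_la (1 - p_la)

where p_ila is individual i's allele frequency (0, 1/2 or 1 for a diploid;
0 or 1 for a haploid plastid haplotype treated as a single locus), p_la the
reference frequency estimated from the individuals scored at that locus, and
N_l the number of scored gene copies there (twice the scored individuals for
diploids). The (N_l - 1) correction makes the estimator mean-zero over pairs
of individuals drawn independently from the reference frequencies. Multilocus values
combine loci as a ratio of sums: F_ij = sum_l num_ij,l / sum_l den_l, with
per-locus pairwise deletion (a locus contributes to a pair only when both
individuals are scored there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import GenotypeTable

__all__ = ["KinshipMatrix", "kinship_matrix"]


@dataclass
class KinshipMatrix:
    """Pairwise kinship with per-locus components for jackknife resampling.

    ``values`` is the multilocus ratio-of-sums matrix (NaN on the diagonal and
    for pairs sharing no scored locus). ``num_per_locus`` and
    ``den_per_locus`` retain the per-locus numerator and denominator matrices
    (zero where a pair does not share the locus) so that delete-one-locus
    statistics can be rebuilt exactly without re-estimating frequencies.
    """

    values: np.ndarray
    ids: list[str]
    cohorts: np.ndarray
    ploidy: str
    locus_names: list[str]
    num_per_locus: np.ndarray          # (L, n, n), zero where pair invalid
    den_per_locus: np.ndarray          # (L, n, n), zero where pair invalid
    reference_freqs: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def multilocus(self, drop_locus: int | None = None) -> np.ndarray:
        """Ratio-of-sums multilocus matrix, optionally deleting one locus."""
        keep = np.ones(self.n_loci, dtype=bool)
        if drop_locus is not None:
            keep[drop_locus] = False
        num = self.num_per_locus[keep].sum(axis=0)
        den = self.den_per_locus[keep].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        np.fill_diagonal(F, np.nan)
        return F


def _locus_components(P: np.ndarray, scored: np.ndarray, copies_per_ind: int
                      ) -> tuple[np.ndarray, float, np.ndarray] | None:
    """Numerator matrix, denominator and reference freqs for one locus."""
    n_l = int(scored.sum())
    if n_l < 2:
        return None
    p = P[scored].mean(axis=0)
    den = float(np.sum(p * (1.0 - p)))
    if den <= 0.0:
        return None  # monomorphic in the reference sample
    C = np.where(scored[:, None], P - p[None, :], 0.0)
    num = C @ C.T + den / (copies_per_ind * n_l - 1)
    return num, den, p


def kinship_matrix(g: GenotypeTable, marker: str = "ssr",
                   freq_scope: str = "pooled") -> KinshipMatrix:
    """Loiselle/Nason kinship matrix for SSR genotypes or plastid haplotypes.

    Parameters
    ----------
    g
        Genotype table; for ``marker="plastid"`` its haplotype column is
        treated as a single haploid locus.
    marker
        ``"ssr"`` (diploid, all loci) or ``"plastid"`` (haploid, one locus).
    freq_scope
        ``"pooled"`` references allele frequencies to the whole sample (the
        scale shared by within- and between-cohort analyses); ``"per_cohort"``
        re-estimates frequencies within each cohort and defines kinship only
        for same-cohort pairs.
    """
    if g.n_individuals < 3:
        raise ValueError("kinship requires at least 3 individuals")
    if marker not in ("ssr", "plastid"):
        raise ValueError(f"unknown marker {marker!r}")
    if freq_scope not in ("pooled", "per_cohort"):
        raise ValueError(f"unknown freq_scope {freq_scope!r}")

    n = g.n_individuals
    if marker == "ssr":
        locus_names = list(g.loci)
        dosages = [g.dosage(j) for j in range(g.n_loci)]
        ploidy = "diploid"
    else:
        locus_names = ["plastid"]
        dosages = [g.haplotype_dosage()]
        ploidy = "haploid"

    L = len(locus_names)
    num = np.zeros((L, n, n))
    den = np.zeros((L, n, n))
    freqs: dict[str, np.ndarray] = {}

    if freq_scope == "pooled":
        groups: list[tuple[str, np.ndarray]] = [("pooled", np.ones(n, dtype=bool))]
    else:
        coh = g.cohorts.astype(str)
        groups = [(lab, coh == lab) for lab in g.cohort_labels]

    copies = 2 if ploidy == "diploid" else 1
    kept = np.zeros(L, dtype=bool)
    for l, (P, scored, _alleles) in enumerate(dosages):
        for gname, grp in groups:
            comp = _locus_components(P[grp], scored[grp], copies)
            if comp is None:
                continue
            num_g, den_g, p = comp
            gi = np.where(grp)[0]
            pair_ok = np.outer(scored[grp], scored[grp])
            num[l][np.ix_(gi, gi)] = np.where(pair_ok, num_g, 0.0)
            den[l][np.ix_(gi, gi)] = np.where(pair_ok, den_g, 0.0)
            key = locus_names[l] if freq_scope == "pooled" \
                else f"{locus_names[l]}|{gname}"
            freqs[key] = p
            kept[l] = True
    if not kept.any():
        raise ValueError("no polymorphic locus with >=2 scored individuals")
    dropped = [locus_names[l] for l in range(L) if not kept[l]]
    if dropped:
        warnings.warn(f"monomorphic/unscorable loci skipped: {dropped}")
    keep_idx = np.where(kept)[0]
    num, den = num[keep_idx], den[keep_idx]
    locus_names = [locus_names[l] for l in keep_idx]

    km = KinshipMatrix(
        values=np.empty((n, n)), ids=list(g.ids), cohorts=g.cohorts.copy(),
        ploidy=ploidy, locus_names=locus_names, num_per_locus=num,
        den_per_locus=den, reference_freqs=freqs,
    )
    km.values = km.multilocus()
    return km
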