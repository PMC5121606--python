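"""Domain types and file I/O for georeferenced multilocus genotype data.

The core containers are :class:`GenotypeTable` (diploid codominant calls plus
an optional haploid plastid haplotype per individual, with cohort labels),
:class:`SpatialFrame` (x/y coordinates in meters on a rectangular plot) and
:class:`EnvironmentTable` (per-individual light and soil covariates).
Genotypes are read from GENEPOP files or from a tidy CSV dialect with one
"a1/a2" column per locus; coordinates and environment travel as plain CSV.

Allele codes are opaque non-negative integers; a missing call is stored as
``MISSING`` (-1) in both allele slots of a locus.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeTable",
    "SpatialFrame",
    "EnvironmentTable",
    "AnalysisConfig",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes_csv",
    "write_genotypes_genepop",
    "read_coordinates",
    "read_environment",
    "pairwise_geometry",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed; names the offending line."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls plus optional plastid haplotype.

    Parameters
    ----------
    ids
        Unique individual identifiers, length n.
    cohorts
        Cohort label per individual (e.g. flowering year "2010"/"2011").
    loci
        Ordered locus names, length L.
    calls
        Integer array of shape (n, L, 2); ``MISSING`` in both slots marks a
        missing call at that locus.
    haplotypes
        Optional integer array of shape (n,); haploid plastid haplotype codes,
        ``MISSING`` where unscored.
    """

    ids: list[str]
    cohorts: np.ndarray
    loci: list[str]
    calls: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cohorts = np.asarray(self.cohorts, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int64)
        self.validate()

    # -- basic properties ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def cohort_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cohorts:
            seen.setdefault(str(c), None)
        return list(seen)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return np.any(self.calls == MISSING, axis=2)

    def validate(self) -> None:
        n, L = len(self.ids), len(self.loci)
        if len(set(self.ids)) != n:
            raise ValueError("individual ids must be unique")
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.cohorts) != n:
            raise ValueError("one cohort label per individual required")
        # a missing slot must mean a fully missing call: half-calls disallowed
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call for individual {self.ids[i]!r} at locus "
                f"{self.loci[l]!r}: both allele slots must be present or missing"
            )
        if ((self.calls < MISSING)).any():
            raise ValueError("allele codes must be non-negative (or MISSING)")
        if self.haplotypes is not None and len(self.haplotypes) != n:
            raise ValueError("one haplotype per individual required")

    # -- derived views ------------------------------------------------------
    def alleles_at(self, locus: str | int) -> np.ndarray:
        """Sorted distinct (non-missing) allele codes at a locus."""
        l = locus if isinstance(locus, int) else self.loci.index(locus)
        a = self.calls[:, l, :].ravel()
        return np.unique(a[a != MISSING])

    def dosage(self, locus: str | int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-individual allele frequencies at one locus.

        Returns ``(P, scored, alleles)`` where ``P`` is (n, A) with rows of
        individual allele frequencies p_ila in {0, 1/2, 1}, ``scored`` marks
        individuals with a non-missing call, and ``alleles`` lists the allele
        codes for the columns. Rows of unscored individuals are zero.
        """
        l = locus if isinstance(locus, int) else self.loci.index(locus)
        alleles = self.alleles_at(l)
        scored = ~self.missing_mask[:, l]
        P = np.zeros((self.n_individuals, len(alleles)))
        if len(alleles):
            idx = np.searchsorted(alleles, self.calls[:, l, :])
            for slot in (0, 1):
                rows = np.where(scored)[0]
                P[rows, idx[rows, slot]] += 0.5
        return P, scored, alleles

    def haplotype_dosage(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One-hot haplotype indicator matrix, analogous to :meth:`dosage`."""
        if self.haplotypes is None:
            raise ValueError("table carries no haplotypes")
        scored = self.haplotypes != MISSING
        haps = np.unique(self.haplotypes[scored])
        P = np.zeros((self.n_individuals, len(haps)))
        rows = np.where(scored)[0]
        P[rows, np.searchsorted(haps, self.haplotypes[rows])] = 1.0
        return P, scored, haps

    def subset(self, index: np.ndarray | Sequence[int]) -> "GenotypeTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.where(index)[0]
        return GenotypeTable(
            ids=[self.ids[i] for i in index],
            cohorts=self.cohorts[index],
            loci=list(self.loci),
            calls=self.calls[index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
        )

    def cohort_subset(self, label: str) -> "GenotypeTable":
        return self.subset(self.cohorts.astype(str) == str(label))


@dataclass
class SpatialFrame:
    """Per-individual coordinates (meters) inside a rectangular plot."""

    ids: list[str]
    x: np.ndarray
    y: np.ndarray
    plot_bounds: tuple[float, float, float, float] | None = None  # xmin,xmax,ymin,ymax

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise ValueError("ids, x and y must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids must be unique")
        if self.plot_bounds is not None:
            xmin, xmax, ymin, ymax = self.plot_bounds
            if (self.x < xmin).any() or (self.x > xmax).any() \
                    or (self.y < ymin).any() or (self.y > ymax).any():
                raise ValueError("coordinates outside plot_bounds")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def align_to(self, ids: Sequence[str]) -> "SpatialFrame":
        """Reorder to match another id sequence (must be a permutation)."""
        pos = {s: i for i, s in enumerate(self.ids)}
        try:
            order = [pos[s] for s in ids]
        except KeyError as e:
            raise ValueError(f"id {e.args[0]!r} not present in SpatialFrame") from None
        return SpatialFrame(list(ids), self.x[order], self.y[order], self.plot_bounds)


@dataclass
class EnvironmentTable:
    """Per-individual environmental covariates.

    ``dsf`` is the Direct Site Factor (fraction of direct light, unitless in
    [0, 1]); ``na``/``k``/``mg`` are soil cation concentrations and
    ``n_total``/``p_total`` soil anion concentrations, each in one declared
    unit; ``field_capacity`` is the soil moisture fraction at field capacity.
    Missing values are NaN and are never silently imputed.
    """

    COLUMNS = ("dsf", "na", "k", "mg", "n_total", "p_total", "field_capacity")

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if "individual_id" not in self.data.columns:
            raise ValueError("environment table needs an individual_id column")
        if self.data["individual_id"].duplicated().any():
            raise ValueError("one row per individual required")
        missing_cols = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"environment table missing columns: {missing_cols}")

    @property
    def ids(self) -> list[str]:
        return self.data["individual_id"].astype(str).tolist()

    def align_to(self, ids: Sequence[str]) -> "EnvironmentTable":
        df = self.data.set_index("individual_id").loc[list(ids)].reset_index()
        return EnvironmentTable(df)


@dataclass
class AnalysisConfig:
    """Permutation counts, distance-class width and angular settings.

    Defaults follow common practice for fine-scale SGS studies on ~100-plant
    plots: 0.5 m distance classes, 9999 distogram permutations, 999 Mantel
    permutations, 500 F_ST permutations, 128 bearing angles and 30-degree
    sectors (half-width 15 degrees).
    """

    distance_class_width: float = 0.5
    n_perm_distogram: int = 9999
    n_perm_mantel: int = 999
    n_perm_fst: int = 500
    n_bearing_angles: int = 128
    sector_halfwidth: float = 15.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_perm_distogram", "n_perm_mantel", "n_perm_fst",
                     "n_bearing_angles"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.sector_halfwidth <= 90:
            raise ValueError("sector_halfwidth must be in (0, 90] degrees")
        if self.distance_class_width <= 0:
            raise ValueError("distance_class_width must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def _parse_genepop_call(tok: str, width: int, lineno: int) -> tuple[int, int]:
    if len(tok) != 2 * width or not tok.isdigit():
        raise GenotypeParseError(
            f"line {lineno}: genotype token {tok!r} is not {2 * width} digits"
        )
    a1, a2 = int(tok[:width]), int(tok[width:])
    if a1 == 0 or a2 == 0:
        return (MISSING, MISSING)
    return (a1, a2)


def _read_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeParseError("line 1: empty GENEPOP file")
    # line 1 is a free title; locus names follow, one per line or comma-separated
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise GenotypeParseError("line 2: no locus names before first 'pop'")
    ids: list[str] = []
    cohorts: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise GenotypeParseError(
                f"line {i + 1}: expected 'id , genotypes' (missing comma)"
            )
        ind_id, geno = line.split(",", 1)
        toks = geno.split()
        if len(toks) != len(loci):
            raise GenotypeParseError(
                f"line {i + 1}: {len(toks)} genotype tokens for {len(loci)} loci"
            )
        for tok in toks:
            w = len(tok) // 2
            if len(tok) not in (4, 6) or (width is not None and w != width):
                raise GenotypeParseError(
                    f"line {i + 1}: inconsistent allele-code width in token {tok!r}"
                )
            width = w
        rows.append([_parse_genepop_call(t, width, i + 1) for t in toks])
        ids.append(ind_id.strip())
        cohorts.append(f"pop{pop_idx}")
        i += 1
    if pop_idx == 0:
        raise GenotypeParseError("no 'pop' line found")
    calls = np.array(rows, dtype=np.int64)
    return GenotypeTable(ids=ids, cohorts=np.array(cohorts, dtype=object),
                         loci=loci, calls=calls)


_CALL_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")


def _read_genotypes_csv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str)
    required = {"individual_id", "cohort"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(
            f"CSV must contain columns {sorted(required)}"
        )
    loci = [c for c in df.columns
            if c not in ("individual_id", "cohort", "haplotype")]
    if not loci:
        raise GenotypeParseError("CSV contains no locus columns")
    n = len(df)
    calls = np.full((n, len(loci), 2), MISSING, dtype=np.int64)
    for j, locus in enumerate(loci):
        for i, cell in enumerate(df[locus]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip().upper() in ("", "NA", "NAN"):
                continue
            m = _CALL_RE.match(str(cell))
            if not m:
                raise GenotypeParseError(
                    f"line {i + 2}: malformed call {cell!r} at locus {locus!r}"
                )
            calls[i, j] = (int(m.group(1)), int(m.group(2)))
    haplotypes = None
    if "haplotype" in df.columns:
        h = df["haplotype"].fillna("NA").astype(str).str.strip()
        haplotypes = np.where(h.str.upper().isin(["", "NA", "NAN"]),
                              MISSING, pd.to_numeric(h, errors="coerce")
                              .fillna(MISSING)).astype(np.int64)
    return GenotypeTable(
        ids=df["individual_id"].astype(str).tolist(),
        cohorts=df["cohort"].astype(str).to_numpy(dtype=object),
        loci=loci, calls=calls, haplotypes=haplotypes,
    )


def read_genotypes(path: str | Path, format: str = "csv") -> GenotypeTable:
    """Read genotypes from a GENEPOP or tidy-CSV file.

    In GENEPOP files, ``00``/``000`` allele codes become missing and the k-th
    ``pop`` block maps to cohort label ``pop<k>``. The CSV dialect has columns
    ``individual_id``, ``cohort``, optional ``haplotype`` and one ``a1/a2``
    column per locus ("NA" or empty = missing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genepop":
        return _read_genepop(path)
    if format == "csv":
        return _read_genotypes_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes_csv(g: GenotypeTable, path: str | Path) -> None:
    """Write the tidy-CSV dialect read by :func:`read_genotypes`."""
    cols: dict[str, list[str]] = {
        "individual_id": list(g.ids),
        "cohort": [str(c) for c in g.cohorts],
    }
    if g.haplotypes is not None:
        cols["haplotype"] = ["NA" if h == MISSING else str(h)
                             for h in g.haplotypes]
    for j, locus in enumerate(g.loci):
        col = []
        for i in range(g.n_individuals):
            a1, a2 = g.calls[i, j]
            col.append("NA" if a1 == MISSING else f"{a1}/{a2}")
        cols[locus] = col
    pd.DataFrame(cols).to_csv(path, index=False)


def write_genotypes_genepop(g: GenotypeTable, path: str | Path,
                            title: str = "finesgs export") -> None:
    """Write a 3-digit GENEPOP file, one pop block per cohort."""
    out = [title]
    out.extend(g.loci)
    for label in g.cohort_labels:
        out.append("pop")
        for i in np.where(g.cohorts.astype(str) == label)[0]:
            toks = []
            for j in range(g.n_loci):
                a1, a2 = g.calls[i, j]
                if a1 == MISSING:
                    toks.append("000000")
                else:
                    toks.append(f"{a1:03d}{a2:03d}")
            out.append(f"{g.ids[i]} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def read_coordinates(path: str | Path,
                     plot_bounds: tuple[float, float, float, float] | None = None,
                     ) -> SpatialFrame:
    """Read a CSV with columns individual_id, x, y (meters)."""
    df = pd.read_csv(path)
    return SpatialFrame(
        ids=df["individual_id"].astype(str).tolist(),
        x=df["x"].to_numpy(float), y=df["y"].to_numpy(float),
        plot_bounds=plot_bounds,
    )


def read_environment(path: str | Path) -> EnvironmentTable:
    """Read a CSV with individual_id plus the standard covariate columns."""
    return EnvironmentTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# pairwise geometry
# ---------------------------------------------------------------------------

def pairwise_geometry(frame: SpatialFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Euclidean distances and clockwise-from-north bearings.

    The bearing of pair (i, j) is the clockwise angle between the plot's
    +Y axis ("north") and the undirected segment i-j, reduced to [0, 180)
    degrees, so that it is symmetric: points due north of each other have
    bearing 0, points due east/west bearing 90. The bearing of a zero-length
    segment is 0 by convention; such pairs are reported for downstream
    exclusion from log-distance fits.

    Returns
    -------
    (D, A)
        Symmetric (n, n) matrices of distances in meters and bearings in
        degrees within [0, 180).
    """
    if frame.n_individuals < 2:
        raise ValueError("pairwise geometry needs at least 2 individuals")
    dx = frame.x[None, :] - frame.x[:, None]
    dy = frame.y[None, :] - frame.y[:, None]
    D = np.hypot(dx, dy)
    A = np.degrees(np.arctan2(dx, dy)) % 180.0
    np.fill_diagonal(A, 0.0)
    A[D == 0] = 0.0
    # symmetrize exactly (arctan2 of opposite vectors differs by 180 degrees,
    # but floating point can leave 1-ulp asymmetries after the modulo)
    iu = np.triu_indices_from(A, k=1)
    A[(iu[1], iu[0])] = A[iu]
    return D, A


def duplicated_coordinate_pairs(D: np.ndarray) -> list[tuple[int, int]]:
    """Index pairs (i < j) at zero distance (co-located plants)."""
    i, j = np.where(np.triu(D == 0, k=1))
    return list(zip(i.tolist(), j.tolist()))
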