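"""Forward-in-time simulator of a facultative-biennial plant population.

Two interleaved lineages model the odd/even flowering-year structure of a
biennial: plants flowering in year t are the offspring of matings in years
t - 2 (same lineage) and, for inter-annual migrants, t - 1 (the other
lineage). Each offspring draws a mother uniformly from the flowering adults,
a father by distance-weighted pollen flow (probability proportional to
exp(-d / pollen_kernel_mean), or selfing), and establishes at an
exponential-kernel seed-dispersal displacement from the mother with uniform
direction, optionally compressed along one axis (anisotropy) and optionally
filtered by an environment-matching establishment probability
exp(-gamma * |g - e(x, y)|) tied to one designated locus. Plastid haplotypes
are maternally inherited and never mutate. After a burn-in the last two
consecutive flowering cohorts are subsampled and returned together with the
full ground truth (parameters, realized migrant count, pedigree).

Defaults emulate a 20 x 20 m plot with ~100 plants per cohort, a seed
kernel mean of 0.3 m (most mass inside the 0-0.4 m range typical of
barochorous dispersal), short-distance pollen flow and a 15% inter-annual
migrant fraction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_model import MISSING, EnvironmentTable, GenotypeTable, SpatialFrame

__all__ = [
    "SimulationConfig",
    "EnvironmentSurfaces",
    "SimOutput",
    "ExtinctionError",
    "make_environment",
    "simulate",
]


class ExtinctionError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    plot_size: tuple[float, float] = (20.0, 20.0)
    n_per_cohort: int = 100
    n_loci: int = 10
    n_alleles_per_locus: int = 10
    n_haplotypes: int = 5
    seed_kernel_mean: float = 0.3          # meters
    pollen_kernel_mean: float = 2.0        # meters
    selfing_rate: float = 0.05
    migrant_fraction: float = 0.15         # cross-lineage recruitment prob m
    anisotropy_ratio: float = 1.0          # a >= 1; 1 = isotropic
    anisotropy_axis: float = 0.0           # degrees clockwise from +Y
    env_coupling: float = 0.0              # gamma >= 0
    dsf_cline: float = 0.5                 # DSF change across the plot in X
    dsf_noise: float = 0.1                 # SD of the smoothed DSF noise
    missing_rate: float = 0.0              # per-call missing probability
    recruit_pool_factor: float = 6.0       # established recruits per flowering plant sampled
    burn_in_generations: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("selfing_rate", "migrant_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.seed_kernel_mean <= 0 or self.pollen_kernel_mean <= 0:
            raise ValueError("kernel means must be positive")
        if self.anisotropy_ratio < 1.0:
            raise ValueError("anisotropy_ratio must be >= 1")
        if self.env_coupling < 0:
            raise ValueError("env_coupling must be >= 0")
        if self.recruit_pool_factor < 1.0:
            raise ValueError("recruit_pool_factor must be >= 1")


# ---------------------------------------------------------------------------
# environmental surfaces
# ---------------------------------------------------------------------------

_GRID = 64
_SOIL_VARS = {"na": (8.0, 2.0), "k": (5.0, 1.5), "mg": (3.0, 1.0),
              "n_total": (2.0, 0.6), "p_total": (1.0, 0.3),
              "field_capacity": (0.3, 0.08)}  # (baseline, patch amplitude)


class EnvironmentSurfaces:
    """Deterministic surfaces over the plot, sampled at plant positions.

    DSF is a linear cline along X plus smoothed Gaussian noise, clipped to
    [0, 1]; soil variables are independent smoothed-noise patchy surfaces.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.rng_seed) % (2 ** 31), 7]))
        lx, ly = config.plot_size
        self._lx, self._ly = lx, ly
        gx = np.linspace(0, 1, _GRID)
        cline = 0.25 + config.dsf_cline * gx[None, :]  # varies along X
        noise = self._smooth_noise(rng) * config.dsf_noise
        self._dsf = np.clip(cline + noise, 0.0, 1.0)
        self._soil = {}
        for name, (base, amp) in _SOIL_VARS.items():
            self._soil[name] = base + amp * self._smooth_noise(rng)
        self._soil["field_capacity"] = np.clip(self._soil["field_capacity"],
                                               0.01, 0.99)
        lo, hi = self._dsf.min(), self._dsf.max()
        self._dsf_std = (self._dsf - lo) / (hi - lo) if hi > lo \
            else np.full_like(self._dsf, 0.5)

    @staticmethod
    def _smooth_noise(rng: np.random.Generator) -> np.ndarray:
        z = ndimage.gaussian_filter(rng.standard_normal((_GRID, _GRID)), 6.0,
                                    mode="reflect")
        sd = z.std()
        return z / sd if sd > 0 else z

    def _sample(self, grid: np.ndarray, x: np.ndarray, y: np.ndarray
                ) -> np.ndarray:
        # bilinear interpolation; grid indexed [y, x]
        gx = np.clip(x / self._lx, 0, 1) * (_GRID - 1)
        gy = np.clip(y / self._ly, 0, 1) * (_GRID - 1)
        x0 = np.clip(gx.astype(int), 0, _GRID - 2)
        y0 = np.clip(gy.astype(int), 0, _GRID - 2)
        fx, fy = gx - x0, gy - y0
        return (grid[y0, x0] * (1 - fx) * (1 - fy)
                + grid[y0, x0 + 1] * fx * (1 - fy)
                + grid[y0 + 1, x0] * (1 - fx) * fy
                + grid[y0 + 1, x0 + 1] * fx * fy)

    def dsf(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self._sample(self._dsf, np.asarray(x, float), np.asarray(y, float))

    def dsf_standardized(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """DSF min-max standardized to [0, 1] (establishment target)."""
        return self._sample(self._dsf_std, np.asarray(x, float),
                            np.asarray(y, float))

    def table(self, ids: list[str], x: np.ndarray, y: np.ndarray
              ) -> EnvironmentTable:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        data = {"individual_id": ids, "dsf": self.dsf(x, y)}
        for name in ("na", "k", "mg", "n_total", "p_total", "field_capacity"):
            data[name] = self._sample(self._soil[name], x, y)
        return EnvironmentTable(pd.DataFrame(data))


def make_environment(config: SimulationConfig) -> EnvironmentSurfaces:
    """Build the deterministic environment surfaces for a configuration."""
    return EnvironmentSurfaces(config)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

@dataclass
class SimOutput:
    genotypes: GenotypeTable
    frame: SpatialFrame
    environment: EnvironmentTable
    truth: dict
    pedigree: dict


class _Pool:
    """One year's recruits: positions, genotypes, haplotypes, pedigree."""

    def __init__(self):
        self.pos: list[np.ndarray] = []
        self.calls: list[np.ndarray] = []
        self.hap: list[np.ndarray] = []
        self.mother_calls: list[np.ndarray] = []
        self.father_calls: list[np.ndarray] = []
        self.mother_hap: list[np.ndarray] = []
        self.displacement: list[np.ndarray] = []
        self.is_migrant: list[np.ndarray] = []

    def add(self, pos, calls, hap, mcalls, fcalls, mhap, disp, migrant):
        self.pos.append(pos)
        self.calls.append(calls)
        self.hap.append(hap)
        self.mother_calls.append(mcalls)
        self.father_calls.append(fcalls)
        self.mother_hap.append(mhap)
        self.displacement.append(disp)
        self.is_migrant.append(migrant)

    def concat(self) -> dict[str, np.ndarray]:
        if not self.pos:
            return {"pos": np.empty((0, 2)), "calls": np.empty((0, 0, 2), int),
                    "hap": np.empty(0, int),
                    "mother_calls": np.empty((0, 0, 2), int),
                    "father_calls": np.empty((0, 0, 2), int),
                    "mother_hap": np.empty(0, int),
                    "displacement": np.empty((0, 2)),
                    "is_migrant": np.empty(0, bool)}
        return {"pos": np.concatenate(self.pos),
                "calls": np.concatenate(self.calls),
                "hap": np.concatenate(self.hap),
                "mother_calls": np.concatenate(self.mother_calls),
                "father_calls": np.concatenate(self.father_calls),
                "mother_hap": np.concatenate(self.mother_hap),
                "displacement": np.concatenate(self.displacement),
                "is_migrant": np.concatenate(self.is_migrant)}


def _reflect(v: np.ndarray, hi: float) -> np.ndarray:
    """Fold coordinates into [0, hi] by reflection at the boundaries."""
    period = 2.0 * hi
    v = np.mod(v, period)
    return np.where(v > hi, period - v, v)


def _genotypic_score(calls: np.ndarray, n_alleles: int) -> np.ndarray:
    """Score of the designated (first) locus mapped to [0, 1]."""
    if n_alleles <= 1:
        return np.full(len(calls), 0.5)
    return (calls[:, 0, 0] + calls[:, 0, 1] - 2.0) / (2.0 * (n_alleles - 1))


def simulate(config: SimulationConfig) -> SimOutput:
    """Run the forward simulation and return the last two flowering cohorts.

    Raises :class:`ExtinctionError` if a lineage dies out during burn-in
    (increase ``n_per_cohort`` or loosen establishment filtering).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.rng_seed) % (2 ** 31), 11]))
    env = make_environment(config)
    lx, ly = config.plot_size
    L, A = config.n_loci, config.n_alleles_per_locus
    K = max(int(np.ceil(config.recruit_pool_factor
                    * config.n_per_cohort)), 4)

    y_final2 = 2 * config.burn_in_generations + 1   # second sampled year
    pools: dict[int, _Pool] = {t: _Pool() for t in range(y_final2 + 1)}

    # founding cohorts for years 0 and 1: random genotypes and positions
    for t in (0, 1):
        pos = np.column_stack([rng.uniform(0, lx, K), rng.uniform(0, ly, K)])
        calls = rng.integers(1, A + 1, size=(K, L, 2))
        hap = rng.integers(1, config.n_haplotypes + 1, size=K)
        zero = np.zeros((K, 2))
        pools[t].add(pos, calls, hap, calls.copy(), calls.copy(), hap.copy(),
                     zero, np.zeros(K, dtype=bool))

    theta = np.radians(config.anisotropy_axis)
    axis = np.array([np.sin(theta), np.cos(theta)])   # clockwise from +Y
    shrink = 1.0 - 1.0 / config.anisotropy_ratio

    for t in range(y_final2):
        adults = pools[t].concat()
        n_ad = len(adults["pos"])
        if n_ad < 2:
            raise ExtinctionError(
                f"flowering cohort of year {t} has {n_ad} plant(s); "
                "increase n_per_cohort or reduce env_coupling")
        need = K
        accepted = {k: [] for k in ("pos", "calls", "hap", "mcalls", "fcalls",
                                    "mhap", "disp")}
        rounds = 0
        while need > 0:
            rounds += 1
            if rounds > 200:
                raise ExtinctionError(
                    "establishment acceptance too low; reduce env_coupling")
            m_idx = rng.integers(0, n_ad, need)
            mpos = adults["pos"][m_idx]
            # pollen: softmax of exp(-d/lambda) over adults, self excluded
            d = np.linalg.norm(mpos[:, None, :] - adults["pos"][None, :, :],
                               axis=2)
            wgt = np.exp(-d / config.pollen_kernel_mean)
            if n_ad > 1:
                wgt[np.arange(need), m_idx] = 0.0
            wgt /= wgt.sum(axis=1, keepdims=True)
            u = rng.random((need, 1))
            f_idx = (wgt.cumsum(axis=1) < u).sum(axis=1).clip(max=n_ad - 1)
            selfed = rng.random(need) < config.selfing_rate
            f_idx = np.where(selfed, m_idx, f_idx)

            mcalls = adults["calls"][m_idx]
            fcalls = adults["calls"][f_idx]
            pick_m = rng.integers(0, 2, size=(need, L))
            pick_f = rng.integers(0, 2, size=(need, L))
            calls = np.stack([
                np.take_along_axis(mcalls, pick_m[:, :, None], axis=2)[:, :, 0],
                np.take_along_axis(fcalls, pick_f[:, :, None], axis=2)[:, :, 0],
            ], axis=2)
            hap = adults["hap"][m_idx]          # maternal plastid inheritance

            dist = rng.exponential(config.seed_kernel_mean, need)
            ang = rng.uniform(0, 2 * np.pi, need)
            disp = np.column_stack([dist * np.sin(ang), dist * np.cos(ang)])
            if shrink > 0:
                disp = disp - shrink * (disp @ axis)[:, None] * axis[None, :]
            pos = mpos + disp
            pos[:, 0] = _reflect(pos[:, 0], lx)
            pos[:, 1] = _reflect(pos[:, 1], ly)

            if config.env_coupling > 0:
                gscore = _genotypic_score(calls, A)
                e = env.dsf_standardized(pos[:, 0], pos[:, 1])
                acc = rng.random(need) < np.exp(
                    -config.env_coupling * np.abs(gscore - e))
            else:
                acc = np.ones(need, dtype=bool)
            for key, val in (("pos", pos), ("calls", calls), ("hap", hap),
                             ("mcalls", mcalls), ("fcalls", fcalls),
                             ("mhap", hap), ("disp", disp)):
                accepted[key].append(val[acc])
            need -= int(acc.sum())

        pos = np.concatenate(accepted["pos"])[:K]
        calls = np.concatenate(accepted["calls"])[:K]
        hap = np.concatenate(accepted["hap"])[:K]
        mcalls = np.concatenate(accepted["mcalls"])[:K]
        fcalls = np.concatenate(accepted["fcalls"])[:K]
        mhap = np.concatenate(accepted["mhap"])[:K]
        disp = np.concatenate(accepted["disp"])[:K]

        migrant = rng.random(K) < config.migrant_fraction
        for target, mask in ((t + 1, migrant), ((t + 2), ~migrant)):
            if target <= y_final2 and mask.any():
                pools[target].add(pos[mask], calls[mask], hap[mask],
                                  mcalls[mask], fcalls[mask], mhap[mask],
                                  disp[mask], migrant[mask])

    # sample the two final consecutive cohorts
    labels = ("2010", "2011")
    parts = []
    for lab, year in zip(labels, (y_final2 - 1, y_final2)):
        pool = pools[year].concat()
        n_avail = len(pool["pos"])
        if n_avail < config.n_per_cohort:
            raise ExtinctionError(
                f"final cohort {lab} has only {n_avail} plants; "
                f"needs {config.n_per_cohort}")
        take = rng.choice(n_avail, size=config.n_per_cohort, replace=False)
        take.sort()
        parts.append((lab, {k: v[take] for k, v in pool.items()}))

    ids = [f"{lab}_{i + 1:03d}" for lab, part in parts
           for i in range(config.n_per_cohort)]
    cohorts = np.array([lab for lab, part in parts
                        for _ in range(config.n_per_cohort)], dtype=object)
    calls = np.concatenate([part["calls"] for _, part in parts])
    hap = np.concatenate([part["hap"] for _, part in parts])
    pos = np.concatenate([part["pos"] for _, part in parts])

    if config.missing_rate > 0:
        drop = rng.random(calls.shape[:2]) < config.missing_rate
        calls = np.where(drop[:, :, None], MISSING, calls)

    loci = [f"L{j + 1}" for j in range(L)]
    genotypes = GenotypeTable(ids=ids, cohorts=cohorts, loci=loci,
                              calls=calls, haplotypes=hap)
    frame = SpatialFrame(ids=list(ids), x=pos[:, 0], y=pos[:, 1],
                         plot_bounds=(0, lx, 0, ly))
    environment = env.table(list(ids), pos[:, 0], pos[:, 1])

    is_migrant = np.concatenate([part["is_migrant"] for _, part in parts])
    pedigree = {
        "mother_calls": np.concatenate([p["mother_calls"] for _, p in parts]),
        "father_calls": np.concatenate([p["father_calls"] for _, p in parts]),
        "mother_hap": np.concatenate([p["mother_hap"] for _, p in parts]),
        "displacement": np.concatenate([p["displacement"] for _, p in parts]),
        "is_migrant": is_migrant,
    }
    truth = dict(asdict(config))
    truth["realized_migrant_count"] = int(is_migrant.sum())
    truth["realized_migrant_fraction"] = float(is_migrant.mean())
    return SimOutput(genotypes=genotypes, frame=frame,
                     environment=environment, truth=truth, pedigree=pedigree)
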