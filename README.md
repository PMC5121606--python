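# finesgs

Fine-scale spatial genetic structure (SGS) analysis for georeferenced,
codominant genotypes — built for the situation where two consecutive
flowering cohorts of a (facultative) biennial plant are mapped on a single
plot and genotyped at nuclear microsatellites plus a maternally inherited
plastid marker, and the questions are: are the cohorts one gene pool, how
strong and how far does isolation by distance reach, is it directional, and
does the micro-environment leave a signature on the spatial distribution of
genotypes?

## What it computes

* **Diversity and cohort differentiation** — per-locus allelic richness,
  observed and unbiased expected heterozygosity, F_IS = 1 − H_O/H_E, a
  Monte-Carlo exact Hardy–Weinberg test; Weir–Cockerham θ (F_ST) between
  cohorts with a label-permutation test, and a distance-based AMOVA on
  individual-level chord distances.
* **Kinship** — pairwise Loiselle/Nason kinship coefficients F_ij,
  standardized to sample allele frequencies, for diploid SSRs or haploid
  plastid haplotypes, with per-locus components retained for jackknifing.
* **Isotropic SGS** — distograms of mean kinship per 0.5 m distance class
  (F_D) with permutation envelopes; the regression slope b_F of F_ij on
  ln(d_ij); the first-class mean F_1; and the SGS intensity

  `Sp = −b_F / (1 − F_1)`

  with jackknife-over-loci standard errors, permutation p-values, an
  optional density-driven iterative distance-range restriction, within- and
  between-cohort modes, and jackknife t-tests between cohorts.
* **Anisotropic SGS** — Rosenberg bearing correlograms: Mantel correlation
  of kinship with `ln(d)·cos²(α − θ)` over a grid of compass directions θ,
  giving the strongest/weakest SGS directions θ_s/θ_w, plus Sp re-estimated
  inside 30° sectors around them.
* **sPCA** — spatial principal component analysis of allele frequencies
  under an inverse-distance connection network, with permutation tests for
  global (cline/patch) and local (neighbour-contrast) structure.
* **Genotype–environment models** — spatially lagged simultaneous
  autoregressive (SAR) models `G = ρWG + Xβ + ε` of sPCA scores on light
  availability (DSF), soil-ion PCs and field capacity, with all-subsets AIC
  selection, Burnham–Anderson model averaging and relative importance w+,
  and residual Moran's I diagnostics.
* **A forward simulator** of two interleaved flowering lineages with known
  seed/pollen dispersal kernels, selfing, inter-annual migrants, optional
  dispersal anisotropy and environment-coupled establishment — the
  ground-truthed test bed for every estimator above.

## Worked example

Simulate two cohorts of 100 plants on a 20 × 20 m plot (0.3 m mean seed
dispersal, 15% inter-annual migrants) and measure their SGS:

```python
import numpy as np
from finesgs import (SimulationConfig, simulate, kinship_matrix,
                     pairwise_geometry, AnalysisConfig, sp_statistic,
                     fst_between_cohorts)

sim = simulate(SimulationConfig(rng_seed=1))
kin = kinship_matrix(sim.genotypes)
D, _ = pairwise_geometry(sim.frame)
cfg = AnalysisConfig(n_perm_distogram=999, rng_seed=1)

res = sp_statistic(kin, D, "within_2010", cfg)
print(f"b_F = {res.b_F:.4f} +/- {res.se_bF:.4f}")
print(f"F_1 = {res.F_1:.4f} +/- {res.se_F1:.4f}")
print(f"Sp  = {res.Sp:.4f} +/- {res.se_Sp:.4f}  (permutation p = {res.p_Sp:.3f})")
fst = fst_between_cohorts(sim.genotypes, n_perm=500,
                          rng=np.random.default_rng(1))
print(f"F_ST = {fst.fst:.5f} (p = {fst.fst_p:.3f})")
```

prints

```
b_F = -0.0107 +/- 0.0018
F_1 = 0.0401 +/- 0.0150
Sp  = 0.0112 +/- 0.0019  (permutation p = 0.002)
F_ST = 0.00100 (p = 0.094)
```

Read: kinship declines significantly with log distance (b_F ≈ −0.011), the
closest neighbours (< 0.5 m) are measurably related (F_1 ≈ 0.04), overall
SGS intensity Sp ≈ 0.011 indicates strongly restricted gene dispersal, and
the two flowering cohorts are not genetically differentiated (θ ≈ 0.001,
permutation p ≈ 0.09) — the regime a biennial with very limited seed
dispersal and abundant inter-annual migrants is expected to occupy.

The same pipeline runs from the shell:

```bash
finesgs simulate --seed 1 --out data/
finesgs sgs --genotypes data/genotypes.csv --coords data/coords.csv \
        --mode within_2010 --out sgs/
finesgs run --config pipeline.yaml         # all stages, one YAML
```

Genotypes are read/written as GENEPOP or tidy CSV (one `a1/a2` column per
locus); coordinates and environment as CSV; every stage emits TSV/JSON
artifacts plus a consolidated `report.json`/`report.md`.

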