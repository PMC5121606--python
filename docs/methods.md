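# Methods

This note documents the statistical models, estimators and simulator behind
`finesgs`, the numerical choices that were genuinely open, and what the test
suite does and does not demonstrate.

## Kinship

The pairwise kinship coefficient between individuals i and j at locus l is
the Loiselle/Nason estimator

    F_ij,l = Σ_a [ (p_ila − p_la)(p_jla − p_la) + p_la(1 − p_la)/(N_l − 1) ]
             / Σ_a p_la(1 − p_la)

with p_ila the within-individual allele frequency (0, ½, 1 for diploids;
0, 1 for the haploid plastid haplotype treated as a one-locus haploid
genotype), p_la the reference frequency from the scored sample, and N_l the
number of scored **gene copies** (2n for diploids, n for haploids). Using
gene copies rather than individuals in the bias correction makes the
estimator mean-zero over pairs of individuals drawn independently from the
reference frequencies — the property the permutation nulls rely on — and a
property test verifies it. Multilocus values combine loci as a ratio of
sums (numerators and denominators summed separately), and a locus
contributes to a pair only when both individuals are scored there
(per-locus pairwise deletion; roughly 3% missing data is typical for SSR
panels of this kind, and nothing is imputed in kinship estimation).
Reference frequencies are pooled over both cohorts by default, so within-
and between-cohort analyses share one kinship scale; a per-cohort scope is
available for strictly within-cohort work. Monomorphic loci are skipped
with a warning.

## Isotropic SGS

Distograms average F_ij in contiguous distance classes (default width
0.5 m). The Sp statistic is Sp = −b_F/(1 − F_1), where b_F is the
least-squares slope of F_ij on ln(d_ij) and F_1 the mean kinship in the
first class. Co-located pairs (d = 0) count toward F_1 but are excluded
from the log regression. If the user supplies an effective density D
(plants/m²), the regression range is restricted iteratively to
(σ̂, 20σ̂) with σ̂ = √(Nb/4πD) and Nb = (1 − F_1)/Sp, until σ̂ changes by
less than 1% (20 iterations; non-convergence reverts to the full range and
is flagged). Without a density the full range is used and labelled as such.

Standard errors come from delete-one-locus jackknifing,
SE = √(((L−1)/L)·Σ(θ₍₋l₎ − θ̄)²); the kinship matrix retains per-locus
numerator/denominator components so the delete-one statistics are rebuilt
exactly. Cohorts are compared by t = (θ_a − θ_b)/√(SE_a² + SE_b²) on
L − 1 degrees of freedom.

Significance of F_D per class and of Sp uses the same null: the
genotype-to-coordinate assignment is shuffled **within each cohort**
(9999 draws by default), which preserves each cohort's spatial point
pattern; between-cohort analyses shuffle within cohorts independently.
P-values are two-sided, computed as (1 + hits)/(1 + permutations) per tail
and doubled; a 10⁻¹² comparison slack keeps degenerate nulls (identical up
to floating-point summation order) from becoming coin flips.

## Anisotropic SGS

For a compass direction θ (degrees clockwise from the plot's +Y axis,
bearings reduced to [0°, 180°)), the transformed distance is
T_ij(θ) = ln(d_ij)·cos²(α_ij − θ). The bearing correlogram is the Pearson
(Mantel) correlation of F_ij with T_ij(θ) over 128 equidistant directions;
one set of 999 row/column permutations of the kinship matrix is reused
across all angles, so the p-value profile is a deterministic function of
data and seed and the θ_s/θ_w comparison is coherent. θ_s is the direction
of minimum r (strongest kinship-distance decay), θ_w the maximum; both are
reported at grid resolution (180/128 ≈ 1.4°). No multiple-testing
correction is applied across angles — per-angle significance is raw, and
users should read the profile, not single angles. Sector-restricted Sp
keeps pairs whose bearing lies within ±15° of a chosen direction on the
half-circle (so a sector around 170° includes bearings near 5°), then runs
the full Sp machinery, permutations included, on that pair set; a ±90°
half-width reproduces the isotropic analysis exactly.

Note on direction semantics: in the simulator, `anisotropy_axis` names the
axis along which seed displacement is **compressed**; kinship then decays
fastest for pairs oriented along that same axis, so θ_s is expected at the
compressed axis. The direction-recovery test therefore compresses X
(axis = 90°) to emulate a population whose strongest SGS lies along the
plot's X direction.

## Diversity and differentiation

H_E is Nei's unbiased expected heterozygosity (2n/(2n−1))(1 − Σp²);
F_IS = 1 − H_O/H_E, undefined (flagged, not raised) for monomorphic loci.
The Hardy–Weinberg test shuffles the 2n observed allele copies into random
diploid genotypes and compares genotype-count χ² values; a test verifies
the Monte-Carlo p against the closed-form pairing (Levene) distribution on
a biallelic toy. F_ST is Weir–Cockerham θ, combined over alleles and loci
as a ratio of summed variance components; its null permutes cohort labels,
one-sided for θ > 0 (500 permutations by default). The AMOVA works on
individual-pair chord distances over shared non-missing loci,
D_ij = √(2(1 − (1/L)Σ_l Σ_a √(p_ila·p_jla))), partitions Excoffier-style
sums of squared distances among/within cohorts, and reports σ²_among
clamped at zero with the raw value retained; an oracle test checks the
components against a Gower-centering trace computation.

## sPCA and structure tests

Allele columns hold within-individual frequencies (0, ½, 1); missing calls
are imputed with the column mean **only here** (kinship never imputes — a
deliberate asymmetry: sPCA needs a complete matrix, kinship supports
pairwise deletion); monomorphic columns are dropped. With W the
inverse-distance weights (co-located pairs get the weight of half the
smallest nonzero distance), W_s = (W + Wᵀ)/2 and S0 = ΣW_s, sPCA
eigen-decomposes (1/S0)·Xᵀ W_s X. This normalization makes each eigenvalue
exactly var(score) × Moran's I(score) — the self-consistency a test asserts
at 10⁻¹⁰ — and coincides with the (1/2n)Xᵀ(W+Wᵀ)X convention when W is
row-standardized. Positive eigenvalues flag global structure, negative
local structure; the spectrum is reported in full and component retention
is left to the user.

The global/local tests compute Moran eigenvectors (eigenvectors of the
double-centered W_s), score each allele column by squared correlation with
each eigenvector, split the spectrum at the null expectation
E[I] = −1/(n−1) (above: global; below: local), order by Moran's I, and take
max(t) over a width-3 sliding mean (width exposed; the split is what keeps
the two tests from being mirror images of one sequence). The null permutes
rows of X. Calibration tests confirm ≈5% rejection under spatially random
genotypes.

## Lagged SAR models

G = ρWG + Xβ + ε with row-standardized W and Gaussian ε. The likelihood is
profiled in ρ: given ρ, β̂ is OLS of (I − ρW)G on [1 X], σ̂² = RSS/n, and
the concentrated log-likelihood adds Σ log|1 − ρλ_i| over the eigenvalues
of W (complex pairs handled via the modulus, so asymmetric
nearest-neighbour weights are valid); ρ is maximized by bounded scalar
search (tolerance 10⁻⁸) inside (1/λ_min, 1/λ_max). β standard errors are
Wald, conditional on ρ̂; the ρ standard error comes from the numerical
curvature of the profile likelihood. AIC = −2ℓ + 2k with k = #β + 2 (ρ and
σ²). A zero W degenerates exactly to OLS.

All 2⁵ predictor subsets of {DSF, anions PC1, cations PC1/PC2, field
capacity} are fitted (intercept and ρ always present). Akaike weights are
computed over all 32 models; the ΔAIC < 2 set is retained and its weights
renormalized. The default averaging is the "full" Burnham–Anderson variant
(β = 0 substituted where a predictor is absent; unconditional
SE = Σw_m√(se_m² + (β_m − β̄)²)); conditional averaging is available. w+ is
the summed renormalized weight of selected models containing the predictor;
ρ's w+ is 1 by construction (structural parameter). Soil PCAs are on
correlation matrices with the sign anchored so the largest-|loading|
variable loads positively; all predictors are standardized to mean 0, SD 1.
sPCA scores enter unstandardized — ρ and w+ are scale-free, β is not.

A caveat established during development: with the **dense** row-standardized
1/d weights over a single 20 × 20 m plot, the leading eigenvector of W is
nearly constant and collinear with the intercept, so the profile likelihood
in ρ is almost flat and ML ρ̂ is unreliable (strongly biased toward zero in
simulation). The parameter-recovery test therefore uses a sparse
4-nearest-neighbour row-standardized W, where the same code recovers
ρ = 0.8 with |bias| < 0.05 and ≈94% Wald coverage for β. Fitted ρ values on
dense-W field data should be read as descriptive of autocorrelation
strength, not as precisely estimated parameters.

## The simulator

Two lineages model the odd/even flowering years of a biennial: plants
flowering in year t were recruited from matings in year t − 2 (same
lineage) or, with probability m (default 0.15), in year t − 1 — the single
rate m collapses every biological pathway for inter-annual migration
(dormancy, delayed or repeated flowering) into what the estimators can
actually see. Each year the flowering adults produce a pool of established
recruits: mother uniform among adults; father ∝ exp(−d/pollen mean
[2 m]) or selfing (rate 0.05); offspring displaced from the mother by an
exponential distance (mean 0.3 m — placing most mass in the 0–0.4 m range
reported for barochorous seed dispersal in this system) with uniform
direction, the component along `anisotropy_axis` divided by a ≥ 1;
reflective plot boundaries; plastid haplotype copied from the mother; no
mutation (tens of generations; SSR mutation would only add noise). With
environment coupling γ > 0, establishment is accepted with probability
exp(−γ·|g − e(x,y)|), where g is a score from one designated locus and e
the min-max-standardized DSF surface — coupling acts on establishment only
and through a single locus, so a genotype–environment association exists
without confounding every locus. After 20 burn-in lineage-generations the
final two cohorts are subsampled to 100 plants each and returned with full
truth (parameters, realized migrant count, pedigree).

The per-year established-recruit pool is 6 × the sampled cohort size. The
sampled flowering plants are survivors of a much larger seedling cohort,
and this factor is the one free demographic quantity; it was calibrated so
the generator reproduces the study condition of near-zero, non-significant
cohort F_ST at m = 0.15 (a 1.5× pool leaves the two-lineage drift–migration
equilibrium at θ ≈ 0.003, which a 200-individual permutation test reliably
detects), while preserving significantly positive short-distance kinship —
denser recruitment overlaps family clusters and dilutes F_1, so the factor
trades the two conditions off against each other.

Environment surfaces are deterministic given the seed: DSF is a linear
cline along X plus smoothed Gaussian noise (clipped to [0, 1]); the five
soil variables are independent smoothed-noise patchy surfaces sampled at
plant positions by bilinear interpolation of a 64×64 grid.

What the simulator does **not** emulate: age-structured seed banks, density
regulation beyond establishment filtering, SSR mutation and genotyping
error, gene flow from outside the plot, and any correlation structure among
soil variables. Tests passing on these simulations show the estimators
recover known truth under the stated mechanism; they do not certify
behaviour under demographic features the generator lacks.

## Problem sizes and runtime choices

The default test run uses reduced permutation counts (49–999 instead of
9999) and, for replicate-heavy checks, 10–200 replicates at 40–100
individuals per cohort — sizes at which every qualitative conclusion above
is stable across reseeding. Calibration checks use 199 (distogram) and 99
(sPCA) permutations so that the attainable p-values tile the 5% level
exactly. Permutation p-values never report zero ((1 + hits)/(1 + perms)).

## Known limitations

* Direction recovery from bearing correlograms is weak at realistic
  parameter values: with isotropic pollen flow contributing far more
  gene-dispersal variance than the compressed seed kernel, θ_s of a single
  realization is dominated by drift-generated directional structure, and
  the ±15° recovery rate at a = 3 is nearer 1–3/10 than the 7/10 a sharp
  detector would give. The averaged correlogram across many replicates does
  sit at the compressed axis; single-plot θ_s estimates should be read with
  their permutation p-values and compared across cohorts, as in the
  analyses this package supports.
* The HWE χ² statistic under Monte-Carlo shuffling is a pragmatic exact
  test; it is not the full Guo–Thompson Markov chain.
* GENEPOP cohort labels are positional (pop1, pop2, …); round-tripping
  named cohorts requires the CSV dialect.
* The iterative Sp distance-range restriction needs a user-supplied
  effective density; none is assumed.
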