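# Methods

## Relationship model

Honeybee queens are diploid, drones haploid.  A drone transmits his whole
genome, which is a single gamete of his mother; a queen mates once with a
set of D drones (the *sire group*) whose mothers are m drone-producing
queens (DPQs) heading colonies at an isolated mating station.  Individual
drones are unobservable, so the sire group is the paternal entity of the
pedigree.

Kinship φ(i, j) is the probability that two alleles, one sampled from each
individual, are identical by descent.  The package computes it by a single
dense tabular pass in topological order:

- founders (unknown parents) are unrelated and non-inbred, φ(i, i) = ½;
- queen i with dam d and sire group S: φ(i, x) = ½[φ(d, x) + φ(S, x)] for
  any earlier entity x; inbreeding F_i = φ(d, S); φ(i, i) = ½(1 + F_i);
- sire group S with DPQ mothers M₁..M_m: φ(S, x) = (1/m) Σ_k φ(M_k, x);
- the group's self-kinship is the co-kinship of two drones drawn at random
  from the group, φ(S, S) = 1/D + (1 − 1/D) · (1/m) Σ_k φ(M_k, S).
  The 1/D term is the probability the two draws are the *same* drone,
  which is what makes super-sisters (a = 0.75) more related than diploid
  full sisters; the remaining mass reduces to the DPQ-mother kinships with
  ½(1 + F) on the diagonal, so two distinct drones share a mother with
  probability 1/m.

Additive relationships are a_ij = 2 φ_ij with diagonal 1 + F.  Two sire
groups from the same station-year pool may share DPQ mothers but never a
drone (a drone mates once and dies), so the cross-group term has no 1/D
mass — this falls out of the generic group rule automatically.

Assumptions: drones are sampled uniformly and independently across the
group's DPQ mothers (sampling weights of real stations are unknown), and
unknown parents are unrelated non-inbred founders.  The computation is
O(n²) dense, adequate for the few hundred to few thousand individuals of a
breeding program; no sparse-inverse machinery is attempted.  Worker-group
and colony-level relationship extensions (breeding values expressed by
groups of workers) are out of scope: only queen-expressed, single-record
traits are modelled.

### Gene-dropping oracle

`gene_dropping` estimates the same matrix by direct simulation: founder
queens carry two unique alleles; each sire group is realised as D concrete
drones (each one random allele of a random DPQ mother); each daughter
receives a random maternal allele and the genome of a drone drawn
uniformly from her group.  Kinship is the IBD probability of one allele
from each individual, averaged exactly over the four allele pairings per
replicate.  The estimator is unbiased with at worst binomial noise, so
recursion and oracle must agree to Monte-Carlo error — the suite checks a
30-queen pedigree at 2×10⁵ replicates within 0.02 elementwise.

## Synthetic populations

`BreedingDesign` defaults encode the reference study: seasons 2017/2018
with 10 and 7 maternal lines, 7 and 11 queens per line (70 + 77 = 147
phenotyped queens; the per-line counts divide the published yearly totals
evenly, the split itself being unreported), 6 + 9 week-of-year harvest
classes, and one mating per line dam with D = 12 drones from that year's
DPQ pool (12 colonies by default, the low end of the reported 12–15).
Maternal lines share ancestresses through `shared_ancestor_depth`
generations of grand-dams (default 1, each ancestress heading about three
daughter lines, shared across seasons); ancestral matings use founder DPQ
pools of the same size.  All matings of a season draw from the same DPQ
pool, which relates lines paternally (a ≈ 1/(2m) between lines within
year) on top of the maternal sharing.

Phenotypes follow the fitted model exactly: y = μ + week + a + e with
breeding values matrix-normal (row covariance A over phenotyped queens,
column covariance G), iid residuals with covariance R, and one effect per
week class and trait.  Week effects are drawn with SD `week_effect_sd` ×
the trait's phenotypic SD (default 0.5 — seasonal harvest effects are
substantial; an absolute scalar would be meaningless across traits whose
units span four orders of magnitude) but are *estimated as fixed effects*
downstream, so their generating distribution is immaterial to the genetic
parameters.

Trait means, SDs and default heritabilities are the published 12-trait
values; G and R default to diagonal matrices from h²·σ²_p and
(1−h²)·σ²_p.  Spermatheca volume is not simulated: the recorded diameter
is the mean of three replicate measurements (replicate noise 0.02 mm by
default) and volume = (π/6)·d̄³, mm³ ≡ µl, exactly as in the laboratory
protocol.  This reproduces the near-unit diameter–volume phenotypic
correlation (analytic value 0.982 for Gaussian diameters at mean 1.32 mm,
SD 0.18 mm).  Sperm count is missing for 4/147 queens on average,
mirroring the unequal published trait counts.  Independent Bernoulli
defect flags default to the five observed prevalences (16%, 9%, 8%, 2.7%,
0.7%).

What the generator does *not* emulate: traits are Gaussian, so counts
(ovarioles, sperm) can in principle go negative and their realised CVs
drift in small samples; defects are independent of traits; week classes
are assigned uniformly within year rather than by breeding schedule; DPQ
pools are founders each year.  Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the stated
model, not robustness to non-Gaussian or confounded real data.

## REML estimation

Univariate: V = σ²ₐA + σ²ₑI over the phenotyped queens (one record each,
Z = I), X an intercept plus reference-coded week-class indicators (first
sorted level dropped; the restricted likelihood is invariant to this
choice, which the suite checks).  A is diagonalised once, A = UΛU′, making
each evaluation of

  ℓ_R = −½[log|V| + log|X′V⁻¹X| + y′Py + (n − p) log 2π]

O(n·p²), with analytic gradients from the standard REML score.
Optimisation is L-BFGS-B on log-variances with a floor of 10⁻⁸ × the
phenotypic variance (boundary flagged), at most 200 iterations, with a
derivative-free Nelder-Mead polish if the line search stalls.

Bivariate: 6 parameters via unconstrained Cholesky factors of G and R
(log-diagonals), started from the two univariate fits plus the sample
correlation.  With both traits complete the likelihood block-diagonalises
into n 2×2 problems in the eigenbasis of A; with missing records V is
assembled densely over the observed (queen, trait) cells — cell-level
deletion, no imputation.  Both paths are checked against brute-force dense
evaluations, and a block-diagonal (G, R) reproduces the sum of the two
univariate likelihoods exactly.

Standard errors: observed information by central finite differences of
ℓ_R with relative step 10⁻⁴ in the variance-scale parameters, inverted to
a parameter covariance; first-order delta method for h², r_g and r_p.  If
the information matrix is singular or has condition number above 10⁸ —
e.g. A = I, where σ²ₐ and σ²ₑ are not separately identifiable from single
records — the fit is flagged non-identifiable and SEs are reported as NaN
rather than numbers.  r_g is undefined (NaN, with reason) when either
genetic variance sits at the zero boundary, and clamped to [−1, 1] with a
flag otherwise.

## Reporting

Descriptives use the sample SD (n − 1) and CV% = 100·SD/mean; report
tables round CV% and defect percentages to 1 decimal and genetic
parameters to 2, with full precision preserved in JSON.  The full analysis
runs 12 univariate and 66 bivariate fits independently (no
multiple-testing adjustment), records every failure or boundary in a
per-cell status flag, and is byte-identical across reruns at the same
seed.  The reported phenotypic correlation is always the bivariate-fit
value, not the raw sample correlation; with no week-effect variance the
two agree closely, which the suite checks.

A note on the volume transform: one might expect the cubing of the
diameter to act as a fixed multiplicative factor on the variance
components, but a cubic transform has no such dimensionally coherent
constant effect; the package therefore documents the empirical behaviour
(near-unit r_p, volume heritability driven by the diameter's genetic
signal amplified through the nonlinearity) instead of asserting an
algebraic invariant.

## Problem sizes and runtime

Recovery studies use 100 replicates of n = 500 queens (25 lines × 20, 15
week classes, 12-drone matings from 12 DPQs) — large enough that the mean
estimate's Monte-Carlo SE is ≈ 0.01–0.015, comfortably inside the ±0.05
acceptance band, yet each 100-replicate setting completes in a few seconds
on one CPU.  Oracle-equivalence checks use 2×10⁵ gene-dropping replicates
on a 30-queen pedigree and 200-draw parametric bootstraps at n ≈ 200.

## Known limitations

- Dense O(n²)–O(n³) algebra throughout; thousands of individuals are fine,
  national evaluations are not the target.
- No BLUP breeding-value prediction, no genomic relationships, no
  maternal or permanent-environment effects, no >2-trait models.
- The week factor is the combined year-week class (15 levels in the
  default design); year is fully absorbed by it and is not fitted
  separately.
- Gaussian trait marginals; see the generator caveats above.
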