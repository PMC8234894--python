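# Methods

This note documents the models implemented in `ssgblup`, the choices made
where the method left room, and what the synthetic-data tests do and do
not demonstrate.

## Animal model and solvers

The core is the single-trait animal model y = Xb + Za + e with fixed
contemporary-group and parity effects and a random additive genetic
effect a ~ N(0, K σa²).  Fixed effects use an explicit intercept with
drop-first dummy coding; levels without records are dropped per dataset.
EBV contrasts are invariant to this estimability choice (checked by
test); absolute fixed-effect values are reported under that constraint.

Henderson's mixed-model equations are assembled sparse and solved by
LU factorisation (`scipy.sparse.linalg.splu`), with a conjugate-gradient
fallback (tol 1e−10, max 10⁴ iterations) and a residual check of
‖Cθ − r‖ ≤ 1e−8 ‖r‖.  Variance components enter only through
λ = σe²/σa²; they are either supplied or estimated by the Gibbs sampler.
No REML is provided.

## Pedigree algebra

* Topological sort: stable (generation depth, input order); unknown
  parents use the configurable token "0"; parents referenced but absent
  are auto-added as founders with a warning.  Founders are treated as
  unrelated and non-inbred; unknown-parent groups are not modelled.
* Inbreeding: Meuwissen–Luo-type recursion computing A_ii = Σ L²d without
  forming A (numba-compiled; linear memory, fast beyond 10⁴ animals).
* A and A22: tabular method restricted to the ancestor closure of the
  requested subset, so a small genotyped group in a large pedigree never
  triggers the full dense A.
* A⁻¹: Henderson's rules with inbreeding-corrected Mendelian-sampling
  variances d_i (1, 0.75 − F_p/4, or 0.5 − (F_s + F_d)/4), assembled as
  triplets (≤ 9 nonzeros per animal) into CSR with both triangles stored.

## Genomic relationships and H⁻¹

Genotype QC applies, in order: SNP call rate, MAF, a Hardy–Weinberg
filter removing SNPs whose observed heterozygote frequency deviates from
2p(1−p) by more than 0.15, then animal call rate; residual missing calls
are mean-imputed to 2p.  Default thresholds: call rates 0.90, MAF 0.05.
Allele frequencies are always the observed ("current") frequencies of the
supplied genotyped set; base-population frequencies are not estimated.

G follows VanRaden's first method with optional diagonal SNP weights.
Before entering H⁻¹, G is tuned (a + bG solving the 2×2 system matching
A22's mean diagonal and off-diagonal — the compatibility-of-bases
adjustment) and then blended, G_b = 0.95·G + 0.05·A22.  Tune-then-blend
is the default ordering; both steps are switchable.  G_b and A22 are
inverted by dense Cholesky — adequate for the few-thousand-genotyped
scale this package targets — and the correction block
(G_b⁻¹ − A22⁻¹) is added onto sparse A⁻¹ at the genotyped indices.

## Weighted ssGBLUP (nonlinearA)

Per iteration t: solve the single-step MME with G(D(t)) (D(1) = I, so
iteration 1 is exactly ssGBLUP — asserted to 1e−10); backsolve SNP
effects û = δ·D M′(M D M′)⁻¹ â from the genotyped animals' EBVs (δ = 1:
the genetic-base and 2Σp(1−p) scale constants cancel in the weights,
which depend on |û|/sd(û) only; sd is the population SD of û); apply
dᵢ = CT^(|ûᵢ|/sd(û) − 2); cap at `limit` (default CT³) and floor at
1/limit — the cap is read as a bound on the weight value, and the floor
mirrors it because a "maximum change in variance" bounds both
directions; renormalise to tr(D) = n_SNP.  Because a single
clip-and-rescale can push weights back over the cap, clipping and trace
renormalisation are alternated to their joint fixed point, so both
invariants hold simultaneously at every iteration.  G is fully rebuilt
(tune + blend + H⁻¹) each iteration; MDM′ receives a ridge of
1e−8·mean(diag) only if its Cholesky fails.  Iteration count is fixed
(`n_iter`), with an optional early stop when successive weight vectors
correlate above a threshold.

Variance explained is reported per window of 20 consecutive
non-overlapping SNPs (restarting at chromosome boundaries) as
Var(M_w û_w)/Var(M û) × 100 over the genotyped animals; windows can
overlap in contribution through LD, so the percentages need not sum
to 100.

## Gibbs variance components

Location parameters are updated by single-site sweeps of their full
conditionals over the MME coefficient matrix; in the multi-trait sampler
each effect level's T-vector is drawn jointly from its T-variate full
conditional.  The blocked update was chosen because scalar trait-by-trait
updates mix very slowly when genetic correlations are high (≈ 0.9), which
these traits exhibit; the stationary distribution is identical.  The
coefficient matrix is stored once as a sparse pattern with separate value
vectors for the data part (W′W) and the kernel part (A⁻¹ or H⁻¹), so each
draw only rescales values; sweeps are numba-compiled and consume
pre-drawn standard normals so that every random number comes from one
seeded NumPy generator (chains are bit-reproducible given the seed).

Priors: flat on fixed effects; σ² ~ scaled inverse chi-square with
ν = −2 and zero scale (flat on the variance).  The multi-trait covariance
prior is the exact analogue — inverse-Wishart with df = −(T+1) and zero
scale, i.e. |Σ|⁰.  A "minimally proper" inverse-Wishart
(df = T+1, scale → 0) was evaluated and rejected: its density
∝ |Σ|^−(T+1) concentrates on singular matrices and, at the few-hundred-
record scale, visibly dragged the smaller genetic variance toward zero
and the genetic correlation toward ±1 in exact-model recovery runs.
Records must be complete across traits (equal design); datasets with
missing trait values are rejected rather than imputed.

Chain defaults are desk-scale — 20,000 iterations, 2,000 burn-in,
thinning 10 — with a `GibbsConfig.reference()` preset of
200,000 / 5,000 / 100 retaining 1,950 draws.  Retention follows
floor((chain − burn-in)/thin).  Posterior summaries report means and 95%
highest-posterior-density intervals (shortest window over sorted draws);
heritabilities and correlations are computed per draw, then summarised.

## LR cross-validation

The partial dataset keeps records of animals born in or before the
cut-off year (truncation is by the phenotyped animal's birth year; record
dates are not modelled); the focal group is the genotyped animals born
after it.  Estimators (sample n−1 covariances throughout):
bias = mean(û_p) − mean(û_w), also divided by σa; dispersion
= cov(û_w, û_p)/var(û_p); acc = corr(û_w, û_p);
rel = cov(û_w, û_p)/((1 − F̄) σu²) with σu² the whole-data genetic
variance and F̄ the mean inbreeding of the focal group (a switch allows
the whole-population mean; the focal mean is the default because rel
targets the focal animals); inc = ρ_{A,G}⁻¹ − 1 and
inc_adj = (σA²/σG²)·inc from partial-data pedigree vs genomic EBVs.
Genetic trend is the per-birth-year mean EBV in genetic-SD units with its
OLS slope.

## Synthetic data

The generator emulates a small dual-purpose cattle population under
performance testing: discrete generations, founders' haplotype alleles
drawn Bernoulli(p) with p ~ Uniform over a configurable range, descent by
gene dropping with Haldane crossovers on a uniform map of 1 Morgan per
chromosome, QTL effects (a subset of the emitted SNP panel, so weighting
schemes can find them) drawn jointly across traits via the Cholesky
factor of the target genetic correlation matrix and rescaled so the
population TBV variance hits the target h² exactly (phenotypic variance
1); phenotypes add contemporary-group (birth-year cohort × random
subgroup) and parity effects plus correlated residuals.  Genotyping
fractions per cohort mimic recent-cohort genotyping; phenotyping can be
restricted to males of recent cohorts to mimic performance-tested bulls.
Truncation selection, when enabled, selects the top fraction of each sex
on the first trait's phenotype, with gene dropping interleaved
generation by generation so selection decisions and emitted genotypes
stay consistent.  Randomness is split into three seeded substreams
(structure / gene dropping / traits), making the composable operations
and the one-call bundle identical for the same configuration and the
output files byte-reproducible.

`rendena_like_dataset(seed, scale)` packages a scaled emulation of a
local-breed study design: at scale 0.25, seven ~300-animal cohorts
(~2,100 pedigree animals), males of the last three cohorts phenotyped
(~450), genotyping fractions (0.3, 0.5, 0.7) in the last three cohorts
(~450 genotyped), 29 chromosomes, three traits with h² targets
(0.335, 0.304, 0.392) and genetic correlations (0.364, 0.398, 0.981).
The SNP count (8,000·scale) is a desk-scale choice, not an emulation of
any particular chip.

What the simulator does **not** reproduce: realistic LD structure from a
coalescent founder population, mutation, non-uniform recombination maps,
overlapping generations, missing genotypes/parentage errors, and
imputation artifacts.  Passing calibration and recovery tests therefore
demonstrates internal consistency of the estimators under the stated
generative model, not performance on any real population.

## Calibration experiment (acceptance script)

`scripts/acceptance.py` runs 30 replicates (seeds derived from `--seed`)
of `lr_calibration_replicate`: five cohorts of 200 animals under random
mating, one trait with h² = 0.35 built from 100 QTL on a 300-SNP panel,
contemporary-group and parity effects included and fitted, PBLUP with the
true λ on whole data and on data truncated before the last cohort, LR
statistics on the 200 last-cohort animals.  Under this correctly
specified null, the across-replicate mean dispersion is expected to be 1
and the mean standardized bias 0; the script reports both.  Problem sizes
here (and the chain lengths in the recovery tests) were chosen so the
whole suite runs on one desktop CPU in minutes while leaving Monte-Carlo
error comfortably inside the stated expectations.

## Known limitations

Single-trait prediction only (multi-trait appears in variance estimation
only); no genetic groups/metafounders, no APY inverse, no dominance or
maternal effects, no repeated records; dense inversion of G limits the
genotyped set to a few thousand animals; the HWE filter implements the
heterozygote-deviation convention, not an exact test.
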