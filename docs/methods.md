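# Methods

## Model

The package studies a three-locus system: an unobserved biallelic causal
locus (QTL) `z` and two biallelic markers `x1`, `x2`, all expressed as
centered diploid allele counts. The trait is generated by a single-locus
additive model `y = z b + δ` (or its dominance/multi-locus extensions), and
an analyst fits the instrumental interaction regression
`y = intercept + x1 β1 + x2 β2 + x1x2 β12 + ε` by OLS and tests
H0: β12 = 0 with a two-sided Wald test.

The population coefficients are the solution of a 3×3 linear system whose
matrix `T` collects genotypic moments of the markers up to fourth order and
whose right-hand side collects the QTL–marker moments `E(zx1)`, `E(zx2)`,
`E(zx1x2)` scaled by `b`. `T` is the covariance matrix of the regressors
`(x1, x2, x1x2)` once an intercept absorbs the mean of the product term —
hence the `−E(x1x2)²` correction in its (3,3) entry — so the exact solve
and the intercept-including OLS estimate the same population quantities.
`β12` is additionally computed through the explicit third-row-of-`T⁻¹`
formula and the two routes are required to agree to 1e-10.

Key analytic facts the test suite pins down:

- **Necessary conditions.** β12 can be nonzero only when the three loci are
  in mutual but imperfect LD: the QTL in LD with at least one marker, the
  QTL not a linear function of the marker pair, and the haploid law not
  factorizable over any bipartition of the three loci. The condition
  checker evaluates all three from exact moments and the factorization test
  operates directly on the marginal haplotype tables.
- **Perfect LD ⇒ β12 = 0.** When `z = c1 x1 + c2 x2` almost surely, the
  right-hand side lies in the span of the first two columns of `T`, so a
  nonsingular solve returns β12 = 0 automatically; when `T` is itself
  singular the solver reports β12 = 0 with `degenerate=True` if the QTL's
  R² on the marker pair equals 1, and withholds all coefficients (NaN)
  otherwise. No silent pseudo-inverse is used.
- **Random-mating factor 2.** Because a diploid code is the sum of two
  independent haplotype indicators, every mixed central moment across loci
  involving one allele per locus doubles its haploid counterpart; this
  holds for pairwise `D` and for the three-locus `D` (cross-haplotype terms
  carry a vanishing first central moment). The law is asserted by
  64-diplotype enumeration over a sweep of distributions.
- **Dominance.** With `y = a z + d z² + δ`, the right-hand side becomes
  `a·(E(zx1), E(zx2), E(zx1x2)) + d·(E(z²x1), E(z²x2), E(z²x1x2))` with `z`
  centered and `z²` not re-centered (the intercept absorbs its mean). At
  QTL allele frequency exactly 1/2 the dominance right-hand side vanishes
  identically (the squared centered haploid indicator is constant), so
  dominance-driven phantom interaction requires an asymmetric QTL
  frequency.
- **Multiple QTLs.** The combined β12 is the third component of
  `T⁻¹ Σ_j b_j rhs_j`, exactly linear in each effect. In the three-pair
  geometry the term `b2 E(x1 x3 z2)` of the unaccounted middle QTL is the
  dominant driver.

## Haplotype distributions

`HaplotypeDistribution` stores the full table of 2^L haplotype frequencies;
all LD quantities are derived from it by enumeration, which is the
canonical computation (closed forms are used only as cross-checks in
tests). The 2- and 3-locus constructor uses the central-moment (Bennett)
parametrization: each haplotype frequency is the product of its marginals
plus signed corrections from the pairwise `D`s and the three-locus `D`.
Feasibility is enforced by explicit frequency reconstruction; an infeasible
combination raises an error naming the violated haplotype. Distributions
over more loci are built from explicit frequencies (e.g. the exact marginal
law of the Markov chromosome below).

## Synthetic data generator

- **Genotypes.** Diploids are formed by the union of two independent
  haplotypes (random mating / HWE; no inbreeding parameter). Analytic work
  centers codes at population means `2p`; data paths sample-center by
  default. Both conventions are exposed and recorded because the
  interaction test is insensitive to the choice at large n while main
  effects are not.
- **Chromosome emulator.** A first-order Markov chain over loci gives the
  adjacent haploid allele correlation `exp(−Δbp/λ)`; correlations between
  distant loci multiply along the chain, so pairwise R² decays
  exponentially with distance. The default decay length λ = 0.3 Mb puts R²
  near zero at 1–2 Mb, emulating the qualitative shape of short-range LD
  decay on a dense SNP array; it is a stand-in, not a model of human LD.
  Exact joint laws over any subset of loci are available by multiplying
  transition kernels, which is how experiments obtain analytic β12 values
  for chromosome-based scenarios. Requested adjacent correlations
  infeasible for a MAF pair are clamped to the feasible maximum with a
  warning.
- **Phenotypes.** The additive simulator scales the effect as
  `b = √(φ/Var z)` so the QTL explains a stated fraction φ of a unit total
  variance; residuals are Normal(0, 1−φ). The dominance simulator takes
  `(a, d, σ²)` directly and mean-centers `y`. The multi-locus simulator
  scales per-QTL effects the same way and adds an optional infinitesimal
  component: equal effects on the standardized scale over a set of
  background loci, scaled empirically to the requested variance share (or
  an independent Normal deviate when no background loci are supplied), with
  the residual topping total variance to 1. The variance budget must stay
  below 1.
- **What the generator does not emulate:** real human LD maps and their
  long-range irregularities, allele-frequency spectra, genotyping error or
  missingness, population structure and relatedness. Passing tests
  demonstrate the mechanism and calibration of the method on a known LD
  law; empirical rejection rates on real genotype panels depend on the
  actual LD structure and are expected to differ numerically (their
  qualitative behavior — hump-shaped distance profiles, growth with n and
  φ, limits at R² → 0 and R² → 1 — is what the experiment suite asserts).

## Statistical testing

OLS (via statsmodels) with an intercept, classical standard errors by
default (an HC0 robust option is exposed). The interaction regressor is the
product of the centered markers, not re-centered. The Wald statistic uses
the t reference with n−p degrees of freedom; at the sample sizes studied
(n ≥ 10,000) this coincides with the normal reference, which also covers
the non-Gaussian (three-component mixture) model errors that imperfect LD
induces — a property the suite checks empirically. Rank-deficient designs
raise a collinearity error naming the offending columns; experiments count
and exclude such replicates.

## Experiments

Every experiment is a pure function of its scenario, master seed included:
per-replicate streams are spawned from the master seed via
`numpy.random.SeedSequence`, so reruns are byte-identical. Rejection rates
are reported with binomial Monte Carlo standard errors `√(r(1−r)/m)`;
replicate-level tables carry marker R² and mean MAF so results can be
binned (by R², or MAF × R²; empty bins are missing, not zero). Results are
tidy TSV; plotting is left to the consumer.

Default problem sizes are chosen so each study resolves its effect at desk
scale: 500 replicates per cell for power curves (n up to 100,000), 2,000
replicates at n = 10,000 for null calibration, 300 replicates at
n = 250,000 for the three-pair geometry — the analytic solver predicts a
noncentrality of ≈1.2 there at 1% total genetic variance, so the expected
rate (≈0.2) is well separated from the 0.05 null at that replicate count.
The three-pair geometry uses MAF 0.3 throughout: at MAF 0.5 all haploid
third central moments vanish by symmetry and the phantom interaction is
exactly zero.

## Numerical choices

- Rank decisions use an SVD with relative tolerance 1e-10; the two β12
  routes must agree to 1e-10; analytic zero assertions use 1e-10.
- Haplotype feasibility tolerance 1e-12 (tiny negative frequencies from
  boundary parameter sets are clipped to zero after the feasibility check).
- Condition-check tolerance defaults to 1e-10 on exact moments and is a
  parameter, never hard-coded into comparisons.
- Empirical moments refuse uncentered input rather than silently centering,
  so the convention in use is always explicit.
- Master seeds are reduced modulo 2³¹ before use where external callers
  supply them.

## Known limitations

- The closed-form distribution constructor covers 2–3 loci; larger systems
  are built from explicit frequency tables or the Markov chromosome, which
  cannot represent arbitrary higher-order LD (it is first-order Markov by
  construction).
- Haploid LD cannot be recovered from unphased genotypes; empirical
  summaries expose only genotypic quantities.
- The experiment drivers test one pre-specified marker pair per replicate;
  genome-wide all-pairs scans and multiple-testing control are out of
  scope, as are mixed-model or score tests and non-random-mating
  (inbred/structured) populations.
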