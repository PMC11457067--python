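# Methods

`gxepred` implements a multi-site, multi-trait genomic prediction workflow
for perennial biomass crops evaluated as spaced plants across a latitudinal
transect of common gardens, together with a synthetic-data generator that
reproduces the statistical structure such a study assumes. This note records
the models, the numerical choices, and what the synthetic data do and do not
establish.

## Marker data and the relationship matrix

Markers are biallelic SNP dosages coded 0/1/2. The crop is a tetraploid with
disomic inheritance, so diploid coding is the appropriate dosage model; no
polysomic dosage classes are supported. QC retains markers with missing
fraction strictly below 20% and minor allele frequency strictly above 0.005
(both comparisons strict), and missing calls are imputed to the marker's
population mean. The kinship estimator is VanRaden's method 1,

    G = W W' / (2 Σ_m p_m (1 − p_m)),    W = X − 2p,

with observed allele frequencies, no shrinkage, and no internal MAF floor (QC
is a separate step). The centered crossproduct makes G exactly singular
(G·1 = 0), so downstream code that needs G⁻¹ adds a ridge of
`1e-6 · mean(diag(G))`; without it EM-REML is numerically non-monotone. If
the smallest eigenvalue of a computed G falls below −1e−8 the matrix is bent
by adding |λ_min| + 1e−6 to the diagonal and the adjustment is recorded on
the result.

## Phenotypes

Phenotypes are long-format records (genotype, site, year, trait, value) for
three traits: biomass on the square-root-gram scale (dead plants recorded as
0 and kept in all means), fall height in cm, and flowering time as day of
year in [1, 366]. Clone replicates are averaged into the genotype-site-year
cell first, then years are averaged over the available years — no imputation
of missing years. Yield-surrogate values per genotype are means of the
site-level surrogate over two designated central sites (defaults KBSM and
CLMB, the pair covering nearly all individuals), falling back to whichever
of the two a genotype has.

## AMMI

The two-way genotype (or subpopulation) × site biomass table is decomposed
as Y_ij = μ + g_i + l_j + Σ_k λ_k α_ik γ_jk + E_ij, with the multiplicative
terms obtained by SVD of the double-centered interaction matrix. "Variance
explained" fractions use the interaction sum of squares as the denominator
(λ_k² / Σ λ²), i.e. fractions of GxE, not of total variance. Unbalanced
tables are completed first by an additive-EM fill (missing cells iteratively
replaced by μ + g_i + l_j; observed cells untouched; fill mask reported).
The fill iterates to a squared-change tolerance of 1e−12 (up to 1000
iterations): EM's linear convergence means a looser tolerance can leave
fills ~1e−4 from the additive fixed point. SVD sign ambiguity is pinned by
flipping each component so the site score of largest magnitude is positive;
near-degenerate singular-value pairs (relative gap < 1e−6) are flagged. When
the interaction sum of squares is below 1e−12 the table is flagged
zero-interaction and all fractions are reported as 0.

## Multitrait GBLUP (REML)

The mixed model per trait t and record r is y_r = s_{site(r),t} +
g_{geno(r),t} + e_r with fixed site effects (cell-means coding per trait),
genotype effects vec(g) ~ MVN(0, Ta ⊗ G) with unstructured t×t genetic
covariance Ta, and independent residuals with per-trait variances (diagonal
residual covariance, following the i.i.d.-residual form of the model; an
unstructured residual would be identifiable only with strong replication).
Two optimizers maximize the same REML objective:

* **General unbalanced designs:** EM-REML on the mixed-model equations.
  Convergence is declared when the maximum relative parameter change falls
  below 1e−6, with the denominator floored at 1e−6 of the largest phenotypic
  variance so components collapsing to the zero boundary cannot stall the
  criterion; at most 1000 iterations. Aitken extrapolation is applied every
  fourth step with the multiplier capped at 100 and the extrapolated point
  accepted only if Ta stays positive definite and residual variances stay
  positive. The EM log-likelihood trace is retained and is non-decreasing.
* **Genotype-mean data** (single site, one complete record per genotype and
  trait): the exact REML likelihood factorizes in the eigenbasis of G into
  independent t×t Gaussian terms; it is maximized derivative-free
  (Nelder-Mead on a log-Cholesky parameterization of Ta and log residual
  variances), one restart from a perturbed point if the first run does not
  converge. Each evaluation costs O(n t³), so 500-genotype fits take
  seconds.

Both paths were cross-checked against an independent direct-V
profile-likelihood grid search (agreement to 1e−4) and against each other.
Genetic correlations are r_ab = Ta_ab/√(Ta_aa Ta_bb); traits with zero
genetic variance get missing correlations with a warning. Heritability is the
generalized (Cullis) form on a genotype-difference basis, H² = 1 −
v̄_Δ/(2σ_g²), with v̄_Δ the mean prediction-error variance of a BLUP
difference computed from the genotype block of the inverse mixed-model
coefficient matrix; the exact published variant of this statistic is not
fixed by convention, and this BLUP-difference form is the one implemented
throughout.

## Bayesian multisite model (Gibbs)

For prediction across sites, genotype-site biomass means (plus optional
surrogate columns) form an n×t response with sites as correlated traits:
y_i = μ_i·1 + g_i + e_i per column, vec(g) ~ MVN(0, Ta ⊗ G), independent
per-column residual variances, and per-column z-scoring before fitting
(predictive ability is correlation-based, hence scale-free). Priors are
weakly informative on the standardized scale: Ta ~ inverse-Wishart(ν = t+2,
S = 0.5·ν·I), residuals ~ scaled-inv-χ²(df = 5, scale = 0.5), flat
intercepts. The sampler works in the eigenbasis of G so the breeding-value
full conditional factorizes into n independent t×t solves per sweep; no
nt×nt matrix is ever formed.

Missing response cells are Gibbs-augmented: each sweep draws them from
N(μ_i + g_ji, σ²_i). This is the package's deliberate design choice: the
joint chain over (g, Ta, σ², y_miss) has the correct posterior for the
breeding values given the observed cells, and augmentation keeps every full
conditional in closed form where observed-cell-only conditioning would break
the eigenbasis factorization for partially observed rows. The trade-off is
slightly slower mixing when much of the matrix is missing; the retained-draw
schedule (default 3000 iterations, burn-in 200, thinning 5; the reference
analysis-scale chain of 25,000/200/5 giving 4,960 retained draws is
available via configuration) was adequate in calibration checks (split-R̂ on
the Ta diagonal ≈ 1, posterior Ta covering the generating values). The
sampler can pin Ta and the residual variances at known values, which is used
to verify that its posterior-mean breeding values match REML BLUPs (r >
0.99 on complete data).

Predictions for masked cells are posterior means μ_i + ḡ_ji on the
standardized scale; back-transformation through the stored per-column
mean/sd is available but unnecessary for correlation-based evaluation.

## Sparse-testing cross-validation

Validation populations are built per subpopulation from non-admixed
genotypes with biomass observed at six or more sites (">5 sites");
subpopulations with fewer than 60 eligible genotypes are dropped. Admixed
individuals remain in training data. Eligible genotypes are split into k
folds (default 8) of sizes differing by at most one, deterministically from
the seed and invariant to input order; with the default 5 replicates this is
40 model fits per subpopulation per scenario. Scenario masks hide validation
data from training: CV1 hides everything; CV2_k keeps biomass at k sites
sampled uniformly without replacement per genotype (re-randomized per
replicate; genotypes with fewer than k observed sites keep all of them); the
resource-limited scenarios FT/HT/FT_HT/B1/B1_FT/B5 operate on the
surrogate-augmented response (10 site columns + flowering + height) and keep
only the named cells. CV1 is evaluated on the surrogate-free response — it
is the zero-observed-sites point of the site-count curve.

Predictive ability is the Pearson correlation, per site, between predicted
and observed genotype-site means over validation genotypes whose training
data excluded that site; the observed breeding value is operationalized as
the 3-year genotype-site mean. Sites with fewer than 3 validation pairs are
skipped; zero-variance predictions yield a missing correlation, never 0.
Summaries average sites → folds → replicates, unweighted. Every run audits
leakage structurally: a scored cell must be masked and absent from the
training response, and the run aborts if any cell violates this.

## Synthetic data

The generator emulates the study conditions end to end: four subpopulations
(default sizes Texas 119, Coastal 147, Midwest 67, Gulf 51) under a
Balding-Nichols model with divergence F = 0.15 and ancestral frequencies
U(0.05, 0.95); ten sites with the transect's codes, regions and latitudes;
site-to-site genetic correlations exp(−0.12·|Δlat|) so that north-south
correlations are ≈ 0.13 and within-region ≈ 0.8; trait genetic correlations
to overall biomass merit of 0.85 (height) and 0.45 (flowering) and 0.31
between surrogates, built by a latent-factor construction that is positive
semidefinite by design; per-column heritabilities 0.6/0.7/0.8 for
biomass/height/flowering (the surrogates are deliberately more heritable, as
surrogate-based selection presumes); replication profile 53% of genotypes at
8-10 sites, 36% at ≤5, the rest at 6-7; three years of records per cell with
i.i.d. year noise; biomass truncated at zero; a latitude-aligned
subpopulation contrast (±2.5 √g per latitude SD, northern-adapted groups up
north) so subpopulation-level AMMI is non-trivial; and winterkill-style
zeros — genotypes whose total site value falls below −6 √g die with
probability 0.5 at that site. Where the emulated study fixes a value the
generator uses it; the remaining defaults (σ_g of 4 √g / 25 cm / 12 d, year
noise 1.5/8/5, contrast, death threshold) are single realistic choices and
are not tuned.

What the generator does **not** emulate: linkage disequilibrium (markers are
independent), pedigree structure, spatial field trends, site-year
interactions, and any real allele-frequency spectrum. Passing tests
therefore demonstrate correctness of the estimators and machinery under the
assumed generative model, not real-data performance.

One property worth noting: under these conditions a single height
measurement (genetically correlated 0.85 with overall merit and free of GxE)
is more informative about performance across the whole transect than a
single biomass site observation, which is mostly local because of the strong
latitudinal GxE. The scenario ordering on synthetic data is therefore
CV1 < FT < B1 < B5 with HT above B1 — the relative order of HT and B1
depends on how local the biomass information is and is close to a tie in
less GxE-dominated settings.

## Test and acceptance problem sizes

The test suite and `scripts/acceptance.py` run the pipeline at sizes chosen
for desk-scale reproducibility: the panel fixture (384 genotypes × 5000
markers × 10 sites), CV with 4 folds × 1 replicate and an 800/150/5 chain,
parameter-recovery at n = 500 over 10-20 seeds, and Gibbs calibration at
n = 400, t = 4, 3000 iterations over 10 replicates. The full analysis-scale
protocol (8 folds × 5 replicates, 25,000-iteration chains) is available
through function arguments and the CLI. Predictive abilities at the scaled
settings are lower than an analysis-scale run would give (shorter chains,
fewer folds, smaller training sets); orderings and shapes are stable.
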