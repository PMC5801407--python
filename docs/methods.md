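# Methods

This note records the statistical models, the defaults and why they are
what they are, the numerical choices, and what the synthetic data do and do
not establish.

## Data model and coding conventions

Genotypes are biallelic dosages in {0, 1, 2} with an explicit missing
sentinel. At load time the counted allele is re-oriented to the minor
allele; the original orientation is kept per marker (`flipped`) so effect
signs are reportable either way. Every analysis is orientation-invariant
except the sign of a reported effect and the "advantageous allele"
frequency, which are derived from the stored orientation.

Three codings appear, and they are not interchangeable:

* **M ∈ {−1, 0, 1}** (dosage − 1, missing → 0): single-marker regressors
  and distance computations. Setting missing to zero is the field's
  convention of imputing to the mean of the 1/0/−1 scale at the coding
  step, never at I/O time.
* **Z₂ = M − P**, with P's column j equal to 2(p_j − ½) and p_j the
  counted-allele frequency: the VanRaden relationship numerator. With no
  missingness each Z₂ column has mean exactly zero.
* **Z₃ ∈ {0, 1, 2}** (missing → 0): the Bayesian whole-genome regression.
  Uncentered by default; a centered mode exists. Centering changes only
  the intercept's meaning, not GEBV contrasts.

Marker QC drops markers with > 10% missing calls first, then markers with
MAF < 1% among the survivors. The sequential order makes the two dropped
counts disjoint, so they add up to the total removed.

Fold-specific relationship matrices reuse allele frequencies computed once
on the full analysis panel (one G serves all folds); `freqs=` arguments
allow fold-local frequencies for sensitivity analyses.

## REML / GBLUP

Model: y = Xb + u + e, u ~ N(0, G σ²g), e ~ N(0, I σ²e); X is an intercept
plus a single combined set/year factor (treatment coding, reference = first
level alphabetically) — with one record per line, year and set cannot be
separated, so one categorical factor is the only fixed effect besides the
mean. Aliased columns are dropped by pivoted QR (this matters in
leave-set-out training folds, where the set contrast collapses into the
intercept).

The restricted likelihood is profiled on the eigenbasis of G: one O(n³)
eigendecomposition, then a 1-D bounded Brent search on log γ, γ = σ²g/σ²e
(tolerance 1e-8), with a closed-form profile for σ²e and an explicit
boundary check at γ → 0 (σ²g is floored at zero there; h² reports 0).
A single random effect makes this exact; no AI-REML iterations are needed.
Standard errors of the variance components come from the numerically
differentiated curvature (observed information) of the restricted
likelihood at the optimum.

Genomic heritability on a single-record basis is
h² = d(G)σ²g/(d(G)σ²g + σ²e) with d(G) the average diagonal of the
all-marker G. For fully inbred material d(G) sits near 2, which is why σ²g
alone understates the genetic variance of line means.

Prediction of unphenotyped lines is the conditional-mean BLUP
u_test = σ²g G[test,train] V_train⁻¹ (y_train − X_train b̂), algebraically
identical to G[test,train] G[train,train]⁻¹ û_train but requiring no
inverse of a possibly singular G block (V = σ²g G + σ²e I is always
positive definite, so no ridge is ever needed on this route).

SNP-BLUP backsolving uses the matched-variance identity
â = (σ²g/denom) Z₂′ V⁻¹ (y − Xb̂) with denom = 2Σp(1−p); Z₂â reproduces
the GEBVs to machine precision, which the tests assert.

Cross-validation re-estimates variance components inside every training
fold by default (`refit_per_fold=False` reuses full-data components), and
corrects validation phenotypes with the training fold's fixed-effect
estimates (`correction="full"` covers the alternative). Training-fold
correction avoids any flow of validation phenotypes into the metric.

## GWAS

Each SNP is tested as a fixed effect in the GBLUP model whose polygenic
covariance is the LOCO G-matrix of the SNP's chromosome; unmapped SNPs are
corrected with the full-genome G (an unknown chromosome cannot be
excluded) and flagged. Null variance components are estimated once per
chromosome and reused for that chromosome's SNPs (the standard two-stage
approximation); an exact per-SNP REML refit is available and agrees with
the approximation to < 0.2 −log₁₀(p) for ≥ 95% of SNPs on test fixtures.

The test statistic is the Wald χ²₁ = (â/SE)². The inflation factor
λ_IF = median(χ²)/0.4549 rescales all statistics when λ_IF > 1; deflated
scans are left untouched. One operational finding worth recording: on
*family-structured* marker panels the per-SNP statistics are strongly
dependent (markers share family-block directions), so a single null scan's
λ_IF fluctuates far more than χ²-median asymptotics suggest; λ_IF ≈ 1 is a
property of structure-free nulls, and the calibration tests respect that
distinction.

Per-marker variance explained is 2p(1−p)â²/σ²g (clipped at 1 with a
warning); heterozygous calls contribute 0 to the ±1 regressor; two-locus
genotype-class tables exclude heterozygotes from the homozygous classes and
report them separately.

## Bayesian Power Lasso

Model: y = Xb + Z₃u + e with exponential-power priors on SNP effects and
flat priors on b, σ²e and the rate parameter λ. The prior density is used
in its normalized form

p(uᵢ | λ, β) = β λ^{1/β} / (2Γ(1/β)) · exp(−λ|uᵢ|^β),

so the rate parameter's full conditional is Gamma(m/β + 1, Σ|uᵢ|^β)
(reducing to Gamma(m+1, ·) at β = 1, the Bayesian-Lasso case). The
normalizer is not cosmetic: with the β-independent "λ/2" convention and a
flat prior on λ, the joint posterior is improper whenever
β < (m − n)/(m + 1) — the likelihood is flat along the null space of Z₃
while the marginal prior decays too slowly — and a sampler run under that
convention degenerates numerically (residual variance drifting to 10⁴⁰ in
our trials). Since genomic panels always have m ≫ n, the normalized
density is the only coherent choice for the sub-Lasso shapes this model
exists for. DIC itself is deviance-based and unaffected.

Sampler: Metropolis-within-Gibbs. Gaussian Gibbs for fixed effects, scaled
inverse-χ² for σ²e, Gamma for λ, and for each SNP effect a 50/50 random
mixture of (a) an adaptive random-walk proposal accepted on likelihood ×
prior, and (b) an independence proposal from the Gaussian
likelihood-conditional N(û_j, σ²e/z_j′z_j), whose likelihood factor cancels
so acceptance is the prior ratio alone. Both kernels are exact; the
mixture matters because a pure random walk can spiral into a λ → ∞ trap
(effects pinned near zero make Σ|u|^β collapse, which inflates λ, which
pins the effects harder), whereas the independence proposal keeps null
effects at their likelihood scale and stabilizes λ's conditional. Effects
are initialized at shrunken marginal regressions for the same reason.
Random-walk scales adapt toward ~40% acceptance during burn-in only, so
detailed balance holds over the retained samples. Chains are bitwise
reproducible from a seed.

DIC = D̄ + p_D with p_D = D̄ − D(θ̄), deviance −2 log N(y | Xb + Z₃u, σ²e I),
θ̄ the posterior means. Shape selection runs one chain per grid value
{0.2, 0.4, 0.6, 0.8, 1.0} with deterministic per-shape seeds; ties take the
smaller β. DIC's chain-to-chain Monte-Carlo noise is substantial (tens of
units on small fixtures), so the architecture-sensitivity tests assert
paired and averaged comparisons rather than single-chain selections, and do
so in the m ≫ n regime where the shapes genuinely differ.

Bayesian h² is reported two ways: var(Z₃ū)/var(y − Xb̄) (variance of GEBVs
over phenotypic variance) and additive/(additive + σ²e) (component ratio).
Chain defaults are a test profile (5,000 sweeps, 1,500 burn-in, thin 10);
`ChainConfig.paper_profile()` gives the long profile (100,000 / 30,000).
Convergence diagnostics are split-R̂ and an initial-positive-sequence ESS.

## Cross-validation designs

* **LOO** — maximal training size and relatedness.
* **LFO** — one validation unit per crossing parent (half-sib family);
  training excludes every line sharing a parent with any validation line.
  A line belongs to its mother's and father's units; the retained
  prediction comes from the mother's (deterministic rule; averaging is a
  flag). A full-sib (per-cross) unit definition is also implemented —
  the two readings genuinely differ, and on dense pedigrees the half-sib
  rule can legitimately leave a unit with no training lines, which is
  reported as an error naming the unit.
* **LSO** — one fold per breeding-cycle set.
* **k-fold** — seeded random partition into near-equal folds (sizes differ
  by ≤ 1); k = n reduces to LOO.

Metrics pool all folds' predictions (per-fold metrics are also emitted).
Folds with fewer than `min_train` (default 10) training lines are skipped
with a warning. If every fold sits at the zero-genetic-variance boundary
the pooled GEBVs are constant and the metrics are reported as NaN rather
than fabricated.

## Top-SNP panels

Selection: best 3 or 10 markers by single-marker significance (at most one
per chromosome, so linked markers tagging one QTL are not double-counted)
or by |posterior effect| from the Power Lasso (no chromosome constraint).
Re-estimation: keep the scan estimates, joint panel-only SNP-BLUP (common
variance by REML on K = WW′), or a panel-only Power-Lasso chain. Panel
prediction uses the coding the effects were estimated in (±1 for
scan/SNP-BLUP, 0/1/2 for the Lasso). Evaluation is a seeded 5-fold CV with
selection and estimation strictly inside each training fold; the fold
partition is shared across selector/re-estimation combinations so the
comparison grid is paired.

## Synthetic populations

The generator emulates a two-cycle line-breeding program: fully inbred
founders (allele frequencies Beta(½, ½), conditioned on polymorphism among
the sampled founders to mimic array ascertainment), biparental families
with the empirical family-size distribution (159 families, sizes 1–33, 635
lines), single-seed descent with five selfing generations (F6), whole
families assigned to two sets with balanced line counts, multinomial marker
assignment over 21 chromosomes plus an unmapped bin with the observed
density skew (D-genome sparse), uniform missingness (default 1%), and
additive traits y = μ + set + Σ w_j u_j + e where n_qtl markers carry
large effects totalling `qtl_var_share` of the additive variance and all
others small Gaussian effects, rescaled so realized var(TBV) = h² and
var(e) = 1 − h². Defaults: 3 QTL at 18.9% of additive variance, h² = 0.8,
set-effect SD 0.5.

Two modelling choices deserve comment. First, no within-chromosome linkage
is simulated: none of the analyses uses genetic distances, and independent
Mendelian sampling per locus is the simplest model supporting all of them;
LD enters only through family co-segregation. Second, pure selfing from
divergent inbred parents bounds expected F6 heterozygosity by
0.5⁵ × divergence ≈ 1.6% at best, below the ~2.5% arrays report for real
F6 material (outcrossing, seed admixture, scoring artifacts). The
generator therefore retains extra heterozygous calls at parent-divergent
loci — never elsewhere, so every call stays Mendelian-attainable — with the
retention rate solved from the realized divergence so the population mean
lands at the 2.5% target (`target_het=None` disables this).

What passing tests on these populations show: the estimators recover
parameters under their own assumptions (additive effects, no GxE, no
epistasis, missingness at random), the schemes rank as relatedness/
training-size theory predicts, and the implementations agree with
independent oracles. What they do not show: behavior under GxE,
selection, genotyping error beyond random missingness, or real LD decay —
the real-data headline numbers are not reproducible from simulation and
are exercised only when the original supplementary files are supplied
(tests/test_acceptance.py documents the expected location and formats).

## Problem sizes

The default test suite runs tiny (50 × 200) to medium (240 × 500)
populations, 20-replicate REML recovery at n = 400, a 2,200-marker null
scan, and six paired DIC-selection fixtures at 100 × 800; the full suite
completes in about two minutes. `scripts/acceptance.py` uses the complete
635-line, 159-family design with a 6,000-marker panel (scaled from 10,802;
per-line statistics such as heterozygosity and relationship structure are
marker-count-invariant) and a 2,000-marker subsample for the five-shape
DIC grid; one run takes about two minutes.

## Known limitations

* Single-trait, single-random-effect models only; no GxE covariances, no
  multi-environment structures, no pedigree A-matrix.
* The EMMAX-style scan reuses null variance components within a
  chromosome; p-values for markers with very large effects are slightly
  conservative relative to the exact refit (flag available).
* DIC is reported from a single chain per shape; its Monte-Carlo spread
  means shape selection between adjacent grid values is not always stable
  on small data.
* The LFO training-exclusion rule can empty a unit's training set on
  densely interconnected pedigrees; this is surfaced, not silently
  repaired.
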