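# Methods

This note documents the statistical models implemented in `triangulate`,
the conventions chosen where the field leaves room, and what the synthetic
benchmark does and does not demonstrate.

## Summary-statistic model and harmonization

Every record carries (variant, β, SE, z, p, EAF, N) with enforced internal
consistency: z = β/SE to 1e-6 relative, and p equal to the two-sided normal
tail of z up to the rounding of values printed at ~3 significant figures.
Missing z or p are recomputed; records lacking both β/SE are rejected — the
pipeline never imputes effect sizes. Below p ≈ 1e-290 the z↔p consistency
check is skipped and log-space tails (`p_from_z(..., log=True)`) are the
supported representation, since the linear-space p-value underflows doubles
near |z| ≈ 38.

Harmonization orients outcome records onto the exposure's effect allele:
swapped alleles flip the sign and EAF; strand complements are flipped and
re-matched; palindromic variants (A/T, C/G) are oriented by EAF only when
both frequencies fall outside [0.42, 0.58], and are dropped as ambiguous
otherwise. The band is the common two-sample-MR default; published
analyses rarely state their choice, so this is a declared convention, not
an inference. Harmonization is idempotent (property-tested).

Coordinates are 1-based; the cis window is transcription start ± 1 Mb.

## LD stabilization

The xWAS denominator `wᵀRw` requires a positive-definite LD matrix, but
sample correlation matrices from finite panels (or matrices assembled from
files) can be numerically singular. `stabilize_ld` shrinks toward the
identity, `(1−λ)R + λI`, taking the smallest λ from the fixed schedule
{0, 1e-4, 1e-3, 1e-2, 0.1} that raises the minimum eigenvalue to 1e-8, and
restores a unit diagonal. The schedule spans the shrinkage range used in
practice by weight-based association tools; the chosen λ is returned so
callers can log it.

## Cis heritability and weight training

Heritability uses the single-variance-component LMM
y ~ N(μ, σ²_g K + σ²_e I) with K = XXᵀ/m on per-SNP standardized
genotypes. The restricted likelihood is profiled over the total variance
and maximized over h² on a grid plus bounded refinement; the spectrum of K
comes from the thin SVD of X, so cost is O(nm²) and sample sizes of tens of
thousands are routine. The null h² = 0 lies on the boundary, so the LRT is
referred to the 0.5·χ²₀ + 0.5·χ²₁ mixture. Null simulations show the
nominal 5% level is held to within Monte-Carlo error.

Genes pass to weight training only below the gate p < 0.01. Four models are
fitted: `top1` (best marginal variant, its simple-regression coefficient),
`blup` (ridge with the LMM-equivalent penalty λ = m(1−ĥ²)/ĥ², ĥ² clamped
to [0.01, 0.99]), `lasso`, and `enet` (l1_ratio 0.5). The lasso/enet
penalties are chosen once on the full panel by their internal
cross-validation; all four models are then compared on one shared k-fold
split (k = 5) by pooled out-of-fold R², and the winner is refit on the full
panel. Re-tuning penalties inside every outer fold would be more orthodox
but costs ~10× and does not change model ranking at cis-locus
dimensionality; the shared split keeps the comparison fair across models.
A Bayesian sparse LMM is deliberately absent from the menu: the pipeline's
logic exercises the CV-selection step, not any particular fifth model, and
the MCMC machinery it needs is orthogonal to everything else here.

Weight variants absent from the outcome GWAS are dropped jointly from `w`
and `R` (with the used count recorded) — a convention, since weight-based
association tools do not document a single canonical behavior.

## Mendelian randomization

The Wald-ratio SE is first-order delta method, SE_out/|β_exp|, matching
the default of standard two-sample MR software; the second-order form
(adding β²_out·SE²_exp/β⁴_exp) is available behind a flag and agrees within
2% for strong instruments (|β_exp/SE_exp| > 10 with a modest outcome
signal). IVW weights the per-instrument ratios by their inverse variance.
The fixed/random choice is codified explicitly: multiplicative SE inflation
√max(1, Q/(k−1)) when Cochran's Q has p < 0.05 and k ≥ 4. Published
analyses typically say only "fixed- or random-effects"; this rule is the
package's declared convention.

Steiger directionality approximates each instrument's variance explained as
z²/(z² + n) per trait, sums over instruments, and compares the
Fisher-transformed correlation magnitudes with a two-sample z-test on the
two sample sizes (means across instruments when they differ). Exact ties
resolve conservatively to "not correct". Binary-trait r² refinements are
out of scope.

Clumping is greedy: lowest-p candidate becomes an index, partners with
r² above the threshold are removed, repeat. The retained set has pairwise
r² ≤ 0.001 ("remove when r² > 0.001" reading of the threshold). Ordering
is by (p, variant id), making the output invariant to input order.

## Colocalization

Wakefield log-ABF: `0.5·log(V/(V+w)) + z²w/(2(V+w))`, V = SE². Prior
effect SDs default to 0.15 (quantitative molecular trait) and 0.20
(log-odds outcome), the cited defaults of the standard implementation;
priors p1 = p2 = 1e-4, p12 = 1e-5. All hypothesis sums run in log space.
H3's sum over ordered pairs i ≠ j is evaluated on the full (i, j) log-grid
rather than via (Σ₁)(Σ₂) − Σ₁₂, because that algebraic shortcut cancels
catastrophically exactly when one shared variant dominates both traits —
the regime of interest. The O(n²) grid is negligible at locus scale
(hundreds to thousands of variants). Variants present in only one dataset
are dropped (intersection semantics); fewer than two shared variants is an
error. A p+MAF+n fallback ABF is provided for records lacking β/SE.

## Synthetic-data generator

Genotypes: per-SNP MAFs uniform on the configured range; two haplotypes per
individual from a latent Gaussian AR(1) copula (correlation ρ^|i−j|)
thresholded at the MAF quantile. Monomorphic columns in small panels get a
single planted heterozygote so correlation matrices exist. The exposure
panel doubles as the LD reference, as in real pipelines where the reference
is drawn from the QTL study's population.

The molecular trait is E = Σ bⱼXⱼ + ε with b Gaussian on the chosen causal
set and rescaled so the realized genetic variance is exactly the target
cis-h²; noise variance 1 − h². Exposure and outcome samples are disjoint
(two-sample design). Outcomes, all with unit residual noise:

- `mediation`: Y = γ·E_out + N(0,1), E_out the same generative law in the
  outcome sample. The Wald ratio at the causal variant estimates γ.
- `pleiotropy`: the exposure's causal variants act on Y directly with
  total outcome heritability γ²·cis-h² — commensurate with the outcome
  signal a mediated gene of the same γ would produce.
- `linkage`: as pleiotropy, but through a distinct variant with r² < 0.05
  to every exposure causal variant (rejection-sampled from realized LD).
- `null` / `qtl_only` / `outcome_only`: the corresponding signals removed.

Scenario defaults (200 SNPs, n = 10,000 per trait, cis-h² = 1%, γ = 1,
ρ = 0.9) describe the colocalization reference locus: a realistic,
strongly-powered single-signal cis region where each trait's causal variant
explains 1% of variance. Recovery experiments override the sizes they
state: MR recovery uses γ = 0.3, five causal variants at cis-h² = 5%, and
n = 50,000 with independent SNPs; type-I-error panels use 500 genes at
n = 800/5,000 with cis-h² = 0.3 so instruments and weights reliably exist
under a null outcome; the tiering benchmark uses γ = 0.5, cis-h² = 0.2,
n = 20,000 (three replicate 30-gene panels in the test suite).

What the generator does *not* emulate: binary outcomes analyzed on the
observed scale (a logistic/liability case-control mode is a non-goal here
because every implemented statistic operates on summary scales, where the
quantitative outcome is equivalent up to effect-size units), population
structure and relatedness, allele-frequency-dependent architecture,
strand/allele errors (harmonization is tested by construction instead),
and sample overlap between exposure and outcome studies. Passing tests
therefore demonstrate correctness of the statistical machinery and its
calibration under the stated generative model, not robustness to those
real-data pathologies.

## Tier logic

The taxonomy codifies how integrative studies argue: `tier1` = full chain
(xWAS ∧ MR ∧ Steiger ∧ coloc) at both molecular layers; `tier2` = full
chain at exactly one layer; `supportive` = significant xWAS or MR without a
complete chain (the typical "associated but not colocalized" pattern);
`none` otherwise. Blood protein evidence omits the colocalization
requirement, mirroring designs where colocalization is run only for eQTL
data. Single-instrument MR cannot separate mediation from single-variant
pleiotropy, so pleiotropic genes legitimately reach tier ≥ 2; the
benchmark reports this rather than asserting it away.

## Numerical/infrastructure choices

- Every run's randomness flows from one configured seed; child seeds come
  from a seeded generator and stay below 2³¹.
- All thresholds live in `config.py` (a test enforces that the distinctive
  literals appear nowhere else in the source tree), so a logged config
  fully determines a run.
- p-values are floored at the smallest subnormal double rather than zero;
  ordering across genes at extreme significance should use z or log-p.
- BH adjustment with an external denominator pads the p-vector with ones,
  which provably leaves the step-up values of the real entries unchanged.

## Known limitations

- The xWAS null calibration relies on the LD reference matching the GWAS
  population; the generator satisfies this by construction, real data may
  not.
- Steiger's z²/(z²+n) variance-explained approximation is for quantitative
  traits; for binary outcomes it is conservative in the common case of
  large outcome n.
- Colocalization assumes at most one causal variant per trait per locus;
  multi-signal loci require conditional or SuSiE-style extensions, which
  are out of scope.
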