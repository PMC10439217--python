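# Methods

`gsemkit` implements a two-stage genomic structural equation modelling
pipeline for GWAS summary statistics, together with a z-score-level
simulator that generates multi-trait summary statistics with known genetic
truth. This note records the models, the numerical choices, and what the
synthetic data do and do not establish.

## Stage 1 — multivariable LD score regression

For traits *i*, *k* and SNP *j* with LD score ℓ_j (normalized over M SNPs),
the estimator regresses z-score products on LD scores:

    E[z_ij z_kj] = √(N_i N_k) · σ_g(i,k) · ℓ_j / M + a_ik

The slope gives the genetic covariance σ_g(i,k) (SNP heritability when
i = k); the free intercept a_ik absorbs confounding on the diagonal and
sample overlap off it. All m(m+1)/2 pairwise regressions run on the common
SNP intersection, genome-ordered.

**Weights.** Two passes: the first pass is unweighted and provides fitted
mean functions μ; the second pass uses
w_j = 1 / [max(ℓ_j, 1) · (μ_i(j) μ_k(j) + μ_ik(j)²)]. The product term is
the large-sample variance of a product of correlated normals (for i = k it
reduces to 2μ², the variance of a scaled χ²); the max(ℓ, 1) term counters
over-counting of shared signal across SNPs in LD. Predicted means are
floored at 0.05 so early-pass estimates cannot produce negative or
exploding weights.

**Sampling covariance V.** A delete-one block jackknife over `n_blocks`
(default 200) contiguous blocks in genome order, shared across all pairs.
Leave-one-block-out estimates come from per-block normal-equation sums, so
the full jackknife is O(n) per pair. V is the covariance of the pseudovalue
vectors of the whole vech(S), which preserves the cross-element
dependencies that the stage-2 chi-square correction and sandwich standard
errors need. The half-vectorization order (row-major lower triangle,
diagonal included) is fixed package-wide and written into every S/V file.

**Liability conversion.** For a case/control trait with population
prevalence K and sample prevalence P, observed-scale estimates are
multiplied by

    c = K²(1−K)² / (φ(t)² · P(1−P)),   t = Φ⁻¹(1−K)

(√(c_i c_k) for covariances); V rows and columns are scaled by the same
pair factors. At K = P = 0.5 the factor is exactly π/2, which the tests use
as an analytic anchor. The regression itself uses raw per-SNP N for binary
traits, with the conversion applied afterwards; the effective sample size
4/(1/N_cases + 1/N_controls) is carried as metadata for the alternative
convention but does not enter the default regression.

**QC.** The munging step removes, in fixed order: non-SNP alleles
(anything outside single-character A/C/G/T), strand-ambiguous pairs
(A/T, C/G), INFO < 0.90, MAF < 0.01, and SNPs with
N < (90th percentile of N)/1.5. The fixed order makes the removal counts in
the harmonization report reproducible; the min-N rule is scale-free and
removes nothing for fixed-N cohorts. Allele alignment to the LD score
reference negates z for swapped orientations, complements strand flips, and
drops anything else; fewer than 200 overlapping SNPs is a hard error
because the regression would be meaningless.

## Stage 2 — DWLS factor models

A model is a loading pattern Λ, factor covariance pattern Ψ and diagonal
residual matrix Θ for the implied covariance Σ(θ) = ΛΨΛ′ + Θ. All factor
variances are fixed to 1, so free off-diagonal Ψ entries are directly the
genetic correlations between factors. Estimation minimizes

    F(θ) = (s − σ(θ))′ W (s − σ(θ)),   W = diag(V)⁻¹,  s = vech(S)

with S eigenvalue-smoothed to positive definite first if needed (clipping
at ε = 10⁻⁸·max diag; the maximum element change is logged as a warning on
the fit).

**Optimizer.** Levenberg–Marquardt on the weighted residuals with the
analytic Jacobian of σ(θ); starting values are 0.5·√(item variance) for
loadings, 0.5·item variance for residuals, 0 for factor covariances.
Convergence is declared only when the maximum gradient of F is below
10⁻⁸ relative to the weighted data norm s′Ws — the weights carry the
arbitrary scale of V, so an absolute gradient cutoff would be meaningless
across inputs. The flag is honest: non-convergence is reported, never
masked, and the model ladder continues past a non-converged model while
flagging it.

**Inference.** Parameter covariance is the sandwich
(Δ′WΔ)⁻¹ Δ′W V WΔ (Δ′WΔ)⁻¹ with Δ the Jacobian at the optimum, which
accounts for W being only the diagonal of V. The model chi-square is the
mean-scaled residual statistic

    χ² = df · (e′We) / tr(W A V A′),   A = I − Δ(Δ′WΔ)⁻¹Δ′W

whose scaling gives it expectation df under the model, so it is referred to
χ²_df. Exact corrected-statistic definitions differ between
implementations of this methodology; this variant was chosen for its
simple mean calibration (verified by the simulation tests: p-values are
approximately uniform under the truth) and is the one reported everywhere.
AIC = χ² + 2q with q the number of free parameters. CFI compares against an
independence model (free variances, all covariances fixed at 0) fitted with
the same machinery and is clipped to [0, 1]; if the independence χ² does
not exceed its df, CFI is undefined and reported as missing with a warning.
SRMR standardizes observed and implied matrices by the *observed* variances
and takes the root mean square over all m(m+1)/2 unique elements, so
diagonal misfit counts.

**Heywood cases.** Residual variances are unconstrained; negative estimates
produce a warning, not a bound, because bounding would silently change χ²
relative to the unconstrained estimator. Standardized loadings divide by
√|implied variance| and flag non-positive variances. Each factor is
oriented so its largest-magnitude loading is positive, a deterministic
tie-break.

## The model ladder

Eleven indicators: drinks per week, two AUDIT-C measures (alcohol use);
maximum habitual alcohol use, AUDIT-P, AUD and alcohol dependence
case/control (AUD block); four life-satisfaction items. The ladder fits a
one-factor satisfaction sanity model, then: A — one common factor over all
11; B — correlated alcohol (7) and satisfaction (4) factors; C — correlated
use (3), AUD (4) and satisfaction factors; D — bifactor with a common
alcohol factor over all 7 alcohol items plus mutually orthogonal unique-use
(3 items) and unique-AUD (3 items) group factors, the satisfaction factor
free to correlate with all three. Alcohol dependence stays off the unique
AUD factor in D: with only case/control signal and the smallest cohort it
destabilizes the group factor, and the resulting parameter counts
(q = 22/23/25/31, df = 44/43/41/35) are what the df arithmetic checks pin
down. Models pass or fail on CFI ≥ 0.9 and SRMR ≤ 0.08; the lowest-AIC
converged model among A–D is selected. The AUDIT total score (23andMe) is
handled by a separate 12-item screening model in which it cross-loads on
both the use and AUD factors; exclusion is recommended when a loading is
below |0.10| and non-significant at α = 0.05 (both thresholds
configurable; at threshold 0 nothing is ever excluded).

## Synthetic data

The generator works at the z-score level: for SNP j the trait vector is
multivariate normal with covariance C_j = ℓ_j·B + O, where
B = √(N N′) ∘ Σ_obs / M and O is the intercept matrix. This is the exact
generative inverse of the stage-1 regression — the module's core contract —
and is drawn with a single factorization (√ℓ_j·L_B u_j + L_O v_j), so no
per-SNP Cholesky is needed. Binary traits are generated on the observed
scale by dividing Σ_g entries analytically by the liability factors, making
the liability conversion exactly invertible in expectation. LD scores are
gamma-distributed (shape 1.2, mean 30), right-skewed like real genome-wide
LD score distributions.

The 11-trait study design uses a standardized bifactor truth: common
alcohol loadings 0.55–0.70, unique-use loadings 0.50–0.55, unique-AUD
loadings 0.45–0.50, satisfaction loadings 0.50–0.88, and factor
correlations −0.17 (satisfaction–common), 0.22 (satisfaction–unique use),
0 (satisfaction–unique AUD) — magnitudes consistent with the constraint
that all indicator loadings exceed |0.4| on their factors. SNP
heritabilities are 0.04–0.09 by trait class. Alcohol dependence
(K = 0.159, P ≈ 0.248) and AUD (K = 0.159, P ≈ 0.203) are binary. Overlap
intercepts: 0.35 among the four satisfaction items (one cohort, moderately
correlated phenotypes), 0.20 between the two same-cohort AUDIT subscales,
0.10 between drinks-per-week and each of those (partial cohort sharing).
True phenotypic correlations are not identifiable from the genetic design,
so these proxies are free configuration, chosen once.

**Desk scale.** Defaults are M = 20,000 SNPs and N = 20,000 per trait —
roughly 1/60 of a real analysis in both dimensions — chosen so a full
20-seed stage-1 recovery study runs in seconds while keeping per-element
jackknife SEs small enough (≈0.005 on the h² scale) that the factor
structure is decisively recoverable. Larger dimensions are plain function
arguments.

**What passing tests do not show.** Simulated SNPs are independent given
their LD scores, so the block jackknife is exactly valid here; on real data
residual LD correlation between blocks makes V slightly optimistic.
The simulator has no population stratification (intercepts deviate from 1
only through overlap), no annotation-stratified architecture, no
MAF-dependent effects, and no genotype-level sampling, so it validates the
estimator's moment structure and the pipeline's plumbing, not robustness to
those real-data violations.

## Known limitations

- The fixture generator `make_sv_fixture` draws noise from exactly the V it
  reports, which is what makes the stage-2 calibration test a clean check
  of the sandwich formula — it does not test V misspecification.
- The empirical reproduction check needs the study's supplementary stage-1
  matrices converted to the package's S/V format (`data/empirical_sv.tsv`);
  without that file it cannot run.
- One-step estimation with a free intercept only; constrained-intercept and
  partitioned variants are out of scope, as are ML estimation, multi-group
  models and SNP-level effects on factors.
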