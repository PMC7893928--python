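# Methods

## Scope and design

`lipidprs` reimplements a summary-statistics PRS study as a pipeline of
testable stages: simulate (or read) genotypes and GWAS summary statistics,
harmonize and QC, derive candidate weight sets by pruning-and-thresholding
(P+T) and by point-normal Bayesian shrinkage, select one candidate by pooled
validation correlation, and evaluate the winner against lipid levels and
clinical outcomes. Real individual-level cohort data cannot be
redistributed, so the package ships a generative model with known ground
truth instead; every statistical claim made by the tests is a claim about
recovery of planted truth or agreement with an independent oracle, not about
any real population.

## The synthetic-data generator

**Genotypes.** Variants live in LD blocks of `block_size` (default 20) laid
out 10 kb apart, 10 blocks per chromosome. Within a block, each haplotype is
a latent Gaussian AR(1) process with lag-one correlation `ld_decay`
(default 0.7), thresholded at $\Phi^{-1}(f_k)$ so the allele frequency is
$f_k \sim U(\text{maf\_range})$ (default 0.05–0.5) and genotype classes are
in Hardy-Weinberg proportions. Blocks are independent, so LD is exactly
blockwise and adjacent-pair $r^2$ increases monotonically in `ld_decay`.
This reproduces the two features the methods depend on — local correlation
and physical windows — but not real haplotype structure, allele-frequency
spectra, demography, or long-range LD.

**Architecture and traits.** A fraction `p_causal` of variants (default
0.01) receives $N(0, h^2/(M\,p_{\text{causal}}))$ effects, rescaled so the
genetic variance over a panel equals `h2` (default 0.5) exactly on the
unit-variance latent scale. The GWAS trait is this latent value plus
$N(0, 1-h^2)$ noise; summary statistics are per-variant simple regressions
(effect, SE, two-sided t-test p, N) on a fresh sample of `n_gwas`
individuals, so reference panel, GWAS, and all cohorts are non-overlapping
draws from one process — mirroring a design where the derivation biobank
and the validation/testing cohorts are disjoint.

**Cohorts.** Each cohort draws fresh genotypes and builds four ln-scale
lipid traits as $\mu_t + 0.2\,(g + \varepsilon_t + \text{covariates})$ with
the shared genetic value $g$ and independent per-trait noise; natural-scale
traits are exponentials. The ln-scale SD of 0.2 matches the order of real
lipid variability, which puts per-SD regression coefficients in the few-percent
range. Geometric means (TC 5.0, TG 1.4, HDL 1.35, LDL 2.9 mmol/l)
sit near adult reference values so the clinical dyslipidemia thresholds
(adult TC ≥ 5.2; TG ≥ 1.7 / 1.97; LDL ≥ 1.8 / 2.6; pediatric and adolescent
cutoffs analogous) yield realistic prevalences of roughly 30–45%. Covariates
(sex, age, BMI, blood pressure, diabetes duration, HbA1c, renal measures)
are independent draws with small configurable effects; the `pc1..pc4`
columns are exchangeable noise because the simulated population is
homogeneous — principal components computed from structured panels are
exercised separately in the QC module. Role-specific outcomes: longitudinal
cohorts get follow-up lipids with a tracking correlation (default 0.7)
between baseline and follow-up noise; cIMT cohorts get a log-normal
thickness with a small per-SD genetic slope; CHD cohorts get case status
from a logistic model in the standardized genetic value with a configured
log-odds per SD and target prevalence. Using one genetic value for all four
traits keeps the ground truth singular — a pipeline run targets one trait,
and the other columns exist to exercise labelling and multi-trait plumbing.

**What passing tests do not show.** Calibration and recovery under this
generator do not establish performance on real data: real LD is not
blockwise, real effect-size distributions are not point-normal, trait
heritabilities differ by lipid, covariates correlate with genotype through
population structure, and selection at desk scale (thousands of variants)
is far less noisy than at genome scale (millions).

## Derivation

**P+T.** Clumping follows the greedy convention: restrict to variants with
$p \le$ threshold, repeatedly index the smallest p (ties broken by
chromosome, then position, so output is invariant to row order), and remove
same-chromosome variants within 250 kb (inclusive) at $r^2 \ge$ cutoff.
Only variants that passed the p-threshold participate; since the score uses
index variants only, clumping sub-threshold variants would not change the
result. LD is the squared Pearson correlation of dosages with pairwise-complete
missingness handling. The grid is 9 p-thresholds × 3 $r^2$ cutoffs = 27
candidates.

**Shrinkage.** The point-normal model operates on standardized (per-SD)
effects with sampling variance $1/N$. Marginal effects are converted with
$\hat\beta_{\text{std}} = \hat\beta\sqrt{2f(1-f)}$ (unit-variance trait) and
converted back after shrinkage. Each Gibbs sweep residualizes a variant's
marginal effect against current sampled effects of neighbours within
`ld_radius` positions (default $\max(10, M/3000)$, windows never crossing
chromosomes), computes the posterior causal probability and conditional
mean/variance, samples, and accumulates the posterior mean; weights average
post-burn-in accumulations (defaults: 100 iterations, 10 burn-in, fixed
seed recorded in provenance). A chain whose weights exceed 10× the largest
marginal effect aborts as divergent. The heritability input defaults to the
aggregate estimator $\hat h^2 = M(\overline{\chi^2}-1)/(N\,\bar\ell)$ with
windowed LD scores $\ell_j$, clipped to [0.01, 0.99]. An optional
variant-ID allow-list restricts the shrinkage input (the HapMap3-style
restriction used in practice); it is configuration, not hardcoded.

## Selection and evaluation

Validation correlations are Pearson on ln-transformed traits (consistent
with every regression in the package; the natural scale would break
affine-invariance arguments used in the tests). Pooling uses Fisher-Z with
weights $n_i - 3$; selection flags the maximal pooled r, ties broken by
fewer variants then derivation order. Standardization and quintile cuts
(right-closed at the 20/40/60/80th percentiles) come from one designated
reference cohort — the largest — and are applied unchanged to every other
cohort.

Association models: OLS and maximum-likelihood logistic regression (Newton
IRLS, tolerance 1e-8 or tighter, hard failure on separation or
non-convergence), Wald p-values throughout, matching the β ± SE reporting
convention. An exactly-fitting linear model (zero residual variance) is
flagged and reports p = 1 when the coefficient is 0 and p = 0 otherwise.
Fixed-effects meta-analysis uses inverse-variance weights with Cochran's Q
on $k-1$ df. AUC is the Mann-Whitney estimator with ties counted ½. No
multiple-testing correction is applied anywhere; two-sided α = 0.05.

**DeLong comparisons.** `delta_auc` mirrors the standard three-model design
(clinical factors + PCs; PRS only; both) and compares models 3 and 1 with
DeLong's paired-components test. Note that DeLong applied to *nested fitted
models* is known to be severely conservative under the null (the added
predictor is estimated on the same data), so its null rejection rate is far
below nominal; the package's calibration tests therefore verify the DeLong
statistic on exogenous score pairs, where it is exact, and verify the
nested usage only for Δ ≈ 0 behaviour. A self-comparison returns Δ = 0,
p = 1 by convention.

## Quality control

Marker filters run in a fixed order so removal counts are reproducible:
call rate ≥ 95% → MAF ≥ 1% → call rate ≥ 99% for MAF in [1%, 5%] → exact
HWE p ≥ 1e-4 → optional imputation-quality r² cutoff (per-dataset
configuration; 0.7/0.5/0.3 are typical derivation/validation/testing
choices). The HWE test is the standard exact tail sum over heterozygote
counts conditional on allele counts, without mid-p. Sample QC removes call
rate < 95% and heterozygosity beyond ±3 SD (no published cutoff exists; ±3
SD is the common array-QC default). Harmonization matches variants by
chromosome:position (IDs drift between panels), removes strand-ambiguous
A/T and C/G pairs, flips signs for swapped alleles, resolves strand flips
by complementing, and is idempotent. HWE is tested in all samples, not
controls only.

## Numerical and testing choices

Acceptance-scale simulations use M = 2000, reference n = 500, GWAS
N = 20,000, cohorts of 500–2000 — sizes chosen so a replicate takes seconds
to tens of seconds on one CPU while keeping selection and calibration
behaviour asymptotic. Oracles are independent implementations: brute-force
greedy clumping, full HWE enumeration, normal-equations regression,
quadrature for the no-LD point-normal posterior, and a direct regularized
solve for the infinitesimal model. Gibbs equivalence tests compare means
over ≥10 seeded chains against 3× the across-seed Monte-Carlo SE, with
burn-in long enough that initialization bias is negligible relative to that
SE. The "planted architecture recovery" test declares success when the
selected candidate's configuration is within one grid step (same method,
adjacent p-threshold or ρ) of the candidate most correlated with the true
genetic value in a held-out cohort.

## Known limitations

- Biallelic SNPs only; no indels, multi-allelics, or chromosome X.
- No relatedness/IBD pruning, no sex checks, no imputation — imputation
  quality enters only as a per-variant annotation filter.
- The Gibbs sampler is the classic point-normal sampler; grid/auto variants
  with h² jointly sampled are out of scope.
- CHD is cross-sectional case-control, not time-to-event.
- The cIMT outcome is a single value per individual, not an average of
  repeated sonographic measurements.
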