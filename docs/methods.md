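# Methods

`pleionet` implements a multi-trait genetic-architecture analysis for
homozygous (inbred) association panels: multi-environment BLUP and
broad-sense heritability, single-trait association scans, cross-trait
LD-score regression, a moment-based multi-trait joint estimator, LD
clumping into QTL regions, an Inter-LD trait–QTL network with pleiotropy
hubs, and RT-qPCR co-expression statistics. This note records the models,
the defaults and why they are what they are, and what the synthetic panel
does and does not emulate.

## Phenotype model and heritability

One trait observed on *n* lines in *L* environments with *R* replicates is
modeled as

    y_ijr = mu + env_j + line_i + (line x env)_ij + e_ijr

with environment fixed and line and line-by-environment random. The
environment-fixed split is standard multi-environment-trial practice and
makes the heritability identifiable. Broad-sense heritability on a
line-mean basis is

    H2 = V_g / (V_g + V_ge/L + V_e/(R*L)).

Balanced data is decomposed by equating ANOVA mean squares to their
expectations (E[MS_line] = V_e + R·V_ge + L·R·V_g, etc.); unbalanced data —
the normal state after outlier removal — is fit by REML via
`statsmodels.MixedLM` with a per-line random intercept and a line×env
variance component. Negative ANOVA solutions are truncated at zero. BLUPs
are the grand mean plus the environment-adjusted line-mean deviation shrunk
by V_g / Var(line mean); their correlation with the true genotypic value
exceeds that of the raw line mean whenever V_ge + V_e > 0.

Outliers are removed per trait × environment with the 1.5×IQR fence rule
(type-7 quantiles). The rule is deliberately applied once: it is not
idempotent in general (removing a point reshapes the quartiles of tiny or
heavily tied samples), though on field-trial-like data a second pass
removes nothing.

Pearson trait–trait correlations are computed on BLUPs with
pairwise-complete observations. Note that BLUP correlations attenuate
toward zero by roughly the line-mean repeatability, so a genetic
correlation of 0.9 is recovered as ~0.9·H2.

## Association scan

The scan regresses BLUPs on SNP dosage plus structure covariates
(11 principal components by default) with two models:

* `ols` — covariates projected out once, then a fully vectorized per-SNP
  simple regression (exactly equal to per-SNP multiple regression with
  those covariates);
* `mlm` — an EMMAX-style single-variance-component mixed model: the
  VanRaden kinship matrix is spectrally decomposed once, the variance
  ratio REML-optimized under the null, and each SNP tested by GLS in the
  rotated, whitened basis.

Iterative pseudo-QTN scans in the FarmCPU style are intentionally not
implemented; the downstream stages need well-calibrated per-SNP summary
statistics (effect, SE, Z = beta/SE, p), which the PC-covariate OLS/MLM
scan provides. The genome-wide threshold is the constant p < 5.61e-6
(a multiple-testing-corrected constant; the effective-number-of-tests
derivation behind it is out of scope).

Per-SNP variance explained is reported as PVE = Var(dosage)·beta²/V_y ×100.
For {0,2}-coded inbreds Var(dosage) = 4p(1−p); this is the inbred-coding
form of the usual 2p(1−p)β² definition (which assumes HWE diploid dosage
variance and would halve the reported share here).

LD is composite r²: squared Pearson correlation of dosage vectors, the
appropriate measure for unphased homozygous lines. Decay curves average r²
in distance bins up to 600 kb; empty bins are reported missing, not zero.
The candidate-gene window is ±10 kb around significant SNPs by default,
with the LD-derived alternative (distance at which mean r² falls to half
its short-range maximum, linearly interpolated) available through
`ld_window_from_decay`.

## LD scores and cross-trait regression

The LD score of SNP i is l_i = Σ_j r²(i,j) over SNPs within 1 Mb on the
same chromosome, self included, with the small-sample correction
r²_adj = r² − (1−r²)/(n−2) applied to cross terms so an unlinked SNP's
score is unbiased for 1. The cross-trait regression models

    E[Z1_i Z2_i | l_i] = sqrt(N1 N2) rho_g / M * l_i + rho Ns / sqrt(N1 N2)

whose slope estimates the genetic covariance rho_g and whose intercept
absorbs phenotypic correlation among overlapping samples; the univariate
special case (Z² on l) estimates SNP heritability with intercept ≈ 1.
r_g = rho_g / sqrt(h2_1 h2_2), clipped at |1.05| with a warning.

Fitting is two-step weighted least squares: a first pass with 1/l_i
weights, a second adding the model-implied variance of the regressand
(e.g. (1 + N h2 l/M)² for chi²). At desk scale (thousands of SNPs, a few
hundred effective LD blocks) plain 1/l weights leave the slope noisy
enough that per-seed heritability estimates cross zero and the r_g ratio
degenerates; the heteroskedasticity weights are the standard remedy.
Standard errors come from a 20-block jackknife.

## The joint multi-trait estimator

Per-trait summary statistics are combined per SNP with the moment-based
estimator: with Omega the T×T per-SNP genetic covariance (standardized
effect scale), omega_t its t-th column, Sigma_j the per-SNP sampling
covariance, and x_t = omega_t/Omega_tt,

    W_jt = (Omega − omega_t omega_t'/Omega_tt + Sigma_j)^(−1)
    beta_t,j = x_t' W_jt beta_j / (x_t' W_jt x_t),  SE = (x_t' W_jt x_t)^(−1/2)

computed on the Z/sqrt(N) scale internally and mapped back to each input's
beta scale. The estimator reduces exactly to the single-trait input when
T = 1 or Omega is diagonal with disjoint samples, and to
inverse-variance-weighted meta-analysis (joint Z = (Z1+Z2)/sqrt(2)) for
perfectly correlated traits with equal diagonals and SEs. Its p-values are
model-based: they are calibrated when Omega reflects the data, which is
why Omega is estimated, never assumed.

`estimate_omega_sigma` builds Omega from the univariate LDSC slopes
(diagonal) and pairwise rho_g (off-diagonal), and the sampling-overlap
matrix from the cross-trait intercepts. Three guards keep the construction
sane at desk scale, where single-fit LDSC estimates are heavy-tailed:

* off-diagonals indistinguishable from zero (< 2 jackknife SEs) are set to
  zero — a spurious correlation destabilizes the joint weights far more
  than it informs them;
* a diagonal far below the method-of-moments bound
  (mean(chi²)−1)·M/(N·mean(l)) is replaced by it — an Omega diagonal near
  zero would make the estimator discard the trait's own evidence (the
  moment bound conflates confounding with heritability, so it is a guard,
  not the estimator);
* correlations implied by Omega are kept at |rho| ≤ 0.98 and overlap
  intercepts inside (−0.95, 0.95), since the estimator requires them to be
  valid correlations.

## Clumping, Inter-LD and hubs

Clumping is the greedy lead-SNP rule: repeatedly take the most significant
unassigned SNP below threshold as lead, assign every unassigned
significant SNP on its chromosome within 500 kb and with r² ≥ 0.2 to it;
p-ties break by (chrom, pos). Every significant SNP lands in exactly one
QTL; the region interval is the member span. The clump defaults are
deliberately permissive and configurable, and the LD-decay-derived window
is offered as the principled alternative.

Inter-LD between two QTL regions is

    Inter-LD = 1/2 ( LD(Q1,Q2)/PmaxLD(Q1) + LD(Q1,Q2)/PmaxLD(Q2) )

with LD(Q1,Q2) the mean r² over cross-region SNP pairs and PmaxLD(Qk) the
maximum pairwise r² within region k ("maximum average LD among any two
variants" read as the pairwise maximum; the alternative reading — the
maximum over variants of their mean r² to co-members — is available as
`pmax_mode="mean"`). A single-SNP region takes PmaxLD = 1 (self-LD) and
the edge is flagged. The trait–QTL network keeps QTL–QTL edges with
Inter-LD ≥ 0.4; a hub is a connected component of that subgraph with ≥ 2
QTLs, a central hub one whose members associate with ≥ 3 distinct traits,
and hubs are labeled hub-1, hub-2, … by decreasing size. The
component-based hub definition is the minimal one consistent with "central
hubs linked to three or more traits"; cross-chromosome pairs are evaluated
(configurable).

## Co-expression

Relative expression is 2^(−ddCt) with ddCt = (Ct_target − Ct_reference) −
dCt_calibrator. Gene-pair Pearson correlations across 12 tissues are
tested two-sided and corrected within stage by the Benjamini–Hochberg
step-up (the "FDR" of the reported table layout; the procedure is not
named there, BH is the standard choice). Correlations are computed on the
relative-expression scale; gene pairs are drawn from QTL pairs with
Inter-LD strictly above 0.8, ranked descending, 30 pairs by default.

## The synthetic panel

The generator emulates, at desk scale, the statistical structure a large
genotyped inbred panel presents to this analysis:

* **Genotypes** — dosages in {0,2} only (fully homozygous lines).
  Subpopulation allele frequencies follow a Balding–Nichols model
  (Beta(p(1−F)/F, (1−p)(1−F)/F) around a Uniform ancestral frequency) at a
  target Fst; lines are assigned balanced primary subpopulations with
  Dirichlet admixture (5% foreign mass by default, emulating an admixed
  multi-subgroup panel). LD is a Gaussian-copula block model: each line
  draws one latent factor per block and each SNP mixes it with independent
  noise (weight sqrt(within_block_corr), default latent correlation 0.85),
  giving strong within-block LD and near-zero across. Block sizes are
  stick-breaking-heterogeneous and each block occupies a compact physical
  segment (50–400 kb) separated by recombination gaps — the wide
  block-length spectrum matters: near-constant LD scores would make the
  LD-score regression ill-conditioned, and it is also how fast-decay
  inbred LD maps actually look. SNPs with realized MAF outside the
  requested range are resampled (20 rounds, then a warning).
* **Phenotypes** — causal effects act on the standardized genotype (equal
  expected variance per causal SNP regardless of MAF — the architecture
  LDSC and the joint estimator assume; dosage-scale draws couple per-SNP
  heritability to MAF and bias LDSC slopes). Shared regions draw
  correlated effects across their traits from a specified correlation
  matrix and can pin their share of the trait's genetic variance
  (`var_share`). Genetic values are normalized to variance 1 and V_ge, V_e
  scaled so expected H2 equals the target, with `gxe_fraction` splitting
  the non-genetic denominator. Planted effect sizes ("a SNP explaining x%
  of variance") are defined against the observation-level (plot) variance
  V_g + V_ge + V_e — the variance of what is measured in the field; on the
  BLUP scale the same effect explains a larger share because replication
  averages the noise.
* **Truth ledger** — every phenotype simulation records causal SNP ids and
  indices, effects (dosage and standardized scale), variance components,
  per-line genetic values and the realized genetic-correlation matrix;
  recovery tests consume it.
* **Annotation / expression** — non-overlapping gene intervals tiled with
  jitter; expression matrices are positive values (latent Gaussian around
  10, sd 1) with designated pairs at a target Pearson correlation.

Not emulated: realistic recombination maps or demographic history,
sequencing reads, genotyping error beyond missingness, dominance or
epistasis, multi-year trial structure, and selection. Passing recovery
tests therefore show the estimators are correct under the stated
generative assumptions, not that field data meets those assumptions.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: heritability
recovery at 500 lines × 3 environments × 2 replicates (20 seeds); null
calibration on 500 lines × 2,000 near-independent SNPs (20 seeds, pooled);
cross-trait LDSC recovery at 800 lines × 4,000 SNPs with an infinitesimal
shared architecture, r_g = 0.6, h² = 0.5 (20 seeds; the infinitesimal
architecture is the regime the regression is derived for — sparse causal
sets attenuate the slope through LD-score measurement error); joint-
estimator power at 1,000 lines split into two disjoint 500-line samples,
r_g = 0.9, 820 causal SNPs of which 20 carry half the genetic variance
(25 seeds; disjoint samples are the estimator's primary setting and make
the power comparison clean of overlap corrections); and end-to-end
central-hub recovery at 500 lines × 2,000 SNPs with one variant causal for
three traits at 5% of plot variance each, scanned with the mixed model
(25 seeds). These sizes keep every experiment to seconds-to-minutes while
leaving the recovery bands comfortably wider than the Monte-Carlo error of
the seed means.

## Known limitations

* The ANOVA/REML split handles the balanced/unbalanced distinction but not
  heteroskedastic environments or spatial field trends.
* LDSC quantities at a few thousand SNPs have large sampling error by
  big-data standards; the guards above stabilize Omega, and genuine
  per-fit estimates (CrossTraitFit) are reported unguarded with jackknife
  SEs.
* Qualitative traits (scored categories) are treated as numeric.
* The joint estimator assumes a homogeneous per-SNP effect covariance
  (no maxFDR-style diagnostics for sparse violations).
* Candidate-gene annotation is purely positional; no functional lookup.
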