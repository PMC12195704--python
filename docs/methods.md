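# Methods

This note records the statistical model the package implements, the
design decisions taken where conventions diverge, and what the
simulation-based tests do and do not establish.

## Data model and conventions

A summary-statistics record is one biallelic SNP's additive association
in one study: effect/other allele, effect-allele frequency, beta,
standard error, p-value, sample size. Betas are stored as given
(log-odds for binary traits, SD units for quantitative traits); the
scale is study metadata. Genomic coordinates are 1-based inclusive.
Indels and multi-allelic rows are rejected at parse time — every
estimator here assumes biallelic SNPs.

The 97.5% normal quantile is fixed at 1.959964 (not 1.96) so that
OR↔beta conversions are exact inverses; comparisons against printed
tables carry an explicit 5% relative tolerance, which absorbs the
3-decimal rounding of published CIs. Supplied p-values that disagree
with the two-sided normal recomputation from beta/se are a validator
flag, not an error: consortium files routinely disagree at low
precision.

## Instrument selection

Four criteria, strict inequalities throughout: MAF > 0.01; association
p < 5e-8; cis-window ±1 Mb around the gene body (replication ±100 kb),
measured from the nearer gene edge rather than the TSS (configurable);
LD clumping at r² < 0.001 within 10,000 kb; instrument strength
F = (beta/se)² > 10 (the single-variant approximation — the squared
z-score). Clumping is greedy by ascending p with ties broken by
(chrom, pos, variant id), the de-facto standard; variants absent from
the LD matrix are treated as independent with a logged warning —
conservative for survivorship, loud in the audit trail. Genes with zero
survivors are reported as "no instruments" rows, never errors.

## Harmonization

Outcome effects are aligned to the exposure's effect allele. Allele
labels resolve plain coding swaps and strand flips (A↔T, C↔G
complement); only the outcome beta's sign ever changes, never its
magnitude. Palindromic variants cannot be resolved by labels, so
orientation is inferred from allele frequency, and variants whose MAF
lies in the open band (0.42, 0.58) in *either* study are dropped — the
stricter of the possible readings, since the band is symmetric about
0.5 the effect-allele/minor-allele distinction is immaterial.
Non-ambiguous palindromes are frequency-aligned by default
(`drop_all_palindromic=True` discards them all). Variants present in
only one study are counted in the report but silently omitted from the
pairs.

## Estimators

* **Wald ratio** uses the first-order delta SE `se_out/|beta_exp|`;
  the second-order correction is negligible at F > 10 and the
  first-order form is the common default.
* **IVW** is weighted least squares through the origin with outcome
  weights only; the random-effects variant is multiplicative with the
  inflation floored at 1, the standard two-sample choice. It is exactly
  the precision-weighted mean of per-variant Wald ratios with weights
  `beta_exp²/se_out²` (asserted to 1e-10 in the tests). A single
  instrument delegates to the Wald ratio with a notice.
* **Cochran's Q** and **MR-Egger** are gated at K ≥ 2 and K ≥ 3;
  Egger output is annotated as unstable for sparse instrument sets.
  Egger orients all exposure betas non-negative first (estimators are
  invariant to per-instrument sign flips, a property the suite checks).
  The regression itself is statsmodels WLS; tests verify it against
  hand-rolled normal equations.
* **cML-MA**: for each k = 0..K−2 the profile likelihood treats the k
  instruments with the largest standardized residuals as invalid (their
  direct effects are free parameters, so they leave the likelihood) and
  re-estimates theta by IVW on the rest, iterating to a fixed point
  (tol 1e-8 on theta plus a stable invalid set, max 200 iterations).
  Because these coordinate updates can stall in local optima, each k is
  solved from several starts — the IVW estimate plus the 0/25/50/75/100
  percent quantiles of the per-variant ratios — keeping the converged
  solution with the smallest negative log-likelihood; at K = 5 this
  provably attains the exhaustive-enumeration optimum on the test
  fixture. BIC_k = 2·nll_k + k·ln(n), with n defaulting to the smaller
  of the two study sample sizes (the conservative choice; configurable).
  Averaging weights are softmax(−BIC/2) over converged k; the averaged
  variance adds the between-model spread Σ w_k (θ_k − θ̄)² to the
  within-model variances. Non-converged k values are flagged and
  excluded.
* **Directionality test**: per-instrument variance explained is
  r²_j = 2p(1−p)β̂², summed per study (for the binary outcome this is
  the observed-scale approximation; no liability-scale transform is
  attempted). The two sums are compared by a Fisher-z test on the
  implied correlations with 1/(n−3) variances — a Steiger-style
  comparison; `direction_ok` requires the exposure sum to strictly
  exceed the outcome sum, so identical inputs yield False with p = 1.

## Mediation

The indirect effect is the product of coefficients
(exposure→mediator × mediator→outcome), matching the ratio definition
of the proportion mediated (100·indirect/total, percent; undefined and
flagged when the total is zero). The bootstrap is parametric — normal
draws from each leg's sampling distribution, 1000 by default, seeded —
because only summary statistics exist; the CI is the 2.5/97.5
percentile of the products. Only the two legs entering the product are
perturbed: the CI is on the indirect effect, where the total does not
appear. A pathway is direction-consistent when sign(indirect) equals
sign(total) and both legs have p < 0.05; a failed directionality test
on either leg raises the reverse-causality flag. Mediation is run for
IVW and cML-MA side by side and legs are never mixed across methods.

## Synthetic data generator

Summary statistics are simulated directly on the (beta, se) scale — the
exact structure every estimator consumes — rather than from
individual-level genotypes; this keeps full calibration studies in
seconds. Per variant: MAF ~ Uniform(0.05, 0.5); true instrument effect
b_j ~ N(0.15, 0.05²), a strong cis-QTL scale chosen so instruments
clear genome-wide significance and F > 10 at consortium sample sizes
(defaults: exposure n = 31,684, outcome n = 24,589 — eQTL-consortium
and case-control-GWAS scale); sampling SEs follow
1/sqrt(2·maf·(1−maf)·n), which the suite verifies empirically to 5%.
Invalid instruments receive directional pleiotropy α_j ~ N(0.05, 0.02²)
by default — comparable in magnitude to the mediated path θ·E[b] = 0.03,
i.e. the hard, IVW-biasing case that motivates cML-MA; set the mean to
0 for balanced pleiotropy. Palindromic and coding-flipped variants are
planted in configurable fractions with between-study frequency noise
(SD 0.005), and the truth record lists every flag, including which
palindromes are frequency-ambiguous. LD is equicorrelated blocks with
one r² parameter — enough to exercise clumping, deliberately not a
population-genetic model. p-values come from the normal formula so the
consistency validator holds exactly.

The mediation generator wires a gene→protein→disease chain with
disjoint gene and protein instrument sets (defaults β_EM = 0.5,
β_MO = 0.04, direct = 0.18, i.e. total 0.2 and a true 10% mediated
proportion, the order of magnitude of interest in protein-mediation
screens).

What passing simulation tests do **not** show about real data: no
winner's curse, no sample overlap between studies, no realistic LD or
allele-frequency spectra, no liability-scale effects for the binary
outcome, and instrument effects far stronger and cleaner than a
marginal eQTL. Calibration statements (type-I ≈ 5%, CI coverage ≈ 95%)
are statements about this generative model.

## Problem sizes in the checks

The calibration studies use 1000 replicates at K = 50 instruments and
n = 20,000 per study; pleiotropy-robustness uses 200 replicates at
K = 30 with 30% invalid instruments; mediation recovery uses 200
replicates at n = 100,000 per leg with 1000 bootstrap draws; the
clumping oracle runs on a 12-variant, 3-block instance where exhaustive
reasoning is possible; the phenome scan uses 11,958 phenotypes. These
sizes make Monte-Carlo error small relative to the tolerance bands
([0.035, 0.065] for the rejection rate, [0.93, 0.97] for coverages)
while completing in seconds to a couple of minutes.

## Known limitations

No LD-proxy lookup, reference-panel LD computation, GWAS-VCF parsing or
liftover; no median/mode estimators or MR-PRESSO; no multi-allelic
reconciliation; no multiple-testing correction across the gene screen
(raw p-values are reported, by design); the PheWAS stage scans an
existing p-value table and does not compute the per-phenotype
associations themselves.
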