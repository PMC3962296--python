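# Methods

This note documents the statistical models and numerical conventions behind
`radpopgen`, the choices made where several defensible options existed, and
what the synthetic-data generators do and do not emulate.

## Data model and Genepop conventions

Genotypes are stored as reference-allele dosages (0/1/2, NaN for missing)
per individual x locus, with per-individual population labels and per-locus
metadata (RAD tag, 1-based position within the tag, optional linkage-group
and centimorgan placement). Genepop is the interchange format; both the
2-digit and 3-digit allele-code dialects are read.

Genepop does not define a reference allele. The reader takes the
*numerically smallest* allele code observed at a locus as the reference; a
locus where only one code is observed is oriented against the conventional
first allele code (001), so a locus fixed for code 002 reads as dosage 0.
This convention is deterministic, identical across the two dialects, and —
unlike "first code encountered in file order" — makes the writer and reader
exact inverses, including for loci whose first non-missing genotype is
homozygous for the non-reference allele. Half-missing genotypes (exactly
one zero allele code) are treated as fully missing with a logged warning,
since a diploid dosage cannot be formed from one allele. Genepop has no
population-label field; the writer stashes labels in the free-text title
line (`pops=...`) and the reader falls back to the first individual's name
per `POP` block for foreign files.

## SNP-validation cascade

Filters are pure functions `dataset -> (dataset, removed)`; the cascade
applies them in a configurable order and records an audit trail whose
replay reproduces the output exactly. The default order is: call rate
(keep when >= 0.80), tag position (remove >= 88 bp, the error-prone read
tail), one SNP per RAD tag (keep the highest overall theta; ties break to
the lowest tag position, then lexicographic locus ID, so results are
invariant under input permutation), per-population MAF (remove only when
below 0.05 in *every* population), the haploid paralog screen (remove when
heterozygous-call fraction > 0.10 — a haploid cannot be heterozygous at a
correctly segregating locus), Hardy-Weinberg exact tests (remove when
p < 0.05 in >= 3 populations), LD pruning (genotypic r² > 0.8 in >= 3
populations removes the lower-call-rate member), individual missingness
(remove when > 15% missing), and duplicate removal (identity-based
R > 0.9). All boundary readings are documented above and configurable; the
underlying prose rules ("more than 80%", "greater than 87 bp") are
boundary-ambiguous.

The Hardy-Weinberg test is the exact conditional test: given the allele
counts, every compatible heterozygote count is enumerated and the
probabilities of configurations no more likely than the observed one are
summed. Probabilities are computed in log space via `lgamma` and
renormalised; a relative tolerance of 1e-9 keeps exactly tied
configurations together under floating-point rounding. The test suite
verifies agreement with an exact rational-arithmetic oracle to 1e-12.

LD pruning uses the squared Pearson correlation of dosages over
pairwise-complete individuals (genotypic r²), not an EM haplotype r²:
phase is unobserved in this data, dosage correlation is deterministic and
oracle-testable, and at the 0.8 threshold the two statistics do not differ
materially.

The relatedness statistic is deliberately simple: R = 2·(mean IBS allele
sharing) − 1 = 1 − mean|d_i − d_j| over co-genotyped loci. It is an
identity statistic, not a likelihood-based relatedness estimate; its only
role is duplicate detection, where R > 0.9 essentially requires genotype
identity. With realistically many loci the chance of two unrelated
individuals exceeding 0.9 is negligible; with very few loci (tens) it is
not, which is why duplicate screening belongs after locus filtering only
when enough loci survive.

## Population structure

Per-locus Weir-Cockerham variance components (a: among populations, b:
among individuals within populations, c: within individuals) are computed
with the standard unequal-sample-size weights; multi-locus theta is the
ratio of sums Σa / Σ(a+b+c). Negative components and negative theta are
reported as computed — truncation would bias the ratio of sums. Loci with
data in fewer than two populations, or with mean sample size <= 1, are
excluded (NaN components).

The pairwise differentiation test permutes individuals between the two
populations and recomputes multi-locus theta; p-values use the add-one
estimator (1 + #{theta_perm >= theta_obs}) / (n_perm + 1), which cannot be
zero. This is an exchangeability test in the spirit of, but not a
replication of, the exact tests in the common desktop packages.

Hierarchical AMOVA treats each individual as two exchangeable allele
copies and performs a nested ANOVA (among groups / among populations
within groups / within populations) with unequal-cell-size coefficients,
locus by locus; components are summed over loci before forming
percentages. The within-individual (inbreeding) stratum is intentionally
omitted — the reported decomposition has exactly three strata. As a
consequence the AMOVA ratio agrees with Weir-Cockerham theta only in
expectation, not identically: theta uses observed heterozygosity to split
the within-population variance into individual strata, the AMOVA does not.

PCA centres each locus by mean dosage, imputes missing values with the
locus mean (neutral after centring), and applies no variance scaling.
Axis significance compares observed eigenvalues against PCAs of data with
every locus column permuted independently, which preserves allele
frequencies while destroying inter-locus and inter-individual structure.

The F_ST outlier utility flags loci above an empirical quantile of the
per-locus theta distribution (top floor(n·(1−q)) loci, ties broken by
locus ID). It is a descriptive screen, explicitly not a coalescent-null
outlier test: it makes no statement about neutrality and by construction
flags about (1−q) of loci on any dataset.

## Assignment

Baseline allele frequencies per population are posterior means under a
uniform Dirichlet prior: (x + 1/k)/(n + 1) with k = 2 alleles. An
individual's log-likelihood in a population sums Hardy-Weinberg genotype
probabilities over its non-missing loci; missing loci contribute nothing.
Leave-one-out evaluation subtracts the individual's two allele copies per
locus from its home population's counts before computing its home
likelihood, so no individual informs its own baseline (verified against
explicit dataset-minus-one recomputation to 1e-12). Assignment is the
likelihood argmax; exact ties are reported unassigned rather than broken
arbitrarily. No population priors are applied.

## LD effective population size

Pairwise association is the squared standardised Burrows composite
disequilibrium: Delta = cov(g_A, g_B)/2 with sample covariance (divisor
S−1) over the S individuals genotyped at both loci, standardised by the
product of binomial allele variances with maximum-likelihood frequencies
from the same individuals, capped at 1. Pairs are screened per pair:
S >= 2 and within-pair MAF >= 0.02 (computed on co-genotyped individuals,
for consistency with per-pair missingness). Pairs are weighted by S in the
mean; the effective sample size is the S-weighted harmonic mean of the S
values (which reduces to their arithmetic mean under these weights).

The sampling expectation subtracted from the mean r² must match the
statistic actually computed. For the statistic above it is, to leading
order, 1/(S−1); the full correction used is

    E(r²_sample) = 1/(S−1) + 1/S²        (S >= 30)

where the 1/S² coefficient was calibrated once on pure-sampling
simulations (independent binomial genotypes, i.e. infinite Ne) across
S = 30–200 and two allele-frequency regimes; the fit is stable at ~1.0
with standard errors of order 1e-4 on E itself. The widely used published
constants (1/S + 3.19/S²) were fitted to a differently standardised r²
and overstate this statistic's sampling expectation by ~1.4/S², which is
irrelevant for small Ne but makes estimates of Ne in the many-hundreds
inconsistent (the residual drift signal 1/(3Ne) is of the same order).
The drift-inversion constants are the published ones:

    Ne = (1/3 + sqrt(1/9 − 2.76 r²')) / (2 r²')      (S >= 30)

with r²' the drift residual; a non-positive residual or negative
square-root argument reports an infinite estimate (no resolvable drift
signal). For S < 30 the published small-sample branch is retained
verbatim; no analysis in this package operates there, and its expectation
and inversion constants were fitted jointly to the other statistic.

Physical linkage inflates r² between same-linkage-group pairs, biasing Ne
downward. With a linkage map, same-group pairs can be excluded
(`unlinked_only` mode); pairs involving unmapped loci are never treated as
same-group, and by default the analysis restricts to mapped loci when any
map information is present. Loci flagged as selection candidates can be
excluded by ID.

The parametric confidence interval treats n·r̄²/E[r²] as chi-square with
n = number of retained pairs. This is the standard parametric form and it
is materially anti-conservative: with L loci the n ≈ L²/2 pairs are far
from independent (the effective number of independent comparisons measured
under pure sampling at L = 200 is ~4,000, not 19,900), and the shared
pedigree adds further across-replicate variance. Measured coverage at
S = 50 with 200 loci is 25–55% rather than 95%. The interval is reported
because it is the conventional one; treat it as a lower bound on
uncertainty. Jackknife intervals, the usual remedy, are out of scope.

Census ratios divide the point estimate by mean yearly escapement (Ne/N)
and by escapement times generation length (Ne/NG), bracketing the
per-year and per-generation readings of a single-sample estimate from a
mixed-age spawning aggregation; ratios are reported at 2 decimals and are
undefined for infinite estimates.

## Sliding-window scan

Per-locus pairwise theta values of mapped SNPs are averaged in 5-cM
windows stepped by 1 cM, anchored at 0 cM on each linkage group, with
half-open membership so boundary loci are never double-counted. Windows
need >= 2 SNPs to be tested. The null for a window with n SNPs is the
distribution of means of n values resampled with replacement from the
pair's complete per-locus theta set (negative values included); 1000
bootstrap replicates are drawn, refined to 5000 exactly when the window
mean exceeds the 90% quantile, and a window is significant when its mean
strictly exceeds the 95% quantile at its final replicate count. Empirical
quantiles use the nearest-rank definition, so the scan is bit-reproducible
given a seed. Significant windows that overlap or touch merge into
regions; a cross-pair summary counts, per 1-cM bin, how many population
pairs have a significant region covering it.

Overlapping windows share loci, so window-level flags are positively
correlated and the realised exceedance rate on neutral data can sit
slightly above the nominal 5% (measured ~4–6%). Note that even a pair of
*identical* populations is flagged at about the nominal rate: the null is
calibrated to the pair's own theta distribution, so exceedances are
quantile noise, recognisable by their non-positive window means.

## Synthetic data

The generators are test scaffolding: the analyses they feed were designed
for real fish, and nothing below is a claim about any real dataset.

* **Island model.** Per locus, an ancestral frequency is drawn from
  Uniform(0.05, 0.5); a group frequency is drawn from the Balding-Nichols
  Beta with F = 0.05; a population frequency around the group's with
  F = 0.005; genotypes are Binomial(2, p). Defaults mirror the study
  conditions: five populations of 56/54/57/56/47 samples in three groups
  (three closely related populations, plus two isolated ones), ~2% missing
  genotypes, tag positions 1–87. These defaults reproduce an overall
  multi-locus theta of ~0.04 and an AMOVA decomposition of roughly
  5%/0.5%/94.5% across the three strata. The symmetric two-level hierarchy
  cannot simultaneously reproduce the full observed pairwise range
  (0.003–0.098): with one group-level F the most distant pairs sit near
  0.06. Crucially, frequencies are drawn independently per locus, so the
  model has no drift LD: LD-based Ne estimates on island data are
  correctly near-infinite.
* **Wright-Fisher.** A forward population of Ne diploids; each offspring
  draws two parents uniformly (selfing allowed) and receives recombinant
  gametes; recombination between adjacent mapped loci follows Haldane's
  map function c = (1 − exp(−2d/100))/2 of the cM gap, with free
  recombination across linkage groups; unmapped loci are fully unlinked.
  Initial haplotypes are in linkage equilibrium at frequencies
  Uniform(0.2, 0.8), so output LD is purely drift plus linkage; 30
  generations comfortably reach quasi-equilibrium LD for loosely linked
  loci. Default recovery conditions: S = 50 sampled without replacement,
  200 loci.
* **Artifacts.** Paralog-contaminated loci are built by summing two latent
  binomial loci and collapsing any mixed signal (1–3 of 4 allele copies)
  to a heterozygous call — diploid heterozygosity inflates and haploids
  read heterozygous with probability p1(1−p2) + p2(1−p1). Error SNPs are
  new low-MAF loci at tag positions 88–93. Duplicate individuals are
  genotype copies with independent missingness. A truth record of every
  injected defect supports sensitivity/specificity scoring.
* **Planted selection.** Loci inside a chosen map interval have their
  genotypes redrawn in the named populations from Balding-Nichols with an
  elevated F around the locus's current overall frequency, creating a
  contiguous divergent region of tunable strength for scan power tests.

What passing tests on these generators shows: the estimators recover the
parameters of their own generative models at the stated sample sizes, the
permutation and bootstrap procedures are calibrated under exchangeability,
and the filters detect the defect classes they were designed for. What it
does not show: robustness to genotyping-error structure correlated with
depth or batch, linked selection, admixture gradients, age-structured
sampling, or null-allele dropout — none of which the generators emulate.

## Problem sizes in tests

The test and acceptance suites run the full pipeline at reduced scale —
hundreds to a few thousand loci, 20 replicate seeds for stochastic
recovery checks — chosen so the whole suite completes in well under a
minute while keeping Monte-Carlo bands tight enough to be informative.
Tolerances on stochastic checks are derived from binomial/chi-square
sampling error at those sizes, not tuned to outcomes.
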