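# Methods

This note documents the statistical model, the defaults and why they are
set as they are, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Differential methylation model

Each CpG site carries, per sample, a pair (methylated reads, total
reads). Two groups are compared with a binomial logistic GLM on these
counts,

    logit(pi_j) = b0 + b1 * group_j (+ sum_f gamma_f * family_f),

fit by iteratively reweighted least squares to a deviance change below
1e-8 (at most 100 iterations). The group effect is tested by the
likelihood-ratio statistic (null deviance minus full deviance) against
chi-square with one degree of freedom. With two groups and no covariate
the group MLE saturates the pooled 2x2 table, so the LRT equals the
pooled G-statistic exactly; the test suite verifies this identity to
1e-6 on 1,000 random instances and cross-checks the covariate case
against an independent GLM implementation (statsmodels).

Complete separation (a group with pooled methylation 0 or 1) is handled
by capping the linear predictor at |eta| = 30, which makes the fit
finite and leaves the deviance within ~1e-11 of its supremum; such
sites are flagged. A family factor fully confounded with the group
(rank-deficient design) yields a flagged missing p-value rather than an
arbitrary number.

The family covariate is attached automatically whenever both compared
groups are experimental: the split-clutch design places siblings in
every treatment group, so clutch effects are estimable and must be
absorbed. Wild-vs-wild and wild-vs-control comparisons have no family
structure and are fit without it.

P-values are adjusted with Benjamini-Hochberg. The original analysis
chain used a sliding-linear-model q-value estimator whose pi0 step is
too loosely specified to re-implement faithfully; BH is the transparent,
standard choice and the adjuster argument accepts any callable so an
alternative estimator can be plugged in without API change. The
significance level 0.0125 (0.05 Bonferroni-corrected for the four
pairwise designs sharing groups) is applied to q, and a DMS additionally
requires a coverage-weighted group difference of at least 15 percentage
points, where the weighted group level is 100 * sum(methylated) /
sum(coverage) over the group's present samples.

The test models binomial sampling only — no overdispersion parameter —
matching the default of the tooling this pipeline mirrors. The simulator
deliberately generates *beta-binomially* overdispersed counts (see
below), so the pipeline's recovery numbers are measured under data
harsher than the test's assumptions.

## Filter chain

Applied in this order, each step only removes or rescales:

1. **Minimum coverage** (default 10 reads): cells below the threshold
   become absent; sites absent everywhere are dropped.
2. **High-coverage cap** (default 99.9th percentile, per sample,
   linear-interpolation definition): guards against PCR duplicates.
   The threshold is recomputed from the data it censors, so this step is
   inherently one-shot: re-applying it to its own output lowers the
   empirical percentile and removes a few more cells. It is applied
   exactly once, as in the original protocol.
3. **SNP correction**: bisulfite conversion reads unmethylated C as T,
   so a C>T SNP at the C (or G>A at the paired G at pos+1) mimics
   unmethylation; such CpGs are removed outright. A variant qualifies
   when its mean genotype quality is >= 20 and its sample minor-allele
   frequency is >= 0.005, computed from the wild reference cohort.
4. **Coverage normalisation**: per-sample scaling to the median of
   per-sample median coverages (max available via config), with
   half-away-from-zero rounding — deterministic and order-independent —
   then clamping so 0 <= methylated <= coverage and coverage >= 1 for
   present cells. Methylation fractions are preserved to within one
   read. Like the cap, exact idempotence holds only at the fixed point
   (equal medians); re-running moves counts within rounding.
5. **Presence filter**: a site must be observed in >= 9 individuals of
   *every* group entering the analysis.
6. **Sex-chromosome removal** (label `chr19` by default): sex-specific
   methylation would otherwise leak into group differences.

A laboratory-artifact **blacklist** — the DMS of the wild-reference vs
experimental-control comparison, where no biological difference is
expected — is subtracted from the wild DMS set to form the final
pop-DMS.

## Channel classification

For each pop-DMS, the control-vs-within and control-vs-trans comparisons
yield (q, diff) pairs. The site is **inducible** if at least one
comparison is a full DMS (q < 0.0125 and |diff| >= 15), **stable** if
neither comparison is significant, and **inconclusive** otherwise
(significant somewhere, threshold reached nowhere). Precedence is
inducible > inconclusive > stable, following the "at least one
acclimation group" definition; the three categories partition the
pop-DMS by construction.

Direction matching compares the sign of each inducing comparison's
difference to the sign of the wild difference (target population minus
reference). If both comparisons induce and disagree, the
transgenerational comparison decides and the conflict is flagged — the
two-generation response is the one hypothesised to approach the wild
state.

delta.meth.diff = 100 - (meth.diff.wild - meth.diff.exp) is computed
after orienting each site so the wild difference is non-negative (both
signs flipped when negative, orientation recorded per site). Without
orientation the formula would reward overshooting in one sign direction
and punish it in the other. The methylation direction (hypo/hyper) used
in the ANOVA is the sign of the oriented induced change, taken from the
transgenerational comparison when it induces, else the within one.

The ANOVA delta.meth.diff ~ direction x acclimation is ordinary least
squares with Type-II sums of squares, robust to the unbalanced cell
counts these data produce; an empty cell downgrades the model to main
effects with the interaction flagged inestimable.

The enrichment randomization classifies *every* tested CpG with the same
rules, draws `n_enrich_reps` (default 1000) random site sets the size of
the pop-DMS set without replacement, averages the category counts into
expected values, and compares the observed counts by chi-square with
df = 2. Drawing without replacement from a finite universe makes the
statistic slightly conservative when the set size approaches the
universe; at the default sizes the null p is approximately uniform
(verified in the suite at a 200-of-3,300 draw).

## Windowed FST and delta.mean.FST

Per-SNP differentiation is the two-population Weir-Cockerham
theta-hat = a / (a + b + c) from the among-population, among-individual
and within-individual variance components (sample sizes, alt-allele
frequencies, observed heterozygosities). Negative estimates are
retained; a site monomorphic overall is undefined (NaN). The test suite
checks the implementation against an independently coded brute-force
ANOVA oracle (sums of squares over expanded allele copies) to 1e-10.

The windowed statistic is the arithmetic mean of retained per-SNP
estimates within +/-5 kb of a focal CpG, after masking genotypes with
depth < 5 and discarding SNPs with more than 60% missing genotypes
jointly across both populations (the convention of the variant tools
this mirrors). The arithmetic mean of per-site ratios is known to be
biased downward relative to the parameter; it is kept as the primary
per-window statistic for fidelity with that convention, while the
ratio-of-sums estimator sum(a)/sum(a+b+c) — the Weir-Cockerham
prescription for combining loci, and the estimator that actually
recovers a simulated F (0.10 -> ~0.10, versus ~0.078 for the mean of
ratios at n = 16 per population) — is computed alongside and used for
F-recovery checks.

delta.mean.FST = mean(expected-site windows) - mean(opposite-site
windows), tested one-tailed (H1: opposite sites more differentiated,
delta < 0) by randomly reassigning the pooled window means to the two
group sizes (default 10,000 permutations without replacement; a
with-replacement bootstrap mode exists behind a config flag).
p = #(delta* < delta_obs) / n_boot exactly as defined, which can return
0; the (count+1)/(n_boot+1) correction is available via config and off
by default.

## Gene annotation and the per-gene exact test

Features are assigned with precedence promoter > exon > intron >
intergenic across all overlapping genes; the promoter is 1,500 bp
upstream to 500 bp downstream of the TSS, strand-aware, 1-based
inclusive. The nearest TSS is chosen by absolute distance with ties
broken toward the lexicographically smallest gene id, making annotation
independent of gene input order. A site is associated with a gene when
it lies inside the gene or within 10 kb of the TSS (boundary inclusive);
sites on unplaced scaffolds (chrUn*) are never gene-associated. Feature
randomness of the pop-DMS is a chi-square goodness-of-fit against the
feature proportions of all tested CpGs (df = 3; empty background
categories are dropped with df reduced).

The per-gene correlated-response test builds, for each gene with >= 2
associated pop-DMS, the 2x3 table of that gene's
inducible/stable/inconclusive counts against those of all remaining
pop-DMS of the contrast, and computes the two-sided Fisher exact p by
exhaustive enumeration of tables with the observed margins, summing
probabilities not exceeding the observed table's (ties within 1e-12).
Margin spaces above 10^7 tables fall back to seeded Monte-Carlo
sampling, flagged in the log. The gene-vs-rest construction is the most
direct reading of the hypothesis; published per-gene p-values from the
original study are not comparable targets because that study's exact
table construction is not recoverable.

## Synthetic data generator

The generator is the package's test bed and defines the study
conditions; all draws are pure functions of (parameters, seed).

* **Design**: three wild populations — reference KIE20 (n = 16) and
  targets NYN6, SYL33 (n = 15 each) — and five experimental groups bred
  from the reference (ctrl20, within6, within33, trans6, trans33,
  n = 12 each) with six split-clutch families, each family present in
  every experimental group.
* **Genome**: 3 chromosomes of 1 Mb, 5,000 CpGs (>= 2 bp apart so C and
  paired-G positions never collide), 60 non-overlapping genes with 2-8
  exons; the last chromosome is the sex chromosome `chr19`.
* **Baseline methylation**: a 50:50 mixture of Beta(0.5, 8) and
  Beta(8, 0.5) — the classic bimodal low/high methylation landscape of
  vertebrate CpGs. Calibration scenarios can switch to uniform baselines
  (below).
* **Planted classes** (100 sites total by default): 40
  inducible-expected, 20 inducible-opposite, 20 inconclusive-effect, 20
  stable-only. Wild differences are drawn uniformly from 25-35
  percentage points — comfortably above the 15-point call threshold, as
  in the field pattern the pipeline targets. Planting is restricted to
  autosomal sites with baseline in [0.15, 0.85], and the effect sign
  points away from the nearer probability boundary, so a planted
  30-point difference is realised as ~30 points instead of being
  clipped; group means are clipped to [0.01, 0.99] with a logged count.
  Induced effects follow delta_trans = 0.9 x delta_wild and
  delta_within = 0.6 x delta_trans (accentuation across generations:
  the transgenerational group sits closer to the wild difference);
  opposite-class sites flip the induced sign. Inconclusive-class sites
  carry an induced effect of 7.5 points — half the call threshold and
  about two standard errors below it at n = 12 and coverage 30 — so the
  planted "sub-threshold" label is consistent with what the data can
  show.
* **Noise**: logit-scale family effects ~ Normal(0, 0.3); coverage ~
  negative binomial (mean 30, dispersion 5) truncated at >= 1;
  methylated counts beta-binomial with intra-sample correlation
  rho = 0.01. The beta-binomial makes the data *harsher* than the
  binomial test assumes, so recovery numbers are not flattered.
* **Genotypes**: Balding-Nichols — ancestral frequency ~ U(0.05, 0.95),
  population frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F), Hardy-Weinberg
  genotypes, depth ~ Poisson(20), GQ 60. Class-specific target F:
  background 0.02 (the genome-wide differentiation scale of the study
  system), 0.005 near inducible-expected sites, 0.15 near
  inducible-opposite sites, with >= 10 SNPs guaranteed within +/-5 kb of
  every planted inducible site. This encodes the hypothesis that
  opposite responses sit in diverged genomic backgrounds, so the
  delta.mean.FST machinery has signal to find.
* **CpG-SNP injection**: 1% of (non-planted) CpG sites receive a C>T
  variant at the C or a G>A at the paired G with allele frequency
  0.1-0.5, exercising the SNP-correction filter against exact truth.

**Calibration scenario** (`null_params`): no planted effects, no family
effects, rho = 0, baseline methylation uniform in [0.2, 0.8]. The
chi-square reference of the LRT is only exercisable where counts are
informative; under the bimodal baseline, near-fixed sites (pi0 ~ 0 or 1)
give a degenerate LRT of 0 and p of 1, making the raw p < 0.05 fraction
conservative rather than 5%. The uniform-baseline null isolates the
test's own calibration: the measured raw p < 0.05 rate is ~0.05-0.06
(the LRT is very mildly liberal at coverage ~30), and BH at q < 0.0125
yields essentially zero false DMS. Under the default rho = 0.01 the raw
test would be anticonservative — which is precisely why the thresholded,
BH-adjusted DMS call, not the raw p, is the unit of inference.

**What the generator does not emulate**: read-level artifacts (M-bias,
conversion failure, mapping bias), linkage between SNPs, methylation
autocorrelation along the genome, selection/mortality during the
experiment, and environment-dependent coverage. Passing closed-loop
tests therefore demonstrates correctness of the statistical machinery
under the stated generative model, not robustness to every artifact of
real bisulfite data.

## Problem sizes and determinism

Default analyses run 5,000 CpGs x 118 samples, 2,000+ SNPs, 1,000
enrichment replicates and 10,000 FST permutations — sizes chosen so a
full end-to-end run takes well under a minute on one core while keeping
every rate estimate's Monte-Carlo error small relative to the margins
being tested. One master seed drives everything; the CLI derives
stage-specific streams by hashing the stage name, so adding or
reordering stages never perturbs another stage's results, and rerunning
any stage with the same inputs reproduces its artifacts bit-exactly
(provenance JSONs record config hash, seed and input hashes).

## Known limitations

* SLIM-style q-values are not implemented; BH is the default (pluggable).
* Overdispersion is not modelled in the site test (by design, above).
* The per-gene Fisher construction is one of several defensible choices.
* FST machinery is two-population only; no LD pruning or haplotype
  statistics.
* The high-coverage cap and coverage normalisation are one-shot
  operations (thresholds recomputed on their own output shift within
  rounding); all removal filters with data-independent thresholds are
  exactly idempotent.
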