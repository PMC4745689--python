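# Methods

This note records the statistical model behind `sdrsurv`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing output.

## Population-genetics QC

**Allele frequencies** are simple counts: major-allele frequency
(2·n_hom-major + n_het) / 2n over non-missing calls; major/minor assignment
is by observed frequency with ties broken to the lexicographically smaller
allele.

**Hardy–Weinberg testing.** Two tests are reported side by side. The
headline value is the two-sided *exact conditional* test: conditioning on
the observed allele counts, every compatible heterozygote count is
enumerated, and the p-value sums the probabilities of configurations no
more probable than the observed one. The 1-df Pearson χ² against p², 2pq,
q² expectations (no continuity correction) is reported alongside because
candidate-SNP reports often quote it; for monomorphic SNPs it is defined as
(stat 0, p 1). The two disagree noticeably at cohort sizes in the hundreds
(we measured gaps above 0.05 in the mid-p range at n = 1000) and converge
only for much larger samples — which is exactly why both columns appear in
the QC table. Published candidate-panel p-values in this field typically
match the exact test even when a χ² test is nominally cited.

**Haplotypes and LD.** Haplotype frequencies over ≤ 6 SNPs are maximum-
likelihood estimates under HWE via EM (enumeration of the 2^k haplotypes;
convergence when the log-likelihood gain drops below 1e−8, cap 1000
iterations; initialization at the product of single-locus allele
frequencies). Pairwise D′ and r² are computed from the EM two-locus
frequencies — the same approach standard LD browsers use for unphased data
— not from composite-genotype correlation. Haplotype survival analysis uses
per-subject posterior-mean haplotype dosages in a Cox model, common
haplotypes only (frequency ≥ 0.05 by default) against the most common
haplotype as reference. This dosage-Cox construction is the standard
surrogate when full Bayesian phasing is out of scope; phase uncertainty is
averaged, not propagated.

## Survival statistics

Kaplan–Meier estimation, log-rank testing and Cox proportional-hazards
fitting are delegated to lifelines. Cox models use the Efron tie
approximation (times are recorded at month resolution, so ties are
guaranteed) with the Newton tolerance tightened to 1e−11 so coefficients
agree with a brute-force Efron partial-likelihood maximization to 1e−6.
Median survival confidence intervals invert the log-log (exponential
Greenwood) band — the Brookmeyer–Crowley construction. Non-convergence and
monotone likelihood (complete separation) produce a *flagged* CoxFit, never
a silent number.

**Genetic codings** follow the major-allele orientation that candidate-gene
survival tables conventionally print: "dominant" contrasts the minor-allele
homozygote against {major-hom, het}; "recessive" contrasts any minor-allele
carrier against the major-allele homozygote; "additive" uses two indicator
columns (het, minor-hom) against the major-hom reference. This is reversed
from the minor-allele-centric convention some GWAS tools use; the coding
tables print group sizes so the orientation is always auditable. The per-SNP
report flags p-values against a Bonferroni threshold 0.05/(panel size),
0.0083 for a six-SNP panel.

**IPCW Brier score.** The Graf inverse-probability-of-censoring-weighted
Brier score uses the censoring-distribution KM *fitted on training data
only*; the integration bound τ is the largest training event time with
positive censoring survival, also training-only — the test fold never
influences its own scoring weights. IBS integrates BS(t) by the trapezoid
rule over {0} ∪ {unique test event times ≤ τ} ∪ {τ} and divides by τ.
Subjects with G(Tᵢ⁻) = 0 would have undefined weights; τ's definition
prevents this on the evaluation grid.

## The SDR engine

For a SNP subset, subjects with complete calls are partitioned into
multilocus genotype cells (subjects missing any call in the subset are
excluded from that subset's evaluation, listwise within model, and
counted). Each cell is classified by the default **log-rank O−E rule**: the
observed-minus-expected death count of the cell against the full training
sample; negative → favorable, positive → unfavorable, zero (e.g. a lone
subject censored before the first death) → unclassifiable. The original SDR
literature does not pin this rule down in a form recomputable here, so it
is exposed as configuration: the alternative `median` rule labels a cell by
its KM median versus the training-sample median. Both rules run through
identical evaluation machinery.

Model evaluation predicts each subject's survival with the training KM
curve of their profile group, scored by the IPCW IBS above. Test subjects
falling in cells unseen or unclassifiable in training are excluded and
counted by default; the `unfavorable` policy instead predicts them with the
unfavorable training curve (a conservatism knob, off by default because it
biases IBS toward pessimism). A model whose training data contain only one
profile group is degenerate and receives the worst-case IBS sentinel 1.0,
flagged.

Cross-validation is 10-fold by default (the MDR-family convention; the fold
count is configurable), event-stratified — events and censored subjects are
shuffled separately with a seeded generator and dealt round-robin, so every
fold's event fraction is within one subject of the cohort's. Folds whose
training part has zero events are skipped and counted. The search is
exhaustive over all C(p, k) subsets per k (candidate panels are small by
design; no heuristic search is provided). Best-per-k minimizes mean testing
IBS with lexicographic tie-break; the overall winner minimizes over k with
ties broken toward smaller k (parsimony). The winner is refit on the full
cohort to produce the published-style genotype-combination table; CV is
used only for selection.

**Permutation test.** The observed statistic is the full-data log-rank χ²
between the selected model's favorable and unfavorable profiles. Each of B
permutations shuffles the (time, event) rows jointly against the genotype
rows, re-runs the *entire* search at the same k with the same fold plan,
refits the permuted winner, and recomputes the statistic;
p = (1 + #{perm ≥ observed}) / (B + 1). B defaults to 1000 and is
configurable (permutation counts of 100 and 1000 both appear in the MDR/SDR
literature). Under a null cohort the test is calibrated: we measure a
rejection rate of ~0.04–0.05 at α = 0.05 across null replicates.

The engine runs on integer genotype codes with vectorized numpy KM,
log-rank and IBS internals (a permutation test is B full search re-runs);
the test suite cross-checks these internals against lifelines to 1e−9.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, for
a metastatic prostate-cancer candidate-SNP study of VEGFR-2 and P2X7R:

* **Genotypes** — six SNPs, independent, drawn from HWE proportions at
  minor-allele frequencies (0.46, 0.06, 0.16, 0.45, 0.25, 0.47); n = 100
  by default.
* **Planted profile** — a cell → favorable/unfavorable map over a 4-SNP
  subset (rs2071559, rs11133360, rs3751143, rs208294 by default). Cells
  outside an explicit map fall back to a threshold rule: ≥ 1
  minor-allele-homozygous locus in the subset → unfavorable, which splits
  the default cohort roughly in half. The effect is planted at the
  *profile* level; note the threshold rule still leaks some marginal signal
  into each subset SNP (a fully marginal-null interaction would require a
  balanced XOR-type map, available via an explicit `profile_map`).
* **Survival** — exponential by default (Weibull optional): unfavorable
  subjects have median 65.65 months; the favorable hazard is scaled by a
  hazard ratio of 0.29. Censoring is administrative at a 480-month horizon
  plus a 10% uniform-dropout fraction. The long horizon is what makes an
  80%+ event fraction compatible with a marginal HR of 0.29 on that
  baseline (the favorable group's uncensored median is 65.65/0.29 ≈ 226
  months); under a shorter, study-like follow-up the same configuration
  yields observed favorable medians near 130 months — censoring, not the
  hazard, shapes that number. The realized event fraction is ≈ 0.85–0.90.
* **Covariates** — age, ECOG PS, Gleason group, PSA, metastatic-site count
  and therapy are drawn with plausible marginals, independent of the
  profile (so adjusted and unadjusted profile HRs agree in expectation);
  the generator does not attempt the real joint clinical distribution,
  survival-covariate dependence, between-SNP LD (an LD knob exists for
  pairs) or genotyping error. Passing tests therefore demonstrate
  correctness of the machinery under the stated generative model, not
  robustness to those real-data features.

Everything is seeded (`numpy.random.default_rng`); identical config + seed
gives byte-identical fixture files.

## Numerical conventions and edge cases

* Genotype strings are unordered on input ("AG" ≡ "GA"); heterozygotes are
  printed alphabetically, matching how published genotype tables are set.
* Exact-HWE tie comparison uses a 1 + 1e−12 relative guard so the observed
  configuration always counts itself.
* p-value floors: permutation p ≥ 1/(B+1) by construction; ties between a
  permuted and the observed statistic count toward the null (conservative).
* Times must be strictly positive; the generator clips at 1e−6 months.
* Degenerate inputs (monomorphic SNPs, single profile group, folds without
  events, years beyond follow-up) return flagged results rather than
  raising, wherever a flagged result is representable.

## Problem sizes used in validation

The suite validates stochastic behavior at deliberately chosen scales:
planted 2-way recovery at n = 400 over 20 seeds; permutation null
calibration over 200 replicates at B = 99 on a reduced 3-SNP/k = 2/3-fold
configuration; Cox HR recovery at n = 2000; log-HR bias over 120 replicates
at n = 1000; selection consistency at n ∈ {100, 1600}. These sizes give
binomial/Monte-Carlo error comfortably inside the asserted bands while
keeping the default test run short.

## Known limitations

* No covariate-adjusted SDR (adjustment happens downstream in the Cox
  stage), no time-varying covariates or frailty, and only a warning-level
  hook for proportional-hazards diagnostics.
* The haplotype stage is a dosage approximation, not full phasing.
* The published IBS values of the study this design mirrors are not
  recomputable without patient-level data; the engine's IBS is validated
  against closed forms and oracles instead.
* VCF input is deliberately thin: biallelic SNVs, GT field only; no
  liftover, strand flipping or imputation.
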