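"""Survival dimensionality reduction: search, profiles, permutation test.

Generates a cohort with a planted 4-way genotype-profile interaction,
searches all SNP subsets of size 1..4 by cross-validated testing Integrated
Brier Score (IBS, lower = better out-of-fold survival prediction), reports
the per-k best models, and certifies the winner with a permutation test
(outcomes shuffled against genotypes, full search re-run each time).
"""

import numpy as np

from sdrsurv import sdr, survival_stats, synthetic

cohort = synthetic.gen_cohort(synthetic.SyntheticConfig(seed=11, hazard_ratio=0.2))
gm, outcome = cohort.genotypes, cohort.outcome

plan = sdr.make_cv_plan(outcome, n_folds=10, seed=11)
result = sdr.search(gm, outcome, k_range=(1, 4), plan=plan)

print(f"{'k':<3}{'best subset':<52}{'train IBS':<11}{'test IBS'}")
for k in sorted(result.best_per_k):
    m = result.best_per_k[k]
    mark = " <- selected" if k == result.best.k else ""
    print(f"{k:<3}{','.join(m.snp_subset):<52}"
          f"{m.train_ibs:<11.4f}{m.test_ibs:.4f}{mark}")

best = result.best
profile = sdr.subject_profiles(gm, best.assignment)
n_fav, n_unf = int((profile == 1).sum()), int((profile == -1).sum())
print(f"\nSelected {best.k}-way model partitions the cohort into "
      f"{n_fav} favorable / {n_unf} unfavorable subjects "
      f"({len(best.assignment.labels)} genotype cells).")

for label, code in (("favorable", 1), ("unfavorable", -1)):
    km = survival_stats.kaplan_meier(outcome.subset(np.where(profile == code)[0]))
    med = "not reached" if np.isinf(km.median) else f"{km.median:.1f} months"
    print(f"  median OS, {label}: {med}")

perm = sdr.permutation_test(
    gm, outcome, best.k, plan, B=199, seed=99,
    observed=sdr.model_logrank_chi2(gm, outcome, best.assignment),
)
print(f"\nlog-rank chi2 between profiles: {perm.observed_chi2:.2f}; "
      f"permutation p = {perm.p:.4f} (B = {perm.n_permutations}).")
print("(At n = 100 cross-validation may select a parsimonious subset of the "
      "planted 4-way model; the planted subset is "
      + ", ".join(cohort.config.planted_subset) + ".)")
print("A small p says survival separation this strong essentially never "
      "arises when outcomes are shuffled against genotypes.")
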