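"""One-command orchestration of the full candidate-SNP survival analysis.

Stages, in order: population-genetics QC table -> univariate clinical Cox ->
per-SNP Cox under additive/dominant/recessive codings with Bonferroni flags
-> per-gene-region haplotype dosage Cox -> SDR subset search with
permutation certification -> full-data profile table -> Kaplan-Meier export
by profile (with medians and 2-/3-year survival) -> multivariate Cox of the
profile plus screened clinical covariates.

The output is a ReportBundle of named tables, a pure function of
(input files, configuration, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import popgen, sdr, survival_stats
from .io_cohort import (
    GenotypeMatrix,
    ReportBundle,
    SurvivalOutcome,
    join_cohort,
    read_genotypes,
    read_survival,
)

logger = logging.getLogger("sdrsurv")


@dataclass
class PipelineConfig:
    genotypes_path: str | None = None
    survival_path: str | None = None
    k_range: tuple[int, int] = (1, 4)
    folds: int = 10
    permutations: int = 1000
    seed: int = 0
    bonferroni_family: int | None = None  # default: panel size
    haplotype_threshold: float = 0.05
    covariates: list[str] | None = None  # None -> univariate screen at 0.05
    force_covariates: list[str] = field(default_factory=list)
    cell_rule: str = "logrank-oe"
    unseen_cell: str = "exclude"  # or "unfavorable"
    km_years: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        if not 0 < self.haplotype_threshold < 1:
            raise ValueError("haplotype threshold must be in (0,1)")


def summarize_survival_at(
    km: survival_stats.KmEstimate, years: list[int] | tuple[int, ...],
    outcome: SurvivalOutcome | None = None,
) -> pd.DataFrame:
    """Survival probability (with log-log CI) at t = 12*years months.

    Years beyond the last observed time are flagged missing. When the
    originating outcome is supplied, the CI is read off the fitted log-log
    band; otherwise only the point estimate is reported.
    """
    from lifelines import KaplanMeierFitter

    rows = []
    kmf = None
    if outcome is not None:
        kmf = KaplanMeierFitter()
        kmf.fit(outcome.time, outcome.event)
    horizon = km.times.max() if len(km.times) else 0.0
    for y in years:
        t = 12.0 * y
        if t > horizon:
            rows.append({"years": y, "months": t, "survival": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan, "beyond_tau": True})
            continue
        s = km.survival_at(t)
        lo = hi = np.nan
        if kmf is not None:
            ci = kmf.confidence_interval_
            idx = ci.index.searchsorted(t, side="right") - 1
            if idx >= 0:
                lo, hi = float(ci.iloc[idx, 0]), float(ci.iloc[idx, 1])
        rows.append({"years": y, "months": t, "survival": s,
                     "ci_lower": lo, "ci_upper": hi, "beyond_tau": False})
    return pd.DataFrame(rows)


def _popgen_table(gm: GenotypeMatrix) -> pd.DataFrame:
    rows = []
    for snp in gm.panel:
        counts = popgen.GenotypeCounts.from_matrix(gm, snp.snp_id)
        res = popgen.hwe_test(counts)
        maj_f = popgen.allele_frequency(counts)
        rows.append(
            {
                "snp_id": snp.snp_id,
                "gene": snp.gene,
                "n_hom_major": counts.n_hom_major,
                "n_het": counts.n_het,
                "n_hom_minor": counts.n_hom_minor,
                "allele_major": snp.allele_major,
                "allele_minor": snp.allele_minor,
                "freq_major": round(maj_f, 4),
                "freq_minor": round(1 - maj_f, 4),
                "hwe_p_exact": round(res.p_exact, 4),
                "hwe_chi2": round(res.chi2_stat, 4),
                "hwe_p_chi2": round(res.p_chi2, 4),
            }
        )
    return pd.DataFrame(rows)


def _clinical_cox_table(outcome: SurvivalOutcome) -> pd.DataFrame:
    rows = []
    if outcome.covariates is None:
        return pd.DataFrame(
            columns=["variable", "hr", "p", "hr_lower", "hr_upper", "n"]
        )
    for col in outcome.covariates.columns:
        x = outcome.covariates[col]
        keep = x.notna().to_numpy()
        sub = outcome.subset(np.where(keep)[0])
        cov = pd.DataFrame({col: x[keep].to_numpy(float)})
        if cov[col].nunique() <= 1:
            continue
        fit = survival_stats.cox_fit(sub, cov)
        r = fit.table.iloc[0]
        rows.append(
            {"variable": col, "hr": r["hr"], "p": r["p"],
             "hr_lower": r["hr_lower"], "hr_upper": r["hr_upper"], "n": fit.n}
        )
    return pd.DataFrame(rows)


def _snp_cox_table(
    gm: GenotypeMatrix, outcome: SurvivalOutcome, alpha_bonf: float
) -> pd.DataFrame:
    rows = []
    for snp in gm.panel:
        for scheme in survival_stats.SCHEMES:
            coding = survival_stats.encode_genotype(gm, snp.snp_id, scheme)
            if not coding.usable:
                rows.append({"snp_id": snp.snp_id, "gene": snp.gene,
                             "scheme": scheme, "term": "(unusable)",
                             "groups": str(coding.group_sizes), "hr": np.nan,
                             "p": np.nan, "hr_lower": np.nan, "hr_upper": np.nan,
                             "significant": False})
                continue
            keep = coding.columns.notna().all(axis=1).to_numpy()
            sub = outcome.subset(np.where(keep)[0])
            fit = survival_stats.cox_fit(sub, coding.columns[keep])
            for term, r in fit.table.iterrows():
                rows.append(
                    {
                        "snp_id": snp.snp_id,
                        "gene": snp.gene,
                        "scheme": scheme,
                        "term": term,
                        "groups": str(coding.group_sizes),
                        "hr": r["hr"],
                        "p": r["p"],
                        "hr_lower": r["hr_lower"],
                        "hr_upper": r["hr_upper"],
                        "significant": bool(r["p"] < alpha_bonf),
                    }
                )
    return pd.DataFrame(rows)


def _haplotype_table(
    gm: GenotypeMatrix, outcome: SurvivalOutcome, threshold: float
) -> pd.DataFrame:
    """Per gene region: EM haplotype frequencies and dosage Cox vs the most
    common haplotype (common haplotypes only)."""
    rows = []
    genes: dict[str, list[str]] = {}
    for snp in gm.panel:
        genes.setdefault(snp.gene or "(none)", []).append(snp.snp_id)
    for gene, snp_ids in genes.items():
        if len(snp_ids) < 2:
            continue
        hf = popgen.em_haplotypes(gm, snp_ids, rare_threshold=threshold)
        dos = popgen.haplotype_dosages(gm, snp_ids, hf)
        labels = sorted(hf.freqs)
        common = [h for h in labels if hf.freqs[h] >= threshold]
        if not common:
            continue
        ref = max(common, key=lambda h: hf.freqs[h])
        for hap in common:
            row = {"gene": gene, "haplotype": hap,
                   "frequency": round(hf.freqs[hap], 4),
                   "is_reference": hap == ref,
                   "hr": np.nan, "p": np.nan, "hr_lower": np.nan,
                   "hr_upper": np.nan}
            if hap != ref:
                col = dos[:, labels.index(hap)]
                keep = ~np.isnan(col)
                cov = pd.DataFrame({f"hap_{hap}": col[keep]})
                if cov.iloc[:, 0].nunique() > 1:
                    fit = survival_stats.cox_fit(
                        outcome.subset(np.where(keep)[0]), cov
                    )
                    r = fit.table.iloc[0]
                    row.update(hr=r["hr"], p=r["p"], hr_lower=r["hr_lower"],
                               hr_upper=r["hr_upper"])
            rows.append(row)
    return pd.DataFrame(rows)


def _profile_table(assignment: sdr.ProfileAssignment) -> pd.DataFrame:
    rows = []
    for key in sorted(assignment.labels):
        info = assignment.cells[key]
        rows.append(
            {
                **{s: g for s, g in zip(assignment.snp_subset, key)},
                "profile": assignment.labels[key],
                "n": info["n"],
                "events": info["events"],
                "score": round(info["score"], 4),
            }
        )
    return pd.DataFrame(rows)


def _km_profile_tables(
    outcome: SurvivalOutcome, profile: np.ndarray, years: tuple[int, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    curves = []
    summaries = []
    for label, code in (("all", None), ("favorable", 1), ("unfavorable", -1)):
        idx = (
            np.arange(len(profile))
            if code is None
            else np.where(profile == code)[0]
        )
        if len(idx) == 0:
            continue
        sub = outcome.subset(idx)
        km = survival_stats.kaplan_meier(sub)
        curves.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time_months": km.times,
                    "survival": km.survival,
                    "ci_lower": km.ci_lower,
                    "ci_upper": km.ci_upper,
                    "n_at_risk": km.n_at_risk,
                }
            )
        )
        at_years = summarize_survival_at(km, years, sub)
        at_years.insert(0, "group", label)
        at_years["median_os"] = km.median
        at_years["median_ci_lower"] = km.median_ci[0]
        at_years["median_ci_upper"] = km.median_ci[1]
        summaries.append(at_years)
    return pd.concat(curves, ignore_index=True), pd.concat(summaries, ignore_index=True)


def run_pipeline(
    config: PipelineConfig,
    gm: GenotypeMatrix | None = None,
    outcome: SurvivalOutcome | None = None,
) -> ReportBundle:
    """Execute the full analysis; returns the bundle of report tables.

    Inputs can be passed in memory or read from the configured paths.
    Any stage failure raises with the stage name; previously completed
    tables remain in the (partial) bundle attached to the exception.
    """
    if gm is None or outcome is None:
        if config.genotypes_path is None or config.survival_path is None:
            raise ValueError("either in-memory cohort or input paths required")
        gm = read_genotypes(config.genotypes_path)
        outcome = read_survival(config.survival_path)
    gm, outcome = join_cohort(gm, outcome)

    family = config.bonferroni_family or len(gm.panel)
    alpha_bonf = 0.05 / family
    bundle = ReportBundle()
    stage = "popgen"
    try:
        bundle.add("popgen", _popgen_table(gm))
        stage = "clinical_cox"
        bundle.add("clinical_cox", _clinical_cox_table(outcome))
        stage = "snp_cox"
        bundle.add("snp_cox", _snp_cox_table(gm, outcome, alpha_bonf))
        stage = "haplotypes"
        bundle.add(
            "haplotypes",
            _haplotype_table(gm, outcome, config.haplotype_threshold),
        )

        stage = "sdr_search"
        plan = sdr.make_cv_plan(outcome, config.folds, config.seed)
        result = sdr.search(gm, outcome, config.k_range, plan,
                            config.cell_rule, config.unseen_cell)
        stage = "permutation"
        perm = sdr.permutation_test(
            gm,
            outcome,
            result.best.k,
            plan,
            B=config.permutations,
            seed=config.seed + 1,
            rule=config.cell_rule,
            observed=sdr.model_logrank_chi2(gm, outcome, result.best.assignment),
        )
        result.best.permutation_p = perm.p
        sdr_rows = []
        for k in sorted(result.best_per_k):
            m = result.best_per_k[k]
            sdr_rows.append(
                {
                    "k": k,
                    "snps": ",".join(m.snp_subset),
                    "training_ibs": round(m.train_ibs, 4),
                    "testing_ibs": round(m.test_ibs, 4),
                    "permutation_p": m.permutation_p if m.permutation_p else np.nan,
                    "selected": k == result.best.k,
                }
            )
        bundle.add("sdr_models", pd.DataFrame(sdr_rows))

        stage = "profile_table"
        bundle.add("profile_table", _profile_table(result.best.assignment))

        stage = "km_profile"
        profile = sdr.subject_profiles(gm, result.best.assignment)
        curves, summary = _km_profile_tables(outcome, profile, config.km_years)
        bundle.add("km_curves", curves)
        bundle.add("km_summary", summary)

        stage = "multivariate_cox"
        bundle.add(
            "multivariate_cox",
            _multivariate_table(outcome, profile, bundle.tables["clinical_cox"],
                                config),
        )
    except Exception as err:
        err.partial_bundle = bundle  # type: ignore[attr-defined]
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return bundle


def _multivariate_table(
    outcome: SurvivalOutcome,
    profile: np.ndarray,
    clinical: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    if config.covariates is not None:
        chosen = list(config.covariates)
    else:
        chosen = (
            clinical.loc[clinical["p"] < 0.05, "variable"].tolist()
            if len(clinical)
            else []
        )
    for c in config.force_covariates:
        if c not in chosen:
            chosen.append(c)
    cov = pd.DataFrame({"favorable_profile": (profile == 1).astype(float)})
    if outcome.covariates is not None:
        for c in chosen:
            if c in outcome.covariates.columns:
                cov[c] = outcome.covariates[c].to_numpy(float)
    keep = (profile != 0) & cov.notna().all(axis=1).to_numpy()
    sub = outcome.subset(np.where(keep)[0])
    fit = survival_stats.cox_fit(sub, cov[keep].reset_index(drop=True))
    out = fit.table.reset_index(names="variable")
    out["n"] = fit.n
    out["n_events"] = fit.n_events
    return out
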