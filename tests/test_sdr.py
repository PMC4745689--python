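"""SDR engine: cell partition, profile classification, cross-validated
subset search and permutation testing, plus cross-checks of the engine's
vectorized survival internals against lifelines."""

from __future__ import annotations

import numpy as np
import pytest
from lifelines.statistics import logrank_test

from sdrsurv import sdr, synthetic
from sdrsurv.io_cohort import SurvivalOutcome
from sdrsurv.sdr import (
    FAVORABLE,
    UNFAVORABLE,
    UNCLASSIFIABLE,
    _km_curve,
    _logrank_2group,
    classify_cell,
    cross_validate,
    derive_profiles,
    evaluate_model,
    make_cv_plan,
    partition_cells,
    permutation_test,
    search,
    select_best_k,
    subject_profiles,
)


def _outcome(times, events):
    return SurvivalOutcome(
        [f"S{i}" for i in range(len(times))],
        np.asarray(times, float),
        np.asarray(events, int),
    )


def _planted_cohort(n, subset, hr, seed, panel=None):
    cfg = synthetic.SyntheticConfig(
        n=n,
        planted_subset=subset,
        hazard_ratio=hr,
        seed=seed,
        covariates=False,
        **({"panel": panel} if panel else {}),
    )
    return synthetic.gen_cohort(cfg)


class TestFastInternals:
    """The engine's numpy KM and log-rank must agree with lifelines."""

    def test_km_curve_matches_lifelines(self):
        rng = np.random.default_rng(0)
        t = np.round(rng.exponential(50, size=80)) + 1
        e = (rng.uniform(size=80) < 0.8).astype(int)
        grid, surv = _km_curve(t, e)
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(t, e)
        for g, s in zip(grid, surv):
            assert s == pytest.approx(
                kmf.survival_function_at_times(g).iloc[0], abs=1e-10
            )

    def test_two_group_logrank_matches_lifelines(self):
        rng = np.random.default_rng(1)
        t = np.round(rng.exponential(40, size=60)) + 1
        e = (rng.uniform(size=60) < 0.85).astype(int)
        g = rng.integers(0, 2, size=60)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert _logrank_2group(t, e, g) == pytest.approx(
            ref.test_statistic, abs=1e-9
        )


class TestPartitionCells:
    def test_at_most_3_to_k_cells(self, panel_gm):
        subset = ["rs2071559", "rs11133360", "rs3751143", "rs208294"]
        cells = partition_cells(panel_gm, subset)
        assert len(cells) <= 81
        total = sum(c.n for c in cells)
        assert total == 100  # complete calls in the fixture

    def test_memberships_disjoint_and_exhaustive(self, panel_gm):
        cells = partition_cells(panel_gm, ["rs3751143", "rs208294"])
        all_members = np.concatenate([c.members for c in cells])
        assert len(all_members) == len(set(all_members)) == 100

    def test_duplicated_subjects_double_memberships(self):
        coh = _planted_cohort(50, ("rs2071559",), 0.5, 3)
        gm = coh.genotypes
        from sdrsurv.io_cohort import GenotypeMatrix

        gm2 = GenotypeMatrix(
            gm.subject_ids + [s + "b" for s in gm.subject_ids],
            gm.panel,
            np.vstack([gm.codes, gm.codes]),
        )
        c1 = {c.key: c.n for c in partition_cells(gm, ["rs2071559", "rs208294"])}
        c2 = {c.key: c.n for c in partition_cells(gm2, ["rs2071559", "rs208294"])}
        assert set(c1) == set(c2)
        assert all(c2[k] == 2 * c1[k] for k in c1)

    def test_empty_subject_set_rejected(self, panel_gm):
        with pytest.raises(ValueError):
            partition_cells(panel_gm, ["rs2071559"], subjects=np.array([], dtype=int))


class TestClassifyCell:
    def test_zero_death_cell_favorable(self):
        out = _outcome([10, 20, 30, 5, 6, 7], [0, 0, 0, 1, 1, 1])
        cell = sdr.GenotypeCell(("s",), ("AA",), np.array([0, 1, 2]))
        label, score = classify_cell(cell, out)
        assert label == FAVORABLE and score < 0

    def test_all_early_death_cell_unfavorable(self):
        out = _outcome([1, 2, 3, 50, 60, 70], [1, 1, 1, 1, 0, 0])
        cell = sdr.GenotypeCell(("s",), ("GG",), np.array([0, 1, 2]))
        label, score = classify_cell(cell, out)
        assert label == UNFAVORABLE and score > 0

    def test_censored_before_first_death_unclassifiable(self):
        # lone member censored before any death: no at-risk contribution
        out = _outcome([0.5, 10, 20, 30], [0, 1, 1, 1])
        cell = sdr.GenotypeCell(("s",), ("AG",), np.array([0]))
        label, score = classify_cell(cell, out)
        assert label == UNCLASSIFIABLE and score == 0.0


class TestDeriveProfiles:
    def test_planted_truth_recovered(self):
        hits = []
        for seed in range(20):
            coh = _planted_cohort(
                400, ("rs2071559", "rs208294"), 0.2, 100 + seed
            )
            assign = derive_profiles(
                coh.genotypes, coh.outcome, ("rs2071559", "rs208294")
            )
            prof = subject_profiles(coh.genotypes, assign)
            truth = np.where(coh.true_profile == "favorable", 1, -1)
            classified = prof != 0
            agree = (prof[classified] == truth[classified]).mean()
            hits.append(agree)
        assert np.mean([a >= 0.9 for a in hits]) >= 0.9

    def test_null_outcome_mixes_labels(self):
        for seed in (0, 1):
            coh = _planted_cohort(300, ("rs2071559",), 1.0, 200 + seed)
            assign = derive_profiles(
                coh.genotypes, coh.outcome, ("rs11133360", "rs208294")
            )
            labs = [v for v in assign.labels.values() if v != UNCLASSIFIABLE]
            frac_fav = np.mean([v == FAVORABLE for v in labs])
            assert 0.15 < frac_fav < 0.85

    def test_snp_order_symmetry(self, panel_gm):
        out = _outcome(
            np.arange(1, 101, dtype=float), (np.arange(100) % 5 != 0).astype(int)
        )
        a1 = derive_profiles(panel_gm, out, ("rs3751143", "rs208294"))
        a2 = derive_profiles(panel_gm, out, ("rs208294", "rs3751143"))
        for key, lab in a1.labels.items():
            assert a2.labels[(key[1], key[0])] == lab


class TestEvaluateModel:
    def test_identity_split_train_equals_test(self):
        coh = _planted_cohort(120, ("rs2071559", "rs208294"), 0.3, 7)
        subs = np.arange(120)
        assign = derive_profiles(coh.genotypes, coh.outcome, ("rs2071559", "rs208294"))
        ev = evaluate_model(coh.genotypes, coh.outcome, assign, subs, subs)
        assert ev.train_ibs == pytest.approx(ev.test_ibs, abs=1e-12)
        assert not ev.degenerate

    def test_true_assignment_beats_random_labels(self):
        rng = np.random.default_rng(42)
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            coh = _planted_cohort(150, ("rs2071559", "rs208294"), 0.25, 300 + rep)
            subs = np.arange(150)
            truth = derive_profiles(
                coh.genotypes, coh.outcome, ("rs2071559", "rs208294")
            )
            # random relabeling of the same cells
            rand = sdr.ProfileAssignment(
                truth.snp_subset,
                {
                    k: (FAVORABLE if rng.uniform() < 0.5 else UNFAVORABLE)
                    for k in truth.labels
                },
                truth.cells,
                truth.rule,
            )
            ev_t = evaluate_model(coh.genotypes, coh.outcome, truth, subs, subs)
            ev_r = evaluate_model(coh.genotypes, coh.outcome, rand, subs, subs)
            if ev_t.test_ibs < ev_r.test_ibs or ev_r.degenerate:
                wins += 1
        assert wins / n_rep >= 0.95

    def test_single_profile_degenerate(self):
        coh = _planted_cohort(50, ("rs2071559",), 0.5, 9)
        assign = derive_profiles(coh.genotypes, coh.outcome, ("rs2071559",))
        forced = sdr.ProfileAssignment(
            assign.snp_subset,
            {k: FAVORABLE for k in assign.labels},
            assign.cells,
            assign.rule,
        )
        subs = np.arange(50)
        ev = evaluate_model(coh.genotypes, coh.outcome, forced, subs, subs)
        assert ev.degenerate and ev.test_ibs == sdr.DEGENERATE_IBS


class TestCrossValidate:
    def test_duplicated_cohort_fold_split_equalizes(self):
        coh = _planted_cohort(80, ("rs2071559", "rs208294"), 0.3, 13)
        gm, out = coh.genotypes, coh.outcome
        from sdrsurv.io_cohort import GenotypeMatrix

        gm2 = GenotypeMatrix(
            gm.subject_ids + [s + "b" for s in gm.subject_ids],
            gm.panel,
            np.vstack([gm.codes, gm.codes]),
        )
        out2 = SurvivalOutcome(
            gm2.subject_ids,
            np.concatenate([out.time, out.time]),
            np.concatenate([out.event, out.event]),
        )
        plan = sdr.CvPlan(2, np.array([0] * 80 + [1] * 80), seed=0)
        cv = cross_validate(gm2, out2, ("rs2071559", "rs208294"), plan)
        assert cv.mean_test_ibs == pytest.approx(cv.mean_train_ibs, abs=1e-12)

    def test_same_seed_identical_plan_and_results(self):
        coh = _planted_cohort(100, ("rs2071559", "rs208294"), 0.3, 17)
        p1 = make_cv_plan(coh.outcome, 10, seed=5)
        p2 = make_cv_plan(coh.outcome, 10, seed=5)
        assert np.array_equal(p1.fold_of, p2.fold_of)
        cv1 = cross_validate(coh.genotypes, coh.outcome, ("rs2071559",), p1)
        cv2 = cross_validate(coh.genotypes, coh.outcome, ("rs2071559",), p2)
        assert cv1.mean_test_ibs == cv2.mean_test_ibs

    def test_event_stratified_folds(self):
        coh = _planted_cohort(100, ("rs2071559",), 0.5, 19)
        plan = make_cv_plan(coh.outcome, 5, seed=2)
        overall = coh.outcome.event.sum() / 5
        for f in range(5):
            in_fold = coh.outcome.event[plan.fold_of == f].sum()
            assert abs(in_fold - overall) <= 1


class TestSearch:
    def test_exhaustive_evaluation_count(self):
        coh = synthetic.gen_cohort(synthetic.SyntheticConfig(seed=23, covariates=False))
        plan = make_cv_plan(coh.outcome, 5, seed=1)
        res = search(coh.genotypes, coh.outcome, (1, 4), plan)
        assert len(res.evaluations) == 6 + 15 + 20 + 15

    def test_selection_on_published_testing_ibs(self):
        assert select_best_k({1: 0.1877, 2: 0.1852, 3: 0.1784, 4: 0.1689}) == 4

    def test_tie_breaks_toward_smaller_k(self):
        assert select_best_k({2: 0.17, 3: 0.17, 4: 0.18}) == 2

    def test_overall_best_is_min_over_k(self):
        coh = synthetic.gen_cohort(synthetic.SyntheticConfig(seed=29, covariates=False))
        plan = make_cv_plan(coh.outcome, 5, seed=3)
        res = search(coh.genotypes, coh.outcome, (1, 3), plan)
        assert res.best.test_ibs == min(m.test_ibs for m in res.best_per_k.values())
        assert res.best.assignment is not None

    def test_subject_order_invariance(self):
        coh = _planted_cohort(100, ("rs2071559", "rs208294"), 0.25, 31)
        plan = make_cv_plan(coh.outcome, 5, seed=4)
        res1 = search(coh.genotypes, coh.outcome, (1, 2), plan)
        rng = np.random.default_rng(0)
        perm = rng.permutation(100)
        gm2 = sdr.GenotypeMatrix(
            [coh.genotypes.subject_ids[i] for i in perm],
            coh.genotypes.panel,
            coh.genotypes.codes[perm],
        )
        out2 = coh.outcome.subset(perm)
        plan2 = sdr.CvPlan(plan.n_folds, plan.fold_of[perm], plan.seed)
        res2 = search(gm2, out2, (1, 2), plan2)
        assert res1.best.snp_subset == res2.best.snp_subset
        assert res1.best.test_ibs == pytest.approx(res2.best.test_ibs, abs=1e-12)

    def test_selection_consistency_grows_with_n(self):
        pair = ("rs2071559", "rs208294")
        rates = {}
        for n in (100, 1600):
            hits = 0
            for s in range(5):
                coh = _planted_cohort(n, pair, 0.25, 500 + s)
                plan = make_cv_plan(coh.outcome, 10, seed=s)
                res = search(coh.genotypes, coh.outcome, (1, 2), plan)
                hits += tuple(sorted(res.best.snp_subset)) == tuple(sorted(pair))
            rates[n] = hits / 5
        assert rates[1600] >= rates[100]
        assert rates[1600] >= 0.8

    def test_overfitting_direction_on_average(self):
        # train IBS <= test IBS for the selected model, as a trend
        gaps = []
        for s in range(20):
            coh = _planted_cohort(100, ("rs2071559", "rs208294"), 0.3, 700 + s)
            plan = make_cv_plan(coh.outcome, 5, seed=s)
            res = search(coh.genotypes, coh.outcome, (1, 3), plan)
            gaps.append(res.best.test_ibs - res.best.train_ibs)
        assert np.mean(gaps) >= 0

    def test_empty_k_range_rejected(self, panel_gm):
        out = _outcome(np.arange(1, 101, dtype=float), np.ones(100, dtype=int))
        with pytest.raises(ValueError):
            search(panel_gm, out, [], make_cv_plan(out, 5, 0))


class TestPermutation:
    def test_p_bounds_and_determinism(self):
        coh = _planted_cohort(60, ("rs2071559",), 0.4, 41, panel=list(
            synthetic.DEFAULT_PANEL[:3]
        ))
        plan = make_cv_plan(coh.outcome, 3, seed=1)
        r1 = permutation_test(coh.genotypes, coh.outcome, 1, plan, B=49, seed=9)
        r2 = permutation_test(coh.genotypes, coh.outcome, 1, plan, B=49, seed=9)
        assert 1 / 50 <= r1.p <= 1.0
        assert r1.p == r2.p
        assert np.array_equal(r1.perm_stats, r2.perm_stats)

    def test_p_monotone_in_observed_statistic(self):
        coh = _planted_cohort(60, ("rs2071559",), 0.4, 43, panel=list(
            synthetic.DEFAULT_PANEL[:3]
        ))
        plan = make_cv_plan(coh.outcome, 3, seed=1)
        res = permutation_test(coh.genotypes, coh.outcome, 1, plan, B=49, seed=3)
        stats = res.perm_stats
        p_small = (1 + np.sum(stats >= 1.0)) / 50
        p_large = (1 + np.sum(stats >= 10.0)) / 50
        assert p_large <= p_small

    def test_strong_planted_model_small_p(self):
        # strong 4-way profile effect: permutation p at or near its minimum
        small = 0
        for s in range(4):
            coh = _planted_cohort(
                100,
                synthetic.DEFAULT_PLANTED_SUBSET,
                0.15,
                900 + s,
                panel=[synthetic.DEFAULT_PANEL[i] for i in (0, 1, 3, 4, 5)],
            )
            plan = make_cv_plan(coh.outcome, 5, seed=s)
            res = permutation_test(coh.genotypes, coh.outcome, 4, plan, B=99, seed=s)
            small += res.p <= 0.02
        assert small >= 3

    def test_zero_permutations_rejected(self):
        coh = _planted_cohort(40, ("rs2071559",), 0.5, 47)
        plan = make_cv_plan(coh.outcome, 3, seed=0)
        with pytest.raises(ValueError):
            permutation_test(coh.genotypes, coh.outcome, 1, plan, B=0)


class TestUnseenCellPolicy:
    def test_unfavorable_policy_uses_all_test_subjects(self):
        coh = _planted_cohort(100, ("rs2071559", "rs208294"), 0.3, 61)
        plan = make_cv_plan(coh.outcome, 5, seed=6)
        subset = ("rs2071559", "rs11133360", "rs3751143", "rs208294")
        cv_ex = cross_validate(coh.genotypes, coh.outcome, subset, plan)
        cv_un = cross_validate(
            coh.genotypes, coh.outcome, subset, plan, unseen="unfavorable"
        )
        assert cv_un.n_excluded_total == 0
        # a 4-way model on n=100 leaves unseen test cells under exclusion
        assert cv_ex.n_excluded_total > 0
        assert 0 <= cv_un.mean_test_ibs <= 1
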