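"""Survival dimensionality reduction (SDR) engine.

SDR is the censored-outcome analog of multifactor dimensionality reduction:
for a candidate subset of k SNPs, subjects are partitioned into at most 3^k
multilocus genotype cells, each cell is collapsed to a one-dimensional
binary attribute — a *favorable* or *unfavorable* survival profile — and the
two profile groups' training Kaplan-Meier curves serve as the survival
prediction for held-out subjects. Candidate subsets are compared by
cross-validated testing Integrated Brier Score (IBS, lower is better), and
the selected model is certified by a permutation test on the full-data
log-rank statistic between its two profiles.

Cell-classification rules
-------------------------
``"logrank-oe"`` (default): score a cell by the log-rank observed-minus-
expected deaths (O - E) of its members against the full training sample;
O - E < 0 (fewer deaths than expected) is favorable, O - E > 0 unfavorable,
O - E = 0 unclassifiable. This is the censored-data analog of MDR's
case/control-ratio threshold.

``"median"``: compare the cell's KM median to the training-sample KM median
(cell median above overall, or never reached while the overall is, is
favorable).

All heavy lifting runs on integer genotype codes and flat numpy arrays so
that permutation testing (B x full search re-runs) stays fast; the numpy
KM/log-rank/IBS internals are cross-checked against lifelines in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io_cohort import GenotypeMatrix, SurvivalOutcome

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"
UNCLASSIFIABLE = "unclassifiable"

#: IBS sentinel for degenerate models (one profile group empty in training)
DEGENERATE_IBS = 1.0

CELL_RULES = ("logrank-oe", "median")


# ---------------------------------------------------------------------------
# data containers


@dataclass
class GenotypeCell:
    snp_subset: tuple[str, ...]
    key: tuple[str, ...]
    members: np.ndarray  # subject indices

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class ProfileAssignment:
    """Map from genotype-cell key to survival-profile label, with per-cell
    summaries (n, events, classification score)."""

    snp_subset: tuple[str, ...]
    labels: dict[tuple[str, ...], str]
    cells: dict[tuple[str, ...], dict]  # key -> {n, events, score}
    rule: str

    def label_of(self, key: tuple[str, ...]) -> str:
        return self.labels.get(key, UNCLASSIFIABLE)


@dataclass
class CvPlan:
    """Event-stratified cross-validation fold assignment."""

    n_folds: int
    fold_of: np.ndarray
    seed: int


@dataclass
class ModelEvaluation:
    train_ibs: float
    test_ibs: float
    n_test_used: int
    n_test_excluded: int
    degenerate: bool = False


@dataclass
class CvResult:
    mean_train_ibs: float
    mean_test_ibs: float
    fold_evals: list[ModelEvaluation]
    n_folds_used: int
    n_excluded_total: int


@dataclass
class SDRModel:
    k: int
    snp_subset: tuple[str, ...]
    assignment: ProfileAssignment | None
    train_ibs: float
    test_ibs: float
    permutation_p: float | None = None


@dataclass
class SDRSearchResult:
    best_per_k: dict[int, SDRModel]
    best: SDRModel
    evaluations: list[tuple[tuple[str, ...], float, float]] = field(
        default_factory=list
    )


@dataclass
class PermutationResult:
    p: float
    observed_chi2: float
    n_permutations: int
    perm_stats: np.ndarray


# ---------------------------------------------------------------------------
# fast numpy internals (operate on integer codes / flat arrays)


def _cell_codes(codes_subset: np.ndarray) -> tuple[np.ndarray, int]:
    """Base-3 cell index per subject; -1 where any call is missing."""
    n, k = codes_subset.shape
    ncells = 3**k
    cell = np.zeros(n, dtype=np.int64)
    for j in range(k):
        cell = cell * 3 + codes_subset[:, j]
    cell[(codes_subset < 0).any(axis=1)] = -1
    return cell, ncells


def _cell_oe(
    times: np.ndarray, events: np.ndarray, cell: np.ndarray, ncells: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell observed and expected deaths vs the pooled sample.

    Expected deaths for cell c sum d_t * n_c(t)/n(t) over distinct death
    times t of the pooled sample.
    """
    order = np.argsort(times, kind="stable")
    t, e, c = times[order], events[order], cell[order]
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    onehot = np.zeros((n, ncells))
    onehot[np.arange(n), c] = 1.0
    # at-risk per cell at each unique time = members with time >= that time
    at_risk_cell = np.cumsum(onehot[::-1], axis=0)[::-1][start]
    at_risk_tot = (n - start).astype(float)
    d_tot = np.add.reduceat(e.astype(float), start)
    death_rows = onehot * e[:, None]
    d_cell = np.add.reduceat(death_rows, start, axis=0)
    death_times = d_tot > 0
    expected = (
        (d_tot[death_times, None] / at_risk_tot[death_times, None])
        * at_risk_cell[death_times]
    ).sum(axis=0)
    observed = d_cell.sum(axis=0)
    counts = onehot.sum(axis=0)
    return observed, expected, counts


def _km_curve(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, start = np.unique(t, return_index=True)
    at_risk = (len(t) - start).astype(float)
    deaths = np.add.reduceat(e.astype(float), start)
    surv = np.cumprod(1.0 - deaths / at_risk)
    return uniq, surv


def _km_median(grid: np.ndarray, surv: np.ndarray) -> float:
    below = np.where(surv <= 0.5)[0]
    return float(grid[below[0]]) if len(below) else float("inf")


def _step(grid: np.ndarray, values: np.ndarray, t: np.ndarray, left: bool = False
          ) -> np.ndarray:
    idx = np.searchsorted(grid, t, side="left" if left else "right") - 1
    out = np.ones(len(t))
    mask = idx >= 0
    out[mask] = values[idx[mask]]
    return out


def _logrank_2group(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> float:
    """Two-group log-rank chi-square (1 df); group is a 0/1 array."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], group[order]
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    n_tot = (n - start).astype(float)
    in1 = (g == 1).astype(float)
    n1 = np.cumsum(in1[::-1])[::-1][start]
    d_tot = np.add.reduceat(e.astype(float), start)
    d1 = np.add.reduceat(e * in1, start)
    mask = d_tot > 0
    n_tot, n1, d_tot, d1 = n_tot[mask], n1[mask], d_tot[mask], d1[mask]
    e1 = d_tot * n1 / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    v = np.where(n_tot > 1, v, 0.0)
    var = v.sum()
    if var <= 0:
        return 0.0
    return float((d1.sum() - e1.sum()) ** 2 / var)


def _classify_cells(
    times: np.ndarray,
    events: np.ndarray,
    cell: np.ndarray,
    ncells: int,
    rule: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Label every observed cell.

    Returns (labels, scores, counts, events_per_cell); labels are int8:
    +1 favorable, -1 unfavorable, 0 unclassifiable/unobserved.
    """
    keep = cell >= 0
    t, e, c = times[keep], events[keep], cell[keep]
    labels = np.zeros(ncells, dtype=np.int8)
    if rule == "logrank-oe":
        observed, expected, counts = _cell_oe(t, e, c, ncells)
        score = observed - expected
        tol = 1e-12
        labels[score < -tol] = 1
        labels[score > tol] = -1
    elif rule == "median":
        grid, surv = _km_curve(t, e)
        overall = _km_median(grid, surv)
        counts = np.bincount(c, minlength=ncells).astype(float)
        observed = np.bincount(c, weights=e.astype(float), minlength=ncells)
        score = np.zeros(ncells)
        for cc in np.nonzero(counts)[0]:
            m = c == cc
            cg, cs = _km_curve(t[m], e[m])
            med = _km_median(cg, cs)
            if med == overall or (np.isinf(med) and np.isinf(overall)):
                score[cc] = 0.0
            else:
                score[cc] = 1.0 if med > overall else -1.0
        labels[score > 0] = 1
        labels[score < 0] = -1
    else:
        raise ValueError(f"unknown cell rule {rule!r}; choose from {CELL_RULES}")
    labels[counts == 0] = 0
    return labels, score, counts, observed


def _ibs_for_split(
    times: np.ndarray,
    events: np.ndarray,
    profile: np.ndarray,  # +1/-1/0 per subject (0 = unclassifiable/excluded)
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    pred_profile: np.ndarray | None = None,
) -> tuple[float, int, int]:
    """Testing IBS of the two-profile KM predictor.

    Predictions and censoring weights come from the training split; the
    training KM groups follow ``profile`` while test membership/prediction
    follows ``pred_profile`` (defaults to ``profile``; subjects at 0 are
    excluded and counted). Degenerate groups must be handled upstream.
    """
    if pred_profile is None:
        pred_profile = profile
    tr = train_mask
    te = test_mask & (pred_profile != 0)
    n_excluded = int((test_mask & (pred_profile == 0)).sum())
    t_tr, e_tr = times[tr], events[tr]
    t_te, e_te, p_te = times[te], events[te], pred_profile[te]
    if len(t_te) == 0:
        return float("nan"), 0, n_excluded

    g_grid, g_surv = _km_curve(t_tr, 1 - e_tr)
    ev = np.unique(t_tr[e_tr == 1])
    if len(ev) == 0:
        return float("nan"), 0, n_excluded
    g_at_ev = _step(g_grid, g_surv, ev)
    pos = ev[g_at_ev > 0]
    if len(pos) == 0:
        return float("nan"), 0, n_excluded
    tau = pos[-1]

    fav_grid, fav_surv = _km_curve(times[tr & (profile == 1)], events[tr & (profile == 1)])
    unf_grid, unf_surv = _km_curve(times[tr & (profile == -1)], events[tr & (profile == -1)])

    grid = np.unique(np.concatenate([[0.0], np.unique(t_te[e_te == 1]), [tau]]))
    grid = grid[grid <= tau]
    s_fav = _step(fav_grid, fav_surv, grid)
    s_unf = _step(unf_grid, unf_surv, grid)
    s_pred = np.where(p_te[:, None] == 1, s_fav[None, :], s_unf[None, :])

    g_at_grid = _step(g_grid, g_surv, grid)
    g_at_ti = _step(g_grid, g_surv, t_te, left=True)

    died = (t_te[:, None] <= grid[None, :]) & (e_te[:, None] == 1)
    alive = t_te[:, None] > grid[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_died = np.where(g_at_ti[:, None] > 0, 1.0 / g_at_ti[:, None], 0.0)
        w_alive = np.where(g_at_grid[None, :] > 0, 1.0 / g_at_grid[None, :], 0.0)
    terms = died * w_died * s_pred**2 + alive * w_alive * (1.0 - s_pred) ** 2
    bs = terms.mean(axis=0)
    ibs = float(np.trapezoid(bs, grid) / tau) if tau > 0 else float("nan")
    return ibs, int(te.sum()), n_excluded


def _evaluate_split(
    times: np.ndarray,
    events: np.ndarray,
    cell: np.ndarray,
    ncells: int,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    rule: str,
    unseen: str = "exclude",
) -> ModelEvaluation:
    """Derive profiles on the training split and score train/test IBS.

    ``unseen`` controls test subjects in cells unseen or unclassifiable in
    training: "exclude" (count and drop) or "unfavorable" (predict with the
    unfavorable training curve).
    """
    tr_cells = cell[train_mask]
    labels, _, _, _ = _classify_cells(
        times[train_mask], events[train_mask], tr_cells, ncells, rule
    )
    profile = np.zeros(len(cell), dtype=np.int8)
    seen = cell >= 0
    profile[seen] = labels[cell[seen]]
    # cells never observed in training stay 0 via labels[counts==0]=0
    if not ((profile[train_mask] == 1).any() and (profile[train_mask] == -1).any()):
        return ModelEvaluation(DEGENERATE_IBS, DEGENERATE_IBS, 0,
                               int(test_mask.sum()), degenerate=True)
    pred_profile = profile
    if unseen == "unfavorable":
        pred_profile = profile.copy()
        pred_profile[seen & (pred_profile == 0)] = -1
    elif unseen != "exclude":
        raise ValueError(f"unknown unseen-cell policy {unseen!r}")
    train_ibs, _, _ = _ibs_for_split(times, events, profile, train_mask, train_mask)
    test_ibs, n_used, n_excl = _ibs_for_split(
        times, events, profile, train_mask, test_mask, pred_profile
    )
    if np.isnan(test_ibs):
        return ModelEvaluation(train_ibs, DEGENERATE_IBS, 0, n_excl, degenerate=True)
    return ModelEvaluation(train_ibs, test_ibs, n_used, n_excl)


def _cross_validate_codes(
    times: np.ndarray,
    events: np.ndarray,
    cell: np.ndarray,
    ncells: int,
    fold_of: np.ndarray,
    rule: str,
    unseen: str = "exclude",
) -> CvResult:
    evals: list[ModelEvaluation] = []
    n_excl = 0
    for f in range(fold_of.max() + 1):
        test_mask = fold_of == f
        train_mask = ~test_mask
        if events[train_mask].sum() == 0 or test_mask.sum() == 0:
            continue  # fold without training events: skipped, logged upstream
        ev = _evaluate_split(times, events, cell, ncells, train_mask,
                             test_mask, rule, unseen)
        evals.append(ev)
        n_excl += ev.n_test_excluded
    if not evals:
        return CvResult(float("nan"), float("nan"), [], 0, n_excl)
    return CvResult(
        float(np.mean([e.train_ibs for e in evals])),
        float(np.mean([e.test_ibs for e in evals])),
        evals,
        len(evals),
        n_excl,
    )


def _search_codes(
    codes: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    k_list: list[int],
    fold_of: np.ndarray,
    rule: str,
    unseen: str = "exclude",
) -> tuple[dict[int, tuple[tuple[int, ...], float, float]], list]:
    """Exhaustive subset search on integer codes.

    Returns per-k best as (subset-indices, train_ibs, test_ibs) plus the
    full evaluation log.
    """
    p = codes.shape[1]
    best_per_k: dict[int, tuple[tuple[int, ...], float, float]] = {}
    log = []
    for k in k_list:
        best = None
        for subset in combinations(range(p), k):
            cell, ncells = _cell_codes(codes[:, subset])
            cv = _cross_validate_codes(times, events, cell, ncells, fold_of,
                                       rule, unseen)
            log.append((subset, cv.mean_train_ibs, cv.mean_test_ibs))
            key = (cv.mean_test_ibs, subset)
            if best is None or key < best[0]:
                best = (key, subset, cv.mean_train_ibs, cv.mean_test_ibs)
        best_per_k[k] = (best[1], best[2], best[3])
    return best_per_k, log


def _select_overall(per_k: dict[int, tuple[float, object]]) -> int:
    """Argmin of testing IBS over k; ties break to smaller k."""
    return min(per_k, key=lambda k: (per_k[k][0], k))


# ---------------------------------------------------------------------------
# public API on cohort objects


def make_cv_plan(outcome: SurvivalOutcome, n_folds: int = 10, seed: int = 0) -> CvPlan:
    """Event-stratified fold assignment: events and censored subjects are
    shuffled separately and dealt round-robin, so each fold's event fraction
    is within one subject of the overall fraction."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    n = len(outcome.time)
    fold_of = np.empty(n, dtype=np.int64)
    for group in (np.where(outcome.event == 1)[0], np.where(outcome.event == 0)[0]):
        perm = rng.permutation(group)
        fold_of[perm] = np.arange(len(perm)) % n_folds
    return CvPlan(n_folds, fold_of, seed)


def _subset_indices(gm: GenotypeMatrix, subset: list[str] | tuple[str, ...]) -> list[int]:
    if not subset:
        raise ValueError("empty SNP subset")
    return [gm.snp_index(s) for s in subset]


def _keys_for_subset(gm: GenotypeMatrix, idx: list[int], cell_ids: np.ndarray
                     ) -> dict[int, tuple[str, ...]]:
    keys = {}
    k = len(idx)
    for cc in np.unique(cell_ids[cell_ids >= 0]):
        digits = []
        rem = int(cc)
        for _ in range(k):
            digits.append(rem % 3)
            rem //= 3
        digits.reverse()
        keys[int(cc)] = tuple(
            gm.panel[j].genotype_string(d) for j, d in zip(idx, digits)
        )
    return keys


def partition_cells(
    gm: GenotypeMatrix,
    subset: list[str] | tuple[str, ...],
    subjects: np.ndarray | None = None,
) -> list[GenotypeCell]:
    """Partition subjects with complete calls at ``subset`` into multilocus
    genotype cells (at most 3^k non-empty)."""
    idx = _subset_indices(gm, subset)
    if subjects is None:
        subjects = np.arange(gm.n_subjects)
    subjects = np.asarray(subjects)
    if len(subjects) == 0:
        raise ValueError("empty subject set")
    cell, _ = _cell_codes(gm.codes[np.ix_(subjects, idx)])
    keys = _keys_for_subset(gm, idx, cell)
    out = []
    for cc, key in sorted(keys.items(), key=lambda kv: kv[1]):
        members = subjects[cell == cc]
        out.append(GenotypeCell(tuple(subset), key, members))
    return out


def classify_cell(
    cell: GenotypeCell,
    training_outcome: SurvivalOutcome,
    rule: str = "logrank-oe",
) -> tuple[str, float]:
    """Label one cell against the full training sample; returns (label, score).

    With the default rule the score is the log-rank O - E of cell members
    versus the training sample.
    """
    if cell.n == 0:
        raise ValueError("empty cell")
    member = np.zeros(len(training_outcome.time), dtype=np.int64)
    member[cell.members] = 1
    observed, expected, _ = _cell_oe(
        training_outcome.time, training_outcome.event, member, 2
    )
    if rule == "logrank-oe":
        score = float(observed[1] - expected[1])
        if abs(score) <= 1e-12:
            return UNCLASSIFIABLE, 0.0
        return (FAVORABLE if score < 0 else UNFAVORABLE), score
    if rule == "median":
        grid, surv = _km_curve(training_outcome.time, training_outcome.event)
        overall = _km_median(grid, surv)
        cg, cs = _km_curve(
            training_outcome.time[cell.members], training_outcome.event[cell.members]
        )
        med = _km_median(cg, cs)
        if med == overall:
            return UNCLASSIFIABLE, 0.0
        return (FAVORABLE if med > overall else UNFAVORABLE), float(
            1.0 if med > overall else -1.0
        )
    raise ValueError(f"unknown cell rule {rule!r}")


def derive_profiles(
    gm: GenotypeMatrix,
    outcome: SurvivalOutcome,
    subset: list[str] | tuple[str, ...],
    training_subjects: np.ndarray | None = None,
    rule: str = "logrank-oe",
) -> ProfileAssignment:
    """Classify every genotype cell observed among the training subjects."""
    idx = _subset_indices(gm, subset)
    if training_subjects is None:
        training_subjects = np.arange(gm.n_subjects)
    training_subjects = np.asarray(training_subjects)
    sub_codes = gm.codes[np.ix_(training_subjects, idx)]
    cell, ncells = _cell_codes(sub_codes)
    keep = cell >= 0
    labels_arr, scores, counts, ev_counts = _classify_cells(
        outcome.time[training_subjects][keep],
        outcome.event[training_subjects][keep],
        cell[keep],
        ncells,
        rule,
    )
    keys = _keys_for_subset(gm, idx, cell)
    label_names = {1: FAVORABLE, -1: UNFAVORABLE, 0: UNCLASSIFIABLE}
    labels = {}
    cells = {}
    for cc, key in keys.items():
        labels[key] = label_names[int(labels_arr[cc])]
        cells[key] = {
            "n": int(counts[cc]),
            "events": int(ev_counts[cc]),
            "score": float(scores[cc]),
        }
    return ProfileAssignment(tuple(subset), labels, cells, rule)


def subject_profiles(
    gm: GenotypeMatrix, assignment: ProfileAssignment
) -> np.ndarray:
    """Profile label per subject (+1 favorable, -1 unfavorable, 0 otherwise)."""
    idx = _subset_indices(gm, assignment.snp_subset)
    cell, _ = _cell_codes(gm.codes[:, idx])
    keys = _keys_for_subset(gm, idx, cell)
    out = np.zeros(gm.n_subjects, dtype=np.int8)
    to_int = {FAVORABLE: 1, UNFAVORABLE: -1, UNCLASSIFIABLE: 0}
    for cc, key in keys.items():
        out[cell == cc] = to_int[assignment.label_of(key)]
    return out


def evaluate_model(
    gm: GenotypeMatrix,
    outcome: SurvivalOutcome,
    assignment: ProfileAssignment,
    training_subjects: np.ndarray,
    test_subjects: np.ndarray,
) -> ModelEvaluation:
    """Train/test IBS of the two-profile KM predictor given an assignment
    derived from the training subjects only."""
    profile = subject_profiles(gm, assignment)
    n = gm.n_subjects
    train_mask = np.zeros(n, dtype=bool)
    train_mask[np.asarray(training_subjects)] = True
    test_mask = np.zeros(n, dtype=bool)
    test_mask[np.asarray(test_subjects)] = True
    if not ((profile[train_mask] == 1).any() and (profile[train_mask] == -1).any()):
        return ModelEvaluation(
            DEGENERATE_IBS, DEGENERATE_IBS, 0, int(test_mask.sum()), degenerate=True
        )
    train_ibs, _, _ = _ibs_for_split(
        outcome.time, outcome.event, profile, train_mask, train_mask
    )
    test_ibs, n_used, n_excl = _ibs_for_split(
        outcome.time, outcome.event, profile, train_mask, test_mask
    )
    if np.isnan(test_ibs):
        return ModelEvaluation(train_ibs, DEGENERATE_IBS, 0, n_excl, degenerate=True)
    return ModelEvaluation(train_ibs, test_ibs, n_used, n_excl)


def cross_validate(
    gm: GenotypeMatrix,
    outcome: SurvivalOutcome,
    subset: list[str] | tuple[str, ...],
    plan: CvPlan,
    rule: str = "logrank-oe",
    unseen: str = "exclude",
) -> CvResult:
    """Mean training/testing IBS of a subset over the fold plan: profiles are
    derived on the out-of-fold data and scored on the held-out fold."""
    idx = _subset_indices(gm, subset)
    cell, ncells = _cell_codes(gm.codes[:, idx])
    return _cross_validate_codes(
        outcome.time, outcome.event, cell, ncells, plan.fold_of, rule, unseen
    )


def select_best_k(testing_ibs_per_k: dict[int, float]) -> int:
    """Model-selection rule on testing IBS values: global minimum, ties
    broken toward smaller k (parsimony)."""
    return _select_overall({k: (v, None) for k, v in testing_ibs_per_k.items()})


def search(
    gm: GenotypeMatrix,
    outcome: SurvivalOutcome,
    k_range: tuple[int, int] | list[int],
    plan: CvPlan,
    rule: str = "logrank-oe",
    unseen: str = "exclude",
) -> SDRSearchResult:
    """Exhaustive SDR search over all C(p, k) subsets for each k.

    Best per k minimizes mean testing IBS (ties -> lexicographic subset
    order); the overall best minimizes over k (ties -> smaller k). The
    winning model is refit on the full cohort for the published-style
    profile table.
    """
    if isinstance(k_range, tuple):
        k_list = list(range(k_range[0], k_range[1] + 1))
    else:
        k_list = list(k_range)
    p = gm.codes.shape[1]
    if not k_list or min(k_list) < 1 or max(k_list) > p:
        raise ValueError(f"k_range must be within [1, {p}] and non-empty")
    best_per_k_idx, log = _search_codes(
        gm.codes, outcome.time, outcome.event, k_list, plan.fold_of, rule, unseen
    )
    snp_ids = gm.snp_ids
    best_per_k: dict[int, SDRModel] = {}
    for k, (subset_idx, tr, te) in best_per_k_idx.items():
        names = tuple(snp_ids[j] for j in subset_idx)
        best_per_k[k] = SDRModel(k, names, None, tr, te)
    k_star = _select_overall({k: (m.test_ibs, None) for k, m in best_per_k.items()})
    best = best_per_k[k_star]
    best.assignment = derive_profiles(gm, outcome, best.snp_subset, rule=rule)
    evaluations = [
        (tuple(snp_ids[j] for j in s), tr, te) for (s, tr, te) in log
    ]
    return SDRSearchResult(best_per_k, best, evaluations)


def model_logrank_chi2(
    gm: GenotypeMatrix,
    outcome: SurvivalOutcome,
    assignment: ProfileAssignment,
) -> float:
    """Full-data log-rank chi-square between the model's two profiles."""
    profile = subject_profiles(gm, assignment)
    keep = profile != 0
    if len(np.unique(profile[keep])) < 2:
        return 0.0
    return _logrank_2group(
        outcome.time[keep], outcome.event[keep], (profile[keep] == 1).astype(np.int64)
    )


def permutation_test(
    gm: GenotypeMatrix,
    outcome: SurvivalOutcome,
    k: int,
    plan: CvPlan,
    B: int = 1000,
    seed: int = 0,
    rule: str = "logrank-oe",
    observed: float | None = None,
) -> PermutationResult:
    """Permutation significance of the selected k-way model.

    The observed statistic is the full-data log-rank chi-square between the
    favorable and unfavorable profiles of the best k-way model. Each
    permutation jointly permutes (time, event) rows against the genotype
    rows, re-runs the full search at the same k with the same fold plan,
    refits the winner on the permuted full data, and recomputes the
    statistic. p = (1 + #{perm >= observed}) / (B + 1).
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    codes = gm.codes
    times, events = outcome.time, outcome.event
    k_list = [k]
    if observed is None:
        best, _ = _search_codes(codes, times, events, k_list, plan.fold_of, rule)
        subset = best[k][0]
        observed = _observed_stat(codes, times, events, subset, rule)
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    n = len(times)
    for b in range(B):
        perm = rng.permutation(n)
        t_p, e_p = times[perm], events[perm]
        best, _ = _search_codes(codes, t_p, e_p, k_list, plan.fold_of, rule)
        stats[b] = _observed_stat(codes, t_p, e_p, best[k][0], rule)
    p = (1.0 + np.sum(stats >= observed - 1e-12)) / (B + 1.0)
    return PermutationResult(float(p), float(observed), B, stats)


def _observed_stat(codes, times, events, subset_idx, rule) -> float:
    cell, ncells = _cell_codes(codes[:, subset_idx])
    keep = cell >= 0
    labels, _, _, _ = _classify_cells(
        times[keep], events[keep], cell[keep], ncells, rule
    )
    profile = np.zeros(len(times), dtype=np.int8)
    profile[keep] = labels[cell[keep]]
    use = profile != 0
    if len(np.unique(profile[use])) < 2:
        return 0.0
    return _logrank_2group(times[use], events[use], (profile[use] == 1).astype(np.int64))
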