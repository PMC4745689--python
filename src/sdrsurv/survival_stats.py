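"""Survival statistics: Kaplan-Meier, log-rank, Cox PH under genetic codings,
and IPCW (Graf-style) Brier / Integrated Brier scoring.

Kaplan-Meier and Cox fits are backed by lifelines (Efron tie handling for
Cox — times recorded at month resolution guarantee ties). Median confidence
intervals come from inverting the log-log (exponential Greenwood) band, i.e.
the Brookmeyer-Crowley construction.

The Brier score follows Graf et al.'s inverse-probability-of-censoring
weighting: for prediction S_i(t) of subject i with observed (T_i, d_i),

    BS(t) = n^-1 sum_i [ S_i(t)^2 1{T_i <= t, d_i = 1} / G(T_i-)
                         + (1 - S_i(t))^2 1{T_i > t} / G(t) ]

with G the Kaplan-Meier estimate of the censoring distribution fitted on the
TRAINING sample only (no test leakage, including the integration bound tau).
IBS = tau^-1 * integral_0^tau BS(t) dt by the trapezoid rule over {0} union
the unique test event times (capped at tau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times

from .io_cohort import GenotypeMatrix, SurvivalOutcome

SCHEMES = ("additive", "dominant", "recessive")


@dataclass
class KmEstimate:
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    median: float
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        """Step-function lookup S(t) (right-continuous)."""
        if t < 0:
            return 1.0
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (per-covariate rows)."""

    table: pd.DataFrame  # columns: coef, hr, hr_lower, hr_upper, p
    log_likelihood: float
    n: int
    n_events: int
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


@dataclass
class GeneticCoding:
    scheme: str
    columns: pd.DataFrame
    group_sizes: dict[str, int]
    usable: bool = True


@dataclass
class BrierCurve:
    times: np.ndarray
    bs: np.ndarray
    tau: float
    ibs: float


def kaplan_meier(outcome: SurvivalOutcome, alpha: float = 0.05) -> KmEstimate:
    """Product-limit survival estimate with Greenwood variance and
    Brookmeyer-Crowley (log-log) median CI."""
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(outcome.time, outcome.event)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy()
    med = kmf.median_survival_time_
    med_ci_df = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1])
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(float)
    # Greenwood variance of S(t)
    tab = kmf.event_table
    with np.errstate(divide="ignore", invalid="ignore"):
        term = tab["observed"] / (tab["at_risk"] * (tab["at_risk"] - tab["observed"]))
    var = (surv**2) * term.cumsum().reindex(sf.index).fillna(0).to_numpy()
    return KmEstimate(
        times=times,
        survival=surv,
        variance=var,
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        n_at_risk=at_risk,
        median=float(med),
        median_ci=(lo, hi),
    )


def logrank(outcome: SurvivalOutcome, groups: np.ndarray) -> LogRankResult:
    """Standard (unweighted) log-rank test across >= 2 non-empty groups."""
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank requires at least two non-empty groups")
    res = multivariate_logrank_test(outcome.time, groups, outcome.event)
    return LogRankResult(float(res.test_statistic), len(labels) - 1, float(res.p_value))


def cox_fit(
    outcome: SurvivalOutcome, covariates: pd.DataFrame, alpha: float = 0.05
) -> CoxFit:
    """Cox PH via partial-likelihood maximization, Efron ties, Wald CIs.

    Non-convergence or monotone likelihood (complete separation) yields a
    flagged result rather than an exception.
    """
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            raise ValueError(f"constant covariate column {col!r}")
    if outcome.n_events < 1:
        raise ValueError("Cox fit requires at least one event")
    df = covariates.reset_index(drop=True).copy()
    df["time"] = outcome.time
    df["event"] = outcome.event
    cph = CoxPHFitter(alpha=alpha)
    caught: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                fit_options={"precision": 1e-11},
            )
        caught = [str(w.message) for w in wlist]
        converged = not any("convergence" in m.lower() for m in caught)
    except ConvergenceError as err:
        return CoxFit(
            table=pd.DataFrame(
                np.nan,
                index=covariates.columns,
                columns=["coef", "hr", "hr_lower", "hr_upper", "p"],
            ),
            log_likelihood=np.nan,
            n=len(df),
            n_events=outcome.n_events,
            converged=False,
            warnings=[str(err)],
        )
    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "hr_lower": np.exp(summ["coef lower 95%"]),
            "hr_upper": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    return CoxFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=outcome.n_events,
        converged=converged,
        warnings=caught,
    )


def encode_genotype(gm: GenotypeMatrix, snp_id: str, scheme: str) -> GeneticCoding:
    """Code one SNP for regression.

    Groupings are defined with respect to the major (first-listed) allele:

    * additive — two indicators (het, hom-minor) vs hom-major reference;
    * dominant — indicator {hom-minor} vs {hom-major, het};
    * recessive — indicator {het, hom-minor} vs {hom-major}.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    j = gm.snp_index(snp_id)
    snp = gm.panel[j]
    codes = gm.codes[:, j].astype(float)
    codes[gm.codes[:, j] < 0] = np.nan
    g_maj, g_het, g_min = (
        snp.genotype_string(0),
        snp.genotype_string(1),
        snp.genotype_string(2),
    )
    if scheme == "additive":
        cols = pd.DataFrame(
            {
                f"{snp_id}_het": (codes == 1).astype(float),
                f"{snp_id}_hom_minor": (codes == 2).astype(float),
            }
        )
        sizes = {
            g_maj: int((codes == 0).sum()),
            g_het: int((codes == 1).sum()),
            g_min: int((codes == 2).sum()),
        }
    elif scheme == "dominant":
        cols = pd.DataFrame({f"{snp_id}_dom": (codes == 2).astype(float)})
        sizes = {
            f"{g_maj}/{g_het}": int((codes <= 1).sum()),
            g_min: int((codes == 2).sum()),
        }
    else:
        cols = pd.DataFrame({f"{snp_id}_rec": (codes >= 1).astype(float)})
        sizes = {
            g_maj: int((codes == 0).sum()),
            f"{g_het}/{g_min}": int((codes >= 1).sum()),
        }
    cols[np.isnan(codes)] = np.nan
    usable = all(cols[c].dropna().nunique() > 1 for c in cols.columns)
    return GeneticCoding(scheme, cols, sizes, usable)


# ---------------------------------------------------------------------------
# IPCW Brier / integrated Brier score


def _km_step(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier step function as (event-time grid, survival values)."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - start
    deaths = np.add.reduceat(e, start)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - deaths / at_risk
    surv = np.cumprod(factors)
    return uniq, surv


def _step_eval(grid: np.ndarray, values: np.ndarray, t: np.ndarray, left: bool = False
               ) -> np.ndarray:
    """Evaluate a right-continuous step function; ``left`` gives S(t-)."""
    side = "left" if left else "right"
    idx = np.searchsorted(grid, t, side=side) - 1
    out = np.ones(len(t))
    mask = idx >= 0
    out[mask] = values[idx[mask]]
    return out


def censoring_km(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """KM of the censoring distribution G (censorings are the 'events')."""
    return _km_step(np.asarray(times, float), 1 - np.asarray(events, int))


def brier_ibs(
    train: SurvivalOutcome | tuple[np.ndarray, np.ndarray],
    test: SurvivalOutcome | tuple[np.ndarray, np.ndarray],
    predict: Callable[[np.ndarray], np.ndarray],
) -> BrierCurve:
    """Graf-style IPCW Brier curve and integrated Brier score.

    Parameters
    ----------
    train, test
        Survival samples; the censoring distribution and the integration
        bound tau always come from ``train``.
    predict
        Callable mapping an evaluation-time grid (m,) to an (n_test, m)
        matrix of predicted survival probabilities S_i(t).
    """
    tr_t, tr_e = _as_arrays(train)
    te_t, te_e = _as_arrays(test)
    g_grid, g_surv = censoring_km(tr_t, tr_e)

    ev = np.sort(np.unique(tr_t[tr_e == 1]))
    if len(ev) == 0:
        raise ValueError("no events in training data: tau undefined")
    g_at_ev = _step_eval(g_grid, g_surv, ev)
    pos = ev[g_at_ev > 0]
    if len(pos) == 0:
        raise ValueError("censoring-survival vanishes before the first event")
    tau = float(pos[-1])

    grid = np.unique(np.concatenate([[0.0], np.sort(np.unique(te_t[te_e == 1])), [tau]]))
    grid = grid[grid <= tau]

    s_pred = np.asarray(predict(grid), float)
    if s_pred.shape != (len(te_t), len(grid)):
        raise ValueError("predict must return an (n_test, n_grid) matrix")

    g_at_grid = _step_eval(g_grid, g_surv, grid)
    g_at_ti = _step_eval(g_grid, g_surv, te_t, left=True)

    bs = np.empty(len(grid))
    for j, t in enumerate(grid):
        died = (te_t <= t) & (te_e == 1)
        alive = te_t > t
        terms = np.zeros(len(te_t))
        terms[died] = s_pred[died, j] ** 2 / g_at_ti[died]
        if g_at_grid[j] > 0:
            terms[alive] = (1.0 - s_pred[alive, j]) ** 2 / g_at_grid[j]
        bs[j] = terms.mean()
    ibs = float(np.trapezoid(bs, grid) / tau) if tau > 0 else float("nan")
    return BrierCurve(times=grid, bs=bs, tau=tau, ibs=ibs)


def _as_arrays(x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, SurvivalOutcome):
        return x.time, x.event
    t, e = x
    return np.asarray(t, float), np.asarray(e, int)
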