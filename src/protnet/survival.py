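"""Prognostic validation of component activities.

The signature-building procedure, per component activity:

1. rank components by the log-rank p of a Kaplan-Meier split of the cohort
   into high- and low-risk groups at an activity percentile cutoff;
2. validate the candidate with a univariate Cox regression and a
   leave-one-out (LOO) cross-validated risk assignment: each sample's risk
   label comes from a model fitted without it (refit direction + refit
   percentile threshold);
3. refer the cross-validated (signed, directional) log-rank statistic of the
   LOO risk groups to a permutation null built by re-running the *entire*
   LOO procedure on B permutations of the survival data against the
   activities, giving
   ``permutation_p = (1 + #{perm stat >= observed}) / (B + 1)``.

The "adverse" direction of an activity (whether high or low values carry
risk) is the sign of the fitted Cox coefficient; ties at the percentile
cutoff go to the low-risk group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fastcox import CoxStructure, logrank_p
from .errors import DomainError, InsufficientDataError
from .group_stats import ClinicalTable

logger = logging.getLogger(__name__)

from scipy import stats as _stats


@dataclass(frozen=True)
class CoxResult:
    coef: float
    hazard_ratio: float
    se: float
    p_value: float  # score test
    converged: bool
    flagged: bool  # monotone likelihood / non-convergence


@dataclass
class SurvivalResult:
    component_id: str
    hazard_ratio: float
    coef: float
    cox_p: float
    km_logrank_p: float
    risk_threshold: float  # percentile used for the reported split
    permutation_p: float
    observed_statistic: float
    risk_labels: pd.Series  # 'low' / 'high' per sample (LOO-assigned)
    n_permutations: int
    seed: int
    converged: bool


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def km_logrank(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    if events.sum() == 0:
        raise InsufficientDataError("zero events; log-rank undefined")
    struct = CoxStructure(times, events)
    chi2 = float(struct.logrank_multi((labels == uniq[1])[None, :])[0])
    return chi2, float(logrank_p(chi2))


def cox_univariate(times, events, covariate) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, score-test p).

    Monotone likelihood or non-convergence yields a flagged result rather
    than an exception.
    """
    covariate = np.asarray(covariate, float)
    if not np.isfinite(covariate).all():
        raise DomainError("non-finite covariate")
    events = np.asarray(events, bool)
    if events.sum() < 2:
        raise InsufficientDataError("need at least 2 events for a Cox fit")
    struct = CoxStructure(times, events)
    beta, info, converged = struct.fit(covariate)
    u0, i0 = struct.score_test(covariate)
    if i0[0] > 0:
        p = float(_stats.chi2.sf(u0[0] ** 2 / i0[0], df=1))
    else:
        p = 1.0
    flagged = not bool(converged[0])
    if flagged:
        logger.warning("Cox fit flagged (monotone likelihood or non-convergence)")
    se = float(1.0 / np.sqrt(info[0])) if info[0] > 0 else np.inf
    return CoxResult(
        coef=float(beta[0]),
        hazard_ratio=float(np.exp(beta[0])),
        se=se,
        p_value=p,
        converged=bool(converged[0]),
        flagged=flagged,
    )


def dichotomize_risk(
    activity: pd.Series,
    clinical: ClinicalTable | None = None,
    threshold_percentile: float = 50.0,
    direction: int | None = None,
) -> pd.Series:
    """Split samples into 'high'/'low' risk at an activity percentile.

    The adverse side is given by ``direction`` (sign of the Cox coefficient);
    when it is not supplied, a univariate Cox fit on ``clinical`` determines
    it.  Samples exactly at the cutoff are labelled low-risk.
    """
    if not (0.0 < threshold_percentile < 100.0):
        raise ValueError("threshold_percentile must be in (0, 100)")
    values = activity.to_numpy(float)
    if np.all(values == values[0]):
        raise DomainError("degenerate activity: all samples equal")
    if direction is None:
        if clinical is None:
            raise ValueError("either clinical data or an explicit direction is required")
        aligned = clinical.df.loc[activity.index]
        direction = 1 if cox_univariate(
            aligned["time"], aligned["event"], values
        ).coef >= 0 else -1
    cutoff = np.percentile(values, threshold_percentile)
    high = values > cutoff if direction >= 0 else values < cutoff
    return pd.Series(np.where(high, "high", "low"), index=activity.index)


# ---------------------------------------------------------------------------
# LOO + permutation validation
# ---------------------------------------------------------------------------

def _loo_statistics(
    struct: CoxStructure,
    loo_coeffs: list[np.ndarray],
    X: np.ndarray,
    percentiles: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated log-rank statistic for each covariate row of X.

    For each left-out sample i the direction is the sign of the LOO Cox score
    at beta = 0 (equals the MLE sign) and the cutoff the given percentile of
    the remaining activities; the row's statistic is the *signed* standardised
    log-rank excess of the assembled high-risk group, maximised over
    ``percentiles`` (a single-element array in the fixed-split mode).  The
    signed form keeps the test directional: an assignment whose "high-risk"
    patients do *better* than expected scores negative instead of producing a
    large spurious chi-square.  Returns (statistics, best-percentile index
    per row).
    """
    m, n = X.shape
    n_pct = len(percentiles)
    labels = np.zeros((n_pct, m, n), bool)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        Xi = X[:, mask]                      # (m, n-1)
        dirs = Xi @ loo_coeffs[i]            # (m,)
        cuts = np.percentile(Xi, percentiles, axis=1)  # (n_pct, m)
        xi = X[:, i]
        pos = dirs >= 0
        for q in range(n_pct):
            labels[q, :, i] = np.where(pos, xi > cuts[q], xi < cuts[q])
    stats_all = np.empty((n_pct, m))
    for q in range(n_pct):
        stats_all[q] = struct.logrank_signed(labels[q])
    best = stats_all.argmax(axis=0)
    return stats_all.max(axis=0), best


def loo_permutation_validate(
    activities: pd.DataFrame,
    clinical: ClinicalTable,
    B: int = 1000,
    seed: int = 0,
    threshold_percentile: float = 50.0,
    scan: tuple[float, float, float] | None = None,
) -> list[SurvivalResult]:
    """Leave-one-out, permutation-validated prognostic test per component.

    ``activities`` is components x samples.  ``scan`` optionally gives
    (low, high, step) percentiles to scan — e.g. (30, 70, 5) — in which case
    the observed statistic is the best split *and* every permutation repeats
    the same scan, so the selection is built into the null.  Deterministic
    given ``seed``.  Components whose full-data Cox fit fails to converge
    are skipped with a log entry.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    clinical.check_samples(activities.columns)
    aligned = clinical.df.loc[activities.columns]
    times = aligned["time"].to_numpy(float)
    events = aligned["event"].to_numpy(bool)
    n = len(times)
    struct = CoxStructure(times, events)
    if scan is not None:
        lo, hi, step = scan
        percentiles = np.arange(lo, hi + 1e-9, step)
    else:
        percentiles = np.array([threshold_percentile])

    # LOO score-coefficient vectors depend only on (time, event): reuse
    loo_coeffs = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        if events[mask].sum() == 0:
            loo_coeffs.append(np.zeros(n - 1))
        else:
            loo_coeffs.append(CoxStructure(times[mask], events[mask]).score0_coeffs())

    ss = np.random.SeedSequence(seed)
    results = []
    for comp_seed, (cid, row) in zip(ss.spawn(len(activities)), activities.iterrows()):
        x = row.to_numpy(float)
        fit = cox_univariate(times, events, x)
        if fit.flagged:
            logger.warning("component %s: Cox fit did not converge; skipped", cid)
            continue
        rng = np.random.default_rng(comp_seed)
        X = np.empty((B + 1, n))
        X[0] = x
        for b in range(1, B + 1):
            X[b] = x[rng.permutation(n)]
        stats_arr, best = _loo_statistics(struct, loo_coeffs, X, percentiles)
        observed = stats_arr[0]
        perm_p = float((1 + np.sum(stats_arr[1:] >= observed)) / (B + 1))

        # reported split / labels: observed LOO assignment at best percentile
        best_pct = float(percentiles[best[0]])
        lab = _loo_labels_single(x, loo_coeffs, best_pct)
        full_split = dichotomize_risk(
            row, threshold_percentile=best_pct,
            direction=1 if fit.coef >= 0 else -1,
        )
        km_stat, km_p = km_logrank(times, events, full_split.to_numpy())
        results.append(
            SurvivalResult(
                component_id=str(cid),
                hazard_ratio=fit.hazard_ratio,
                coef=fit.coef,
                cox_p=fit.p_value,
                km_logrank_p=km_p,
                risk_threshold=best_pct,
                permutation_p=perm_p,
                observed_statistic=float(observed),
                risk_labels=pd.Series(
                    np.where(lab, "high", "low"), index=activities.columns
                ),
                n_permutations=B,
                seed=seed,
                converged=fit.converged,
            )
        )
    return results


def _loo_labels_single(
    x: np.ndarray, loo_coeffs: list[np.ndarray], percentile: float
) -> np.ndarray:
    n = len(x)
    lab = np.zeros(n, bool)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        xi = x[mask]
        direction = xi @ loo_coeffs[i]
        cut = np.percentile(xi, percentile)
        lab[i] = x[i] > cut if direction >= 0 else x[i] < cut
    return lab


def rank_components_by_survival(
    activities: pd.DataFrame,
    clinical: ClinicalTable,
    threshold_percentile: float = 50.0,
) -> pd.DataFrame:
    """Rank components by the log-rank p of their dichotomised activity.

    Per component: Cox fit gives the adverse direction, the cohort is split
    at the percentile cutoff, and the two-group log-rank p is computed.
    Sorted by p ascending, ties broken by |log HR| descending.
    """
    clinical.check_samples(activities.columns)
    aligned = clinical.df.loc[activities.columns]
    rows = []
    for cid, row in activities.iterrows():
        fit = cox_univariate(aligned["time"], aligned["event"], row.to_numpy(float))
        labels = dichotomize_risk(
            row, threshold_percentile=threshold_percentile,
            direction=1 if fit.coef >= 0 else -1,
        )
        stat, p = km_logrank(
            aligned["time"], aligned["event"], labels.to_numpy()
        )
        rows.append(
            {
                "component_id": cid,
                "km_logrank_p": p,
                "km_statistic": stat,
                "coef": fit.coef,
                "hazard_ratio": fit.hazard_ratio,
                "cox_p": fit.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["abs_log_hr"] = out["coef"].abs()
    out = out.sort_values(
        ["km_logrank_p", "abs_log_hr"], ascending=[True, False]
    ).drop(columns="abs_log_hr").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def risk_by_subtype(result: SurvivalResult, clinical: ClinicalTable) -> pd.DataFrame:
    """Cross-tabulate LOO risk labels by subtype (report-shaped table)."""
    sub = clinical.df.loc[result.risk_labels.index, "subtype"]
    tab = pd.crosstab(sub, result.risk_labels)
    for col in ("low", "high"):
        if col not in tab.columns:
            tab[col] = 0
    return tab[["low", "high"]]
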