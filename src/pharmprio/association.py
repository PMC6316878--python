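"""Per-variant association statistics.

* Pearson chi-square test of genotype group vs therapy response (no
  continuity correction).
* Kaplan-Meier estimation and the k-group log-rank test for disease-free
  survival, with administrative truncation at a 120-month study horizon.
* A permutation engine producing Monte-Carlo adjusted p-values: outcomes are
  relabelled (optionally within strata), the raw test is recomputed, and the
  adjusted p is the add-one-smoothed proportion of permuted raw p-values at
  or below the observed one.  Defaults: 1000 permutations for response,
  100 for survival.
* Multivariate adjustment: Cox proportional hazards (Efron ties, lifelines)
  and binary logistic regression (statsmodels), both reporting a
  likelihood-ratio p for the variant term.
* Classical multiplicity corrections (Bonferroni, Holm, Hochberg, Hommel,
  Benjamini-Hochberg FDR).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DFS_HORIZON_MONTHS = 120.0
DEFAULT_RESPONSE_PERMUTATIONS = 1000
DEFAULT_SURVIVAL_PERMUTATIONS = 100

_P_TOL = 1e-12  # tolerance when comparing permuted p-values to the observed one


class DegenerateTableError(ValueError):
    """Contingency table with a zero row or column total."""


# ---------------------------------------------------------------------------
# response: Pearson chi-square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p_value: float


def response_chisq(table: np.ndarray) -> ChisqResult:
    """Pearson chi-square on a genotype-group x responder/non-responder table.

    X^2 = sum (O - E)^2 / E without continuity correction;
    df = (rows - 1) * (cols - 1); upper-tail chi-square p.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(f"need a 2-D table with >=2 rows/cols, got {table.shape}")
    if (table < 0).any():
        raise ValueError("negative cell counts")
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise DegenerateTableError("zero row or column total")
    expected = np.outer(row_tot, col_tot) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return ChisqResult(stat, df, float(stats.chi2.sf(stat, df)))


def contingency_from_labels(groups: np.ndarray, outcome: np.ndarray) -> np.ndarray:
    """Group x outcome count table from per-sample integer labels.

    Rows are groups 0..max(groups), columns outcomes 0..max(outcome); entries
    with a negative label on either side are dropped.
    """
    groups = np.asarray(groups)
    outcome = np.asarray(outcome)
    keep = (groups >= 0) & (outcome >= 0)
    groups, outcome = groups[keep], outcome[keep]
    n_g = int(groups.max()) + 1 if groups.size else 0
    n_o = int(outcome.max()) + 1 if outcome.size else 0
    table = np.zeros((n_g, n_o), dtype=int)
    np.add.at(table, (groups, outcome), 1)
    return table


# ---------------------------------------------------------------------------
# survival: truncation, Kaplan-Meier, log-rank
# ---------------------------------------------------------------------------

def truncate_dfs(
    months: np.ndarray, events: np.ndarray, horizon: float = DFS_HORIZON_MONTHS
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the study-horizon rule: times above ``horizon`` are set to the
    horizon and censored; everything else (the boundary included) is kept."""
    months = np.asarray(months, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (months < 0).any():
        raise ValueError("negative survival times")
    over = months > horizon
    return np.where(over, horizon, months), np.where(over, False, events)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate as a right-continuous step function.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S = 1 before the
    first event.  Subjects censored exactly at an event time count as at risk
    at that time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def rmst(self, horizon: float = DFS_HORIZON_MONTHS) -> float:
        """Restricted mean survival time: area under the curve on [0, horizon]."""
        times = np.concatenate(([0.0], self.event_times, [horizon]))
        surv = np.concatenate(([1.0], self.survival, [self.survival_at(horizon)]))
        keep = times <= horizon
        times, surv = times[keep], surv[keep]
        if times[-1] < horizon:
            times = np.append(times, horizon)
            surv = np.append(surv, surv[-1])
        return float(np.sum(np.diff(times) * surv[:-1]))


def km_estimate(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier estimate for one group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    event_times = np.unique(times[events])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    n_events = np.array([((times == t) & events).sum() for t in event_times], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - n_events / at_risk) if event_times.size else np.array([])
    return SurvivalCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        censor_times=np.sort(times[~events]),
        n_subjects=int(times.size),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    flagged: bool = False
    note: str = ""


def logrank(groups: list[tuple[np.ndarray, np.ndarray]]) -> LogrankResult:
    """k-group log-rank test with hypergeometric variance; df = k - 1.

    ``groups`` is a list of (times, events) pairs.  If no events occur at all
    the test is undefined; p = 1 is returned with a flag.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    times_list, events_list = [], []
    for t, e in groups:
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError("empty group in log-rank test")
        times_list.append(t)
        events_list.append(e)
    all_event_times = np.unique(np.concatenate([t[e] for t, e in zip(times_list, events_list)]))
    if all_event_times.size == 0:
        return LogrankResult(0.0, k - 1, 1.0, flagged=True, note="no events in any group")
    observed = np.zeros(k)
    expected = np.zeros(k)
    variance = np.zeros((k, k))
    for t in all_event_times:
        n_at_risk = np.array([(tt >= t).sum() for tt in times_list], dtype=float)
        d_events = np.array(
            [((tt == t) & ee).sum() for tt, ee in zip(times_list, events_list)], dtype=float
        )
        n_tot = n_at_risk.sum()
        d_tot = d_events.sum()
        observed += d_events
        expected += d_tot * n_at_risk / n_tot
        if n_tot > 1:
            frac = n_at_risk / n_tot
            variance += (
                d_tot
                * (n_tot - d_tot)
                / (n_tot - 1)
                * (np.diag(frac) - np.outer(frac, frac))
            )
    z = (observed - expected)[:-1]
    v = variance[:-1, :-1]
    stat = float(z @ np.linalg.pinv(v) @ z)
    stat = max(stat, 0.0)
    return LogrankResult(stat, k - 1, float(stats.chi2.sf(stat, k - 1)))


def km_curve_table(curves: dict[int, SurvivalCurve]) -> pd.DataFrame:
    """Flatten per-group KM curves into a step-function table (one row per
    event time: group, time, survival, at-risk, events) for TSV export."""
    rows = []
    for g, c in sorted(curves.items()):
        rows.append({"group": g, "time": 0.0, "survival": 1.0,
                     "at_risk": c.n_subjects, "n_events": 0})
        for t, s, n, d in zip(c.event_times, c.survival, c.at_risk, c.n_events):
            rows.append({"group": g, "time": float(t), "survival": float(s),
                         "at_risk": int(n), "n_events": int(d)})
    return pd.DataFrame(rows, columns=["group", "time", "survival", "at_risk", "n_events"])


def km_by_group(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> dict[int, SurvivalCurve]:
    """Kaplan-Meier curve per group label (negative labels dropped)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    out = {}
    for g in sorted(set(groups[groups >= 0].tolist())):
        mask = groups == g
        out[int(g)] = km_estimate(times[mask], events[mask])
    return out


# ---------------------------------------------------------------------------
# permutation-adjusted p-values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    raw_p: float
    adjusted_p: float
    n_permutations: int
    exact: bool = False
    flagged: bool = False
    note: str = ""


def _response_p(outcome: np.ndarray, groups: np.ndarray) -> float:
    table = contingency_from_labels(groups, outcome)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    return response_chisq(table).p_value


def _dfs_p(outcome: np.ndarray, groups: np.ndarray) -> float:
    # outcome rows are (time, event)
    per_group = [
        (outcome[groups == g, 0], outcome[groups == g, 1].astype(bool))
        for g in sorted(set(groups.tolist()))
    ]
    return logrank(per_group).p_value


def perm_adjust(
    test,
    outcome_data,
    genotype_groups: np.ndarray,
    n_permutations: int | None = None,
    strata: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    exact: bool = False,
) -> PermutationResult:
    """Permutation-adjusted p-value for one variant.

    Parameters
    ----------
    test
        ``"response"`` (chi-square on group x outcome counts), ``"dfs"``
        (log-rank across groups), or a callable ``f(outcome, groups) -> p``.
    outcome_data
        For response, a vector of 0/1 outcome labels.  For dfs, a
        ``(times, events)`` pair permuted jointly.
    genotype_groups
        Integer group label per sample; negative labels are excluded.
    n_permutations
        Monte-Carlo sample size B; defaults to 1000 (response) / 100 (dfs).
    strata
        Optional stratum label per sample; outcomes are permuted within
        strata only.
    exact
        Enumerate every within-stratum arrangement instead of sampling
        (small n only); the adjusted p is then the exact proportion of
        arrangements with a raw p at or below the observed one.

    Monte-Carlo adjusted p uses add-one smoothing:
    (1 + #{permuted p <= observed p}) / (B + 1).
    """
    groups = np.asarray(genotype_groups)
    if test == "response":
        outcome = np.asarray(outcome_data)
        stat_fn = _response_p
        default_b = DEFAULT_RESPONSE_PERMUTATIONS
    elif test == "dfs":
        t, e = outcome_data
        outcome = np.column_stack([np.asarray(t, dtype=float), np.asarray(e, dtype=float)])
        stat_fn = _dfs_p
        default_b = DEFAULT_SURVIVAL_PERMUTATIONS
    elif callable(test):
        outcome = np.asarray(outcome_data)
        stat_fn = test
        default_b = DEFAULT_RESPONSE_PERMUTATIONS
    else:
        raise ValueError(f"unknown test: {test!r}")

    keep = groups >= 0
    groups = groups[keep]
    outcome = outcome[keep]
    n = groups.size
    if strata is not None:
        strata = np.asarray(strata)[keep]
    else:
        strata = np.zeros(n, dtype=int)
    if n == 0:
        raise ValueError("no samples after removing missing genotypes")

    b = int(n_permutations) if n_permutations is not None else default_b
    if b < 1 and not exact:
        raise ValueError("n_permutations must be >= 1")

    raw_p = stat_fn(outcome, groups)

    flat = outcome.reshape(n, -1)
    degenerate = bool((flat == flat[0]).all())
    if degenerate:
        return PermutationResult(raw_p, 1.0, 0, exact=exact, flagged=True,
                                 note="constant outcome; all permutations identical")

    stratum_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    if exact:
        counts = [math.factorial(len(ix)) for ix in stratum_idx]
        total = math.prod(counts)
        if total > 500_000:
            raise ValueError(f"exact enumeration infeasible: {total} arrangements")
        n_le = 0
        perm = np.empty(n, dtype=int)
        for combo in itertools.product(*(itertools.permutations(ix) for ix in stratum_idx)):
            for ix, arrangement in zip(stratum_idx, combo):
                perm[ix] = arrangement
            p = stat_fn(outcome[perm], groups)
            if p <= raw_p + _P_TOL:
                n_le += 1
        return PermutationResult(raw_p, n_le / total, total, exact=True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_le = 0
    perm = np.arange(n)
    for _ in range(b):
        for ix in stratum_idx:
            perm[ix] = rng.permutation(ix)
        p = stat_fn(outcome[perm], groups)
        if p <= raw_p + _P_TOL:
            n_le += 1
    adjusted = (1 + n_le) / (b + 1)
    return PermutationResult(raw_p, adjusted, b)


# ---------------------------------------------------------------------------
# multivariate adjustment
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """Shared shape of Cox and logistic fits for the variant term."""

    coef: float
    ratio: float          # hazard ratio (Cox) or odds ratio (logistic)
    ci_low: float
    ci_high: float
    lrt_p: float
    covariates: list[str] = field(default_factory=list)
    flagged: bool = False
    note: str = ""


CoxFit = RegressionFit
LogisticFit = RegressionFit


def _as_covariate_frame(covariates, n: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n))
    if isinstance(covariates, pd.DataFrame):
        return covariates.reset_index(drop=True)
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in covariates.items()})


def cox_fit(times, events, variant_dose, covariates=None) -> CoxFit:
    """Cox proportional-hazards fit of the variant dose, optionally adjusted.

    Efron tie handling; the p-value is a likelihood-ratio test of the model
    with vs without the variant term; HR with a Wald 95% CI.
    Non-convergence or monotone likelihood yields a flagged result instead of
    an exception.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < 1:
        return CoxFit(np.nan, np.nan, np.nan, np.nan, 1.0, flagged=True, note="no events")
    covs = _as_covariate_frame(covariates, times.size)
    df = pd.DataFrame({"time": times, "event": events.astype(int),
                       "dose": np.asarray(variant_dose, dtype=float)})
    for c in covs.columns:
        df[c] = covs[c].to_numpy()
    note = ""
    flagged = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            full = CoxPHFitter()
            full.fit(df, duration_col="time", event_col="event")
            if covs.shape[1] > 0:
                reduced = CoxPHFitter()
                reduced.fit(df.drop(columns=["dose"]), duration_col="time", event_col="event")
                ll_reduced = reduced.log_likelihood_
            else:
                ll_reduced = None
        for w in caught:
            if "converg" in str(w.message).lower() or "monoton" in str(w.message).lower():
                flagged = True
                note = str(w.message).splitlines()[0]
    except ConvergenceError as exc:
        return CoxFit(np.nan, np.nan, np.nan, np.nan, 1.0,
                      covariates=list(covs.columns), flagged=True, note=str(exc))
    coef = float(full.params_["dose"])
    se = float(full.standard_errors_["dose"])
    zcrit = stats.norm.ppf(0.975)
    if ll_reduced is None:
        lrt_stat = full.log_likelihood_ratio_test().test_statistic
    else:
        lrt_stat = 2.0 * (full.log_likelihood_ - ll_reduced)
    lrt_p = float(stats.chi2.sf(max(lrt_stat, 0.0), 1))
    return CoxFit(
        coef=coef,
        ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zcrit * se)),
        ci_high=float(np.exp(coef + zcrit * se)),
        lrt_p=lrt_p,
        covariates=list(covs.columns),
        flagged=flagged,
        note=note,
    )


def logistic_fit(response, variant_dose, covariates=None) -> LogisticFit:
    """Binary logistic regression of response on the variant dose.

    Likelihood-ratio p for the variant term; OR with Wald 95% CI.  Perfect
    separation is flagged, never silently estimated.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(response, dtype=float)
    dose = np.asarray(variant_dose, dtype=float)
    covs = _as_covariate_frame(covariates, y.size)
    x_full = np.column_stack([np.ones(y.size), dose] + [covs[c].to_numpy() for c in covs])
    x_reduced = np.column_stack([np.ones(y.size)] + [covs[c].to_numpy() for c in covs])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, x_full).fit(disp=0, maxiter=200)
            reduced = sm.Logit(y, x_reduced).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, 1.0,
                           covariates=list(covs.columns), flagged=True, note=str(exc))
    coef = float(full.params[1])
    se = float(full.bse[1])
    flagged = False
    note = ""
    if not full.mle_retvals.get("converged", True) or abs(coef) > 15 or not np.isfinite(se):
        flagged = True
        note = "non-convergence or separation suspected"
    lrt_stat = 2.0 * (full.llf - reduced.llf)
    lrt_p = float(stats.chi2.sf(max(lrt_stat, 0.0), 1))
    zcrit = stats.norm.ppf(0.975)
    return LogisticFit(
        coef=coef,
        ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zcrit * se)),
        ci_high=float(np.exp(coef + zcrit * se)),
        lrt_p=lrt_p,
        covariates=list(covs.columns),
        flagged=flagged,
        note=note,
    )


# ---------------------------------------------------------------------------
# multiplicity corrections
# ---------------------------------------------------------------------------

_MULTITEST_METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "fdr_bh": "fdr_bh",
}


def p_adjust(p_values, method: str = "bonferroni") -> np.ndarray:
    """Adjust a p-value vector for multiplicity; results are clipped to 1."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0,1]")
    if method not in _MULTITEST_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_MULTITEST_METHODS)}")
    _, adjusted, _, _ = multipletests(p, method=_MULTITEST_METHODS[method])
    return np.minimum(adjusted, 1.0)


# ---------------------------------------------------------------------------
# per-variant result container
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Raw and permutation-adjusted association for one variant/endpoint."""

    variant_id: str
    test: str  # "response_chisq" | "dfs_logrank"
    raw_p: float
    adjusted_p: float
    n_permutations: int
    group_names: list[str] = field(default_factory=list)
    group_counts: list[int] = field(default_factory=list)
    strata: str = ""
    flagged: bool = False
    note: str = ""
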