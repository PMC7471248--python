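"""Cohort-level statistics: exclusions, associations, and survival models.

This module mirrors the statistical workflow of a TSR prognostic study on
a cohort table (synthetic or user-supplied): exclusion filtering with
priority-ordered counting, baseline group comparisons (chi-squared /
rank-sum), multivariate logistic association with the low-stromal-component
label, Cox proportional-hazards modeling with univariate screening and
forward selection, Kaplan-Meier estimation, the log-rank test, and
TSR-stratified survival analysis within TNM stage.

Model fitting is delegated to lifelines (Cox with Efron tie handling,
Kaplan-Meier) and statsmodels (logistic regression); this module owns the
screening, selection, and stratification logic around them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .labels import CATEGORIES
from .synthdata import EXCLUSION_FLAGS

__all__ = [
    "RegressionResult",
    "ModelSelectionResult",
    "SurvivalCurve",
    "TestResult",
    "StratumResult",
    "apply_exclusions",
    "baseline_compare",
    "logistic_association",
    "cox_model",
    "km_estimate",
    "logrank_test",
    "stratified_tsr_analysis",
]


@dataclass(frozen=True)
class RegressionResult:
    """One model term: coefficient, ratio (OR/HR) with Wald CI, p-value."""

    term: str
    estimate: float  # log-OR or log-HR
    ratio: float     # exp(estimate)
    ci_low: float
    ci_high: float
    p_value: float
    note: str | None = None


@dataclass(frozen=True)
class ModelSelectionResult:
    """Univariate screen plus the multivariate model built from it."""

    univariate: tuple[RegressionResult, ...]
    screened: tuple[str, ...]      # candidates passing the univariate screen
    selected: tuple[str, ...]      # terms in the final multivariate model
    multivariate: tuple[RegressionResult, ...]
    warning: str | None = None


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    test: str


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance."""

    times: np.ndarray          # distinct event/censor times, ascending
    survival: np.ndarray       # S(t) at each time (right-continuous steps)
    at_risk: np.ndarray        # risk-set size just before each time
    variance: np.ndarray       # Greenwood variance of S(t)

    def step_function(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate S(t) at arbitrary times (S=1 before the first time)."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if np.ndim(t) else float(out[0])


@dataclass(frozen=True)
class StratumResult:
    """One TNM stratum: KM curve per TSR category plus the log-rank test."""

    stratum: str
    curves: Mapping[str, SurvivalCurve]
    group_sizes: Mapping[str, int]
    logrank: TestResult


def apply_exclusions(
    roster: pd.DataFrame, flag_order: Sequence[str] = EXCLUSION_FLAGS
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a roster by its exclusion flags.

    A patient is excluded iff any flag is true; each excluded patient is
    counted once, under the first true flag in ``flag_order`` (the study's
    listing priority), so multi-flag patients are not double counted.
    Returns the included cohort and the per-category exclusion counts.
    """
    missing = [f for f in flag_order if f not in roster.columns]
    if missing:
        raise KeyError(f"roster is missing exclusion flag columns: {missing}")
    flags = roster[list(flag_order)].astype(bool)
    excluded_any = flags.any(axis=1)
    counts: dict[str, int] = {}
    remaining = excluded_any.copy()
    for name in flag_order:
        hit = flags[name] & remaining
        counts[name] = int(hit.sum())
        remaining &= ~hit
    included = roster.loc[~excluded_any].reset_index(drop=True)
    return included, counts


def baseline_compare(
    cohort: pd.DataFrame,
    grouping: str,
    variable: str,
    kind: str = "auto",
    correction: bool = False,
) -> TestResult:
    """Compare a variable's distribution across groups.

    Categorical variables use Pearson's chi-squared on the contingency
    table (no continuity correction by default); ordered/continuous ones
    use the Wilcoxon rank-sum (two groups) or Kruskal-Wallis test.
    """
    groups = cohort[grouping]
    values = cohort[variable]
    levels = pd.unique(groups.dropna())
    if len(levels) < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than 2 groups")
    if kind == "auto":
        kind = "continuous" if pd.api.types.is_float_dtype(values) else "categorical"
    if kind == "categorical":
        table = pd.crosstab(groups, values)
        zero_rows = table.index[(table.sum(axis=1) == 0)].tolist()
        zero_cols = table.columns[(table.sum(axis=0) == 0)].tolist()
        if zero_rows or zero_cols:
            raise ValueError(f"empty contingency margins: rows {zero_rows}, cols {zero_cols}")
        chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
        return TestResult(float(chi2), float(dof), float(p), "chi2")
    samples = [values[groups == g].to_numpy(dtype=float) for g in levels]
    if len(samples) == 2:
        stat, p = stats.ranksums(samples[0], samples[1])
        return TestResult(float(stat), 1.0, float(p), "ranksum")
    stat, p = stats.kruskal(*samples)
    return TestResult(float(stat), float(len(samples) - 1), float(p), "kruskal")


def _wald_results(params, bse, pvalues, terms, scale_z: float = 1.959963984540054) -> list[RegressionResult]:
    out = []
    for term in terms:
        beta = float(params[term])
        se = float(bse[term])
        note = None
        if not math.isfinite(se) or se > 50:
            note = "unstable estimate (possible separation)"
        out.append(
            RegressionResult(
                term=term,
                estimate=beta,
                ratio=math.exp(beta),
                ci_low=math.exp(beta - scale_z * se),
                ci_high=math.exp(beta + scale_z * se),
                p_value=float(pvalues[term]),
                note=note,
            )
        )
    return out


def _fit_logit(cohort: pd.DataFrame, outcome: str, terms: Sequence[str]):
    import statsmodels.api as sm

    x = sm.add_constant(cohort[list(terms)].astype(float), has_constant="add")
    y = cohort[outcome].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, x).fit(disp=0, maxiter=200)


def logistic_association(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "low_stromal",
    entry_p: float = 0.05,
) -> ModelSelectionResult:
    """Logistic association of covariates with the low-stromal outcome.

    Each candidate is screened in a univariate logistic fit; candidates
    with Wald p below ``entry_p`` enter a single multivariate fit, whose
    odds ratios and Wald CIs are reported.  Perfect separation is flagged
    on the affected term rather than raised.
    """
    if not candidates:
        raise ValueError("at least one candidate covariate is required")
    if set(pd.unique(cohort[outcome])) - {0, 1}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    univariate = []
    for term in candidates:
        fit = _fit_logit(cohort, outcome, [term])
        univariate.extend(_wald_results(fit.params, fit.bse, fit.pvalues, [term]))
    screened = tuple(r.term for r in univariate if r.p_value < entry_p)
    warning = None
    if not screened:
        warning = "no candidate passed the univariate screen; returning univariate table"
        return ModelSelectionResult(tuple(univariate), (), (), (), warning)
    fit = _fit_logit(cohort, outcome, screened)
    multi = tuple(_wald_results(fit.params, fit.bse, fit.pvalues, screened))
    return ModelSelectionResult(tuple(univariate), screened, screened, multi, warning)


def _fit_cox(cohort: pd.DataFrame, terms: Sequence[str], time_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()  # Efron tie handling is the lifelines default
    data = cohort[[time_col, event_col, *terms]].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col=time_col, event_col=event_col)
    return cph


def cox_model(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    time_col: str = "os_months",
    event_col: str = "event",
    screen_p: float = 0.1,
    forward: bool = True,
    entry_p: float = 0.05,
) -> ModelSelectionResult:
    """Cox proportional-hazards modeling with screening and forward selection.

    Every candidate gets a univariate Cox fit; candidates with p below
    ``screen_p`` become eligible for the multivariate model.  With
    ``forward=True`` terms are added greedily by the partial-likelihood-
    ratio test (entry at p < ``entry_p``; ties broken by candidate order);
    otherwise all screened terms are fitted together.  Hazard ratios carry
    Wald CIs; ties are handled by Efron's method.
    """
    if not candidates:
        raise ValueError("at least one candidate covariate is required")
    if int(cohort[event_col].sum()) < 1:
        raise ValueError("at least one observed event is required")

    univariate: list[RegressionResult] = []
    null_ll: float | None = None
    for term in candidates:
        fit = _fit_cox(cohort, [term], time_col, event_col)
        s = fit.summary.loc[term]
        if null_ll is None:
            null_ll = fit.log_likelihood_ - fit.log_likelihood_ratio_test().test_statistic / 2.0
        univariate.append(
            RegressionResult(
                term=term,
                estimate=float(s["coef"]),
                ratio=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p_value=float(s["p"]),
            )
        )
    screened = tuple(r.term for r in univariate if r.p_value < screen_p)
    if not screened:
        return ModelSelectionResult(
            tuple(univariate), (), (), (),
            warning="no candidate passed the univariate screen; returning univariate table",
        )

    if not forward:
        selected = list(screened)
    else:
        selected = []
        current_ll = float(null_ll)
        remaining = list(screened)
        while remaining:
            best = None  # (p, order_index, term, fit)
            for idx, term in enumerate(remaining):
                try:
                    fit = _fit_cox(cohort, selected + [term], time_col, event_col)
                except Exception:
                    continue  # collinear with already-selected terms: cannot enter
                lr = 2.0 * (fit.log_likelihood_ - current_ll)
                p = float(stats.chi2.sf(max(lr, 0.0), df=1))
                if best is None or (p, idx) < (best[0], best[1]):
                    best = (p, idx, term, fit)
            if best is None or best[0] >= entry_p:
                break
            selected.append(best[2])
            current_ll = float(best[3].log_likelihood_)
            remaining.remove(best[2])
        if not selected:
            return ModelSelectionResult(
                tuple(univariate), screened, (), (),
                warning="forward selection admitted no term",
            )

    fit = _fit_cox(cohort, selected, time_col, event_col)
    multi = []
    for term in selected:
        s = fit.summary.loc[term]
        multi.append(
            RegressionResult(
                term=term,
                estimate=float(s["coef"]),
                ratio=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p_value=float(s["p"]),
            )
        )
    return ModelSelectionResult(tuple(univariate), screened, tuple(selected), tuple(multi))


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    Subjects censored at t leave the risk set just after t (standard
    risk-set convention).  Returned arrays are indexed by the distinct
    observed times (events and censorings), ascending.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size < 1:
        raise ValueError("at least one subject is required")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and kmf.event_table.iloc[0][["observed", "censored"]].sum() == 0 else kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
    surv = np.array([kmf.predict(x) for x in grid], dtype=float)
    variance = surv**2 * np.cumsum(frac)
    return SurvivalCurve(times=grid, survival=surv, at_risk=at_risk, variance=variance)


def logrank_test(
    group_times: Sequence[Sequence[float]], group_events: Sequence[Sequence[int]]
) -> TestResult:
    """Log-rank test across two or more groups (observed-minus-expected)."""
    if len(group_times) < 2 or len(group_times) != len(group_events):
        raise ValueError("need matching times/events for at least 2 groups")
    durations, events, groups = [], [], []
    for g, (ts, es) in enumerate(zip(group_times, group_events)):
        ts = np.asarray(ts, dtype=float)
        es = np.asarray(es, dtype=int)
        if ts.size == 0:
            raise ValueError(f"group {g} has no subjects")
        durations.append(ts)
        events.append(es)
        groups.append(np.full(ts.size, g))
    durations, events, groups = map(np.concatenate, (durations, events, groups))
    if events.sum() < 1:
        raise ValueError("at least one observed event is required")
    res = multivariate_logrank_test(durations, groups, events)
    return TestResult(
        statistic=float(res.test_statistic),
        df=float(len(group_times) - 1),
        p_value=float(res.p_value),
        test="logrank",
    )


def stratified_tsr_analysis(
    cohort: pd.DataFrame,
    stage_col: str = "tnm_stage",
    category_col: str = "tsr_category",
    time_col: str = "os_months",
    event_col: str = "event",
) -> dict[str, StratumResult]:
    """KM curves and log-rank test for TSR categories within each TNM stage.

    Strata containing a single TSR category are skipped with a warning.
    Returns one :class:`StratumResult` per stage, keyed by stage label.
    """
    for col in (stage_col, category_col, time_col, event_col):
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing column {col!r}")
    results: dict[str, StratumResult] = {}
    for stage in sorted(cohort[stage_col].dropna().unique(), key=str):
        sub = cohort[cohort[stage_col] == stage]
        cats = [c for c in CATEGORIES if (sub[category_col] == c).any()]
        if len(cats) < 2:
            warnings.warn(
                f"stratum {stage!r} has a single TSR category; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        curves = {}
        sizes = {}
        times, events = [], []
        for cat in cats:
            grp = sub[sub[category_col] == cat]
            curves[cat] = km_estimate(grp[time_col], grp[event_col])
            sizes[cat] = len(grp)
            times.append(grp[time_col].to_numpy())
            events.append(grp[event_col].to_numpy())
        results[str(stage)] = StratumResult(
            stratum=str(stage),
            curves=curves,
            group_sizes=sizes,
            logrank=logrank_test(times, events),
        )
    return results
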