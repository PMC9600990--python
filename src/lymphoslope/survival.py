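"""Survival statistics: Kaplan-Meier, log-rank, Cox with AIC backward elimination.

The estimators themselves are delegated to lifelines (KaplanMeierFitter,
logrank_test, CoxPHFitter with Efron tie handling); this module wraps them
in the cohort's vocabulary and adds the AIC-driven backward elimination
used for multivariate model building, plus the two-group characteristics
comparison (chi-square for categorical variables; t-test or Wilcoxon
rank-sum for continuous variables, routed by a Shapiro-Wilk normality
gate).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .endpoints import SurvivalEndpoint
from .exosome import wilcoxon_ranksum

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxTerm",
    "CoxFit",
    "GroupComparison",
    "km_estimate",
    "km_at",
    "logrank",
    "cox_backward",
    "group_compare",
]


def _unpack(endpoints: Sequence[SurvivalEndpoint]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([e.time for e in endpoints], dtype=float)
    ev = np.array([e.event for e in endpoints], dtype=bool)
    return t, ev


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival and at-risk counts at each event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int
    max_time: float  # last observed time (event or censoring)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float


@dataclass(frozen=True)
class CoxTerm:
    name: str
    coefficient: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class CoxFit:
    terms: tuple[CoxTerm, ...]
    aic: float
    n_events: int
    aic_trace: tuple[float, ...] = ()  # AIC after each elimination step (starts at full model)

    def term(self, name: str) -> CoxTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "coef": t.coefficient,
                    "hr": t.hazard_ratio,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p": t.p_value,
                }
                for t in self.terms
            ]
        )


def km_estimate(endpoints: Sequence[SurvivalEndpoint]) -> KMCurve:
    """Kaplan-Meier product-limit estimator (ties handled as simultaneous events)."""
    if len(endpoints) == 0:
        raise ValueError("endpoints must be non-empty")
    t, ev = _unpack(endpoints)
    kmf = KaplanMeierFitter().fit(t, ev)
    table = kmf.event_table
    mask = table["observed"] > 0
    times = table.index.to_numpy(dtype=float)[mask.to_numpy()]
    surv = kmf.survival_function_["KM_estimate"].reindex(times).to_numpy(dtype=float)
    at_risk = table.loc[mask, "at_risk"].to_numpy(dtype=float)
    n_ev = table.loc[mask, "observed"].to_numpy(dtype=float)
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_ev,
        n=len(endpoints),
        max_time=float(t.max()),
    )


def km_at(curve: KMCurve, t: float) -> float:
    """Survival probability at time t (step function; 1 before the first event)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > curve.max_time:
        warnings.warn(
            f"t={t} beyond last observed time {curve.max_time}; extrapolating the "
            "last estimate",
            stacklevel=2,
        )
    idx = int(np.searchsorted(curve.event_times, t, side="right")) - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank(
    group_a: Sequence[SurvivalEndpoint], group_b: Sequence[SurvivalEndpoint]
) -> LogRankResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("each group must be non-empty")
    ta, ea = _unpack(group_a)
    tb, eb = _unpack(group_b)
    if ea.sum() + eb.sum() == 0:
        return LogRankResult(statistic=0.0, p_value=1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def _null_partial_loglik(t: np.ndarray, ev: np.ndarray) -> float:
    """Efron partial log-likelihood of the covariate-free model (all betas 0)."""
    ll = 0.0
    for time in np.unique(t[ev]):
        d = int(((t == time) & ev).sum())
        r = int((t >= time).sum())
        ll -= sum(np.log(r - j) for j in range(d))
    return ll


def _fit_cox(df: pd.DataFrame, cols: list[str]) -> tuple[CoxPHFitter | None, float]:
    """Fit a Cox model on the given columns; (None, inf) if it cannot converge."""
    if not cols:
        ll0 = _null_partial_loglik(df["T"].to_numpy(), df["E"].to_numpy(bool))
        return None, -2.0 * ll0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df[cols + ["T", "E"]], duration_col="T", event_col="E")
        return cph, float(cph.AIC_partial_)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None, float("inf")


def cox_backward(
    covariates: pd.DataFrame,
    endpoints: Sequence[SurvivalEndpoint],
    allow_empty: bool = True,
) -> CoxFit:
    """Cox proportional hazards with AIC-driven backward elimination.

    Starts from the model containing every column of ``covariates`` and
    repeatedly removes the term whose removal most decreases the partial
    AIC, stopping when no removal improves it. A model that fails to
    converge (e.g. perfectly collinear covariates) is treated as having
    infinite AIC, so elimination resolves collinearity naturally.
    Hazard-ratio confidence intervals are 95% Wald; ties use Efron's
    method (the lifelines default).
    """
    t, ev = _unpack(endpoints)
    if ev.sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    df = covariates.reset_index(drop=True).copy()
    cols = list(df.columns)
    df["T"], df["E"] = t, ev.astype(int)

    current = list(cols)
    fit, aic = _fit_cox(df, current)
    trace = [aic]
    while current:
        best_cols, best_fit, best_aic = None, None, aic
        for c in current:
            cand = [x for x in current if x != c]
            if not cand and not allow_empty:
                continue
            f, a = _fit_cox(df, cand)
            if a < best_aic - 1e-10:
                best_cols, best_fit, best_aic = cand, f, a
        if best_cols is None:
            break
        current, fit, aic = best_cols, best_fit, best_aic
        trace.append(aic)
    if not np.isfinite(aic):
        raise ConvergenceError(
            "no Cox model converged; check covariates for separation/collinearity"
        )

    terms: tuple[CoxTerm, ...] = ()
    if fit is not None:
        s = fit.summary
        terms = tuple(
            CoxTerm(
                name=str(ix),
                coefficient=float(row["coef"]),
                hazard_ratio=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
            )
            for ix, row in s.iterrows()
        )
    return CoxFit(terms=terms, aic=float(aic), n_events=int(ev.sum()), aic_trace=tuple(trace))


class ComparisonTest(str, enum.Enum):
    CHI_SQUARE = "chi_square"
    T_TEST = "t_test"
    WILCOXON = "wilcoxon"


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    test_used: ComparisonTest
    statistic: float
    p_value: float
    flag: str = ""


@dataclass(frozen=True)
class GroupComparison:
    rows: tuple[ComparisonRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "test": r.test_used.value,
                    "statistic": r.statistic,
                    "p": r.p_value,
                    "flag": r.flag,
                }
                for r in self.rows
            ]
        )

    def row(self, variable: str) -> ComparisonRow:
        for r in self.rows:
            if r.variable == variable:
                return r
        raise KeyError(variable)


def group_compare(
    data: pd.DataFrame,
    group_labels: Sequence,
    categorical: Sequence[str] = (),
    continuous: Sequence[str] = (),
    yates: bool = False,
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Table-1 style two-group comparison of cohort characteristics.

    Categorical variables use the chi-square test on the contingency table
    (uncorrected unless ``yates``); continuous variables use Welch's t-test
    when both groups pass Shapiro-Wilk normality at ``normality_alpha``,
    otherwise the Wilcoxon rank-sum test.
    """
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq.size}")
    a_mask, b_mask = labels == uniq[0], labels == uniq[1]
    rows: list[ComparisonRow] = []
    for var in categorical:
        ct = pd.crosstab(data[var], labels)
        flag = ""
        # a category absent from one group is fine; a category with zero total
        # cannot occur in crosstab, but guard single-category tables
        if ct.shape[0] < 2:
            rows.append(ComparisonRow(var, ComparisonTest.CHI_SQUARE, 0.0, 1.0, "single category"))
            continue
        chi2, p, _, expected = stats.chi2_contingency(ct.to_numpy(), correction=yates)
        if (expected == 0).any():
            flag = "zero expected cell"
        rows.append(ComparisonRow(var, ComparisonTest.CHI_SQUARE, float(chi2), float(p), flag))
    for var in continuous:
        x = data.loc[a_mask, var].dropna().to_numpy(dtype=float)
        y = data.loc[b_mask, var].dropna().to_numpy(dtype=float)
        normal = (
            len(x) >= 3
            and len(y) >= 3
            and stats.shapiro(x).pvalue > normality_alpha
            and stats.shapiro(y).pvalue > normality_alpha
        )
        if normal:
            res = stats.ttest_ind(x, y, equal_var=False)
            rows.append(ComparisonRow(var, ComparisonTest.T_TEST, float(res.statistic), float(res.pvalue)))
        else:
            stat, p = wilcoxon_ranksum(x, y)
            rows.append(ComparisonRow(var, ComparisonTest.WILCOXON, float(stat), float(p)))
    return GroupComparison(rows=tuple(rows))
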