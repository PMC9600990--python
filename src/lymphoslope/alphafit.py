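"""Constrained exponential-decay fitting of serial lymphocyte counts.

Each patient's absolute lymphocyte counts (ALC) during chemoradiotherapy
are fitted to

    ALC(t) = a1 * exp(-alpha * t) + e1,        a1 >= 0,  e1 >= e1_floor > 0

where t is days since the first radiotherapy fraction. ``alpha`` (1/day)
is the depletion slope — the candidate immune-capacity biomarker — ``e1``
the estimated nadir under continued irradiation, and ``a2 = a1 + e1`` the
estimated pre-treatment ALC.

The fit is a profile search: for every alpha on a dense grid over
[alpha_min, alpha_max], the amplitude and offset (a1, e1) solve a
box-constrained linear least-squares problem in closed form (the active-set
cases of a 2-variable convex QP). Candidates are ranked by R^2 and, among
the ``top_k`` best-fitting candidates, the *lowest* alpha is selected.
This ranked-candidates-then-lowest-alpha rule makes the estimator
conservative: when several decay rates explain the data almost equally
well, the shallowest slope is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import ALCSeries, CohortTable

__all__ = [
    "FitConfig",
    "CandidateFit",
    "ExpDecayFit",
    "DegenerateFitError",
    "profile_fit",
    "fit_alpha",
    "predict",
    "fit_cohort",
    "CohortFitResult",
]


class DegenerateFitError(ValueError):
    """The series cannot support a fit (e.g. zero variance, R^2 undefined)."""


@dataclass(frozen=True)
class FitConfig:
    """Grid-search configuration for the decay-rate profile fit.

    alpha_min/alpha_max bound the admissible slope (1/day); grid_step sets
    the search resolution (0.0005 gives 381 candidates over [0.01, 0.2]);
    top_k is the size of the best-R^2 candidate pool from which the lowest
    alpha is selected; e1_floor (cells/uL) makes the strict positivity of
    the nadir computable.
    """

    alpha_min: float = 0.01
    alpha_max: float = 0.2
    grid_step: float = 0.0005
    top_k: int = 10
    e1_floor: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_min < self.alpha_max):
            raise ValueError("need 0 < alpha_min < alpha_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.e1_floor <= 0:
            raise ValueError("e1_floor must be > 0")

    def grid(self) -> np.ndarray:
        n = int(math.floor((self.alpha_max - self.alpha_min) / self.grid_step + 1e-9)) + 1
        return self.alpha_min + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class CandidateFit:
    alpha: float
    a1: float
    e1: float
    r_squared: float


@dataclass(frozen=True)
class ExpDecayFit:
    """Selected fit plus the ranked candidate pool behind the selection rule."""

    selected: CandidateFit
    candidates: tuple[CandidateFit, ...]  # ranked by R^2 descending

    @property
    def a2(self) -> float:
        """Estimated pre-treatment ALC, a1 + e1 (the curve at t = 0)."""
        return self.selected.a1 + self.selected.e1

    @property
    def alpha(self) -> float:
        return self.selected.alpha

    @property
    def e1(self) -> float:
        return self.selected.e1

    @property
    def a1(self) -> float:
        return self.selected.a1

    @property
    def r_squared(self) -> float:
        return self.selected.r_squared


def _profile_grid(
    days: np.ndarray, values: np.ndarray, alphas: np.ndarray, e1_floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form constrained least squares for each alpha on the grid.

    For fixed alpha the model is linear in (a1, e1) with design columns
    {exp(-alpha*day), 1}; the constraints a1 >= 0, e1 >= e1_floor define a
    convex feasible region, so the minimiser is either the unconstrained
    normal-equations solution (if feasible) or lies on a constraint face,
    each of which has a one-line solution after clamping. Returns
    (a1, e1, r2) arrays aligned with ``alphas``.
    """
    y = values
    n = y.size
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise DegenerateFitError("zero-variance series: R^2 undefined")
    syy = float(np.sum(y * y))
    sy = float(np.sum(y))

    x = np.exp(-np.outer(alphas, days))  # (G, n)
    sx = x.sum(axis=1)
    sxx = np.einsum("ij,ij->i", x, x)
    sxy = x @ y

    def sse(a1: np.ndarray, e1: np.ndarray) -> np.ndarray:
        return (
            syy
            + a1 * a1 * sxx
            + n * e1 * e1
            - 2 * a1 * sxy
            - 2 * e1 * sy
            + 2 * a1 * e1 * sx
        )

    det = n * sxx - sx * sx
    tiny = 1e-12 * n * np.maximum(sxx, 1.0)
    safe_det = np.where(det > tiny, det, 1.0)
    a1_u = (n * sxy - sx * sy) / safe_det
    e1_u = (sy - a1_u * sx) / n
    feas = (det > tiny) & (a1_u >= 0) & (e1_u >= e1_floor)

    # face e1 = floor (a1 clamped at 0 covers the vertex)
    a1_f = np.clip((sxy - e1_floor * sx) / np.maximum(sxx, 1e-300), 0.0, None)
    e1_f = np.full_like(a1_f, e1_floor)
    # face a1 = 0 (e1 clamped at floor)
    e1_z = np.full_like(a1_f, max(e1_floor, sy / n))
    a1_z = np.zeros_like(a1_f)

    sse_f = sse(a1_f, e1_f)
    sse_z = sse(a1_z, e1_z)
    use_f = sse_f <= sse_z
    a1_b = np.where(use_f, a1_f, a1_z)
    e1_b = np.where(use_f, e1_f, e1_z)
    sse_b = np.where(use_f, sse_f, sse_z)

    a1 = np.where(feas, a1_u, a1_b)
    e1 = np.where(feas, e1_u, e1_b)
    s = np.where(feas, sse(a1_u, e1_u), sse_b)
    r2 = 1.0 - np.maximum(s, 0.0) / sst
    return a1, e1, r2


def profile_fit(alpha: float, series: ALCSeries, e1_floor: float = 1.0) -> CandidateFit:
    """Best (a1, e1) for a fixed decay rate, with a1 >= 0 and e1 >= e1_floor.

    R^2 is computed against the mean-only model (1 - SSE/SST); under the
    constraints it can be negative and is deliberately not clipped, so that
    candidate ranking remains well-defined.
    """
    a1, e1, r2 = _profile_grid(
        series.days, series.values, np.array([alpha], dtype=float), e1_floor
    )
    return CandidateFit(alpha=float(alpha), a1=float(a1[0]), e1=float(e1[0]), r_squared=float(r2[0]))


def fit_alpha(series: ALCSeries, config: FitConfig = FitConfig()) -> ExpDecayFit:
    """Grid-profile fit with the ranked-candidates / lowest-alpha selection rule.

    Profiles (a1, e1) at every alpha on the config grid, ranks candidates by
    R^2 (ties broken toward lower alpha), keeps the ``top_k`` best, and
    selects the candidate with the smallest alpha among them.
    """
    alphas = config.grid()
    a1, e1, r2 = _profile_grid(series.days, series.values, alphas, config.e1_floor)
    k = min(config.top_k, alphas.size)
    if k < config.top_k:
        import warnings

        warnings.warn(
            f"grid has only {alphas.size} points; top_k truncated to {k}", stacklevel=2
        )
    order = np.lexsort((alphas, -r2))  # R^2 desc, alpha asc on ties
    top = order[:k]
    ranked = tuple(
        CandidateFit(alpha=float(alphas[i]), a1=float(a1[i]), e1=float(e1[i]), r_squared=float(r2[i]))
        for i in top
    )
    sel = ranked[int(np.argmin([c.alpha for c in ranked]))]
    return ExpDecayFit(selected=sel, candidates=ranked)


def predict(fit: ExpDecayFit, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted curve a1*exp(-alpha*t) + e1 at time t (days)."""
    c = fit.selected
    out = c.a1 * np.exp(-c.alpha * np.asarray(t, dtype=float)) + c.e1
    return float(out) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


@dataclass
class CohortFitResult:
    """Per-patient fits plus flags for patients whose series was degenerate."""

    fits: dict[str, ExpDecayFit]
    flagged: dict[str, str] = field(default_factory=dict)
    n_points: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        """Median alpha with IQR, and median a2/e1 over the fitted patients."""
        al = np.array([f.alpha for f in self.fits.values()])
        a2 = np.array([f.a2 for f in self.fits.values()])
        e1 = np.array([f.e1 for f in self.fits.values()])
        q1, med, q3 = np.percentile(al, [25, 50, 75])
        return {
            "n_fitted": len(self.fits),
            "n_flagged": len(self.flagged),
            "alpha_median": float(med),
            "alpha_q1": float(q1),
            "alpha_q3": float(q3),
            "a2_median": float(np.median(a2)),
            "e1_median": float(np.median(e1)),
        }

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for pid, f in self.fits.items():
            recs.append(
                {
                    "patient_id": pid,
                    "alpha": f.alpha,
                    "a1": f.a1,
                    "e1": f.e1,
                    "a2": f.a2,
                    "r_squared": f.r_squared,
                    "n_points": self.n_points.get(pid),
                    "flag": "",
                }
            )
        for pid, reason in self.flagged.items():
            recs.append(
                {
                    "patient_id": pid,
                    "alpha": np.nan,
                    "a1": np.nan,
                    "e1": np.nan,
                    "a2": np.nan,
                    "r_squared": np.nan,
                    "n_points": self.n_points.get(pid),
                    "flag": reason,
                }
            )
        return pd.DataFrame.from_records(recs)

    def alpha_map(self) -> dict[str, float]:
        return {pid: f.alpha for pid, f in self.fits.items()}


def fit_cohort(table: CohortTable, config: FitConfig = FitConfig()) -> CohortFitResult:
    """Fit every patient in the cohort; degenerate series are flagged, not fatal."""
    fits: dict[str, ExpDecayFit] = {}
    flagged: dict[str, str] = {}
    n_points: dict[str, int] = {}
    for pid in table.patient_ids:
        n_points[pid] = len(table.alc_series[pid])
        try:
            fits[pid] = fit_alpha(table.alc_series[pid], config)
        except DegenerateFitError as exc:
            flagged[pid] = str(exc)
    return CohortFitResult(fits=fits, flagged=flagged, n_points=n_points)
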