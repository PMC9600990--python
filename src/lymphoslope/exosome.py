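"""Paired exosomal-mRNA analysis: TMM-normalised log2 fold changes, a
correlation screen against the slope biomarker / NLR / outcome, exhaustive
best-subset regression, and sum/difference composite scores.

The input is a genes x samples read-count matrix in which every patient
contributes exactly one pre-treatment (control) and one week-2
(treatment) sample. Genes detected in fewer than half the samples are
removed, libraries are scaled by trimmed-mean-of-M-values (TMM) factors,
and a per-patient, per-gene log2 fold change is computed on the
counts-per-million scale with a pseudocount. Downstream, genes whose fold
change correlates with the decay slope alpha or with disease-specific
death (or with both NLR and death) are screened in, an exhaustive subset
search maximises adjusted R^2 per gene count for predicting death, and
signed sums of gene fold changes form per-patient composite scores.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "CompositeScoreDef",
    "ScreenResult",
    "SubsetSearchResult",
    "filter_detected",
    "tmm_factors",
    "paired_log2fc",
    "correlation_screen",
    "best_subset",
    "composite_score",
    "wilcoxon_ranksum",
]


@dataclass
class CountMatrix:
    """Read counts (genes x samples) with a paired control/treatment sample sheet.

    ``samples`` has one row per sample with columns ``patient_id`` and
    ``role`` ("control" = pre-treatment, "treatment" = week 2), indexed by
    sample id matching the count columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            self.samples = self.samples.loc[list(self.counts.columns)]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        roles = set(self.samples["role"])
        if not roles <= {"control", "treatment"}:
            raise ValueError(f"unknown sample roles: {roles - {'control', 'treatment'}}")
        for pid, grp in self.samples.groupby("patient_id"):
            if sorted(grp["role"]) != ["control", "treatment"]:
                raise ValueError(
                    f"patient {pid} must have exactly one control and one treatment sample"
                )

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.samples["patient_id"]))

    def sample_of(self, patient_id: str, role: str) -> str:
        sel = self.samples[
            (self.samples["patient_id"] == patient_id) & (self.samples["role"] == role)
        ]
        return str(sel.index[0])

    def write(self, counts_path: str | Path, sheet_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        self.samples.to_csv(sheet_path, index_label="sample_id")

    @classmethod
    def read(cls, counts_path: str | Path, sheet_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        sheet = pd.read_csv(sheet_path, index_col="sample_id", dtype={"patient_id": str})
        return cls(counts=counts, samples=sheet)


def filter_detected(
    counts: CountMatrix, min_detect_frac: float = 0.5
) -> tuple[CountMatrix, list[str]]:
    """Remove genes with nonzero counts in fewer than ``min_detect_frac`` of samples.

    A gene nonzero in exactly the boundary fraction is retained. Returns the
    filtered matrix and the list of removed genes. Idempotent.
    """
    if counts.counts.empty:
        raise ValueError("count matrix is empty")
    frac = (counts.counts > 0).mean(axis=1)
    keep = frac >= min_detect_frac
    removed = list(counts.counts.index[~keep])
    return CountMatrix(counts=counts.counts.loc[keep].copy(), samples=counts.samples.copy()), removed


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise ValueError("sample shares no co-detected genes with the reference")
    o, r = obs[mask], ref[mask]
    log_r = np.log2((o / n_obs) / (r / n_ref))  # M values
    abs_e = 0.5 * (np.log2(o / n_obs) + np.log2(r / n_ref))  # A values
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)  # asymptotic var of M
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = stats.rankdata(log_r)
    rank_s = stats.rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f) if np.isfinite(f) else 1.0


def tmm_factors(
    counts: CountMatrix, logratio_trim: float = 0.30, sum_trim: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor for each library.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper quartile. M (log ratio) and A (log
    abundance) values over genes co-detected with the reference are
    trimmed (30% on M, 5% on A by default), and the factor is the
    precision-weighted mean M on the linear scale. Factors are normalised
    to have geometric mean 1, so they multiply to 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every library size must be > 0")
    f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_j:
            continue
        factors[j] = _tmm_pair(mat[:, j], mat[:, ref_j], lib[j], lib[ref_j], logratio_trim, sum_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="tmm_factor")


def paired_log2fc(
    counts: CountMatrix, factors: pd.Series | None = None, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-patient, per-gene log2 fold change treatment vs control.

    Counts are scaled to counts-per-million using TMM-effective library
    sizes (library size x factor); the pseudocount keeps all fold changes
    finite, and a gene with zero counts in both samples has log2FC 0.
    Returns a genes x patients DataFrame.
    """
    if factors is None:
        factors = tmm_factors(counts)
    lib = counts.counts.sum(axis=0)
    eff = lib * factors.reindex(counts.counts.columns)
    cpm = counts.counts / eff * 1e6
    out = {}
    for pid in counts.patient_ids:
        c = cpm[counts.sample_of(pid, "control")]
        t = cpm[counts.sample_of(pid, "treatment")]
        out[pid] = np.log2((t + pseudocount) / (c + pseudocount))
    return pd.DataFrame(out, index=counts.counts.index)


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of each row of x against the vector y."""
    n = y.size
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return r, p


@dataclass
class ScreenResult:
    table: pd.DataFrame  # gene-level correlations, selection flag, and tag
    selected: list[str]
    flagged: list[str]  # zero-variance genes excluded from the screen


def correlation_screen(
    fc: pd.DataFrame,
    alpha: Mapping[str, float] | pd.Series,
    nlr: Mapping[str, float] | pd.Series,
    dsd: Mapping[str, bool] | pd.Series,
    progression: Mapping[str, bool] | pd.Series | None = None,
    p_threshold: float = 0.05,
) -> ScreenResult:
    """Select genes whose log2FC correlates with alpha, with death, or with both NLR and death.

    Pearson correlations are computed per gene against each covariate
    (binary outcomes coded 0/1); a gene is selected iff it is significant
    (p < ``p_threshold``) against alpha, or against disease-specific death,
    or against *both* NLR and death. The progression correlation, if
    provided, is reported but does not enter the rule. Zero-variance genes
    are excluded with a flag.
    """
    pids = list(fc.columns)
    if len(pids) < 3:
        raise ValueError("need at least 3 patients for the correlation screen")
    a = np.array([float(pd.Series(alpha)[p]) for p in pids])
    nl = np.array([float(pd.Series(nlr)[p]) for p in pids])
    d = np.array([float(pd.Series(dsd)[p]) for p in pids])
    x = fc.to_numpy(dtype=float)
    var_ok = x.var(axis=1) > 0
    flagged = list(fc.index[~var_ok])
    xs = x[var_ok]
    genes = fc.index[var_ok]

    r_a, p_a = _pearson_matrix(xs, a)
    r_n, p_n = _pearson_matrix(xs, nl)
    r_d, p_d = _pearson_matrix(xs, d)
    cols = {
        "r_alpha": r_a, "p_alpha": p_a,
        "r_nlr": r_n, "p_nlr": p_n,
        "r_dsd": r_d, "p_dsd": p_d,
    }
    if progression is not None:
        pr = np.array([float(pd.Series(progression)[p]) for p in pids])
        cols["r_prog"], cols["p_prog"] = _pearson_matrix(xs, pr)

    sig_a = p_a < p_threshold
    sig_d = p_d < p_threshold
    sig_n = p_n < p_threshold
    selected_mask = sig_a | sig_d | (sig_n & sig_d)
    tags = []
    for i in range(len(genes)):
        t = []
        if sig_a[i]:
            t.append("alpha")
        if sig_d[i]:
            t.append("dsd")
        if sig_n[i] and sig_d[i]:
            t.append("nlr+dsd")
        tags.append("|".join(t))
    table = pd.DataFrame(cols, index=genes)
    table["selected"] = selected_mask
    table["tag"] = tags
    return ScreenResult(
        table=table, selected=list(genes[selected_mask]), flagged=flagged
    )


@dataclass
class SubsetSearchResult:
    """Best gene subset under the adjusted-R^2-per-gene criterion.

    ``trace`` holds, for each subset size k, the best subset of that size
    with its R^2, adjusted R^2 and score (adjusted R^2 / k).
    """

    selected_genes: list[str]
    adj_r2: float
    score: float
    trace: pd.DataFrame


def _subset_r2(xmat: np.ndarray, y: np.ndarray) -> float:
    x1 = np.column_stack([np.ones(len(y)), xmat])
    coef, *_ = np.linalg.lstsq(x1, y, rcond=None)
    resid = y - x1 @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0


def best_subset(
    candidates: Sequence[str],
    fc: pd.DataFrame,
    outcome: Mapping[str, float] | pd.Series,
    max_k: int = 15,
    budget: int = 200_000,
) -> SubsetSearchResult:
    """Exhaustive best-subset linear regression of the death indicator on gene log2FCs.

    For each size k up to ``max_k``, enumerates every k-gene subset, fits
    the linear (probability) model by least squares, and records the
    subset with the highest adjusted R^2. The returned optimum maximises
    adjusted R^2 divided by the number of genes. Raises if the total
    number of subsets exceeds ``budget`` (lower ``max_k`` in that case).
    """
    genes = list(candidates)
    if not genes:
        raise ValueError("need at least one candidate gene")
    pids = list(fc.columns)
    y = np.array([float(pd.Series(outcome)[p]) for p in pids])
    n = len(pids)
    max_k = min(max_k, len(genes), n - 2)
    if max_k < 1:
        raise ValueError("too few patients for any subset size")
    total = sum(math.comb(len(genes), k) for k in range(1, max_k + 1))
    if total > budget:
        raise ValueError(
            f"{total} subsets exceed the search budget {budget}; lower max_k"
        )
    x_all = fc.loc[genes, pids].to_numpy(dtype=float).T  # patients x genes
    rows = []
    for k in range(1, max_k + 1):
        best = None
        for combo in itertools.combinations(range(len(genes)), k):
            r2 = _subset_r2(x_all[:, combo], y)
            if best is None or r2 > best[0]:
                best = (r2, combo)
        r2, combo = best
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
        rows.append(
            {
                "k": k,
                "genes": "|".join(genes[i] for i in combo),
                "r2": r2,
                "adj_r2": adj,
                "score": adj / k,
            }
        )
    trace = pd.DataFrame(rows)
    ibest = int(trace["score"].idxmax())
    return SubsetSearchResult(
        selected_genes=trace.loc[ibest, "genes"].split("|"),
        adj_r2=float(trace.loc[ibest, "adj_r2"]),
        score=float(trace.loc[ibest, "score"]),
        trace=trace,
    )


@dataclass(frozen=True)
class CompositeScoreDef:
    """Signed gene set: score = sum of plus-gene log2FCs minus sum of minus-gene log2FCs."""

    plus_genes: frozenset[str] = frozenset()
    minus_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = set(self.plus_genes) & set(self.minus_genes)
        if overlap:
            raise ValueError(f"genes in both plus and minus sets: {sorted(overlap)}")


def composite_score(fc: pd.DataFrame, definition: CompositeScoreDef) -> pd.Series:
    """Per-patient composite score from signed sums of gene log2 fold changes."""
    missing = (set(definition.plus_genes) | set(definition.minus_genes)) - set(fc.index)
    if missing:
        raise KeyError(f"genes missing from log2FC matrix: {sorted(missing)}")
    score = pd.Series(0.0, index=fc.columns)
    for g in definition.plus_genes:
        score = score + fc.loc[g]
    for g in definition.minus_genes:
        score = score - fc.loc[g]
    score.name = "composite_score"
    return score


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when the smaller sample has at most 8
    observations and there are no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise. Returns the
    Mann-Whitney U statistic of ``x`` and the p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
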