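"""Independent oracles used by the test suite.

Each oracle recomputes a quantity through a different route than the
implementation under test: bounded least squares via scipy for the decay
profile, per-event-time hypergeometric moments for the log-rank test,
exhaustive permutation enumeration for the rank-sum test, and
statsmodels OLS for subset regression.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import lsq_linear

from lymphoslope.alphafit import FitConfig
from lymphoslope.cohort import ALCSeries


def lsq_profile(alpha: float, days: np.ndarray, values: np.ndarray, e1_floor: float):
    """Bounded linear least squares for fixed alpha (scipy route)."""
    a = np.column_stack([np.exp(-alpha * days), np.ones_like(days, dtype=float)])
    res = lsq_linear(a, values, bounds=([0.0, e1_floor], [np.inf, np.inf]), tol=1e-14)
    sse = float(np.sum((values - a @ res.x) ** 2))
    sst = float(np.sum((values - values.mean()) ** 2))
    return res.x[0], res.x[1], 1.0 - sse / sst


def oracle_fit_alpha(series: ALCSeries, config: FitConfig = FitConfig()):
    """Grid scan with scipy bounded least squares + independent selection rule.

    Returns (alpha, a1, e1, r2) of the selected candidate: among the
    ``top_k`` highest-R^2 grid points (ties toward lower alpha), the one
    with the lowest alpha.
    """
    days, values = series.days, series.values
    grid = config.grid()
    fits = [lsq_profile(al, days, values, config.e1_floor) for al in grid]
    r2 = np.array([f[2] for f in fits])
    order = sorted(range(len(grid)), key=lambda i: (-r2[i], grid[i]))
    top = order[: config.top_k]
    i = min(top, key=lambda j: grid[j])
    return grid[i], fits[i][0], fits[i][1], r2[i]


def logrank_hypergeom(t1, e1, t2, e2):
    """Two-group log-rank statistic from per-event-time hypergeometric moments."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, bool)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, bool)
    times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    o_minus_e, var = 0.0, 0.0
    for tt in times:
        n1 = int((t1 >= tt).sum())
        n2 = int((t2 >= tt).sum())
        d1 = int(((t1 == tt) & e1).sum())
        d2 = int(((t2 == tt) & e2).sum())
        n, d = n1 + n2, d1 + d2
        if n < 1 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def ranksum_exact_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    assert np.unique(combined).size == combined.size, "oracle assumes no ties"

    def u_stat(xi):
        xs = combined[list(xi)]
        ys = np.delete(combined, list(xi))
        return sum((a > b) for a in xs for b in ys)

    u_obs = u_stat(range(nx))
    us = [u_stat(c) for c in itertools.combinations(range(nx + ny), nx)]
    total = len(us)
    cdf = sum(u <= u_obs for u in us) / total
    sf = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2.0 * min(cdf, sf))


def km_hand(times, events):
    """Step-by-step product-limit estimator (returns event_times, survival)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    s = 1.0
    out_t, out_s = [], []
    for tt in np.unique(times[events]):
        n = int((times >= tt).sum())
        d = int(((times == tt) & events).sum())
        s *= 1 - d / n
        out_t.append(tt)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def best_subsets_ols(candidates, fc, y, max_k):
    """Exhaustive subset search via statsmodels OLS (independent route)."""
    import statsmodels.api as sm

    pids = list(fc.columns)
    y = np.asarray(y, float)
    x_all = fc.loc[list(candidates), pids].to_numpy(float).T
    per_k = {}
    for k in range(1, max_k + 1):
        best = None
        for combo in itertools.combinations(range(len(candidates)), k):
            model = sm.OLS(y, sm.add_constant(x_all[:, combo])).fit()
            if best is None or model.rsquared > best[0]:
                best = (model.rsquared, model.rsquared_adj, combo)
        per_k[k] = (
            tuple(candidates[i] for i in best[2]),
            best[0],
            best[1],
        )
    return per_k


def tmm_reference_recipe(counts, logratio_trim=0.30, sum_trim=0.05):
    """Step-by-step TMM factors written directly from the published recipe.

    Deliberately scalar/loop-based (no shared code with the implementation).
    """
    mat = np.asarray(counts, float)
    n_genes, n_samples = mat.shape
    lib = mat.sum(axis=0)
    f75 = []
    for j in range(n_samples):
        f75.append(np.quantile(mat[:, j] / lib[j], 0.75))
    mean75 = sum(f75) / len(f75)
    ref = min(range(n_samples), key=lambda j: abs(f75[j] - mean75))
    factors = []
    for j in range(n_samples):
        if j == ref:
            factors.append(1.0)
            continue
        ms, aas, ws = [], [], []
        for g in range(n_genes):
            o, r = mat[g, j], mat[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                ms.append(math.log2(po / pr))
                aas.append(0.5 * (math.log2(po) + math.log2(pr)))
                ws.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        if max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        lo_l = math.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = math.floor(n * sum_trim) + 1
        hi_s = n + 1 - lo_s

        def rank(vals):
            order = sorted(range(len(vals)), key=lambda i: vals[i])
            r = [0.0] * len(vals)
            i = 0
            while i < len(order):
                jj = i
                while jj + 1 < len(order) and vals[order[jj + 1]] == vals[order[i]]:
                    jj += 1
                avg = (i + jj) / 2 + 1
                for kk in range(i, jj + 1):
                    r[order[kk]] = avg
                i = jj + 1
            return r

        rm, ra = rank(ms), rank(aas)
        num = den = 0.0
        kept = False
        for i in range(n):
            if lo_l <= rm[i] <= hi_l and lo_s <= ra[i] <= hi_s:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
                kept = True
        factors.append(2.0 ** (num / den) if kept else 1.0)
    log_factors = [math.log(f) for f in factors]
    gm = math.exp(sum(log_factors) / len(log_factors))
    return [f / gm for f in factors]
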