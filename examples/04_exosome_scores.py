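"""Paired exosomal-mRNA arm: TMM log2 fold changes, screen, subset, score.

Simulates paired pre-treatment / week-2 read counts with genes planted on
alpha and NLR, normalises with TMM, screens genes by correlation, runs
the exhaustive best-subset search against the death indicator, and
compares the resulting composite score between deceased and surviving
patients with the Wilcoxon rank-sum test.
"""

import numpy as np
import pandas as pd

from lymphoslope import (
    CompositeScoreDef,
    SimulationConfig,
    best_subset,
    composite_score,
    correlation_screen,
    filter_detected,
    paired_log2fc,
    simulate_cohort,
    tmm_factors,
    wilcoxon_ranksum,
)

sim = simulate_cohort(SimulationConfig(n_patients=39, seed=12, n_genes=400))
pids = sim.cohort.patient_ids
truth = sim.truth.set_index("patient_id")
dsd = pd.Series({p: sim.cohort.outcome(p).dsd for p in pids})

filtered, removed = filter_detected(sim.counts)
factors = tmm_factors(filtered)
fc = paired_log2fc(filtered, factors)
print(f"genes kept after detection filter: {filtered.counts.shape[0]} "
      f"({len(removed)} removed)")
print(f"TMM factors span [{factors.min():.3f}, {factors.max():.3f}]")

screen = correlation_screen(
    fc, alpha=truth["alpha_true"], nlr=truth["nlr_true"], dsd=dsd
)
planted = set(sim.planted["gene"])
hits = set(screen.selected)
print(f"screen selected {len(hits)} genes; "
      f"{len(hits & planted)}/{len(planted)} planted genes among them")

candidates = screen.selected[:10]
res = best_subset(candidates, fc, dsd.astype(float), max_k=5)
print(f"best subset (adj R^2/k criterion): {res.selected_genes} "
      f"(adj R^2 = {res.adj_r2:.2f})")

score = composite_score(fc, CompositeScoreDef(plus_genes=frozenset(res.selected_genes)))
u, p = wilcoxon_ranksum(score[dsd[score.index]], score[~dsd[score.index]])
print(f"composite score, deceased vs surviving: rank-sum p = {p:.3g}")
print("\nA higher composite log2FC score in patients who died of disease mirrors")
print("the intended use of the signed gene-sum scores as survival correlates.")
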