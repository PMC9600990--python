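"""Aggressive / non-aggressive survival endpoints and the alpha reversal.

Simulates a cohort in which low alpha raises the early death hazard and
high alpha the late one, splits disease-specific deaths at the mean
time-to-death, and contrasts the alpha groups on the aggressive (DSS-A)
and non-aggressive (DSS-NA) endpoints with Kaplan-Meier rates, log-rank
tests and a Cox model.
"""

import numpy as np
import pandas as pd

from lymphoslope import (
    EndpointConfig,
    SimulationConfig,
    cohort_endpoints,
    cox_backward,
    dichotomize,
    fit_cohort,
    km_at,
    km_estimate,
    logrank,
    simulate_cohort,
    split_dsd,
)

sim = simulate_cohort(SimulationConfig(n_patients=300, seed=0, n_genes=0))
fits = fit_cohort(sim.cohort)
alpha = np.array([fits.fits[p].alpha for p in sim.cohort.patient_ids])
groups, thr = dichotomize(alpha, "median")
outcomes = [sim.cohort.outcome(p) for p in sim.cohort.patient_ids]

labels, split = split_dsd(outcomes, EndpointConfig("auto"))
n_a = sum(l.value == "aggressive" for l in labels)
n_na = sum(l.value == "non_aggressive" for l in labels)
print(f"DSD split threshold (mean time-to-death): {split:.1f} months")
print(f"aggressive deaths: {n_a}   non-aggressive deaths: {n_na}")

cfg = EndpointConfig(split)
for kind, horizon in (("dss_a", 30.0), ("dss_na", 90.0)):
    es = cohort_endpoints(outcomes, kind, cfg, labels=labels)
    hi = [e for e, g in zip(es, groups) if g == "high"]
    lo = [e for e, g in zip(es, groups) if g == "low"]
    s_hi = km_at(km_estimate(hi), horizon) * 100
    s_lo = km_at(km_estimate(lo), horizon) * 100
    lr = logrank(hi, lo)
    print(f"{kind:7s} at {horizon:.0f} mo: alpha>=med {s_hi:5.1f}%  "
          f"alpha<med {s_lo:5.1f}%  (log-rank p = {lr.p_value:.3g})")

cov = pd.DataFrame({"alpha_low": [float(g == "low") for g in groups]})
for kind in ("dss_a", "dss_na"):
    es = cohort_endpoints(outcomes, kind, cfg, labels=labels)
    fit = cox_backward(cov, es, allow_empty=False)
    t = fit.term("alpha_low")
    print(f"Cox {kind}: HR(alpha<median) = {t.hazard_ratio:.2f} "
          f"[{t.ci_low:.2f}-{t.ci_high:.2f}], p = {t.p_value:.3g}")

print("\nLow alpha raises the aggressive-death hazard (HR > 1 on DSS-A) while")
print("tending to protect on DSS-NA (HR < 1); noise in the estimated slope")
print("attenuates the late effect, so single cohorts vary around that pattern.")
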