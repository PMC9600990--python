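# lymphoslope

Radiotherapy depletes circulating lymphocytes, and how *fast* a patient's
absolute lymphocyte count (ALC) falls during concurrent chemoradiotherapy
carries prognostic information that pre-treatment counts do not.
`lymphoslope` implements, as a tested and reusable pipeline, the
exponential-slope biomarker built on that observation for cervical-cancer
chemoradiotherapy cohorts, together with the survival-endpoint framework
and the paired exosomal-mRNA scoring arm that surround it, and a synthetic
cohort generator so that every stage is testable without patient data.

It is written for biostatisticians and radiation-oncology researchers who
work from per-patient clinical CSV tables, serial ALC measurements, and
(optionally) a paired genes x samples read-count matrix.

## The model

Each patient's serial ALCs during treatment are fitted to a constrained
exponential decay in days `t` since the first radiotherapy fraction:

```
ALC(t) = a1 · exp(−α t) + e1,        a1 ≥ 0,  e1 > 0
```

* **α** (1/day) — the depletion slope, the candidate immune-capacity biomarker;
* **e1** — the asymptote, interpreted as the estimated ALC nadir under
  continued irradiation;
* **a2 = a1 + e1** — the curve at `t = 0`, the estimated pre-treatment ALC.

For every α on a dense grid over [0.01, 0.2]/day, `(a1, e1)` solve a
box-constrained least-squares problem in closed form; candidates are ranked
by R², and among the ten best-fitting candidates the **lowest** α is
selected — a deliberately conservative rule that reports the shallowest
slope when several explain the data almost equally well.

Downstream, disease-specific deaths (DSD) are split at a time threshold
(by default the mean time-to-death among the deaths, ~30 months) into an
*aggressive* and a *non-aggressive* class, defining the cause-specific
endpoints DSS-A and DSS-NA alongside DSS and PFS. These are analysed with
Kaplan–Meier curves, log-rank tests, and Cox proportional-hazards models
with AIC-driven backward elimination. The exosome arm computes per-patient
TMM-normalised log2 fold changes (week-2 vs pre-treatment), screens genes
by Pearson correlation against α / NLR / death, finds the gene subset
maximising adjusted R² per gene by exhaustive search, and forms signed
sum/difference composite scores compared by Wilcoxon rank-sum test.

## Worked example

`examples/` contains one narrative script per capability. Fitting a noisy
series simulated from α = 0.09/day (`examples/01_fit_decay_slope.py`)
prints:

```
alpha      = 0.0895 /day   (depletion slope; truth was 0.09)
a2 = a1+e1 =  1589.3 cells/uL (estimated pre-treatment ALC)
e1         =   185.6 cells/uL (estimated nadir under continued RT)
R^2        = 0.9989
```

The recovered slope matches the truth to about half a percent of its
range, and `a2`/`e1` land near the simulated pre-treatment count and
nadir. On the survival side (`examples/03_survival_endpoints.py`, 300
simulated patients in which low α multiplies the early death hazard and
high α the late one):

```
dss_a   at 30 mo: alpha>=med  85.3%  alpha<med  70.7%  (log-rank p = 0.00257)
dss_na  at 90 mo: alpha>=med  49.9%  alpha<med  89.1%  (log-rank p = 0.00273)
Cox dss_a: HR(alpha<median) = 2.16 [1.29-3.60], p = 0.00326
Cox dss_na: HR(alpha<median) = 0.37 [0.19-0.73], p = 0.00403
```

— the hazard ratio of the low-α group flips across the 30-month split,
which is precisely the pattern the aggressive/non-aggressive endpoint
framework is designed to expose.

A full run over CSV inputs (or a simulated stand-in) is one call:

```bash
lymphoslope full --simulate 300 --seed 1 --outdir run/
# or: lymphoslope full --clinical clinical.csv --alc alc.csv --outdir run/
```

writing tidy CSVs (per-patient fits, derived variables, KM curves,
log-rank and Cox tables, screen/subset/score outputs) plus a `run_log.json`
with the package version, config hash and seed needed to reproduce the
bundle bit-for-bit.

## Layout

| Module | Role |
| --- | --- |
| `lymphoslope.cohort` | domain types, CSV ingestion, imputation, min-ALC, dichotomization |
| `lymphoslope.alphafit` | the constrained exponential-slope fitter and selection rule |
| `lymphoslope.endpoints` | DSD aggressive/non-aggressive split; DSS/DSS-A/DSS-NA/PFS |
| `lymphoslope.survival` | Kaplan–Meier, log-rank, Cox + AIC backward elimination, group tables |
| `lymphoslope.exosome` | detection filter, TMM, paired log2FC, screen, best subset, composite scores |
| `lymphoslope.simulate` | seeded synthetic cohorts with known truth |
| `lymphoslope.pipeline` / `cli` | end-to-end orchestration and the thin command line |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and their provenance, and known limitations.
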