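# Methods

## The decay model and the selection rule

Serial absolute lymphocyte counts (ALC, cells/uL) measured during
chemoradiotherapy are modelled per patient as

    ALC(t) = a1 · exp(−α t) + e1,     a1 ≥ 0,   e1 ≥ e1_floor > 0,

with `t` in days since the first radiotherapy fraction. The time origin
and unit are a modelling choice: with days, the plausible slope range
[0.01, 0.2]/day spans half-lives from about 3 to 70 days, which brackets
what weekly blood draws over an eight-week course can resolve.

The fit is a profile search. For each α on a grid over
[`alpha_min`, `alpha_max`] (defaults 0.01–0.2, step 0.0005 → 381
candidates), the model is linear in `(a1, e1)` and the box-constrained
least-squares minimiser is found in closed form by checking the
unconstrained normal-equations solution and, where infeasible, each
constraint face with the other coordinate clamped — the complete KKT case
set of a two-variable convex QP. R² is computed against the mean-only
model (1 − SSE/SST); under the constraints it can be negative and is kept
unclipped so that the candidate ranking stays well-defined.

Candidates are ranked by R², ties broken toward lower α, and among the
`top_k = 10` best the **lowest** α is selected. Two consequences are worth
stating plainly:

* With a dense grid, the top-10 pool around a sharp optimum is simply the
  ten nearest grid points, so the selected α sits up to ~`top_k`·`grid_step`
  (0.005/day) *below* the R²-maximising α — even on noiseless data, where
  the top-ranked candidate recovers the truth exactly (R² = 1, parameters
  to numerical tolerance). The rule trades a small systematic shrinkage
  for robustness against over-steep fits, and the tests distinguish the
  two facets: exact recovery is asserted for the top-ranked candidate,
  a `top_k`-step bound for the selected one.
* On data the model cannot fit at all (e.g. non-decaying noise where the
  best amplitude is a1 = 0 at every α), the R² profile is exactly flat and
  any α is an equally good selection; the implementation then returns the
  grid minimum via the tie-break. Oracle comparisons treat members of such
  tie classes as equivalent.

`e1 > 0` is made computable as `e1 ≥ e1_floor` (default 1 cell/uL);
`a1 ≥ 0` enforces that fitted curves decay. `a2 = a1 + e1` is reported as
the estimated pre-treatment ALC and `e1` as the estimated nadir under
continued irradiation.

## Derived clinical variables

* **Min-ALC** — minimum ALC among measurements within 40 days of RT start;
  the window is closed at day 40. No measurement in the window yields a
  missing value with a warning rather than a silent global minimum.
* **Imputation** — only `pre_alc` and `nlr` may be missing; missing values
  are replaced by the cohort median of observed values (standard sample
  median, midpoint convention for even counts). Any other missing field is
  a validation error.
* **Dichotomization** — at the sample median by default, or at a supplied
  constant; values equal to the threshold go to the "high" group, matching
  the ≥/-< group-label convention of cohort characteristic tables.
* Patients with fewer than three ALC measurements cannot identify three
  parameters and are excluded at read time into a logged exclusion table.

## Endpoints

Disease-specific deaths are split at `split_months` — `"auto"` uses the
mean time-to-death among the deaths (~30 months in the motivating
setting) — into aggressive (death strictly before the threshold; a death
at exactly the threshold is non-aggressive) and non-aggressive classes.
Endpoints, all timed from the end of treatment:

* **DSS** — any disease-specific death is an event;
* **DSS-A / DSS-NA** — only the corresponding class is an event; a death
  of the other class is censored at its death time (the cause-specific
  convention; a `censor_mode="threshold"` switch censors at the split
  instead, since the original analyses do not state their convention);
* **PFS** — first of progression or disease-specific death; the composite
  is the conventional definition, adopted because the endpoint is named
  but never defined in the source analyses.

These definitions guarantee two assertable identities: every death is
labelled exactly once, and DSS events = DSS-A events + DSS-NA events.

## Survival statistics

Kaplan–Meier, log-rank and Cox estimation are delegated to lifelines;
this package contributes the cohort vocabulary and the model-building
loop. Backward elimination is AIC-driven: from the full model, the term
whose removal most decreases the partial AIC is dropped until no removal
helps; a non-converging model (e.g. perfectly collinear covariates) is
treated as infinite-AIC, which resolves collinearity without special
casing, and the covariate-free model's partial likelihood is computed
directly so elimination may terminate empty. Ties use Efron's method
(month-resolution data has many), hazard-ratio intervals are 95% Wald.
Group comparison tables use the uncorrected chi-square test for
categorical variables (a Yates flag exists), and route continuous
variables to Welch's t-test or the Wilcoxon rank-sum test by a
Shapiro–Wilk gate at 0.05 per group.

The rank-sum test uses exact enumeration when the smaller sample has ≤ 8
observations without ties, and the tie-corrected normal approximation
with continuity correction otherwise.

## Exosomal-mRNA arm

Input is a genes x samples count matrix with exactly one pre-treatment
(control) and one week-2 (treatment) sample per patient. Genes with
nonzero counts in fewer than 50% of samples are removed (a gene at
exactly 50% is kept). Libraries are scaled by trimmed-mean-of-M-values
(TMM) factors implemented from the published recipe — reference sample by
upper-quartile closest to the mean, 30% trim on M, 5% on A, inverse
(asymptotic) variance weighting, factors normalised to geometric mean 1 —
and cross-checked in the test suite against edgeR's `calcNormFactors` to
1e-6. Fold changes are computed per patient on the counts-per-million
scale with a pseudocount of 0.5 (configurable; CPM and the pseudocount
are choices the source analyses leave unstated).

The correlation screen selects genes whose log2FC is Pearson-significant
(p < 0.05, configurable) against α, or against the death indicator, or
against both NLR and death; progression correlations are reported but do
not enter the rule. The subset search regresses the 0/1 death indicator
on gene log2FCs — a linear probability model, the only reading consistent
with ranking subsets by adjusted R² — exhaustively over all subsets up to
`max_k`, and the reported optimum maximises adjusted R² divided by the
subset size. Composite scores are signed sums of gene log2FCs and are
linear in the fold-change matrix by construction.

## Synthetic cohort generator

The generator is the package's study-conditions oracle: it produces data
with the statistical structure the analysis assumes, with known truth.

* **ALC series** — per-patient `(α, a1, e1)` from log-normals with medians
  0.08/day, 1485 and 144 cells/uL (σ of log 0.51, 0.40, 1.0), anchored to
  published cohort medians and interquartile ranges; measurement counts
  3 + Poisson(2) capped at 18 (median 5); a jittered weekly schedule over
  56 days; multiplicative log-normal noise with CV 0.10; values floored
  at 1 cell/uL. α truth is clipped to [0.012, 0.195] so recovery is
  measured within the fitter's admissible range.
* **Outcomes** — piecewise-exponential time to disease-specific death:
  monthly hazard `h_early = 0.003` before the 30-month split, multiplied
  by 2.5 for below-median α and by 2.5 for at-or-above-median NLR;
  `h_late = 0.003` after the split, multiplied by 2.5 for high α. The
  early-hazard baseline was set so the fraction of early deaths matches
  the ~14% reported in the motivating cohort. Follow-up is censored
  administratively, staggered uniformly between 40% and 100% of 96
  months (mean ≈ 67 months, near the published median follow-up).
  Progression events precede death with an exponential lead time (mean 9
  months) in 80% of deaths and occur sporadically in 8% of survivors,
  with LP/DM/LP+DM type probabilities (0.23, 0.55, 0.22).
* **Expression** — negative-binomial counts (var = m + φm², φ = 0.1) on a
  log-normal gene-abundance profile; planted genes carry a true log2FC of
  `effect_slope` (default 0.8) per z-score of α or NLR plus per-(gene,
  patient) noise (sd 0.2); all other genes are null.
* **Subset-search benchmark** — `simulate_subset_candidates` plants two
  genes that share a latent confound and carry opposite-signed halves of
  the outcome signal, so their *difference* is strongly predictive while
  each alone is weak; this is the configuration the sum/difference
  composite design is meant to discover, and it makes the adjusted-R²/k
  optimum the planted pair rather than any single gene.

Hazard multipliers and effect sizes are configuration, not canon: the
generator emulates the direction and rough magnitude of the published
associations, it does not reproduce any cohort's numbers. What passing
tests show is that the pipeline recovers planted structure at realistic
noise; what they cannot show is transportability to real cohorts, where
ALC measurement schedules are informative, hazards are not piecewise
constant, covariates are correlated (e.g. stage with NLR), and expression
has batch structure the negative-binomial model omits.

## Calibration and power under the defaults

Measured by `scripts/acceptance.py` and the acceptance tests (problem
sizes chosen to estimate each rate with a ~1–2% standard error):

* with all effects off, the α-group DSS-A log-rank rejects at the nominal
  5% (400 replicates) and the screen flags ~5% of null genes;
* under the full defaults at n = 300 the DSS-A α effect is detected in
  ~94% of replicates, and the Cox coefficient of the low-α group flips
  sign between DSS-A and DSS-NA in essentially all replicates when true
  α is used. With the NLR effect switched off — fewer events — the same
  detection rate drops to ~84%, a reminder that the endpoint's power is
  driven by the early event count;
* the planted two-gene subset is the adjusted-R²/k optimum in ~94–96% of
  replicates at effect 0.8, n = 39.

## Numerical notes and limitations

* The α grid makes the selection rule deterministic and reproducible; a
  solver with restarts could find marginally higher R² off-grid but would
  make "the 10 best candidates" ill-defined.
* Degenerate series (zero variance) raise a typed error per patient and
  are flagged, not fatal, at cohort level.
* The log-rank statistic is the two-group (O−E)²/V form; with no events
  it is defined as 0 with p = 1.
* The linear probability model for the subset search can predict outside
  [0, 1]; it is used only to rank subsets, never for calibrated risk.
* No competing-risks cumulative-incidence estimators and no
  proportional-hazards diagnostics are provided; the class-specific
  censoring convention treats the competing death class as
  non-informative censoring, which is an approximation.
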