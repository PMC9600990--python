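"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator produces, from one seeded random stream:

* serial ALC measurements decaying as ``a1*exp(-alpha*t) + e1`` with
  multiplicative log-normal noise, on a jittered weekly schedule over
  roughly eight weeks;
* clinical covariates (age, pathology mix, FIGO strata, RT field,
  treatment time, dose, NLR) with marginals anchored to a published
  chemoradiotherapy cohort (median alpha 0.08 with IQR ~[0.055, 0.11],
  median NLR 2.43, median estimated nadir ~144 cells/uL);
* survival outcomes from a piecewise-exponential hazard in which low
  alpha and high NLR raise the *early* (pre-split) death hazard while
  high alpha raises the *late* hazard — the qualitative reversal the
  endpoint split is designed to expose;
* a paired negative-binomial count matrix in which planted genes carry a
  true log2 fold change proportional to the patient's standardised alpha
  or NLR.

Every effect size is configuration, not canon: the generator emulates the
structure of the real data, it does not reproduce any cohort's numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    ALCMeasurement,
    ALCSeries,
    ClinicalCovariates,
    CohortTable,
    OutcomeRecord,
    Pathology,
    ProgressionClass,
    RTField,
    write_cohort,
)
from .exosome import CountMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_alc_series",
    "simulate_outcomes",
    "simulate_expression",
    "simulate_cohort",
    "simulate_subset_candidates",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; a fixed seed makes the cohort fully reproducible.

    Distribution parameters are log-normal (median, sigma-of-log) pairs.
    Hazards are monthly; the early/late boundary is ``split_months``.
    """

    n_patients: int = 200
    seed: int = 0

    # ALC decay truth
    alpha_median: float = 0.08  # 1/day
    alpha_sigma: float = 0.51  # reproduces IQR ~ [0.055, 0.11]
    alpha_clip: tuple[float, float] = (0.012, 0.195)
    a1_median: float = 1485.0  # cells/uL
    a1_sigma: float = 0.40
    e1_median: float = 144.0  # cells/uL
    e1_sigma: float = 1.0
    e1_clip: tuple[float, float] = (2.0, 1500.0)

    # measurement schedule
    n_meas_poisson_mean: float = 2.0  # n = 3 + Poisson, clipped at n_meas_max
    n_meas_max: int = 18
    schedule_span_days: int = 56
    noise_cv: float = 0.10  # multiplicative log-normal CV
    alc_floor: float = 1.0  # cells/uL

    # clinical covariates
    nlr_median: float = 2.43
    nlr_sigma: float = 0.60
    p_missing: float = 0.01  # chance pre_alc / nlr is recorded missing

    # survival (monthly hazards; multipliers act on the indicated group)
    h_early: float = 0.003
    h_late: float = 0.003
    hr_low_alpha_early: float = 2.5
    hr_high_nlr_early: float = 2.5
    hr_high_alpha_late: float = 2.5
    split_months: float = 30.0
    admin_censor_months: float = 96.0
    p_prog_given_dsd: float = 0.8
    prog_lead_mean_months: float = 9.0
    p_prog_censored: float = 0.08
    prog_type_probs: tuple[float, float, float] = (0.23, 0.55, 0.22)  # LP, DM, LP+DM

    # expression arm
    n_genes: int = 500
    n_planted_alpha: int = 5
    n_planted_nlr: int = 5
    effect_slope: float = 0.8  # log2FC per covariate z-score
    lfc_noise_sd: float = 0.2
    nb_dispersion: float = 0.1
    gene_logmean: float = np.log(200.0)
    gene_logsd: float = 1.2

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("alpha_sigma", "a1_sigma", "e1_sigma", "nlr_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0 or self.nb_dispersion < 0:
            raise ValueError("noise_cv and nb_dispersion must be >= 0")
        if self.split_months <= 0 or self.admin_censor_months <= 0:
            raise ValueError("time parameters must be > 0")


@dataclass
class SimulatedCohort:
    """Cohort plus ground truth: per-patient decay parameters and planted genes."""

    cohort: CohortTable
    truth: pd.DataFrame  # patient_id, alpha_true, a1_true, e1_true, nlr_true
    counts: CountMatrix | None = None
    planted: pd.DataFrame | None = None  # gene, covariate, effect

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(self.cohort, outdir / "clinical.csv", outdir / "alc.csv")
        self.truth.to_csv(outdir / "truth_registry.csv", index=False)
        if self.counts is not None:
            self.counts.write(outdir / "counts.tsv", outdir / "samples.csv")
        if self.planted is not None:
            self.planted.to_csv(outdir / "planted_genes.csv", index=False)


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(median), sigma, size))


def simulate_alc_series(
    config: SimulationConfig,
    patient_id: str,
    alpha: float,
    a1: float,
    e1: float,
    rng: np.random.Generator,
    n_measurements: int | None = None,
) -> ALCSeries:
    """One patient's ALC series: the decay curve times multiplicative noise.

    Measurement days follow a jittered weekly schedule over the treatment
    span, sorted and de-duplicated (topped up from a fixed fallback grid
    if deduplication leaves fewer than three days). Values are floored at
    1 cell/uL.
    """
    if n_measurements is None:
        n_measurements = int(min(config.n_meas_max, 3 + rng.poisson(config.n_meas_poisson_mean)))
    n_weeks = config.schedule_span_days // 7 + 1
    weeks = rng.integers(0, n_weeks, n_measurements)
    jitter = rng.integers(-2, 3, n_measurements)
    days = np.unique(np.clip(weeks * 7 + jitter, 0, config.schedule_span_days))
    fallback = iter([0, config.schedule_span_days, config.schedule_span_days // 2, 7, 21, 35])
    while days.size < 3:
        days = np.unique(np.append(days, next(fallback)))
    curve = a1 * np.exp(-alpha * days) + e1
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        curve = curve * np.exp(rng.normal(0.0, sigma, days.size))
    values = np.maximum(curve, config.alc_floor)
    return ALCSeries(
        patient_id=patient_id,
        measurements=tuple(
            ALCMeasurement(day=int(d), value=float(v)) for d, v in zip(days, values)
        ),
    )


def _piecewise_exp_time(
    rng: np.random.Generator, lam_early: float, lam_late: float, split: float
) -> float:
    """Draw an event time from a two-piece exponential hazard; inf if both rates 0."""
    u = rng.uniform()
    target = -np.log(u)
    if lam_early > 0 and target < lam_early * split:
        return target / lam_early
    target -= lam_early * split
    if lam_late <= 0:
        return np.inf
    return split + target / lam_late


def simulate_outcomes(
    config: SimulationConfig,
    alpha: np.ndarray,
    nlr: np.ndarray,
    rng: np.random.Generator,
) -> list[OutcomeRecord]:
    """Piecewise-exponential disease-specific deaths with group-specific hazards.

    Before ``split_months`` the hazard is ``h_early`` multiplied by
    ``hr_low_alpha_early`` for below-median alpha and ``hr_high_nlr_early``
    for at-or-above-median NLR; after the split it is ``h_late`` times
    ``hr_high_alpha_late`` for at-or-above-median alpha. Follow-up is
    administratively censored (staggered between 40% and 100% of
    ``admin_censor_months``). Progression events are drawn with a lead
    time before death for the deceased and sporadically for survivors.
    """
    alpha = np.asarray(alpha, dtype=float)
    nlr = np.asarray(nlr, dtype=float)
    a_med = np.median(alpha)
    n_med = np.median(nlr)
    records: list[OutcomeRecord] = []
    for i in range(alpha.size):
        lam_e = config.h_early
        if alpha[i] < a_med:
            lam_e *= config.hr_low_alpha_early
        if nlr[i] >= n_med:
            lam_e *= config.hr_high_nlr_early
        lam_l = config.h_late
        if alpha[i] >= a_med:
            lam_l *= config.hr_high_alpha_late
        t_death = _piecewise_exp_time(rng, lam_e, lam_l, config.split_months)
        censor = rng.uniform(0.4, 1.0) * config.admin_censor_months
        dsd = bool(t_death < censor)
        followup = float(min(t_death, censor))
        t_dsd = followup if dsd else None

        prog = ProgressionClass.NONE
        t_prog = None
        if dsd and rng.uniform() < config.p_prog_given_dsd:
            lead = rng.exponential(config.prog_lead_mean_months)
            t_prog = float(max(0.5, t_dsd - lead))
            t_prog = min(t_prog, t_dsd)
        elif not dsd and rng.uniform() < config.p_prog_censored:
            t_prog = float(rng.uniform(0.0, followup)) if followup > 0 else 0.0
        if t_prog is not None:
            prog = ProgressionClass(
                rng.choice(["LP", "DM", "LP+DM"], p=np.asarray(config.prog_type_probs))
            )
        records.append(
            OutcomeRecord(
                followup_months=followup,
                dsd=dsd,
                time_to_dsd_months=t_dsd,
                progression=prog,
                time_to_progression_months=t_prog,
            )
        )
    return records


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion*m^2 (Poisson when dispersion ~ 0)."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression(
    config: SimulationConfig,
    patient_ids: list[str],
    alpha: np.ndarray,
    nlr: np.ndarray,
    rng: np.random.Generator,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Paired control/treatment counts with planted alpha- and NLR-linked genes.

    The first ``n_planted_alpha`` genes carry a true log2FC of
    ``effect_slope`` per z-score of alpha, the next ``n_planted_nlr`` per
    z-score of NLR; all other genes are null. Per-(gene, patient) noise of
    sd ``lfc_noise_sd`` is added on the log2FC scale. Returns the count
    matrix and the planted-gene registry.
    """
    n_p = len(patient_ids)
    n_g = config.n_genes
    genes = [f"G{i:04d}" for i in range(n_g)]
    base = np.exp(rng.normal(config.gene_logmean, config.gene_logsd, n_g))

    def z(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    za, zn = z(np.asarray(alpha, float)), z(np.asarray(nlr, float))
    true_lfc = np.zeros((n_g, n_p))
    planted_rows = []
    for i in range(min(config.n_planted_alpha, n_g)):
        true_lfc[i] = config.effect_slope * za
        planted_rows.append({"gene": genes[i], "covariate": "alpha", "effect": config.effect_slope})
    for k in range(min(config.n_planted_nlr, max(0, n_g - config.n_planted_alpha))):
        i = config.n_planted_alpha + k
        true_lfc[i] = config.effect_slope * zn
        planted_rows.append({"gene": genes[i], "covariate": "nlr", "effect": config.effect_slope})

    lfc = true_lfc + rng.normal(0.0, config.lfc_noise_sd, (n_g, n_p))
    cols, names, sheet = [], [], []
    for j, pid in enumerate(patient_ids):
        ctrl = _nb_draw(rng, base, config.nb_dispersion)
        trt = _nb_draw(rng, base * 2.0 ** lfc[:, j], config.nb_dispersion)
        cols += [ctrl, trt]
        names += [f"{pid}_C", f"{pid}_T"]
        sheet += [
            {"sample_id": f"{pid}_C", "patient_id": pid, "role": "control"},
            {"sample_id": f"{pid}_T", "patient_id": pid, "role": "treatment"},
        ]
    counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
    samples = pd.DataFrame(sheet).set_index("sample_id")
    planted = pd.DataFrame(planted_rows, columns=["gene", "covariate", "effect"])
    return CountMatrix(counts=counts, samples=samples), planted


_PATHOLOGY_PROBS = {
    Pathology.SQUAMOUS: 0.892,
    Pathology.ADENOCARCINOMA: 0.062,
    Pathology.ADENOSQUAMOUS: 0.037,
    Pathology.CARCINOMA: 0.009,
}
_STAGE_CHOICES = {
    "IB-IIB": ["IB2", "IIA", "IIB"],
    "IIIA-IIIC1": ["IIIB", "IIIC1"],
    "IIIC2-IVB": ["IIIC2", "IVA", "IVB"],
}
_STAGE_PROBS = (0.266, 0.588, 0.146)


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(), expression: bool | None = None
) -> SimulatedCohort:
    """Generate a full cohort (clinical table, ALC series, outcomes, counts).

    ``expression=None`` generates the count matrix iff ``config.n_genes > 0``.
    The same config (including seed) always yields the identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i:04d}" for i in range(n)]

    alpha = np.clip(
        _lognormal(rng, config.alpha_median, config.alpha_sigma, n), *config.alpha_clip
    )
    a1 = _lognormal(rng, config.a1_median, config.a1_sigma, n)
    e1 = np.clip(_lognormal(rng, config.e1_median, config.e1_sigma, n), *config.e1_clip)
    nlr = _lognormal(rng, config.nlr_median, config.nlr_sigma, n)

    series = {
        pid: simulate_alc_series(config, pid, alpha[i], a1[i], e1[i], rng)
        for i, pid in enumerate(pids)
    }
    outcomes = simulate_outcomes(config, alpha, nlr, rng)

    age = rng.normal(57.0, 12.0, n).clip(25, 90)
    pathology = rng.choice(
        [p.value for p in _PATHOLOGY_PROBS], n, p=list(_PATHOLOGY_PROBS.values())
    )
    stage_grp = rng.choice(list(_STAGE_CHOICES), n, p=_STAGE_PROBS)
    figo = [str(rng.choice(_STAGE_CHOICES[g])) for g in stage_grp]
    rt = rng.choice([RTField.PELVIS.value, RTField.PELVIS_PALN.value], n, p=[0.805, 0.195])
    ot = rng.normal(53.0, 4.0, n).clip(35, 80)
    td = rng.normal(70.2, 2.2, n).clip(55, 85)
    pre_alc = (a1 + e1) * np.exp(rng.normal(0.0, 0.15, n))
    miss_pre = rng.uniform(size=n) < config.p_missing
    miss_nlr = rng.uniform(size=n) < config.p_missing

    rows = []
    for i, pid in enumerate(pids):
        cov = ClinicalCovariates(
            age_at_diagnosis=float(age[i]),
            pathology=Pathology(pathology[i]),
            figo_stage=figo[i],
            rt_field=RTField(rt[i]),
            overall_treatment_time=float(ot[i]),
            total_dose_eqd2=float(td[i]),
            pre_alc=None if miss_pre[i] else float(pre_alc[i]),
            nlr=None if miss_nlr[i] else float(nlr[i]),
        )
        rows.append((pid, cov, outcomes[i]))
    cohort = CohortTable(rows=rows, alc_series=series)
    truth = pd.DataFrame(
        {
            "patient_id": pids,
            "alpha_true": alpha,
            "a1_true": a1,
            "e1_true": e1,
            "nlr_true": nlr,
        }
    )

    counts = planted = None
    if expression or (expression is None and config.n_genes > 0):
        counts, planted = simulate_expression(config, pids, alpha, nlr, rng)
    return SimulatedCohort(cohort=cohort, truth=truth, counts=counts, planted=planted)


def simulate_subset_candidates(
    n_patients: int,
    effect_slope: float = 0.8,
    n_null: int = 6,
    rng: np.random.Generator | None = None,
    confound_sd: float = 1.0,
    noise_sd: float = 0.3,
    p_event: float = 0.35,
) -> tuple[pd.DataFrame, pd.Series]:
    """Candidate log2FC features for benchmarking the best-subset search.

    Two planted genes share a latent confound and carry opposite-signed
    halves of the outcome signal, so their *difference* predicts the death
    indicator strongly while each gene alone is weak — the configuration
    the sum/difference composite design is meant to find. The remaining
    ``n_null`` genes are pure noise. Returns (genes x patients log2FC
    frame, 0/1 outcome series).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    pids = [f"P{i:03d}" for i in range(n_patients)]
    y = (rng.uniform(size=n_patients) < p_event).astype(float)
    u = rng.normal(0.0, confound_sd, n_patients)
    g1 = u + 0.5 * effect_slope * y + rng.normal(0.0, noise_sd, n_patients)
    g2 = u - 0.5 * effect_slope * y + rng.normal(0.0, noise_sd, n_patients)
    data = {"PLANT1": g1, "PLANT2": g2}
    for k in range(n_null):
        data[f"NULL{k}"] = rng.normal(0.0, 1.0, n_patients)
    fc = pd.DataFrame(data, index=pids).T
    return fc, pd.Series(y, index=pids, name="dsd")
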