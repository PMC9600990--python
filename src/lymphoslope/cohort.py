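"""Clinical cohort model: domain types, CSV ingestion, and derived variables.

The cohort couples three pieces of information per patient: clinical
covariates recorded at diagnosis (age, pathology, FIGO stage, radiotherapy
field, overall treatment time, total dose in EQD2, pre-treatment absolute
lymphocyte count, neutrophil-to-lymphocyte ratio), outcome follow-up
(disease-specific death, progression, and their timings), and the serial
absolute lymphocyte counts (ALC, cells/uL) measured during
chemoradiotherapy that feed the exponential-slope fitter.

Patients with fewer than three ALC measurements cannot support a
three-parameter exponential fit and are excluded at read time with a
logged reason, mirroring the loss-to-ALC exclusions of retrospective
series.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pathology",
    "StageGroup",
    "RTField",
    "ProgressionClass",
    "ALCMeasurement",
    "ALCSeries",
    "ClinicalCovariates",
    "OutcomeRecord",
    "CohortTable",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "impute_median",
    "derive_min_alc",
    "dichotomize",
]


class SchemaError(ValueError):
    """An input table does not conform to the expected column schema."""


class Pathology(str, enum.Enum):
    SQUAMOUS = "squamous"
    ADENOCARCINOMA = "adenocarcinoma"
    ADENOSQUAMOUS = "adenosquamous"
    CARCINOMA = "carcinoma"


class StageGroup(str, enum.Enum):
    """2018 FIGO stage collapsed to the three analysis strata."""

    IB_IIB = "IB-IIB"
    IIIA_IIIC1 = "IIIA-IIIC1"
    IIIC2_IVB = "IIIC2-IVB"


class RTField(str, enum.Enum):
    PELVIS = "pelvis"
    PELVIS_PALN = "pelvis+PALN"


class ProgressionClass(str, enum.Enum):
    NONE = "none"
    LP = "LP"
    DM = "DM"
    LP_DM = "LP+DM"


def stage_group(figo_stage: str) -> StageGroup:
    """Collapse a granular 2018 FIGO stage string (e.g. ``IIIC1``) to its stratum."""
    s = figo_stage.strip().upper()
    if s.startswith("IV") or s.startswith("IIIC2"):
        return StageGroup.IIIC2_IVB
    if s.startswith("III"):
        return StageGroup.IIIA_IIIC1
    if s.startswith("I"):
        return StageGroup.IB_IIB
    raise ValueError(f"unrecognised FIGO stage {figo_stage!r}")


@dataclass(frozen=True)
class ALCMeasurement:
    """One absolute lymphocyte count: ``day`` since first RT fraction, value in cells/uL."""

    day: int
    value: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        if not self.value > 0:
            raise ValueError(f"ALC value must be > 0, got {self.value}")


@dataclass(frozen=True)
class ALCSeries:
    """Ordered serial ALC measurements for one patient (at least 3 points)."""

    patient_id: str
    measurements: tuple[ALCMeasurement, ...]

    def __post_init__(self) -> None:
        ms = tuple(sorted(self.measurements, key=lambda m: m.day))
        object.__setattr__(self, "measurements", ms)
        if len(ms) < 3:
            raise ValueError(
                f"patient {self.patient_id}: need >= 3 ALC measurements, got {len(ms)}"
            )
        days = [m.day for m in ms]
        if len(set(days)) != len(days):
            raise ValueError(f"patient {self.patient_id}: duplicate measurement days")

    @property
    def days(self) -> np.ndarray:
        return np.array([m.day for m in self.measurements], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.measurements], dtype=float)

    def __len__(self) -> int:
        return len(self.measurements)


@dataclass(frozen=True)
class ClinicalCovariates:
    age_at_diagnosis: float
    pathology: Pathology
    figo_stage: str  # granular stage string; stratum via `stage_group`
    rt_field: RTField
    overall_treatment_time: float  # days
    total_dose_eqd2: float  # Gy
    pre_alc: float | None = None  # cells/uL; None = missing
    nlr: float | None = None  # ratio; None = missing

    def __post_init__(self) -> None:
        if not self.total_dose_eqd2 > 0:
            raise ValueError("total_dose_eqd2 must be > 0")
        if not self.overall_treatment_time > 0:
            raise ValueError("overall_treatment_time must be > 0")
        if self.nlr is not None and self.nlr < 0:
            raise ValueError("nlr must be >= 0")
        stage_group(self.figo_stage)  # validates

    @property
    def stage_group(self) -> StageGroup:
        return stage_group(self.figo_stage)


@dataclass(frozen=True)
class OutcomeRecord:
    """Follow-up outcome, timed in months from the end of treatment."""

    followup_months: float
    dsd: bool
    time_to_dsd_months: float | None = None
    progression: ProgressionClass = ProgressionClass.NONE
    time_to_progression_months: float | None = None

    def __post_init__(self) -> None:
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")
        if self.dsd:
            if self.time_to_dsd_months is None:
                raise ValueError("dsd=True requires time_to_dsd_months")
            if self.time_to_dsd_months > self.followup_months + 1e-9:
                raise ValueError("time_to_dsd_months exceeds followup_months")
        if self.progression is not ProgressionClass.NONE:
            if self.time_to_progression_months is None:
                raise ValueError("progression requires time_to_progression_months")
            if self.time_to_progression_months > self.followup_months + 1e-9:
                raise ValueError("time_to_progression_months exceeds followup_months")


@dataclass
class CohortTable:
    """Validated cohort: one (covariates, outcome) row and one ALC series per patient."""

    rows: list[tuple[str, ClinicalCovariates, OutcomeRecord]]
    alc_series: dict[str, ALCSeries]

    def __post_init__(self) -> None:
        ids = [pid for pid, _, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")
        missing = [pid for pid in ids if pid not in self.alc_series]
        if missing:
            raise ValueError(f"patients without ALC series: {missing[:5]}")

    @property
    def patient_ids(self) -> list[str]:
        return [pid for pid, _, _ in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def covariates(self, patient_id: str) -> ClinicalCovariates:
        return self._index()[patient_id][0]

    def outcome(self, patient_id: str) -> OutcomeRecord:
        return self._index()[patient_id][1]

    def _index(self) -> dict[str, tuple[ClinicalCovariates, OutcomeRecord]]:
        return {pid: (cov, out) for pid, cov, out in self.rows}

    def to_frame(self) -> pd.DataFrame:
        """Flatten covariates + outcomes to one DataFrame row per patient."""
        recs = []
        for pid, cov, out in self.rows:
            recs.append(
                {
                    "patient_id": pid,
                    "age": cov.age_at_diagnosis,
                    "pathology": cov.pathology.value,
                    "figo_stage": cov.figo_stage,
                    "stage_group": cov.stage_group.value,
                    "rt_field": cov.rt_field.value,
                    "ot_days": cov.overall_treatment_time,
                    "td_eqd2": cov.total_dose_eqd2,
                    "pre_alc": cov.pre_alc,
                    "nlr": cov.nlr,
                    "followup_months": out.followup_months,
                    "dsd": int(out.dsd),
                    "time_to_dsd_months": out.time_to_dsd_months,
                    "progression": out.progression.value,
                    "time_to_progression_months": out.time_to_progression_months,
                }
            )
        return pd.DataFrame.from_records(recs)


CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "pathology",
    "figo_stage",
    "rt_field",
    "ot_days",
    "td_eqd2",
    "pre_alc",
    "nlr",
    "followup_months",
    "dsd",
    "time_to_dsd_months",
    "progression",
    "time_to_progression_months",
]

ALC_COLUMNS = ["patient_id", "day", "alc"]


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def read_cohort(
    clinical_path: str | Path, alc_path: str | Path
) -> tuple[CohortTable, pd.DataFrame]:
    """Read the clinical and ALC CSVs into a validated :class:`CohortTable`.

    Returns ``(table, exclusions)`` where ``exclusions`` is a DataFrame with
    columns ``patient_id, reason`` listing patients dropped for invariant
    violations (e.g. fewer than 3 ALC measurements) with a per-row diagnostic.
    Raises :class:`SchemaError` naming the column when a required column is
    absent (including the degenerate empty-file case).
    """
    try:
        clin = pd.read_csv(clinical_path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"clinical file {clinical_path} is empty") from exc
    try:
        alc = pd.read_csv(alc_path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"ALC file {alc_path} is empty") from exc

    for col in CLINICAL_COLUMNS:
        if col not in clin.columns:
            raise SchemaError(f"clinical file missing required column {col!r}")
    for col in ALC_COLUMNS:
        if col not in alc.columns:
            raise SchemaError(f"ALC file missing required column {col!r}")

    exclusions: list[tuple[str, str]] = []
    series: dict[str, ALCSeries] = {}
    for pid, grp in alc.groupby("patient_id", sort=False):
        try:
            ms = tuple(
                ALCMeasurement(day=int(d), value=float(v))
                for d, v in zip(grp["day"], grp["alc"])
            )
            series[str(pid)] = ALCSeries(patient_id=str(pid), measurements=ms)
        except ValueError as exc:
            exclusions.append((str(pid), str(exc)))

    rows: list[tuple[str, ClinicalCovariates, OutcomeRecord]] = []
    for rec in clin.to_dict("records"):
        pid = str(rec["patient_id"])
        if pid not in series:
            if not any(e[0] == pid for e in exclusions):
                exclusions.append((pid, "no ALC measurements"))
            continue
        try:
            cov = ClinicalCovariates(
                age_at_diagnosis=float(rec["age"]),
                pathology=Pathology(rec["pathology"]),
                figo_stage=str(rec["figo_stage"]),
                rt_field=RTField(rec["rt_field"]),
                overall_treatment_time=float(rec["ot_days"]),
                total_dose_eqd2=float(rec["td_eqd2"]),
                pre_alc=_opt_float(rec["pre_alc"]),
                nlr=_opt_float(rec["nlr"]),
            )
            out = OutcomeRecord(
                followup_months=float(rec["followup_months"]),
                dsd=bool(int(rec["dsd"])),
                time_to_dsd_months=_opt_float(rec["time_to_dsd_months"]),
                progression=ProgressionClass(rec["progression"]),
                time_to_progression_months=_opt_float(
                    rec["time_to_progression_months"]
                ),
            )
        except (ValueError, KeyError) as exc:
            exclusions.append((pid, f"invalid row: {exc}"))
            continue
        rows.append((pid, cov, out))

    kept = {pid for pid, _, _ in rows}
    table = CohortTable(rows=rows, alc_series={p: s for p, s in series.items() if p in kept})
    excl = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return table, excl


def write_cohort(
    table: CohortTable, clinical_path: str | Path, alc_path: str | Path
) -> None:
    """Write a cohort back to the two-CSV external interface (inverse of read)."""
    table.to_frame().to_csv(clinical_path, index=False)
    recs = [
        {"patient_id": pid, "day": m.day, "alc": m.value}
        for pid in table.patient_ids
        for m in table.alc_series[pid].measurements
    ]
    pd.DataFrame.from_records(recs, columns=ALC_COLUMNS).to_csv(alc_path, index=False)


_IMPUTABLE = {"pre_alc", "nlr"}


def impute_median(
    table: CohortTable, fields: Iterable[str] = ("pre_alc", "nlr")
) -> tuple[CohortTable, dict[str, int]]:
    """Replace missing ``pre_alc``/``nlr`` by the cohort median of observed values.

    Only the two fields the analysis allows to be missing are imputable;
    asking for any other field is an error, as is a field with no observed
    values at all. Returns the imputed table and the per-field count of
    replacements.
    """
    fields = set(fields)
    bad = fields - _IMPUTABLE
    if bad:
        raise ValueError(f"fields not imputable: {sorted(bad)}")
    counts: dict[str, int] = {}
    rows = list(table.rows)
    for f in sorted(fields):
        vals = [getattr(cov, f) for _, cov, _ in rows if getattr(cov, f) is not None]
        if not vals:
            raise ValueError(f"all values missing for field {f!r}; cannot impute")
        med = float(np.median(vals))
        n = 0
        new_rows = []
        for pid, cov, out in rows:
            if getattr(cov, f) is None:
                cov = replace(cov, **{f: med})
                n += 1
            new_rows.append((pid, cov, out))
        rows = new_rows
        counts[f] = n
    return CohortTable(rows=rows, alc_series=dict(table.alc_series)), counts


def derive_min_alc(series: ALCSeries, window_days: float = 40) -> float | None:
    """Minimum ALC among measurements within ``window_days`` of RT start.

    The window is closed at the boundary (day == window_days counts). If no
    measurement falls inside the window, returns None with a warning.
    """
    vals = [m.value for m in series.measurements if m.day <= window_days]
    if not vals:
        warnings.warn(
            f"patient {series.patient_id}: no ALC within {window_days} days; "
            "min-ALC undefined",
            stacklevel=2,
        )
        return None
    return float(min(vals))


def dichotomize(
    values: Sequence[float], threshold: float | str = "median"
) -> tuple[list[str], float]:
    """Split values into "high"/"low" at a threshold (or the sample median).

    A value equal to the threshold is "high", matching the >=median group
    convention used for cohort characteristic tables.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    thr = float(np.median(arr)) if isinstance(threshold, str) else float(threshold)
    labels = ["high" if v >= thr else "low" for v in arr]
    return labels, thr
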