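"""Survival endpoints, including the aggressive / non-aggressive death split.

Disease-specific deaths (DSD) are partitioned at a time threshold — by
default the mean time-to-death among the deaths themselves — into an
aggressive class (death strictly before the threshold) and a
non-aggressive class (death at or after it). Four endpoints are built on
this partition:

* ``dss``    — disease-specific survival: any DSD is an event;
* ``dss_a``  — only aggressive deaths are events; non-aggressive deaths
  are censored (at their death time by default);
* ``dss_na`` — the mirror image, only non-aggressive deaths are events;
* ``pfs``    — progression-free survival: the first of progression or DSD.

All times are months from the end of treatment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .cohort import OutcomeRecord, ProgressionClass

__all__ = [
    "EndpointConfig",
    "SurvivalEndpoint",
    "DsdLabel",
    "EndpointKind",
    "split_dsd",
    "build_endpoint",
    "classify_progression",
    "cohort_endpoints",
]


class DsdLabel(str, enum.Enum):
    NONE = "none"
    AGGRESSIVE = "aggressive"
    NON_AGGRESSIVE = "non_aggressive"


EndpointKind = Literal["dss", "dss_a", "dss_na", "pfs"]


@dataclass(frozen=True)
class EndpointConfig:
    """Split threshold and evaluation horizons for the four endpoints.

    ``split_months="auto"`` uses the mean time-to-death among the
    disease-specific deaths (30 months in the motivating cohort).
    ``censor_mode`` controls how a death of the *other* class is censored
    in the class-specific endpoints: at its death time ("death", the
    cause-specific convention, default) or at the split threshold
    ("threshold").
    """

    split_months: float | str = "auto"
    horizons: dict = field(
        default_factory=lambda: {"dss_a": 30.0, "dss_na": 96.0, "dss": 96.0, "pfs": 96.0}
    )
    censor_mode: Literal["death", "threshold"] = "death"

    def __post_init__(self) -> None:
        if not isinstance(self.split_months, str) and self.split_months <= 0:
            raise ValueError("split_months must be > 0")


@dataclass(frozen=True)
class SurvivalEndpoint:
    time: float  # months
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")


def split_dsd(
    outcomes: Sequence[OutcomeRecord], config: EndpointConfig = EndpointConfig()
) -> tuple[list[DsdLabel], float]:
    """Label every disease-specific death aggressive or non-aggressive.

    Aggressive means death strictly before the threshold; a death at
    exactly the threshold is non-aggressive. With ``split_months="auto"``
    the threshold is the mean time-to-death among the deaths (an error if
    there are none).
    """
    dsd_times = [o.time_to_dsd_months for o in outcomes if o.dsd]
    if isinstance(config.split_months, str):
        if not dsd_times:
            raise ValueError('split_months="auto" requires at least one DSD')
        threshold = float(np.mean(dsd_times))
    else:
        threshold = float(config.split_months)
    labels = []
    for o in outcomes:
        if not o.dsd:
            labels.append(DsdLabel.NONE)
        elif o.time_to_dsd_months < threshold:
            labels.append(DsdLabel.AGGRESSIVE)
        else:
            labels.append(DsdLabel.NON_AGGRESSIVE)
    return labels, threshold


def classify_progression(
    lp_time: float | None, dm_time: float | None
) -> ProgressionClass:
    """Progression class from the presence of local / distant event times."""
    if lp_time is not None and dm_time is not None:
        return ProgressionClass.LP_DM
    if lp_time is not None:
        return ProgressionClass.LP
    if dm_time is not None:
        return ProgressionClass.DM
    return ProgressionClass.NONE


def build_endpoint(
    record: OutcomeRecord,
    label: DsdLabel,
    kind: EndpointKind,
    config: EndpointConfig = EndpointConfig(),
) -> SurvivalEndpoint:
    """(time, event) pair for one patient under one endpoint definition."""
    if (label is not DsdLabel.NONE) != record.dsd:
        raise ValueError("DSD label inconsistent with outcome record")
    if kind == "dss":
        if record.dsd:
            return SurvivalEndpoint(record.time_to_dsd_months, True)
        return SurvivalEndpoint(record.followup_months, False)
    if kind in ("dss_a", "dss_na"):
        target = DsdLabel.AGGRESSIVE if kind == "dss_a" else DsdLabel.NON_AGGRESSIVE
        if record.dsd:
            if label is target:
                return SurvivalEndpoint(record.time_to_dsd_months, True)
            # competing-class death: censor
            if config.censor_mode == "death":
                return SurvivalEndpoint(record.time_to_dsd_months, False)
            thr = config.split_months if not isinstance(config.split_months, str) else 30.0
            return SurvivalEndpoint(min(record.time_to_dsd_months, thr), False)
        return SurvivalEndpoint(record.followup_months, False)
    if kind == "pfs":
        times = []
        if record.progression is not ProgressionClass.NONE:
            times.append(record.time_to_progression_months)
        if record.dsd:
            times.append(record.time_to_dsd_months)
        if times:
            return SurvivalEndpoint(min(times), True)
        return SurvivalEndpoint(record.followup_months, False)
    raise ValueError(f"unknown endpoint kind {kind!r}")


def cohort_endpoints(
    outcomes: Sequence[OutcomeRecord],
    kind: EndpointKind,
    config: EndpointConfig = EndpointConfig(),
    labels: Sequence[DsdLabel] | None = None,
) -> list[SurvivalEndpoint]:
    """Build one endpoint for every patient, splitting DSDs if labels not given."""
    if labels is None:
        labels, _ = split_dsd(outcomes, config)
    return [build_endpoint(o, l, kind, config) for o, l in zip(outcomes, labels)]
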