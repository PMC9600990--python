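"""End-to-end orchestration: fit -> endpoints -> survival stats -> exosome arm.

`run_full` executes the whole analysis on a cohort read from CSV (or
simulated), writing tidy CSV outputs and a run log (software version,
config hash, seed) sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alphafit import FitConfig, fit_cohort
from .cohort import CohortTable, derive_min_alc, dichotomize, impute_median, read_cohort
from .endpoints import EndpointConfig, cohort_endpoints, split_dsd
from .exosome import (
    CountMatrix,
    best_subset,
    composite_score,
    correlation_screen,
    filter_detected,
    paired_log2fc,
    tmm_factors,
    CompositeScoreDef,
)
from .survival import cox_backward, group_compare, km_estimate, logrank

log = logging.getLogger("lymphoslope")

__all__ = ["RunConfig", "run_full"]


@dataclass(frozen=True)
class RunConfig:
    """Paths, thresholds and sub-configs for a full pipeline run.

    Dichotomization thresholds default to the cohort median; fixed
    constants (e.g. alpha 0.08 / NLR 2.43) can be supplied to replicate an
    external analysis.
    """

    clinical_path: str | None = None
    alc_path: str | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    outdir: str = "lymphoslope_run"
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    endpoint: EndpointConfig = field(default_factory=EndpointConfig)
    alpha_threshold: float | str = "median"
    nlr_threshold: float | str = "median"
    screen_p: float = 0.05
    subset_max_k: int = 8
    exosome: bool = False

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        enc = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:16]


def _survival_arm(df: pd.DataFrame, outcomes, endpoint_cfg, outdir: Path) -> dict:
    """KM/log-rank by alpha group and Cox backward elimination per endpoint."""
    report = {}
    labels, threshold = split_dsd(outcomes, endpoint_cfg)
    report["dsd_split_threshold"] = threshold
    cov = pd.DataFrame(
        {
            "alpha_low": (df["alpha_group"] == "low").astype(float),
            "nlr_high": (df["nlr_group"] == "high").astype(float),
            "non_squamous": (df["pathology"] != "squamous").astype(float),
            "stage_iii_plus": (df["stage_group"] != "IB-IIB").astype(float),
            "age": df["age"].astype(float),
        }
    )
    km_rows, lr_rows, cox_frames = [], [], []
    for kind in ("dss", "dss_a", "dss_na", "pfs"):
        eps = cohort_endpoints(outcomes, kind, endpoint_cfg, labels=labels)
        grp_a = [e for e, g in zip(eps, df["alpha_group"]) if g == "high"]
        grp_b = [e for e, g in zip(eps, df["alpha_group"]) if g == "low"]
        for gname, grp in (("alpha_high", grp_a), ("alpha_low", grp_b)):
            if grp:
                c = km_estimate(grp)
                f = c.to_frame()
                f.insert(0, "group", gname)
                f.insert(0, "endpoint", kind)
                km_rows.append(f)
        if grp_a and grp_b:
            lr = logrank(grp_a, grp_b)
            lr_rows.append(
                {"endpoint": kind, "groups": "alpha_high_vs_low", "statistic": lr.statistic, "p": lr.p_value}
            )
        if sum(e.event for e in eps) >= 5:
            fit = cox_backward(cov, eps)
            f = fit.to_frame()
            aic_row = pd.DataFrame(
                [
                    {
                        "term": "(model AIC)",
                        "coef": np.nan,
                        "hr": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": fit.aic,
                    }
                ]
            )
            f = aic_row if f.empty else pd.concat([f, aic_row], ignore_index=True)
            f.insert(0, "endpoint", kind)
            cox_frames.append(f)
        report[f"n_events_{kind}"] = int(sum(e.event for e in eps))
    if km_rows:
        pd.concat(km_rows).to_csv(outdir / "km_curves.csv", index=False)
    pd.DataFrame(lr_rows).to_csv(outdir / "logrank.csv", index=False)
    if cox_frames:
        pd.concat(cox_frames).to_csv(outdir / "cox_models.csv", index=False)
    return report


def _exosome_arm(
    counts: CountMatrix, df: pd.DataFrame, config: RunConfig, outdir: Path
) -> dict:
    filtered, removed = filter_detected(counts)
    factors = tmm_factors(filtered)
    fc = paired_log2fc(filtered, factors)
    fc = fc[[p for p in fc.columns if p in set(df["patient_id"])]]
    meta = df.set_index("patient_id").loc[list(fc.columns)]
    screen = correlation_screen(
        fc,
        alpha=meta["alpha"],
        nlr=meta["nlr"],
        dsd=meta["dsd"].astype(bool),
        p_threshold=config.screen_p,
    )
    fc.to_csv(outdir / "log2fc.tsv", sep="\t")
    screen.table.to_csv(outdir / "screen.csv")
    report = {
        "n_genes_removed": len(removed),
        "n_genes_selected": len(screen.selected),
    }
    n_cand = len(screen.selected)
    if 1 <= n_cand:
        cands = screen.selected
        if n_cand > config.subset_max_k + 4:
            # keep the search tractable: strongest screen hits first
            strength = screen.table.loc[cands, ["p_alpha", "p_dsd"]].min(axis=1)
            cands = list(strength.sort_values().index[: config.subset_max_k + 4])
        subset = best_subset(cands, fc, meta["dsd"].astype(float), max_k=config.subset_max_k)
        subset.trace.to_csv(outdir / "subset_trace.csv", index=False)
        report["subset_genes"] = subset.selected_genes
        report["subset_adj_r2"] = subset.adj_r2
        score = composite_score(fc, CompositeScoreDef(plus_genes=frozenset(subset.selected_genes)))
        score.rename_axis("patient_id").to_csv(outdir / "composite_scores.csv")
    return report


def run_full(config: RunConfig, cohort: CohortTable | None = None,
             counts: CountMatrix | None = None) -> dict:
    """Run the complete analysis; returns a report dict and writes the bundle.

    A cohort (and optional count matrix) can be passed in-memory; otherwise
    they are read from the configured paths. Any stage failure raises with
    the stage name in the message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "config_hash": config.config_hash()}

    stage = "read_cohort"
    try:
        if cohort is None:
            if not config.clinical_path or not config.alc_path:
                raise ValueError("clinical_path and alc_path required when no cohort given")
            cohort, exclusions = read_cohort(config.clinical_path, config.alc_path)
            exclusions.to_csv(outdir / "exclusions.csv", index=False)
            report["n_excluded"] = len(exclusions)
        cohort, imputed = impute_median(cohort)
        report["n_imputed"] = imputed

        stage = "fit_cohort"
        fits = fit_cohort(cohort, config.fit)
        fits.to_frame().to_csv(outdir / "alpha_fits.csv", index=False)
        report["fit_summary"] = fits.summary()

        stage = "derive_variables"
        df = cohort.to_frame()
        df = df[df["patient_id"].isin(fits.fits)].reset_index(drop=True)
        df["alpha"] = [fits.fits[p].alpha for p in df["patient_id"]]
        df["a2"] = [fits.fits[p].a2 for p in df["patient_id"]]
        df["e1"] = [fits.fits[p].e1 for p in df["patient_id"]]
        df["min_alc"] = [
            derive_min_alc(cohort.alc_series[p]) for p in df["patient_id"]
        ]
        df["alpha_group"], report["alpha_threshold"] = dichotomize(
            df["alpha"], config.alpha_threshold
        )
        df["nlr_group"], report["nlr_threshold"] = dichotomize(
            df["nlr"], config.nlr_threshold
        )
        df.to_csv(outdir / "derived.csv", index=False)

        stage = "group_compare"
        comp = group_compare(
            df,
            df["alpha_group"],
            categorical=["pathology", "stage_group", "rt_field", "nlr_group"],
            continuous=["age", "ot_days", "td_eqd2", "pre_alc", "min_alc", "a2", "e1"],
        )
        comp.to_frame().to_csv(outdir / "group_comparison.csv", index=False)

        stage = "survival"
        outcomes = [cohort.outcome(p) for p in df["patient_id"]]
        report.update(_survival_arm(df, outcomes, config.endpoint, outdir))

        if config.exosome:
            stage = "exosome"
            if counts is None:
                if not config.counts_path or not config.samples_path:
                    raise ValueError(
                        "exosome arm enabled but counts_path/samples_path not configured"
                    )
                counts = CountMatrix.read(config.counts_path, config.samples_path)
            report["exosome"] = _exosome_arm(counts, df, config, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    log.info("run complete: %s", outdir)
    return report
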