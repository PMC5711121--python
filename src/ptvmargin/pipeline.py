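"""End-to-end pipeline: cohort logs -> motion, step, and margin reports.

Ties the stages together deterministically: read (or simulate) a cohort
of fraction logs, summarize motion per fraction, estimate the four step
uncertainties per fraction, average them per patient, combine by
quadrature, expand with k=2, and evaluate the margin grid.  Every
threshold is carried in :class:`PipelineConfig`; stage code takes them
as arguments and hard-codes nothing.  All intermediates are written as
CSV next to a JSON/text summary, and every sample-exclusion decision is
logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .combine import (
    COVERAGE_FACTOR,
    DEFAULT_MARGINS_MM,
    TrackingTerm,
    margin_pass_table,
    patient_uncertainty_from_steps,
)
from .log_model import PatientGeometry
from .motion_range import (
    DEFAULT_BREATHING_PERIOD_S,
    cohort_motion_stats,
    peak_to_trough_amplitudes,
    summarize_motion,
)
from .step_uncertainty import (
    CORRELATION_REBUILD_MM,
    CORRELATION_REBUILD_RUN,
    SRERROR_SEED_REMOVAL_MM,
    aggregate_over_fractions,
    assign_deformation_uncertainty,
    correlation_uncertainty,
    detect_seed_migration,
    filter_correlation_samples,
    pairwise_distance_deltas,
    prediction_uncertainty,
    seeds_uncertainty,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ptvmargin")

_AXIS_COLS = ("si", "lat", "ap")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serializable to/from YAML."""

    input_dir: str = ""
    output_dir: str = "ptvmargin_out"
    # correlation-model exclusion rule: error > threshold, run-length times
    correlation_rebuild_mm: float = CORRELATION_REBUILD_MM
    correlation_rebuild_run: int = CORRELATION_REBUILD_RUN
    # persistent-SRerror seed-removal rule
    srerror_removal_mm: float = SRERROR_SEED_REMOVAL_MM
    srerror_persistence: float = 0.5
    # motion segmentation
    breathing_period_s: float = DEFAULT_BREATHING_PERIOD_S
    # combination
    coverage_factor: float = COVERAGE_FACTOR
    tracking_term_enabled: bool = False
    tracking_term_mm: float = 0.7
    literal_seed_variance: bool = False
    margins_mm: tuple[float, ...] = DEFAULT_MARGINS_MM
    random_seed: int = 0

    def __post_init__(self):
        self.margins_mm = tuple(sorted(float(m) for m in self.margins_mm))
        for name in ("correlation_rebuild_mm", "srerror_removal_mm", "breathing_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["margins_mm"] = list(self.margins_mm)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @property
    def tracking_term(self) -> TrackingTerm:
        return TrackingTerm(u_tracking=self.tracking_term_mm, enabled=self.tracking_term_enabled)


def _fraction_steps(ds, geom: PatientGeometry, config: PipelineConfig) -> dict:
    disabled, flagged = detect_seed_migration(
        ds.fiducials,
        ds.live_images,
        threshold_mm=config.srerror_removal_mm,
        persistence=config.srerror_persistence,
    )
    fiducials = ds.fiducials
    for seed in sorted(disabled):
        log.info(
            "%s/%s: disabling seed %s (persistent SRerror > %g mm)",
            ds.patient_id, ds.fraction_id, seed, config.srerror_removal_mm,
        )
        fiducials = fiducials.disable(seed)
    if flagged:
        log.warning(
            "%s/%s: persistent SRerror remains but only 2 seeds available",
            ds.patient_id, ds.fraction_id,
        )
    retained = filter_correlation_samples(
        ds.correlation,
        rebuild_threshold_mm=config.correlation_rebuild_mm,
        rebuild_run=config.correlation_rebuild_run,
    )
    n_dropped = len(ds.correlation) - len(retained)
    if n_dropped:
        log.info(
            "%s/%s: excluded %d correlation samples (model-build or rebuild runs)",
            ds.patient_id, ds.fraction_id, n_dropped,
        )
    deltas = pairwise_distance_deltas(fiducials, ds.live_images)
    return {
        "deformation": assign_deformation_uncertainty(geom),
        "seeds": seeds_uncertainty(deltas, literal_variance=config.literal_seed_variance),
        "correlation": correlation_uncertainty(retained),
        "prediction": prediction_uncertainty(ds.prediction),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis over a cohort directory; return the bundle.

    Expects ``config.input_dir`` in the cohort layout written by
    :func:`ptvmargin.io.write_cohort`.  Writes per-fraction motion and
    step CSVs, per-patient aggregates, the per-patient combined expanded
    uncertainty, the margin pass table, and a JSON summary to
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fractions, geometry = pio.read_cohort(config.input_dir)
    geom_by_pid = {g.patient_id: g for g in geometry}

    motion_rows = []
    per_patient_motion: dict[str, list] = {}
    per_patient_steps: dict[str, list] = {}
    step_rows = []
    for ds in fractions:
        geom = geom_by_pid[ds.patient_id]
        amps = peak_to_trough_amplitudes(
            ds.modeled_trace(), nominal_period_s=config.breathing_period_s
        )
        summary = summarize_motion(amps)
        per_patient_motion.setdefault(ds.patient_id, []).append(summary)
        row = {"patient_id": ds.patient_id, "fraction_id": ds.fraction_id, "n_cycles": summary.n_cycles}
        for i, ax in enumerate(_AXIS_COLS):
            row[f"rm_{ax}"] = summary.rm[i]
            row[f"r95_{ax}"] = summary.r95[i]
            row[f"median_{ax}"] = summary.median[i]
            row[f"trimmed_mean_{ax}"] = summary.trimmed_mean[i]
        motion_rows.append(row)

        steps = _fraction_steps(ds, geom, config)
        per_patient_steps.setdefault(ds.patient_id, []).append(steps)
        for name, su in steps.items():
            srow = {"patient_id": ds.patient_id, "fraction_id": ds.fraction_id,
                    "step": name, "n_samples": su.n_samples}
            for i, ax in enumerate(_AXIS_COLS):
                srow[f"u_{ax}"] = su.u[i]
            step_rows.append(srow)

    motion_df = pd.DataFrame(motion_rows)
    steps_df = pd.DataFrame(step_rows)
    patients_motion, cohort_motion = cohort_motion_stats(per_patient_motion)

    patient_rows = []
    patient_uncertainties = []
    for pid, frac_steps in per_patient_steps.items():
        agg = aggregate_over_fractions(frac_steps)
        pu = patient_uncertainty_from_steps(
            pid,
            [agg.loc["deformation", f"u_{ax}_mean"] for ax in _AXIS_COLS],
            [agg.loc["seeds", f"u_{ax}_mean"] for ax in _AXIS_COLS],
            [agg.loc["correlation", f"u_{ax}_mean"] for ax in _AXIS_COLS],
            [agg.loc["prediction", f"u_{ax}_mean"] for ax in _AXIS_COLS],
            k=config.coverage_factor,
            tracking=config.tracking_term,
        )
        patient_uncertainties.append(pu)
        row = {"patient_id": pid}
        for i, ax in enumerate(_AXIS_COLS):
            row[f"u_combined_{ax}"] = pu.u_combined[i]
        patient_rows.append(row)
    global_df = pd.DataFrame(patient_rows).set_index("patient_id")
    margins = margin_pass_table(patient_uncertainties, config.margins_mm)

    motion_df.to_csv(out / "motion_per_fraction.csv", index=False)
    patients_motion.to_csv(out / "motion_per_patient.csv")
    cohort_motion.to_csv(out / "motion_cohort.csv")
    steps_df.to_csv(out / "steps_per_fraction.csv", index=False)
    global_df.to_csv(out / "global_uncertainty.csv")
    margins.to_csv(out / "margin_pass_table.csv")

    u = global_df.to_numpy()
    summary = {
        "n_patients": int(global_df.shape[0]),
        "n_fractions": int(len(fractions)),
        "u_combined_min_mm": float(u.min()),
        "u_combined_max_mm": float(u.max()),
        "patients_over_5mm": global_df.index[(u > 5.0).any(axis=1)].tolist(),
        "margin_pass_pct": {
            str(m): {ax: int(margins.loc[m, ax]) for ax in _AXIS_COLS}
            for m in margins.index
        },
        "thresholds": {
            "correlation_rebuild_mm": config.correlation_rebuild_mm,
            "correlation_rebuild_run": config.correlation_rebuild_run,
            "srerror_removal_mm": config.srerror_removal_mm,
            "coverage_factor": config.coverage_factor,
            "tracking_term_enabled": config.tracking_term_enabled,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {
        "motion_per_fraction": motion_df,
        "motion_per_patient": patients_motion,
        "motion_cohort": cohort_motion,
        "steps_per_fraction": steps_df,
        "global_uncertainty": global_df,
        "margin_pass_table": margins,
        "summary": summary,
    }
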