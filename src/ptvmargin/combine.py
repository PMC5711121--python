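"""Quadrature combination of step uncertainties and margin evaluation.

Treating the four tracking steps as independent, the per-axis combined
standard uncertainty of a patient is the root-sum-square

    e_combined = sqrt(e_def^2 + e_seeds^2 + e_corr^2 + e_pred^2),

and the expanded uncertainty at ~95% confidence (normal PDF) is
``U_combined = k * e_combined`` with coverage factor ``k = 2``.  Each
step's standard uncertainty is half its expanded value, ``e = U/2``.

A candidate CTV-to-PTV margin ``m`` covers a patient on an axis when
``U_combined <= m``; evaluating a margin grid over a cohort yields the
percentage of patients covered per margin and axis.

An optional end-to-end tracking term (phantom-measured delivery
accuracy, 0.7 mm expanded) can be folded in by quadrature; the primary
analysis excludes it because phantom end-to-end tests already exercise
the correlation/prediction chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .log_model import AXES
from .reference import ReferenceCohort, load_reference_cohort
from .motion_range import cohort_stats_from_patient_means

__all__ = [
    "COVERAGE_FACTOR",
    "DEFAULT_MARGINS_MM",
    "PatientUncertainty",
    "TrackingTerm",
    "combine",
    "expand",
    "add_tracking_term",
    "margin_pass_table",
    "patient_uncertainty_from_steps",
    "cohort_global_uncertainty",
    "reproduce_reference",
    "ReferenceReport",
]

COVERAGE_FACTOR = 2.0
DEFAULT_MARGINS_MM = (2.0, 3.0, 4.0, 5.0, 6.0)

_AXIS_COLS = ("si", "lat", "ap")


@dataclass(frozen=True)
class TrackingTerm:
    """End-to-end delivery-accuracy term, expanded mm (phantom measured)."""

    u_tracking: float = 0.7
    sd: float = 0.3
    n: int = 20
    enabled: bool = False

    def __post_init__(self):
        if self.u_tracking < 0:
            raise ValueError("tracking term must be >= 0")


@dataclass
class PatientUncertainty:
    """Combined standard and expanded uncertainty of one patient, per axis."""

    patient_id: str
    e_combined: np.ndarray  # (3,) mm
    k: float = COVERAGE_FACTOR
    step_e: dict = field(default_factory=dict)  # step name -> (3,) standard e used

    def __post_init__(self):
        self.e_combined = np.asarray(self.e_combined, dtype=float)
        if self.e_combined.shape != (3,):
            raise ValueError("e_combined must be a per-axis 3-vector")
        if np.any(self.e_combined < 0):
            raise ValueError("e_combined must be >= 0")

    @property
    def u_combined(self) -> np.ndarray:
        return self.k * self.e_combined


def combine(*step_e: np.ndarray) -> np.ndarray:
    """Root-sum-square of per-axis standard uncertainties (any number of terms)."""
    if not step_e:
        raise ValueError("no step uncertainties to combine")
    stack = np.stack([np.broadcast_to(np.asarray(e, dtype=float), (3,)) for e in step_e])
    if np.any(stack < 0):
        raise ValueError("standard uncertainties must be >= 0")
    return np.sqrt((stack**2).sum(axis=0))


def expand(e_combined: np.ndarray, k: float = COVERAGE_FACTOR) -> np.ndarray:
    """Expanded uncertainty U = k * e (k=2 -> ~95% confidence, normal PDF)."""
    if k <= 0:
        raise ValueError("coverage factor must be positive")
    e = np.asarray(e_combined, dtype=float)
    if np.any(e < 0):
        raise ValueError("e_combined must be >= 0")
    return k * e


def add_tracking_term(e_combined: np.ndarray, term: TrackingTerm) -> np.ndarray:
    """Quadrature-add the end-to-end tracking term (no-op when disabled)."""
    e = np.asarray(e_combined, dtype=float)
    if not term.enabled:
        return e.copy()
    return np.sqrt(e**2 + (term.u_tracking / 2.0) ** 2)


def patient_uncertainty_from_steps(
    patient_id: str,
    u_deformation,
    u_seeds,
    u_correlation,
    u_prediction,
    k: float = COVERAGE_FACTOR,
    tracking: TrackingTerm | None = None,
) -> PatientUncertainty:
    """Combine four expanded per-axis step values (e = U/2 each) for a patient."""
    es = {
        "deformation": np.broadcast_to(np.asarray(u_deformation, dtype=float), (3,)) / 2.0,
        "seeds": np.broadcast_to(np.asarray(u_seeds, dtype=float), (3,)) / 2.0,
        "correlation": np.broadcast_to(np.asarray(u_correlation, dtype=float), (3,)) / 2.0,
        "prediction": np.broadcast_to(np.asarray(u_prediction, dtype=float), (3,)) / 2.0,
    }
    e = combine(*es.values())
    if tracking is not None:
        e = add_tracking_term(e, tracking)
    return PatientUncertainty(patient_id=patient_id, e_combined=e, k=k, step_e=es)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def margin_pass_table(
    cohort: list[PatientUncertainty],
    margins_mm=DEFAULT_MARGINS_MM,
) -> pd.DataFrame:
    """Percentage of patients with U_combined within each candidate margin.

    Pass is inclusive (``U <= margin``); percentages are rounded half-up
    to whole percent.  Indexed by margin, one column per axis; the
    percentage is non-decreasing in the margin on every axis.
    """
    if not cohort:
        raise ValueError("empty cohort")
    u = np.stack([p.u_combined for p in cohort])  # (n_patients, 3)
    rows = {}
    for m in margins_mm:
        pct = _round_half_up(100.0 * (u <= m).mean(axis=0))
        rows[float(m)] = dict(zip(_AXIS_COLS, pct))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "margin_mm"
    return df


def cohort_global_uncertainty(
    steps: pd.DataFrame,
    k: float = COVERAGE_FACTOR,
    tracking: TrackingTerm | None = None,
) -> list[PatientUncertainty]:
    """Per-patient combined uncertainties from a step-uncertainty table.

    ``steps`` is shaped like :func:`ptvmargin.reference.reference_step_uncertainties`:
    indexed by patient id with ``u_deformation``, ``u_seeds_mean`` and
    per-axis ``u_corr_*_mean`` / ``u_pred_*_mean`` columns (expanded mm).
    """
    out = []
    for pid, row in steps.iterrows():
        out.append(
            patient_uncertainty_from_steps(
                str(pid),
                row["u_deformation"],
                row["u_seeds_mean"],
                [row[f"u_corr_{ax}_mean"] for ax in _AXIS_COLS],
                [row[f"u_pred_{ax}_mean"] for ax in _AXIS_COLS],
                k=k,
                tracking=tracking,
            )
        )
    return out


@dataclass
class ReferenceReport:
    """Recomputed margin budget of the embedded reference cohort."""

    global_uncertainty: pd.DataFrame  # per patient/axis, computed U (mm)
    global_uncertainty_deviation: pd.DataFrame  # computed - published (mm)
    margin_table: pd.DataFrame  # computed pass percentages
    published_margin_table: pd.DataFrame
    cohort_motion: pd.DataFrame  # cohort mean/SD of Rm and R95 per axis
    u_min: float  # min computed U over patients/axes, mm
    u_max: float
    patients_over_5mm: list[str]

    def summary_text(self) -> str:
        lines = [
            "Reference-cohort margin budget (recomputed)",
            "===========================================",
            "",
            "Expanded global uncertainty U = 2*sqrt(sum_m (U_m/2)^2), mm:",
            self.global_uncertainty.round(2).to_string(),
            "",
            f"Range over patients/axes: {self.u_min:.1f} - {self.u_max:.1f} mm",
            f"Patients exceeding 5 mm on some axis: "
            f"{', '.join(self.patients_over_5mm) or 'none'}",
            "",
            "Margin pass percentages (computed | published):",
        ]
        merged = self.margin_table.astype(str) + " | " + self.published_margin_table.astype(str)
        lines.append(merged.to_string())
        lines += [
            "",
            "Cohort motion (mean over per-patient means, mm):",
            self.cohort_motion.round(2).to_string(),
            "",
            "Max |computed - published| global uncertainty: "
            f"{self.global_uncertainty_deviation.abs().to_numpy().max():.2f} mm",
        ]
        return "\n".join(lines)


def reproduce_reference(
    cohort: ReferenceCohort | None = None,
    margins_mm=DEFAULT_MARGINS_MM,
    tracking: TrackingTerm | None = None,
) -> ReferenceReport:
    """Recompute the reference cohort's full margin budget from its inputs.

    Combines each patient's published step uncertainties by quadrature,
    expands with k=2, evaluates the margin grid, and summarizes the
    cohort motion table — reporting per-cell deviations from the
    published global-uncertainty values rather than forcing agreement
    (the published step values are rounded to one decimal, which
    propagates visibly into a few cells).
    """
    ref = cohort or load_reference_cohort()
    patients = cohort_global_uncertainty(ref.step_uncertainties, tracking=tracking)
    computed = pd.DataFrame(
        np.stack([p.u_combined for p in patients]),
        index=[p.patient_id for p in patients],
        columns=list(_AXIS_COLS),
    )
    computed.index.name = "patient_id"
    deviation = computed - ref.published_global_uncertainty
    table = margin_pass_table(patients, margins_mm)
    u = computed.to_numpy()
    over = computed.index[(u > 5.0).any(axis=1)].tolist()
    return ReferenceReport(
        global_uncertainty=computed,
        global_uncertainty_deviation=deviation,
        margin_table=table,
        published_margin_table=ref.published_margin_table,
        cohort_motion=cohort_stats_from_patient_means(ref.motion),
        u_min=float(u.min()),
        u_max=float(u.max()),
        patients_over_5mm=over,
    )
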