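"""Published 16-patient thoracic reference cohort.

A retrospective fiducial-tracking study of 16 thoracic-tumor patients
(54 fractions) treated on a robotic radiosurgery system reported, per
patient: the planning-CT seed-configuration geometry relative to the CTV,
per-axis motion-range summaries (mean and 95th-percentile peak-to-trough
amplitudes over fractions), and the four assigned/estimated step
uncertainties (deformation, seed-configuration, correlation model,
prediction model) as mean ± SD across fractions.  Those per-patient
values are transcribed here verbatim and serve as the input cohort for
the margin-budget computation, which this package reproduces end to end.

The published per-patient expanded global uncertainties and margin pass
percentages are also embedded, but only as comparison values — the
package always recomputes them from the step uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .log_model import PatientGeometry

__all__ = [
    "ReferenceCohort",
    "load_reference_cohort",
    "reference_geometry",
    "reference_motion",
    "reference_step_uncertainties",
    "reference_global_uncertainty",
    "reference_margin_table",
]

# patient_id, seeds implanted, seeds tracking, CoM->CTV-center (mm),
# CoM->closest-CTV-border (mm, negative = CoM inside the CTV)
_GEOMETRY = (
    (1, 4, 4, 10.7, 1.4),
    (2, 3, 3, 24.6, -4.2),
    (3, 4, 4, 13.4, 3.2),
    (4, 4, 4, 18.2, 5.0),
    (5, 3, 3, 10.9, -0.9),
    (6, 4, 3, 22.9, 12.2),
    (7, 3, 2, 15.0, -2.3),
    (8, 4, 4, 5.6, -1.0),
    (9, 4, 4, 13.3, 8.6),
    (10, 2, 2, 6.3, -2.6),
    (11, 3, 2, 19.9, 15.2),
    (12, 4, 3, 11.5, -0.6),
    (13, 3, 2, 25.2, 17.2),
    (14, 3, 2, 20.0, 17.0),
    (15, 2, 2, 29.0, 21.0),
    (16, 4, 3, 9.5, 2.3),
)

# Per-patient motion ranges, mean +/- SD over 3-5 fractions:
# Rm (mean peak-to-trough amplitude) and R95% per axis, mm.
# columns: rm_si, rm_lat, rm_ap, r95_si, r95_lat, r95_ap as (mean, sd)
_MOTION = (
    ((17.0, 0.4), (1.6, 0.5), (1.6, 0.2), (22.6, 1.9), (2.2, 0.5), (2.3, 0.1)),
    ((0.3, 0.1), (0.3, 0.1), (0.2, 0.1), (0.7, 0.1), (0.6, 0.2), (0.5, 0.1)),
    ((4.1, 0.4), (0.4, 0.2), (1.7, 0.1), (5.1, 0.7), (1.1, 0.4), (2.4, 0.1)),
    ((0.2, 0.1), (0.3, 0.1), (0.4, 0.1), (0.5, 0.3), (1.0, 0.4), (0.9, 0.3)),
    ((13.5, 0.3), (1.0, 0.1), (1.6, 0.4), (18.5, 0.9), (1.9, 0.1), (3.0, 0.2)),
    ((4.4, 0.6), (0.4, 0.2), (0.8, 0.3), (6.3, 0.2), (1.2, 0.3), (2.1, 0.4)),
    ((8.6, 0.7), (2.9, 0.4), (2.0, 0.4), (11.3, 0.9), (4.0, 0.7), (2.8, 0.3)),
    ((3.9, 1.4), (0.6, 0.7), (4.0, 0.4), (7.9, 0.9), (0.6, 0.7), (6.2, 0.9)),
    ((2.3, 0.5), (1.5, 0.3), (3.3, 0.3), (3.6, 0.5), (2.5, 0.2), (4.6, 0.5)),
    ((8.1, 0.3), (1.0, 0.4), (3.2, 1.2), (10.2, 0.6), (1.6, 0.4), (4.4, 1.6)),
    ((14.0, 0.6), (2.0, 0.1), (0.9, 0.2), (24.0, 4.1), (4.1, 1.2), (2.1, 0.5)),
    ((1.4, 0.2), (0.5, 0.1), (2.2, 0.5), (2.7, 0.5), (1.2, 0.3), (4.3, 1.4)),
    ((7.1, 2.3), (1.6, 1.0), (9.3, 3.6), (10.9, 2.6), (3.0, 1.0), (14.4, 4.0)),
    ((1.5, 0.2), (4.3, 0.1), (1.7, 0.4), (2.7, 0.2), (6.4, 1.0), (3.5, 0.7)),
    ((10.6, 0.9), (0.8, 0.3), (1.2, 0.3), (15.1, 1.1), (1.7, 0.3), (2.1, 0.4)),
    ((3.7, 0.3), (0.6, 0.2), (2.8, 0.9), (5.1, 0.3), (1.0, 0.1), (4.3, 1.2)),
)

# Per-patient step uncertainties U (expanded, mm).  Deformation is a single
# assigned constant (no SD); the rest are mean +/- SD across fractions.
# columns: u_def, u_seeds, u_corr_si, u_corr_lat, u_corr_ap,
#          u_pred_si, u_pred_lat, u_pred_ap
_STEPS = (
    (3.0, (0.9, 0.2), (3.4, 0.3), (1.0, 0.2), (0.6, 0.1), (1.2, 0.2), (0.3, 0.1), (0.2, 0.1)),
    (2.1, (0.9, 0.3), (0.5, 0.2), (0.7, 0.2), (0.4, 0.2), (0.1, 0.1), (0.1, 0.1), (0.1, 0.1)),
    (3.0, (1.2, 0.2), (1.2, 0.2), (1.0, 0.2), (0.9, 0.1), (0.3, 0.1), (0.2, 0.1), (0.2, 0.1)),
    (3.0, (1.0, 0.4), (0.6, 0.1), (1.2, 0.2), (1.0, 0.1), (0.1, 0.1), (0.2, 0.1), (0.1, 0.1)),
    (2.1, (1.0, 0.2), (2.5, 0.3), (1.4, 0.1), (2.3, 0.3), (1.0, 0.1), (0.4, 0.1), (0.2, 0.1)),
    (3.0, (1.8, 0.2), (1.1, 0.1), (1.1, 0.5), (1.9, 0.3), (0.4, 0.1), (0.2, 0.1), (0.2, 0.1)),
    (2.1, (2.0, 1.0), (2.8, 0.3), (1.1, 0.3), (0.8, 0.1), (0.6, 0.1), (0.2, 0.1), (0.1, 0.1)),
    (2.1, (1.0, 0.1), (1.9, 0.5), (1.1, 0.3), (0.9, 0.2), (0.4, 0.1), (0.1, 0.1), (0.3, 0.2)),
    (3.0, (0.6, 0.1), (1.6, 0.3), (1.2, 0.3), (1.0, 0.2), (0.3, 0.1), (0.1, 0.1), (0.3, 0.2)),
    (2.1, (1.2, 0.3), (2.5, 0.7), (1.7, 0.3), (2.2, 0.2), (0.8, 0.1), (0.1, 0.1), (0.4, 0.1)),
    (3.0, (0.5, 0.1), (3.9, 0.1), (1.3, 0.3), (0.9, 0.1), (1.4, 0.5), (0.3, 0.1), (0.1, 0.1)),
    (2.1, (1.6, 0.2), (1.1, 0.5), (0.8, 0.3), (1.3, 0.3), (0.4, 0.4), (0.1, 0.1), (0.2, 0.1)),
    (3.0, (1.5, 0.3), (3.0, 0.2), (1.2, 0.4), (3.8, 0.1), (0.8, 0.3), (0.3, 0.1), (1.1, 0.5)),
    (3.0, (1.0, 0.5), (1.6, 0.2), (2.0, 0.2), (2.1, 0.2), (0.2, 0.1), (0.3, 0.1), (0.2, 0.1)),
    (3.0, (1.2, 0.3), (2.6, 0.2), (1.6, 0.4), (1.1, 0.2), (1.2, 0.1), (0.2, 0.1), (0.1, 0.1)),
    (3.0, (1.3, 0.3), (0.7, 0.1), (0.5, 0.1), (1.6, 0.1), (0.3, 0.1), (0.2, 0.1), (0.3, 0.1)),
)

# Published per-patient expanded global uncertainty U (k=2), mm, per axis —
# comparison values only, never inputs.
_GLOBAL_U = (
    (4.8, 3.3, 3.2),
    (2.3, 2.4, 2.3),
    (3.4, 3.4, 3.4),
    (3.2, 3.4, 3.3),
    (3.6, 2.7, 3.3),
    (3.7, 3.7, 4.0),
    (4.1, 3.1, 3.0),
    (3.0, 2.6, 2.5),
    (3.5, 3.3, 3.2),
    (3.5, 2.9, 3.3),
    (5.1, 3.3, 3.2),
    (2.9, 2.8, 3.0),
    (4.6, 3.6, 5.2),
    (3.6, 3.7, 3.8),
    (4.2, 3.6, 3.5),
    (3.4, 3.4, 3.7),
)

# Published percentage of patients within each candidate margin, per axis.
_MARGIN_TABLE = (
    (2, 0, 0, 0),
    (3, 12, 25, 12),
    (4, 68, 100, 93),
    (5, 94, 100, 94),
    (6, 100, 100, 100),
)


def reference_geometry() -> list[PatientGeometry]:
    """Seed-configuration geometry for the 16 reference patients."""
    return [
        PatientGeometry(
            patient_id=str(pid),
            n_seeds_implanted=ni,
            n_seeds_tracking=nt,
            dist_com_to_ctv_center=dc,
            dist_com_to_ctv_border=db,
        )
        for pid, ni, nt, dc, db in _GEOMETRY
    ]


def reference_motion() -> pd.DataFrame:
    """Per-patient Rm / R95% motion summaries (mean, sd) per axis, mm."""
    cols = ["rm_si", "rm_lat", "rm_ap", "r95_si", "r95_lat", "r95_ap"]
    data = {}
    for j, c in enumerate(cols):
        data[f"{c}_mean"] = [row[j][0] for row in _MOTION]
        data[f"{c}_sd"] = [row[j][1] for row in _MOTION]
    df = pd.DataFrame(data, index=[str(p) for p in range(1, 17)])
    df.index.name = "patient_id"
    return df


def reference_step_uncertainties() -> pd.DataFrame:
    """Per-patient expanded step uncertainties U (mm), mean and SD.

    The deformation term is a single assigned constant (identical on all
    axes, no fraction-to-fraction SD); the seed-configuration term is one
    value applied to all axes; correlation and prediction are per axis.
    """
    rows = []
    for row in _STEPS:
        u_def = row[0]
        (u_seeds, sd_seeds) = row[1]
        rows.append(
            {
                "u_deformation": u_def,
                "u_seeds_mean": u_seeds,
                "u_seeds_sd": sd_seeds,
                "u_corr_si_mean": row[2][0], "u_corr_si_sd": row[2][1],
                "u_corr_lat_mean": row[3][0], "u_corr_lat_sd": row[3][1],
                "u_corr_ap_mean": row[4][0], "u_corr_ap_sd": row[4][1],
                "u_pred_si_mean": row[5][0], "u_pred_si_sd": row[5][1],
                "u_pred_lat_mean": row[6][0], "u_pred_lat_sd": row[6][1],
                "u_pred_ap_mean": row[7][0], "u_pred_ap_sd": row[7][1],
            }
        )
    df = pd.DataFrame(rows, index=[str(p) for p in range(1, 17)])
    df.index.name = "patient_id"
    return df


def reference_global_uncertainty() -> pd.DataFrame:
    """Published expanded global uncertainty per patient/axis (comparison only)."""
    df = pd.DataFrame(_GLOBAL_U, columns=["si", "lat", "ap"], index=[str(p) for p in range(1, 17)])
    df.index.name = "patient_id"
    return df


def reference_margin_table() -> pd.DataFrame:
    """Published margin pass percentages per axis (comparison only)."""
    df = pd.DataFrame(_MARGIN_TABLE, columns=["margin_mm", "si", "lat", "ap"])
    return df.set_index("margin_mm")


@dataclass(frozen=True)
class ReferenceCohort:
    geometry: tuple[PatientGeometry, ...]
    motion: pd.DataFrame
    step_uncertainties: pd.DataFrame
    published_global_uncertainty: pd.DataFrame
    published_margin_table: pd.DataFrame

    @property
    def n_patients(self) -> int:
        return len(self.geometry)


def load_reference_cohort() -> ReferenceCohort:
    """All embedded reference-cohort tables as one immutable bundle."""
    return ReferenceCohort(
        geometry=tuple(reference_geometry()),
        motion=reference_motion(),
        step_uncertainties=reference_step_uncertainties(),
        published_global_uncertainty=reference_global_uncertainty(),
        published_margin_table=reference_margin_table(),
    )
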