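"""Per-step uncertainty estimators for the four-stage tracking chain.

Localizing a CTV point through fiducial tracking decomposes into four
steps, each contributing a geometric uncertainty:

1. *Deformation* — the seed CoM is a surrogate for the CTV; tumor
   deformation/rotation decorrelates the two.  Assigned from the
   planning-CT geometry (published deformation-field analyses give
   2.1 mm with the CoM inside the CTV, 3.0 mm outside but within 30 mm
   of the border).
2. *Seeds* — the implanted configuration is not rigid; the live CoM
   wanders around the CT CoM.  Estimated from signed inter-seed distance
   changes between CT and each live image, halved (in the two-seed case
   a distance change of d moves the CoM by d/2).
3. *Correlation* — the external-marker-to-internal-CoM correlation model
   errs; estimated from the correlation-error stream after excluding
   model-build and rebuild-trigger samples.
4. *Prediction* — the 115 ms look-ahead predictor errs; estimated from
   the predictor-vs-correlation error stream, irrespective of beam
   status.

Steps 2-4 all reduce an error distribution to an expanded uncertainty
``U = |mu| + 2*sigma`` (sample SD), with standard uncertainty
``e = U / 2`` under a normal-PDF assumption.  All values in mm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .log_model import (
    AXES,
    CorrelationFlag,
    FiducialSet,
    LiveImageRecord,
    PatientGeometry,
    TrackingInfeasibleError,
    validate_correlation,
    validate_prediction,
)

__all__ = [
    "StepUncertainty",
    "SRerrorSeries",
    "DeformationRuleNotApplicable",
    "DEFORMATION_U_INSIDE_MM",
    "DEFORMATION_U_NEAR_MM",
    "DEFORMATION_BORDER_CUT_MM",
    "SRERROR_STANDARD_LIMIT_MM",
    "SRERROR_SEED_REMOVAL_MM",
    "SRERROR_TREAT_LIMIT_MM",
    "CORRELATION_REBUILD_MM",
    "CORRELATION_REBUILD_RUN",
    "assign_deformation_uncertainty",
    "solid_rigid_error",
    "sr_error_series",
    "detect_seed_migration",
    "pairwise_distance_deltas",
    "seeds_uncertainty",
    "filter_correlation_samples",
    "correlation_uncertainty",
    "prediction_uncertainty",
    "fraction_step_uncertainties",
    "aggregate_over_fractions",
]

# Deformation-step assignment rule (from published deformation-field data)
DEFORMATION_U_INSIDE_MM = 2.1  # seed CoM inside the CTV
DEFORMATION_U_NEAR_MM = 3.0  # outside, border distance < 30 mm
DEFORMATION_BORDER_CUT_MM = 30.0  # beyond: no rule, case-by-case analysis

# Solid-rigid-error operating thresholds
SRERROR_STANDARD_LIMIT_MM = 1.5
SRERROR_SEED_REMOVAL_MM = 3.0  # persistent excess triggers seed disabling
SRERROR_TREAT_LIMIT_MM = 5.0  # system refuses to treat above this

# Correlation-model rebuild rule: error > 3 mm three times consecutively
CORRELATION_REBUILD_MM = 3.0
CORRELATION_REBUILD_RUN = 3

_ERR_COLS = ["err_si", "err_lat", "err_ap"]


class DeformationRuleNotApplicable(ValueError):
    """Seed CoM is >=30 mm outside the CTV: no tabulated uncertainty applies."""


@dataclass
class StepUncertainty:
    """Expanded (U) and standard (e = U/2) uncertainty of one step, per axis."""

    step: str  # deformation | seeds | correlation | prediction
    u: np.ndarray  # (3,) mm, expanded
    n_samples: int = 0
    mu: np.ndarray | None = None  # (3,) mm where an error distribution exists
    sigma: np.ndarray | None = None  # (3,) mm, sample SD
    out_of_rule: bool = False

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (3,):
            raise ValueError("u must be a per-axis 3-vector")
        if not self.out_of_rule and np.any(self.u < 0):
            raise ValueError("uncertainties must be non-negative")

    @property
    def e(self) -> np.ndarray:
        """Standard uncertainty, exactly half the expanded value."""
        return self.u / 2.0


@dataclass
class SRerrorSeries:
    """Solid rigid error per live image, with operating-threshold flags."""

    timestamps: np.ndarray  # (n,) s
    values: np.ndarray  # (n,) mm, >= 0
    over_standard: np.ndarray = field(init=False)  # > 1.5 mm
    over_removal: np.ndarray = field(init=False)  # > 3 mm
    over_treat: np.ndarray = field(init=False)  # > 5 mm

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("SRerror is a maximum of absolute values, must be >= 0")
        self.over_standard = self.values > SRERROR_STANDARD_LIMIT_MM
        self.over_removal = self.values > SRERROR_SEED_REMOVAL_MM
        self.over_treat = self.values > SRERROR_TREAT_LIMIT_MM


def _mu_2sigma(samples: np.ndarray, literal_variance: bool = False) -> tuple[float, float, float]:
    """U = |mu| + 2*sigma of a 1-D sample set (sample SD, ddof=1)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need >=2 samples for a |mu|+2*sigma estimate")
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    spread = sigma**2 if literal_variance else sigma
    return abs(mu) + 2.0 * spread, mu, sigma


def assign_deformation_uncertainty(geom: PatientGeometry) -> StepUncertainty:
    """Step-1 uncertainty from the CT geometry; same value on all axes.

    Border distance <= 0 (CoM inside the CTV) -> 2.1 mm; within 30 mm
    outside -> 3.0 mm; at or beyond 30 mm no tabulated value exists and
    :class:`DeformationRuleNotApplicable` is raised — such a
    configuration needs a dedicated analysis, never a silent number.
    """
    d = geom.dist_com_to_ctv_border
    if d <= 0:
        u = DEFORMATION_U_INSIDE_MM
    elif d < DEFORMATION_BORDER_CUT_MM:
        u = DEFORMATION_U_NEAR_MM
    else:
        raise DeformationRuleNotApplicable(
            f"patient {geom.patient_id}: seed CoM is {d:g} mm outside the CTV "
            f"(>= {DEFORMATION_BORDER_CUT_MM:g} mm); no assigned uncertainty"
        )
    return StepUncertainty(step="deformation", u=np.full(3, u))


def _pair_distances(positions: np.ndarray, mask: np.ndarray) -> dict[tuple[int, int], float]:
    idx = np.flatnonzero(mask)
    return {
        (i, j): float(np.linalg.norm(positions[i] - positions[j]))
        for i, j in itertools.combinations(idx, 2)
    }


def solid_rigid_error(ct: FiducialSet, live: LiveImageRecord) -> float:
    """Maximum absolute CT-vs-live inter-seed distance change, mm.

    A proxy for deformation/migration of the implanted configuration:
    0 for a rigidly translated/rotated configuration.
    """
    mask = ct.enabled & live.valid
    if int(mask.sum()) < 2:
        raise TrackingInfeasibleError("SRerror needs >=2 seeds valid in CT and live")
    d_ct = _pair_distances(ct.positions, mask)
    d_live = _pair_distances(live.positions, mask)
    return max(abs(d_ct[p] - d_live[p]) for p in d_ct)


def sr_error_series(ct: FiducialSet, lives: list[LiveImageRecord]) -> SRerrorSeries:
    return SRerrorSeries(
        timestamps=np.array([rec.timestamp for rec in lives]),
        values=np.array([solid_rigid_error(ct, rec) for rec in lives]),
    )


def detect_seed_migration(
    ct: FiducialSet,
    lives: list[LiveImageRecord],
    threshold_mm: float = SRERROR_SEED_REMOVAL_MM,
    persistence: float = 0.5,
) -> tuple[set[str], bool]:
    """Identify migrated/uncorrelated seeds to disable from tracking.

    If the SRerror exceeds ``threshold_mm`` in more than ``persistence``
    of the live images, the seed whose removal most reduces the median
    SRerror is disabled, and the check repeats on the reduced
    configuration.  Tracking needs at least two seeds, so if a removal
    would drop below two the situation is only flagged.

    Returns ``(disabled_seed_ids, flagged)`` where ``flagged`` means a
    persistent excess remained that could not be resolved by removal.
    """
    current = ct
    disabled: set[str] = set()
    while True:
        series = sr_error_series(current, lives)
        frac_over = float(np.mean(series.values > threshold_mm))
        if frac_over <= persistence:
            return disabled, False
        if current.n_enabled <= 2:
            return disabled, True
        candidates = [s for s, on in zip(current.seed_ids, current.enabled) if on]
        best_seed, best_median = None, np.inf
        for seed in candidates:
            trial = current.disable(seed)
            med = float(np.median(sr_error_series(trial, lives).values))
            if med < best_median:
                best_seed, best_median = seed, med
        current = current.disable(best_seed)
        disabled.add(best_seed)


def pairwise_distance_deltas(ct: FiducialSet, lives: list[LiveImageRecord]) -> np.ndarray:
    """Signed live-minus-CT inter-seed distance changes, mm.

    One sample per enabled seed pair per live image; positive when seeds
    separate relative to the CT, negative when they close in.
    """
    if ct.n_enabled < 2:
        raise TrackingInfeasibleError("need >=2 enabled seeds")
    samples = []
    for rec in lives:
        mask = ct.enabled & rec.valid
        if int(mask.sum()) < 2:
            continue
        d_ct = _pair_distances(ct.positions, mask)
        d_live = _pair_distances(rec.positions, mask)
        samples.extend(d_live[p] - d_ct[p] for p in d_ct)
    return np.asarray(samples, dtype=float)


def seeds_uncertainty(samples: np.ndarray, literal_variance: bool = False) -> StepUncertainty:
    """Step-2 uncertainty from inter-seed distance changes; same on all axes.

    Each signed distance change is halved before taking ``|mu|+2*sigma``:
    with two seeds, the CoM moves by half of any distance change, and
    that is taken as the worst case regardless of seed count.

    ``literal_variance`` switches the spread term to ``2*sigma**2``.
    The default is ``2*sigma``, which is dimensionally consistent (mm,
    matching the correlation and prediction estimators); the variance
    form is exposed only for comparison.
    """
    halved = np.asarray(samples, dtype=float) / 2.0
    u, mu, sigma = _mu_2sigma(halved, literal_variance=literal_variance)
    return StepUncertainty(
        step="seeds",
        u=np.full(3, u),
        n_samples=halved.size,
        mu=np.full(3, mu),
        sigma=np.full(3, sigma),
    )


def filter_correlation_samples(
    correlation: pd.DataFrame,
    rebuild_threshold_mm: float = CORRELATION_REBUILD_MM,
    rebuild_run: int = CORRELATION_REBUILD_RUN,
) -> pd.DataFrame:
    """Drop correlation samples that never describe treatment-time accuracy.

    Excluded: samples flagged as model-build (pre-irradiation) or
    rebuild-trigger, and any run of ``rebuild_run`` or more consecutive
    samples whose error exceeds ``rebuild_threshold_mm`` on some axis —
    those runs are what forces a model rebuild.
    """
    validate_correlation(correlation)
    df = correlation.reset_index(drop=True)
    flag = df["flag"].astype(str)
    drop = flag.isin([CorrelationFlag.MODEL_BUILD.value, CorrelationFlag.REBUILD_TRIGGER.value]).to_numpy()
    over = (df[_ERR_COLS].abs().to_numpy() > rebuild_threshold_mm).any(axis=1)
    # mark maximal runs of consecutive over-threshold samples of length >= rebuild_run
    n = len(df)
    i = 0
    while i < n:
        if over[i]:
            j = i
            while j < n and over[j]:
                j += 1
            if j - i >= rebuild_run:
                drop[i:j] = True
            i = j
        else:
            i += 1
    return df.loc[~drop].reset_index(drop=True)


def _per_axis_mu_2sigma(df: pd.DataFrame, step: str, literal_variance: bool = False) -> StepUncertainty:
    errs = df[_ERR_COLS].to_numpy(dtype=float)
    if errs.shape[0] < 2:
        raise ValueError(f"{step}: need >=2 samples, got {errs.shape[0]}")
    u = np.empty(3)
    mu = np.empty(3)
    sigma = np.empty(3)
    for ax in AXES:
        u[ax], mu[ax], sigma[ax] = _mu_2sigma(errs[:, ax], literal_variance)
    return StepUncertainty(step=step, u=u, n_samples=errs.shape[0], mu=mu, sigma=sigma)


def correlation_uncertainty(retained: pd.DataFrame) -> StepUncertainty:
    """Step-3 uncertainty: per-axis |mu|+2*sigma of retained correlation errors."""
    return _per_axis_mu_2sigma(retained, "correlation")


def prediction_uncertainty(prediction: pd.DataFrame) -> StepUncertainty:
    """Step-4 uncertainty: per-axis |mu|+2*sigma of 115 ms predictor errors.

    All samples are used regardless of beam status.
    """
    validate_prediction(prediction)
    return _per_axis_mu_2sigma(prediction, "prediction")


def fraction_step_uncertainties(
    ds,
    geometry: PatientGeometry,
    literal_seed_variance: bool = False,
) -> dict[str, StepUncertainty]:
    """All four step uncertainties for one fraction, keyed by step name."""
    deltas = pairwise_distance_deltas(ds.fiducials, ds.live_images)
    retained = filter_correlation_samples(ds.correlation)
    return {
        "deformation": assign_deformation_uncertainty(geometry),
        "seeds": seeds_uncertainty(deltas, literal_variance=literal_seed_variance),
        "correlation": correlation_uncertainty(retained),
        "prediction": prediction_uncertainty(ds.prediction),
    }


def aggregate_over_fractions(per_fraction: list[dict[str, StepUncertainty]]) -> pd.DataFrame:
    """Mean and SD of each step's U across a patient's fractions.

    Returns a frame indexed by step with columns
    ``u_{si,lat,ap}_mean`` and ``u_{si,lat,ap}_sd`` (sample SD; NaN for a
    single fraction).
    """
    if not per_fraction:
        raise ValueError("no fractions to aggregate")
    steps = per_fraction[0].keys()
    rows = {}
    for step in steps:
        stack = np.stack([frac[step].u for frac in per_fraction])  # (n_frac, 3)
        row = {}
        for ax in AXES:
            name = ax.label.lower()
            row[f"u_{name}_mean"] = stack[:, ax].mean()
            row[f"u_{name}_sd"] = stack[:, ax].std(ddof=1) if stack.shape[0] > 1 else np.nan
        rows[step] = row
    return pd.DataFrame.from_dict(rows, orient="index")
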