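"""Synthetic tracking-log generator with known ground truth.

Emulates the measurement chain of a fiducial-based respiratory tracking
fraction well enough that every downstream estimator can be validated
against generating values:

* a quasi-periodic breathing waveform — by default ``cos**4``-shaped,
  which dwells near the exhale baseline (planning CTs are acquired at
  exhale, the longer phase) — with per-cycle period jitter and a linear
  baseline drift along the dominant-motion direction;
* a rigid CT seed configuration carried along the breathing motion, with
  independent isotropic Gaussian per-seed jitter (configuration
  deformation), sampled at the live X-ray cadence (~1/min);
* correlation-model errors drawn per axis from ``Normal(mu_c, sigma_c)``,
  with the first samples flagged as model-build;
* predictor errors drawn per axis from ``Normal(0, scale * amplitude)``
  — predictor error grows with motion amplitude, matching the observed
  positive error-vs-range correlation.

Default values describe a typical mid-size thoracic case: per-axis
amplitudes reproducing the reference cohort's mean peak-to-trough ranges
(6.3 / 1.2 / 2.3 mm SI/LAT/AP), a 4 s breathing period, a 60 s X-ray
interval and a 30-minute fraction.

Randomness derives from one seed through named child streams in a fixed
spawn order, so adding a stream never perturbs the others and identical
parameters yield bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .log_model import (
    CorrelationFlag,
    FiducialSet,
    FractionDataset,
    LiveImageRecord,
    PatientGeometry,
)
from .step_uncertainty import (
    DEFORMATION_BORDER_CUT_MM,
    DEFORMATION_U_INSIDE_MM,
    DEFORMATION_U_NEAR_MM,
)

__all__ = ["SimulationParams", "GroundTruth", "SimulatedPatient", "simulate_fraction", "make_cohort"]

_STREAMS = ("phase", "seed_jitter", "correlation", "prediction")


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters of one synthetic fraction (lengths in mm)."""

    amplitude_mm: tuple[float, float, float] = (3.15, 0.6, 1.15)  # peak-to-trough / 2
    period_s: float = 4.0
    period_jitter: float = 0.05  # SD of per-cycle period, fraction of period
    drift_mm_per_min: float = 0.5  # baseline drift along dominant-motion direction
    seed_jitter_sd_mm: float = 0.5  # per-seed isotropic configuration jitter
    correlation_mu_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    correlation_sd_mm: tuple[float, float, float] = (0.75, 0.35, 0.45)
    prediction_sd_scale: float = 0.08  # predictor SD = scale * per-axis amplitude
    xray_interval_s: float = 60.0
    fraction_duration_s: float = 1800.0
    model_rate_hz: float = 4.0  # correlation/prediction sampling rate
    n_model_build_samples: int = 8
    n_seeds: int = 3
    seed_spread_mm: float = 15.0  # radius of the implanted configuration
    ctv_radius_mm: float = 15.0
    com_offset_mm: tuple[float, float, float] = (8.0, 3.0, 3.0)  # seed CoM - CTV center
    waveform: str = "cos4"  # or "sin"
    random_seed: int = 0

    def validate(self) -> "SimulationParams":
        amp = np.asarray(self.amplitude_mm, dtype=float)
        if amp.shape != (3,) or np.any(amp < 0):
            raise ValueError("amplitude_mm must be three non-negative values")
        for name in ("period_jitter", "seed_jitter_sd_mm", "prediction_sd_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if np.any(np.asarray(self.correlation_sd_mm) < 0):
            raise ValueError("correlation_sd_mm must be >= 0")
        if self.period_s <= 0 or self.model_rate_hz <= 0 or self.xray_interval_s <= 0:
            raise ValueError("period, model rate and x-ray interval must be positive")
        if self.fraction_duration_s < 2 * self.xray_interval_s:
            raise ValueError("fraction must span at least two x-ray intervals")
        if self.n_seeds < 2:
            raise ValueError("tracking needs at least 2 seeds")
        if self.waveform not in ("cos4", "sin"):
            raise ValueError("waveform must be 'cos4' or 'sin'")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Generating values each estimator should recover."""

    u_deformation: float  # mm, from the geometry assignment rule
    u_seeds: float  # mm = sqrt(2) * seed jitter SD (see docs)
    u_correlation: np.ndarray  # (3,) mm = |mu_c| + 2*sigma_c
    u_prediction: np.ndarray  # (3,) mm = 2 * scale * amplitude
    rm: np.ndarray  # (3,) mm = 2 * amplitude
    r95: np.ndarray  # (3,) mm
    geometry: PatientGeometry | None = None

    def __post_init__(self):
        for name in ("u_correlation", "u_prediction", "rm", "r95"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if np.any(v < 0):
                raise ValueError(f"{name} must be >= 0")


def _breathing_phase(t: np.ndarray, params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Cumulative phase in cycles; each cycle's period is jittered."""
    n_cycles = int(np.ceil(t[-1] / params.period_s)) + 3
    periods = params.period_s * (1.0 + params.period_jitter * rng.standard_normal(n_cycles))
    periods = np.maximum(periods, 0.2 * params.period_s)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    k = np.searchsorted(boundaries, t, side="right") - 1
    return k + (t - boundaries[k]) / periods[k]


def _waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Unit waveform in [0, 1]; 0 is the exhale baseline, 1 full inhale."""
    if kind == "cos4":
        return np.cos(np.pi * phase) ** 4
    return 0.5 * (1.0 + np.sin(2.0 * np.pi * phase))


def _ct_configuration(params: SimulationParams) -> np.ndarray:
    """Deterministic seed positions: spread on a circle, zero mean offsetting."""
    n = params.n_seeds
    ang = 2.0 * np.pi * np.arange(n) / n
    pts = params.seed_spread_mm * np.column_stack(
        [np.cos(ang), np.sin(ang), np.sin(2.0 * ang + 0.5)]
    )
    pts -= pts.mean(axis=0)  # CoM exactly at the nominal offset
    return pts + np.asarray(params.com_offset_mm, dtype=float)


def _geometry(params: SimulationParams, patient_id: str) -> tuple[PatientGeometry, float]:
    center_dist = float(np.linalg.norm(params.com_offset_mm))
    border = center_dist - params.ctv_radius_mm
    geom = PatientGeometry(
        patient_id=patient_id,
        n_seeds_implanted=params.n_seeds,
        n_seeds_tracking=params.n_seeds,
        dist_com_to_ctv_center=center_dist,
        dist_com_to_ctv_border=border,
    )
    if border <= 0:
        u_def = DEFORMATION_U_INSIDE_MM
    elif border < DEFORMATION_BORDER_CUT_MM:
        u_def = DEFORMATION_U_NEAR_MM
    else:
        u_def = float("nan")  # outside the assignment rule
    return geom, u_def


def simulate_fraction(
    params: SimulationParams,
    patient_id: str = "sim",
    fraction_id: str = "f1",
) -> tuple[FractionDataset, GroundTruth]:
    """Generate one fraction and the ground truth its estimators target."""
    params.validate()
    amp = np.asarray(params.amplitude_mm, dtype=float)
    streams = dict(zip(_STREAMS, np.random.SeedSequence(params.random_seed).spawn(len(_STREAMS))))
    rng_phase = np.random.default_rng(streams["phase"])
    rng_jitter = np.random.default_rng(streams["seed_jitter"])
    rng_corr = np.random.default_rng(streams["correlation"])
    rng_pred = np.random.default_rng(streams["prediction"])

    dt = 1.0 / params.model_rate_hz
    t_model = np.arange(0.0, params.fraction_duration_s, dt)
    phase = _breathing_phase(t_model, params, rng_phase)
    unit = _waveform(phase, params.waveform)  # (n,)
    drift_dir = amp / np.linalg.norm(amp) if np.linalg.norm(amp) > 0 else np.zeros(3)
    drift = np.outer(t_model / 60.0 * params.drift_mm_per_min, drift_dir)
    motion = unit[:, None] * (2.0 * amp)[None, :] + drift  # (n, 3)

    ct_positions = _ct_configuration(params)
    fiducials = FiducialSet(
        [f"s{k + 1}" for k in range(params.n_seeds)], ct_positions
    )

    # Live X-ray images: rigid configuration + motion + per-seed jitter
    t_live = np.arange(params.xray_interval_s, params.fraction_duration_s, params.xray_interval_s)
    live_motion = np.column_stack(
        [np.interp(t_live, t_model, motion[:, i]) for i in range(3)]
    )
    live_images = []
    for k, t in enumerate(t_live):
        jitter = params.seed_jitter_sd_mm * rng_jitter.standard_normal((params.n_seeds, 3))
        live_images.append(LiveImageRecord(float(t), ct_positions + live_motion[k] + jitter))

    # Correlation-model samples: modeled CoM trace + error stream
    mu_c = np.asarray(params.correlation_mu_mm, dtype=float)
    sd_c = np.asarray(params.correlation_sd_mm, dtype=float)
    corr_err = mu_c + sd_c * rng_corr.standard_normal((t_model.size, 3))
    com_ct = ct_positions.mean(axis=0)
    # the recorded model trace is the smooth model output; its error vs the
    # live images is carried separately in the err_* columns
    modeled = com_ct[None, :] + motion
    flags = np.full(t_model.size, CorrelationFlag.NORMAL.value, dtype=object)
    flags[: params.n_model_build_samples] = CorrelationFlag.MODEL_BUILD.value
    correlation = pd.DataFrame(
        {
            "time_s": t_model,
            "err_si": corr_err[:, 0],
            "err_lat": corr_err[:, 1],
            "err_ap": corr_err[:, 2],
            "flag": flags,
            "pos_si": modeled[:, 0],
            "pos_lat": modeled[:, 1],
            "pos_ap": modeled[:, 2],
        }
    )

    # Predictor samples: error SD proportional to per-axis amplitude
    pred_sd = params.prediction_sd_scale * amp
    pred_err = pred_sd[None, :] * rng_pred.standard_normal((t_model.size, 3))
    beam_on = t_model > params.n_model_build_samples * dt
    prediction = pd.DataFrame(
        {
            "time_s": t_model,
            "err_si": pred_err[:, 0],
            "err_lat": pred_err[:, 1],
            "err_ap": pred_err[:, 2],
            "beam_on": beam_on,
        }
    )

    ds = FractionDataset(
        patient_id=patient_id,
        fraction_id=fraction_id,
        fiducials=fiducials,
        live_images=live_images,
        correlation=correlation,
        prediction=prediction,
    ).validate()

    geom, u_def = _geometry(params, patient_id)
    truth = GroundTruth(
        u_deformation=u_def,
        # a distance change between two jittered seeds has SD sqrt(2)*sigma
        # (linearized); halving gives sigma/sqrt(2), so U = 2*that
        u_seeds=float(np.sqrt(2.0) * params.seed_jitter_sd_mm),
        u_correlation=np.abs(mu_c) + 2.0 * sd_c,
        u_prediction=2.0 * pred_sd,
        rm=2.0 * amp,
        r95=2.0 * amp,
        geometry=geom,
    )
    return ds, truth


@dataclass
class SimulatedPatient:
    patient_id: str
    params: SimulationParams
    geometry: PatientGeometry
    fractions: list[FractionDataset] = field(default_factory=list)
    ground_truth: GroundTruth | None = None


def make_cohort(
    n_patients: int,
    template: SimulationParams | None = None,
    master_seed: int = 0,
    amplitude_scale_range: tuple[float, float] = (0.5, 2.0),
) -> list[SimulatedPatient]:
    """Simulate a cohort of patients with 3-5 fractions each.

    Per patient, the template's per-axis amplitudes and correlation-error
    SDs are scaled by one uniform draw from ``amplitude_scale_range`` —
    larger movers have larger correlation errors, which is what produces
    the positive error-vs-range correlation across a cohort — and the
    seed-CoM offset is scaled so the cohort mixes CoM-inside and
    CoM-outside CTV geometries.  Everything is reproducible from
    ``master_seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    template = (template or SimulationParams()).validate()
    patient_seqs = np.random.SeedSequence(master_seed).spawn(n_patients)
    cohort = []
    lo, hi = amplitude_scale_range
    for j, seq in enumerate(patient_seqs):
        rng = np.random.default_rng(seq)
        scale = float(rng.uniform(lo, hi))
        offset_scale = float(rng.uniform(0.5, 2.5))  # mixes CoM inside/outside CTV
        n_fractions = int(rng.integers(3, 6))
        fraction_seeds = rng.integers(0, 2**31 - 1, size=n_fractions)
        pid = f"p{j + 1:02d}"
        params = replace(
            template,
            amplitude_mm=tuple(scale * np.asarray(template.amplitude_mm)),
            correlation_sd_mm=tuple(scale * np.asarray(template.correlation_sd_mm)),
            com_offset_mm=tuple(offset_scale * np.asarray(template.com_offset_mm)),
        )
        fractions = []
        truth = None
        for f in range(n_fractions):
            ds, truth = simulate_fraction(
                replace(params, random_seed=int(fraction_seeds[f])),
                patient_id=pid,
                fraction_id=f"f{f + 1}",
            )
            fractions.append(ds)
        cohort.append(
            SimulatedPatient(
                patient_id=pid,
                params=params,
                geometry=truth.geometry,
                fractions=fractions,
                ground_truth=truth,
            )
        )
    return cohort
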