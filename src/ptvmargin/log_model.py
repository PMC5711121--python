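"""Domain types for fiducial-based respiratory tumor tracking logs.

A robotic-radiosurgery respiratory tracking system localizes a moving
thoracic target through the center of mass (CoM) of an implanted fiducial
("seed") configuration.  During a treatment fraction the system records

* live stereo X-ray images of the seed configuration (roughly one per
  minute), from which the live CoM and inter-seed distances are measured;
* a correlation-model error stream: the difference between the internal
  CoM position predicted from external chest markers and the position
  actually measured in each live image;
* a predictor error stream: the difference between the short-horizon
  (115 ms) predictor output and the correlation-model position it tries
  to anticipate.

This module defines the in-memory representation of one treated fraction
and of the per-patient planning-CT geometry, plus the CoM computation.
All lengths are millimetres; the three motion axes are superior-inferior
(SI), lateral (LAT) and anterior-posterior (AP), stored in that order.
Timestamps are seconds from the start of the fraction.

Sample streams (correlation, prediction) are pandas DataFrames with fixed
schemas — see :data:`CORRELATION_COLUMNS` and :data:`PREDICTION_COLUMNS` —
because their only consumers are vectorized filtering and distribution
statistics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Axis",
    "AXES",
    "CorrelationFlag",
    "FiducialSet",
    "LiveImageRecord",
    "PatientGeometry",
    "FractionDataset",
    "TrackingInfeasibleError",
    "compute_com",
    "CORRELATION_COLUMNS",
    "PREDICTION_COLUMNS",
    "validate_correlation",
    "validate_prediction",
    "PREDICTOR_LATENCY_S",
]

#: Robot adjustment latency compensated by the predictor model, seconds.
PREDICTOR_LATENCY_S = 0.115


class Axis(enum.IntEnum):
    """Motion axis; integer value is the column index in 3-vectors."""

    SI = 0  # superior-inferior
    LAT = 1  # lateral
    AP = 2  # anterior-posterior

    @property
    def label(self) -> str:
        return self.name


AXES: tuple[Axis, Axis, Axis] = (Axis.SI, Axis.LAT, Axis.AP)


class CorrelationFlag(str, enum.Enum):
    """Provenance of one correlation-error sample.

    ``MODEL_BUILD`` samples were used to build the model before beam-on;
    ``REBUILD_TRIGGER`` samples caused the model to be discarded and
    rebuilt.  Both are excluded from uncertainty estimation.
    """

    NORMAL = "normal"
    MODEL_BUILD = "model_build"
    REBUILD_TRIGGER = "rebuild_trigger"


class TrackingInfeasibleError(ValueError):
    """Raised when fewer than two usable seeds remain for tracking."""


def _as_positions(positions: np.ndarray, n: int) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.shape != (n, 3):
        raise ValueError(f"positions must have shape ({n}, 3), got {pos.shape}")
    if not np.all(np.isfinite(pos)):
        raise ValueError("seed positions must be finite")
    return pos


@dataclass
class FiducialSet:
    """Implanted seed configuration in the planning-CT patient frame.

    The CoM of the *enabled* seeds is the reference point the tracking
    system follows; seeds found migrated or uncorrelated are disabled.
    """

    seed_ids: tuple[str, ...]
    positions: np.ndarray  # (n_seeds, 3) mm
    enabled: np.ndarray  # (n_seeds,) bool

    def __init__(self, seed_ids: Sequence[str], positions, enabled=None):
        self.seed_ids = tuple(str(s) for s in seed_ids)
        if len(set(self.seed_ids)) != len(self.seed_ids):
            raise ValueError("seed_ids must be unique")
        self.positions = _as_positions(positions, len(self.seed_ids))
        if enabled is None:
            enabled = np.ones(len(self.seed_ids), dtype=bool)
        self.enabled = np.asarray(enabled, dtype=bool)
        if self.enabled.shape != (len(self.seed_ids),):
            raise ValueError("enabled must have one flag per seed")

    @property
    def n_seeds(self) -> int:
        return len(self.seed_ids)

    @property
    def n_enabled(self) -> int:
        return int(self.enabled.sum())

    def com(self) -> np.ndarray:
        return compute_com(self)

    def disable(self, seed_id: str) -> "FiducialSet":
        """Return a copy with ``seed_id`` disabled."""
        if seed_id not in self.seed_ids:
            raise KeyError(f"unknown seed_id {seed_id!r}")
        enabled = self.enabled.copy()
        enabled[self.seed_ids.index(seed_id)] = False
        return FiducialSet(self.seed_ids, self.positions, enabled)


@dataclass
class LiveImageRecord:
    """Seed positions measured in one live stereo X-ray image."""

    timestamp: float  # s from fraction start
    positions: np.ndarray  # (n_seeds, 3) mm, same seed order as FiducialSet
    valid: np.ndarray  # (n_seeds,) bool — seed resolved in this image

    def __init__(self, timestamp: float, positions, valid=None):
        self.timestamp = float(timestamp)
        pos = np.asarray(positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_seeds, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("live seed positions must be finite")
        self.positions = pos
        if valid is None:
            valid = np.ones(pos.shape[0], dtype=bool)
        self.valid = np.asarray(valid, dtype=bool)
        if self.valid.shape != (pos.shape[0],):
            raise ValueError("valid must have one flag per seed")


@dataclass(frozen=True)
class PatientGeometry:
    """Planning-CT relationship between the seed CoM and the CTV.

    ``dist_com_to_ctv_border`` is signed: negative means the seed CoM lies
    inside the CTV, positive means outside (distance to the closest
    border, measured in the three planes).
    """

    patient_id: str
    n_seeds_implanted: int
    n_seeds_tracking: int
    dist_com_to_ctv_center: float  # mm
    dist_com_to_ctv_border: float  # mm, signed

    def __post_init__(self):
        if self.n_seeds_tracking > self.n_seeds_implanted:
            raise ValueError("cannot track more seeds than implanted")
        if self.n_seeds_tracking < 2:
            raise ValueError("tracking requires at least 2 seeds")
        if not np.isfinite(self.dist_com_to_ctv_border):
            raise ValueError("border distance must be finite")


CORRELATION_COLUMNS = (
    "time_s",
    "err_si",
    "err_lat",
    "err_ap",
    "flag",
    "pos_si",
    "pos_lat",
    "pos_ap",
)
PREDICTION_COLUMNS = ("time_s", "err_si", "err_lat", "err_ap", "beam_on")

_FLAG_VALUES = frozenset(f.value for f in CorrelationFlag)


def validate_correlation(df: pd.DataFrame) -> pd.DataFrame:
    """Check a correlation-sample frame against its schema invariants."""
    missing = set(CORRELATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"correlation stream missing columns {sorted(missing)}")
    errs = df[["err_si", "err_lat", "err_ap"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(errs)):
        raise ValueError("correlation errors must be finite")
    bad = set(df["flag"].unique()) - _FLAG_VALUES
    if bad:
        raise ValueError(f"unknown correlation flags {sorted(bad)}")
    return df


def validate_prediction(df: pd.DataFrame) -> pd.DataFrame:
    """Check a prediction-sample frame against its schema invariants."""
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"prediction stream missing columns {sorted(missing)}")
    errs = df[["err_si", "err_lat", "err_ap"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(errs)):
        raise ValueError("prediction errors must be finite")
    return df


@dataclass
class FractionDataset:
    """Everything recorded for one treated fraction of one patient."""

    patient_id: str
    fraction_id: str
    fiducials: FiducialSet
    live_images: list[LiveImageRecord] = field(default_factory=list)
    correlation: pd.DataFrame = field(default_factory=pd.DataFrame)
    prediction: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> "FractionDataset":
        if not self.live_images:
            raise ValueError("fraction has no live images")
        ts = np.array([rec.timestamp for rec in self.live_images])
        if np.any(np.diff(ts) <= 0):
            i = int(np.argmax(np.diff(ts) <= 0)) + 1
            raise ValueError(
                f"live-image timestamps must be strictly increasing "
                f"(violated at record {i}, t={ts[i]:g})"
            )
        n = self.fiducials.n_seeds
        for i, rec in enumerate(self.live_images):
            if rec.positions.shape[0] != n:
                raise ValueError(
                    f"live image {i} has {rec.positions.shape[0]} seeds, "
                    f"fiducial set has {n}"
                )
        validate_correlation(self.correlation)
        validate_prediction(self.prediction)
        for name, frame in (("correlation", self.correlation), ("prediction", self.prediction)):
            t = frame["time_s"].to_numpy(dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                i = int(np.argmax(np.diff(t) <= 0)) + 1
                raise ValueError(
                    f"{name} timestamps must be strictly increasing "
                    f"(violated at sample {i})"
                )
        return self

    def modeled_trace(self) -> pd.DataFrame:
        """Correlation-model CoM trajectory: time_s, si, lat, ap (mm)."""
        return pd.DataFrame(
            {
                "time_s": self.correlation["time_s"].to_numpy(dtype=float),
                "si": self.correlation["pos_si"].to_numpy(dtype=float),
                "lat": self.correlation["pos_lat"].to_numpy(dtype=float),
                "ap": self.correlation["pos_ap"].to_numpy(dtype=float),
            }
        )


def compute_com(obj: FiducialSet | LiveImageRecord) -> np.ndarray:
    """Center of mass (arithmetic mean position) of the usable seeds.

    For a :class:`FiducialSet` the usable seeds are the enabled ones
    (CoM_CT); for a :class:`LiveImageRecord` they are the valid ones
    (CoM_LIVE).  At least two usable seeds are required — a single seed
    does not define a trackable configuration.
    """
    if isinstance(obj, FiducialSet):
        mask = obj.enabled
    elif isinstance(obj, LiveImageRecord):
        mask = obj.valid
    else:
        raise TypeError(f"cannot compute CoM of {type(obj).__name__}")
    if int(mask.sum()) < 2:
        raise TrackingInfeasibleError(
            f"CoM requires >=2 usable seeds, got {int(mask.sum())}"
        )
    return obj.positions[mask].mean(axis=0)
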