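"""Peak-to-trough motion-range statistics of the tracked CoM trajectory.

The breathing motion of a thoracic target is summarized per fraction by
segmenting the correlation-model CoM trajectory into breathing cycles
and measuring, per cycle and axis, the peak-to-trough amplitude
(max - min within the cycle).  Four summaries are reported per axis:

* ``Rm`` — mean cycle amplitude over the fraction;
* ``R95`` — 95th-percentile cycle amplitude (robust to occasional deep
  inspirations or couch moves);
* the median amplitude;
* a trimmed mean over amplitudes between the 5th and 95th percentiles.

No amplitude exclusion criterion is applied before summarizing, and the
intrafraction baseline drift is deliberately not removed: a drifting
baseline inflates per-cycle ranges and that is part of what the margin
must cover.  Quantiles use linear interpolation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .log_model import AXES

__all__ = [
    "MotionRangeSummary",
    "peak_to_trough_amplitudes",
    "summarize_motion",
    "cohort_motion_stats",
    "DEFAULT_BREATHING_PERIOD_S",
]

DEFAULT_BREATHING_PERIOD_S = 4.0

_AXIS_COLS = ("si", "lat", "ap")


@dataclass(frozen=True)
class MotionRangeSummary:
    """Per-axis amplitude summaries of one fraction, mm."""

    rm: np.ndarray  # (3,) mean cycle amplitude
    r95: np.ndarray  # (3,) 95th-percentile cycle amplitude
    median: np.ndarray  # (3,)
    trimmed_mean: np.ndarray  # (3,) mean over [p5, p95] amplitudes
    n_cycles: int

    def __post_init__(self):
        for name in ("rm", "r95", "median", "trimmed_mean"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (3,) or np.any(v < 0):
                raise ValueError(f"{name} must be a non-negative 3-vector")
        if self.n_cycles < 1:
            raise ValueError("need at least one full cycle")


def peak_to_trough_amplitudes(
    trace: pd.DataFrame,
    nominal_period_s: float = DEFAULT_BREATHING_PERIOD_S,
) -> np.ndarray:
    """Per-cycle, per-axis peak-to-trough amplitudes of a CoM trace.

    ``trace`` has columns ``time_s, si, lat, ap`` (mm).  Cycles are
    delimited by successive maxima of the dominant-motion axis after a
    linear detrend, with a minimum peak separation of half the nominal
    breathing period to suppress noise peaks.  Amplitudes are measured
    on the raw (non-detrended) trace.

    Returns an ``(n_cycles, 3)`` array.  Raises ``ValueError`` when no
    full cycle is detectable (e.g. a constant trace).
    """
    t = trace["time_s"].to_numpy(dtype=float)
    pos = trace[list(_AXIS_COLS)].to_numpy(dtype=float)
    if t.size < 3:
        raise ValueError("trace too short to contain a breathing cycle")
    detrended = signal.detrend(pos, axis=0)
    dominant = int(np.argmax(detrended.max(axis=0) - detrended.min(axis=0)))
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError("trace timestamps must be increasing")
    min_sep = max(1, int(round(0.5 * nominal_period_s / dt)))
    y = detrended[:, dominant]
    span = y.max() - y.min()
    if span <= 0:
        raise ValueError("constant trace: no breathing cycles detectable")
    peaks, _ = signal.find_peaks(y, distance=min_sep, prominence=0.1 * span)
    if peaks.size < 2:
        raise ValueError("fewer than one full breathing cycle in trace")
    amps = np.empty((peaks.size - 1, 3))
    for k in range(peaks.size - 1):
        seg = pos[peaks[k] : peaks[k + 1] + 1]
        amps[k] = seg.max(axis=0) - seg.min(axis=0)
    return amps


def summarize_motion(amplitudes: np.ndarray) -> MotionRangeSummary:
    """Reduce an ``(n_cycles, 3)`` amplitude array to per-axis summaries."""
    a = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if a.size == 0:
        raise ValueError("empty amplitude list")
    if a.shape[1] != 3:
        raise ValueError("amplitudes must have one column per axis")
    p5 = np.percentile(a, 5, axis=0)
    p95 = np.percentile(a, 95, axis=0)
    trimmed = np.empty(3)
    for ax in AXES:
        keep = a[(a[:, ax] >= p5[ax]) & (a[:, ax] <= p95[ax]), ax]
        trimmed[ax] = keep.mean() if keep.size else a[:, ax].mean()
    return MotionRangeSummary(
        rm=a.mean(axis=0),
        r95=p95,
        median=np.median(a, axis=0),
        trimmed_mean=trimmed,
        n_cycles=a.shape[0],
    )


def cohort_motion_stats(
    per_patient: dict[str, list[MotionRangeSummary]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level and cohort-level motion statistics.

    ``per_patient`` maps patient id to that patient's per-fraction
    summaries.  Returns ``(patients, cohort)``:

    * ``patients`` — per patient, mean and sample SD (ddof=1) over
      fractions of Rm and R95 per axis;
    * ``cohort`` — per axis, mean and sample SD over the per-patient Rm
      (and R95) means.  Averaging patient means (rather than pooling
      fractions) weights every patient equally.
    """
    rows = {}
    for pid, summaries in per_patient.items():
        if not summaries:
            raise ValueError(f"patient {pid}: no fractions")
        rm = np.stack([s.rm for s in summaries])
        r95 = np.stack([s.r95 for s in summaries])
        row = {}
        for ax in AXES:
            name = ax.label.lower()
            row[f"rm_{name}_mean"] = rm[:, ax].mean()
            row[f"rm_{name}_sd"] = rm[:, ax].std(ddof=1) if rm.shape[0] > 1 else 0.0
            row[f"r95_{name}_mean"] = r95[:, ax].mean()
            row[f"r95_{name}_sd"] = r95[:, ax].std(ddof=1) if r95.shape[0] > 1 else 0.0
        rows[pid] = row
    patients = pd.DataFrame.from_dict(rows, orient="index")
    patients.index.name = "patient_id"
    cohort = cohort_stats_from_patient_means(patients)
    return patients, cohort


def cohort_stats_from_patient_means(patients: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean/SD per axis from a per-patient table of Rm/R95 means.

    Accepts any frame with ``rm_{axis}_mean`` / ``r95_{axis}_mean``
    columns (e.g. the embedded reference motion table).
    """
    rows = {}
    for metric in ("rm", "r95"):
        for ax in _AXIS_COLS:
            col = patients[f"{metric}_{ax}_mean"]
            rows[f"{metric}_{ax}"] = {
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)),
            }
    return pd.DataFrame.from_dict(rows, orient="index")
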