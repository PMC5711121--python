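import numpy as np
import pandas as pd
import pytest

from ptvmargin.log_model import (
    CorrelationFlag,
    FiducialSet,
    FractionDataset,
    LiveImageRecord,
)


def make_correlation(errors, flags=None, t0=0.0, dt=1.0, positions=None):
    """Correlation-sample frame from an (n, 3) error array."""
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    n = errors.shape[0]
    if flags is None:
        flags = [CorrelationFlag.NORMAL.value] * n
    if positions is None:
        positions = np.zeros((n, 3))
    return pd.DataFrame(
        {
            "time_s": t0 + dt * np.arange(n),
            "err_si": errors[:, 0],
            "err_lat": errors[:, 1],
            "err_ap": errors[:, 2],
            "flag": list(flags),
            "pos_si": positions[:, 0],
            "pos_lat": positions[:, 1],
            "pos_ap": positions[:, 2],
        }
    )


def make_prediction(errors, beam_on=None, dt=1.0):
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    n = errors.shape[0]
    if beam_on is None:
        beam_on = [True] * n
    return pd.DataFrame(
        {
            "time_s": dt * np.arange(n),
            "err_si": errors[:, 0],
            "err_lat": errors[:, 1],
            "err_ap": errors[:, 2],
            "beam_on": list(beam_on),
        }
    )


@pytest.fixture
def two_seed_ct():
    return FiducialSet(["a", "b"], [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])


@pytest.fixture
def small_fraction(two_seed_ct):
    """Tiny hand-built fraction for round-trip and plumbing tests."""
    lives = [
        LiveImageRecord(10.0, [[0.1, 0.0, 0.0], [10.2, 0.0, 0.0]]),
        LiveImageRecord(70.0, [[-0.1, 0.1, 0.0], [9.9, 0.0, 0.2]]),
    ]
    corr = make_correlation(
        [[0.1, 0.0, -0.2], [0.3, 0.1, 0.0], [-0.1, -0.1, 0.1]],
        flags=[CorrelationFlag.MODEL_BUILD.value, "normal", "normal"],
    )
    pred = make_prediction([[0.05, 0.0, 0.0], [-0.02, 0.01, 0.0]])
    return FractionDataset(
        patient_id="p1",
        fraction_id="f1",
        fiducials=two_seed_ct,
        live_images=lives,
        correlation=corr,
        prediction=pred,
    )
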