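"""Delimited-text serialization of tracking-log fractions.

Vendor tracking logs are proprietary and undocumented, so this package
defines its own clean, versioned record-per-line schema.  One fraction is
a directory of four CSV files, each starting with a schema-version
comment line (``# ptvmargin-log v1``):

``fiducials.csv``
    seed_id, x_si, y_lat, z_ap, enabled — planning-CT seed configuration.
``live_images.csv``
    time_s, seed_id, x_si, y_lat, z_ap, valid — one row per seed per
    live X-ray image.
``correlation.csv``
    time_s, err_si, err_lat, err_ap, flag, pos_si, pos_lat, pos_ap.
``prediction.csv``
    time_s, err_si, err_lat, err_ap, beam_on.

A cohort adds a ``geometry.csv`` (one row per patient) and a
``manifest.csv`` mapping patient/fraction ids to fraction directories.
Round-tripping any dataset through :func:`write_fraction` /
:func:`read_fraction` is content-identical up to float formatting.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .log_model import (
    CORRELATION_COLUMNS,
    PREDICTION_COLUMNS,
    FiducialSet,
    FractionDataset,
    LiveImageRecord,
    PatientGeometry,
)

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_fraction",
    "read_fraction",
    "write_geometry",
    "read_geometry",
    "write_cohort",
    "read_cohort",
]

SCHEMA_VERSION = "ptvmargin-log v1"
_FLOAT_FMT = "%.6f"

_FRACTION_FILES = ("fiducials.csv", "live_images.csv", "correlation.csv", "prediction.csv")


class SchemaError(ValueError):
    """File does not carry the expected schema-version header."""


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_csv(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# {SCHEMA_VERSION}":
            raise SchemaError(
                f"{path}: expected schema header '# {SCHEMA_VERSION}', got {header!r}"
            )
        return pd.read_csv(fh)


def write_fraction(ds: FractionDataset, directory: str | os.PathLike) -> Path:
    """Write one fraction to ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fid = ds.fiducials
    _write_csv(
        pd.DataFrame(
            {
                "seed_id": fid.seed_ids,
                "x_si": fid.positions[:, 0],
                "y_lat": fid.positions[:, 1],
                "z_ap": fid.positions[:, 2],
                "enabled": fid.enabled.astype(int),
            }
        ),
        directory / "fiducials.csv",
    )
    rows = []
    for rec in ds.live_images:
        for k, seed_id in enumerate(fid.seed_ids):
            rows.append(
                (
                    rec.timestamp,
                    seed_id,
                    rec.positions[k, 0],
                    rec.positions[k, 1],
                    rec.positions[k, 2],
                    int(rec.valid[k]),
                )
            )
    _write_csv(
        pd.DataFrame(rows, columns=["time_s", "seed_id", "x_si", "y_lat", "z_ap", "valid"]),
        directory / "live_images.csv",
    )
    _write_csv(ds.correlation[list(CORRELATION_COLUMNS)], directory / "correlation.csv")
    _write_csv(ds.prediction[list(PREDICTION_COLUMNS)], directory / "prediction.csv")
    return directory


def read_fraction(
    directory: str | os.PathLike,
    patient_id: str = "",
    fraction_id: str = "",
) -> FractionDataset:
    """Read a fraction directory into a validated :class:`FractionDataset`.

    Malformed content (schema mismatch, non-monotone timestamps, unknown
    seed ids) raises with the offending file and record identified.
    """
    directory = Path(directory)
    fdf = _read_csv(directory / "fiducials.csv")
    fiducials = FiducialSet(
        fdf["seed_id"].astype(str).tolist(),
        fdf[["x_si", "y_lat", "z_ap"]].to_numpy(dtype=float),
        fdf["enabled"].to_numpy(dtype=bool),
    )
    ldf = _read_csv(directory / "live_images.csv")
    unknown = set(ldf["seed_id"].astype(str)) - set(fiducials.seed_ids)
    if unknown:
        raise ValueError(
            f"{directory / 'live_images.csv'}: unknown seed_id(s) {sorted(unknown)}"
        )
    order = {s: k for k, s in enumerate(fiducials.seed_ids)}
    live_images = []
    for t, grp in ldf.groupby("time_s", sort=True):
        pos = np.full((fiducials.n_seeds, 3), np.nan)
        valid = np.zeros(fiducials.n_seeds, dtype=bool)
        for _, row in grp.iterrows():
            k = order[str(row["seed_id"])]
            pos[k] = (row["x_si"], row["y_lat"], row["z_ap"])
            valid[k] = bool(row["valid"])
        pos[~np.isfinite(pos).all(axis=1)] = 0.0  # invalid seeds carry no position
        live_images.append(LiveImageRecord(float(t), pos, valid))
    ds = FractionDataset(
        patient_id=patient_id or directory.name,
        fraction_id=fraction_id or directory.name,
        fiducials=fiducials,
        live_images=live_images,
        correlation=_read_csv(directory / "correlation.csv"),
        prediction=_read_csv(directory / "prediction.csv"),
    )
    try:
        ds.validate()
    except ValueError as exc:
        raise ValueError(f"{directory}: {exc}") from exc
    return ds


def write_geometry(geoms: list[PatientGeometry], path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_csv(
        pd.DataFrame(
            {
                "patient_id": [g.patient_id for g in geoms],
                "n_seeds_implanted": [g.n_seeds_implanted for g in geoms],
                "n_seeds_tracking": [g.n_seeds_tracking for g in geoms],
                "dist_com_to_ctv_center": [g.dist_com_to_ctv_center for g in geoms],
                "dist_com_to_ctv_border": [g.dist_com_to_ctv_border for g in geoms],
            }
        ),
        path,
    )
    return path


def read_geometry(path: str | os.PathLike) -> list[PatientGeometry]:
    df = _read_csv(Path(path))
    return [
        PatientGeometry(
            patient_id=str(row.patient_id),
            n_seeds_implanted=int(row.n_seeds_implanted),
            n_seeds_tracking=int(row.n_seeds_tracking),
            dist_com_to_ctv_center=float(row.dist_com_to_ctv_center),
            dist_com_to_ctv_border=float(row.dist_com_to_ctv_border),
        )
        for row in df.itertuples()
    ]


def write_cohort(
    fractions: list[FractionDataset],
    geometry: list[PatientGeometry],
    root: str | os.PathLike,
) -> Path:
    """Write a whole cohort: manifest + geometry + one dir per fraction."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in fractions:
        sub = f"{ds.patient_id}_{ds.fraction_id}"
        write_fraction(ds, root / sub)
        rows.append((ds.patient_id, ds.fraction_id, sub))
    _write_csv(
        pd.DataFrame(rows, columns=["patient_id", "fraction_id", "directory"]),
        root / "manifest.csv",
    )
    write_geometry(geometry, root / "geometry.csv")
    return root


def read_cohort(root: str | os.PathLike) -> tuple[list[FractionDataset], list[PatientGeometry]]:
    root = Path(root)
    manifest = _read_csv(root / "manifest.csv")
    fractions = [
        read_fraction(root / str(row.directory), str(row.patient_id), str(row.fraction_id))
        for row in manifest.itertuples()
    ]
    geometry = read_geometry(root / "geometry.csv")
    return fractions, geometry
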