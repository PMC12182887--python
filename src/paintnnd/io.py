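"""Reading, writing and validating localization tables and regions of interest.

This module is the contract boundary between upstream localization software
(PSF fitting, drift correction and channel alignment happen there) and the
analysis pipeline. Tables are exchanged as HDF5 (one dataset per channel,
Picasso-style column names) or CSV with identical headers; all coordinates
and precisions are continuous nanometres, origin at the field-of-view corner,
y increasing downward, z = 0 at the focal plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import shapely

__all__ = [
    "LocalizationTable",
    "RegionOfInterest",
    "read_localizations",
    "write_localizations",
    "filter_roi",
    "read_roi",
    "write_roi",
]

#: Required columns of a 2D localization table, in canonical order.
REQUIRED_COLUMNS = ("frame", "x", "y", "photons", "lpx", "lpy")
#: Additional columns carried by 3D tables.
AXIAL_COLUMNS = ("z", "lpz")


class SchemaError(ValueError):
    """A localization file is missing a required column."""


class ValidationError(ValueError):
    """A localization table violates a structural invariant."""


@dataclass
class LocalizationTable:
    """Per-channel list of localizations in nanometres.

    Parameters
    ----------
    channel_id : str
        Label of the imaging channel (unique within a run).
    data : pandas.DataFrame
        Columns ``frame, x, y, photons, lpx, lpy`` and, for 3D tables,
        ``z, lpz``. Coordinates and precisions in nm; ``lp*`` are the
        per-localization fitted precision estimates (standard-deviation
        scale) used downstream as clustering weights.
    n_rejected : int
        Number of input rows dropped during validation (non-finite
        coordinates or non-positive precisions).
    """

    channel_id: str
    data: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_z(self) -> bool:
        return "z" in self.data.columns

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of lateral coordinates in nm."""
        return self.data[["x", "y"]].to_numpy(float)

    @property
    def xyz(self) -> np.ndarray:
        if not self.has_z:
            raise ValidationError(f"channel {self.channel_id!r} carries no z coordinates")
        return self.data[["x", "y", "z"]].to_numpy(float)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_z = "z" in df.columns
    if has_z and "lpz" not in df.columns:
        raise SchemaError("table has z but is missing column lpz")
    cols = list(REQUIRED_COLUMNS) + (list(AXIAL_COLUMNS) if has_z else [])
    df = df[cols].reset_index(drop=True)
    if has_z:
        nz = df["z"].isna() | df["lpz"].isna()
        if nz.any() and not nz.all():
            raise ValidationError("mixed 2D/3D rows: some rows lack z/lpz")
        if nz.all():
            df = df.drop(columns=["z", "lpz"])
    if (df["frame"] < 0).any():
        raise ValidationError("negative frame indices")
    df = df.astype({c: (np.int64 if c == "frame" else np.float64)
                    for c in df.columns})
    return df


def _drop_invalid(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows with non-finite values or non-positive precisions."""
    num = df.select_dtypes(include=[np.number])
    ok = np.isfinite(num.to_numpy(float)).all(axis=1)
    for c in ("lpx", "lpy", "lpz"):
        if c in df.columns:
            ok &= df[c].to_numpy(float) > 0
    n_rejected = int((~ok).sum())
    return df.loc[ok].reset_index(drop=True), n_rejected


def read_localizations(
    path: str | Path,
    pixel_size: float | None = None,
    channel_id: str | None = None,
) -> LocalizationTable:
    """Read one channel's localization table from HDF5 or CSV.

    Parameters
    ----------
    path : path
        ``.hdf5``/``.h5`` file (one dataset per channel) or a ``.csv`` file
        holding a single channel.
    pixel_size : float, optional
        nm per camera pixel. Give this iff the stored lateral coordinates
        and precisions are in pixel units; they are multiplied by it so the
        returned table is in nm. (z/lpz are assumed to already be in nm, as
        produced by astigmatism calibration.)
    channel_id : str, optional
        Which dataset to read from an HDF5 file with several channels; for
        CSV it only sets the returned table's label (default: file stem).

    Returns
    -------
    LocalizationTable
        All coordinates/precisions in nm. Rows with non-finite values or
        non-positive precisions are rejected; the count is recorded on
        ``n_rejected`` and reported as a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            keys = list(f.keys())
            if channel_id is None:
                if len(keys) != 1:
                    raise ValueError(
                        f"file has channels {keys}; pass channel_id to pick one"
                    )
                channel_id = keys[0]
            if channel_id not in f:
                raise SchemaError(f"channel {channel_id!r} not in file (has {keys})")
            df = pd.DataFrame(f[channel_id][()])
    else:
        # round_trip parser: exact float64 recovery of %.17g-written values
        df = pd.read_csv(path, float_precision="round_trip")
        if channel_id is None:
            channel_id = path.stem

    df = _validate_frame(df)
    if pixel_size is not None:
        if pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for c in ("x", "y", "lpx", "lpy"):
            df[c] = df[c] * float(pixel_size)
    df, n_rejected = _drop_invalid(df)
    if n_rejected:
        warnings.warn(
            f"{path.name}/{channel_id}: rejected {n_rejected} invalid row(s)",
            stacklevel=2,
        )
    return LocalizationTable(channel_id=channel_id, data=df, n_rejected=n_rejected)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table to HDF5 (dataset named by channel) or CSV by extension."""
    path = Path(path)
    df = table.data
    if path.suffix.lower() in (".h5", ".hdf5"):
        rec = df.to_records(index=False)
        mode = "a" if path.exists() else "w"
        with h5py.File(path, mode) as f:
            if table.channel_id in f:
                del f[table.channel_id]
            f.create_dataset(table.channel_id, data=rec)
    else:
        # %.17g guarantees float64 round-trips bit-exactly through text
        df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RegionOfInterest:
    """A simple polygon in nm defining the region of an analysis.

    Densities are measured over it and CSR nulls are simulated at the
    density it yields. Boundary points count as inside (determinism).
    """

    polygon: np.ndarray
    _geom: shapely.Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("polygon must be an (n>=3, 2) vertex array")
        if not np.isfinite(poly).all():
            raise ValueError("polygon vertices must be finite")
        self.polygon = poly
        geom = shapely.Polygon(poly)
        if not geom.is_valid:
            raise ValueError("polygon is not simple (self-intersecting or degenerate)")
        if geom.area <= 0:
            raise ValueError("polygon area must be positive")
        self._geom = geom

    @classmethod
    def rectangle(cls, width: float, height: float, x0: float = 0.0, y0: float = 0.0):
        return cls(np.array([[x0, y0], [x0 + width, y0],
                             [x0 + width, y0 + height], [x0, y0 + height]]))

    @property
    def area_nm2(self) -> float:
        """Polygon area in nm² (shoelace)."""
        return float(self._geom.area)

    @property
    def area_um2(self) -> float:
        return self.area_nm2 * 1e-6

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask: which points lie inside or on the boundary."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return shapely.covers(self._geom, shapely.points(xy))


def filter_roi(table: LocalizationTable, roi: RegionOfInterest) -> LocalizationTable:
    """Retain exactly the localizations whose (x, y) lies in the ROI.

    Idempotent; an empty result is permitted but flagged with a warning.
    """
    mask = roi.contains(table.xy)
    out = table.data.loc[mask].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn(f"ROI filter left channel {table.channel_id!r} empty", stacklevel=2)
    return LocalizationTable(channel_id=table.channel_id, data=out,
                             n_rejected=table.n_rejected)


def read_roi(path: str | Path) -> RegionOfInterest:
    """Read an ROI stored as a JSON list of [x, y] vertices in nm."""
    with open(path) as f:
        return RegionOfInterest(np.asarray(json.load(f), dtype=float))


def write_roi(roi: RegionOfInterest, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(roi.polygon.tolist(), f)
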