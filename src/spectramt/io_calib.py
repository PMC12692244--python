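"""Reflectance calibration, ROI extraction, replicate averaging, and table I/O.

Two-point (dark/white) calibration converts raw sensor intensities to
reflectance: R_cal = (R_raw - R_dark) / (R_white - R_dark).  A mean spectrum is
taken over a region of interest (default 20 x 20 pixels, centred), and the
repeated scans of a sample are averaged with a per-band coefficient-of-variation
stability check (warn threshold 2%).

Spectra tables travel as wide CSV (scan_id, egg_id, variety, day, then one
column per band named w<wavelength>), with the wavelength grid repeated in a
sidecar ``.grid.json``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthspec import LABEL_COLUMNS, FrameTriplet, SpectraTable, WavelengthGrid

__all__ = [
    "CalibrationFrames",
    "ROISpec",
    "DeadPixelError",
    "calibrate",
    "roi_mean_spectrum",
    "average_replicates",
    "average_scan_replicates",
    "read_spectra_csv",
    "write_spectra_csv",
    "write_frame_triplet",
    "read_frame_triplet",
]

CV_WARN_THRESHOLD = 0.02  # repeated-scan stability ceiling


class DeadPixelError(ValueError):
    """White and dark references coincide somewhere: calibration undefined."""

    def __init__(self, indices: np.ndarray):
        self.indices = indices
        shown = [tuple(int(v) for v in ix) for ix in indices[:10]]
        super().__init__(
            f"white == dark at {len(indices)} position(s); first offenders: {shown}"
        )


@dataclass
class CalibrationFrames:
    """Raw, dark-reference and white-reference intensity arrays of one shape."""

    raw: np.ndarray
    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if not (self.raw.shape == self.dark.shape == self.white.shape):
            raise ValueError("raw/dark/white shapes must match")

    @classmethod
    def from_triplet(cls, t: FrameTriplet) -> "CalibrationFrames":
        return cls(raw=t.raw, dark=t.dark, white=t.white)


@dataclass(frozen=True)
class ROISpec:
    row_start: int
    col_start: int
    height: int = 20
    width: int = 20

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI extents must be positive")
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI origin must be non-negative")

    @classmethod
    def centered(cls, n_rows: int, n_cols: int, height: int = 20,
                 width: int = 20) -> "ROISpec":
        if height > n_rows or width > n_cols:
            raise ValueError("ROI larger than frame")
        return cls((n_rows - height) // 2, (n_cols - width) // 2, height, width)


def calibrate(frames: CalibrationFrames) -> np.ndarray:
    """Elementwise two-point reflectance calibration.

    Invariant under adding one constant to all three frames and under scaling
    all three by any k > 0.  Values are NOT clipped to [0, 1]: noisy scans may
    legitimately stray outside, and SNV is location/scale invariant anyway.
    """
    denom = frames.white - frames.dark
    dead = np.argwhere(denom == 0)
    if dead.size:
        raise DeadPixelError(dead)
    return (frames.raw - frames.dark) / denom


def roi_mean_spectrum(reflectance: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Per-band arithmetic mean over the ROI of a (rows, cols, bands) frame."""
    reflectance = np.asarray(reflectance)
    if reflectance.ndim != 3:
        raise ValueError("expected a rows x cols x bands reflectance array")
    r1, c1 = roi.row_start + roi.height, roi.col_start + roi.width
    if r1 > reflectance.shape[0] or c1 > reflectance.shape[1]:
        raise ValueError(
            f"ROI {roi} exceeds frame of shape {reflectance.shape[:2]}"
        )
    patch = reflectance[roi.row_start:r1, roi.col_start:c1, :]
    return patch.mean(axis=(0, 1))


def average_replicates(scans, cv_warn: float = CV_WARN_THRESHOLD):
    """Average repeated scans of one sample; report per-band CV = sd/mean.

    CV uses the sample (N-1) standard deviation.  Bands whose mean is zero
    have undefined CV; they are returned as NaN and reported in the warning.
    A warning (never an error) is raised when any band's CV exceeds
    ``cv_warn`` — the caller decides whether instability is fatal.
    """
    arr = np.asarray(list(scans), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need >= 1 equal-length scans")
    mean = arr.mean(axis=0)
    if arr.shape[0] == 1:
        return mean, np.zeros_like(mean)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    zero_mean = np.flatnonzero(mean == 0)
    if zero_mean.size:
        warnings.warn(
            f"CV undefined (zero mean) at band indices {zero_mean.tolist()[:10]}",
            RuntimeWarning, stacklevel=2,
        )
    bad = np.flatnonzero(np.abs(cv) > cv_warn)
    if bad.size:
        warnings.warn(
            f"replicate CV above {cv_warn:.0%} at {bad.size} band(s), "
            f"first indices {bad.tolist()[:10]}",
            RuntimeWarning, stacklevel=2,
        )
    return mean, cv


def average_scan_replicates(table: SpectraTable,
                            cv_warn: float = CV_WARN_THRESHOLD) -> SpectraTable:
    """Collapse repeated scans to one mean spectrum per (egg, day) sample.

    This is the analysis-ready view of a campaign: each sample's replicate
    scans are averaged (with the CV stability warning of
    :func:`average_replicates`) so downstream stages see one spectrum per
    egg per storage day.
    """
    rows = []
    spectra = []
    keys = table.labels.groupby(["egg_id", "day"], sort=True).indices
    for (egg, day), idx in keys.items():
        mean, _ = average_replicates(table.X[idx], cv_warn=cv_warn)
        variety = table.labels["variety"].iloc[idx[0]]
        rows.append((f"{egg}_d{int(day):02d}_avg", egg, variety, int(day)))
        spectra.append(mean)
    labels = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    return SpectraTable(labels, np.vstack(spectra), table.grid)


# ---------------------------------------------------------------------------
# CSV exchange format
# ---------------------------------------------------------------------------

def write_spectra_csv(table: SpectraTable, path) -> None:
    """Write the wide-layout CSV plus a ``.grid.json`` wavelength sidecar."""
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".grid.json")
    sidecar.write_text(json.dumps({
        "wavelength_nm": [float(w) for w in table.grid.values],
    }))


def read_spectra_csv(path) -> SpectraTable:
    """Read a wide-layout spectra CSV back into a :class:`SpectraTable`.

    Rejects missing cells, non-monotone wavelength columns, and duplicate
    scan ids, naming the offending rows/columns.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing label columns {missing} in {path}")
    band_cols = [c for c in df.columns if c.startswith("w")]
    if not band_cols:
        raise ValueError(f"no band columns (w<wavelength>) found in {path}")
    try:
        wavelengths = np.array([float(c[1:]) for c in band_cols])
    except ValueError as exc:
        raise ValueError(f"malformed band column name in {path}: {exc}") from exc
    if not np.all(np.diff(wavelengths) > 0):
        raise ValueError(f"band columns of {path} are not in increasing wavelength order")
    sidecar = path.with_suffix(path.suffix + ".grid.json")
    if sidecar.exists():
        # column names are rounded for readability; the sidecar is exact
        exact = np.array(json.loads(sidecar.read_text())["wavelength_nm"])
        if exact.size != wavelengths.size or np.abs(exact - wavelengths).max() > 0.1:
            raise ValueError(f"sidecar grid of {path} disagrees with band columns")
        wavelengths = exact
    values = df[band_cols]
    if values.isna().any().any():
        bad = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in {path} at row {bad[0]}, column {band_cols[bad[1]]}"
        )
    labels = df[LABEL_COLUMNS].copy()
    labels["day"] = labels["day"].astype(int)
    return SpectraTable(labels, values.to_numpy(dtype=float), WavelengthGrid(wavelengths))


# ---------------------------------------------------------------------------
# Minimal band-sequential cube I/O for frame triplets
# ---------------------------------------------------------------------------

def write_frame_triplet(triplet: FrameTriplet, directory) -> None:
    """Write raw/dark/white as flat float64 binaries plus a JSON header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("raw", "dark", "white"):
        getattr(triplet, name).astype("<f8").tofile(directory / f"{name}.bin")
    header = {
        "shape": list(triplet.raw.shape),
        "dtype": "<f8",
        "wavelength_nm": [float(w) for w in triplet.grid.values],
    }
    (directory / "header.json").write_text(json.dumps(header))


def read_frame_triplet(directory) -> FrameTriplet:
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    shape = tuple(header["shape"])
    arrays = {}
    for name in ("raw", "dark", "white"):
        arrays[name] = np.fromfile(directory / f"{name}.bin",
                                   dtype=header["dtype"]).reshape(shape)
    grid = WavelengthGrid(np.array(header["wavelength_nm"]))
    return FrameTriplet(grid=grid, **arrays)
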