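"""Synthetic NIR egg-spectra simulator.

Generates labelled reflectance datasets whose class structure mimics shell-egg
NIR phenomenology: Gaussian absorption bands riding on a smooth reflectance
baseline, with water bands (~1450/1950 nm) and lipid bands (1700-1800 nm) that
attenuate over storage, protein/carbohydrate bands (2100-2300 nm) with
variety-dependent intensity, per-egg biological variability, and the
multiplicative-scatter / baseline-offset artefacts that SNV preprocessing is
meant to remove.  Ground truth (which grid indices are informative) is exported
so band-selection algorithms can be scored against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "PeakSpec",
    "SimConfig",
    "SpectraTable",
    "FrameTriplet",
    "default_egg_sim_config",
    "clean_spectrum",
    "apply_artifacts",
    "simulate_dataset",
    "simulate_frame_triplet",
    "informative_bands",
]

LABEL_COLUMNS = ["scan_id", "egg_id", "variety", "day"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        # 1000-2500 nm at ~5.5 nm spacing: 273 bands
        return cls(np.linspace(1000.0, 2500.0, 273))

    def band_names(self) -> list[str]:
        return [f"w{w:.1f}" for w in self.values]


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian absorption band and how it evolves with storage.

    ``base_depth`` is the dimensionless absorbance depth of the band for a
    variety with multiplier 1 at day 0; ``decay_per_day`` is the fractional
    depth loss per storage day, so depth at day d is
    ``base_depth * multiplier * (1 - decay_per_day)**d``.
    """

    center_nm: float
    width_nm: float
    base_depth: float
    variety_multipliers: tuple[float, ...]
    decay_per_day: float = 0.0
    shift_per_day_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if not (0.0 < self.base_depth < 1.0):
            raise ValueError("base_depth must lie in (0, 1)")
        if any(m <= 0 for m in self.variety_multipliers):
            raise ValueError("variety multipliers must be positive")
        if not (0.0 <= self.decay_per_day < 1.0):
            raise ValueError("decay_per_day must lie in [0, 1)")
        if self.base_depth * max(self.variety_multipliers) >= 1.0:
            raise ValueError("base_depth x max multiplier must stay below 1")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic acquisition campaign."""

    grid: WavelengthGrid
    peaks: tuple[PeakSpec, ...]
    varieties: tuple[str, ...] = ("enshi", "mulanhu", "zhengda")
    days: tuple[int, ...] = (1, 20, 40)
    n_eggs_per_variety: int = 100
    scans_per_egg: int = 3
    base_reflectance: float = 0.80
    scatter_gain_sd: float = 0.08
    scatter_tilt_sd: float = 0.06
    baseline_offset_sd: float = 0.04
    baseline_slope_sd: float = 0.05
    noise_sd: float = 0.002
    egg_effect_sd: float = 0.12
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_eggs_per_variety < 1:
            raise ValueError("n_eggs_per_variety must be >= 1")
        if self.scans_per_egg < 1:
            raise ValueError("scans_per_egg must be >= 1")
        for name in ("scatter_gain_sd", "scatter_tilt_sd", "baseline_offset_sd",
                     "baseline_slope_sd", "noise_sd", "egg_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(set(self.varieties)) != len(self.varieties):
            raise ValueError("variety labels must be distinct")
        if len(set(self.days)) != len(self.days):
            raise ValueError("day labels must be distinct")
        for p in self.peaks:
            if len(p.variety_multipliers) != len(self.varieties):
                raise ValueError(
                    f"peak at {p.center_nm} nm has {len(p.variety_multipliers)} "
                    f"multipliers for {len(self.varieties)} varieties"
                )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SpectraTable:
    """Labelled reflectance spectra on a shared wavelength grid.

    ``labels`` carries one row per scan (scan_id, egg_id, variety, day) and
    ``X`` the matching reflectance matrix (n_scans x n_bands).
    """

    labels: pd.DataFrame
    X: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if list(self.labels.columns) != LABEL_COLUMNS:
            raise ValueError(f"label columns must be {LABEL_COLUMNS}")
        if self.X.shape != (len(self.labels), self.grid.n_bands):
            raise ValueError(
                f"X shape {self.X.shape} inconsistent with {len(self.labels)} scans "
                f"x {self.grid.n_bands} bands"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("reflectance values must be finite")
        if self.labels["scan_id"].duplicated().any():
            dup = self.labels.loc[self.labels["scan_id"].duplicated(), "scan_id"]
            raise ValueError(f"duplicate scan_id values: {sorted(set(dup))[:5]}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_bands(self) -> int:
        return self.grid.n_bands

    def subset(self, mask) -> "SpectraTable":
        mask = np.asarray(mask)
        return SpectraTable(
            self.labels.loc[mask].reset_index(drop=True),
            self.X[mask],
            self.grid,
        )

    def select_eggs(self, egg_ids: Sequence[str]) -> "SpectraTable":
        keep = self.labels["egg_id"].isin(set(egg_ids)).to_numpy()
        return self.subset(keep)

    def to_frame(self) -> pd.DataFrame:
        bands = pd.DataFrame(self.X, columns=self.grid.band_names())
        return pd.concat([self.labels.reset_index(drop=True), bands], axis=1)


@dataclass
class FrameTriplet:
    """Raw/dark/white intensity cubes (rows x cols x bands) for calibration."""

    raw: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        shapes = {self.raw.shape, self.dark.shape, self.white.shape}
        if len(shapes) != 1:
            raise ValueError("raw/dark/white frames must share one shape")
        if self.raw.shape[-1] != self.grid.n_bands:
            raise ValueError("trailing frame axis must match grid band count")
        if not np.all(self.white > self.dark):
            raise ValueError("white frame must exceed dark frame elementwise")


# ---------------------------------------------------------------------------
# Default configuration: band placement per shell-egg NIR phenomenology
# ---------------------------------------------------------------------------

def default_egg_sim_config(seed: int = 42) -> SimConfig:
    """Simulation config for three commercial egg varieties over cold storage.

    Peak placement follows the standard NIR band assignments: O-H second
    overtone near 1200 nm, the 1450 nm first O-H overtone and the 1950 nm O-H
    combination band (both water, attenuating as the egg loses moisture), C-H
    lipid bands at 1720/1780 nm (declining with lipid oxidation), and N-H
    protein / C-O carbohydrate bands at 2180/2280 nm whose intensity differs
    between varieties.  Variety 1 is strongest at 1200 nm, variety 2 in the
    lipid region, variety 3 in the protein/carbohydrate region.  Amplitudes
    place a linear classifier in the ~60-75% day-40 variety-accuracy regime.
    """
    # shift_per_day values place the day-40 displacement of the
    # variety-discriminative bands at roughly one grid spacing: storage both
    # attenuates AND shifts the bands, so late-day variety decoding benefits
    # from knowing the storage stage — the cross-temporal coupling that makes
    # joint variety/period modelling worthwhile
    peaks = (
        PeakSpec(1200.0, 40.0, 0.070, (1.30, 1.00, 0.90), 0.004, 0.12),
        PeakSpec(1450.0, 45.0, 0.300, (1.02, 1.00, 0.98), 0.010, 0.15),
        PeakSpec(1720.0, 24.0, 0.100, (0.90, 1.30, 1.00), 0.012, 0.12),
        PeakSpec(1780.0, 24.0, 0.080, (0.92, 1.26, 1.02), 0.012, 0.12),
        PeakSpec(1950.0, 55.0, 0.340, (1.00, 1.02, 0.98), 0.008, 0.20),
        PeakSpec(2180.0, 35.0, 0.120, (0.95, 1.00, 1.30), 0.003, 0.10),
        PeakSpec(2280.0, 35.0, 0.100, (0.90, 1.00, 1.28), 0.003, 0.10),
    )
    return SimConfig(grid=WavelengthGrid.default(), peaks=peaks, seed=seed)


# ---------------------------------------------------------------------------
# Spectrum construction
# ---------------------------------------------------------------------------

def _variety_index(variety, config: SimConfig) -> int:
    try:
        return config.varieties.index(variety)
    except ValueError:
        raise ValueError(f"unknown variety {variety!r}; known: {config.varieties}")


def _spectrum(variety, day: int, config: SimConfig,
              depth_scale: np.ndarray | None = None) -> np.ndarray:
    """Noise-free reflectance, optionally with per-peak depth multipliers."""
    vi = _variety_index(variety, config)
    if day not in config.days:
        raise ValueError(f"day {day!r} not in config.days {config.days}")
    lam = config.grid.values
    r = np.full_like(lam, config.base_reflectance)
    for j, p in enumerate(config.peaks):
        depth = p.base_depth * p.variety_multipliers[vi] * (1.0 - p.decay_per_day) ** day
        if depth_scale is not None:
            depth = depth * depth_scale[j]
        center = p.center_nm + p.shift_per_day_nm * day
        r -= depth * np.exp(-((lam - center) ** 2) / (2.0 * p.width_nm ** 2))
    return np.clip(r, 1e-6, 1.0)


def clean_spectrum(variety, day: int, config: SimConfig) -> np.ndarray:
    """Deterministic noise-free reflectance for one (variety, day) cell."""
    return _spectrum(variety, day, config)


def apply_artifacts(spectrum: np.ndarray, config: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Wavelength-dependent scatter gain, affine baseline, and white noise.

    Output is ``g(λ)*r + b0 + b1*t + eps`` where the multiplicative scatter
    gain g(λ) = exp(η + ζ·(t − 1/2)) has a per-sample log-gain η (sd
    ``scatter_gain_sd``) and a per-sample log-tilt ζ (sd ``scatter_tilt_sd``)
    over the 0..1 normalised wavelength t — scattering strength varies with
    wavelength, so the gain is not a constant; b0, b1 are Gaussian offset and
    slope, eps iid Gaussian.  All randomness is consumed from ``rng``.  SNV
    removes the constant-gain and offset parts exactly; the gain tilt and the
    slope survive it.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    lam = config.grid.values
    t = (lam - lam[0]) / (lam[-1] - lam[0])
    eta = float(rng.normal(0.0, config.scatter_gain_sd)) if config.scatter_gain_sd > 0 else 0.0
    zeta = float(rng.normal(0.0, config.scatter_tilt_sd)) if config.scatter_tilt_sd > 0 else 0.0
    g = np.exp(eta + zeta * (t - 0.5))
    b0 = float(rng.normal(0.0, config.baseline_offset_sd)) if config.baseline_offset_sd > 0 else 0.0
    b1 = float(rng.normal(0.0, config.baseline_slope_sd)) if config.baseline_slope_sd > 0 else 0.0
    eps = rng.normal(0.0, config.noise_sd, size=spectrum.shape) if config.noise_sd > 0 else 0.0
    return g * spectrum + b0 + b1 * t + eps


def simulate_dataset(config: SimConfig) -> SpectraTable:
    """Simulate the full repeated-measures campaign.

    Every egg is scanned ``scans_per_egg`` times at every day in
    ``config.days`` (same physical egg tracked across storage).  Each egg
    draws one per-peak log-normal depth jitter (biological variability, sd
    ``egg_effect_sd``) held fixed across its days.  Scatter gain and baseline
    artefacts are drawn once per (egg, day) — they come from sample placement
    and surface state, so immediate repeat scans share them — while each
    replicate scan adds independent sensor noise, keeping the replicate CV
    within instrument-stability levels.  Per-egg RNG substreams are spawned
    by counter so adding eggs never perturbs existing ones.
    """
    rows = []
    spectra = []
    for vi, variety in enumerate(config.varieties):
        for e in range(config.n_eggs_per_variety):
            # per-egg substream keyed by (variety, egg): growing the campaign
            # never perturbs spectra of already-simulated eggs
            ss = np.random.SeedSequence(config.seed, spawn_key=(vi, e))
            rng = np.random.Generator(np.random.PCG64(ss))
            egg_id = f"{variety}_e{e:03d}"
            if config.egg_effect_sd > 0:
                depth_scale = np.exp(rng.normal(0.0, config.egg_effect_sd,
                                                size=len(config.peaks)))
            else:
                depth_scale = np.ones(len(config.peaks))
            for day in config.days:
                clean = _spectrum(variety, day, config, depth_scale)
                noiseless = dataclasses.replace(config, noise_sd=0.0)
                sample = apply_artifacts(clean, noiseless, rng)
                for s in range(config.scans_per_egg):
                    rows.append((f"{egg_id}_d{day:02d}_s{s}", egg_id, variety, day))
                    if config.noise_sd > 0:
                        spectra.append(sample + rng.normal(0.0, config.noise_sd,
                                                           size=sample.shape))
                    else:
                        spectra.append(sample.copy())

    labels = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    return SpectraTable(labels, np.vstack(spectra), config.grid)


def simulate_frame_triplet(spectrum: np.ndarray, roi_rows: int, roi_cols: int,
                           config: SimConfig, rng: np.random.Generator,
                           dark_level: float = 100.0, white_level: float = 1000.0,
                           noise_sd: float = 0.0) -> FrameTriplet:
    """Raw/dark/white intensity cubes for one homogeneous ROI.

    raw = dark + (white - dark) * spectrum, per pixel per band, plus optional
    Gaussian sensor noise on every frame.
    """
    if roi_rows < 1 or roi_cols < 1:
        raise ValueError("ROI dimensions must be >= 1")
    if white_level <= dark_level:
        raise ValueError("white_level must exceed dark_level")
    spectrum = np.asarray(spectrum, dtype=float)
    shape = (roi_rows, roi_cols, config.grid.n_bands)
    dark = np.full(shape, dark_level)
    white = np.full(shape, white_level)
    raw = dark + (white - dark) * spectrum[None, None, :]
    if noise_sd > 0:
        dark = dark + rng.normal(0.0, noise_sd, shape)
        white = white + rng.normal(0.0, noise_sd, shape)
        raw = raw + rng.normal(0.0, noise_sd, shape)
    return FrameTriplet(raw=raw, dark=dark, white=white, grid=config.grid)


def informative_bands(config: SimConfig, k_sigma: float = 2.0) -> np.ndarray:
    """Grid indices within ``k_sigma`` peak widths of any absorption center."""
    lam = config.grid.values
    mask = np.zeros(lam.size, dtype=bool)
    for p in config.peaks:
        mask |= np.abs(lam - p.center_nm) <= k_sigma * p.width_nm
    return np.flatnonzero(mask)
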