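"""Synthetic FTIR spectra with the statistical structure of a forage study.

Emulates a 90-sample crude-protein (CP) calibration population: absorbance
spectra on a 10,329-point 4000->400 cm^-1 axis built by Beer-Lambert mixing
of Gaussian (optionally Lorentzian) constituent bands, a smooth per-sample
baseline (low-order polynomial plus one broad drift term), a broad ~3400
cm^-1 water band, and additive noise.  Protein band amplitudes scale
linearly with CP (mid-range normalised, ``cp/15``); other constituents vary
as independent nuisance levels.  A sidecar truth table records the
noise-free ingredients so downstream stages (baseline correction, wavelength
selection, calibration) can be tested by parameter recovery.

Everything is driven by one :class:`SimulationConfig` and a single seed;
identical configs produce bit-identical datasets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra_core import (
    ABSORBANCE,
    DEFAULT_AXIS_END,
    DEFAULT_AXIS_START,
    DEFAULT_CP_RANGE,
    DEFAULT_N_POINTS,
    TRANSMITTANCE,
    SpectraSet,
    Spectrum,
    SpectraError,
    WavenumberAxis,
    absorbance_to_transmittance_values,
)

PROTEIN = "protein"
CARBOHYDRATE = "carbohydrate"
WATER = "water"
MINERAL = "mineral"

# Amplitude normalisation: protein band concentration = base_amplitude * cp / 15,
# so base amplitudes are the band heights of a mid-range (15% CP) sample.
CP_AMPLITUDE_PIVOT = 15.0


@dataclass(frozen=True)
class Band:
    """One absorption band: centre/width in cm^-1, height in absorbance."""

    center: float
    width: float
    base_amplitude: float
    constituent: str
    shape: str = "gaussian"
    label: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("band amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-height band shape evaluated on the axis."""
        u = (np.asarray(wavenumbers, dtype=float) - self.center) / self.width
        if self.shape == "gaussian":
            return np.exp(-0.5 * u * u)
        return 1.0 / (1.0 + u * u)


def default_band_library() -> list[Band]:
    """Constituent band library for alfalfa-like mid-IR spectra.

    Protein chemistry: N-H asymmetric stretch (3394), amide N-H bend (1630),
    amide II / N-H+C-N (1512), COOH in-plane bend (1417) and C-N / COOH
    stretch (1246).  Carbohydrate C-H and C-O/C-OH bands, mineral
    fingerprint bands below 700 cm^-1, and one broad water band near 3400
    cm^-1 (hygroscopic KBr) complete the library.
    """
    return [
        Band(3394.0, 60.0, 0.45, PROTEIN, label="NH2 asymmetric stretch"),
        Band(1630.0, 25.0, 0.50, PROTEIN, label="NH2 bend (amide I region)"),
        Band(1512.0, 18.0, 0.22, PROTEIN, label="amide II"),
        Band(1417.0, 14.0, 0.28, PROTEIN, label="COOH in-plane bend"),
        Band(1246.0, 16.0, 0.30, PROTEIN, label="C-N / COOH stretch"),
        Band(2915.0, 35.0, 0.35, CARBOHYDRATE, label="C-H stretch"),
        Band(1381.0, 14.0, 0.25, CARBOHYDRATE, label="C-H bend"),
        Band(1102.0, 18.0, 0.40, CARBOHYDRATE, label="C-O stretch"),
        Band(1053.0, 16.0, 0.45, CARBOHYDRATE, label="C-OH stretch"),
        Band(665.0, 12.0, 0.18, MINERAL, label="C-OH vibration"),
        Band(600.0, 10.0, 0.15, MINERAL, label="C-OH vibration"),
        Band(593.0, 10.0, 0.14, MINERAL, label="fingerprint"),
        Band(3400.0, 200.0, 0.30, WATER, label="O-H stretch (moisture)"),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic population.

    Defaults emulate the calibration study the package targets: 90 samples,
    CP uniform over 9.00-22.04 % dry matter, 10,329 points spanning
    4000-400 cm^-1, additive white absorbance noise giving band-height
    signal-to-noise near 20, a smaller smoothly correlated noise component
    (correlation length ``correlated_noise_length_cm``) standing in for
    detector drift and imperfect background subtraction, per-sample
    multiplicative jitter of the protein band amplitudes (band ratios are
    not perfectly locked to total CP), and a Kjeldahl-like reference error
    of 0.15 %CP.
    """

    n_samples: int = 90
    cp_range: tuple[float, float] = DEFAULT_CP_RANGE
    axis_start: float = DEFAULT_AXIS_START
    axis_end: float = DEFAULT_AXIS_END
    n_points: int = DEFAULT_N_POINTS
    bands: tuple[Band, ...] = field(
        default_factory=lambda: tuple(default_band_library())
    )
    baseline_degree: int = 2
    baseline_coeff_scale: float = 0.3
    drift_amplitude: float = 0.4
    noise_sd: float = 0.02
    correlated_noise_sd: float = 0.01
    correlated_noise_length_cm: float = 25.0
    heteroscedastic_noise: bool = False
    protein_jitter_sd: float = 0.05
    reference_noise_sd: float = 0.15
    nuisance_sd: float = 0.2
    water_band_variability: float = 0.3
    replicates: int = 1
    mode: str = TRANSMITTANCE  # instrument-native output; modelling converts
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cp_range
        if not (0.0 < lo < hi < 100.0):
            raise ValueError("cp_range must be within (0, 100) with lo < hi")
        if min(self.noise_sd, self.correlated_noise_sd, self.reference_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.protein_jitter_sd < 0:
            raise ValueError("protein_jitter_sd must be >= 0")
        if self.correlated_noise_length_cm <= 0:
            raise ValueError("correlated_noise_length_cm must be positive")
        if self.n_points < 2:
            raise ValueError("need at least 2 axis points")
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mode not in (ABSORBANCE, TRANSMITTANCE):
            raise ValueError(f"unknown output mode {self.mode!r}")

    def make_axis(self) -> WavenumberAxis:
        return WavenumberAxis(
            np.linspace(self.axis_start, self.axis_end, self.n_points)
        )


@dataclass(frozen=True)
class DatasetTruth:
    """Noise-free generating quantities for recovery tests."""

    sample_ids: tuple[str, ...]
    cp_true: np.ndarray
    band_centers: np.ndarray
    band_constituents: tuple[str, ...]
    concentrations: np.ndarray  # n_samples x n_bands band heights
    baselines: np.ndarray  # n_samples x n_points, absorbance units

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "sample_id": list(self.sample_ids),
            "cp_true": self.cp_true,
        }
        for j, (c, who) in enumerate(zip(self.band_centers, self.band_constituents)):
            cols[f"conc_{who}_{c:g}"] = self.concentrations[:, j]
        return pd.DataFrame(cols)


def _band_concentrations(
    cp_percent: float,
    nuisance_levels: Mapping[str, float] | Sequence[float] | float,
    bands: Sequence[Band],
) -> np.ndarray:
    """Per-band height: protein scales with CP, others with nuisance levels."""
    conc = np.empty(len(bands))
    for j, b in enumerate(bands):
        if b.constituent == PROTEIN:
            conc[j] = b.base_amplitude * (cp_percent / CP_AMPLITUDE_PIVOT)
        else:
            if isinstance(nuisance_levels, Mapping):
                level = float(nuisance_levels.get(b.constituent, 1.0))
            elif np.isscalar(nuisance_levels):
                level = float(nuisance_levels)
            else:
                level = float(nuisance_levels[j])
            conc[j] = b.base_amplitude * level
    return conc


def _baseline(
    axis_values: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Smooth per-sample background: random polynomial + one broad drift."""
    u = (axis_values - axis_values.min()) / (axis_values.max() - axis_values.min())
    # coefficient magnitudes bounded away from zero: scattering baselines
    # always slope/curve, and a near-flat draw would be a degenerate
    # condition (its dynamic range -> 0) rather than a realistic one
    mags = rng.uniform(
        config.baseline_coeff_scale / 3.0,
        config.baseline_coeff_scale,
        size=config.baseline_degree,
    )
    signs = rng.choice([-1.0, 1.0], size=config.baseline_degree)
    coeffs = np.concatenate(
        [rng.uniform(0.0, 2.0 * config.baseline_coeff_scale, size=1), mags * signs]
    )
    z = np.polynomial.polynomial.polyval(u, coeffs)
    amp = rng.uniform(0.25 * config.drift_amplitude, config.drift_amplitude)
    center = rng.uniform(1000.0, 3500.0)
    width = rng.uniform(800.0, 1500.0)
    z = z + amp * np.exp(-0.5 * ((axis_values - center) / width) ** 2)
    return z


def _measurement_noise(
    clean: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """White + smoothly correlated additive noise for one spectrum.

    The correlated component is white noise convolved with a Gaussian of
    ``correlated_noise_length_cm`` (converted to grid points), rescaled to
    unit standard deviation — a stand-in for detector drift / background
    ripple, which no latent-variable model can average out across samples.
    Replicate averaging divides both components' variance by r.
    """
    reps = max(1, config.replicates)
    p = clean.size
    eps = np.zeros(p)
    if config.noise_sd > 0:
        eps = rng.normal(0.0, config.noise_sd, size=(reps, p)).mean(axis=0)
    if config.correlated_noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        spacing = abs(config.axis_start - config.axis_end) / (p - 1)
        sigma_pts = max(config.correlated_noise_length_cm / spacing, 0.5)
        rip = gaussian_filter1d(rng.normal(size=(reps, p)), sigma_pts, axis=1)
        rip /= rip.std(axis=1, keepdims=True)
        eps = eps + config.correlated_noise_sd * rip.mean(axis=0)
    if config.heteroscedastic_noise:
        eps = eps * (1.0 + np.abs(clean))
    return eps


def simulate_spectrum(
    cp_percent: float,
    nuisance_levels: Mapping[str, float] | Sequence[float] | float,
    config: SimulationConfig,
    rng: np.random.Generator,
    protein_jitter: Sequence[float] | None = None,
) -> Spectrum:
    """Simulate one sample's spectrum by Beer-Lambert band mixing.

    ``A(v) = sum_b c_b * shape_b(v) + baseline(v) + eps(v)`` with protein
    heights ``c_b = base_amplitude * cp/15`` (optionally jittered) and
    nuisance heights ``base_amplitude * level``.  Converted to percent
    transmittance when the config says so.
    """
    lo, hi = config.cp_range
    if not (lo <= cp_percent <= hi):
        raise ValueError(f"cp_percent {cp_percent} outside cp_range [{lo}, {hi}]")
    axis = config.make_axis()
    conc = _band_concentrations(cp_percent, nuisance_levels, config.bands)
    if protein_jitter is not None:
        jit = np.asarray(protein_jitter, dtype=float)
        for j, b in enumerate(config.bands):
            if b.constituent == PROTEIN:
                conc[j] *= 1.0 + jit[j]
    a = np.zeros(config.n_points)
    for c, band in zip(conc, config.bands):
        if c != 0.0:
            a += c * band.profile(axis.values)
    if config.baseline_coeff_scale > 0 or config.drift_amplitude > 0:
        a += _baseline(axis.values, config, rng)
    if config.noise_sd > 0 or config.correlated_noise_sd > 0:
        a = a + _measurement_noise(a, config, rng)
    if config.mode == TRANSMITTANCE:
        return Spectrum(axis, absorbance_to_transmittance_values(a), TRANSMITTANCE)
    return Spectrum(axis, a, ABSORBANCE)


def generate_dataset(config: SimulationConfig) -> tuple[SpectraSet, DatasetTruth]:
    """Generate the full synthetic study population plus its truth table.

    True CP is uniform over ``cp_range``; the recorded reference value adds
    Normal(0, ``reference_noise_sd``) Kjeldahl-proxy error, clipped back to
    the declared range.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.make_axis()
    lo, hi = config.cp_range
    n = config.n_samples
    cp_true = rng.uniform(lo, hi, size=n)
    nuisance = {}
    for constituent in (CARBOHYDRATE, MINERAL):
        nuisance[constituent] = np.clip(
            rng.normal(1.0, config.nuisance_sd, size=n), 0.0, None
        )
    nuisance[WATER] = np.clip(
        rng.normal(1.0, config.water_band_variability, size=n), 0.0, None
    )

    is_protein = np.array([b.constituent == PROTEIN for b in config.bands])
    profiles = np.stack([b.profile(axis.values) for b in config.bands])
    concentrations = np.empty((n, len(config.bands)))
    baselines = np.zeros((n, config.n_points))
    X = np.empty((n, config.n_points))
    for i in range(n):
        levels = {k: v[i] for k, v in nuisance.items()}
        concentrations[i] = _band_concentrations(cp_true[i], levels, config.bands)
        if config.protein_jitter_sd > 0 and is_protein.any():
            jit = rng.normal(0.0, config.protein_jitter_sd, size=is_protein.sum())
            concentrations[i, is_protein] *= np.clip(1.0 + jit, 0.0, None)
        a = concentrations[i] @ profiles
        if config.baseline_coeff_scale > 0 or config.drift_amplitude > 0:
            baselines[i] = _baseline(axis.values, config, rng)
            a = a + baselines[i]
        if config.noise_sd > 0 or config.correlated_noise_sd > 0:
            a = a + _measurement_noise(a, config, rng)
        X[i] = a

    if config.reference_noise_sd > 0:
        y = cp_true + rng.normal(0.0, config.reference_noise_sd, size=n)
        y = np.clip(y, lo, hi)
    else:
        y = cp_true.copy()

    if config.mode == TRANSMITTANCE:
        X = absorbance_to_transmittance_values(X)

    width = len(str(n))
    ids = tuple(f"sample_{i + 1:0{width}d}" for i in range(n))
    sset = SpectraSet(
        axis=axis,
        X=X,
        sample_ids=ids,
        y=y,
        mode=config.mode,
        cp_range=config.cp_range,
    ).with_metadata(generator_seed=str(config.seed))
    truth = DatasetTruth(
        sample_ids=ids,
        cp_true=cp_true,
        band_centers=np.array([b.center for b in config.bands]),
        band_constituents=tuple(b.constituent for b in config.bands),
        concentrations=concentrations,
        baselines=baselines,
    )
    return sset, truth


def write_truth_csv(truth: DatasetTruth, path: str | os.PathLike) -> None:
    truth.to_frame().to_csv(path, index=False, float_format="%.17g")


def three_band_config(
    n_samples: int = 63,
    n_points: int = 400,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> SimulationConfig:
    """Small configuration with exactly three protein bands.

    Used to study wavelength-selection behaviour where the informative
    support is known: no nuisance constituents, no baseline and no band
    jitter (the benchmark isolates band localization), but with the
    default measurement-noise structure — a small white component plus the
    larger smoothly correlated component.  The correlated part is what
    gives uninformative wavelengths a real cross-validation cost (it does
    not average away across channels), which is the phenomenon adaptive
    wavelength selection exploits; the low white level keeps the
    regression-coefficient competition sharp.  Band widths of 30 cm^-1
    keep the ripple-reference shoulders (useful within about two
    correlation lengths of a band core) inside the band support.
    """
    bands = (
        Band(3394.0, 30.0, 0.45, PROTEIN, label="NH2 asymmetric stretch"),
        Band(1630.0, 30.0, 0.50, PROTEIN, label="NH2 bend"),
        Band(1246.0, 30.0, 0.30, PROTEIN, label="C-N stretch"),
    )
    return SimulationConfig(
        n_samples=n_samples,
        n_points=n_points,
        bands=bands,
        baseline_coeff_scale=0.0,
        drift_amplitude=0.0,
        noise_sd=noise_sd,
        protein_jitter_sd=0.0,
        reference_noise_sd=0.0,
        nuisance_sd=0.0,
        water_band_variability=0.0,
        seed=seed,
    )
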