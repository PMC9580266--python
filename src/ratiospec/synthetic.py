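"""Synthetic fingerprint-region FTIR spectra with known class-discriminating bands.

Emulates the statistical structure of an infrared spectral-histopathology
study of oral epithelial dysplasia: 10 transforming (T) and 7
non-transforming (NT) patients, many spectra (pixels) per patient, Gaussian
vibrational bands on a 1000-1800 cm^-1 grid, a multiplicative per-spectrum
scale factor standing in for sample-to-sample systematic variation, small
per-patient band-amplitude offsets, and additive detector noise.

Class signal is planted as an additive amplitude difference (T minus NT) on
selected bands, so every downstream stage can be tested against a known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import LABEL_NT, LABEL_T, ConfigurationError, SpectralDataset

#: Key wavenumbers (cm^-1) reported by the reference PCA-LDA model, printed order.
PCA_LDA_KEY_WAVENUMBERS = (1678.0, 1653.0, 1628.0, 1574.0, 1242.0, 1020.0)

#: Band centers (cm^-1) carrying planted class signal in the default preset.
DEFAULT_PLANTED_CENTERS = (1684.0, 1656.0, 1614.0, 1575.0, 1236.0)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian vibrational band.

    ``amplitude`` is the mean NT peak absorbance; ``class_delta`` is added to
    the amplitude for T spectra (T minus NT difference at the band center);
    ``width`` is the Gaussian sigma in cm^-1.
    """

    center: float
    width: float
    amplitude: float
    class_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError(f"band at {self.center:g} cm^-1: width must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError(f"band at {self.center:g} cm^-1: amplitude must be >= 0")


@dataclass
class SyntheticConfig:
    """Full description of a simulated dataset; a pure function of its fields."""

    grid_min: float = 1000.0
    grid_max: float = 1800.0
    n_grid: int = 317
    bands: list[BandSpec] = field(default_factory=list)
    n_patients_T: int = 10
    n_patients_NT: int = 7
    spectra_per_patient: int = 50
    noise_sd: float = 0.02
    scale_sd: float = 0.10
    patient_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_grid < 2:
            raise ConfigurationError("n_grid must be >= 2")
        if self.grid_min >= self.grid_max:
            raise ConfigurationError("grid_min must be < grid_max")
        if min(self.noise_sd, self.scale_sd, self.patient_sd) < 0:
            raise ConfigurationError("noise_sd, scale_sd and patient_sd must be >= 0")
        if min(self.n_patients_T, self.n_patients_NT) < 1:
            raise ConfigurationError("patient counts must be >= 1")
        if self.spectra_per_patient < 1:
            raise ConfigurationError("spectra_per_patient must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_grid)

    @property
    def planted_wavenumbers(self) -> list[float]:
        return [b.center for b in self.bands if b.class_delta != 0.0]


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    planted_wavenumbers: np.ndarray  # centers of bands with class_delta != 0
    neutral_wavenumbers: np.ndarray  # centers of bands with class_delta == 0
    scale_factors: np.ndarray        # per spectrum, aligned with dataset rows
    patient_offsets: pd.DataFrame    # rows = patients, columns = band centers


def _default_bands(class_delta: float = 0.15) -> list[BandSpec]:
    """Fingerprint-region band table: five signal bands + neutral reference bands.

    Signal bands sit at the key wavenumbers the ratio-metric analysis is
    expected to find (Amide I shoulder/center, 1614, 1575, Amide III region);
    neutral bands (Amide II, CH deformation, symmetric phosphate,
    carbohydrate) provide stable ratio denominators.
    """
    planted = [BandSpec(c, 6.0, 1.0, class_delta) for c in DEFAULT_PLANTED_CENTERS]
    background = [
        BandSpec(1545.0, 12.0, 0.75),  # Amide II
        BandSpec(1450.0, 9.0, 0.45),
        BandSpec(1400.0, 9.0, 0.40),
        BandSpec(1080.0, 11.0, 0.50),
        BandSpec(1020.0, 9.0, 0.45),
    ]
    return planted + background


def default_config(seed: int) -> SyntheticConfig:
    """Default preset: planted class signal at the five key-wavenumber centers."""
    return SyntheticConfig(bands=_default_bands(), seed=seed)


def null_config(seed: int) -> SyntheticConfig:
    """Null preset: identical band table but every class_delta = 0."""
    cfg = default_config(seed)
    cfg.bands = [replace(b, class_delta=0.0) for b in cfg.bands]
    return cfg


def strong_signal_config(seed: int) -> SyntheticConfig:
    """Cleanly separable preset: large deltas, low noise, no patient variation."""
    cfg = default_config(seed)
    cfg.bands = [
        replace(b, class_delta=0.5 if b.class_delta != 0.0 else 0.0) for b in cfg.bands
    ]
    cfg.noise_sd = 0.005
    cfg.patient_sd = 0.0
    return cfg


PRESETS = {
    "default": default_config,
    "null": null_config,
    "strong-signal": strong_signal_config,
}


def make_pca_lda_reference() -> list[float]:
    """Key wavenumbers of the reference PCA-LDA model, descending (printed order)."""
    return list(PCA_LDA_KEY_WAVENUMBERS)


def generate_dataset(config: SyntheticConfig) -> tuple[SpectralDataset, GroundTruth]:
    """Simulate a labelled dataset from ``config``; reproducible from ``config.seed``.

    Each spectrum is

        scale * sum_b (amplitude_b + delta_b * 1[T] + offset_pb) * G_b(nu) + noise

    with ``G_b`` a unit-height Gaussian at the band center, ``scale =
    exp(N(0, scale_sd))`` per spectrum, ``offset_pb ~ N(0, patient_sd)`` per
    patient and band, and i.i.d. ``N(0, noise_sd)`` noise per grid point.
    """
    if not config.bands:
        raise ConfigurationError("config.bands must contain at least one band")
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    centers = np.array([b.center for b in config.bands])
    widths = np.array([b.width for b in config.bands])
    amps = np.array([b.amplitude for b in config.bands])
    deltas = np.array([b.class_delta for b in config.bands])
    # (n_bands, n_grid) unit-height profiles
    profiles = np.exp(-((grid[None, :] - centers[:, None]) ** 2) / (2.0 * widths[:, None] ** 2))

    patients = [(f"T{p + 1:02d}", LABEL_T) for p in range(config.n_patients_T)] + [
        (f"NT{p + 1:02d}", LABEL_NT) for p in range(config.n_patients_NT)
    ]
    offsets = rng.normal(0.0, config.patient_sd, size=(len(patients), len(config.bands)))

    n_total = len(patients) * config.spectra_per_patient
    absorbance = np.empty((n_total, grid.size))
    spectrum_ids, patient_ids, labels = [], [], []
    scales = np.empty(n_total)
    row = 0
    for p, (pid, label) in enumerate(patients):
        band_amp = amps + (deltas if label == LABEL_T else 0.0) + offsets[p]
        clean = band_amp @ profiles
        for s in range(config.spectra_per_patient):
            scale = float(np.exp(rng.normal(0.0, config.scale_sd)))
            noise = rng.normal(0.0, config.noise_sd, size=grid.size)
            absorbance[row] = scale * clean + noise
            scales[row] = scale
            spectrum_ids.append(f"{pid}_s{s + 1:03d}")
            patient_ids.append(pid)
            labels.append(label)
            row += 1

    dataset = SpectralDataset(
        grid=grid,
        absorbance=absorbance,
        spectrum_ids=np.array(spectrum_ids, dtype=object),
        patient_ids=np.array(patient_ids, dtype=object),
        labels=np.array(labels, dtype=object),
    )
    truth = GroundTruth(
        planted_wavenumbers=centers[deltas != 0.0].copy(),
        neutral_wavenumbers=centers[deltas == 0.0].copy(),
        scale_factors=scales,
        patient_offsets=pd.DataFrame(offsets, index=[pid for pid, _ in patients], columns=centers),
    )
    return dataset, truth


def write_ground_truth(config: SyntheticConfig, path) -> None:
    """Write the band table (center, width, amplitude, class_delta) as CSV."""
    pd.DataFrame(
        {
            "center_cm1": [b.center for b in config.bands],
            "width_cm1": [b.width for b in config.bands],
            "amplitude": [b.amplitude for b in config.bands],
            "class_delta": [b.class_delta for b in config.bands],
        }
    ).to_csv(path, index=False)
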