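import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ratiospec.io import SpectralDataset
from ratiospec.synthetic import BandSpec, SyntheticConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(absorbance, labels, grid=None, patients=None) -> SpectralDataset:
    """Hand-rolled dataset for unit tests."""
    absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
    n, g = absorbance.shape
    if grid is None:
        grid = 1000.0 + 4.0 * np.arange(g)
    labels = np.asarray(labels, dtype=object)
    if patients is None:
        patients = [f"p{i}" for i in range(n)]
    return SpectralDataset(
        grid=np.asarray(grid, dtype=float),
        absorbance=absorbance,
        spectrum_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        patient_ids=np.asarray(patients, dtype=object),
        labels=labels,
    )


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Down-scaled synthetic config for fast pipeline tests: 41-point grid,
    three patients per class, one planted band plus two references."""
    defaults = dict(
        grid_min=1400.0,
        grid_max=1720.0,
        n_grid=41,
        bands=[
            BandSpec(1656.0, 8.0, 1.0, 0.3),
            BandSpec(1545.0, 10.0, 0.7, 0.0),
            BandSpec(1450.0, 8.0, 0.5, 0.0),
        ],
        n_patients_T=3,
        n_patients_NT=3,
        spectra_per_patient=12,
        noise_sd=0.02,
        scale_sd=0.1,
        patient_sd=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def toy_dataset() -> SpectralDataset:
    rng = np.random.default_rng(7)
    return make_dataset(
        rng.uniform(0.1, 1.5, size=(12, 8)),
        labels=["T"] * 7 + ["NT"] * 5,
    )
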