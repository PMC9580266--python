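"""Reading, writing, validation and light pre-processing of tabular FTIR datasets.

A dataset is a pair of comma-delimited text files: a wide spectra table
(rows = spectra, first column = spectrum id, remaining column headers =
wavenumbers in cm^-1) and a metadata table with columns ``spectrum_id``,
``patient_id`` and ``label`` (``T`` = lesion underwent malignant
transformation, ``NT`` = did not).

Absorbance is dimensionless; wavenumbers are cm^-1 and stored on a strictly
increasing grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

LABEL_T = "T"
LABEL_NT = "NT"
VALID_LABELS = (LABEL_T, LABEL_NT)

#: Tolerance (cm^-1) for treating two wavenumbers as the same grid point.
WAVENUMBER_TOL = 1e-6


class SpectraValidationError(ValueError):
    """A dataset or its on-disk representation violates an invariant."""


class SpectraParseError(ValueError):
    """A spectra/metadata file could not be parsed."""


class ConfigurationError(ValueError):
    """A parameter object is internally inconsistent or inapplicable."""


@dataclass
class SpectralDataset:
    """An absorbance matrix on a common wavenumber grid plus per-spectrum metadata.

    Parameters
    ----------
    grid
        Strictly increasing wavenumbers, cm^-1, shape ``(n_wavenumbers,)``.
    absorbance
        Matrix of shape ``(n_spectra, n_wavenumbers)``, finite values.
    spectrum_ids, patient_ids, labels
        One entry per spectrum; labels are ``"T"`` or ``"NT"``.
    resolution
        Instrument spectral resolution in cm^-1 (default 4).
    """

    grid: np.ndarray
    absorbance: np.ndarray
    spectrum_ids: np.ndarray
    patient_ids: np.ndarray
    labels: np.ndarray
    resolution: float = 4.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.spectrum_ids = np.asarray(self.spectrum_ids, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(0, self.grid.size)
        self.validate()

    def validate(self) -> None:
        if self.grid.ndim != 1 or self.grid.size < 1:
            raise SpectraValidationError("wavenumber grid must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.grid)):
            raise SpectraValidationError("wavenumber grid contains non-finite values")
        if np.any(np.diff(self.grid) <= 0):
            raise SpectraValidationError("wavenumber grid must be strictly increasing with no duplicates")
        n = self.absorbance.shape[0]
        if self.absorbance.shape[1] != self.grid.size:
            raise SpectraValidationError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has {self.grid.size} points"
            )
        for name, arr in (
            ("spectrum_ids", self.spectrum_ids),
            ("patient_ids", self.patient_ids),
            ("labels", self.labels),
        ):
            if arr.shape != (n,):
                raise SpectraValidationError(f"{name} has length {arr.size}, expected {n}")
        ids, counts = np.unique(self.spectrum_ids.astype(str), return_counts=True)
        dup = ids[counts > 1]
        if dup.size:
            raise SpectraValidationError(f"duplicate spectrum id: {dup[0]!r}")
        bad = [str(s) for s, l in zip(self.spectrum_ids, self.labels) if l not in VALID_LABELS]
        if bad:
            raise SpectraValidationError(
                f"spectrum {bad[0]!r} has label outside {{T, NT}}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraValidationError("absorbance matrix contains non-finite values")

    # -- conveniences used throughout the pipeline ---------------------------

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.grid.size

    def class_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def subset(self, indices) -> "SpectralDataset":
        """New dataset holding the rows ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            spectrum_ids=self.spectrum_ids[idx],
            patient_ids=self.patient_ids[idx],
            labels=self.labels[idx],
            resolution=self.resolution,
        )


@dataclass
class QcParams:
    """Bounds on the peak absorbance inside a quality-control band.

    Default band is Amide I (1600-1700 cm^-1); spectra whose maximum
    absorbance in the band falls outside ``[min_peak_absorbance,
    max_peak_absorbance]`` are rejected.
    """

    min_peak_absorbance: float = 0.1
    max_peak_absorbance: float = 2.0
    qc_band: tuple[float, float] = (1600.0, 1700.0)

    def __post_init__(self) -> None:
        if not self.min_peak_absorbance < self.max_peak_absorbance:
            raise ConfigurationError("min_peak_absorbance must be < max_peak_absorbance")
        if self.qc_band[0] > self.qc_band[1]:
            raise ConfigurationError("qc_band must be (lo, hi) with lo <= hi")


_FLOAT_FMT = "%.17g"  # full float64 round trip through text


def read_spectra_table(spectra_path, metadata_path) -> SpectralDataset:
    """Read a spectra matrix + metadata table into a validated dataset.

    Rows are returned in metadata order; wavenumber columns are sorted
    ascending regardless of file order.
    """
    raw = pd.read_csv(spectra_path, dtype=str)
    if raw.shape[1] < 2:
        raise SpectraParseError(f"{spectra_path}: expected an id column plus wavenumber columns")
    id_col = raw.columns[0]
    try:
        grid = np.array([float(c) for c in raw.columns[1:]])
    except ValueError as exc:
        raise SpectraParseError(f"{spectra_path}: non-numeric wavenumber header: {exc}") from exc
    values = np.empty((raw.shape[0], grid.size), dtype=float)
    for j, col in enumerate(raw.columns[1:]):
        try:
            values[:, j] = raw[col].astype(float)
        except ValueError:
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise SpectraParseError(
                        f"{spectra_path}: non-numeric absorbance at row {i + 1}, column {col!r}: {cell!r}"
                    ) from None
            raise
    spec_ids = raw[id_col].astype(str).to_numpy()
    ids, counts = np.unique(spec_ids, return_counts=True)
    if np.any(counts > 1):
        raise SpectraValidationError(f"duplicate spectrum id in {spectra_path}: {ids[counts > 1][0]!r}")

    meta = pd.read_csv(metadata_path, dtype=str)
    for col in ("spectrum_id", "patient_id", "label"):
        if col not in meta.columns:
            raise SpectraParseError(f"{metadata_path}: missing required column {col!r}")
    meta_ids = meta["spectrum_id"].astype(str).to_numpy()
    mids, mcounts = np.unique(meta_ids, return_counts=True)
    if np.any(mcounts > 1):
        raise SpectraValidationError(f"duplicate spectrum id in {metadata_path}: {mids[mcounts > 1][0]!r}")
    missing = set(meta_ids) ^ set(spec_ids)
    if missing:
        raise SpectraValidationError(
            f"spectrum id {sorted(missing)[0]!r} present in only one of spectra/metadata files"
        )

    # rows into metadata order, columns ascending
    row_of = {s: i for i, s in enumerate(spec_ids)}
    row_order = np.array([row_of[s] for s in meta_ids], dtype=int)
    col_order = np.argsort(grid, kind="stable")
    return SpectralDataset(
        grid=grid[col_order],
        absorbance=values[np.ix_(row_order, col_order)],
        spectrum_ids=meta_ids,
        patient_ids=meta["patient_id"].astype(str).to_numpy(),
        labels=meta["label"].astype(str).to_numpy(),
    )


def write_spectra_table(dataset: SpectralDataset, spectra_path, metadata_path) -> None:
    """Write the two-file text representation read back by :func:`read_spectra_table`."""
    header = ["spectrum_id"] + [_FLOAT_FMT % w for w in dataset.grid]
    with open(spectra_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for sid, row in zip(dataset.spectrum_ids, dataset.absorbance):
            fh.write(str(sid) + "," + ",".join(_FLOAT_FMT % v for v in row) + "\n")
    meta = pd.DataFrame(
        {
            "spectrum_id": dataset.spectrum_ids.astype(str),
            "patient_id": dataset.patient_ids.astype(str),
            "label": dataset.labels.astype(str),
        }
    )
    meta.to_csv(metadata_path, index=False)


def quality_filter(dataset: SpectralDataset, params: QcParams) -> tuple[SpectralDataset, pd.DataFrame]:
    """Drop spectra whose peak absorbance in the QC band is out of bounds.

    Returns the filtered dataset (survivor order preserved) and a rejection
    report with one row per rejected spectrum (``spectrum_id``,
    ``peak_absorbance``).
    """
    lo, hi = params.qc_band
    band = (dataset.grid >= lo - WAVENUMBER_TOL) & (dataset.grid <= hi + WAVENUMBER_TOL)
    if not band.any():
        raise ConfigurationError(
            f"QC band {params.qc_band} does not overlap the grid "
            f"[{dataset.grid[0]:g}, {dataset.grid[-1]:g}]"
        )
    if dataset.n_spectra == 0:
        return dataset, pd.DataFrame(columns=["spectrum_id", "peak_absorbance"])
    peaks = dataset.absorbance[:, band].max(axis=1)
    keep = (peaks >= params.min_peak_absorbance) & (peaks <= params.max_peak_absorbance)
    report = pd.DataFrame(
        {
            "spectrum_id": dataset.spectrum_ids[~keep].astype(str),
            "peak_absorbance": peaks[~keep],
        }
    )
    return dataset.subset(np.flatnonzero(keep)), report


def resample_to_grid(dataset: SpectralDataset, target_grid) -> SpectralDataset:
    """Linear interpolation of every spectrum onto ``target_grid`` (no extrapolation)."""
    target = np.asarray(target_grid, dtype=float)
    if target.ndim != 1 or np.any(np.diff(target) <= 0):
        raise ConfigurationError("target grid must be 1-d and strictly increasing")
    if target[0] < dataset.grid[0] - WAVENUMBER_TOL or target[-1] > dataset.grid[-1] + WAVENUMBER_TOL:
        raise ConfigurationError(
            f"target grid [{target[0]:g}, {target[-1]:g}] extends beyond the data span "
            f"[{dataset.grid[0]:g}, {dataset.grid[-1]:g}]; extrapolation is not supported"
        )
    resampled = np.empty((dataset.n_spectra, target.size))
    for i in range(dataset.n_spectra):
        resampled[i] = np.interp(target, dataset.grid, dataset.absorbance[i])
    return replace(dataset, grid=target, absorbance=resampled)
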