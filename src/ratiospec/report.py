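"""Downstream key-wavenumber analysis of top-ranked ratio metrics.

Builds the wavenumber-frequency histogram of the selected metrics, annotates
each wavenumber against a reference model's important/neutral spectral
regions, collapses neighbouring discriminating wavenumbers into
count-weighted key wavenumbers, and matches those keys to a reference key
list under a wavenumber tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .io import WAVENUMBER_TOL, ConfigurationError

CATEGORY_DISCRIMINATING = "discriminating"  # inside a reference-important region
CATEGORY_REFERENCE = "reference"            # inside a reference-neutral region
CATEGORY_UNASSIGNED = "unassigned"


@dataclass
class WavenumberHistogram:
    """Occurrence count of each grid wavenumber among selected metrics.

    Every selected metric contributes +1 to both of its wavenumbers, so the
    counts always sum to twice the number of metric instances counted.
    """

    grid: np.ndarray
    counts: np.ndarray
    categories: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.categories is None:
            self.categories = np.full(self.grid.size, CATEGORY_UNASSIGNED, dtype=object)
        if not (self.grid.size == self.counts.size == self.categories.size):
            raise ConfigurationError("histogram grid/counts/categories lengths differ")
        if np.any(self.counts < 0):
            raise ConfigurationError("histogram counts must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber_cm1": self.grid, "count": self.counts, "category": self.categories}
        )


@dataclass
class ReferenceAnnotation:
    """Reference model's spectral regions and key wavenumbers.

    ``important_intervals``: (lo, hi) cm^-1 regions carrying positive or
    negative reference-model weight; ``neutral_intervals``: regions the
    reference model ignores (usable as ratio references); ``reference_keys``:
    its key wavenumbers for concordance; ``resolution``: spectral resolution
    in cm^-1, also the matching tolerance unit.
    """

    important_intervals: list[tuple[float, float]] = field(default_factory=list)
    neutral_intervals: list[tuple[float, float]] = field(default_factory=list)
    reference_keys: list[float] = field(default_factory=list)
    resolution: float = 4.0

    def __post_init__(self) -> None:
        for lo, hi in list(self.important_intervals) + list(self.neutral_intervals):
            if lo > hi:
                raise ConfigurationError(f"malformed interval ({lo:g}, {hi:g})")


class ConcordanceRow(NamedTuple):
    mla_key: float | None
    reference_key: float | None
    difference: float | None
    matched: bool


@dataclass
class ConcordanceTable:
    """One row per key wavenumber: matched pair or one-sided leftover."""

    rows: list[ConcordanceRow]
    tolerance: float

    @property
    def n_matched(self) -> int:
        return sum(r.matched for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mla_key_cm1": r.mla_key,
                    "reference_key_cm1": r.reference_key,
                    "difference_cm1": r.difference,
                    "matched": r.matched,
                }
                for r in self.rows
            ]
        )


def _ranking_pairs(ranking) -> tuple[np.ndarray, np.ndarray]:
    """Wavenumber pairs (cm^-1) of one ranking: MetricRanking needs a grid-bearing
    frame, so accept the serialised DataFrame or any (w_num, w_den) column table."""
    if isinstance(ranking, pd.DataFrame):
        return ranking["w_num_cm1"].to_numpy(float), ranking["w_den_cm1"].to_numpy(float)
    raise TypeError("ranking must be a DataFrame with w_num_cm1/w_den_cm1 columns")


def wavenumber_histogram(rankings: Iterable[pd.DataFrame], grid) -> WavenumberHistogram:
    """Count how often each grid wavenumber appears among selected metrics.

    ``rankings`` is one or more serialised rankings (e.g. one per repeat);
    repeats are pooled.  Each metric increments the count of both its
    wavenumbers.  Categories start unassigned.
    """
    grid = np.asarray(grid, dtype=float)
    counts = np.zeros(grid.size, dtype=int)
    for ranking in rankings:
        for w in np.concatenate(_ranking_pairs(ranking)):
            idx = int(np.argmin(np.abs(grid - w)))
            if abs(grid[idx] - w) > WAVENUMBER_TOL:
                raise ConfigurationError(f"metric wavenumber {w:g} cm^-1 not on the histogram grid")
            counts[idx] += 1
    return WavenumberHistogram(grid=grid, counts=counts)


def annotate_histogram(
    hist: WavenumberHistogram, ann: ReferenceAnnotation
) -> WavenumberHistogram:
    """Assign each wavenumber a category against the reference model's regions.

    Important intervals are expanded by ± one resolution element (wavenumbers
    correspond when within the spectral resolution); important beats neutral
    on overlap; everything else is unassigned.  Counts are untouched.
    """
    categories = np.full(hist.grid.size, CATEGORY_UNASSIGNED, dtype=object)
    for lo, hi in ann.neutral_intervals:
        inside = (hist.grid >= lo) & (hist.grid <= hi)
        categories[inside] = CATEGORY_REFERENCE
    for lo, hi in ann.important_intervals:
        inside = (hist.grid >= lo - ann.resolution) & (hist.grid <= hi + ann.resolution)
        categories[inside] = CATEGORY_DISCRIMINATING
    return WavenumberHistogram(grid=hist.grid.copy(), counts=hist.counts.copy(), categories=categories)


def group_key_wavenumbers(hist: WavenumberHistogram, gap: float = 4.0) -> list[float]:
    """Collapse neighbouring discriminating wavenumbers into key wavenumbers.

    Discriminating wavenumbers with nonzero counts are partitioned into
    maximal runs whose consecutive members are at most ``gap`` cm^-1 apart;
    each group's key is its count-weighted mean wavenumber.  Returned
    descending (conventional spectroscopic order).
    """
    mask = (hist.categories == CATEGORY_DISCRIMINATING) & (hist.counts > 0)
    w = hist.grid[mask]
    c = hist.counts[mask]
    if w.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(w) > gap + WAVENUMBER_TOL) + 1
    keys = [
        float(np.average(wg, weights=cg))
        for wg, cg in zip(np.split(w, breaks), np.split(c, breaks))
    ]
    return sorted(keys, reverse=True)


def concordance_table(
    mla_keys: Iterable[float], reference_keys: Iterable[float], tolerance: float = 4.0
) -> ConcordanceTable:
    """Greedy nearest-pair matching of two key-wavenumber lists.

    Repeatedly matches the globally closest unmatched (mla, reference) pair
    with absolute difference <= ``tolerance``; leftovers become one-sided
    rows.  Matched rows come first in descending mla order, then unmatched
    mla keys, then unmatched reference keys (both descending).
    """
    mla = [float(x) for x in mla_keys]
    ref = [float(x) for x in reference_keys]
    if not mla or not ref:
        raise ConfigurationError("both key lists must be non-empty")
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be > 0")
    pairs = sorted(
        ((abs(m - r), -m, -r, i, j) for i, m in enumerate(mla) for j, r in enumerate(ref)),
    )
    used_m: set[int] = set()
    used_r: set[int] = set()
    matched: list[tuple[float, float]] = []
    for diff, negm, negr, i, j in pairs:
        if diff > tolerance + WAVENUMBER_TOL:
            break
        if i in used_m or j in used_r:
            continue
        used_m.add(i)
        used_r.add(j)
        matched.append((mla[i], ref[j]))
    rows = [
        ConcordanceRow(m, r, abs(m - r), True)
        for m, r in sorted(matched, key=lambda p: -p[0])
    ]
    rows += [
        ConcordanceRow(m, None, None, False)
        for m in sorted((mla[i] for i in range(len(mla)) if i not in used_m), reverse=True)
    ]
    rows += [
        ConcordanceRow(None, r, None, False)
        for r in sorted((ref[j] for j in range(len(ref)) if j not in used_r), reverse=True)
    ]
    return ConcordanceTable(rows=rows, tolerance=tolerance)


def default_reference_annotation(
    reference_keys: Iterable[float] | None = None, resolution: float = 4.0
) -> ReferenceAnnotation:
    """Annotation treating each reference key ± one resolution element as important."""
    if reference_keys is None:
        from .synthetic import make_pca_lda_reference

        reference_keys = make_pca_lda_reference()
    keys = [float(k) for k in reference_keys]
    return ReferenceAnnotation(
        important_intervals=[(k - resolution, k + resolution) for k in keys],
        neutral_intervals=[],
        reference_keys=keys,
        resolution=resolution,
    )


def ground_truth_annotation(truth, resolution: float = 4.0) -> ReferenceAnnotation:
    """Annotation built from a synthetic ground truth: planted bands are the
    important regions, zero-delta bands the neutral ones."""
    planted = [float(c) for c in truth.planted_wavenumbers]
    neutral = [float(c) for c in truth.neutral_wavenumbers]
    return ReferenceAnnotation(
        important_intervals=[(c - resolution, c + resolution) for c in planted],
        neutral_intervals=[(c - resolution, c + resolution) for c in neutral],
        reference_keys=planted,
        resolution=resolution,
    )


def read_annotation(path, resolution: float = 4.0) -> ReferenceAnnotation:
    """Read an annotation table: columns ``kind`` (important|neutral), ``lo_cm1``, ``hi_cm1``."""
    table = pd.read_csv(path)
    important, neutral = [], []
    for _, row in table.iterrows():
        kind = str(row["kind"]).strip().lower()
        interval = (float(row["lo_cm1"]), float(row["hi_cm1"]))
        if kind == "important":
            important.append(interval)
        elif kind == "neutral":
            neutral.append(interval)
        else:
            raise ConfigurationError(f"annotation kind must be important|neutral, got {kind!r}")
    keys = [0.5 * (lo + hi) for lo, hi in important]
    return ReferenceAnnotation(important, neutral, keys, resolution)


def plot_histogram(hist: WavenumberHistogram, path) -> None:
    """Bar plot of the annotated histogram (green/blue/grey by category)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        CATEGORY_DISCRIMINATING: "tab:green",
        CATEGORY_REFERENCE: "tab:blue",
        CATEGORY_UNASSIGNED: "0.6",
    }
    fig, ax = plt.subplots(figsize=(9, 3.5))
    width = float(np.median(np.diff(hist.grid))) if hist.grid.size > 1 else 1.0
    ax.bar(hist.grid, hist.counts, width=width, color=[colors[c] for c in hist.categories])
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("count in top metrics")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
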