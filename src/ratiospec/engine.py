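"""Ratio-metric classifier core.

A *metric* is an unordered pair of wavenumbers; its value on a spectrum is
the absorbance ratio A[numerator] / A[denominator].  Ratios are invariant to
per-spectrum multiplicative scaling, so neutral reference bands cancel
sample-to-sample systematic variation.  Training fits a one-dimensional
threshold rule to the class-conditional ratio distributions, testing scores
each rule by balanced accuracy on held-out spectra, and validation
classifies unseen spectra by a score-weighted vote over the top-ranked
metrics.

The heavy lifting is done by vectorised batch functions operating on index
arrays; the per-metric dataclass API wraps the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LABEL_NT, LABEL_T, ConfigurationError, SpectralDataset

#: Denominator absorbances below this magnitude make a ratio undefined.
DEFAULT_EPSILON = 1e-6

#: Marker label for a spectrum on which every selected metric abstained.
UNCLASSIFIABLE = ""

_CHUNK = 8192  # metrics per vectorised block; bounds peak memory


class StratificationError(ValueError):
    """A class is too small to realise the requested split fractions."""


class SelectionError(ValueError):
    """Top-N selection asked for more metrics than are trainable."""


class ScoringError(ValueError):
    """A test or validation set is missing one of the two classes."""


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitConfig:
    """Random train/test/validation split, stratified by class.

    Fractions default to the 60/20/20 protocol.  ``group_by_patient`` keeps
    all spectra of a patient in one subset (off by default: the reference
    protocol randomises at spectrum level).
    """

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratify_by_class: bool = True
    group_by_patient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(not 0 < f < 1 for f in self.fractions):
            raise ConfigurationError("fractions must be three values in (0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError("fractions must sum to 1")


def largest_remainder_sizes(n: int, fractions) -> list[int]:
    """Integer subset sizes summing to ``n``, closest to ``n * fractions``.

    Floors first, then hands remaining units to the largest fractional parts
    (ties broken by subset order), so 70 spectra at (0.6, 0.2, 0.2) give
    (42, 14, 14).
    """
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    rem = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split_dataset(
    dataset: SpectralDataset, config: SplitConfig
) -> tuple[SpectralDataset, SpectralDataset, SpectralDataset]:
    """Partition into (train, test, validation), per-class, reproducibly.

    The T and NT spectra are split as two separate subsets so the class
    balance of the full dataset is preserved in every part.
    """
    rng = np.random.default_rng(config.seed)
    parts: list[list[int]] = [[], [], []]
    groups = [LABEL_T, LABEL_NT] if config.stratify_by_class else [None]
    for label in groups:
        idx = (
            np.flatnonzero(dataset.labels == label)
            if label is not None
            else np.arange(dataset.n_spectra)
        )
        if config.group_by_patient:
            units = list(pd.unique(dataset.patient_ids[idx]))
        else:
            units = list(idx)
        if len(units) < 3:
            raise StratificationError(
                f"class {label!r} has only {len(units)} assignable units; need >= 3 "
                "to populate train/test/validation"
            )
        perm = rng.permutation(len(units))
        sizes = largest_remainder_sizes(len(units), config.fractions)
        start = 0
        for part, size in zip(parts, sizes):
            chosen = [units[k] for k in perm[start : start + size]]
            start += size
            if config.group_by_patient:
                sel = np.flatnonzero(np.isin(dataset.patient_ids[idx], chosen))
                part.extend(idx[sel])
            else:
                part.extend(chosen)
    return tuple(dataset.subset(sorted(p)) for p in parts)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Metric:
    """Canonical unordered wavenumber-index pair: numerator index < denominator index."""

    w_num: int
    w_den: int

    def __post_init__(self) -> None:
        if self.w_num == self.w_den:
            raise ConfigurationError("metric wavenumber indices must differ")
        if self.w_num > self.w_den:
            raise ConfigurationError("metric stored non-canonically; require w_num < w_den")


def pair_indices(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of all C(n, 2) canonical pairs, lexicographic order."""
    if grid_size < 2:
        raise ConfigurationError("need at least 2 wavenumbers to form a metric")
    return np.triu_indices(grid_size, k=1)


def enumerate_metrics(grid_size: int) -> list[Metric]:
    """All unordered wavenumber pairs as :class:`Metric` objects."""
    ii, jj = pair_indices(grid_size)
    return [Metric(int(i), int(j)) for i, j in zip(ii, jj)]


def metric_value(spectrum, metric: Metric, epsilon: float = DEFAULT_EPSILON) -> float:
    """Absorbance ratio of one metric on one spectrum; NaN when undefined.

    The ratio is undefined (NaN) when the denominator magnitude is below
    ``epsilon`` — a guard, not an error.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    den = spectrum[metric.w_den]
    if abs(den) < epsilon:
        return float("nan")
    return float(spectrum[metric.w_num] / den)


def _ratio_matrix(A: np.ndarray, ii, jj, epsilon: float) -> np.ndarray:
    """(n_spectra, n_metrics) ratio matrix with NaN where the denominator is guarded."""
    den = A[:, jj]
    ok = np.abs(den) >= epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        R = A[:, ii] / np.where(ok, den, 1.0)
    R[~ok] = np.nan
    return R


@dataclass
class TrainedMetric:
    """A metric plus its fitted threshold rule and (once scored) test score."""

    metric: Metric
    threshold: float = float("nan")
    polarity: str = LABEL_T           # class whose ratios lie above the threshold
    train_means: dict = field(default_factory=dict)
    train_sds: dict = field(default_factory=dict)
    separation: float = 0.0           # |mean_T - mean_NT| / pooled sd (tie-break key)
    trainable: bool = True
    score: float | None = None

    def predict(self, spectrum, epsilon: float = DEFAULT_EPSILON) -> str | None:
        """Vote for one spectrum; None = abstain (undefined ratio)."""
        r = metric_value(spectrum, self.metric, epsilon)
        if np.isnan(r):
            return None
        other = LABEL_NT if self.polarity == LABEL_T else LABEL_T
        return self.polarity if r > self.threshold else other


@dataclass
class MetricRanking:
    """Top-``n_top`` trained metrics, descending score (deterministic tie order)."""

    metrics: list[TrainedMetric]
    n_top: int

    def __post_init__(self) -> None:
        scores = [tm.score for tm in self.metrics]
        if any(s is None for s in scores):
            raise SelectionError("all ranked metrics must carry a score")
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise SelectionError("ranking scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.metrics)

    def to_frame(self, grid: np.ndarray) -> pd.DataFrame:
        """Serialisable table: w_num_cm1, w_den_cm1, score, threshold, polarity."""
        return pd.DataFrame(
            {
                "w_num_cm1": [grid[tm.metric.w_num] for tm in self.metrics],
                "w_den_cm1": [grid[tm.metric.w_den] for tm in self.metrics],
                "score": [tm.score for tm in self.metrics],
                "threshold": [tm.threshold for tm in self.metrics],
                "polarity": [tm.polarity for tm in self.metrics],
            }
        )


# ---------------------------------------------------------------------------
# batch training / scoring (the fast path)
# ---------------------------------------------------------------------------

def train_metrics_batch(
    train: SpectralDataset,
    ii: np.ndarray,
    jj: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> dict[str, np.ndarray]:
    """Fit threshold rules for many metrics at once.

    Returns arrays aligned with ``ii``/``jj``: ``threshold``, ``polarity_T``
    (bool, True = T lies above the threshold), per-class train means/sds,
    ``separation`` and ``trainable``.  A metric with fewer than two defined
    ratios in either class is untrainable.

    The threshold is the midpoint between adjacent distinct sorted training
    ratios maximising balanced accuracy under the fixed polarity
    (higher-mean class above); when no interior cut reaches 0.5 the
    threshold falls back above the largest ratio so the rule degrades to
    balanced accuracy exactly 0.5.
    """
    yT = train.class_mask(LABEL_T)
    if not yT.any() or yT.all():
        raise ScoringError("training set must contain both classes")
    A = train.absorbance
    n = A.shape[0]
    m = ii.size
    out = {
        "threshold": np.full(m, np.nan),
        "polarity_T": np.ones(m, dtype=bool),
        "mean_T": np.full(m, np.nan),
        "mean_NT": np.full(m, np.nan),
        "sd_T": np.full(m, np.nan),
        "sd_NT": np.full(m, np.nan),
        "separation": np.zeros(m),
        "trainable": np.zeros(m, dtype=bool),
    }
    ks = np.arange(n - 1)
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        R = _ratio_matrix(A, ii[lo:hi], jj[lo:hi], epsilon).T  # (mc, n)
        valid = np.isfinite(R)
        vT = valid & yT[None, :]
        vNT = valid & ~yT[None, :]
        nTv = vT.sum(axis=1)
        nNTv = vNT.sum(axis=1)
        trainable = (nTv >= 2) & (nNTv >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            mT = np.where(vT, R, 0.0).sum(axis=1) / nTv
            mNT = np.where(vNT, R, 0.0).sum(axis=1) / nNTv
            ssT = np.where(vT, (R - mT[:, None]) ** 2, 0.0).sum(axis=1)
            ssNT = np.where(vNT, (R - mNT[:, None]) ** 2, 0.0).sum(axis=1)
            sdT = np.sqrt(ssT / np.maximum(nTv - 1, 1))
            sdNT = np.sqrt(ssNT / np.maximum(nNTv - 1, 1))
            pooled = np.sqrt(
                ((nTv - 1) * sdT**2 + (nNTv - 1) * sdNT**2)
                / np.maximum(nTv + nNTv - 2, 1)
            )
            gap = np.abs(mT - mNT)
            sep = np.where(pooled > 0, gap / np.where(pooled > 0, pooled, 1.0), np.where(gap > 0, np.inf, 0.0))
        polarity_T = mT >= mNT

        # threshold scan over sorted defined ratios (undefined sort to the end)
        Rs = np.where(valid, R, np.inf)
        order = np.argsort(Rs, axis=1, kind="stable")
        sR = np.take_along_axis(Rs, order, axis=1)
        sT = np.take_along_axis(np.broadcast_to(yT, R.shape), order, axis=1)
        nv = valid.sum(axis=1)
        cumT = np.cumsum(sT, axis=1)[:, :-1]  # T count among first k+1 positions
        cut_ok = (ks[None, :] < (nv - 1)[:, None]) & (sR[:, 1:] > sR[:, :-1]) & np.isfinite(sR[:, 1:])
        # exact integer objective: balanced accuracy scaled by 2 * nT * nNT,
        # so ties between cuts are compared without float rounding noise
        ba_T_above = nNTv[:, None] * (nTv[:, None] - cumT) + nTv[:, None] * (ks[None, :] + 1 - cumT)
        full = (2 * nTv * nNTv)[:, None]
        ba = np.where(polarity_T[:, None], ba_T_above, full - ba_T_above)
        ba = np.where(cut_ok, ba, -1)
        if ba.shape[1]:
            kbest = np.argmax(ba, axis=1)
            best_ba = ba[np.arange(ba.shape[0]), kbest]
            thr = 0.5 * (sR[np.arange(ba.shape[0]), kbest] + sR[np.arange(ba.shape[0]), kbest + 1])
        else:
            best_ba = np.full(hi - lo, -1)
            thr = np.full(hi - lo, np.nan)
        # degenerate rows: no usable cut, or no cut beating chance -> rule = 0.5
        fallback = best_ba < nTv * nNTv
        if fallback.any():
            last_valid = np.where(nv > 0, nv - 1, 0)
            thr = np.where(fallback, sR[np.arange(sR.shape[0]), last_valid], thr)

        sl = slice(lo, hi)
        out["threshold"][sl] = thr
        out["polarity_T"][sl] = polarity_T
        out["mean_T"][sl] = mT
        out["mean_NT"][sl] = mNT
        out["sd_T"][sl] = sdT
        out["sd_NT"][sl] = sdNT
        out["separation"][sl] = np.where(trainable, sep, 0.0)
        out["trainable"][sl] = trainable
    return out


def score_metrics_batch(
    test: SpectralDataset,
    ii: np.ndarray,
    jj: np.ndarray,
    threshold: np.ndarray,
    polarity_T: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Balanced accuracy of each trained rule on the test set.

    Undefined ratios count as misclassified for their true class.
    """
    yT = test.class_mask(LABEL_T)
    nT = int(yT.sum())
    nNT = int((~yT).sum())
    if nT == 0 or nNT == 0:
        raise ScoringError("test set must contain both classes")
    A = test.absorbance
    m = ii.size
    scores = np.empty(m)
    for lo in range(0, m, _CHUNK):
        hi = min(lo + _CHUNK, m)
        R = _ratio_matrix(A, ii[lo:hi], jj[lo:hi], epsilon)  # (n, mc)
        valid = np.isfinite(R)
        with np.errstate(invalid="ignore"):
            above = R > threshold[None, lo:hi]
        predT = np.where(polarity_T[None, lo:hi], above, ~above)
        correct = valid & (predT == yT[:, None])
        accT = (correct & yT[:, None]).sum(axis=0) / nT
        accNT = (correct & ~yT[:, None]).sum(axis=0) / nNT
        scores[lo:hi] = 0.5 * (accT + accNT)
    return scores


def rank_order(
    scores: np.ndarray, separation: np.ndarray, trainable: np.ndarray
) -> np.ndarray:
    """Indices of trainable metrics sorted by (score desc, separation desc, index asc)."""
    idx = np.flatnonzero(trainable)
    # np.lexsort: last key is primary
    order = np.lexsort((idx, -separation[idx], -scores[idx]))
    return idx[order]


# ---------------------------------------------------------------------------
# per-metric API (thin wrappers over the batch path)
# ---------------------------------------------------------------------------

def train_metric(
    train: SpectralDataset, metric: Metric, epsilon: float = DEFAULT_EPSILON
) -> TrainedMetric:
    """Fit one metric's threshold rule on the training set."""
    ii = np.array([metric.w_num])
    jj = np.array([metric.w_den])
    res = train_metrics_batch(train, ii, jj, epsilon)
    polarity = LABEL_T if res["polarity_T"][0] else LABEL_NT
    return TrainedMetric(
        metric=metric,
        threshold=float(res["threshold"][0]),
        polarity=polarity,
        train_means={LABEL_T: float(res["mean_T"][0]), LABEL_NT: float(res["mean_NT"][0])},
        train_sds={LABEL_T: float(res["sd_T"][0]), LABEL_NT: float(res["sd_NT"][0])},
        separation=float(res["separation"][0]),
        trainable=bool(res["trainable"][0]),
    )


def score_metric(
    tm: TrainedMetric, test: SpectralDataset, epsilon: float = DEFAULT_EPSILON
) -> float:
    """Balanced accuracy of one trained metric on the test set, in [0, 1]."""
    if not tm.trainable:
        raise ScoringError("cannot score an untrainable metric")
    score = score_metrics_batch(
        test,
        np.array([tm.metric.w_num]),
        np.array([tm.metric.w_den]),
        np.array([tm.threshold]),
        np.array([tm.polarity == LABEL_T]),
        epsilon,
    )[0]
    tm.score = float(score)
    return tm.score


def rank_and_select(trained: list[TrainedMetric], n_top: int) -> MetricRanking:
    """Keep the ``n_top`` best-scoring trainable metrics, deterministic order."""
    usable = [tm for tm in trained if tm.trainable and tm.score is not None]
    if n_top > len(usable):
        raise SelectionError(f"requested top {n_top} but only {len(usable)} scored metrics")
    scores = np.array([tm.score for tm in usable])
    seps = np.array([tm.separation for tm in usable])
    key = np.array([(tm.metric.w_num, tm.metric.w_den) for tm in usable])
    order = np.lexsort((key[:, 1], key[:, 0], -seps, -scores))
    return MetricRanking(metrics=[usable[k] for k in order[:n_top]], n_top=n_top)


def classify_matrix(
    A: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    threshold: np.ndarray,
    polarity_T: np.ndarray,
    weights: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Score-weighted ensemble vote for each row of ``A``.

    Undefined ratios abstain; a spectrum on which every metric abstains gets
    the :data:`UNCLASSIFIABLE` marker.  An exact weighted tie goes to NT
    (a tie never asserts malignancy).
    """
    R = _ratio_matrix(np.atleast_2d(A), ii, jj, epsilon)
    valid = np.isfinite(R)
    with np.errstate(invalid="ignore"):
        above = R > threshold[None, :]
    predT = np.where(polarity_T[None, :], above, ~above)
    wT = np.where(valid & predT, weights[None, :], 0.0).sum(axis=1)
    wNT = np.where(valid & ~predT, weights[None, :], 0.0).sum(axis=1)
    labels = np.where(wT > wNT, LABEL_T, LABEL_NT).astype(object)
    labels[~valid.any(axis=1)] = UNCLASSIFIABLE
    return labels


def classify_spectrum(
    spectrum, ranking: MetricRanking, epsilon: float = DEFAULT_EPSILON
) -> str:
    """Ensemble label for one spectrum ('' when every metric abstains)."""
    if len(ranking) == 0:
        raise SelectionError("ranking is empty")
    ii = np.array([tm.metric.w_num for tm in ranking.metrics])
    jj = np.array([tm.metric.w_den for tm in ranking.metrics])
    thr = np.array([tm.threshold for tm in ranking.metrics])
    polT = np.array([tm.polarity == LABEL_T for tm in ranking.metrics])
    w = np.array([tm.score for tm in ranking.metrics], dtype=float)
    return classify_matrix(np.asarray(spectrum, dtype=float), ii, jj, thr, polT, w, epsilon)[0]


def evaluate_predictions(predicted, truth) -> tuple[float, float, float]:
    """(sensitivity, specificity, precision) with T as the positive class.

    Unclassifiable predictions count as wrong for their true class.
    Precision is NaN when nothing was predicted T.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.size} predictions vs {truth.size} truths")
    isT = truth == LABEL_T
    isNT = truth == LABEL_NT
    if not isT.any() or not isNT.any():
        raise ScoringError("truth must contain both classes")
    tp = int(((predicted == LABEL_T) & isT).sum())
    fn = int(isT.sum()) - tp
    tn = int(((predicted == LABEL_NT) & isNT).sum())
    fp = int(((predicted == LABEL_T) & isNT).sum())
    sensitivity = tp / (tp + fn)
    specificity = tn / int(isNT.sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return sensitivity, specificity, precision
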