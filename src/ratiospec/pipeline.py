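"""One full train/test/select/validate pass, its ten-fold repetition, and
Table-style aggregation of sensitivity, specificity and precision."""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import engine
from .engine import SplitConfig
from .io import LABEL_NT, LABEL_T, SpectralDataset

_M64 = (1 << 64) - 1


def child_seed(master_seed: int, index: int) -> int:
    """Independent per-repeat seed stream (splitmix64 finaliser), < 2^31."""
    z = (int(master_seed) + (index + 1) * 0x9E3779B97F4A7C15) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return (z ^ (z >> 31)) % (1 << 31)


@dataclass
class RunResult:
    """Validation-set performance of one repeat plus the metrics it selected."""

    repeat_index: int
    sensitivity: float
    specificity: float
    precision: float  # NaN when no spectrum was predicted T
    ranking: pd.DataFrame  # w_num_cm1, w_den_cm1, score, threshold, polarity
    seed: int


@dataclass
class AggregateResult:
    """Per-repeat results plus mean and sample standard deviation of each rate."""

    runs: list[RunResult]
    mean_sensitivity: float
    sd_sensitivity: float
    mean_specificity: float
    sd_specificity: float
    mean_precision: float
    sd_precision: float
    n_precision_defined: int

    @property
    def n_repeats(self) -> int:
        return len(self.runs)


def run_once(
    dataset: SpectralDataset,
    split: SplitConfig,
    n_top: int = 150,
    repeat_index: int = 0,
) -> RunResult:
    """Split, train all pairwise ratio metrics, score, select, validate.

    Training fits every unordered wavenumber pair on the training subset;
    each rule is scored by balanced accuracy on the test subset; the top
    ``n_top`` metrics then classify the validation subset by score-weighted
    vote.
    """
    train, test, validation = engine.split_dataset(dataset, split)
    ii, jj = engine.pair_indices(dataset.n_wavenumbers)
    fit = engine.train_metrics_batch(train, ii, jj)
    scores = np.full(ii.size, -1.0)
    trainable = fit["trainable"]
    scores[trainable] = engine.score_metrics_batch(
        test, ii[trainable], jj[trainable], fit["threshold"][trainable], fit["polarity_T"][trainable]
    )
    order = engine.rank_order(scores, fit["separation"], trainable)
    if n_top > order.size:
        raise engine.SelectionError(
            f"requested top {n_top} but only {order.size} trainable metrics"
        )
    top = order[:n_top]
    predicted = engine.classify_matrix(
        validation.absorbance,
        ii[top],
        jj[top],
        fit["threshold"][top],
        fit["polarity_T"][top],
        scores[top],
    )
    sens, spec, prec = engine.evaluate_predictions(predicted, validation.labels)
    ranking = pd.DataFrame(
        {
            "w_num_cm1": dataset.grid[ii[top]],
            "w_den_cm1": dataset.grid[jj[top]],
            "score": scores[top],
            "threshold": fit["threshold"][top],
            "polarity": np.where(fit["polarity_T"][top], LABEL_T, LABEL_NT),
        }
    )
    return RunResult(
        repeat_index=repeat_index,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        ranking=ranking,
        seed=split.seed,
    )


def run_repeated(
    dataset: SpectralDataset,
    split: SplitConfig,
    n_top: int = 150,
    n_repeats: int = 10,
    master_seed: int = 0,
) -> AggregateResult:
    """Repeat the full pass with a freshly randomised three-way split each time."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (sample sd undefined otherwise)")
    runs = []
    for r in range(n_repeats):
        cfg = replace(split, seed=child_seed(master_seed, r))
        runs.append(run_once(dataset, cfg, n_top=n_top, repeat_index=r))
    sens = np.array([r.sensitivity for r in runs])
    spec = np.array([r.specificity for r in runs])
    prec = np.array([r.precision for r in runs])
    prec_ok = np.isfinite(prec)
    return AggregateResult(
        runs=runs,
        mean_sensitivity=float(sens.mean()),
        sd_sensitivity=float(sens.std(ddof=1)),
        mean_specificity=float(spec.mean()),
        sd_specificity=float(spec.std(ddof=1)),
        mean_precision=float(prec[prec_ok].mean()) if prec_ok.any() else float("nan"),
        sd_precision=float(prec[prec_ok].std(ddof=1)) if prec_ok.sum() >= 2 else float("nan"),
        n_precision_defined=int(prec_ok.sum()),
    )


def _pct(x: float) -> int:
    """Round a fraction to a whole percentage, half away from zero."""
    return int((Decimal(str(x)) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize(result: AggregateResult) -> tuple[str, pd.DataFrame]:
    """Render mean ± sd as whole-number percentages, plus a full-precision table.

    Precision is averaged over the repeats where it is defined; the rendered
    row is flagged when any repeat left it undefined.
    """
    rows = [
        ("Sensitivity", result.mean_sensitivity, result.sd_sensitivity, result.n_repeats),
        ("Specificity", result.mean_specificity, result.sd_specificity, result.n_repeats),
        ("Precision", result.mean_precision, result.sd_precision, result.n_precision_defined),
    ]
    lines = []
    for name, mean, sd, n_def in rows:
        if np.isnan(mean):
            cell = "undefined"
        else:
            cell = f"{_pct(mean)} ± {_pct(sd) if np.isfinite(sd) else 0}%"
            if n_def < result.n_repeats:
                cell += f" (defined in {n_def}/{result.n_repeats} repeats)"
        lines.append(f"{name:<12} {cell}")
    frame = pd.DataFrame(
        [(name, mean, sd, n_def) for name, mean, sd, n_def in rows],
        columns=["rate", "mean", "sd", "n_defined"],
    )
    return "\n".join(lines), frame
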