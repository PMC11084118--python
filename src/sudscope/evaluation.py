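"""Splits, stratified sampling, classification metrics and significance testing.

These utilities are shared by every trainable component: 75:5:20 stratified
splits, per-stratum sampling for descriptive tables, macro-averaged precision/
recall/F1, the Wilcoxon signed-rank test for paired model comparisons, and a
median-over-runs reporting helper.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import precision_recall_fscore_support

__all__ = [
    "SplitSpec",
    "stratified_split",
    "stratified_sample",
    "macro_metrics",
    "wilcoxon_test",
    "median_over_runs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Train/dev/test proportions with a seed and a stratification key.

    ``strata_key`` is a callable item -> stratum label, or the name of an
    attribute / mapping key to read off each item.
    """

    ratios: tuple[float, float, float] = (0.75, 0.05, 0.20)
    seed: int = 0
    strata_key: str | Callable = "label"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {self.ratios}")

    def key_fn(self) -> Callable:
        if callable(self.strata_key):
            return self.strata_key
        name = self.strata_key

        def key(item):
            if isinstance(item, dict):
                return item[name]
            return getattr(item, name)

        return key


def _allocate(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items; ties go to the earlier part."""
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(remainders))  # argmax takes the first maximum: train first
        counts[i] += 1
        remainders[i] = -1.0
    return counts


def stratified_split(dataset: Sequence, spec: SplitSpec) -> tuple[list, list, list]:
    """Partition a dataset into train/dev/test with per-stratum proportions.

    The three parts are disjoint and exhaustive; within each stratum the part
    sizes match ``spec.ratios`` to within one item (largest-remainder rounding,
    ties resolved train-first); identical seeds give identical partitions.
    """
    key = spec.key_fn()
    strata: dict = {}
    for idx, item in enumerate(dataset):
        strata.setdefault(key(item), []).append(idx)
    for label, idxs in strata.items():
        if len(idxs) < 3:
            raise ValueError(
                f"stratum {label!r} has only {len(idxs)} items; at least 3 required"
            )
    rng = np.random.default_rng(spec.seed)
    parts: tuple[list, list, list] = ([], [], [])
    for label in sorted(strata, key=repr):
        idxs = np.array(strata[label])
        rng.shuffle(idxs)
        counts = _allocate(len(idxs), spec.ratios)
        offset = 0
        for part, c in zip(parts, counts):
            part.extend(dataset[i] for i in idxs[offset : offset + c])
            offset += c
    return parts


def stratified_sample(
    dataset: Sequence, n_per_stratum: int, seed: int, strata_key="label"
) -> list:
    """Draw ``n_per_stratum`` items per stratum without replacement (seeded).

    Strata smaller than the request contribute all their items, with a warning.
    """
    spec = SplitSpec(seed=seed, strata_key=strata_key)
    key = spec.key_fn()
    strata: dict = {}
    for idx, item in enumerate(dataset):
        strata.setdefault(key(item), []).append(idx)
    rng = np.random.default_rng(seed)
    sample: list = []
    for label in sorted(strata, key=repr):
        idxs = strata[label]
        if len(idxs) <= n_per_stratum:
            if len(idxs) < n_per_stratum:
                warnings.warn(
                    f"stratum {label!r} has {len(idxs)} < {n_per_stratum} items; "
                    "taking all",
                    stacklevel=2,
                )
            chosen = idxs
        else:
            chosen = rng.choice(idxs, size=n_per_stratum, replace=False)
        sample.extend(dataset[i] for i in sorted(chosen))
    return sample


def macro_metrics(y_true: Sequence, y_pred: Sequence) -> tuple[float, float, float]:
    """Macro-averaged (F1, precision, recall) over the union of observed classes.

    Classes absent from the predictions contribute zero precision/F1 rather
    than being dropped, so a degenerate all-one-class predictor is penalized.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if not y_true:
        raise ValueError("cannot compute metrics on empty input")
    labels = sorted(set(y_true) | set(y_pred), key=repr)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    return float(f1), float(precision), float(recall)


def wilcoxon_test(
    paired_scores_a: Sequence[float], paired_scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are discarded and tied absolute differences receive
    mid-ranks. For n <= 25 retained pairs the p-value comes from the exact
    (tie-aware) null distribution of the rank sum; above that, from a normal
    approximation with tie-corrected variance and continuity correction.
    Returns ``(statistic, p_value)`` where the statistic is the smaller of the
    positive- and negative-rank sums.
    """
    a = np.asarray(paired_scores_a, dtype=float)
    b = np.asarray(paired_scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired samples")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test is degenerate")

    ranks = rankdata(np.abs(d))  # mid-ranks for ties
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)

    if n <= 25:
        # exact null: each pair's sign is +/- with probability 1/2; enumerate the
        # distribution of the doubled rank sum by polynomial convolution
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: total + 1 - r]
            counts = counts + shifted
        w2 = int(np.rint(2 * w))
        cdf = counts[: w2 + 1].sum() / counts.sum()
        p = min(1.0, 2.0 * cdf)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w - mean + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * norm.cdf(z))
    return w, float(p)


def median_over_runs(run_records: Sequence[dict]) -> dict:
    """Per-metric medians over repeated runs (reporting convention for tables)."""
    if not run_records:
        raise ValueError("no runs to aggregate")
    keys = run_records[0].keys()
    return {k: float(np.median([rec[k] for rec in run_records])) for k in keys}
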