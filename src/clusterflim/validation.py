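"""In-silico validation: sensitivity/specificity of the cluster analysis.

Unsupervised cluster ids carry no class meaning, so predicted labels are
first matched one-to-one to ground-truth species by optimal assignment
(maximizing the confusion-matrix diagonal).  Performance is then scored
per class one-vs-rest:

    sensitivity = TP / (TP + FN)     (hit rate)
    specificity = TN / (TN + FP)     (correct rejection rate)

and macro-averaged over classes.  ``titration_curve`` repeats the scoring
over simulated images at several photon budgets (mean counts per pixel),
the key variable controlling how well decay signatures can be told apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import cluster_flim
from .synthetic import SceneLayout, block_layout, simulate_image

__all__ = [
    "ConfusionSummary",
    "match_labels",
    "confusion_rates",
    "score_clustering",
    "titration_curve",
]


@dataclass
class ConfusionSummary:
    """Per-class one-vs-rest confusion counts and rates."""

    classes: list
    mapping: dict  # predicted cluster id -> truth class id
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    macro_sensitivity: float
    macro_specificity: float

    @property
    def n_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


def match_labels(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Optimal one-to-one mapping from predicted cluster ids to truth ids.

    Maximizes the total diagonal count of the contingency table (Hungarian
    assignment).  Both label sets must contain the same number of distinct
    classes; entries < 0 are ignored (masked pixels).
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("label arrays must have equal length")
    keep = (pred >= 0) & (truth >= 0)
    pred, truth = pred[keep], truth[keep]
    pred_ids = np.unique(pred)
    truth_ids = np.unique(truth)
    if pred_ids.size != truth_ids.size:
        raise ValueError(
            f"number of clusters ({pred_ids.size}) differs from number of "
            f"classes ({truth_ids.size})"
        )
    table = np.zeros((pred_ids.size, truth_ids.size), dtype=np.int64)
    for i, p in enumerate(pred_ids):
        sel = pred == p
        for j, t in enumerate(truth_ids):
            table[i, j] = np.sum(truth[sel] == t)
    rows, cols = linear_sum_assignment(-table)
    return {int(pred_ids[r]): int(truth_ids[c]) for r, c in zip(rows, cols)}


def confusion_rates(
    pred: np.ndarray, truth: np.ndarray, mapping: dict
) -> ConfusionSummary:
    """One-vs-rest TP/FP/TN/FN and rates per class, macro-averaged."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    keep = (pred >= 0) & (truth >= 0)
    pred, truth = pred[keep], truth[keep]
    mapped = np.array([mapping[p] for p in pred])
    classes = sorted(set(mapping.values()))
    n = mapped.size
    tp = np.zeros(len(classes), dtype=np.int64)
    fp = np.zeros_like(tp)
    tn = np.zeros_like(tp)
    fn = np.zeros_like(tp)
    for j, cls in enumerate(classes):
        p = mapped == cls
        t = truth == cls
        tp[j] = np.sum(p & t)
        fp[j] = np.sum(p & ~t)
        fn[j] = np.sum(~p & t)
        tn[j] = n - tp[j] - fp[j] - fn[j]
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = tp / np.where(tp + fn > 0, tp + fn, 1)
        spec = tn / np.where(tn + fp > 0, tn + fp, 1)
    return ConfusionSummary(
        classes=classes,
        mapping=dict(mapping),
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens,
        specificity=spec,
        macro_sensitivity=float(sens.mean()),
        macro_specificity=float(spec.mean()),
    )


def score_clustering(pred: np.ndarray, truth: np.ndarray) -> ConfusionSummary:
    """Convenience: optimal matching followed by confusion scoring."""
    mapping = match_labels(pred, truth)
    return confusion_rates(pred, truth, mapping)


def titration_curve(
    species: list,
    counts_levels,
    replicates: int = 5,
    k: int | None = None,
    seed: int = 0,
    shape: tuple = (128, 128),
    min_counts: int = 10,
    b: int = 64,
    background_rate: float = 0.0,
) -> pd.DataFrame:
    """Sensitivity/specificity versus mean counts per pixel.

    For each photon-budget level, ``replicates`` images are simulated
    (balanced equal-area blocks, one per species), clustered with
    ``k = len(species)`` and scored against the known layout.  Returns a
    tidy DataFrame with mean and SD of the macro rates per level.
    """
    if k is None:
        k = len(species)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    rng = np.random.default_rng(seed)
    for level in counts_levels:
        if level <= 0:
            raise ValueError("counts levels must be positive")
        sens, spec = [], []
        for _ in range(replicates):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            layout = block_layout(
                len(species), shape=shape,
                mean_counts=float(level), background_rate=background_rate,
            )
            cube, truth = simulate_image(species, layout, seed=rep_seed)
            result = cluster_flim(
                cube, k=k, b=b, min_counts=min_counts, seed=rep_seed
            )
            truth_masked = np.where(result.labels >= 0, truth, -1)
            summary = score_clustering(result.labels, truth_masked)
            sens.append(summary.macro_sensitivity)
            spec.append(summary.macro_specificity)
        rows.append(
            {
                "mean_counts": float(level),
                "sensitivity_mean": float(np.mean(sens)),
                "sensitivity_sd": float(np.std(sens, ddof=1)) if replicates > 1 else 0.0,
                "specificity_mean": float(np.mean(spec)),
                "specificity_sd": float(np.std(spec, ddof=1)) if replicates > 1 else 0.0,
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)
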