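"""Expected Calibration Error of fold-averaged predictions, restricted to a
physical band around the reference contour, with reliability-diagram output.

A model is calibrated when its confidence matches its empirical
correctness: among voxels where the fold-averaged prediction is 90%
confident, the predicted label should be right 90% of the time.  ECE
summarizes the deviation as a bin-count-weighted mean absolute gap
between mean confidence and accuracy,

    ECE = sum_b (n_b / N) * |acc_b - conf_b|,

over equal-width confidence bins.  Evaluation is restricted to a band
(default 10 mm, both sides) around the reference surface so the score
reflects the ambiguous boundary region rather than the trivially
classified far background.

Two confidence modes are provided.  The default, ``"max_confidence"``,
scores the binarized decision: predicted label = (p_bar >= 0.5), with the
tie p_bar = 0.5 predicting foreground, confidence = max(p_bar, 1-p_bar)
in [0.5, 1] (so bins below 0.5 are structurally empty).  The secondary
mode ``"foreground_probability"`` scores the raw foreground probability
against the foreground indicator (frequency calibration).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import boundary_band
from .uncertainty import fold_mean
from .volumes import (
    EnsemblePrediction,
    GridMismatchError,
    LabelVolume,
    ProbabilityVolume,
)

__all__ = [
    "ReliabilityBins",
    "voxel_confidence_and_correctness",
    "expected_calibration_error",
    "ece_for_structure",
    "write_reliability_table",
    "plot_reliability_diagram",
]


@dataclass(frozen=True)
class ReliabilityBins:
    """Per-bin confidence/accuracy table behind an ECE value.

    Empty bins carry NaN mean confidence/accuracy; counts always sum to
    the number of evaluated voxels.
    """

    edges: np.ndarray  # n_bins + 1 edges partitioning [0, 1]
    counts: np.ndarray  # int, per bin
    mean_confidence: np.ndarray  # NaN where count == 0
    mean_accuracy: np.ndarray  # NaN where count == 0

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_evaluated(self) -> int:
        return int(self.counts.sum())


def voxel_confidence_and_correctness(
    fold_mean_p: ProbabilityVolume | np.ndarray,
    reference_mask: np.ndarray,
    mode: str = "max_confidence",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (confidence, correctness) fields for ECE.

    max_confidence mode: predicted label = (p >= 0.5) (tie-break up),
    confidence = max(p, 1-p), correctness = predicted label == reference.
    foreground_probability mode: confidence = p, correctness = reference.
    """
    p = fold_mean_p.p if isinstance(fold_mean_p, ProbabilityVolume) else np.asarray(
        fold_mean_p, dtype=float
    )
    ref = np.asarray(reference_mask).astype(bool)
    if p.shape != ref.shape:
        raise GridMismatchError(
            f"probability shape {p.shape} != reference shape {ref.shape}"
        )
    if mode == "max_confidence":
        predicted = p >= 0.5
        confidence = np.maximum(p, 1.0 - p)
        correctness = (predicted == ref).astype(float)
    elif mode == "foreground_probability":
        confidence = p.copy()
        correctness = ref.astype(float)
    else:
        raise ValueError(
            f"mode must be 'max_confidence' or 'foreground_probability', got {mode!r}"
        )
    return confidence, correctness


def _bin_indices(
    confidence: np.ndarray, n_bins: int, strategy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Bin index per value and the bin edges; bins are right-closed,
    the first bin additionally includes 0."""
    if strategy == "width":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        idx = np.ceil(confidence * n_bins).astype(int) - 1
        idx = np.clip(idx, 0, n_bins - 1)
    elif strategy == "mass":
        qs = np.linspace(0.0, 1.0, n_bins + 1)
        edges = np.quantile(confidence, qs)
        edges[0], edges[-1] = 0.0, 1.0
        idx = np.searchsorted(edges[1:-1], confidence, side="left")
    else:
        raise ValueError(f"strategy must be 'width' or 'mass', got {strategy!r}")
    return idx, edges


def expected_calibration_error(
    confidence: np.ndarray,
    correctness: np.ndarray,
    region: np.ndarray,
    n_bins: int = 10,
    strategy: str = "width",
) -> tuple[float, ReliabilityBins]:
    """ECE over the voxels of ``region`` plus the reliability-bin table.

    Equal-width bins on [0, 1] with right-closed upper edges by default;
    ``strategy="mass"`` uses equal-mass (quantile) bins instead.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    confidence = np.asarray(confidence, dtype=float)
    correctness = np.asarray(correctness, dtype=float)
    region = np.asarray(region).astype(bool)
    if confidence.shape != region.shape or correctness.shape != region.shape:
        raise GridMismatchError("confidence/correctness/region shapes differ")
    if not region.any():
        raise ValueError("ECE over an empty region is undefined")
    conf = confidence[region]
    corr = correctness[region]
    n = conf.size

    idx, edges = _bin_indices(conf, n_bins, strategy)
    counts = np.bincount(idx, minlength=n_bins)
    sum_conf = np.bincount(idx, weights=conf, minlength=n_bins)
    sum_corr = np.bincount(idx, weights=corr, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_conf = np.where(counts > 0, sum_conf / counts, np.nan)
        mean_acc = np.where(counts > 0, sum_corr / counts, np.nan)
    nonempty = counts > 0
    ece = float(
        np.sum(
            counts[nonempty] / n * np.abs(mean_acc[nonempty] - mean_conf[nonempty])
        )
    )
    bins = ReliabilityBins(
        edges=edges,
        counts=counts.astype(int),
        mean_confidence=mean_conf,
        mean_accuracy=mean_acc,
    )
    return ece, bins


def ece_for_structure(
    ensemble: EnsemblePrediction,
    reference: LabelVolume,
    structure: str,
    margin_mm: float = 10.0,
    n_bins: int = 10,
    mode: str = "max_confidence",
    band_sides: str = "both",
    strategy: str = "width",
) -> float:
    """Per-structure band-restricted ECE of the fold-averaged prediction.

    Pipeline: fold mean -> confidence/correctness vs the reference mask
    -> boundary band of the reference -> binned ECE.  Deterministic.
    """
    ensemble.grid.require_compatible(reference.grid)
    ref_mask = reference.mask(structure)  # KeyError if structure absent
    p_bar = fold_mean(ensemble)
    confidence, correctness = voxel_confidence_and_correctness(
        p_bar, ref_mask, mode=mode
    )
    band = boundary_band(ref_mask, reference.grid, margin_mm, sides=band_sides)
    ece, _ = expected_calibration_error(
        confidence, correctness, band, n_bins=n_bins, strategy=strategy
    )
    return ece


def write_reliability_table(bins: ReliabilityBins, path: str | Path) -> None:
    """Export the reliability bins as CSV (bin, edges, count, conf, acc)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["bin", "lower_edge", "upper_edge", "count", "mean_confidence", "mean_accuracy"]
        )
        for b in range(bins.n_bins):
            conf = bins.mean_confidence[b]
            acc = bins.mean_accuracy[b]
            writer.writerow(
                [
                    b,
                    format(bins.edges[b], ".12g"),
                    format(bins.edges[b + 1], ".12g"),
                    int(bins.counts[b]),
                    "NA" if math.isnan(conf) else format(conf, ".12g"),
                    "NA" if math.isnan(acc) else format(acc, ".12g"),
                ]
            )


def plot_reliability_diagram(bins: ReliabilityBins, path: str | Path) -> None:
    """Confidence-vs-accuracy bar diagram (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (bins.edges[:-1] + bins.edges[1:])
    widths = np.diff(bins.edges)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    ok = bins.counts > 0
    ax.bar(
        centers[ok],
        bins.mean_accuracy[ok],
        width=widths[ok] * 0.9,
        color="tab:blue",
        alpha=0.7,
        label="accuracy",
    )
    ax.plot(centers[ok], bins.mean_confidence[ok], "o-", color="tab:orange",
            ms=4, label="confidence")
    ax.set_xlabel("confidence")
    ax.set_ylabel("accuracy")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
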