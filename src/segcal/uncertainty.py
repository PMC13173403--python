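"""Ensemble uncertainty decomposition: voxel-wise mutual information and
fold-wise softmax variance, with region-restricted scalar aggregation.

For a K-member ensemble with one-vs-rest foreground probabilities
``p_1..p_K`` at a voxel, the epistemic (model-disagreement) uncertainty is
the mutual information between the predicted label and the member identity,

    MI = H(p_bar) - (1/K) * sum_k H(p_k),        p_bar = mean_k p_k,

with H the binary entropy.  In bits (the default base) MI lies in
[0, 1]; it is zero iff all members agree, and it ignores aleatoric
uncertainty (members all at p = 0.5 give MI = 0).  Ensemble variance is
the population variance of the member probabilities, bounded by 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import entr

from .volumes import (
    EnsemblePrediction,
    GridMismatchError,
    ProbabilityVolume,
    VolumeGrid,
    write_probability_volume,
)

__all__ = [
    "UncertaintyMaps",
    "binary_entropy",
    "fold_mean",
    "mutual_information",
    "ensemble_variance",
    "aggregate_in_region",
]

_LN2 = math.log(2.0)


def binary_entropy(p: np.ndarray, base: str = "bits") -> np.ndarray:
    """Binary entropy H(p) with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    h = entr(p) + entr(1.0 - p)  # natural log, elementwise, entr(0) = 0
    if base == "bits":
        h = h / _LN2
    elif base != "nats":
        raise ValueError(f"base must be 'bits' or 'nats', got {base!r}")
    return h


def fold_mean(ensemble: EnsemblePrediction) -> ProbabilityVolume:
    """Voxel-wise arithmetic mean of the member probabilities."""
    p_bar = ensemble.stack().mean(axis=0)
    # float round-off can push the mean infinitesimally outside [0, 1]
    return ProbabilityVolume(ensemble.grid, np.clip(p_bar, 0.0, 1.0))


def mutual_information(
    ensemble: EnsemblePrediction, base: str = "bits"
) -> np.ndarray:
    """Per-voxel epistemic mutual information, clamped at 0 from below.

    Jensen's inequality on the concave entropy guarantees MI >= 0 exactly;
    the clamp only absorbs float round-off.
    """
    stack = ensemble.stack()
    h_mean = binary_entropy(stack.mean(axis=0), base=base)
    mean_h = binary_entropy(stack, base=base).mean(axis=0)
    return np.maximum(h_mean - mean_h, 0.0)


def ensemble_variance(ensemble: EnsemblePrediction, ddof: int = 0) -> np.ndarray:
    """Per-voxel variance of member probabilities.

    The default divisor is K (population variance): the folds *are* the
    whole ensemble, not a sample from a larger one.  ``ddof=1`` gives the
    sample variance.
    """
    return ensemble.stack().var(axis=0, ddof=ddof)


def aggregate_in_region(field: np.ndarray, region: np.ndarray) -> float:
    """Arithmetic mean of a voxel field over a region; NaN if region empty."""
    field = np.asarray(field, dtype=float)
    region = np.asarray(region).astype(bool)
    if field.shape != region.shape:
        raise GridMismatchError(
            f"field shape {field.shape} != region shape {region.shape}"
        )
    if not region.any():
        return math.nan
    return float(field[region].mean())


@dataclass(frozen=True)
class UncertaintyMaps:
    """Voxel-wise MI and ensemble-variance maps for one structure."""

    grid: VolumeGrid
    mutual_information: np.ndarray
    ensemble_variance: np.ndarray

    @classmethod
    def from_ensemble(
        cls, ensemble: EnsemblePrediction, base: str = "bits", ddof: int = 0
    ) -> "UncertaintyMaps":
        return cls(
            grid=ensemble.grid,
            mutual_information=mutual_information(ensemble, base=base),
            ensemble_variance=ensemble_variance(ensemble, ddof=ddof),
        )

    def export_nifti(self, mi_path, var_path) -> None:
        """Write both maps as NIfTI volumes (for visual review)."""
        # variance <= 0.25 and MI <= 1 bit, so both fit a probability volume
        write_probability_volume(
            ProbabilityVolume(self.grid, np.clip(self.mutual_information, 0, 1)),
            mi_path,
        )
        write_probability_volume(
            ProbabilityVolume(self.grid, np.clip(self.ensemble_variance, 0, 1)),
            var_path,
        )
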