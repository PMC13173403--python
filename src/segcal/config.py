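"""Evaluation configuration: every convention the pipeline exposes as a dial."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["EvaluationConfig"]


@dataclass(frozen=True)
class EvaluationConfig:
    """Defaults used throughout the evaluation pipeline.

    nsd_tolerance_mm
        surface-agreement tolerance of the normalized surface Dice
        (1.0 mm gives the commonly reported "1NSD").
    band_margin_mm
        half-width of the boundary band restricting ECE and, by default,
        the uncertainty summaries (10 mm isotropic margin).
    binarize_threshold
        threshold on the fold-averaged probability producing the final
        predicted mask.
    band_sides
        "both" (band straddles the boundary) or "outside".
    n_bins / bin_strategy
        ECE binning: 10 equal-width bins by default; "mass" for
        equal-mass bins.
    entropy_base
        "bits" (mutual information in [0, 1]) or "nats".
    variance_ddof
        0 = population variance over the K folds (default), 1 = sample.
    uncertainty_region
        region over which voxel-wise MI/variance are averaged into the
        per-patient scalar: "band" (default, shared with ECE),
        "structure" (inside the reference mask), or "volume".
    ece_mode
        "max_confidence" (binarized decision confidence) or
        "foreground_probability" (frequency calibration).
    alpha
        significance level of the paired Wilcoxon comparison.
    zero_method
        "wilcox" drops zero differences (default); "pratt" keeps them in
        the ranking.
    holm
        apply a Holm step-down correction across comparisons (off by
        default; raw per-cell p-values are reported).
    """

    nsd_tolerance_mm: float = 1.0
    band_margin_mm: float = 10.0
    binarize_threshold: float = 0.5
    band_sides: str = "both"
    n_bins: int = 10
    bin_strategy: str = "width"
    entropy_base: str = "bits"
    variance_ddof: int = 0
    uncertainty_region: str = "band"
    ece_mode: str = "max_confidence"
    alpha: float = 0.05
    zero_method: str = "wilcox"
    holm: bool = False

    def __post_init__(self) -> None:
        if self.band_sides not in ("both", "outside"):
            raise ValueError(f"band_sides must be 'both' or 'outside': {self.band_sides!r}")
        if self.uncertainty_region not in ("band", "structure", "volume"):
            raise ValueError(
                f"uncertainty_region must be band/structure/volume: {self.uncertainty_region!r}"
            )
        if self.ece_mode not in ("max_confidence", "foreground_probability"):
            raise ValueError(f"unknown ece_mode: {self.ece_mode!r}")
        if self.zero_method not in ("wilcox", "pratt"):
            raise ValueError(f"zero_method must be 'wilcox' or 'pratt': {self.zero_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvaluationConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8"
        )
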