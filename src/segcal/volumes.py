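"""Core volume data model, grid contracts, and medical-image / table I/O.

Every quantity in this package is computed on a fixed voxel grid with a
physical spacing in millimetres.  Volumes that enter a cross-volume
operation (Dice, surface distances, uncertainty maps, ...) must live on
*compatible* grids — same shape, same spacing — and incompatible grids are
always rejected rather than silently resampled.  Orientation information
(direction cosines) in NIfTI headers is read but deliberately ignored:
all per-patient volumes are required to share one grid, so metrics are
evaluated in the native voxel frame with distances derived from spacing.

Conventions
-----------
* Voxel indices are 0-based; physical coordinates place the centre of
  voxel ``(0, 0, 0)`` at the origin, voxel ``(i, j, k)`` at
  ``(i*sx, j*sy, k*sz)`` mm.
* Label volumes use ``0`` for background and ``1..S`` for structures.
* Probability volumes hold one-vs-rest foreground probabilities in
  ``[0, 1]``; file values are clamped only within ``PROB_CLAMP_TOL`` of
  the valid range (float round-off in stored softmax outputs).
* Undefined metrics are recorded as NaN in memory and as the literal
  string ``"NA"`` in tables — never silently as 0 or 1.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "SPACING_TOL",
    "PROB_CLAMP_TOL",
    "METRIC_FIELDS",
    "GridMismatchError",
    "VolumeFormatError",
    "VolumeGrid",
    "LabelVolume",
    "ProbabilityVolume",
    "EnsemblePrediction",
    "StructureMetrics",
    "read_label_volume",
    "write_label_volume",
    "read_probability_volume",
    "write_probability_volume",
    "read_ensemble",
    "write_metrics_table",
    "read_metrics_table",
    "write_metrics_json",
]

#: Spacing comparison tolerance for grid compatibility, in mm.
SPACING_TOL = 1e-6

#: Allowed float round-off outside [0, 1] for stored probability volumes.
PROB_CLAMP_TOL = 1e-6

#: Metric columns of a StructureMetrics record, in serialization order.
METRIC_FIELDS = ("dsc", "nsd", "mi", "ens_var", "ece")


class GridMismatchError(ValueError):
    """Two volumes do not share a compatible grid (shape + spacing)."""


class VolumeFormatError(ValueError):
    """A file does not satisfy the volume contract (dimensionality, dtype...)."""


@dataclass(frozen=True)
class VolumeGrid:
    """Shared geometry every volume must agree on.

    Parameters
    ----------
    shape
        Number of voxels along each of the three axes (each >= 1).
    spacing
        Physical voxel size in mm along each axis (each > 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("VolumeGrid is three-dimensional")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(not (s > 0) for s in spacing):
            raise ValueError(f"all spacing entries must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def compatible_with(self, other: "VolumeGrid") -> bool:
        """Equal shape and spacing (spacing within ``SPACING_TOL`` mm)."""
        return self.shape == other.shape and all(
            abs(a - b) <= SPACING_TOL for a, b in zip(self.spacing, other.spacing)
        )

    def require_compatible(self, other: "VolumeGrid") -> None:
        if not self.compatible_with(other):
            raise GridMismatchError(
                f"incompatible grids: shape {self.shape} / spacing {self.spacing} "
                f"vs shape {other.shape} / spacing {other.spacing}"
            )

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open meshgrid of voxel-centre coordinates in mm, one array per axis."""
        axes = [
            np.arange(n, dtype=float) * s for n, s in zip(self.shape, self.spacing)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))


@dataclass(frozen=True)
class LabelVolume:
    """Integer label field over a grid: 0 = background, 1..S = structures."""

    grid: VolumeGrid
    labels: np.ndarray
    structure_names: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise VolumeFormatError(
                f"non-integer labels: dtype {labels.dtype} is not an integer type"
            )
        if labels.shape != self.grid.shape:
            raise GridMismatchError(
                f"label array shape {labels.shape} != grid shape {self.grid.shape}"
            )
        names = tuple(str(n) for n in self.structure_names)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate structure names: {names}")
        if labels.size:
            lo, hi = int(labels.min()), int(labels.max())
            if lo < 0 or hi > len(names):
                raise ValueError(
                    f"labels must lie in 0..{len(names)}, found range [{lo}, {hi}]"
                )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "structure_names", names)

    @property
    def n_structures(self) -> int:
        return len(self.structure_names)

    def structure_index(self, structure: str) -> int:
        """1-based label value of a structure; raises KeyError if absent."""
        try:
            return self.structure_names.index(structure) + 1
        except ValueError:
            raise KeyError(
                f"structure {structure!r} not in {self.structure_names}"
            ) from None

    def mask(self, structure: str) -> np.ndarray:
        """Boolean foreground mask of one structure."""
        return self.labels == self.structure_index(structure)


@dataclass(frozen=True)
class ProbabilityVolume:
    """One-vs-rest foreground probability field for a single structure."""

    grid: VolumeGrid
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != self.grid.shape:
            raise GridMismatchError(
                f"probability array shape {p.shape} != grid shape {self.grid.shape}"
            )
        pmin, pmax = float(p.min()), float(p.max())
        if pmin < 0.0 or pmax > 1.0:
            raise ValueError(
                f"probabilities outside [0, 1]: range [{pmin}, {pmax}]"
            )
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class EnsemblePrediction:
    """K per-fold probability volumes for one structure on one grid (K >= 2)."""

    members: tuple[ProbabilityVolume, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if len(members) < 2:
            raise ValueError("ensemble requires >= 2 members")
        for m in members[1:]:
            members[0].grid.require_compatible(m.grid)
        object.__setattr__(self, "members", members)

    @property
    def K(self) -> int:
        return len(self.members)

    @property
    def grid(self) -> VolumeGrid:
        return self.members[0].grid

    def stack(self) -> np.ndarray:
        """Member probabilities as a (K, *shape) array."""
        return np.stack([m.p for m in self.members], axis=0)


@dataclass(frozen=True)
class StructureMetrics:
    """All evaluated metrics for one patient x structure x model cell.

    NaN encodes an undefined metric ("NA" in tables), e.g. Dice with both
    masks empty, or uncertainty metrics for a structure with no prediction.
    """

    patient_id: str
    model: str
    structure: str
    dsc: float = math.nan
    nsd: float = math.nan
    mi: float = math.nan
    ens_var: float = math.nan
    ece: float = math.nan

    def metric(self, name: str) -> float:
        if name not in METRIC_FIELDS:
            raise KeyError(f"unknown metric {name!r}; known: {METRIC_FIELDS}")
        return getattr(self, name)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume, got {img.ndim}D: {path}")
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, VolumeGrid(img.shape, spacing)


def _affine_for(grid: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    return aff


def read_label_volume(
    path: str | Path, structure_names: Sequence[str] | None = None
) -> LabelVolume:
    """Read an integer label volume from NIfTI; spacing comes from the header.

    NIfTI carries no structure names; supply them via ``structure_names``
    or accept generated names ``structure_1..S`` (S = max label present).
    Files with non-integral voxel values are rejected.
    """
    data, grid = _load_nifti(path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(np.mod(data, 1) == 0):
            raise VolumeFormatError(f"non-integer labels in {path}")
    labels = data.astype(np.int32)
    if structure_names is None:
        n = int(labels.max()) if labels.size else 0
        structure_names = tuple(f"structure_{i}" for i in range(1, n + 1))
    return LabelVolume(grid, labels, tuple(structure_names))


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        volume.labels.astype(np.int16), _affine_for(volume.grid)
    )
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))


def read_probability_volume(path: str | Path) -> ProbabilityVolume:
    """Read a probability field; clamp only round-off within PROB_CLAMP_TOL."""
    data, grid = _load_nifti(path)
    p = np.asarray(data, dtype=float)
    pmin, pmax = float(p.min()), float(p.max())
    if pmin < -PROB_CLAMP_TOL or pmax > 1.0 + PROB_CLAMP_TOL:
        raise ValueError(
            f"probability values outside [-{PROB_CLAMP_TOL}, 1+{PROB_CLAMP_TOL}] "
            f"in {path}: range [{pmin}, {pmax}]"
        )
    return ProbabilityVolume(grid, np.clip(p, 0.0, 1.0))


def write_probability_volume(volume: ProbabilityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        volume.p.astype(np.float32), _affine_for(volume.grid)
    )
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))


def read_ensemble(
    paths: Sequence[str | Path], structure: str | None = None
) -> EnsemblePrediction:
    """Read K >= 2 per-fold probability volumes (one structure) in order.

    ``structure`` is accepted for manifest bookkeeping only; the files are
    single-scalar-per-voxel foreground probabilities already restricted to
    that structure.
    """
    if len(paths) < 2:
        raise ValueError("ensemble requires >= 2 members")
    members = [read_probability_volume(p) for p in paths]
    for m in members[1:]:
        members[0].grid.require_compatible(m.grid)
    return EnsemblePrediction(tuple(members))


# ---------------------------------------------------------------------------
# Metric tables

_TABLE_HEADER = ("patient_id", "model", "structure", "metric", "value")


def _format_value(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return format(float(v), ".12g")


def write_metrics_table(
    records: Iterable[StructureMetrics], path: str | Path
) -> None:
    """Write records as a deterministic long-format CSV.

    One row per patient x model x structure x metric; NaN values are
    written as the literal ``NA``.  Rows follow input order, metrics
    follow ``METRIC_FIELDS``; identical inputs yield identical bytes.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_TABLE_HEADER)
        for rec in records:
            for metric in METRIC_FIELDS:
                writer.writerow(
                    [
                        rec.patient_id,
                        rec.model,
                        rec.structure,
                        metric,
                        _format_value(rec.metric(metric)),
                    ]
                )


def read_metrics_table(path: str | Path) -> list[StructureMetrics]:
    """Inverse of :func:`write_metrics_table`."""
    path = Path(path)
    cells: dict[tuple[str, str, str], dict[str, float]] = {}
    order: list[tuple[str, str, str]] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and tuple(header) != _TABLE_HEADER:
            raise ValueError(f"unexpected metrics-table header: {header}")
        for row in reader:
            patient_id, model, structure, metric, value = row
            key = (patient_id, model, structure)
            if key not in cells:
                cells[key] = {}
                order.append(key)
            cells[key][metric] = math.nan if value == "NA" else float(value)
    return [
        StructureMetrics(patient_id=k[0], model=k[1], structure=k[2], **cells[k])
        for k in order
    ]


def write_metrics_json(
    records: Iterable[StructureMetrics], path: str | Path
) -> None:
    """JSON equivalent of the CSV table (NaN serialized as null)."""
    payload = [
        {
            "patient_id": r.patient_id,
            "model": r.model,
            "structure": r.structure,
            **{
                m: (None if math.isnan(r.metric(m)) else r.metric(m))
                for m in METRIC_FIELDS
            },
        }
        for r in records
    ]
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )
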