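"""Synthetic phantoms and model ensembles with known accuracy, epistemic
disagreement, and calibration.

The generator stands in for a cohort of contoured patient MRI scans.  A
*phantom* is a multi-structure reference segmentation built from
non-overlapping ellipsoids spanning the size spectrum of cranial organs
at risk: one 4-cm-scale structure ("brainstem-like", ~10^4 voxels), one
paired 3-cm structure ("hippocampi-like"), and three sub-centimetre
structures ("chiasm/nerve/pituitary-like", ~10^2-10^3 voxels).  The
pipeline consumes probabilities, not images, so no MRI intensities are
simulated.

From a reference mask, a *latent* probability field is derived as

    p(v) = logistic(d(v) / boundary_sigma),

with d(v) the signed Euclidean distance in mm from the voxel centre to
the reference boundary (positive inside, zero on boundary voxels).  The
latent plays two roles:

* **calibrated-by-construction regime** — the reference itself is
  re-sampled voxel-wise as Bernoulli(p).  Confidence then equals
  correctness probability exactly, so the downstream band ECE has a
  known target of 0.
* **fixed-reference regime** — the phantom mask is the reference and the
  latent is the ensemble's noise-free backbone, for geometric-accuracy
  and model-comparison experiments.

A K-member ensemble perturbs the latent in logit space:

    logit_k(v) = logit(p(v)) / T  +  shared_amp * eta_0(v)
                 + epistemic_amp * eta~_k(v)

where T is the calibration temperature (T = 1 calibrated, T < 1
overconfident, T > 1 underconfident), eta_0 is a smooth unit-variance
random field shared by all members (it displaces the fold-mean boundary
and therefore sets geometric accuracy), and eta~_k are per-member smooth
fields, by default centred across the ensemble so that they control the
member *spread* (the epistemic dial read out by mutual information and
ensemble variance) without systematically displacing the fold mean.
Setting ``center_members=False`` leaves the member fields i.i.d., in
which case epistemic noise also degrades the fold-mean geometry.

All randomness flows from explicit integer seeds through per-purpose
spawn keys, so adding members or structures never shifts earlier
streams, and identical specs yield identical volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .geometry import extract_surface
from .volumes import (
    EnsemblePrediction,
    LabelVolume,
    ProbabilityVolume,
    VolumeGrid,
)

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "EnsembleSpec",
    "SyntheticPatient",
    "make_phantom",
    "latent_probability",
    "sample_calibrated_reference",
    "make_ensemble",
    "smooth_unit_field",
    "default_grid",
    "default_structures",
    "jittered_structures",
    "calibration_grid",
    "calibration_structure",
    "derive_seed",
    "make_patient_reference",
    "build_model_ensembles",
    "generate_two_model_cohort",
    "generate_calibrated_patient",
]

_LOGIT_EPS = 1e-12


@dataclass(frozen=True)
class Ellipsoid:
    """One ellipsoidal structure component: name, centre and semi-axes in mm.

    Several components may share a name (e.g. a left/right pair); they
    rasterize to the same label.
    """

    name: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Reference-phantom description: grid, ellipsoid structures, seed."""

    grid: VolumeGrid
    structures: tuple[Ellipsoid, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        max_spacing = max(self.grid.spacing)
        for e in self.structures:
            if min(e.semi_axes_mm) <= max_spacing:
                raise ValueError(
                    f"structure {e.name!r}: semi-axes {e.semi_axes_mm} mm must all "
                    f"exceed the coarsest voxel spacing ({max_spacing} mm)"
                )

    @property
    def structure_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for e in self.structures:
            if e.name not in names:
                names.append(e.name)
        return tuple(names)


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble-generation dials.

    K
        member count (>= 2); five matches a five-fold cross-validation
        ensemble.
    boundary_sigma
        mm scale of the logistic probability transition at the reference
        boundary.
    temperature
        logit-scaling calibration distortion T (> 0); 1 = calibrated.
    epistemic_amp
        amplitude (logit units) of smooth per-member perturbation fields;
        0 = all members identical.
    perturb_corr_len
        spatial correlation length of the perturbation fields, mm.
    shared_amp
        amplitude of a perturbation field common to all members; sets the
        fold-mean geometric error independently of the epistemic spread.
    center_members
        centre the per-member fields across the ensemble (default) so the
        epistemic dial does not displace the fold mean.
    seed
        integer seed; everything downstream is deterministic in it.
    """

    K: int = 5
    boundary_sigma: float = 2.0
    temperature: float = 1.0
    epistemic_amp: float = 0.0
    perturb_corr_len: float = 6.0
    shared_amp: float = 0.0
    center_members: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if not self.boundary_sigma > 0:
            raise ValueError(f"boundary_sigma must be > 0, got {self.boundary_sigma}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.epistemic_amp < 0:
            raise ValueError(f"epistemic_amp must be >= 0, got {self.epistemic_amp}")
        if self.shared_amp < 0:
            raise ValueError(f"shared_amp must be >= 0, got {self.shared_amp}")
        if not self.perturb_corr_len > 0:
            raise ValueError(
                f"perturb_corr_len must be > 0, got {self.perturb_corr_len}"
            )


@dataclass(frozen=True)
class SyntheticPatient:
    """One synthetic patient: reference plus per-model per-structure ensembles."""

    patient_id: str
    reference: LabelVolume
    ensembles: Mapping[str, Mapping[str, EnsemblePrediction]]  # model -> structure -> K members


def derive_seed(root: int, *key: int) -> int:
    """Counter-based per-purpose seed derivation (stable, < 2**31)."""
    ss = np.random.SeedSequence(root, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _rng(root: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(root, spawn_key=tuple(int(k) for k in key))
    )


# ---------------------------------------------------------------------------
# Phantom construction


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the ellipsoid structures into a label volume.

    A voxel is assigned to structure s iff its centre lies inside one of
    s's ellipsoids; rasterized structures of different names must not
    overlap.  Deterministic given the spec.
    """
    names = spec.structure_names
    labels = np.zeros(spec.grid.shape, dtype=np.int32)
    xs, ys, zs = spec.grid.voxel_centers_mm()
    for e in spec.structures:
        label = names.index(e.name) + 1
        cx, cy, cz = e.center_mm
        ax, ay, az = e.semi_axes_mm
        inside = (
            ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2
        ) <= 1.0
        clash = inside & (labels != 0) & (labels != label)
        if clash.any():
            other = names[int(labels[clash][0]) - 1]
            raise ValueError(
                f"overlapping rasterized structures: {e.name!r} and {other!r}"
            )
        labels[inside] = label
    return LabelVolume(spec.grid, labels, names)


def _signed_distance_mm(mask: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask boundary voxels:
    positive inside the mask, zero on boundary voxels, negative outside."""
    surface = extract_surface(mask, grid)
    if surface.is_empty:
        raise ValueError("structure rasterizes to an empty mask")
    d = ndimage.distance_transform_edt(~surface.mask, sampling=grid.spacing)
    return np.where(mask, d, -d)


def latent_probability(
    reference: LabelVolume, structure: str, boundary_sigma: float
) -> ProbabilityVolume:
    """Logistic-of-signed-distance latent field: p = 0.5 on the boundary,
    -> 1 deep inside, -> 0 far outside, transition scale ``boundary_sigma`` mm."""
    if not boundary_sigma > 0:
        raise ValueError(f"boundary_sigma must be > 0, got {boundary_sigma}")
    mask = reference.mask(structure)  # KeyError if absent
    d = _signed_distance_mm(mask, reference.grid)
    return ProbabilityVolume(reference.grid, expit(d / boundary_sigma))


def sample_calibrated_reference(
    latent: ProbabilityVolume, seed: int, name: str = "structure"
) -> LabelVolume:
    """Draw each voxel label independently as Bernoulli(latent.p).

    By construction the latent is then perfectly calibrated against this
    reference, so downstream ECE tends to 0 as the voxel count grows.
    """
    rng = _rng(seed, 1)
    draws = rng.random(latent.grid.shape) < latent.p
    return LabelVolume(latent.grid, draws.astype(np.int32), (name,))


# ---------------------------------------------------------------------------
# Ensembles


def smooth_unit_field(
    grid: VolumeGrid, corr_len_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary smooth random field, empirically zero-mean, unit-variance.

    White Gaussian noise convolved with a Gaussian kernel whose standard
    deviation equals the correlation length, then renormalized — the
    simplest stationary field with a controllable length scale.
    """
    noise = rng.standard_normal(grid.shape)
    sigma_vox = [corr_len_mm / s for s in grid.spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    f -= f.mean()
    std = f.std()
    if std > 0:
        f /= std
    return f


def _logit(p: np.ndarray) -> np.ndarray:
    q = np.clip(p, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    return np.log(q) - np.log1p(-q)


def make_ensemble(
    latent: ProbabilityVolume, spec: EnsembleSpec
) -> EnsemblePrediction:
    """Perturb the latent in logit space into K member probability volumes.

    With temperature 1 and zero amplitudes the members are exact copies
    of the latent.  Deterministic given the spec's seed; member k's noise
    stream depends only on (seed, k), so changing K does not reshuffle
    the surviving members' fields.
    """
    grid = latent.grid
    if (
        spec.temperature == 1.0
        and spec.epistemic_amp == 0.0
        and spec.shared_amp == 0.0
    ):
        member = ProbabilityVolume(grid, latent.p.copy())
        return EnsemblePrediction(tuple(member for _ in range(spec.K)))

    base = _logit(latent.p) / spec.temperature
    if spec.shared_amp > 0.0:
        eta0 = smooth_unit_field(grid, spec.perturb_corr_len, _rng(spec.seed, 0))
        base = base + spec.shared_amp * eta0
    if spec.epistemic_amp > 0.0:
        etas = np.stack(
            [
                smooth_unit_field(grid, spec.perturb_corr_len, _rng(spec.seed, 1, k))
                for k in range(spec.K)
            ]
        )
        if spec.center_members:
            etas -= etas.mean(axis=0, keepdims=True)
        logits = base[None] + spec.epistemic_amp * etas
    else:
        logits = np.broadcast_to(base, (spec.K,) + grid.shape)
    members = tuple(
        ProbabilityVolume(grid, expit(logits[k])) for k in range(spec.K)
    )
    return EnsemblePrediction(members)


# ---------------------------------------------------------------------------
# Default phantom library and cohort generators


def default_grid() -> VolumeGrid:
    """64^3 grid at 1.25 mm isotropic spacing (80 mm field of view)."""
    return VolumeGrid((64, 64, 64), (1.25, 1.25, 1.25))


def default_structures() -> tuple[Ellipsoid, ...]:
    """Five-structure library spanning the organ-at-risk size spectrum.

    One 4-cm-scale structure, one paired 3-cm structure (two ellipsoids,
    one label), and three sub-centimetre low-volume structures.
    """
    return (
        Ellipsoid("brainstem_like", (24.0, 24.0, 40.0), (10.0, 12.0, 20.0)),
        Ellipsoid("hippocampi_like", (56.0, 20.0, 40.0), (5.0, 7.0, 15.0)),
        Ellipsoid("hippocampi_like", (56.0, 44.0, 40.0), (5.0, 7.0, 15.0)),
        Ellipsoid("chiasm_like", (24.0, 60.0, 20.0), (7.0, 4.0, 3.0)),
        Ellipsoid("nerve_like", (56.0, 64.0, 40.0), (3.0, 3.0, 12.0)),
        Ellipsoid("pituitary_like", (24.0, 60.0, 48.0), (4.0, 4.0, 3.0)),
    )


def jittered_structures(
    rng: np.random.Generator,
    base: Sequence[Ellipsoid] | None = None,
    center_jitter_mm: float = 2.0,
    scale_range: tuple[float, float] = (0.92, 1.08),
) -> tuple[Ellipsoid, ...]:
    """Per-patient anatomical variation: jitter centres, rescale semi-axes."""
    base = tuple(base) if base is not None else default_structures()
    out = []
    for e in base:
        shift = rng.uniform(-center_jitter_mm, center_jitter_mm, size=3)
        scale = rng.uniform(*scale_range)
        out.append(
            Ellipsoid(
                e.name,
                tuple(c + s for c, s in zip(e.center_mm, shift)),
                tuple(a * scale for a in e.semi_axes_mm),
            )
        )
    return tuple(out)


def calibration_grid() -> VolumeGrid:
    """48 x 48 x 64 grid at 1.5 mm, sized for one brainstem-like structure."""
    return VolumeGrid((48, 48, 64), (1.5, 1.5, 1.5))


def calibration_structure() -> Ellipsoid:
    return Ellipsoid("brainstem_like", (36.0, 36.0, 48.0), (10.0, 12.0, 20.0))


def make_patient_reference(seed: int, patient_index: int = 0) -> LabelVolume:
    """Jittered default phantom for one synthetic patient."""
    rng = _rng(seed, 10, patient_index)
    spec = PhantomSpec(default_grid(), jittered_structures(rng), seed=seed)
    return make_phantom(spec)


def build_model_ensembles(
    reference: LabelVolume,
    spec: EnsembleSpec,
    model_seed: int,
) -> dict[str, EnsemblePrediction]:
    """Per-structure ensembles for one model on one patient.

    Each structure gets its own noise stream derived from ``model_seed``
    and the structure index; the ensemble spec's own seed is overridden.
    """
    out: dict[str, EnsemblePrediction] = {}
    for idx, structure in enumerate(reference.structure_names):
        latent = latent_probability(reference, structure, spec.boundary_sigma)
        s_spec = replace(spec, seed=derive_seed(model_seed, 20, idx))
        out[structure] = make_ensemble(latent, s_spec)
    return out


def generate_two_model_cohort(
    n_patients: int,
    spec_a: EnsembleSpec,
    spec_b: EnsembleSpec,
    seed: int,
    model_names: tuple[str, str] = ("model_a", "model_b"),
) -> list[SyntheticPatient]:
    """Fixed-reference cohort: each patient has one jittered phantom and
    independent ensembles from both model specs on it."""
    patients = []
    for i in range(n_patients):
        reference = make_patient_reference(seed, i)
        ensembles = {
            model_names[0]: build_model_ensembles(
                reference, spec_a, derive_seed(seed, 30, i, 0)
            ),
            model_names[1]: build_model_ensembles(
                reference, spec_b, derive_seed(seed, 30, i, 1)
            ),
        }
        patients.append(
            SyntheticPatient(f"synth_{i:03d}", reference, ensembles)
        )
    return patients


def generate_calibrated_patient(
    temperature: float,
    seed: int,
    patient_index: int = 0,
    epistemic_amp: float = 0.0,
    boundary_sigma: float = 2.0,
    K: int = 5,
) -> tuple[LabelVolume, EnsemblePrediction]:
    """Calibrated-by-construction patient (single brainstem-like structure).

    The reference is Bernoulli-sampled from the latent; the ensemble is
    built from the same latent at the requested temperature, so T = 1
    with zero amplitudes is perfectly calibrated by construction and
    T != 1 is miscalibrated by a known, monotone amount.
    """
    rng = _rng(seed, 40, patient_index)
    base = calibration_structure()
    (jittered,) = jittered_structures(rng, base=(base,))
    grid = calibration_grid()
    phantom = make_phantom(PhantomSpec(grid, (jittered,), seed=seed))
    latent = latent_probability(phantom, base.name, boundary_sigma)
    reference = sample_calibrated_reference(
        latent, derive_seed(seed, 41, patient_index), name=base.name
    )
    spec = EnsembleSpec(
        K=K,
        boundary_sigma=boundary_sigma,
        temperature=temperature,
        epistemic_amp=epistemic_amp,
        seed=derive_seed(seed, 42, patient_index),
    )
    ensemble = make_ensemble(latent, spec)
    return reference, ensemble
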