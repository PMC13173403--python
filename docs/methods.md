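# Methods

This note documents the models, conventions and numerical choices
behind `segcal`, in the spirit of a statistics package's methods
appendix: what is computed, under which assumptions, and where the
design was genuinely open.

## Data model and geometry

All computations run on a fixed 3-D voxel grid with physical spacing in
mm. Grids are *compatible* when shape and spacing agree (spacing within
1e-6 mm); every cross-volume operation rejects incompatible grids —
there is no silent resampling, because resampling probabilities or
labels would change every downstream metric in unquantified ways.
Orientation (direction cosines) is read from NIfTI headers but not used:
all volumes of a patient are required to share one grid, so metrics are
computed in the native voxel frame with distances derived from spacing.
Voxel `(i, j, k)` has its centre at `(i·sx, j·sy, k·sz)` mm. NIfTI
carries no structure names, so a label round trip preserves labels and
spacing but not names; readers accept an explicit name list.

Probabilities read from files are clamped into `[0, 1]` only within a
1e-6 tolerance (float round-off of stored softmax outputs); larger
violations are errors. Undefined metrics (e.g. Dice of two empty
masks) are NaN in memory and the literal `NA` in tables, never a
silent 0 or 1, so cohort medians are not biased by degenerate cases.

## Surfaces, distances, band

A *boundary voxel* is a mask voxel with at least one of its six face
neighbours background or outside the volume (the volume border counts
as background). Distances are exact Euclidean distances between voxel
centres, anisotropic spacing respected (`scipy.ndimage.
distance_transform_edt` with per-axis sampling). This voxel-centre
surface model was chosen over a surfel-area model because it is exactly
testable against a brute-force nearest-neighbour oracle; it is isolated
behind `extract_surface`, so a surfel variant could be swapped in
without touching NSD or the band. NSD conventions: both masks empty →
NA; exactly one empty → 0 (total surface disagreement); NSD is
symmetric and non-decreasing in the tolerance.

The *boundary band* is the set of voxels within a margin (default
10 mm) of the reference surface, on both sides by default (an
outside-only variant exists). It restricts ECE — and, by default, the
uncertainty summaries — to the clinically relevant transition zone
rather than the trivially classified far background.

## Uncertainty decomposition

For K fold probabilities `p_1..p_K` per voxel (one-vs-rest per
structure), epistemic uncertainty is the mutual information between the
predicted label and the fold identity,
`MI = H(p̄) − (1/K) Σ_k H(p_k)` with `p̄` the fold mean and H the
binary entropy. Entropy is in bits by default (MI ∈ [0, 1] for the
binary case; nats available). MI is non-negative by Jensen's
inequality; a max(·, 0) clamp absorbs float round-off only. Ensemble
variance uses divisor K (population variance): the folds are the whole
ensemble, not a sample of a larger one (divisor K−1 available).

Voxel maps are reduced to one scalar per patient × structure as the
arithmetic mean over a region. The default region is the 10-mm
boundary band, so all uncertainty columns and ECE share one region;
whole-volume and inside-structure reductions are config options.
Whole-volume means are smaller by orders of magnitude (the volume is
dominated by far background where all members agree), which matters
when comparing absolute magnitudes across studies; the band default
was chosen because band means respond to boundary disagreement with
the least dilution. Within-cohort *comparisons* are insensitive to
this choice since the region is fixed across models.

## Calibration

Confidence/correctness follow the standard binary-decision framing:
predicted label `p̄ ≥ 0.5` (the tie predicts foreground,
deterministically), confidence `max(p̄, 1−p̄) ∈ [0.5, 1]`, correctness
the agreement with the reference label. ECE uses 10 equal-width bins
on [0, 1], right-closed upper edges, first bin including 0 — ten bins
being the dominant convention; equal-mass binning is available. Bins
below 0.5 are structurally empty in this mode. A secondary mode scores
the raw foreground probability against foreground frequency instead;
neither mode is claimed to be the only defensible one, the default is
simply documented. Per-structure ECE composes fold mean →
confidence/correctness → boundary band → binned ECE.

## Synthetic cohorts

The generator emulates the *outputs* of a segmentation ensemble, not
images: no MRI contrast, bias fields or scanner noise are simulated,
and no network is emulated. Phantoms are non-overlapping ellipsoids
rasterized by voxel-centre membership. The default library spans the
organ size spectrum on a 64³ grid at 1.25 mm: one 4-cm structure
(~5×10³ voxels, brainstem-like), one paired 3-cm structure
(hippocampi-like, two components, one label), and three sub-centimetre
structures (~10²–10³ voxels; chiasm-, nerve- and pituitary-like).
Per-patient anatomy jitters ellipsoid centres by ±2 mm and scales axes
by ±8%.

From a reference mask, the latent field is
`p(v) = logistic(d(v)/σ_b)` with `d` the signed distance to the
boundary (positive inside) and `σ_b` = 2 mm by default — a realistic
softmax transition width at organ boundaries. Ensembles perturb the
latent in logit space:

```
logit_k(v) = logit(p(v)) / T + shared_amp·η₀(v) + epistemic_amp·η̃_k(v)
```

* `T` — calibration temperature; 1 calibrated, < 1 overconfident,
  > 1 underconfident.
* `η₀` — smooth unit-variance field shared by all members; it displaces
  the fold-mean boundary and therefore sets geometric accuracy.
* `η̃_k` — per-member smooth fields, **centred across the ensemble by
  default**, controlling fold disagreement.

Random fields are white noise convolved with a Gaussian kernel of the
stated correlation length (6 mm default), renormalized to empirical
zero mean and unit variance — the simplest stationary field with a
controllable length scale. All randomness flows from a root seed
through per-purpose spawn keys (phantom / reference sampling / member
k), so adding members or structures never shifts earlier streams.

The centring of `η̃_k` is a deliberate design choice. With i.i.d.
member fields, fold disagreement necessarily displaces the fold mean
by ~amp/√K, so any increase of the epistemic dial also degrades Dice —
and a paired test over a cohort would then flag a geometric difference
between any two models that differ only in ensemble stability. Real
architecture comparisons show exactly the opposite dissociation:
ensembles can differ strongly in fold-to-fold disagreement while their
mean predictions are geometrically equivalent. Centring decouples the
two axes (spread without mean displacement, to first order), and
`shared_amp` reintroduces geometric error on its own dial. The
uncentred variant remains available (`center_members=False`).

Two regimes are exposed. *Fixed-reference*: the phantom mask is the
reference — used for geometric metrics and model comparison.
*Calibrated-by-construction*: the reference is re-sampled voxel-wise
as Bernoulli(latent), making confidence equal correctness probability
exactly, so band ECE has a known target of 0 at T = 1; these cohorts
use a single brainstem-like structure on a 48×48×64 grid at 1.5 mm,
giving bands of ~3×10⁴ voxels per patient.

What passing tests on these cohorts do **not** show: robustness to
registration errors, inter-observer reference variability, non-smooth
fold disagreement (e.g. fold-specific gross failures), multi-class
interactions between touching structures, or any property of real MRI
appearance. The generator validates the *measurement pipeline*, not
any segmentation model.

## Statistics

Two models are compared per structure × metric by pairing patients on
id, dropping incomplete (NA) pairs — so uneven per-metric cohort sizes
arise mechanically, not by hard-coding — and applying a two-sided
paired Wilcoxon signed-rank test: zero differences dropped (classic
zero method; Pratt available), mid-ranks for tied magnitudes,
statistic `W = min(W⁺, W⁻)`. For n ≤ 20 used pairs the p-value is
exact: the null distribution of W⁺ is built by rank-sum convolution
with mid-ranks doubled to integers, which equals full 2ⁿ sign
enumeration and handles ties exactly (the common all-tied
constant-shift case then yields the minimal attainable p, e.g. 0.0625
at n = 5). Beyond n = 20, a normal approximation with tie correction
and 0.5 continuity correction is used. Degenerate inputs (no nonzero
differences) give an NA p-value with a warning. Cohort cells are
summarized as median (even n: midpoint of the central pair) and
(min, max). Significance is p < 0.05 on raw p-values; no
multiple-testing correction is applied by default since per-cell raw
p-values are the reporting convention here (Holm step-down available).

## Problem sizes and determinism

Default experiment sizes — 15-patient two-model cohorts, 20-patient
calibration cohorts per temperature, 1000 null cohorts for type-I
error, 200 random instances per brute-force oracle — were chosen so
the whole suite runs in minutes on one CPU while keeping binomial /
rank-test resolution comfortably inside the asserted bounds (e.g. a
calibrated band of ~3×10⁴ voxels puts the sampling noise of ECE near
0.002, an order below the 0.02 acceptance threshold). Every stochastic
test fixes its seeds; identical inputs produce byte-identical output
tables and reports.

## Known limitations

* One-vs-rest per structure throughout; no multi-class ECE or
  inter-structure exclusivity constraints.
* Voxel-centre NSD; mesh/surfel NSD would differ slightly at coarse
  spacing (both satisfy the identity/symmetry/monotonicity contracts).
* No resampling or registration: inputs must share a grid.
* The epistemic dial is a free amplitude in logit units, not an
  estimate of any particular trained ensemble's disagreement.
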