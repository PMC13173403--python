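"""Epistemic uncertainty read-out: band-mean mutual information and
ensemble variance as the fold-to-fold disagreement amplitude grows.

Mutual information MI = H(mean prediction) - mean member entropy is zero
when all ensemble members agree (whatever their confidence) and rises
with disagreement; ensemble variance is the voxel-wise variance of the
member probabilities.  Both are averaged over the 10-mm band around the
reference boundary, where autosegmentation uncertainty actually lives.
"""

from segcal.geometry import boundary_band
from segcal.synthetic import EnsembleSpec, latent_probability, make_ensemble, make_patient_reference
from segcal.uncertainty import aggregate_in_region, ensemble_variance, mutual_information

reference = make_patient_reference(seed=7)
structure = "brainstem_like"
latent = latent_probability(reference, structure, boundary_sigma=2.0)
band = boundary_band(reference.mask(structure), reference.grid, margin_mm=10.0)

print(f"{structure}: band of {int(band.sum())} voxels")
print(f"{'epistemic_amp':>13s} {'band-mean MI (bits)':>20s} {'band-mean variance':>19s}")
for amp in (0.0, 0.5, 1.0, 2.0):
    ens = make_ensemble(latent, EnsembleSpec(epistemic_amp=amp, seed=13))
    mi = aggregate_in_region(mutual_information(ens), band)
    var = aggregate_in_region(ensemble_variance(ens), band)
    print(f"{amp:13.2f} {mi:20.3g} {var:19.3g}")
print(
    "\nBoth read-outs increase monotonically with the disagreement dial:\n"
    "an architecture with more stable folds shows lower values on both."
)
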