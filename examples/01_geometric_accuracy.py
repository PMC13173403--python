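"""Geometric accuracy of a noisy ensemble prediction on a synthetic phantom.

Builds a five-structure phantom, generates a five-member ensemble whose
fold-mean boundary is displaced by a smooth shared error field, binarizes
the fold mean at 0.5, and prints Dice and normalized surface Dice (2-mm
tolerance, matching the ~1.25-mm voxels) per structure.
"""

from segcal.cohort import evaluate_patient
from segcal.config import EvaluationConfig
from segcal.synthetic import EnsembleSpec, build_model_ensembles, make_patient_reference

reference = make_patient_reference(seed=42)
spec = EnsembleSpec(epistemic_amp=0.5, shared_amp=0.5)
ensembles = build_model_ensembles(reference, spec, model_seed=42)

config = EvaluationConfig(nsd_tolerance_mm=2.0)
records = evaluate_patient(
    reference, ensembles, config, patient_id="demo", model="demo_model"
)

print(f"{'structure':18s} {'DSC':>6s} {'NSD@2mm':>8s}")
for r in records:
    print(f"{r.structure:18s} {r.dsc:6.3f} {r.nsd:8.3f}")
print(
    "\nDSC is volumetric overlap (1 = perfect); NSD is the fraction of the\n"
    "two boundaries within 2 mm of each other. Large structures score high;\n"
    "small structures lose more Dice per millimetre of boundary error."
)
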