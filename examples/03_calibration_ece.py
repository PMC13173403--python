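"""Expected Calibration Error under controlled miscalibration.

Each synthetic patient has a reference drawn voxel-wise as
Bernoulli(latent probability), so a temperature-1 prediction is
calibrated by construction (band ECE near 0).  Sharpening the logits
(T < 1, overconfidence) or flattening them (T > 1, underconfidence)
produces a known, measurable calibration error within the 10-mm band.
"""

import numpy as np

from segcal.calibration import ece_for_structure
from segcal.synthetic import generate_calibrated_patient

n_patients = 10
print(f"{'temperature':>11s} {'median band ECE':>16s}   interpretation")
for T, label in ((0.25, "overconfident"), (1.0, "calibrated"), (4.0, "underconfident")):
    eces = []
    for i in range(n_patients):
        reference, ensemble = generate_calibrated_patient(T, seed=0, patient_index=i)
        eces.append(ece_for_structure(ensemble, reference, "brainstem_like"))
    print(f"{T:11.2f} {np.median(eces):16.4f}   {label}")
print(
    "\nECE is the bin-weighted gap between confidence and accuracy in the\n"
    "10-mm band around the reference contour: ~0 only when confidence can\n"
    "be taken at face value."
)
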