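"""Detect fissure voxels with the plate-likeness filter and label them.

Shows the intermediate stages the pipeline chains together: Hessian
sheet response, thresholding/thinning, lung splitting and anatomical
labeling (ROF/RHF/LOF).
"""

import numpy as np

from fissint import (
    PhantomSpec,
    classify_patches,
    compute_plateness,
    extract_fissure_voxels,
    generate_phantom,
    split_lungs,
)
from fissint.surfaces import components

spec = PhantomSpec(target_integrity=(70.0, 50.0, 80.0), noise_sd=30.0, seed=7)
volume, truth = generate_phantom(spec)

plateness = compute_plateness(volume, lung_mask=truth.lung_mask)
print(f"plateness response: max={plateness.response.max():.2f} "
      f"(bounded in [0, 1], zero outside the lungs)")

detected = extract_fissure_voxels(
    plateness, threshold=0.6, volume=volume, lung_mask=truth.lung_mask
)
print(f"detected fissure voxels after thinning: {int(detected.sum())}")

left, right = split_lungs(truth.lung_mask)
for side, lung in (("left", left), ("right", right)):
    patches = classify_patches(
        components(detected & lung), side, lung, volume.spacing
    )
    for p in patches:
        nz = abs(p.mean_normal[2])
        print(f"{side} lung -> {p.label}: {p.n_voxels} voxels, "
              f"{p.area_mm2:.0f} mm^2, |normal.z|={nz:.2f}")

# The right oblique sheet's normal makes ~40 degrees with the
# cranio-caudal axis (|normal.z| ~ 0.77) while the horizontal fissure
# is near-axial (|normal.z| > 0.9) — that contrast drives the labeling.
truth_all = np.zeros_like(detected)
for lb in ("ROF", "RHF", "LOF"):
    truth_all |= truth.fissure_truth[lb]
dice = 2.0 * (detected & truth_all).sum() / (detected.sum() + truth_all.sum())
print(f"Dice overlap with ground truth: {dice:.3f}")
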