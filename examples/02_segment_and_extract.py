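"""Segment the jam with the spectral angle mapper and extract grid features.

Renders a noisy scene, picks the reference spectrum from the central patch,
thresholds the per-pixel spectral angle at 0.2 rad, crops to the bounding
box with a 10% margin, subdivides into a 3x3 grid, and prints the unit-norm
mean-spectrum records the downstream models consume.
"""

import numpy as np

from jamspec import (
    AcquisitionDesign,
    apply_margin,
    calibrate_capture,
    default_spectral_model,
    enumerate_design,
    extract_features,
    pick_reference,
    render_scene,
    roi_from_mask,
    sam_mask,
)

design = AcquisitionDesign(
    cultivars=("idared",),
    sugar_levels=(40.0,),
    views_per_thickness={1.0: 1},
    spatial_size=(96, 96),
)
model = default_spectral_model(design.wavelengths, design.cultivars, noise_sd=0.01)
meta = enumerate_design(design)[0]
cube = calibrate_capture(render_scene(meta, model, design, rng_seed=4))

reference = pick_reference(cube)
mask = sam_mask(cube, reference, threshold_rad=0.2)
agreement = (mask.mask == render_scene(meta, model, design, 4).jam_truth).mean()
roi = roi_from_mask(mask)
inner = apply_margin(roi, 0.10)

print(f"jam pixels found:  {mask.mask.sum()} "
      f"({100 * mask.mask.mean():.1f}% of frame; "
      f"{100 * agreement:.1f}% agreement with ground truth)")
print(f"bounding box:      {roi.height}x{roi.width} px, "
      f"after 10% margin {inner.height}x{inner.width} px")

features = extract_features(cube, grid_size=3)
print(f"3x3 grid features: {len(features)} records")
for f in features[:3]:
    print(f"  cell {f.cell}: {f.n_pixels} px, "
          f"|feature| = {np.linalg.norm(f.feature):.6f}, "
          f"first bands {np.round(f.feature[:3], 4)}")
print("-> each record is one row of the regression table: a unit-norm mean")
print("   spectrum plus sugar/cultivar/image metadata.")
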