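"""Compare the two leakage-aware data splits on the full campaign layout.

Builds the 1760-record table of the full design (clean spectra stand in for
rendered scenes — the split logic only reads metadata) and shows the
cultivar-based split (whole varieties held out) versus the
concentration-based split (per-cultivar sugar levels held out).
"""

import numpy as np

from jamspec import (
    AcquisitionDesign,
    build_table,
    default_spectral_model,
    enumerate_design,
    simulate_spectrum,
    split_by_concentration,
    split_by_cultivar,
)
from jamspec.segment import GridCellFeature

design = AcquisitionDesign()
model = default_spectral_model(design.wavelengths, design.cultivars, noise_sd=0.0)
entries = []
for meta in enumerate_design(design):
    spec = simulate_spectrum(model, meta.cultivar, meta.sugar_pct, 0)
    entries.append(
        (meta, [GridCellFeature(1, (0, 0), spec / np.linalg.norm(spec), 100)])
    )
table = build_table(entries)
print(f"table: {len(table)} records, {design.n_samples} jam samples")

cult = split_by_cultivar(table, val_cultivar="gala", test_cultivar="aport")
counts = cult.counts()
print("\ncultivar split (6 train / 1 val / 1 test varieties):")
print(f"  records: {counts} "
      f"({100 * counts['test'] / len(table):.1f}% test)")
print(f"  train cultivars: {cult.manifest['train_cultivars']}")

conc = split_by_concentration(table)
print("\nconcentration split (held-out sugar levels per cultivar):")
print(f"  cell fractions: {conc.manifest['cell_fractions_pct']} "
      "(of 88 cultivar x concentration cells)")
print(f"  records: {conc.counts()}")
print("-> both splits assign whole images to one fold; the image_index sets")
print("   of train/val/test are disjoint by construction, so no subregion of")
print("   an evaluation image is ever seen in training.")
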