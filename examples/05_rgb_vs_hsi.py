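"""Why hyperspectral beats RGB for sugar prediction.

The simulated sugar effect perturbs reflectance only above 700 nm. RGB
features (boxcar means of the blue/green/red 400-700 nm windows) discard
that region, so a model trained on them has nothing to learn from, while
the same model on the full 204-band features succeeds.
"""

from jamspec import (
    AcquisitionDesign,
    build_feature_tables,
    regression_metrics,
    rgb_table_from_hsi,
    rotating_holdout_map,
    split_by_concentration,
    train_svm,
)

design = AcquisitionDesign(
    cultivars=("gala", "aport", "idared", "golden"),
    views_per_thickness={1.0: 2},
    spatial_size=(48, 48),
)
tables = build_feature_tables(design, grids=(2,), seed=9, noise_sd=0.01)
table = tables[2]
rgb = rgb_table_from_hsi(table, design.wavelengths)

holdout = rotating_holdout_map(
    list(design.cultivars), [float(v) for v in design.sugar_levels],
    n_test_cells=4, n_val_cells=4,
)
folds = split_by_concentration(table, held_out_map=holdout)
sel = folds.folds == "val"
y = table.loc[sel, "sugar_pct"].to_numpy(float)

for name, feats in (("HSI (204 bands)", table), ("RGB (3 channels)", rgb)):
    fitted = train_svm(feats, folds)
    r2, rmse, _ = regression_metrics(y, fitted.predict(feats.loc[sel]))
    print(f"{name:>16}: val R^2 = {r2:6.3f}, RMSE = {rmse:5.2f}% sugar")
print("-> the near-zero RGB score reproduces the direction of the published")
print("   RGB-vs-HSI comparison: three broad visible channels cannot carry")
print("   a near-infrared composition signal.")
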