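# jamspec

Hyperspectral imaging chemometrics for processed fruit products: predict the
sugar concentration (soluble solids, % w/w) of apple jam from
visible/near-infrared (VNIR) hyperspectral cubes, with a fully synthetic
acquisition campaign so the entire pipeline runs — and is tested — without
any camera data.

The package is aimed at food-quality and chemometrics researchers who want a
reproducible, end-to-end reference implementation of the HSI → regression
workflow: radiometric calibration, spectral-angle-mapper segmentation,
grid-based spectral features, leakage-aware data splits, and three regression
models including a NumPy 1-D residual network trained with explicit
backpropagation.

## The pipeline

1. **Acquisition design.** A factorial campaign over 8 apple cultivars × 11
   sugar levels (25–75% w/w in 5% steps) × 3 jam-layer thicknesses
   (0.5/1/2 cm) imaged from 6/7/7 views = **1760 captures**, each a
   204-band cube spanning 400–1000 nm. The synthetic module renders each
   capture as an ellipse of jam pixels on a bright dish, with cultivar-
   specific reflectance templates (blue absorption dip at 400–500 nm,
   elevated NIR plateau at 700–900 nm), a strictly monotone sugar-dependent
   NIR perturbation, and Gaussian sensor noise; ENVI `.hdr`/`.dat` I/O is
   included.
2. **Radiometric calibration.** R = (I − D) / (W − D) per pixel and band,
   with an ε-guard and an explicit invalid-pixel mask where the white/dark
   contrast vanishes.
3. **Segmentation and features.** A pixel is jam when its spectral angle to
   a reference spectrum (median of a homogeneous central patch) satisfies
   θ = arccos(p·r / ‖p‖‖r‖) ≤ 0.2 rad. The mask's bounding box, shrunk by a
   10% per-side margin, is subdivided into g×g grids (g = 1…5); each cell
   yields one **unit-norm mean spectrum** record.
4. **Splits without leakage.** Either whole cultivars are held out
   (6 train / 1 val / 1 test) or, per cultivar, specific concentrations are
   held out (62/14/12 of the 88 cultivar×concentration cells ≈
   70.5% / 15.9% / 13.6%). All records of an image share one fold.
5. **Regression.** RBF-SVR (C = 110, ε = 0.1, γ = 0.01), XGBoost
   (η = 0.10, depth 5, colsample 0.95, ≤400 rounds, 40-round early stopping
   on validation RMSE), and a 1-D ResNet: custom-padded stem convolution,
   8 residual blocks with stride-2 downsampling every second block and
   filter doubling 32→512, global average pooling, one output unit; Adam
   (lr 10⁻³, weight decay 10⁻⁴), MAE loss on MinMax-scaled targets,
   ≤30 epochs with patience-5 early stopping. Features are MinMax-scaled on
   the training fold only.
6. **Evaluation.** R² = 1 − SS_res/SS_tot, RMSE and MAE in % sugar, per-
   sugar-level MAE profiles, multi-run sweeps over models × grids × splits
   × batch sizes, and a paired RGB-vs-HSI comparison (RGB = boxcar means of
   the 400–500/500–600/600–700 nm windows).

## Worked example

`examples/` contains one short script per capability. For instance:

```sh
$ python examples/03_split_strategies.py
table: 1760 records, 88 jam samples

cultivar split (6 train / 1 val / 1 test varieties):
  records: {'train': 1320, 'test': 220, 'val': 220} (12.5% test)
  train cultivars: ['golden', 'granny', 'idared', 'prince', 'simirenko', 'starcrimson']

concentration split (held-out sugar levels per cultivar):
  cell fractions: {'train': 70.5, 'val': 13.6, 'test': 15.9} (of 88 cultivar x concentration cells)
  records: {'train': 1240, 'test': 280, 'val': 240}
```

The 12.5% test share is one cultivar of eight; the 70.5/15.9/13.6 fractions
are the held-out cultivar×concentration cells of the default rotating
hold-out map. `examples/05_rgb_vs_hsi.py` shows the central scientific
contrast: an SVM on 204-band features recovers held-out sugar levels with
R² ≳ 0.95 while the same model on 3-channel RGB features scores near zero,
because the sugar signal lives above 700 nm.

A thin CLI wires the stages together for shell use:

```sh
jamspec simulate --seed 1 --out-dir scenes/      # ENVI scene/DARKREF/WHITEREF
jamspec preprocess --scene-dir scenes/ --grid 3 --out-dir records/
jamspec split --records records/records_g3.csv --strategy concentration --out split.yaml
jamspec train --records records/records_g3.csv --split-manifest split.yaml --model svm --out-dir run/
jamspec sweep --records-dir records/ --models svm,xgb --out-dir sweep/
```

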