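# Methods

## Problem and model

The package estimates the sugar concentration of processed apple jam
(% w/w, the regression target) from VNIR hyperspectral reflectance.  The
measurement model is the standard two-point radiometric correction

    R(x, λ) = (I(x, λ) − D(x, λ)) / (W(x, λ) − D(x, λ))

with I the raw intensity cube, D the closed-shutter dark frame, and W the
white reference (the bare dish).  Segmentation uses the spectral angle
mapper, θ(p, r) = arccos(p·r / ‖p‖‖r‖), which is invariant to per-pixel
brightness scaling — appropriate because illumination varies spatially but
material identity is encoded in spectral *shape*.  Features are unit-norm
mean spectra of grid cells inside the margin-shrunk jam bounding box, which
again deliberately removes brightness and retains shape.

## Synthetic campaign: what it emulates, what it does not

The generator reproduces the statistical structure the analysis relies on,
not the optics of a real kitchen-lab acquisition:

* **Factorial design** — 8 cultivars × 11 sugar levels (25–75%, step 5) ×
  thicknesses {0.5 cm: 6, 1 cm: 7, 2 cm: 7} views = 1760 captures; view
  angle/distance are carried as opaque metadata and never influence the
  rendered scene (thickness-dependent optics are out of scope).
* **Cultivar templates** — smooth curves built from a brightness floor, a
  sigmoidal red-edge rise centred at 560 nm, a Gaussian absorption dip near
  440–460 nm, and two Gaussian NIR peaks at 760/870 nm.  Per-cultivar
  parameters are drawn once from a CRC-seeded generator of the cultivar
  name, so templates are stable across runs without any stored data.
* **Sugar effect** — an additive raised-cosine bump supported on
  750–900 nm whose amplitude is `magnitude × sugar/100` (default magnitude
  0.25), i.e. strictly monotone in sugar at every affected band.  Real
  sugar–water absorption shifts several overtone bands nonlinearly; this is
  the minimal monotone, recoverable stand-in.  Its compact NIR support is
  what gives the RGB-vs-HSI contrast its teeth: the three visible windows
  (400–700 nm) contain no trace of it.
* **Noise** — i.i.d. Gaussian per band and pixel, default σ = 0.01
  reflectance units (≈1% of full scale, a realistic snapshot-camera level).
  No spatial correlation, stray light, or specularities.
* **Scene geometry** — a seeded ellipse (~35–45% of the frame) on a bright
  near-flat dish (reflectance ≈0.9), guaranteeing the jam/background
  spectral angle exceeds the 0.2 rad threshold by a wide margin (measured
  ≈0.33 rad).  References D and W carry smooth spatial structure (plane and
  vignette) and the raw cube is synthesized as I = D + (W−D)·R, so the
  calibration equation inverts the construction exactly; with σ = 0 the
  whole chain render → calibrate → segment → extract reproduces the
  template to < 1e-10 (float64 throughout).

Consequently, passing tests show that the *pipeline* is correct and that
the models can recover a monotone NIR composition signal under the study's
split protocols; they do not certify performance on real jam, where
scattering, texture, and cultivar-by-sugar interactions are richer.

## Splits

Both strategies assign folds by group, never by record, so all subregions
of an image share a fold and the image-index sets of train/val/test are
disjoint (asserted on every split):

* **Cultivar split** — 6/1/1 cultivars (75%/12.5%/12.5%); evaluation
  cultivars are entirely unseen.
* **Concentration split** — per cultivar, 1–2 test and 1–2 validation
  concentrations are held out.  The published assignment of specific
  levels per cultivar is not machine-readable, so the default map uses a
  deterministic rotating pattern (cultivar i holds out level indices
  {2i, 2i+5 mod 11} for test — the second entry only for the first six
  cultivars — and the indices shifted by one for validation), reproducing
  the marginal cell fractions 62/14/12 of 88 = 70.5%/15.9%/13.6%.  The map
  ships as packaged YAML and is fully overridable.

## Models and numerical choices

* **Scaling.** MinMax per feature, fitted on the training fold only; the
  scaler records its provenance and trainers assert it ("train"), making
  normalisation leakage a hard error.  Validation/test values outside the
  training range are not clipped.  Targets are additionally rescaled to
  [0, 1] for the residual network (whose loss and early stopping operate on
  that scale) and inverted exactly after prediction; the SVR and the
  boosted trees regress raw percentages, since their printed ε-tube and
  squared-error settings are stated in target units.
* **SVR** — RBF kernel, C = 110, ε = 0.1, γ = 0.01 (γ used literally, not
  as a heuristic).  Deterministic up to the SMO solver tolerance.
* **XGBoost** — η = 0.10, depth 5, colsample 0.95, squared error, ≤400
  rounds, early stop after 40 rounds without validation-RMSE improvement;
  single-threaded and seeded for reproducibility.
* **1-D ResNet** — implemented directly in NumPy with explicit
  forward/backward passes (channels-last activations; each convolution tap
  is one BLAS GEMM via im2col), gradient-checked against central finite
  differences to ~1e-10 in float64.  Architecture: stem convolution
  (kernel 7) then 8 residual blocks (two kernel-3 convolutions each with
  batch normalisation and ReLU, dropout 0.1 after the first activation,
  1×1 strided projection on shape-changing skips), stride-2 downsampling at
  blocks 2/4/6/8 with filter doubling 32→512, global average pooling and a
  single linear output.  "Custom padding" is ⌊k/2⌋ left / k−1−⌊k/2⌋ right,
  the unique choice that preserves length for any kernel size including
  even ones.  204 bands shrink 204→102→51→26→13 before pooling; the default
  configuration has exactly 2,271,521 trainable parameters (asserted in a
  test).  Training: Adam (lr 10⁻³, L2-style weight decay 10⁻⁴ added to the
  gradient), MAE loss, ≤30 epochs, early stopping when validation MAE fails
  to *strictly* improve by ≥1e-6 for 5 consecutive epochs, best-validation
  weights restored.  Stem/block kernel sizes, base filter count and dropout
  rate are package choices exposed in `ResNet1DConfig`.
* **Seeds.** One master seed fans out through `numpy.random.SeedSequence`
  to scene rendering (one child per capture), weight initialisation, epoch
  shuffling, dropout, and tree subsampling; runs are bit-reproducible.

## Problem sizes used in tests and the acceptance script

Desk-scale campaigns keep the suite fast while preserving the study
structure: unit tests render 2–4 cultivars at 48–64 px frames; the
model-recovery study uses the full 8 cultivars × 11 levels with 2 views at
64×64 px (176 captures, 1584 3×3-grid records) and moderate noise
σ = 0.01.  On that campaign the SVM reaches validation R² ≈ 0.96 and the
residual network ≈ 0.95–0.98 under the concentration split, and the RGB
counterpart of the same experiment collapses to R² ≈ 0.  At this scale the
30-epoch protocol provides only ~25 gradient steps per epoch, so the
network is run at batch 64 (and batch 32 in the smallest unit-test
campaign, where 64 would leave too few updates per epoch to converge
before early stopping); both sizes belong to the published batch-size set.

## Known limitations

* Tree ensembles cannot interpolate between concentration levels when every
  record of a cell is spectrally identical (noise-free tables), since their
  prediction surface is piecewise constant in feature space; the XGBoost
  recovery test therefore runs at the generator's default noise.
* The ENVI reader supports the BSQ/BIL/BIP, integer/float, offset-header
  subset of the format that snapshot cameras emit — not bad-band lists,
  map info, or spectral subsetting.
* Reflectance above 1 (sample brighter than the dish reference) is clipped
  at 2 by default; the cap is configurable because the true camera
  behaviour is undocumented.
* The per-class MAE and scatter outputs are emitted as CSV plot data;
  no figures are rendered.
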