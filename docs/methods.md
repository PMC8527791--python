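# Methods

## Problem and data model

The package maps a leaf reflectance spectrum R(λ), λ = 400…2399 nm at 1 nm
steps (2000 values, unitless in [0, 1]), to ten physiological traits
(units: LMA g m⁻²; Narea g N m⁻²; SPAD unitless; Nmass mg N g⁻¹; Vcmax,
Vcmax25, J, A µmol m⁻² s⁻¹; gs mol m⁻² s⁻¹; Vcmax25/Narea
µmol CO₂ s⁻¹ (g N)⁻¹). Trait tables are incomplete in practice — each
trait is measured on a different subset of leaves — so every data structure
carries an explicit missingness mask and every loss/metric is computed over
observed entries only.

## Preprocessing conventions

* **Trim window [400, 2400), half-open.** The half-open convention yields
  exactly 2000 model inputs; a closed interval would give 2001. Spectra
  covering less than the window are zero-padded onto the full grid, the
  same convention the spectral-trimming augmentation uses for absent
  wavelengths.
* **Outlier filter at 800 nm, inclusive band [0.35, 0.6].** Values exactly
  on the boundary are kept (the removal rule is "lower than 0.35 / higher
  than 0.6", strict on both sides).
* **Jump correction.** Splice artifacts are modelled as additive detector
  offsets. For each splice wavelength j, the right segment is shifted so
  the first-difference across j equals the mean of the five differences on
  each side. The estimator is exact (round-trips injected steps to
  numerical precision) whenever the difference sequence is locally linear
  around j; on curved spectra the residual is bounded by the local
  curvature of the differences. The operation is idempotent and never
  changes the grid or sample count. A multiplicative variant is available
  (`mode="multiplicative"`) for gain-type artifacts.
* **Split 70/10/20 at the sample level.** One shared split for all traits:
  a per-trait split cannot be combined with a single multi-task model
  without leaking test spectra into training. Sizes are floor(n·f) for
  validation and test, remainder to train. Per-trait effective counts then
  follow from the missingness mask.

## Model family

* **Dilated 1-D CNN** (the central model): average-pool 10 → four conv
  layers (kernel 5, dilation 2, channels 75/150/225/300, batch norm then
  ReLU) → flatten → FC 800 → ReLU → dropout 0.2 → FC 200 → ReLU → dropout
  0.2 → FC 10 (multi-task) or 1 (single-task). Stride 1 with 'same' zero
  padding keeps sequence length at 200 throughout, making the flatten width
  300·200 = 60 000. The receptive field of a stride-1 stack is
  1 + Σ(kₗ−1)·dₗ: 13 for the worked (5,5)/(1,2) example, 33 pooled
  positions (≈330 nm of raw spectrum) for the default four-layer stack.
  Dilation 2 is used in all four layers, per the tabulated architecture;
  illustrations that warm up with dilation 1 are treated as illustrative.
  Batch norm sits between convolution and ReLU; inference uses running
  statistics, including validation evaluations during early stopping.
* **MLP baseline** reuses the pooled input and the identical FC head
  without the convolutional stack, so CNN-vs-MLP isolates the
  convolutions. (The head shape is this package's choice.)
* **LSTM baseline**: pooled sequence → 2-layer bidirectional LSTM, 100
  hidden units/direction → concatenated final states (200) → FC 200 → ReLU
  → FC 1. Single-task, one model per trait.
* **PLSR** on raw per-nm reflectance of a fixed range, one scikit-learn PLS
  fit per trait (missingness differs) sharing one component count chosen by
  mean validation R² over 1–30 components (capped below the training count,
  with a warning). The published description selects the *lowest* mean
  validation R², which we read as a typo for highest (or lowest error);
  the package maximises validation R². Four fixed-range variants exist —
  [400,900), [400,1000), [400,1700), [400,2400) nm — and narrow inputs are
  matched to the largest range they fully contain.
* **XGBoost** per trait on raw reflectance; (learning rate, max depth,
  colsample_bytree) from the fixed 6×5×4 grid {0.01…0.1}×{3…11}×{0.3…1},
  best mean validation R², ties to shallower trees.
* **Ensemble**: arithmetic mean of member predictions per observation and
  trait. Default membership: spectrally-trimmed multi-task CNN,
  spectrally-trimmed single-task CNNs, full-range PLSR.

Raw (un-pooled) per-nm inputs for PLSR/XGBoost are this package's choice;
pooling is a property of the neural architectures.

## Training

Masked MSE: each trait contributes the mean squared error over its observed
pairs, and per-trait means are summed, so scarce traits are not drowned out.
Targets are z-scored per trait with training-partition statistics
(inverted at prediction); the traits span three orders of magnitude and an
unscaled loss would be dominated by J and Vcmax. Optimiser: Adam, lr 10⁻⁴,
batch size 32 (batch size is unstated upstream; 32 is this package's
documented default, configurable). Checkpoint early stopping: train the
full epoch budget, evaluate masked validation MSE every 10 epochs, return
the best checkpoint. Divergence (non-finite loss) aborts with a
diagnostic rather than returning NaNs.

Augmentation: (i) offline +50% expansion with horizontal shifts — integer
grid shifts, uniform nonzero in [−5, 5], edge values replicated, labels
copied (772 training samples become 1158 at the standard rate); (ii) online
spectral trimming for CNN-family models only — per presentation, bounds are
drawn (low ~ truncated N(400, 100²) on [400, 700]; high ~ truncated
N(2400, 500²) on [1000, 2400]; pairs with span < 350 nm rejected and
redrawn, which preserves the marginals conditional on the constraint) and
the spectrum is zeroed outside them. Trimming is never applied at
evaluation and never to PLSR/XGBoost. The two augmentations are not
combined by default (shifts are offline, trimming online).

Determinism: given a fixed seed and single-threaded BLAS, training
reproduces bit-for-bit on the same platform; across CPU generations BLAS
kernel selection may reorder float32 reductions, so determinism is
platform-level, not universal.

The neural stack (layers, backprop, Adam) is implemented in numpy inside
`leafspec.nn`; gradient correctness is pinned by central-difference tests
for every layer type, and the vectorised dilated convolution is checked
element-wise against a brute-force per-position summation oracle.

## Metrics

R² = 1 − SS_res/SS_tot (may be negative); Abs(Bias%) =
100·|mean(ŷ)−mean(y)|/mean(y); REP = 100·RMSE/mean(y). Bias and REP
formulas follow standard chemometrics usage; the upstream tables do not
print them, so magnitudes of any external comparison depend on that
reading. Reported summaries average per-trait metrics over runs with
seeds {0, 1, 2} where the three-seed protocol is used.

## Synthetic data generator

The generator emulates the statistical structure of a leaf-clip campaign:

* **Traits**: a Gaussian copula with a factor-structured correlation matrix
  (structure / nitrogen–pigment / photosynthesis factors; magnitudes are
  plausible placeholders chosen for a wheat panel, not measured values).
  Marginals are lower-truncated
  normals (traits are non-negative) whose post-truncation mean and sd are
  solved to match the published per-trait summary statistics (e.g. LMA
  59.32 ± 12.54, gs 0.48 ± 0.21). Missingness is Bernoulli per trait at
  the published per-trait sample fractions (488–1013 of 1013).
* **Spectra**: a smooth envelope — visible region with chlorophyll troughs
  at 450/670 nm and a green peak at 550 nm, a sigmoid red edge near 720 nm,
  an NIR plateau, a gentle SWIR decline and multiplicative water-absorption
  dips at 1200/1450/1940 nm. Feature depths/positions are planted linear
  functions of the standardized trait latents: pigment traits (SPAD,
  Nmass) drive the visible features and red-edge position; structural
  traits (LMA, Narea) drive the plateau level and water-band depths; gs
  nudges the water bands. By construction LMA carries the largest total
  linkage, then Narea; the gas-exchange traits are linked only through
  correlation. White noise (sd 0.004) approximates instrument noise.
  Non-outlier plateaus are clipped so R(800) ∈ [0.37, 0.59]; a configurable
  outlier fraction (round(n·f) samples exactly) is pushed outside the
  [0.35, 0.6] band. Additive splice steps (default +0.02 above 1000 nm,
  −0.015 above 1800 nm) emulate the detector boundary; final values are
  clipped to [0, 1] with a count kept in the ground-truth record.
* **Ground truth** (latents, realized features, linkage, pre-artifact
  spectra, outlier list) is returned for oracle tests: regressing each
  realized feature on the latent traits recovers the planted coefficients
  essentially exactly, which certifies that learnable signal exists.

What the generator does **not** model: radiative transfer (no leaf-optics
physics), wavelength-dependent noise, instrument drift, genotype or
environment structure, and realistic inter-trait correlation magnitudes.
Passing tests on synthetic data therefore demonstrate that the pipeline
recovers signal of the planted kind and strength — not field-level accuracy
on real wheat spectra.

## Desk-scale test sizes

The full-width CNN (48.7 M parameters) trains at full scale only in the
optional long-protocol script. The automated test suite uses width-reduced
variants of the same layer pattern so the whole suite stays within minutes
on one CPU:

* signal-recovery acceptance check: n = 400 synthetic samples (seed 0),
  channels 18/37/56/75, FC 200/50, 120 epochs, batch 32, lr 10⁻⁴, shift
  augmentation on. Because this check evaluates full-range spectra, it
  trains the full-range (no spectral-trim) variant — the apt comparison,
  since trimming exists to serve narrow-range inputs and costs accuracy on
  full-range evaluation. Asserted: test R² ≥ 0.8 on the strongly planted
  traits (LMA, Narea); PLSR with validation-tuned components R² ≥ 0.7 on
  the linear-signal traits (LMA, Narea, SPAD, Nmass);
* property tests (noiseless recovery, multi-task vs single-task) use
  two-layer stacks, ~100–160 samples and dropout 0 — they probe the
  training machinery, not the regularisation.

These sizes are the package's own desk-scale choices; thresholds are not
adjusted to them.

## Known limitations

* The jump-correction estimator assumes locally linear differences; sharply
  curved splice neighbourhoods leave a small residual.
* PLSR/XGBoost hyperparameters are selected on a single validation split,
  not cross-validated.
* The LSTM on 200-step pooled sequences is slow in the numpy engine and is
  exercised at reduced sizes in tests.
* Model archives embed pickled fitted objects (with a config hash check on
  load); they are not portable across incompatible library versions.
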