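# leafspec

Predict leaf physiological traits from hyperspectral reflectance.

High-throughput crop phenotyping needs fast surrogates for traits that are
slow or destructive to measure: leaf dry mass per area (LMA), nitrogen per
area and per mass (N<sub>area</sub>, N<sub>mass</sub>), chlorophyll (SPAD)
and the photosynthesis parameters V<sub>cmax</sub>, V<sub>cmax25</sub>, *J*,
*A*, g<sub>s</sub> and V<sub>cmax25</sub>/N<sub>area</sub>. Leaf reflectance
at 400–2400 nm (1 nm resolution, 2000 wavelengths) carries enough signal to
predict all ten; this package provides the full modelling pipeline for
breeders and plant physiologists working with such spectra.

## What is inside

* **Spectra I/O and cleaning** — the field-standard CSV layout (wavelength
  column + one column per observation), additive *jump correction* of
  detector-splice discontinuities (typically at 1000 and 1800/1830 nm), the
  400–2400 nm trim and the 800 nm plausibility filter
  (R(800) ∈ [0.35, 0.6]).
* **A multi-task dilated 1-D CNN** — average-pool 10, then four kernel-5,
  dilation-2 convolutional layers (75/150/225/300 channels, batch norm +
  ReLU), then fully connected 800 → 200 with dropout 0.2 and a 10-output
  head; single-task variants differ only in the 1-output head. Each layer
  computes X⁽ˡ⁾_c₀ = f(Σ_cᵢ W⁽ˡ⁾ᶜⁱ_c₀ ∗ X⁽ˡ⁻¹⁾ᶜⁱ + B⁽ˡ⁾_c₀) with ReLU f and a
  dilated, stride-1, 'same'-padded kernel. The backing
  numpy engine (`leafspec.nn`) implements forward, backprop and Adam.
* **Training protocol** — masked multi-task MSE (per-trait means summed, so
  traits measured on fewer leaves still count), Adam at lr 10⁻⁴, checkpoint
  early stopping (validate every 10 epochs, keep the best), +50% offline
  shift augmentation (±5 nm, edge-replicated) and online *spectral
  trimming*: per presentation, zero the spectrum outside random bounds
  drawn from truncated normals (low ~ N(400, 100²) on [400, 700]; high ~
  N(2400, 500²) on [1000, 2400]; span ≥ 350 nm), teaching a fixed-length
  network to accept narrower-range instruments.
* **Baselines and ensemble** — PLSR (components tuned 1–30 on validation
  R², plus fixed-range variants for [400,900]/[400,1000]/[400,1700]/
  [400,2400] nm inputs), XGBoost (6×5×4 printed grid), MLP and a 2-layer
  bidirectional LSTM; a plain-mean ensemble over members.
* **Evaluation** — per-trait R², Abs(Bias%) = 100·|mean(ŷ)−mean(y)|/mean(y)
  and REP = 100·RMSE/mean(y) on a 70/10/20 sample-level split.
* **A synthetic-spectra generator** — leaf-like envelopes (green peak, red
  edge, NIR plateau, SWIR water bands) whose features are planted linear
  functions of ten correlated traits with realistic locations, spreads and
  per-trait missingness, plus splice artifacts and outliers, so the whole
  pipeline is trainable and testable without any field campaign.

## Worked example

```bash
leafspec simulate --n 350 --seed 0 --outlier-fraction 0 --out data/
leafspec train --spectra data/spectra.csv --traits data/traits.csv \
    --model plsr --seed 0 --jumps 1000,1800 --out plsr.model
leafspec evaluate --spectra data/spectra.csv --traits data/traits.csv \
    --model plsr.model --jumps 1000,1800 --seed 0
```

On this synthetic campaign the training step reports `PLSR components: 5`
(chosen by mean validation R²) and the evaluation prints, per trait, R²,
Abs(Bias%) and REP on the held-out 20% test partition:

```
                  R2  AbsBiasPct     REP
LMA            0.991       0.415   2.409
Narea          0.934       0.716   7.273
SPAD           0.997       0.154   1.087
Nmass          0.869       1.178   6.682
Vcmax         -0.413      11.591  42.472
...
mean: {'R2': 0.353, 'AbsBiasPct': 3.414, 'REP': 20.898}
```

Traits the generator links directly into the spectrum (LMA, N<sub>area</sub>,
SPAD, N<sub>mass</sub>) are recovered with high R²; the gas-exchange traits
are linked only through inter-trait correlation and recover partially or
not at all (R² can legitimately go negative when a prediction is worse than
the observed mean) — REP ≈ 20–50% mirrors how much harder they are. The
same workflow is
available from Python; see `examples/` for narrative scripts covering
simulation, jump correction, CNN training, PLSR range matching and the
ensemble.

## Scope notes

The R Shiny web front end that originally exposed these models is replaced
here by the `leafspec` CLI (same CSV contract, same 100-observation default
cap). Gas-exchange modelling that produced the trait labels is out of
scope; trait values enter as a CSV.
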