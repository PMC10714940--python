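# Methods

## Problem and model

The package classifies per-plant water-stress status (high / moderate /
none, encoded as the treatment labels I1N2 / I2N2 / I3N2) from a
time series of co-registered 5-band reflectance patches (blue 475 nm,
green 560 nm, red 668 nm, red-edge 717 nm, NIR 842 nm) acquired on
successive dates over maize plots under differential irrigation.

The classifier has three stages:

1. **Spatial-spectral feature extractor.** A CNN backbone whose final
   convolution is *deformable*: output `y(a0) = Σ_i w(a_i) · x(a0 + a_i + Δa_i)`,
   where the per-tap offsets Δa_i are predicted per output location by a
   standard convolution over the same input and applied through bilinear
   interpolation with zero padding.  The offset predictor is
   zero-initialized, so an untrained deformable layer is exactly a standard
   convolution; this is also what the equivalence tests exploit.  Backbone
   plans: `alexnet` (11×11/s4 first conv, channel path 96-256-384-384,
   deformable 384→256), `vgg16` (twelve 3×3 convs, 64…512, deformable
   512→512, i.e. the thirteenth conv of the classical stack replaced), and a
   two-block `compact` plan (16-32 channels, deformable 32→32) for
   desk-scale frames on which the AlexNet geometry (two stride-reducing
   pools after an 11×11/s4 conv) cannot operate.  The published tables leave
   pooling rows and intermediate spatial sizes unspecified; we use the
   canonical max-pooling schedules and force the printed 4×4 spatial output
   with an adaptive average pool immediately before the deformable layer.
   Extractor weights are shared across time steps.

2. **Temporal fusion.** Two stacked LSTM layers (gate equations in
   `model_core.lstm_step`): layer 1 runs forward over the per-date feature
   vectors, layer 2 consumes layer 1's hidden sequence in *reverse* order,
   and the hidden-state matrix H collects layer-2 states re-ordered to
   original time order.  This follows the source description literally; a
   `bilstm_mode="concat"` switch provides the conventional bidirectional
   concatenation instead, since the term "BiLSTM" and the stacked-reverse
   description conflict.  Defaults: hidden size 128 (unstated in the
   source; chosen to train on CPU), configurable.

3. **Attention pooling and head.** `M = tanh(H)`, `α = softmax(wᵀM)`,
   `R_att = H αᵀ`; then two affine layers (hidden → 64 → 3) with a
   rectifier between and a softmax.  Ablation variants: Case I standard
   conv + last-state pooling, Case II standard conv + attention, Case III
   deformable + last-state pooling, full = deformable + attention.
   No-attention variants pool with the last time-ordered hidden state.

## Training recipe

Categorical cross-entropy `−Σ_i y_i log(ŷ_i)` (the conventional
orientation; the printed formula multiplies the prediction by the log of
the one-hot target, which is degenerate for one-hot labels), predictions
clamped at 1e-12.  He initialization (weights N(0, 2/fan-in)), biases
zero, offset predictor zero.  Adam, learning rate 1e-4, batch 16,
100 epochs by default.  Augmentation draws one transform per sequence
(rotation by a random multiple of 90°, independent horizontal/vertical
flips) and applies it to every frame identically, preserving the temporal
geometry the recurrent stage tracks.  The train/validation split is
stratified 4:1 with round-half-up per class (32/class → 26 + 6).
Normalization (min-max to [0,1] or per-channel standardization) is
computed on the training split only and reused for validation; zero-range
channels map to zeros with a logged warning.  The best-validation-accuracy
checkpoint is kept, ties to the earlier epoch.  Everything is driven by
explicit integer seeds; two runs with the same seeds produce identical
loss histories.

All tensor computation, including the deformable convolution forward and
backward (bilinear-weight scatter for the input gradient, the piecewise
bilinear derivative for the offset gradient) and the Adam loop, is
implemented in NumPy on a small reverse-mode autodiff engine
(`_autodiff.py`).  Gradients are verified against central finite
differences for every operator and through the full model; note bilinear
sampling is non-differentiable exactly at integer sampling points, so
full-model checks perturb the offset predictor to a generic fractional
point first.

## Synthetic data

No acquisition of the original UAV campaign is publicly deposited, so a
generator (`synthetic_data`) emulates the statistical structure the
classifier exploits.  Each sequence renders 3–6 Gaussian canopy blobs
(thresholded at 0.6) on a constant soil background; per date t the blob
radii scale by (1 − shrink)^t, the canopy mask is warped by a smoothed
random displacement field whose amplitude grows as deform·t (leaf
rolling/twisting at desk scale), canopy reflectance in channel c is
base_c + slope_c·t, and a per-date multiplicative illumination jitter and
i.i.d. Gaussian sensor noise are applied before clipping to [0, 1].

Defaults (versioned in `params/default_trajectories.yaml`, reflectance
units per date): NIR slopes −0.030 / −0.015 / 0.000 and red slopes
+0.010 / +0.005 / 0.000 for high / moderate / no stress — healthy
mesophyll reflects NIR strongly and loses that reflectance under stress,
while red reflectance rises as chlorophyll absorption weakens; shrink
rates 0.030 / 0.015 / 0.000; warp amplitudes 0.40 / 0.20 / 0.05 px/date;
noise sd 0.01; jitter sd 0.02.  Channel bases (canopy / soil): blue
0.05/0.10, green 0.10/0.12, red 0.08/0.15, red-edge 0.30/0.20, NIR
0.55/0.25.  These are typical orders of magnitude for vegetation and dry
sandy-loam reflectance; the NIR decline of 0.36 over 13 dates for the
high-stress class is severe but keeps the trajectory well inside [0, 1].

Variant parameter sets expose separability dials used by the acceptance
studies: `exchangeable_params` (all classes identical — any classifier is
at chance 1/3), `slope_only_params` (classes differ only through temporal
slopes; identical at the first date, so a one-date window carries no class
signal), `nir_only_params` (classes differ only through the NIR
trajectory, so RGB-only input carries no class signal).

What the generator does **not** emulate: radiative-transfer or
soil-moisture physics, within-canopy texture, bidirectional reflectance
effects, registration error, soil heterogeneity, weather-driven trajectory
nonlinearity.  Passing tests therefore demonstrate that the architecture
and recipe can extract class-conditioned spatial-spectral-temporal
structure of this kind — not field-level accuracy on real UAV data.

## Desk-scale study conditions

The synthetic learning studies (tests and `scripts/acceptance.py`) use a
reduced configuration sized for a single CPU: compact backbone, 32×32
frames, 6 dates, 24 sequences per class, hidden size 32, Adam 1e-3,
30 epochs for runs expected to learn and 12 for chance-level controls.
The paper-scale configuration (140×140, 13 dates, 32/class, VGG-16) is
fully supported and exercised by shape tests.  Chance-level checks compare
the number of correct validation predictions against the exact central
95% binomial band at p = 1/3; by construction a truly-chance run falls
outside the band for about 5% of seeds.

## Numerical and design notes

- Bilinear sampling outside the map contributes zero, matching standard
  convolution padding, which makes the zero-offset equivalence exact.
- Canonical channel order is (blue, green, red, rededge, nir); every
  spectral subset preserves it, so first-layer weights have stable
  semantics across subset experiments.
- Border trim removes floor(fraction·dimension) pixels per edge
  (conservative integer grid); ROI extraction enumerates windows row-major
  and defaults to non-overlapping stride = patch size — the source does not
  state the stride, so packaging counts are configuration, not contract.
- Sequences missing an acquisition date are rejected rather than imputed;
  the model assumes fixed-length sequences.
- Per-sequence generator seeds are `seed + index`, making archives pure
  functions of their arguments.
- Experiment grids share one train/validation split across cells so
  ablation comparisons are paired; each cell re-trains from scratch.
- Headline precision/sensitivity are macro averages (a config-free choice
  documented in the report tables; per-class values are reported
  alongside).

## Known limitations

- The published parameter count (14,060,611) and memory figure are not
  reproducible from the printed layer tables under any standard accounting
  and are treated as non-binding; no configuration is tuned toward them.
- Published accuracy tables depend on the undeposited UAV dataset and are
  likewise non-binding; the experiment harness reproduces the experiment
  *matrix*, not those numbers.
- Orthomosaic generation, georeferencing and radiometric calibration are
  upstream of this package (performed in commercial/GIS software) and out
  of scope; input is assumed to be calibrated reflectance rasters.
- Training is CPU-bound NumPy; paper-scale training (VGG-16 at 140×140,
  100 epochs) is supported but slow — the package is sized for method
  verification and desk-scale experimentation.
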