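# Methods

## Problem and pipeline

Turbidity (FNU, 0–55) is estimated from an underwater RGB image in two
stages: an 11-class ordinal classifier produces a confidence
distribution over FNU bins, and a weighted-least-squares (WLS) linear
regression maps the truncated confidence vector to a continuous FNU
value. The package adds a physics-based scene simulator so the whole
chain can be trained, fitted and evaluated on synthetic data alone, a
sample-size planner for hypothetical direct-regression models, and the
dataset/CSV plumbing of the surrounding tool.

## Image-formation model

Each scene is a composite of a clean background (the "direct" signal)
and veiling light:

    observed = direct · T + veiling · (1 − T),      T = exp(−c · d)

- `c` — per-channel beam attenuation coefficient (1/cm), affine in
  turbidity: `c = c0 + k·FNU + 2.0·tint`. Defaults
  `k = (0.0040, 0.0036, 0.0032)` per (R, G, B): red attenuates fastest,
  and the magnitudes make the Secchi disk effectively invisible at
  55 FNU and 23 cm (`T ≈ 0.01`). `c0` defaults to 0 so a 0-FNU,
  tint-free, noise-free scene reproduces its background bit-exactly —
  a deliberate idealization (real "clear" water still attenuates) that
  gives the simulator a clean identity contract.
- `d` — per-pixel distance (cm): constant 30 cm for open water; a
  linear 10→60 cm vertical ramp for substrate and vegetation scenes to
  mimic oblique shots.
- `veiling` — neutral gray (0.55, 0.55, 0.55) by default; ink tints
  shift it away from the absorbing channel.
- Secchi disk — black/white quadrants (albedos 0.05/0.95), 4.2 cm
  diameter, rendered at 12 or 23 cm under a pinhole model with focal
  length equal to the frame width. Its Michelson quadrant contrast has
  the closed form `0.9·T̄ / (1.1 − 0.1·T̄)` with `T̄` the channel-mean
  transmission at the disk distance; the test suite checks renders
  against this expression exactly.
- Sensor noise — additive Gaussian, sd configurable on the [0, 1]
  intensity scale, applied after compositing, clipped to range.

Backgrounds (gravel, sand, open water, vegetation) are seeded
procedural textures. All rendering is bit-deterministic given
(spec, seed).

The dataset generator samples FNU uniformly within each class interval,
exactly `n_per_class` per class. Protocol mix defaults emulate the
reference collection: 38% of frames include the Secchi disk (at 12 or
23 cm with equal probability), 30% carry an ink tint (one dominant
channel, 0.01–0.05 mL/L analog), backgrounds uniform over the four
kinds.

## Class scheme and splits

The 11 bins (0–0.49, 0.5–0.99, 1–2.49, 2.5–4.99, 5–9.99, 10–14.99,
15–20.99, 21–28.99, 29–36.99, 37–44.99, 45–55) are implemented as
half-open intervals `[lower_k, lower_{k+1})` with the last bin closed
at 55. The printed two-decimal uppers leave apparent gaps (0.49→0.5);
the half-open convention covers them, and a value equal to a next lower
bound (e.g. 0.5) goes to the higher class. Splits are stratified per
class at 75/15/10 with largest-remainder apportionment (per-class
counts within one image of target), seeded shuffling, and a strict
no-duplicates partition.

## Classifier

The baseline backbone is intentionally not a neural network: it
extracts ~28 handcrafted statistics per image and trains a multinomial
logistic regression (standardized features, L2, C=10, lbfgs), making
training deterministic under a seed and fast on one CPU. The features
are chosen from the physics: per-channel means/sds and log-sds,
log-mean channel ratios (turbidity raises attenuation in all channels,
an ink tint in one — the ratios separate them), global and
center-region percentile contrast with log copies, per-channel
gradient-energy and near/far (bottom/top) gradient log-ratios along the
oblique distance ramp (which isolate `c·Δd` from the texture's own
amplitude), and vertical luminance ramp. A plugin point accepts any
object with `predict_proba` over image records, so a convolutional
backbone can be mounted behind the same contract.

Inference resizes to the configured side length, computes the full
11-class distribution, then truncates to the top five entries with ties
broken toward the lower class index; the remaining entries are zeroed
and nothing is renormalized, since the regression was defined on raw
truncated confidences. `TrainConfig` keeps the conventional
(320 px, 15 epochs, batch 16) defaults for contract parity; the
baseline solver is full-batch and computes features at ≤64 px, where
these statistics saturate.

## Confidence regression

`ConfidenceRegression(y, X).fit()` solves the weighted normal equations
(via statsmodels WLS; tests verify agreement with an explicit
`(XᵀWX)⁻¹XᵀWy` solve to 1e-8). Design rows are the truncated
confidence vectors, zero-filled where fewer than five classes were
reported; an intercept is always added. Rank checks apply to the
confidence columns only: a complete one-hot design makes the intercept
collinear with the columns, and the pseudoinverse solve then returns
the minimum-norm, exact-interpolation solution rather than an error.

Weights: no canonical choice exists for this problem, so the default is
`w = 1/max(y, 0.5 FNU)`, which equalizes relative error across the
range — consistent with evaluating by RRMSE, where a 2-FNU error at
50 FNU is minor but at 1 FNU is disqualifying. Unit weights (OLS) are
one flag away, and the two are compared in tests. The 0.5 FNU floor
prevents near-zero observations from dominating.

Prediction is the raw affine form `β₀ + Σβᵢxᵢ`; clamping to [0, 55] is
off in the library (preserving residual statistics) and on in the CLI
output (never reporting negative turbidity to users). The bundled
published coefficient table (intercept −60.90; class coefficients
61.34…114.32) is validated on load for shape and strict monotonicity in
class index. By default the regression is fitted on train+test and
reported on the validation split; fitting on everything is a flag.

## Evaluation

RRMSE is defined as `100·RMSE/mean(observed)` (the relative-standard-
deviation reading); it is scale-invariant and undefined (NaN with a
warning) at zero observed mean. Adjusted R² uses df_model = 11. The
banded coverages use a half-open split: the absolute ±0.7 FNU band
covers `y_true < 2.5`, the relative ±33% band `y_true ≥ 2.5`, matching
the binning convention. "Within one class" is adjacency on class
indices, not FNU widths.

## Sample-size planner

The low (absolute-accuracy) range contributes `span/(2·halfwidth)`
pseudo-classes, rounded to nearest; the high (relative-accuracy) range
contributes the smallest integer c with `lo·(1+2r)^c > hi`, computed as
an epsilon-guarded ceiling of `log(hi/lo)/log(1+2r)` so that an exact
geometric step counts as one band. The count is taken as printed for
the reference profile; the last partial band overlapping the 55 FNU cap
is not corrected. Minimum images = pseudo-classes × images/class.

## Problem sizes and determinism

The standard desk-scale run used throughout the tests is 100 images per
class (1,100 total) at 64×64 px with `noise_sd = 0`, split 75/15/10,
which trains and evaluates in a few seconds on one CPU; the README's
worked example uses 30 per class. One seed feeds the generator, which
derives per-image render seeds (all below 2³¹), the splitter and the
solver, so every stage is reproducible bit-for-bit.

## What the synthetic conditions do and do not show

The simulator produces a learnable, physically monotone
turbidity–appearance relationship with the reference protocol's mix of
Secchi presence, tints and backgrounds. It is not photorealistic: no
specific camera model, no forward-scattering blur, no suspended-particle
granularity, no exposure/white-balance variation, no real substrate
diversity, and its optical coefficients are calibrated only to produce
a monotone signal, not matched to any measured ink or sediment spectra.
Passing tests therefore demonstrate that the pipeline's contracts,
statistics and ordinal structure are correct — fitted class
coefficients rise with class index, within-one-class accuracy exceeds
top-1, predictions rank-correlate strongly with truth — but say nothing
quantitative about accuracy on real photographs; headline field-scale
accuracy figures depend on a trained convolutional backbone and a real
image collection, both outside this package's scope.

## Known limitations

- The baseline backbone plateaus well below a trained CNN: at the
  desk-scale conditions its exact-class accuracy is ~0.55–0.73 with
  within-one-class ~0.9–1.0; neighboring low-FNU bins are genuinely
  hard for global statistics.
- The WLS weight rule is a package choice, not an established
  convention for this pipeline.
- The layout reader falls back to class midpoints for `fnu_true` when a
  manifest CSV is absent, losing the continuous ground truth.
- Per-image inference failures are logged and skipped rather than
  imputed, so evaluation counts can be smaller than the manifest.
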