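# Methods

## The measurement model

A dot-blot spot darkens as labelled nanoparticles accumulate where target
DNA was spotted. The readout problem is to invert photographed darkness
back to concentration. `ringblot` treats the photograph as the only input:
no chemistry is modelled, only image statistics.

### Ring-profile features

Each spot is summarized by the mean grayscale intensity over `n_rings`
concentric rings of fixed pixel thickness, normalized to the outermost
ring:

    x_k = mean(I over ring k) / mean(I over ring n_rings-1),   k = 0 .. n_rings-1

Defaults are 6 rings of 6 px. Ring k contains the pixels at metric
distance d from the center with floor(d / thickness) = k; the default
metric is Chebyshev (max(|dx|, |dy|)), giving square annuli that tile the
71×71 px window completely, with Euclidean (circular) annuli as an option.
At the default 45 µm/px scale the mask spans 3.2 mm with 270 µm from ring
to ring, matching the typical dot size of a 3×3 dispenser grid at 0.9 cm
pitch.

Normalization is by *division*, not subtraction: a multiplicative change
of illumination (a brighter lamp, a longer exposure) scales all ring means
equally and cancels exactly. The outermost feature is therefore ≡ 1; it is
retained so the feature vector keeps its stated length of 6. The "outer
edge" reference is the full outermost annulus mean, which is far less
noisy than a 1-px border.

Grayscale reduction defaults to the unweighted channel mean; luma-style
weights are configurable.

### Center refinement

The nominal center (from the dispenser grid) can be off by a few pixels.
The mask center is refined by exhaustive grid search over integer offsets
within ±`search_radius` (default 5 px, step 1): the candidate maximizing
the variance of the normalized profile wins. The rationale: a well-centered
mask aligns rings with the spot's radial structure, giving the
highest-contrast (least blurred) profile; off-center placement mixes dark
and light regions within rings and flattens the profile. Ties are broken
by the smallest Euclidean offset from nominal, then row-major scan order,
so a featureless (uniform) crop deterministically returns the nominal
center. The variance can alternatively be computed on raw (unnormalized)
ring means via `objective="raw"`; the default scores the normalized
profile because that is the vector actually used downstream. Masks that
would leave the image raise an error rather than being padded — padding
policies silently corrupt ring means.

On symmetric noise-free spots this search provably recovers the true
center: the test suite checks exact recovery for 50 randomized
spot/offset cases with offsets up to ±5 px, under both metrics.

### Calibration and validation

Concentration is predicted by ordinary least squares with intercept on the
6 ring features — deliberately the simplest model, since a few dozen spots
cannot support anything richer. With n instances, validation is
leave-one-out: model i is fitted on the other n−1 instances (each fold
must retain at least p+2 = 8 training points) and yields a "clean"
prediction for instance i plus that fold's mean absolute train residual.
Duplicate spots are independent instances by default; `leave_pair_out=True`
holds replicate pairs out together to avoid twin leakage.

Before fitting, each label may receive a multiplicative uniform tweak of
±5% (default), emulating pipetting uncertainty of at least 10%; blanks
stay exactly zero. Metrics are computed against the *original* labels by
default (`metrics_against="jittered"` is available), and negative
predictions are reported raw unless `clip_negative=True`.

Metric suite, all in ppm unless noted:

- `mae_overall` — mean |ĉ − c| over all instances;
- `mae_low_range` — same, restricted to c ≤ 1 ppm (the detection-limit
  regime, where absolute error is the operative figure);
- `mean_relative_error_high` — mean |ĉ − c|/c over c > 2 ppm, where
  relative error is the more informative quantity;
- `mean_train_mae` — per-fold train MAE averaged over folds;
- `generalization_gap` — (mae_overall − mean_train_mae)/mae_overall.

Subset metrics over an empty subset are reported as undefined (`None`),
never as zero.

## The synthetic membrane generator

The generator emulates a standardized acquisition: membranes of 3.6 cm
square imaged at 45 µm/px (800×800 px), a 3×3 grid at 0.9 cm (200 px)
pitch, spotted with a geometric dilution series — by default 10 → 0.1 ppm
at factor 4/3 (17 levels) plus a blank, in duplicate and random order,
i.e. 36 spots spilling onto 4 membranes. The 45 µm/px scale is the unique
value reconciling a 6 px ring thickness with a 270 µm physical ring pitch;
it is an inferred, not measured, quantity.

Per-spot darkness is `A(c) · S(r)` where:

- `A(c) = A_max · c/(c + K)` with defaults A_max = 0.35, K = 2 ppm — a
  saturating, strictly monotone, invertible response. With these defaults
  a 0.42 ppm spot darkens its center by ≈ 6% of full scale, around the
  floor of visual contrast against 2% pixel noise, while remaining clearly
  measurable in ring averages.
- `S(r)` mixes a soft disc (logistic edge, radius 24 px) with 1–3 Gaussian
  annuli whose radii/widths are drawn from a per-spot jittered pool —
  the "multiple coffee rings" morphology. The number of rings is drawn
  per spot; radii, widths and an area-preserving ellipticity are perturbed
  by a relative sd of 8%. S is normalized to unit peak so the peak
  darkness of a spot at c = K is exactly A_max/2; the mixture weights
  alone would not guarantee a unit-peak bracket.

Illumination is a random low-order polynomial field (linear + quadratic
terms) spanning 5% of the base level, emulating imperfect LED uniformity;
the base (white-membrane) level is 0.9 of full scale so that 2% Gaussian
pixel noise essentially never clips at the white end — clipping would bias
blank-spot statistics. Spot placement jitter is Gaussian with sd 2 px.
Crops are cut around the *nominal* grid node (so center refinement has
real work), sized 81 px: the 71 px mask span plus the 5 px search margin
per side.

Determinism: a single top-level seed fans out through
`numpy.random.SeedSequence(entropy=seed, spawn_key=(0,))` for simulation
and `(1,)` for the label tweak, so stages can be rerun independently and
the full simulate → extract → regress chain is byte-reproducible.

### What the generator does and does not emulate

It reproduces the *statistical structure* relevant to the readout: a
monotone saturating concentration–darkness map, irregular coffee-ring
morphology, illumination gradients, pixel noise, placement error, replicate
structure. It does not model plasmon optics, hybridization kinetics,
membrane texture, JPEG-style compression artifacts, or specular highlights.
Passing tests therefore demonstrate that the feature extraction and
calibration machinery is correct and well-conditioned under realistic
image statistics — not that any particular accuracy will be attained on
real photographs, whose error level is set by the physical acquisition.

### Linearity bias on the synthetic series

Under the saturating response, the ring features are (near-)affine in
A(c), while inverting the response requires c = K·A/(A_max − A) — a
hyperbola. A linear model reading near-collinear features of A therefore
carries irreducible model bias at the saturating top of the series; even
noise-free, jitter-free synthetic runs show an overall LOO MAE near
0.9 ppm, dominated by the highest levels, while the low range stays well
resolved. This mirrors the practical observation that absolute error
grows with concentration while relative error stabilizes, and it is why
`mae_low_range` rather than `mae_overall` is the detection-limit figure.

## Numerical choices

- Ring means are computed by boolean-mask averaging in row-major pixel
  order, which matches a naive per-pixel accumulator bit-for-bit; the test
  suite asserts exact (not approximate) equality under both metrics.
- OLS is delegated to `sklearn.linear_model.LinearRegression` (minimum-norm
  under rank deficiency — constant labels yield zero coefficients and an
  intercept equal to the label mean); tests cross-check it against explicit
  normal-equation and fold-by-fold numpy oracles.
- `fit_linear` requires n ≥ p + 2 so every LOO fold retains one more
  instance than it has parameters.
- Degenerate inputs raise typed errors: zero outer-ring mean
  (`DegenerateNormalizationError`), mask or crop out of bounds, empty
  search grid, inverted dilution bounds.
- The dilution enumeration includes the final level when it is within a
  relative tolerance (default 1e-3) of the configured minimum, so the
  printed endpoint 0.1 ppm survives floating-point division by (4/3)^16.

## Known limitations

- Nominal centers must be supplied (dispenser geometry or annotations);
  there is no blind spot detection on unannotated membranes.
- The center search is integer-resolution; subpixel placement error below
  0.5 px is absorbed into the profile rather than corrected.
- Metrics on the synthetic generator characterize the pipeline, not any
  physical assay; real-data error levels require real photographs.
- The problem sizes used throughout (36 spots, 50 recovery cases, 20
  noise replicates, 100 oracle images) are chosen to characterize each
  property tightly at interactive runtimes.
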