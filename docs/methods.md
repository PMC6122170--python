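# Methods

## The measurement

`explantmetrics` quantifies neurite outgrowth from pairs of binary
segmentation masks: an *explant-body* mask covering the cell bodies of a
dorsal-root-ganglion (DRG) explant, and a *neurite* mask covering the halo
of outgrowth around it. Images follow the convention that the chemotropic
gradient (nerve growth factor, NGF), when present, increases toward the top
of the image (row 0); images captured in the flipped orientation are assumed
to have been rotated upstream, so the orientation letter in a filename is
provenance metadata only and triggers no geometric correction here.

The pipeline for one explant:

1. **Contiguity filter.** Connected components (8-connectivity) of the
   neurite mask that neither overlap nor 8-neighbour the explant body are
   removed. This discards segmentation debris; an explant whose outgrowth
   is entirely disconnected is reported as a valid zero-outgrowth case.
2. **Boundary tracing.** The outer boundary of the body, and of the union of
   body and retained outgrowth, are traced as closed pixel chains by
   Moore-neighbour tracing with Jacob's stopping criterion (the classic
   `bwboundaries` behaviour), orientation normalised counter-clockwise in
   the (x = col, y = −row) frame. Tracing the union rather than the neurite
   mask alone makes the outer contour insensitive to hairline gaps at the
   body–halo interface.
3. **Smoothing.** Each chain is smoothed with an unweighted *circular*
   moving average of width 150 samples (≈150 px of 8-connected chain).
   The circular filter preserves curve closure; a non-circular filter would
   open the curve at the seam. Width is a parameter because it should scale
   with image resolution.
4. **Polar parameterisation.** With the origin at the body-mask centroid,
   each curve's radius is sampled at N = 360 angles θ_n = 2πn/N by exact
   ray–polyline intersection: every boundary segment whose endpoint angles
   straddle θ_n contributes a crossing (linear interpolation in angle), and
   the crossing closest to the origin is kept. The radial outgrowth function
   is R(θ_n) = max(0, r_outgrowth(θ_n) − r_body(θ_n)).
5. **Fourier decomposition.** With R̂_k = (1/N) Σ_n R(θ_n) e^(−2πikn/N),
   the folded real series is a_0 = Re R̂_0, a_k = 2 Re R̂_k,
   b_k = −2 Im R̂_k for 1 ≤ k ≤ N/2, giving a 181-row (k = 0…180)
   coefficient table at the default N. a_0 is the mean radial outgrowth
   (reported in µm at 2.58 µm/px), b_1/a_0 the dimensionless outgrowth bias
   up the gradient, a_1/a_0 the bias orthogonal to it, and the k = 2 pair
   captures bipolar growth. Truncation at order 2 (five coefficients)
   reconstructs the major features of explant shape.
6. **Pixel-count measures.** OG = (neurite foreground count)/(body
   foreground count); GR = (H − L)/(H + L), H and L counting retained
   neurite pixels strictly above and strictly below the rounded centroid
   row of the body mask.

## Numerical choices

- **Nyquist folding.** Applying the ×2 folding rule at k = N/2 stores twice
  the Nyquist bin's contribution (the table keeps the conventional 181×2
  shape); synthesis therefore weights that single term by ½, making the
  full-order round trip exact to machine precision. The choice is invisible
  at the default order 2.
- **Analysis normalisation** is 1/N so that a_0 equals the profile mean,
  which the interpretation of a_0 as average outgrowth requires.
- **b_0 placeholder.** Row 0 of the sine column stores 0 (b_0 does not
  exist) to keep the rectangular table shape.
- **Ray sampling.** Ray–polyline intersection was chosen over the simpler
  "bin boundary points by angle, take the minimum radius per bin": on
  unsmoothed chains the bin-minimum systematically selects staircase pixel
  centres up to ~1 px inside the continuous shape, while interpolated
  crossings keep the worst-case error near half a pixel. Angles without a
  crossing (possible only for degenerate curves that do not enclose the
  origin) are filled by circular linear interpolation, with a log message.
- **Negative radial distances** (outer curve locally inside the smoothed
  body curve) are clamped to 0: R is an outgrowth extent and is nowhere
  negative by definition.
- **GR tie-break.** Pixels exactly on the rounded centroid row belong to
  neither H nor L, which keeps GR exactly antisymmetric under a vertical
  mirror. The split row comes from the raw body mask, not the smoothed
  curve.
- **Smoothing bias.** A circular box filter of width w over an M-point
  closed curve attenuates coordinate harmonic m by
  sin(πmw/M)/(w·sin(πm/M)). The measured body radius therefore shrinks by a
  few pixels and the outer radius by slightly fewer, leaving a small
  systematic surplus in a_0 (≈1–2 % at the default geometry) and a slight
  attenuation of b_1 (regression slope of measured on true bias ≈0.99).
  This bias is a property of the smoothing step itself, shared by any
  implementation of the method; the overlay rendered by `render` is
  likewise offset by a few pixels from the pre-smoothing contour, so its
  fidelity is asserted against the measured (smoothed) boundary.
- **Degenerate inputs.** Empty masks raise immediately for single
  operations; the batch driver logs per-file failures and continues. A
  zero-outgrowth explant yields OG = 0, an all-zero coefficient table and
  undefined (null) bias and GR rather than an error.

## The synthetic generator

`synthetic_explants` rasterises explants from explicit ground truth: a
filled ellipse body (default semi-axes 250 × 225 px in a 1024×1024 image,
about the size of a 0.5–1 mm DRG explant body at 2.58 µm/px), an outgrowth
annulus bounded by r_body(θ) + R_true(θ) where R_true is a truncated
order-2 series plus band-limited noise (harmonics 3–8, total amplitude
budget 8 px, random phases), optional debris discs placed clear of the
outgrowth, and an optional fluorescence-like 16-bit rendering (bright soma,
multiplicative speckle on the halo, Gaussian background) whose thresholding
recovers the neurite mask. Rasterisation is a per-pixel polar test sharing
no code with the measurement path, so parameter-recovery tests are not
circular. Body semi-axes were chosen large enough that the fixed
150-sample smoothing window is small relative to the boundary length
(~1400 samples), keeping the smoothing surplus in a_0 within ~2 %; much
smaller bodies make the window a large fraction of the curve and inflate
a_0 materially — worth remembering when applying the method to small
explants at coarser scales.

The `ResponseModel` used by `generate_dataset` is phenomenological: mean
outgrowth follows a bell on log10 concentration (peak near 1 nM, the
effective window of NGF), mean bias scales linearly with gradient steepness
under a similar bell, and between-explant dispersion is Gaussian
(SD 12 px outgrowth, 0.05 bias). These are test-fixture parameters — they
emulate the qualitative shape of real dose–response data, not any measured
values. Consequently, passing recovery tests demonstrate the correctness of
the *measurement* under the generator's assumptions (star-shaped halos,
clean binary masks, known gradient axis); they say nothing about
segmentation quality, non-star-shaped outgrowth (overhanging or looping
neurites), anisotropic debris touching the halo, or gradient axes not
aligned with the image rows, none of which the generator emulates.

Per-explant random streams are seeded by hashing (dataset seed, steepness,
concentration, replicate), so any file is bit-reproducible independently of
generation order.

## Problem sizes in the validation suite

Parameter-recovery statistics use 200 explants spanning biases in
[−0.3, 0.3] at the default image size, the plateau null uses 50
steepness-0 explants, and the ladder in `scripts/acceptance.py` uses 80;
these sizes give standard errors comfortably below the tolerances they are
tested against (e.g. SEM of the plateau mean bias ≈ 0.007 against a ±0.02
band).

## Known limitations

- Thresholding raw images into masks is out of scope: the original masks
  were drawn with per-image thresholds that are not recoverable, so the
  package consumes masks as given (any non-zero value is foreground).
- The per-condition concentration correction factors applied when plotting
  dose–response summaries are distributed with the original dataset and are
  not bundled; `summarize` accepts them as a user-supplied table and
  otherwise uses nominal concentrations, with a log note.
- Condition levels are inferred from the files present rather than
  hard-coded, so irregular grids are handled but typos in filenames create
  spurious conditions.
- Sub-pixel contour extraction (marching squares) is deliberately not used;
  the method is defined on pixel-chain boundaries.
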