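# Methods

`zincolor` implements the quantitative readout of a pigment-based
whole-cell zinc biosensor. Engineered *E. coli* sensor cells report the
zinc concentration of a 25%-serum reaction through the pigment they
accumulate: the purple pigment violacein at low zinc, the red carotenoid
lycopene at intermediate zinc, and the orange carotenoid β-carotene at
high zinc. After incubation the cells are pelleted, photographed against
white paper, and the pellet colors are converted into a serum-zinc
estimate. This note records the models, the defaults and their
rationale, and what the synthetic-data pipeline does and does not show.

## Forward model of the pigment circuit

The circuit is modelled phenomenologically, not mechanistically. With
inducer (IPTG) present, the pigment levels at well zinc concentration
*z* (µM) are

    V(z) = v_max · k_vio^n / (k_vio^n + z^n)          (repressive Hill)
    B(z) = c_tot · z^m / (k_crty^m + z^m)             (activating Hill)
    L(z) = c_tot − B(z)

so total carotenoid is conserved (`L + B = c_tot`), violacein is
strictly decreasing in zinc and β-carotene strictly increasing. Without
inducer all pigments are zero — a colorless pellet signals a failed or
incomplete test, and the scoring stage flags such off-palette colors via
its residual gate.

Defaults: `v_max = 0.5` (OD-normalized absorbance units),
`c_tot = 1.0` (a.u.), `k_vio = 1.5 µM`, `k_crty = 5 µM`, Hill
coefficients 4. These place the purple→red class switch of the
*noiseless* rendered pellet between 1 and 2 µM and the red→orange switch
near 5 µM, the qualitative transition windows of the sensor this package
targets. No quantitative dose-response fit underlies them — the
parameters are explicit placeholders, grouped in the `circuit:` section
of the config, and every downstream stage treats them as configurable.

## Optical model and rendering

Pellet color is produced by subtractive Beer–Lambert-style mixing in
8-bit sRGB: channel *c* of a pellet with pigment vector *p* is

    clamp(round(background_c · gain_c · exp(−Σ_k A[k,c] · p_k)), 0, 255)

where `A` is a 3×3 matrix of effective per-pigment, per-channel
extinction coefficients. No gamma linearization is applied anywhere;
the pipeline deliberately works on raw sRGB bytes, because that is what
a phone camera app reads out of a JPEG, and the per-image calibration
standards absorb the (shared) nonlinearity.

The default `A` is an artifact constant, not a measured spectrum. It was
chosen under four constraints: pure violacein renders in the purple hue
band, pure lycopene red, pure β-carotene orange; the rendered color
locus over 0–10 µM stays close enough to its piecewise-linear chords
that a noiseless mid-range test reaction (2.5 µM against standards
{0, 1, 2, 3.5, 5} µM) inverse-predicts within 0.1 µM; the color score
(below) is monotone in zinc; and score-space and pigment-space
classifications agree along the noiseless locus except at the
discretized boundary crossings. All four are enforced by tests.

Rendering places a disc (Euclidean distance ≤ radius, 0-based
(row, col) coordinates) of the pellet color on the background and adds
i.i.d. per-pixel, per-channel Gaussian noise (σ = 3 channel units by
default) inside the disc only, rounded and clamped to [0, 255]; the
background is left exact, standing in for the light-controlled imaging
box that suppresses background variation in the field protocol. Renders
are seeded and bit-reproducible; a six-tube image derives per-pellet
noise streams from one master seed via `numpy` seed sequences.

The generator emulates: known pellet geometry, zinc-dependent pellet
color, sensor noise, and the five-standards-plus-test layout. It does
not emulate: pellet texture and meniscus highlights, uneven
illumination, white-balance drift between photos, off-center or
partially smeared pellets, serum matrix effects, or growth/lyophilization
variability. Passing the recovery tests therefore demonstrates that the
*readout algorithms* are correct and noise-stable, not that the assay
achieves this accuracy on real photographs.

## Color extraction

`crop_zoom` and `mean_rgb` replicate the two-tap selection flow of the
companion phone app: a 200×200 px zoom around the coarse tap, then the
arithmetic per-channel mean (float64) over the 20×20 px window around
the refined center. A window of side *w* centered at pixel *c* covers
the half-open range `[c − w//2, c − w//2 + w)` per axis, giving an even
20-px window an unambiguous 400-pixel footprint. At image edges windows
are clipped, never padded, and the surviving pixel count is reported so
clipping is visible downstream.

## Color score

A pellet RGB triple is scored on a 0–4 purple→red→orange scale by
orthogonal projection onto a piecewise-linear polyline through reference
anchor colors, interpolating the anchor scores along the projected
segment (equivalent to arc-length interpolation within a segment) and
clamping to [0, 4]. Every anchor maps exactly to its own score; the
Euclidean distance to the projection is reported as a residual, and
residuals above a configurable gate (default 60 channel units) log a
warning — the signature of an off-palette, e.g. colorless, pellet.

Class bands: scores in [0, 1.5) are purple, [1.5, 2.5) red, [2.5, 4]
orange. Boundary scores assign upward (exactly 1.5 is red), making
purple the strict class, consistent with the strict pigment-space rule:
samples with OD-normalized violacein strictly above 0.2 are purple,
otherwise the dominating carotenoid decides (lycopene ≥ β-carotene is
red, else orange).

The default anchors sit on the default forward model's rendered locus at
the class-relevant zinc values (0 µM for score 0, the violacein = 0.2
crossing for 1.5, 3 µM for 2, the lycopene = β-carotene crossing for
2.5, and the high-zinc asymptote for 4). They are artifact constants:
the survey color bar from which the assay's perceptual thresholds were
originally derived is not published, so users who possess a measured
color bar should supply their own anchors in the config to reproduce
their instrument exactly.

## Calibration and inverse prediction

Each image carries its own calibration: per-channel piecewise-linear
curves through the standards' (zinc, mean channel) nodes, with duplicate
zinc values averaged. Piecewise-linear was chosen over any parametric
form because five nodes cannot safely support more parameters and the
per-image standards already absorb run-to-run variation.

The test reaction's zinc is the joint three-channel least-squares
solution along the calibration locus:

    ẑ = argmin_z ‖ observed_rgb − (R(z), G(z), B(z)) ‖²

found by dense grid search (step 0.01 µM, well below biological
resolution) refined by bounded local minimization, ties broken toward
smaller zinc. Joint inversion is used instead of inverting each channel
separately and averaging because individual channels need not be
monotone through the purple→red→orange sequence, while the RGB locus
parameterized by zinc is a well-defined curve. Estimates at a domain
endpoint with the distance still decreasing outward are clamped and
flagged `extrapolated`, never silently extended.

Known limitation: with the steep default Hill switches the locus is
nearly flat below ~1 µM (violacein barely moves), so noiseless tests at
0.5 µM project toward 0 µM. This is a property of the assay's color
response, not of the solver; it does not affect the serum-status call at
the default thresholds because the whole flat region is deep inside the
"low" band.

## Serum conversion and status

The reaction runs 200 µL at a 25% serum fraction (50 µL serum via a 1:4
fixed-volume dilution), so serum zinc = well zinc / 0.25; the clinically
relevant serum range of 2–20 µM maps to 0.5–5 µM in the well. The
estimate is classified low / borderline / high against serum-zinc
cutoffs. The defaults (10 and 13 µM) are placeholders — the applicable
clinical cutoffs are population- and guideline-specific and must be
confirmed in the config; boundaries assign upward.

## Verification problem sizes

The recovery experiment used by the test suite and the acceptance script
simulates 200 six-tube assays (pellet radius 16 px on an 80×360 px
image, noise σ = 3) with test zinc drawn uniformly from the 0.5–5 µM
well range, and measures the median absolute zinc error and the
three-band serum-status accuracy against the generating truth. Two
hundred replicates give the median a standard error of roughly 0.005 µM
here, ample for the 0.25 µM check, while keeping the whole suite in the
seconds range.
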