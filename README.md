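# zincolor

Quantitative readout for a pigment-based whole-cell zinc biosensor.

Engineered sensor bacteria report the zinc concentration of a serum
sample through visible pigments: violacein (purple) at low zinc,
lycopene (red) at intermediate zinc, and β-carotene (orange) at high
zinc. A field test runs 200 µL reactions at 25% serum — five standards
of known zinc alongside one test reaction — pellets the cells, and
photographs all six tubes against white paper. `zincolor` turns such a
photograph into a serum-zinc estimate and a low/borderline/high status
call, and ships a seeded forward model that simulates the whole assay so
every stage can be tested end to end without laboratory data.

The package is aimed at developers of colorimetric point-of-care assays:
it is the desk-side counterpart of a smartphone readout app, with the
same two-stage pellet selection (200×200 px zoom, 20×20 px averaging
window) made scriptable and deterministic.

## The model in brief

**Forward model.** With inducer present, pigment levels at well zinc
*z* follow Hill switches — `V(z) = v_max·k_v^n/(k_v^n + z^n)` for
violacein and `B(z) = c_tot·z^m/(k_c^m + z^m)` for β-carotene, with
lycopene `L = c_tot − B` — and pellet RGB is subtractive
(Beer–Lambert-style) mixing against a white-paper background:
`channel_c ∝ exp(−Σ_k A[k,c]·p_k)`.

**Scoring.** Pellet RGB is projected orthogonally onto a piecewise-linear
palette polyline spanning purple (0) → red (2) → orange (4); scores in
[0, 1.5) are purple, [1.5, 2.5) red, [2.5, 4] orange. Samples with
direct pigment measurements classify in pigment space instead:
OD-normalized violacein > 0.2 is purple, otherwise the dominating
carotenoid decides.

**Quantification.** Per-channel piecewise-linear calibration curves are
fitted through the standards' (zinc, mean RGB) nodes, and the test
reaction's zinc is the joint least-squares solution
`ẑ = argmin_z ‖rgb − (R(z), G(z), B(z))‖²` along the calibration locus.
Serum zinc is `ẑ / 0.25` (the 1:4 dilution undone: the 0.5–5 µM well
range corresponds to 2–20 µM serum) and is classified against
configurable clinical cutoffs.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Simulate a six-tube assay photo (standards {0, 1, 2, 3.5, 5} µM, test
reaction at 2.5 µM well zinc, per-pixel noise σ = 3) and quantify it:

```sh
zincolor simulate --out demo --seed 42
zincolor quantify --image demo/assay.png --layout demo/layout.csv --out demo/report
```

which prints

```
assay zinc: 2.59 uM | serum zinc: 10.37 uM | status: borderline
```

The true test concentration is 2.5 µM in the well, i.e. 10 µM serum —
exactly on the default low/borderline cutoff — and the estimate lands
0.09 µM above it, correctly on the borderline side. `demo/report_tubes.csv`
holds the per-tube extraction and scoring, e.g.:

```
tube_id,role,zinc_uM,center_row,center_col,window_side,n_pixels,r_mean,g_mean,b_mean,score,label,residual
S1,standard,0.0,40,40,20,400,118.9325,38.1425,85.0875,0.0,purple,0.180...
S3,standard,2.0,40,152,20,400,176.6225,54.995,90.895,1.688...,red,3.386...
```

S1 (no zinc) scores 0.0 — the purple end of the scale — and the 2 µM
standard has just crossed the purple/red boundary at 1.5, as expected
for a sensor whose violacein off point lies between 1 and 2 µM. The
`residual` column is the RGB distance to the palette locus; large values
flag off-palette (e.g. colorless, failed-test) pellets.

The same pipeline is available as library calls (`simulate_assay_images`,
`mean_rgb`, `score_from_rgb`, `fit_calibration`, `predict_zinc`,
`quantify_image`); CLI outputs are bit-identical to the direct calls.

## Configuration

Every constant — circuit parameters, optics, palette anchors, class
thresholds, assay volumes, serum cutoffs, ROI geometry — can be
overridden from a single YAML file passed via `--config`; see the
schema in `src/zincolor/config.py`. The default serum cutoffs (10 and
13 µM) and circuit dose-response parameters are explicit placeholders
that users should confirm for their own deployment.
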