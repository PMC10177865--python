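# Methods

`emt-phenotyper` quantifies where a cultured cell population sits on the
epithelial–mesenchymal axis from three independent observables and merges
them into one phenotype model. This note records the model, the numerical
conventions, the synthetic-data design and the open design choices.

## Shape factors

Two dimensionless factors summarize morphology:

- **Nuclear circularity** `C_N = 4πA / P²` of the segmented nucleus outline
  (area `A` in px², perimeter `P` in px). `C_N = 1` for a perfect circle;
  ellipsoid deformation lowers it.
- **Cellular aspect ratio** `A_R = d_min / d_max`, the minor over major full
  axis of the cell body. Cobblestone-like epithelial cells sit near 1,
  spindle-shaped mesenchymal cells near 0.

Both are scale-invariant, so pixel size never enters the analysis (TIFFs
carry a conventional 0.2 µm/px tag purely as metadata).

**Perimeter convention.** `P` is the polygon length of the marching-squares
contour (level 0.5) extracted from a σ = 1 px Gaussian-smoothed copy of the
binary mask. Raw pixel-edge counting or raw marching squares on a binary
mask overestimates circle perimeters by ~5–20 %, which would push the
circularity of a digital circle to ≈ 0.90 instead of 1. The smoothed
contour is within ~0.5 % of the analytic perimeter for radii ≥ 10 px
(`|C_N − 1| ≤ 0.01` for r ≥ 20 px, verified against the closed-form circle
and elliptic-integral ellipse perimeters). The convention is fixed and is
not a tuning parameter.

**Axes.** `d_min`/`d_max` are the full axes of the moment-equivalent
(fitted) ellipse of the object mask — exact for elliptical objects and an
objective, reproducible stand-in for manually drawn axes. Whether manual
axes would include thin protrusions is unknowable from mask moments; the
fitted ellipse is our proxy and is stated as such.

**Segmentation.** Gaussian smoothing (σ = 1 px) → global Otsu threshold →
8-connected labelling → objects under `min_area_px` (default 50) removed.
A contrast guard (foreground–background class separation must exceed 4
background SDs) rejects blank noise-only frames, where Otsu would otherwise
label half the pixels. The nucleus channel additionally splits touching
objects by watershed on the (smoothed, σ = 2) distance transform with peak
markers ≥ 12 px apart; smoothing prevents elongated nuclei, whose
distance-transform ridge is nearly flat, from over-splitting.
Border-touching objects are flagged and excluded from summaries. `C_N` is
clipped at 1.0 (digitization can overshoot); clips are logged.

## Wound-healing migration

Gap closure follows the standard scratch-assay definition
`closure(t) = (1 − area_t / area_0) × 100`, identically 0 at t₀ and 100
when the gap is gone; negative values (widening) are returned and logged,
never silently clamped.

**Cell-free area detector.** The lawn/gap decision is texture-based: a
local-variance filter (default 10 px window) on the frame, Otsu threshold
on the log-variance map, and the largest connected low-variance component
is the gap (holes filled, islands under `area_threshold_px2` = 64 removed).
Two corrections matter:

- *Boundary bias*: windows straddling the lawn edge have high variance, so
  the detected gap is eroded by ~half a window per side; the component is
  dilated by `window // 2` before the area count. Validated against
  generator ground truth: ≤ 2 % area error for gaps wider than the window.
- *Unimodal frames*: when the high/low variance class ratio is < 10 the
  frame has no gap boundary at all, and is classified wholesale by texture
  contrast — median local SD over median intensity < 5 % means an all-gap
  (smooth) frame, otherwise fully confluent (area 0).

Gaps narrower than the window are undetectable and report area 0; with the
default 4 h frame interval this can place full closure up to one frame
early, which is inside the stated t_closure accuracy (one frame interval).

`t_closure` is the first time the closure curve reaches the level (default
100 %), linearly interpolated between flanking frames; never reaching it
yields a censored marker. The apparent velocity is `ν_a = 100 / t_closure`
%/h when closed; for censored series the least-squares slope of the closure
curve is reported instead and explicitly flagged — the two estimators are
never mixed silently. Replicate images of the same gap are averaged at the
area level before closure is computed.

## Marker quantification

Band intensities are normalized to the GAPDH housekeeping band:
`E = CDH1/GAPDH`, `M = VIM/GAPDH`; fold changes are relative to the
untreated control. The marker balance is `M/E` (and its reciprocal `E/M`),
with `me · em = 1` enforced wherever both are defined. A zero denominator
(e.g. an E-cadherin-negative mesenchymal line) marks the ratio *undefined*
rather than substituting an epsilon, so downstream plots can render
"undefined" honestly. qPCR uses `ΔCt = Ct_target − Ct_housekeeper` and
relative expression `2^−ΔCt` (GAPDH housekeeper for mRNA, miR-191 for the
miRNA panel); technical replicates are averaged at the Ct level before ΔCt,
since per-replicate exponentiation would bias the mean upward.
Densitometry from gel images and efficiency-corrected qPCR models are out
of scope; intensities and Cts enter as numbers.

## Phenotype model

Per condition, the record is (mean `C_N`, mean `A_R`, `M/E` or `E/M`, and
optionally `ν_a`). Ordinary least squares of `A_R` on `C_N` over the
untreated control conditions gives the **regression diagonal** (slope,
intercept, R²) — the EMT axis along which conditions move. The regression
direction (A_R on C_N, no errors-in-variables treatment) matches the use of
`C_N` to predict `A_R`; predictions are returned unclipped with an
out-of-range flag when outside (0, 1], because the diagonal is a
diagnostic, not a simulator.

**Classification** (all cutoffs configurable):

- **M** — `A_R < 0.45` and the mesenchymal marker dominates (`M/E ≥ 1`, or
  M/E undefined-high because E-cadherin is absent while vimentin is
  present).
- **E** — `A_R ≥ 0.6` and `C_N ≥ 0.8` (inside or above the epithelial
  bands 0.6–0.8 and 0.8–0.9) with the mesenchymal marker essentially
  absent (`M/E ≤ 0.05`).
- **E/M** — markers present but neither extreme matched.
- **unclassified** — missing shape or marker inputs.

The epithelial bands follow the reference epithelial lines; the mesenchymal
cutoff 0.45 interpolates between the mesenchymal reference (`A_R ≈ 0.24`)
and the epithelial band floor (0.6), and the `M/E ≤ 0.05` "absent" margin
accommodates noisy near-zero vimentin signals. All three are interpretive
defaults, not measured constants. Note that a population whose mean `C_N`
sits exactly at the 0.8 band edge (the MCF7-like preset targets 0.801) can
legitimately fall on either side under sampling noise and flip between E
and E/M; this is a property of hard thresholds near a boundary, not a
defect.

The exported bubble map plots `A_R` against `C_N`, bubble area ∝ marker
ratio (M/E for EMT induction, E/M for MET), color ∝ `ν_a` (yellow =
fastest), grey for records without migration data, with the control
diagonal dashed. CSV/JSON outputs are deterministic for fixed input.

## Synthetic data

The generator produces every input with exact ground truth, so each stage
is tested end to end without deposited images.

**Cell scenes.** Cells are filled ellipses (actin channel) with concentric
nuclear ellipses (nucleus channel, 0.45× linear scale) at random
orientations, 16-bit with additive Gaussian noise. Ellipses were chosen
because both shape factors have closed forms for them: the ground-truth
table lists exact axes, areas, elliptic-integral perimeters, `A_R` and
`C_N` per cell. `A_R` is drawn from a truncated normal on (0.05, 1] and
`C_N` on (0.2, 1]; the underlying location parameter is solved (Brent) so
the *truncated* distribution's mean equals the requested target. This
matters for spindle-shaped populations (target 0.240 ± 0.157), where naive
truncation would inflate the sample mean by ~0.03 and break mean-recovery
guarantees; the solved parameterization recovers targets within 2 SE by
construction (the requested SD is attained only approximately under strong
truncation). Placement rejects overlap against a rasterized occupancy map
with 4 px clearance — enough that σ = 1 segmentation smoothing cannot
bridge neighbors — and cluster members are proposed at bounding-circle
contact plus 3 px, giving visually contiguous islands with guaranteed
disjoint masks. Named presets (`epithelial`, `hybrid`, `mesenchymal`)
carry the shape-factor means/SDs and clustering tendency of the reference
breast-cancer lines.

What the scenes do *not* emulate: overlapping/confluent sheets, protrusions
and non-elliptical outlines, intensity gradients, uneven illumination.
Passing tests therefore demonstrate correctness of the measurement chain,
not robustness to every real-microscopy artifact.

**Wound series.** A centered vertical gap of programmable initial width
shrinks by `2 · edge_velocity · Δt` per interval (one front per side),
floored at 0; true gap area is recorded per frame. The lawn is smoothed
speckle (grain 2 px, SD 300 on a 1000 baseline) and the gap carries only
sensor noise (SD 20), which makes the variance detector well-posed. Cell
fronts advance uniformly — no finger-like protrusion of real wound edges.

**Marker tables.** Band intensities are baselines × programmed fold ×
lognormal noise of unit mean and given CV; Ct tables add Gaussian noise to
`housekeeper + ΔCt`. Noise-free tables round-trip exactly through the
quantification stage, which is asserted in tests.

All generators are seeded (`numpy` `default_rng`) and bit-identical under
a fixed spec.

## Problem sizes and defaults

Scenes default to 40–60 cells at 1024² px (cell equivalent radius
28 ± 3 px), chosen so nuclei (≈ 12 px semi-axis) are comfortably above the
segmentation size floor and a full four-condition demo panel remains a
seconds-scale computation. The demo's closure times (104/96/52/32 h, 280 px
gap, 4 h frames) reproduce the relative migration speeds of the four
reference lines (epithelial ≈ baseline, hybrid ≈ 2×, mesenchymal ≈ 3×
faster). Property tests that need tighter geometric margins use a 400 px
gap in a 600 px frame so the per-frame front advance exceeds the detector's
10 px resolution limit at the slowest (96 h) closure.

## Known limitations

- The control-diagonal coefficients depend on which conditions are declared
  controls; with only four control points the fit is fragile (R² ≈ 0.6) and
  small measurement shifts move the slope by ~0.2. Published coefficients
  from a different (larger) control set are therefore not a correctness
  oracle, only a concordance reference.
- The texture detector assumes the gap is the *largest* smooth region;
  large smooth debris would be misread as gap.
- Classification near band edges is intentionally hard-thresholded; users
  wanting soft assignment should read the continuous record fields instead
  of the class label.
- Real-image robustness (illumination fields, clumped nuclei, partial
  confluence) is outside what the synthetic suite can certify.
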