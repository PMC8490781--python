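# Methods

`tempsub` implements temporal digital subtraction of paired single-slice
brain MR images: a baseline ("original", t1) and a follow-up ("current",
t2) acquisition of the same patient are registered, subtracted, and the
interval change is segmented, colour-coded and measured. This note
records the models, conventions, numerical choices and limitations; the
README covers usage.

## Working raster and conventions

All stages operate on an `ImageGrid`: a 2-D float raster, row-major with
row 0 at the top, 0-based indices, x rightward and y downward. Physical
measurements derive from an isotropic `pixel_spacing` (mm/pixel) and a
`slice_thickness` (mm). Inputs (DICOM, NIfTI, PNG/TIFF) are resampled
bilinearly to a square working raster — 512×512 by default, the
conventional matrix size for this kind of subtraction work — and
intensities are min–max rescaled to [0, 255]. A constant image maps to
all-zeros with a warning rather than erroring. The interpolation and the
intensity standardisation are both configurable because acquisition
protocols vary and no single choice is canonical.

## Registration

Registration corrects the global misregistration between the two
acquisitions before subtraction. Misregistration in serial head imaging
is commonly classified into four causes — brain expansion, lateral
inclination, inclination and rotation — and we model it as a global
translation plus an in-plane rotation-like component.

**Global shift.** A template cut from the original image (by default the
central half-side block) is matched against a window of the current
image dilated by a search radius (±15 px by default) using normalised
cross-correlation (NCC). The production path uses FFT-based NCC
(`skimage.feature.match_template`); the test suite holds it to exact
integer agreement with an independently coded exhaustive-search oracle.
Ties resolve to the smallest |dtx|+|dty|, then lexicographically.
Optional parabolic sub-pixel refinement interpolates the NCC peak.

**Rotation.** A grid search (±10° in 0.5° steps by default) over rigid
rotations about the image centre, minimising the sum of squared
intensity differences over the brain mask, ties broken toward 0°.

**Twirl warp.** The non-linear regional correction is a decaying
rotation in polar coordinates about a centre (x_C, y_C): an output pixel
at radius r ≤ r_max samples the input at the same radius but at polar
angle advanced by α·(r_max − r)/r_max — the full angle α at the centre,
linearly decaying to zero at r_max — and pixels beyond r_max are copied
unchanged. The map is evaluated inversely (output → source) with
bilinear interpolation, the standard construction for gap-free
resampling. `atan2` provides the quadrant-correct polar angle. We allow
r_max = ∞ as the rigid-rotation limit (decay factor 1 everywhere); the
default r_max fit grid is {size/4, 3·size/8, size/2, ∞}. Without the ∞
entry a twirl with finite r_max cannot represent the rigid rotation that
the phantom's "rotation" misregistration class actually applies, and the
fitted α would be biased upward to compensate for the radial decay.

**Fitting.** Shift and rotation estimates are coupled: a rotation biases
the NCC peak (high-contrast features pull the correlation), and an
uncorrected shift biases the rotation search. `register` therefore
alternates the two (up to 3 rounds, usually 1–2), re-matching the
template against the *forward-rotated* original so the residual template
mismatch is a pure translation, and keeps every visited (α, shift) pair
as a candidate. Candidates are scored by intensity RMSE over the brain
mask (pixels above 5% of the original's maximum), and a non-identity
transform is accepted only if it improves the running best by at least
5% relative — otherwise genuine lesion change (growth) can masquerade as
motion through marginal residual gains. The identity transform is always
in the pool, so registration can never increase the residual. How the
warp parameters should be chosen per case is genuinely open; residual
minimisation over a grid is our procedure.

## Subtraction and overlay

The subtraction image is warped-current − original (growth positive).
Display enhancement maps the signed difference to [0, 255] with zero at
mid-gray 128; the window half-width defaults to the 99th percentile of
|difference|. The negative and positive half-ranges get separate slopes
(128/W and 127/W) so that 0 → 128 and ±W → {0, 255} hold exactly — a
single slope cannot satisfy all three endpoint conditions on an integer
display scale. An optional CLAHE pass adaptively equalises the window
output.

The progression overlay renders difference ≥ +τ in pure green (new or
progressive signal) and ≤ −τ in pure red (signal present only at
baseline) over the enhanced grayscale, after removing components smaller
than `min_area` (default 25 px at 512×512). The default threshold is
τ = max(3·1.4826·MAD(difference), 0.5): three robust noise standard
deviations, floored at half an intensity unit so the threshold stays
positive on noiseless synthetic input. No published value exists for
this threshold; it is entirely our choice and is exposed in config.

## Segmentation

Thresholding is the classic iterated mean-of-class-means scheme:
partition pixels at T, set T1 = (h1 + h2)/2 from the two class means,
repeat while |T − T1| ≥ ΔT (default 0.5 on the 0–255 scale); pixels
exactly at the final threshold go to the upper class. T0 defaults to the
population mean. Termination is guaranteed: over a finite intensity
multiset the threshold sequence either converges or cycles, and a
detected cycle stops with the cycle mean. `segment_abnormality` applies
the scheme hierarchically: a first pass on the whole image separates
head from background (anti-aliased/partial-volume edge pixels fall below
this split), and a second pass within the extracted head separates the
hyperintense abnormality from normal parenchyma. A single global pass
would lock onto the head/background split and report the whole brain as
one region.

ROI features come from 8-connected components with area ≥ `min_area`
(default 25 px, suppressing noise speckles): moment-fitted ellipse axes,
and the Feret (maximal caliper) diameter computed as the largest
pairwise distance between boundary *pixel centres* (convex-hull
accelerated). The pixel-centre convention makes a 10×10 square's Feret
diameter √(9²+9²) ≈ 12.73 px, which is what the tests freeze.

The five interval-change features reported per ROI pair are Δarea,
Δmean intensity, ΔFeret diameter and the two centroid displacements —
current-image values minus original-image values. Which five features a
temporal reading should use is not standardised; this set is our choice.

## Measurement

Tumour volume uses the ellipsoid-from-diameters formula. Two conventions
are implemented: `classic`, V = L·W·H·π/6 ≈ 0.5236·L·W·H (the default),
and `printed`, V = L·W·H·0.52·6/π ≈ 0.9931·L·W·H, the literal form some
published tumour-volume tables print — almost certainly a typographical
corruption of 0.52·L·W·H, which is numerically the classic factor. Every
measurement records which convention produced it. The reported ROI
diameter is the maximal Feret diameter in cm; the out-of-plane height
for single-slice data is the slice thickness (5–6 mm typical).

Progression is dV = V(t2) − V(t1), labelled progression/stable/
regression by sign. Cohort summaries report the median (midpoint rule
for even n), min, max and median absolute deviation; a parenthesised
"±" dispersion is deliberately not reproduced because its defining
statistic is ambiguous in the source tables. Registration accuracy is
validated with the RMSE √(Σ(P_i − O_i)²/n) between predicted and
observed translations, in mm.

The package embeds a five-patient reference table of diameters, volumes
and translation RMSEs (`tempsub.reference_data`) as fixed numeric
fixtures; the acceptance checks recompute that table's arithmetic
(progression column, cohort medians 3.03/2.09 cm³, diameter deltas,
translation-RMSE range 0.13–1.03 mm) from the per-timepoint values. One
row (patient 5's current-image diameter delta) is internally
inconsistent in the source and is excluded from assertions.

## ROI-weighted SART

A standalone tomographic component: 2-D parallel-beam geometry with
detector spacing equal to the unit voxel size, exact intersection
lengths by Siddon traversal. Per ray, l_G is the geometric chord through
the grid, l_V the summed crossings over ROI voxels, and k_ROI = l_V/l_G
∈ [0, 1] (exactly 1 when the ROI is the full grid, since the full-grid
row sums of the weight matrix equal the chord length). The update is
angle-sequential with relaxation λ ∈ (0, 2], default 1:

    v_j += λ · Σ_i w_ij (k_i p_i − (Wv)_i / l_G_i) / Σ_i w_ij k_i

with i over the current angle block. Measured data are therefore ray
*means* (line integral divided by chord length); at k ≡ 1 the update is
algebraically the classic SART block iteration, which the tests verify
per-voxel against an independent dense implementation and against a
dense least-squares solution of the same system. The printed source
formula's index sets are typeset ambiguously; this normalisation is the
only internally consistent reading we found and is our decision. Rays
that miss the grid carry empty entries and k = 0 and are excluded from
updates; voxels untouched by a block are left unchanged. The component
is not coupled into the subtraction pipeline — its role there is not
defined by any published procedure we implement — and no fan-beam,
regularised or ordered-subset variants are provided.

## Synthetic phantoms

The phantom generator is the package's ground-truth data source: an
elliptical "brain" (intensity 100) on a dark background (0) carrying an
elliptical tumour (180) on an arbitrary 0–255 scale, mimicking
T1-contrast enhancement without modelling MR physics. Edges are
anti-aliased over ~1 pixel so segmentation tests are not knife-edge
sensitive. The follow-up image replaces the tumour ellipse (size, shape,
location or absence may change), then applies one of the four
misregistration classes about the image centre — radial scaling by
(1+m) for brain expansion, horizontal/vertical shear with tangent m for
the two inclinations, rigid rotation by m degrees — then a global pixel
shift, then additive Gaussian noise clipped to the intensity range,
independently on both timepoints. Identical seeds give bit-identical
output. Default geometry: 512×512, 0.45 mm spacing, 5 mm slice
thickness; tests use a 128 px variant of the same anatomy for speed.

What the phantoms do *not* emulate: multi-slice anatomy, tissue texture,
bias fields, contrast-agent kinetics, partial-volume effects beyond the
1 px edge ramp, and non-rigid anatomical change outside the tumour.
Passing the recovery tests therefore demonstrates correctness of the
algorithms under their stated model, not clinical performance on
patient images.

## Problem sizes and tolerances

Recovery experiments run on 128 px phantoms with a 64 px central
template and ±12 px search radius (shifts drawn from ±10 px), 100 seeded
trials per condition; the SART checks use an 8×8 grid with 10–18 angles
over 180°. Identity contracts are asserted below 1e-9; the twirl warp at
α = 0 and the r > r_max branch are exact by construction. The
shift-recovery criterion demands 100/100 noiseless and ≥95/100 at noise
σ = 5 (both conditions currently recover 100/100). Floating-point
comparisons against the reference tables use half a unit in the last
printed decimal.

## Known limitations

Single-slice, single-template, translation+rotation-class registration
only: no mutual-information or multi-modal matching, no 3-D deformable
models. Volumes extrapolate one slice by its thickness, so dV on real
data inherits that crude height estimate. The colour-overlay threshold
and the brain-mask fraction are heuristics exposed in config, not
estimated from data. The observer-dependent aspects of temporal reading
(diagnostic confidence, reading time, inter-reader agreement) are out of
scope by design.
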