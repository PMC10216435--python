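# Methods

`unmixlabel` implements a pipeline for assigning histopathology
ground-truth labels to pixels of hyperspectral images of breast
lumpectomy specimens, and for training and evaluating a tumor/healthy
classifier on the resulting labeled spectra. Because the clinical data
this kind of pipeline is developed on are not public, the package ships
a synthetic phantom generator that reproduces the statistical structure
the pipeline assumes, so every stage is testable end to end.

## Preprocessing

Two pushbroom cameras cover the visible (VIS) and near-infrared (NIR)
ranges. Raw intensity cubes are converted to diffuse reflectance by
flat-field calibration, `R = (raw - dark) / (white - dark)`, the
canonical correction for dark current and illumination spectrum. The
two cameras are then brought onto a common spatial grid (bilinear
interpolation, with a Gaussian anti-aliasing prefilter when
downscaling; resampling is the identity when the grids already agree).
Low-sensitivity bands at the sensor extremities are trimmed, retaining
450–951 nm (318 bands, VIS) and 954–1650 nm (210 bands, NIR). The two
spectra of every pixel are stitched into one 528-band spectrum by
adding the per-pixel difference `VIS(951 nm) - NIR(954 nm)` to the
whole NIR segment, which removes any constant inter-camera intensity
bias exactly. Finally each pixel spectrum is SNV-normalized
(`(x - mean) / sd`, sample sd with n-1), removing per-pixel
multiplicative effects of surface reflections and tissue curvature.

Ordering: calibrate → resample → trim → stitch → SNV. SNV is applied
last; the stitching offset is computed on calibrated reflectance, where
the camera bias is additive and cancels exactly.

## Linear unmixing

A pixel spectrum is modeled as a convex combination of four pure-tissue
endmember spectra — invasive carcinoma (IC), carcinoma in situ (CIS),
fat, connective tissue — plus Gaussian noise, under the abundance
nonnegativity (ANC) and sum-to-one (ASC) constraints. Endmembers are
taken from the center pixels of marked locations whose histology showed
a single tissue type. The per-pixel malignant abundance (IC + CIS)
over a 10×10 ink-mark patch forms its *tumor prediction map*.

Two constraint treatments are provided:

* **`constrained`** — the exact global minimizer of the residual on the
  unit simplex (fully constrained least squares). With C ≤ 6 classes
  the optimum is found exactly by enumerating all supports of the
  active-set KKT system (2^C − 1 equality-constrained solves) and
  keeping the best feasible candidate; no iterative tolerance is
  involved. Tests verify the solution against an exhaustive
  simplex-grid search at step 0.01.
* **`rescaled`** (pipeline default) — nonnegative least squares without
  the sum constraint, followed by normalization of the coefficients to
  sum one. SNV divides every spectrum by its own standard deviation, so
  in SNV space a noiseless mixture is an exact *conic* combination of
  the SNV endmembers whose coefficient sum carries the per-pixel scale.
  Solving in the cone and renormalizing recovers the true fractions
  exactly in that geometry, whereas a hard ASC fit is biased by the
  per-spectrum rescaling. Both modes agree to ~1e-6 on noiseless convex
  mixtures; the rescaled mode is used wherever SNV spectra are unmixed.

Numerical choices: abundances in (−1e−12, 0) are clamped to zero and the
vector renormalized; larger violations raise. A degenerate all-zero
conic fit (possible for adversarial inputs) falls back to the simplex
solver. Rank-deficient endmember matrices are rejected on construction.

## Label assignment

A ~5×5 mm ink mark (10×10 pixels at 0.5 mm/pixel) receives one binary
histology label from an H&E slide taken somewhere through the mark, but
a single representative training spectrum must be chosen among the 100
pixels. Patch extents are half-open around the mark center
(`[r−5, r+5) × [c−5, c+5)`), and the center pixel of the even-sized
patch is defined as local (5, 5) — i.e. the mark center itself. The
slice notation yields exactly 100 pixels, which fixes the convention.

* **unmixing** — argmax of the tumor prediction map for malignant
  labels, argmin for healthy labels; ties break to the first pixel in
  row-major order. This selects the pixel most likely to match the
  histology section, wherever it was actually cut.
* **center** — patch-local (5, 5), assuming the section went through
  the middle of the mark.
* **average** — element-wise mean of all 100 SNV spectra (averaging
  operates on the preprocessed, SNV-normalized cube).

Marks whose patch would cross the image border are rejected rather than
padded; the clinical protocol places marks interiorly.

## Classification and evaluation

A weighted kNN (k = 10, Euclidean, squared-inverse-distance weights)
is trained on the labeled representative spectra, one per training
mark. Test patches are classified pixel by pixel; the tumor score of a
pixel is the tumor share of the total neighbor weight, with a query
coinciding with training points decided by those points alone (majority
label; all ties go to healthy, favoring specificity). A patch is called
malignant when at least 10 of its 100 pixels classify as tumor — at
0.5 mm/pixel this mirrors the clinical re-excision criterion of > 4 mm
of tumor on the resection surface. The patch ROC score is the
tumor-pixel fraction, so a threshold sweep over the vote count yields
the patch-level ROC.

Metrics: confusion counts, sensitivity/specificity/accuracy with exact
Clopper–Pearson 95% intervals (beta quantiles), Matthews correlation
coefficient (0 returned when a marginal is zero), and trapezoidal AUC
with a Youden-J optimal cutoff. Printed-table comparisons use
round-half-up at two decimals. `recover_confusion` inverts printed
sensitivity/specificity back to the unique integer confusion matrix
given the class counts, enumerating all candidates and rejecting
ambiguous precisions.

Patient-level splitting shuffles patients, not marks, so no patient
contributes to both halves; the training share is the rounded fraction
of patients (80% by default).

## Phantom generator

One seed drives everything through named `SeedSequence` children
(endmembers / fields / noise / marks / census).

**Endmembers.** Four smooth spectral shapes (sums of 3–6 Gaussian bumps
with random centers 430–1670 nm, widths 60–240 nm) are standardized to
zero mean / unit sample sd on the stitched 528-band grid; candidates
are redrawn until pairwise |Pearson r| ≤ 0.95 and condition number
≤ 1e3. Reflectance endmembers are `0.45 + 0.12 × shape`, giving every
class the same mean and sd on the stitched grid. Because the
standardization is computed on the junction-pinned stitched spectrum
(stitching pins NIR to the last VIS band), a noiseless rendered scene
round-trips the entire preprocessing + rescaled-unmixing chain to
machine precision — this is what makes exact forward–inverse testing
possible.

**Scenes.** 40×40-pixel specimen sides at 0.5 mm/pixel. The healthy
background splits between fat and connective tissue through a smoothed
random field (`0.5 + 0.3·tanh`, so both classes are always present).
Malignant marks receive 1–2 tumor lobes with per-mark peak abundance
U(0.65, 0.95), per-lobe radius U(2.5, 3) px and radial offset
U(3.5, 5) px from the mark center; the IC/CIS split is drawn per mark.
Lobes are super-Gaussian (`peak · exp(−(r/ρ)^3 / 2)`): a near-peak
plateau with a steep front whose 10–90% transition spans ~3 px,
matching the sharply bounded bright regions with several-pixel
transitions seen in clinical tumor prediction maps. A plain Gaussian
profile cannot simultaneously give a sizable high-purity core and a
nearly tumor-free mark center, and under it the labeling strategies
become nearly indistinguishable. Tumor is capped at 0.95 so background
classes never vanish. The H&E section position within a 5 mm mark is
effectively arbitrary, so off-center (even patch-edge) hotspots are the
norm, not the exception — this is the premise that makes center-pixel
labeling unreliable. Mark slots are spaced ≥ 20 px so one mark's tumor
tail is negligible inside any other patch.

**Rendering.** Per-pixel linear mixtures of the reflectance endmembers
on each camera's full grid (5 extremity bands per side are added and
later trimmed; 328 VIS + 220 NIR bands rendered, 318 + 210 retained),
plus i.i.d. Gaussian noise and a constant NIR-camera intensity offset
(0.05) that the stitching step removes. Noise sd is stated in SNV
units (default 0.08) and scaled by the reflectance sd when rendering;
the noise is drawn as unit normals and scaled, so scenes sharing a seed
but differing in sd share a common noise realisation — recovery-error
monotonicity in sd is then a strict property. Calibration frames use a
band-ramped white (0.75–0.85) and dark (0.08–0.10); raw counts are
`dark + R·(white − dark)`, so flat-fielding inverts exactly.

**Ground truth.** The annotation mask holds the per-pixel dominant
class (argmax of the abundance fields); the histology rule labels a
mark malignant iff any IC/CIS pixel appears in the mask under the
patch — the planar analog of "any carcinoma within 2 mm below the
inked surface" (sampling depth itself is not modeled). A green-channel
proxy image (fat ≈ 0.97, connective ≈ 0.78, malignant darker) feeds
the fat/connective threshold rule: fat where green > 0.90, with the
boundary value itself assigned to connective. The generator asserts
that the rule reproduces each mark's intended label.

**Cohorts.** 95 patients × 2 marked locations by default (the held-out
20% of patients contributes ~38 locations, the scale of the clinical
test half), 27% malignant overall. Each patient's scene uses a
perturbed variant of the shared tissue shapes — bump amplitudes
jittered by a relative 0.35, centers shifted by ~35 nm — emulating
inter-patient biological variability; the endmember spectra used by the
pipeline come from a separate pure-tissue reference scene built from
the unperturbed shapes, exactly as clinical endmembers come from a few
reference patients. Endmember extraction runs through the real
preprocessing chain.

**Condition calibration.** The hotspot geometry (offset, size, peak,
front sharpness) and the inter-patient variability were calibrated so
the phantom reproduces the qualitative regime reported for the clinical
cohort: imperfect per-strategy MCCs, sensitivity-driven differences
between strategies, and the ordering unmixing > average > center. With
perfectly homogeneous patients or strictly central hotspots, all three
strategies are indistinguishable and perfect — a regime that carries no
information about the method.

## What the phantom does and does not show

The phantom shares the pipeline's model family by construction: linear
mixing, Gaussian noise, smooth endmembers, Gaussian-lobed tumor fields.
Passing tests therefore demonstrate the *internal* correctness of the
chain (calibration, stitching, SNV geometry, constrained optimization,
label selection, voting, metrics) and the *mechanism* of the labeling
advantage — not clinical performance. Real tissue adds nonlinear
photon mixing, sub-surface signal from ~2 mm depth, specular artifacts,
cauterization and blood-saturation effects, deformation of the specimen,
and ink-dispersion uncertainty, none of which are modeled. The
published clinical numbers are therefore only consistency-checked
(integer confusion matrices re-derived from the printed census and
rates), never re-measured.

## Problem sizes

Default test-time problem sizes were chosen so the full suite and the
acceptance script each run in minutes on one CPU: 40×40×528 scenes,
95-patient cohorts, 20-cohort comparisons, 100-case solver-oracle
sweeps, and an exhaustive simplex grid at step 0.01 evaluated via the
Gram-matrix form (≈ 1.8×10^5 points for four classes).

## Known limitations

* The exact-recovery construction requires equal endmember sds on the
  stitched grid; phantom endmembers are built that way, but real
  endmembers are not, so rescaled unmixing on real data is an
  approximation (as is any FCLS on SNV spectra).
* `he_label` uses dominant-class masks; carcinoma present only as a
  minority component of every pixel under a mark would be missed, a
  deliberate simplification of H&E annotation.
* The subset-enumeration FCLS is exact but exponential in the class
  count; it is intended for the ≤ 6-endmember regime of this problem.
* Patch-level ROC scores take at most 101 distinct values (vote
  counts), so phantom AUCs are step-function estimates.
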