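# Methods

## Problem setting

Late gadolinium enhancement (LGE) imaging shows fibrotic myocardium as
hyperintense, but a signal-intensity (SI) threshold must decide what
counts as scar. In non-ischemic disease the lesions are patchy and
low-contrast, so the threshold choice dominates the result. The
extracellular volume fraction (ECV), computed from T1 mapping, is a
quantitative fibrosis marker but is acquired at lower resolution and —
with common protocols — on a single mid-ventricular slice. The method
implemented here uses the ECV map as an arbiter for a per-case LGE
threshold: specific where ECV is trustworthy (the mid slice), applied
everywhere via the LGE stack.

## ECV computation (`ecvlge.ecv`)

ECV = (1 − Hct) · (ΔR1_myo / ΔR1_blood) with ΔR1 = 1/T1_post − 1/T1_pre,
reported in percent. Myocardial T1 values are per-pixel maps; blood T1
values are scalars (ROI means supplied upstream, matching standard
practice and single-slice acquisitions). Pixels with undefined T1 are
excluded via the validity mask; values outside [0, 100] % are *flagged,
not clipped*, because clipping would bias ROI means under noise. The
formula is degree-zero homogeneous in T1, strictly increasing as
post-contrast myocardial T1 falls, and zero at Hct → 1; those
invariants are property-tested.

## Contours, ROIs, segments (`ecvlge.contours`)

* Ring masks rasterize epicardial/endocardial polygons by pixel-center
  containment (0-based, x = column, y = row). Endo must lie strictly
  inside epi; degenerate polygons are rejected.
* The automatic ROI detector divides the ring into 60 angular sectors
  and scans every contiguous 5-sector arc. The minimal-mean arc is the
  **remote** ROI in full (unbiased mean/SD reference). The maximal-mean
  arc hosts the **high-SI** ROI, restricted to its 30 brightest pixels:
  clinical software drops a compact ROI on the maximal-SI area, and a
  full transmural arc would dilute a mid-wall lesion's ECV with remote
  wall, defeating the decision rule. Both sizes are configurable
  (`n_sectors`, `arc_width`, `highsi_px`; `highsi_px=None` keeps the
  full arc). Ties break toward the lowest starting sector, making the
  detector deterministic and invariant to adding a constant to the SI.
* AHA 17-segment labels: slices are split into basal/mid/apical thirds
  (slice 0 basal); basal/mid slices into six 60° sectors, apical into
  four 90° sectors. Angles are measured clockwise from image-up in the
  displayed short-axis orientation, sectors counted clockwise from the
  anterior RV insertion (default 300°), giving the order 1,6,5,4,3,2
  (basal), 7,12,11,10,9,8 (mid), 13,16,15,14 (apical). The apical-cap
  segment 17 is not assigned from short-axis rings. The convention is
  fixed and documented because source conventions vary; the partition
  property (every myocardial pixel exactly one label) is what matters
  downstream.
* LV mass = myocardial pixels × pixel area × slice thickness × density,
  density 1.05 g/mL by CMR convention.

## Thresholding (`ecvlge.thresholds`)

* n-SD: scar = myocardial SI **strictly >** μ_remote + n·σ_remote, with
  sample SD (n−1; remote ROIs are small). A zero remote SD raises a
  degenerate-threshold error rather than producing an all-or-nothing
  mask.
* FWHM: scar = SI **≥** S_max/2, S_max the maximum over the
  hyperenhanced seed ROI (default: the auto-detected high-SI ROI); a
  baseline-corrected variant thresholds at μ_remote + 0.5·(S_max −
  μ_remote). The inequality conventions (strict for n-SD, inclusive for
  FWHM) are arbitrary but fixed for reproducibility.
* Propagation: by default the selected *n* is re-applied per slice with
  per-slice remote statistics, because PSIR SI scales vary by slice;
  this makes the result invariant to slice-wise SI rescaling. Applying
  the mid-slice absolute SI threshold everywhere is available as an
  option, and is the fallback when a slice's remote ROI is degenerate.
* Artifact surrogate: in-slice connected components smaller than
  `min_component_px` (default 5, 8-connectivity) are removed — an
  automated, idempotent stand-in for the manual erasure of small
  acquisition artifacts.
* Scar percent = 100 · scar mass / LV mass; per-segment percent uses
  pixel counts within the segment as the denominator (the segmental
  denominator is otherwise underdetermined).

## ECV-guided analysis (`ecvlge.guided`)

Decision rule: the mean ECV over the high-SI ROI at or above the
cutoff (default 31.5 %) ⇒ scar scenario; below ⇒ non-scar. The boundary
is inclusive by convention. Sampling the ROI *mean* (rather than a
single pixel) is robust to map noise.

* Scar scenario: n* = argmax over the candidate grid of the Dice
  overlap between the mid-slice n-SD mask and the ECV ≥ cutoff pixel
  set. This replaces the human act of matching the delineation to the
  ECV map by eye with a deterministic overlap criterion; Dice is the
  standard choice and the metric is isolated behind one function. Ties
  go to the larger n — the conservative, smaller scar. If no candidate
  produces any pixel, the smallest n is returned with a warning.
* Non-scar scenario: n* = the smallest grid n whose mask contains at
  most `nonscar_tolerance_px` (default 0) pixels of the high-SI ROI —
  the "closest threshold that does not highlight" the bright area. If
  none qualifies, the largest n is returned with a warning.
* Grid default: 1–20 SD in steps of 0.5, covering the 3–18 SD range
  seen in practice with headroom; integer-valued selections are typical
  but the half-step grid lets the optimizer sit between them. Refining
  the grid can only improve the achieved Dice (property-tested).

A non-scar mid-slice decision can still yield scar elsewhere: the
selected threshold is propagated to all slices, and brighter lesions on
other slices survive it. This behavior is exercised explicitly by a
constructed phantom.

## Statistics (`ecvlge.stats`)

ROC points and trapezoidal AUC come from scikit-learn (equivalent to
Mann–Whitney pair counting with half credit for ties — cross-checked
against a brute-force oracle in the tests); the optimal cutoff
maximizes Youden's J, with ties resolved toward higher sensitivity and
then the lower threshold, and the rule is "score ≥ cutoff positive".
Closest-to-corner alternatives were considered and rejected in favor of
the single most common convention. 2×2 tables can be reconstructed from
printed cohort summaries (total, reference-positives, test-positives,
sensitivity) with the rounding convention tp = round(sens·n_pos);
inconsistent summaries fail naming the offending cell, and zero
denominators yield flagged NaNs, never silent zeros. Lin's concordance
correlation coefficient uses population (1/n) moments per its original
definition — sample-moment variants differ slightly, so this is pinned.
Bland–Altman limits are bias ± 1.96·SD(d) with sample SD. Display
rounding is one decimal in percent; tests compare at full precision.

## The phantom (`ecvlge.phantom`)

What it emulates: the *image structure* the analysis consumes — a ring
myocardium (annulus between concentric circles) over 8 short-axis
slices (128², 1 mm pixels, 8 mm slices, 20/30 mm radii), a bright blood
pool, per-slice contours, and a mid-slice T1 pair/ECV map; lesions are
either several compact mid-wall/epicardial patches (non-ischemic mode,
default 5 % of the myocardium over 6 patches) or one contiguous
subendocardial wedge (ischemic mode, default 25 %).

Key constructions and their rationale:

* SI model: piecewise constant (remote at `remote_si_mean` = 25, lesion
  at mean + k·`remote_si_sd`, SD = 8) plus additive Gaussian noise
  (`noise_sd`, defaulting to `remote_si_sd`). PSIR images are signed,
  so Gaussian rather than Rician noise is a stated simplification. The
  low remote mean mimics nulled remote myocardium on PSIR, which is
  what makes the uncorrected FWHM threshold meaningful.
* Lesion contrast k is drawn once per case (U(3, 18) patchy,
  U(8, 18) ischemic) unless specified — one threshold delineates one
  case's scar, implying roughly uniform within-case contrast.
* Lesion ECV: per-patch draws around 34 % truncated above the 31.5 %
  cutoff (patchy) or around 52 % (wedge); remote ECV 27.1 %. These are
  the levels observed in vivo for the corresponding lesion types.
* The T1 pair is synthesized by *inverting* the ECV formula pixelwise
  (fixed blood T1 1900/350 ms, Hct 0.42, native myocardial T1
  1300 ms), so ECV computation reproduces the specified map to machine
  precision; T1/ECV maps carry no noise — SI noise is the only
  stochastic image component.
* Truth masks record lesion pixels whose nominal ECV is at or above
  the cutoff; `truth_scar_percent` follows from the same mass
  arithmetic the analysis uses. Patch pixel quotas are hit exactly, so
  the truth fraction is exactly monotone in `target_scar_fraction`.
* Determinism: one `numpy` generator seeded from `spec.seed` drives
  every draw; identical specs produce byte-identical outputs.

What it does **not** emulate: real anatomy, through-plane motion,
misregistration between LGE and T1 grids, surface-coil intensity
gradients, partial-volume edges, or Rician magnitude statistics.
Passing phantom tests therefore demonstrates the *mechanics* of the
pipeline (thresholding, selection, propagation, bookkeeping, and their
invariances), not clinical performance on patient images.

## Problem sizes in tests and the acceptance script

The phantom experiments use 8-slice 128² phantoms; populations of 50
(patchy, fixed-2SD vs guided comparison) and 20 (ischemic, FWHM vs
guided agreement; threshold monotonicity) phantoms, 200 random draws
for the ROC oracle check. These sizes were chosen so the whole suite
runs in well under a minute while the population statistics are stable
across seeds.

## Known limitations

* The visual n-SD choice is replaced by Dice maximization against the
  ECV ≥ cutoff mask; observer-specific behavior is out of scope.
* The ECV cutoff (31.5 %) and the native-T1 alternative (1317 ms) are
  inputs, not re-derivable here: deriving them needs per-case ROI ECV
  measurements from the original cohort, which only exist as printed
  summaries. The package reproduces all downstream diagnostic
  arithmetic of those summaries instead.
* Single mid-ventricular T1 slice: the decision rule sees one slice;
  propagation extends only the threshold, not the ECV evidence.
* T1 fitting (MOLLI), motion correction, and contour segmentation are
  upstream of this package; maps and contours are inputs.
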