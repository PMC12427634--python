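# Methods

## Problem and pipeline

Lateral cervical-spine radiographs are the first-line study for degenerative
neck disease: a narrowed intervertebral space indicates disc degeneration,
and a reduced distance between a vertebral body and its neural foramen
indexes potential nerve-root compression. `cspine` automates the two pixel
measurements a clinician would otherwise take by hand, for the vertebrae C2
through C7. The pipeline is

1. **Standardize and binarize** — resize to 512×512, 3×3 median filter,
   global histogram equalization, CLAHE, then a binary mask formed as the
   logical AND of an adaptive (local-mean) threshold and a global Otsu
   threshold.
2. **Crop the spine region** — scan the binary image for the row with the
   fewest (nonzero) white pixels, expand its first/last white transitions
   through their contiguous runs, pad 50 px laterally, bound vertically by
   the first/last foreground rows inside that band, pad 50 px again.
3. **Detect** — any object with a `detect(image, frame)` method supplying
   labeled boxes (C2…C7, FORAMEN). Shipped detectors replay YOLO-format
   label files or a phantom's ground truth; training a detector is out of
   scope.
4. **Landmark and measure** — per detection box (expanded 10% per side):
   percentile contrast stretch (2/98), Gaussian blur (σ = 1), Otsu
   binarization, opening+closing with a 3×3 cross, largest 8-connected
   component. The four directional extrema of the component (arg-extrema of
   `y−x` and `y+x`) approximate the body corners regardless of tilt; the
   rounded mid-column between the two bottom (top) corners intersected with
   the lower (upper) white boundary gives the lower (upper) reference point.
   The intervertebral distance at a level is the Euclidean distance from the
   upper body's lower reference point to the lower body's upper reference
   point; the vertebra–foramen distance uses the same construction rotated
   90°, between the facing lateral boundaries.
5. **Evaluate** — greedy IoU matching to confusion counts, precision/recall,
   all-points-interpolated AP and mAP50, and Pearson correlation (PPMCC)
   tables comparing two sets of distance measurements case by case.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| `target_size` | 512 px | standard input size; all coordinates are reported in this frame |
| `median_window` | 3 | smallest window that removes impulse noise while keeping cortical edges |
| `clahe_clip`, `clahe_tiles` | 2.0, 8×8 | conventional CLAHE operating point; clip is relative to a uniform histogram |
| `adaptive_block`, `adaptive_offset` | 31, 5 | a pixel is foreground iff it exceeds its 31×31 local mean minus 5; negative offsets make the rule stricter |
| `pad_x`, `pad_y` | 50 px | crop padding; lateral value from the method definition, vertical chosen symmetric |
| `stretch_percentiles` | (2, 98) | robust contrast stretch inside each ROI |
| `blur_sigma` | 1.0 px | suppresses edge raggedness without displacing the half-maximum edge |
| `roi_margin` | 0.10 | detector boxes may clip the cortical edge that defines a reference point |
| `mm_per_pixel` | None | distances are in pixels; a physical scale is applied only when supplied |

All distances are reported in pixels of the 512×512 frame. Physical
calibration (from DICOM pixel spacing, say) is deliberately a separate,
optional scale factor.

## Numerical choices

* **Border policy** is edge replication for every windowed operation
  (median, local mean, Gaussian, ROI morphology). An implicit black border
  would create dark halos that corrupt the row-scan profile and erode
  components touching an ROI edge.
* **Otsu's threshold** maximizes the between-class variance
  ω₀ω₁(μ₀−μ₁)² over the partition {v ≤ t}/{v > t} — equivalent to
  minimizing the within-class variance ω₀σ₀²+ω₁σ₁² — with ties broken
  toward the lowest maximizer for determinism.
* **The adaptive threshold's local mean** is computed with exact integer
  separable box sums so that boundary pixels (value exactly equal to
  mean − offset) are decided without floating-point drift.
* **CLAHE** shares its lookup-table construction with global histogram
  equalization, so one tile with a non-binding clip limit reduces exactly to
  global equalization. Tile histograms are clipped at `clip·n/256` with the
  excess redistributed uniformly, and mappings are blended bilinearly
  between tile centers.
* **Half-to-even rounding** of the reference mid-column/mid-row happens in
  mask-local coordinates; rounding in global coordinates would make the
  landmark construction depend on where the ROI sits in the image. If the
  rounded column contains no foreground (possible on concave masks) the
  nearest foreground column is used and flagged in the result.
* **Degenerate inputs** fail loudly with descriptive errors: constant images
  at the Otsu stage, all-black rows or bands in the crop stage, constant or
  sub-8×8 ROIs in the measurement stage. The end-to-end pipeline records
  per-level failures in the report notes and continues with the remaining
  levels.
* **Duplicate detections** keep the highest-confidence box per vertebra
  label (ties: larger area, then input order); all foramen detections are
  kept and each is assigned to the vertebra with the nearest box center.
* In detection evaluation, **true negatives are fixed at zero** (there is no
  background class), so the reported four-count "accuracy" reduces to
  Tp/(Tp+Fp+Fn).

## The synthetic phantom

Annotated clinical radiographs are not redistributable, so correctness is
demonstrated on phantoms with analytically known geometry: six tilted
rounded-rectangle bodies (tilt ±10°, width 85–110 px, height 40–52 px)
stacked along a quadratically bowed, lordosis-like axis, separated by gaps
drawn from [5, 25] px; a posterior ellipse per level stands in for the
neural-foramen region; a mid-intensity soft-tissue band, a vertical
(cranio-caudal, heel-effect-like) illumination ramp of amplitude 20, Gaussian
noise (σ = 6) and 0.2% salt-and-pepper noise complete the image. Intensities
are background 40, soft tissue 100, bone 190.

Two generator choices deserve note. Bodies are stacked by their *rotated*
vertical extents, so the sampled gap is the true clearance between
neighbours and tilted corners never interpenetrate; consequently the
ground-truth midpoint-to-midpoint distance is at least the gap, with
equality for untilted aligned neighbours. And the illumination ramp is
vertical because a lateral ramp has no radiographic counterpart and would
systematically bias the binarized speckle — and hence the anchor-row white
run — to one side of the frame.

Ground truth (boxes, edge-midpoint reference points, facing lateral points,
and all distances) is computed from the pre-noise analytic geometry, never
re-measured from the rendered raster, so it is an uncontaminated oracle.
Shape membership is evaluated at integer pixel indices, which keeps analytic
edge coordinates and raster boundary indices within a pixel of each other.

What the phantom does **not** model: projective overlap of shoulders,
mandible or airway, trabecular texture, osteophytes or other pathology,
detector blur, and scatter. Passing on phantoms therefore demonstrates
geometric correctness and robustness to the modeled noise, not clinical
performance on real radiographs.

## Problem sizes used in the test and acceptance runs

Oracle-equivalence checks use ≥100 random instances per primitive at small
sizes (≤64×64 images, ≤20 detections). Crop coverage is measured on 200
seeded phantoms at default noise plus 50 at zero noise; distance recovery on
100 seeded phantoms per noise level; the agreement table on 5 cases of 5
levels, mirroring the five-case design of the reference analysis.

## Known limitations

* The row-scan crop assumes a single, roughly vertical spine; rotated or
  heavily collimated images are out of scope.
* The median filter rounds off single-pixel corner tips, and CLAHE shading
  can leave a fraction of a percent of interior body pixels just below the
  adaptive threshold — the zero-noise binary mask covers ≈99.8% of body
  pixels, not literally all of them.
* A blurred sharp square loses its four corner pixels at the half-maximum
  threshold; landmark constructions are unaffected because they use edge
  midpoints, not corners.
* Foramen-to-vertebra assignment is by nearest box center, which is correct
  by construction on phantoms but untested against clinical anatomy.
* Measurements are in pixels; without a pixel-spacing calibration they
  support longitudinal and relative comparisons, not absolute lengths.
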