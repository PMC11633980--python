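# Methods

`buscurate` curates clinical breast-ultrasound (BUS) screenshot datasets
before AI model training or evaluation. A BUS screenshot is an 8-bit raster
(grayscale or RGB) containing a speckle-textured *scan area* on a black
frame, plus whatever the scanner and sonographer burned into the pixels:
measurement calipers, Doppler or elastography color overlays, indicator
graphics, side-by-side comparison views, and free-text exam labels. The
package flags or removes those artifacts and extracts the labeling fields
into structured metadata. This note records the procedures, the parameters
that matter, and the choices made where the design was genuinely open.

## Coordinate and intensity conventions

All boxes are `(x_left, y_top, x_right, y_bottom)`, 0-based with the origin
at the top-left pixel and half-open on the right and bottom, so
`w = x_right − x_left` exactly. All thresholds are stated on 8-bit
intensities; deeper DICOM frames are min-max rescaled to 0–255 per frame,
and MONOCHROME1 frames are inverted so "black" always means low values.
Color images are reduced to luma (0.299 R + 0.587 G + 0.114 B, rounded)
wherever a detector needs one channel; the choice of luma over
single-channel extraction is configurable in principle but fixed here
because every shipped threshold was calibrated against it.

## Scan filtering

**Invalid frames.** A frame is invalid when more than 75% of the evaluated
area is black, where black means intensity strictly below 5. Both
comparisons are strict, so exactly 75% black is still valid. This catches
machine malfunctions, annotation-only captures, and frames dominated by a
void; it will also flag frames whose scan area is mostly a large hypoechoic
structure, which is accepted behavior.

**Non-B-mode frames** (Doppler blood-flow highlighting, elastography) are
found in four steps:

1. Chromatically flat frames (1-channel, or max per-pixel channel spread ≤
   `grayscale_tol`, default 0) are B-mode. The tolerance exists because JPEG
   chroma noise can tint genuinely grayscale frames.
2. HSV masks are built for the flow palette (red, orange, yellow, green,
   blue) and for green/white indicator graphics, then dilated with a disk of
   radius 2 — the smallest element that reconnects anti-aliased box edges.
   Hue ranges follow the 0–179 half-degree convention: RED [170–10]
   (wrapped), ORANGE [11–25], YELLOW [26–34], GREEN [35–85], BLUE [100–130],
   all requiring S ≥ 80 and V ≥ 80; the indicator mask adds a white range
   (S ≤ 30, V ≥ 220). Vendor palettes vary, so every range is a config key,
   not a constant.
3. The indicator mask is searched for box graphics and image-spanning
   lines. A box registers when a contour at least `min_rect_px` (40 px)
   large in both dimensions has ≥ 3 near-right-angle (80°–100°) vertices in
   its Douglas–Peucker approximation spreading over at least half the
   contour's extent in some axis. Two implementation details matter: the
   polygon tolerance is `min(2% of perimeter, 8 px)`, because a purely
   relative tolerance exceeds the stroke width of long thin outlines and
   collapses their corners; and the absolute 40-px floor exists because
   dilated white text glyphs otherwise form small crisp rectangles and
   would mark every annotated frame non-B-mode. A line registers when a
   run of mask pixels, tolerating gaps ≤ 5 px, spans ≥ 80% of the image
   height or width (elastography overlays draw such a line without quite
   reaching the borders).
4. Otherwise the frame is non-B-mode when the combined flow mask covers
   more than 0.5% of the scan area. The denominator is the stage-1 crop box
   when the pipeline provides one ("of the scan area", not of the frame);
   this is configurable.

## Caliper detection

The base detector enhances the luma frame: the outer 15% of every side is
set to zero (software overlays and text live near the borders), a 3×3
Laplacian-style edge filter and a 3×3 maximum filter are applied, the
result is thresholded at `binarize_threshold` and dilated with a disk of
radius 2. External contours of the binary image whose bounding boxes are
between 10 and 70 px inclusive in *both* height and width are returned as
calipers, in full-image coordinates.

Two numerical choices deserve a note:

* *Binarization.* The edge response of speckle is small but rarely zero, so
  "any nonzero pixel" binarization connects the whole scan area into one
  blob and recall collapses. The default threshold of 60 sits just above
  the speckle response ceiling of the synthetic texture (≈ 58 at the
  generator's defaults) while burnt-in marks saturate at 255. On real data
  this threshold is the first knob to revisit.
* *Boundary artifact.* Zeroing the border creates a step edge along the
  mask boundary itself; the detector erases a band of that width (plus the
  max-filter spread) from the edge image. Without this, the boundary frame
  registers as two long intersecting lines and the Hough extension below
  would fire on every image.

**Hough extension.** Dotted spanning lines that join caliper marks defeat
the size gate: after the maximum filter and dilation, dots, line and end
marks fuse into one object far wider than 70 px. The extension runs
probabilistic Hough line detection (min length 15 px, gap 4 px — the gap
bridges dotted strokes) on the same enhanced binary image and reports a
caliper when two segments differ in angle by more than 5° and their
supporting lines intersect within both segments' extents padded by 3 px.
It is **off by default**: it is the adapt-per-dataset step, to be enabled
when this annotation style appears. It should not be enabled blindly on
datasets whose scan areas have curved or slanted visible boundaries —
boundary corners are exactly two intersecting non-parallel lines.

## Dual-view detection

Side-by-side composites are detected by (1) vetoing frames whose green
mask covers more than 0.1% of pixels (elastography), (2) vetoing frames
with width < 75% of height, (3) Canny edge detection (σ = 1, hysteresis
thresholds 50/150 on the 0–255 scale), and (4) requiring the midline
column `m = ⌊w/2⌋` to hold more than 100 edge pixels and to exceed each of
columns `m ± 10` by more than 10. The test reads a single column, taking
the wording of the procedure literally; a divider that is symmetric about
a column boundary localizes its Canny edges on the two flanking columns,
so the test is sensitive to where the divider sits relative to `m`. This
is a real sensitivity of the method, not of this implementation.

## Scan-area cropping

Stage 1 thresholds pixels strictly above `mode + 10` (the histogram mode of
the luma image is the background value; ties between equally frequent
intensities resolve to the lowest), opens the mask with disk-3 erosion and
dilation to delete text strokes, and takes the tight bounding box of the
largest 8-connected component. A uniform or near-black frame leaves an
empty mask and raises a degenerate-input error that the pipeline records
as a stage failure.

The component is *rectangular* when it fills ≥ 95% of its box (tolerance
for anti-aliasing and small nicks); then the crop ends. Otherwise stage 2
tightens each axis independently from the same stage-1 box: the box is cut
into three equal bands (integer floor at h/3 and 2h/3), each horizontal
band votes with its first and last non-mode column, and the new left/right
edges are the medians (middle value, no interpolation) of the three votes;
the transposed rule gives top/bottom. A band with no non-mode pixel votes
for the stage-1 edge. The median trades a sliver of tissue at the widest
band for far less background on convex, trapezoidal and shadow-dominated
irregular scan areas. Non-mode status is judged against the global image
mode, computed once.

## Knowledge extraction

OCR is an interface: any backend mapping an image to
`(string, box, confidence)` triples. Detections below confidence 0.3 are
dropped (permissive, because the grammars reject garbage anyway), strings
are uppercased and whitespace-collapsed, and regular-expression grammars —
kept in one editable YAML vocabulary (`src/buscurate/vocab.yaml`) — map
strings to fields: laterality (LEFT/RIGHT, with CONFLICT when both sides
match across detections, flagging mislabeled or dual-view frames),
transducer orientation (RAD, ARAD, TRANS, LONG, SAG, OBL with aliases),
clock-face position (hours 1–12 only; quadrant notation is deliberately
not recognized), distance from the nipple (a number adjacent to CM plus a
from-nipple marker), axilla, lesion measurements (all other number–CM
groups, including `A x B cm` pairs), and procedural terms (biopsy, clip,
marker, coil, wire, FNA). A number–CM group is consumed by exactly one of
distance/measurement. The shipped vocabulary is a reconstruction from the
ACR BI-RADS labeling guidance and common annotation dialects, not a
transcription of any clinical site's exact strings; extending it is the
expected adaptation path.

The deterministic stub backend replays ground-truth strings keyed by image
id. It exists so the grammars can be tested exactly, with OCR removed from
the loop; a run with a real OCR engine (the optional EasyOCR adapter)
additionally measures recognition quality, which is outside this package's
control.

## Synthetic phantoms: what they do and do not show

The generator renders the full artifact taxonomy — plain B-mode areas in
four shapes (rectangle, trapezoid, convex fan, irregular/shadowed),
crosses/"X"s/numerals, dotted spanning lines (dash 4 px, gap 3 px),
scattered two-tone Doppler color in a box, green indicator
boxes/partial boxes/lines, 1-px-gap dual views, ≥ 80%-black invalid
frames, and BI-RADS-style text — each with exact ground truth, bit-exactly
reproducible from a seed.

Speckle is a clipped Gaussian field, mean 90, sd 30, spatially smoothed to
a correlation length of about 3 px. The smoothing is load-bearing: on
uncorrelated noise the Laplacian edge response saturates and no threshold
separates texture from marks, i.e. the edge-filter approach presupposes
the smoothness that persistence-filtered real B-mode has. The phantoms
share with real data the properties the detectors actually read (dark
background, textured area, saturated marks, colored overlays, a sharp
divider) and lack everything else: no point-spread function, no
attenuation or shadowing texture, no vendor UI furniture, no JPEG
artifacts, no OCR-hostile fonts. Passing the synthetic suite therefore
demonstrates the logic of each detector and the exactness of the
grammars; it does not predict clinical-data performance, where thresholds
and palettes are expected to need per-site adjustment.

Default problem sizes: unit tests render a handful of phantoms per case;
the acceptance checks use 50 phantoms per class (450 total) for the
detector-recovery floors and 50 + 50 for the dotted-line comparison, sizes
at which the binomial noise on a 0.95 floor is a few percent. Caliper
specificity is the one number with visible seed-to-seed variation
(0.92–0.96): the false positives are caliper-sized fragments of slanted or
wavy scan-area boundaries, the same failure family as the published
method's 0.933 specificity on clinical data.

## Evaluation conventions

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), F1 2tp/(2tp+fp+fn);
undefined ratios are reported as not-available, never as 0. Table output
rounds half-away-from-zero to 3 decimals; raw values stay on the objects.
A text-field prediction counts as a true positive only when the field is
recognized *and* its value matches the label exactly. In suite scoring,
caliper sensitivity is measured on plain-cross phantoms and caliper
specificity on caliper-free B-mode phantoms — caliper cleaning operates on
the population that already passed mode filtering, and dotted-line
phantoms are scored separately as the Hough extension's target.

## Pipeline

Stage order per image: invalid → crop → mode (fed by the stage-1 box) →
dual-view → calipers (± Hough) → OCR. Stages are independently
removable; the two documented couplings are the invalid short-circuit
(near-black frames skip everything else — the downstream tests are
meaningless on them) and the crop → mode denominator feed. A stage error
is recorded on the image's report row without aborting the batch.
Directory processing is lexicographic and, with the stub backend,
byte-identical across runs.

## Known limitations

* No caliper removal or inpainting: boxes are returned for user-side
  cropping decisions.
* Dual-view frames are flagged, not split into two records.
* English-language vocabulary only; extension is by editing the YAML.
* The dual-view midline test reads one column and can miss dividers
  offset from ⌊w/2⌋.
* HSV defaults, the caliper binarization threshold and the Canny
  thresholds are calibrated to the synthetic texture and are the expected
  per-dataset tuning surface on clinical data.
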