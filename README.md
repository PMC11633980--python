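# buscurate

Curation of clinical breast-ultrasound (BUS) screenshot datasets for
medical-AI pipelines.

Clinical BUS images, unlike standardized modalities such as screening
mammography, arrive full of irregularities that scan metadata does not
reveal: sonographer-placed measurement calipers, Color/Power Doppler and
elastography overlays, side-by-side dual-view composites, near-black
invalid captures, and free-text exam labels burnt into the pixels. Left in
a training set, these artifacts become shortcuts — a lesion detector that
learns to find calipers instead of lesions, or a classifier that associates
the mere presence of text with malignancy. `buscurate` is for researchers
assembling BUS datasets at a scale where manual review is impossible: it
flags or removes the artifacts and turns the burnt-in labels into
structured metadata.

## What it does

Every function is modular and independently removable; the default
pipeline runs, per image:

* **Scan filtering** — flag *invalid* frames (> 75% of the area black,
  i.e. intensity < 5) and *non-B-mode* frames, found by a four-step test:
  grayscale frames pass as B-mode; dilated HSV masks are built for the
  flow palette and for green/white indicator graphics; box fragments or
  image-spanning lines in the indicator mask mark the frame non-B-mode; so
  does a flow mask covering > 0.5% of the scan area.
* **Dual-view detection** — Canny edges; a frame is a composite when the
  midline column m = ⌊w/2⌋ holds > 100 edge pixels and exceeds columns
  m ± 10 by > 10 (after green-overlay and aspect-ratio vetoes).
* **Caliper detection** — black-mask the outer 15% per side, apply
  FIND-EDGES and a 3×3 maximum filter, threshold and dilate; every contour
  whose bounding box is 10–70 px in both height and width is a caliper,
  returned as (x_left, y_top, x_right, y_bottom) for user-side cropping.
  An optional Hough extension (off by default) catches the dotted
  spanning-line annotation style that defeats the size gate, by finding
  two non-parallel line segments whose supporting lines intersect within
  both segments.
* **Scan-area cropping** — stage 1: threshold above the background mode
  + 10, open, take the largest connected component's bounding box; stage
  2 (non-rectangular areas only): split the box into thirds per axis and
  move each edge to the median of the three band extremes of non-mode
  pixels.
* **Knowledge extraction** — OCR (pluggable backend; a deterministic stub
  ships for testing, an EasyOCR adapter is optional) followed by
  regex grammars for the ACR BI-RADS labeling fields: laterality,
  clock-face position (1–12 o'clock; quadrant notation deliberately not
  recognized), transducer orientation, distance from the nipple in cm —
  plus axilla, lesion measurements and procedural terms (biopsy,
  clip/marker/coil). The vocabulary is one editable YAML file.
* **Synthetic phantoms** — a generator that renders every artifact class
  with exact ground truth, so the whole pipeline is testable without
  clinical data.
* **Evaluation** — confusion matrices, sensitivity/specificity/F1 per
  binary task; text-field true positives require the value to match
  exactly, not just text to be found.

## Worked example

Generate a labeled synthetic suite (45 images, 9 artifact classes), run
the pipeline with the stub OCR backend, and score it:

```bash
buscurate synthesize --n-per-class 5 --seed 11 --out suite
buscurate process --input suite --report report.csv \
    --ocr-backend stub --stub-manifest suite/manifest.csv
buscurate evaluate --predictions report.csv --manifest suite/manifest.csv \
    --tasks invalid,non_b_mode,dual_view,has_calipers,laterality,distance
```

which prints:

```
        task  tp  fp  tn  fn  sensitivity  specificity    f1
     invalid   5   0  40   0          1.0        1.000 1.000
  non_b_mode  10   0  35   0          1.0        1.000 1.000
   dual_view   5   0  40   0          1.0        1.000 1.000
has_calipers   5   2  33   5          0.5        0.943 0.588
  laterality  10   0  35   0          1.0        1.000 1.000
    distance   4   0  41   0          1.0        1.000 1.000
```

Invalid, non-B-mode, dual-view and the text fields are recovered
perfectly. Caliper detection tells the more interesting story: the five
false negatives are exactly the five *dotted-spanning-line* phantoms — the
dots, the connecting line and the end marks fuse into one object larger
than the 70-px size gate, so the out-of-the-box detector misses all of
them (sensitivity 0.5 over the two caliper classes combined). Re-running
with `--enable-hough-calipers` recovers 9 of the 10 caliper images
(sensitivity 0.9), at a specificity cost on phantoms with curved scan-area
boundaries, whose corner edges are themselves intersecting lines. That
trade-off is the intended workflow: evaluate on a small labeled sample
from your dataset first, and enable the extension when this annotation
style is present (it suits datasets with rectangular scan areas).

As a library, the same run is three calls:

```python
from buscurate import process_image, load_image

flags = process_image(load_image("scan.png"))
flags.is_non_b_mode, flags.has_calipers, flags.caliper_boxes, flags.fields
```

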