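# Methods

## Image model and segmentation

Input micrographs are 8-bit RGB. Under Wright's staining, nuclear
chromatin and platelets take a blue-purple hue (blue channel well above
green), while the background, erythrocytes and leukocyte cytoplasm are
pink-to-neutral (blue ≈ green). The per-pixel clamped difference
`clip(B − G, 0, 255)` therefore collapses the scene into a gray image in
which nuclear material is bright and everything else is near zero. This
difference is deliberately insensitive to the red channel, which varies
strongly with illumination and stain pH.

Otsu's method picks the global threshold T1 on the 256-bin histogram of
the difference image, maximizing the between-class variance
σ²_B(t) = ω₀ω₁(μ₀ − μ₁)² with class 0 = levels ≤ t. Implementation
conventions (the method itself does not fix them): ties break to the
smallest t, σ²_B is defined as 0 when a class is empty, and a
single-level histogram yields t = 0. Binarization keeps pixels strictly
above T1. An explicit `otsu_override` exists for operators who prefer a
fixed empirical threshold.

The binary foreground is both nuclei and platelets. Platelets are removed
by an area threshold S applied per connected component: regions with area
≥ S survive, smaller ones are dropped. S is calibrated as the **minimum**
nucleus(-lobe) area over labeled training data (optionally scaled by a
safety factor < 1); the shipped default of 150 px corresponds to the
default synthetic geometry below, where the smallest lobe is ≈ 170 px and
the largest platelet ≈ 40 px. Components are labeled with 8-connectivity
by default so thin diagonal chromatin filaments do not split a nucleus;
4-connectivity is available in the config.

## Shape descriptors

For each region: area A (pixel count); the tight axis-aligned bounding
box with horizontal extent a₁ and vertical extent b₁, giving plumpness
P₁ = A/(a₁b₁) and aspect ratio s = b₁/a₁ (kept unsorted — s < 1 means a
lying posture, s > 1 upright); and the moment-equivalent ellipse, giving
plumpness P₂ = A/(πa₂b₂) and eccentricity e = √(a₂² − b₂²)/a₂.

The "circumscribed ellipse" is the **moment-equivalent** ellipse — the
unique ellipse with the region's centroid and second central moments —
not a minimum enclosing ellipse, which is neither unique on pixel sets
nor cheap. Semi-axes are a₂ = 2√λ₁, b₂ = 2√λ₂ from the eigenvalues of
the second central moment matrix, with a +1/12 unit-square term per pixel
so a discretized ideal ellipse maps back onto its own axes (a filled
disk of radius 40 yields P₂ = 0.9998, e = 0.0). Under this convention P₂
can slightly exceed 1 for compact convex shapes; nothing downstream
assumes P₂ ≤ 1. Degenerate regions (single pixel, collinear pixels) are
detected on the raw moments, flagged, and given a floor minor semi-axis
of 0.5 px; the classifier treats flagged regions as unilobar so an
artifact can never trigger merging.

P₁ on a discretized disk converges to π/4 from below like
πr²/(2r+1)²; tests use radius-scaled tolerances for it.

## Polylobar decision cascade

A region is a polylobar candidate if, in order:

1. e > X₁ **and** P₂ < X₂ — elongated and under-filling its ellipse:
   the signature of several lobes seen as one region, or of a partially
   reconnected lobe group;
2. else P₁ < X₃ **and** s < X₄ — sprawling, box-underfilling shapes;
3. else A < X₅ — a lone lobe is far smaller than any whole unilobar
   nucleus;
4. otherwise unilobar.

Defaults: X₁ = 0.90, X₂ = 0.85, X₃ = 0.55, X₄ = 0.80, X₅ = 250 px,
chosen for the default synthetic geometry. The X₂ ceiling is the one
threshold whose placement is load-bearing: a pair of bridged lobes
(disks of radius r at edge gap g) has P₂ = r/√(r²/4 + c²) with
c = (2r + g)/2, which stays in 0.70–0.80 for any gap the merge cap
admits (g ≲ 0.6·2r). X₂ must sit **above** that band so a partially
merged lobe group remains a candidate and keeps attracting its remaining
lobes, and **below** the unilobar band (single convex nuclei and
overlapping-lobe blobs have P₂ ≈ 0.95–1.05). 0.85 splits the two bands;
a ceiling below ~0.8 makes three-lobe nuclei unmergeable in principle,
because the intermediate two-lobe region re-classifies as unilobar and
the merge stalls. `calibrate` places X₂ just under the minimum observed
unilobar P₂ and X₅ midway between the largest lobe and the smallest
unilobar nucleus, the same min/max logic as the area threshold S.

S and X₅ are deliberately independent: S rejects platelets before any
shape analysis; X₅ separates lobes from whole nuclei after it.

## Minimal-distance merging

Disconnected lobes of one nucleus are reconnected iteratively:

1. take the first (label-order) unprocessed polylobar candidate;
2. extract Canny edges (σ = 1.0) of it and of every other region — on a
   binary mask the thin Canny trace straddles the step edge, so
   off-region trace pixels are snapped to the adjacent boundary pixel,
   and regions too small for the smoothed gradient to respond fall back
   to their morphological boundary, guaranteeing a non-empty edge set;
3. find the nearest other region by minimum edge-to-edge Euclidean
   distance (ties broken row-major, so runs are reproducible);
4. accept the merge iff the gap ≤ the merge cap, the neighbor is also a
   polylobar candidate, and the combined area ≤ a_max; then draw the
   Bresenham line between the closest pair, fill interior holes, relabel,
   and re-classify the merged region;
5. repeat until a full pass makes no merge (a safety iteration cap
   guards the loop; reaching it raises instead of silently looping).

The merge cap defaults to **adaptive**: 0.6 × the equivalent diameter
2√(A/π) of the larger region of the pair. Lobe gaps are small relative
to lobe size, inter-cell gaps are not, so the cap scales with the
objects rather than with image resolution; an absolute `d_max` can be
set in config. The mutual-candidacy rule means unilobar nuclei are never
absorbed regardless of distance — this, not the distance cap, is what
protects a unilobar cell sitting close to a polylobar one. The area cap
a_max (default 2000 px, several times the largest default nucleus)
bounds pathological chain-merging in dense scenes.

Merging can only reduce the region count, by exactly one per accepted
merge; the procedure is idempotent at its fixpoint. The count report
sets T to the number of final regions. The five per-type counters
(neutrophil, eosinophil, basophil, monocyte, lymphocyte) are bookkeeping
filled from ground truth when provided — the pipeline contains no
five-type visual classifier — and a per-type sum exceeding T raises a
consistency error rather than truncating.

## Evaluation metric

An image is counted **correct** iff the predicted region count equals
the ground-truth cell count and the predicted regions pair 1:1 with
ground-truth nuclei, each by strict majority-pixel overlap. Per-class
accuracy is correct/samples × 100; the pooled accuracy is the ratio of
sums, never the mean of class accuracies. Printed percentages are
truncated (not rounded) to one decimal, the convention of published
per-class accuracy tables (290/300 prints as 96.6).

## Synthetic data: what it does and does not show

The generator emulates the geometry and color logic of a stained smear,
not its optics. Scenes are 192×192 px with a light background
(235,225,230), pink erythrocytes (230,180,190; B−G = 10, deliberately
invisible to the difference image), platelets (120,85,165; B−G = 80) and
nuclei (95,60,160; B−G = 100). By construction the foreground/background
difference margin is ≥ 30 gray levels, so Otsu segmentation is
well-posed on every generated image.

Default geometry, chosen once so the shipped thresholds are coherent:
lobes are disks of radius 7.5–8.5 px (area ≈ 170–230, between S and X₅),
unilobar nuclei are ellipses with semi-major axis 10–13 px and axis
ratio 0.85–1.0 (area ≈ 270–530, above X₅), platelets have radius
2–3.5 px (area ≈ 13–40, below S), and consecutive-lobe edge gaps are
4–6 px (under the adaptive merge cap of ≈ 9 px for the smallest lobe).
Polylobar cells place 2–5 lobes along a chain with ±8° directional
jitter per step in one of three connection modes: *filament* (2-px
bridges), *overlap* (centers at 0.75 × the radius sum), or
*disconnected*. Per-image RNG substreams derive from (seed, image
index), and class labels follow a greedy quota-deficit sequence, so
datasets of different sizes share their common prefix and a 300-image
run hits the reference class mix (113/36/18/69/64) exactly.

Four preset scenes cover the situations that historically cause
miscounts: (1) a single disconnected polylobar nucleus — merging must
fire repeatedly down to one region; (2) two nearby unilobar cells —
nothing may merge; (3) a unilobar next to a two-lobed cell — only the
lobes merge; (4) two polylobar cells — each merges internally, never
across (inter-cell gaps are kept above the adaptive cap).

Passing on this substrate demonstrates the pipeline's *logic*:
threshold selection, platelet filtering, the cascade and the merge
procedure under every lobe topology. It does **not** demonstrate
robustness to what the generator omits: optical blur, uneven
illumination, stain batch/pH variation, touching or overlapping cells,
nuclei clipped at the image border, or lobes that overlap in projection
(a case where any 2-D method is fundamentally limited). Real-smear use
requires recalibrating S and X₁–X₅ on labeled data via `calibrate`.

## Numerical choices and degenerate inputs

- Coordinates are (row, col), 0-based, origin top-left; a₁ is always the
  horizontal (column) extent.
- All scan orders, distance ties and label assignments are row-major
  deterministic; the pipeline is a pure function of (image, config).
- A blank image yields an empty label map and T = 0 without error.
- Canny parameters (σ = 1.0) are fixed in config; on binary masks the
  operator reduces to boundary extraction, so the setting is not
  sensitive.
- 16-bit, palette and alpha-channel images are rejected at load rather
  than silently converted.
- Problem sizes in the shipped tests (300-image corpus, 25 seeds per
  preset scene, 192×192 px scenes) keep the full suite under a minute on
  one core while exercising every code path; accuracy is flat when the
  corpus is grown (checked at 600 images).

## Known limitations

- The merge rule is greedy nearest-neighbor; a pathological chain of
  equally spaced candidate regions merges in scan order, bounded only by
  a_max.
- The evaluation metric is per-image, all-or-nothing; it does not grade
  partial segmentation quality (no IoU/Dice).
- The five-type differential requires ground-truth types; classifying
  leukocyte types from image content is out of scope.
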