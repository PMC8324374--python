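# polylobe

Leukocyte counting in stained blood-smear micrographs, with correct
handling of **polylobar nuclei**.

## The problem

Differential white-blood-cell counts are read from Wright-stained smears.
Neutrophils and eosinophils — the majority of circulating leukocytes —
carry nuclei divided into 2–5 lobes. The chromatin filaments joining the
lobes are often too thin to resolve, so after segmentation one neutrophil
can appear as several disconnected nuclear fragments and be counted as
several cells, skewing the differential. `polylobe` segments nuclei,
recognizes which regions are fragments of a single polylobar nucleus, and
reconnects them before counting, so each leukocyte is counted exactly once.

## Method

1. **Segmentation.** After Wright's staining, nuclei and platelets are
   blue-purple (B ≫ G) while background, erythrocytes and cytoplasm are
   near-neutral pink (B ≈ G). The clamped difference image B − G is
   thresholded with Otsu's method (maximizing the between-class variance
   σ²_B(t) = ω₀ω₁(μ₀ − μ₁)²), and connected components with area below a
   threshold *S* — calibrated as the minimum nucleus area seen in training
   data — are discarded as platelets.

2. **Shape descriptors.** Each remaining region gets five morphological
   features: area *A*; bounding-box plumpness *P₁* = A/(a₁b₁); aspect
   ratio *s* = b₁/a₁; moment-ellipse plumpness *P₂* = A/(πa₂b₂); and
   eccentricity *e* = √(a₂² − b₂²)/a₂ of the moment-equivalent ellipse.

3. **Polylobar decision cascade.** A region is a polylobar candidate if
   (e > X₁ and P₂ < X₂) — elongated and under-filling its ellipse — else
   if (P₁ < X₃ and s < X₄), else if A < X₅ (a lone lobe is far smaller
   than any whole unilobar nucleus); otherwise it is unilobar.

4. **Minimal-distance merging.** Candidate regions are joined iteratively:
   Canny edges are extracted, the closest edge-pixel pair between a
   candidate and its nearest neighbor region is found, and if the gap is
   within the merge cap, the neighbor is also a candidate, and the merged
   area stays plausible for one nucleus, the pair is bridged with a
   straight line, holes are filled, and the merged region is re-classified.
   Unilobar regions are never absorbed. The final count *T* is the number
   of connected regions at the fixpoint.

Because annotated smear corpora are rarely redistributable, the package
ships a synthetic-smear generator with per-cell ground truth (including
the filament-connected / overlapping / disconnected lobe configurations)
that every stage is tested against.

## Worked example

```sh
$ polylobe synth --case 1 --seed 7 -o case1     # one 4-lobed neutrophil
$ polylobe segment case1/img_0000.png -o seg
INFO segmented 4 components (S=150)
$ cat seg/img_0000_features.csv
label,A,P1,s,P2,e
1,180,0.7500,1.0667,0.9934,0.0668
2,210,0.8203,1.0000,0.9951,0.0895
3,211,0.8242,1.0000,0.9965,0.1363
4,212,0.8281,1.0000,0.9964,0.0252
$ polylobe count case1/img_0000.png
INFO components: 4 before merge, 1 after
{
  "T": 1,
  "polylobar_count": 1,
  "unilobar_count": 0,
  ...
}
```

The scene holds a single neutrophil whose nucleus fragments into four
disconnected lobes. Segmentation finds four round regions (each nearly
circular: e ≈ 0.1, P₂ ≈ 1) whose small areas (180–212 px, below
X₅ = 250) mark them as lobes rather than whole nuclei; three
minimal-distance connections later the count is **T = 1** — one
polylobar leukocyte, not four cells.

Batch evaluation against ground truth:

```sh
$ polylobe synth --n 300 --seed 1 -o ds
$ polylobe evaluate ds -o evaluation.csv
pooled accuracy: 100.0%
```

## Configuration

All empirical parameters live in one YAML file (CLI flags override):

```yaml
segmentation:
  area_threshold: 150    # S, px — platelet filter
  connectivity: 8
thresholds:
  x1: 0.90               # eccentricity floor
  x2: 0.85               # ellipse-plumpness ceiling
  x3: 0.55               # box-plumpness ceiling
  x4: 0.80               # aspect-ratio ceiling
  x5: 250                # lone-lobe area ceiling, px
merge:
  d_max: null            # null = adaptive: 0.6 x equivalent diameter
  a_max: 2000            # max plausible single-nucleus area, px
```

`polylobe calibrate` re-derives *S* and X₁–X₅ from labeled synthetic
ground truth; see `docs/methods.md` for the calibration rules and the
limits of what synthetic results imply about real smears.
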