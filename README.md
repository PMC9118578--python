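# pollenquant

Semi-automated counting of germinated pollen grains in brightfield
micrographs of in vitro germination assays.

Scoring pollen viability means answering two questions per field of view:
how many grains are there, and how many of them have extended a pollen
tube longer than their own diameter? Done fully by hand (e.g. clicking in
ImageJ) this is slow; done fully automatically it is unreliable, because
grains clump, tubes cross, and debris mimics pollen. `pollenquant`
implements the middle road used in practice: automatic segmentation and
detection produce a first pass, scripted point corrections replace the
interactive clicks, and the germination percentages feed straight into a
Welch test between conditions. A synthetic micrograph generator with
exact ground truth makes the whole chain testable without a microscope.

## Method

Per image, in order:

1. **Segmentation** — threshold the blue channel of the RGB micrograph at
   grey level 150 (objects darker than background are foreground), fill
   enclosed holes, drop components under 50 px.
2. **Grain detection** — label 8-connected components, measure their
   moment-based eccentricity e = √(1 − λ₂/λ₁) (λ₁ ≥ λ₂ the eigenvalues of
   the pixel covariance), and accept as a grain every region with
   e < 0.65. Circles have e ≈ 0; tubes, clumps and debris are elongated.
   When automatic germination scoring is on, a morphological opening first
   erases the thin tubes so a grain that has already germinated is still
   detected as a disc.
3. **Germination scoring** — for each grain, the tube is the part of its
   connected component outside the grain disc; its length is the geodesic
   length of the tube skeleton (orthogonal steps 1, diagonal √2). A grain
   is germinated iff tube length > grain diameter (strict).
4. **Corrections** — an ordered CSV of edits (`row,col,category,action`)
   reproduces manual refinement: add/remove grains, set/clear germinated
   marks, matched to the nearest detection within 15 px.
5. **Counting & statistics** — per image, percent = 100 · germinated /
   total; per sample, the mean of its image percents; between conditions,
   Welch's t-test with Satterthwaite degrees of freedom (two-sided),
   medians reported alongside.

## Worked example

Generate a two-condition synthetic study (five fields each, ~50 grains
per field; a permissive medium with 45 % tube-bearing grains vs a poor
one with 10 %) and run the full pipeline:

```sh
pollenquant simulate --fields 5 --germinated-fraction 0.45 --seed 11 \
    --condition medium16 --out study/
pollenquant run --input study/ --out results/ \
    --condition-map study/condition_map.csv
```

Or in Python:

```python
from pollenquant import SceneSpec, generate_study
from pollenquant.pipeline import run_pipeline

specs = {
    "medium16": SceneSpec(seed=11, germinated_fraction=0.45, tube_length_factor=(0.6, 1.9)),
    "medium24": SceneSpec(seed=22, germinated_fraction=0.10, tube_length_factor=(0.6, 1.9)),
}
generate_study(specs, 5, "study/")
report = run_pipeline("study/", "results/", condition_map="study/condition_map.csv")
print(report.counts.head(3).to_string(index=False))
print(report.stats.to_string(index=False))
```

prints (abridged):

```
   image_id  n_total  n_germinated  percent_germination  undefined
medium16_f0       48            11            22.916667      False
medium16_f1       51            19            37.254902      False
medium16_f2       57            16            28.070175      False

condition_a condition_b    mean_a   mean_b  median_a  median_b  n_a  n_b        t       df        p
   medium16    medium24 28.489374 6.459893 28.070175       6.0    5    5 8.379073 5.602227 0.000225
```

Reading it: every field's grain total matches the generator's ground
truth exactly; the germination percentages differ by condition (≈28 % vs
≈6 %), and Welch's test puts the difference at t = 8.38 with 5.6 degrees
of freedom, p ≈ 2 × 10⁻⁴ — a clear separation. Grains whose tube length
falls within a few percent of their diameter can be auto-scored either
way (rasterization error); those calls are exactly what the correction
layer exists to fix.

`results/` also holds per-image detection CSVs, review overlays (red X on
every counted grain, blue X on germinated ones), per-sample summaries,
the run log and the effective configuration file, which reproduces the
run byte-for-byte when passed back via `pollenquant run --config`.

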