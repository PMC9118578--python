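# Methods

## The measurement problem

In vitro pollen germination assays quantify pollen viability as the
fraction of grains in a micrograph that have extended a tube longer than
their own diameter. The unit of analysis is the sample (one droplet of
germination medium); its value is the mean of the per-image percentages,
and condition groups (media, incubation times) are compared with Welch's
t-test. `pollenquant` automates the image-analysis half of this workflow
and replaces interactive click-correction with a scripted, replayable
edit list.

## Segmentation

Pollen grains and tubes absorb more light than the surrounding medium, so
a fixed grey-level threshold on one colour channel separates them:
foreground iff blue intensity < 150 (strict; a pixel exactly at the
threshold is background under either polarity). The blue channel gives
the best grain/background contrast in brightfield captures of this kind.
Cleanup is two standard morphological steps: enclosed background regions
(internal reflections of the grain wall) are filled, and 8-connected
components under `min_object_area` = 50 px are discarded. At the ~5×
magnification the defaults assume, a grain of radius ≈ 14 px covers
~600 px, so 50 px sits well below any plausible grain and above salt
noise. Polarity is configurable (`dark_objects`/`bright_objects`);
dark-objects is the default because brightfield pollen is darker than the
medium. Foreground uses 8-connectivity and background 4-connectivity
(the standard duality), consistently in hole filling and labeling.
16-bit input images are rescaled to 8-bit on read (integer division by
257) so the fixed threshold keeps its meaning; greyscale images are
promoted by channel replication.

## Grain detection

Each component is summarised by its second-central-moment geometry
(area, centroid, axis lengths of the moment-equivalent ellipse) and the
eccentricity e = √(1 − λ₂/λ₁), λ₁ ≥ λ₂ the eigenvalues of the pixel
covariance matrix. A region is a grain candidate iff e < 0.65, strictly:
a region at exactly the cut-off is rejected. The detection point is the
region centroid — cheap, deterministic, and matching the X-marking
convention of review overlays. Touching grains that merge into one
elongated component are deliberately not split (no watershed); such
misses are routed to manual correction, which is the workflow's design
philosophy. On rasterized solid ellipses with 10 ≤ b ≤ a ≤ 60 px the
moment estimator tracks the analytic value √(1 − (b/a)²) to within ~0.01
for typical shapes. The absolute error is ill-conditioned for
near-circular regions (analytic e < 0.2), where pixelation noise can
produce errors up to ~0.06; this regime is far below the 0.65 cut-off and
never affects the accept/reject decision.

### Tube suppression

A grain that has extended a long tube forms one elongated component whose
eccentricity far exceeds 0.65, so shape filtering alone would miss
exactly the grains the assay cares about (interactively, a user would
click them back in). When automatic germination scoring is enabled, the
pipeline therefore detects grains on a copy of the mask opened with a
disc structuring element (radius 4 px by default): the opening erases
structures narrower than ~2·radius — tubes are ~3 px wide — while grain
bodies (diameter ≳ 16 px) survive with their centroid and equivalent
diameter essentially intact. Tube geometry is then measured on the
original, unopened mask.

## Germination scoring

The tube of a detected grain is the part of its connected component
outside the circle centred at the grain centroid with the grain's
equivalent diameter, plus a one-pixel margin (a rasterized disc's rim
extends slightly past its equivalent-diameter circle; without the margin,
rim slivers survive the excision). Tube length is the geodesic length of
the tube's morphological skeleton: skeleton pixels form a graph with unit
cost for orthogonal adjacency and √2 for diagonal, and the length is the
longest shortest path within the largest piece (two-sweep farthest-point
search, exact on trees). Only the longest skeleton piece is measured, so
stray specks cannot inflate the estimate. Skeletonization uses Lee's
method: Zhang thinning, the common default, can pathologically erode
diagonal staircase strokes (observed: a 63-px tube segment collapsing to
a 10-px skeleton), while Lee's method tracks arc length to within a few
percent on the same masks.

A grain is scored germinated iff tube length > grain diameter, strictly —
a tube exactly as long as the diameter does not count. When one component
contains several detected grains (a clump with a tube), the whole tube is
credited to the grain whose centroid lies nearest to it and the others
score zero: deterministic, biased toward under-calling, and correctable
downstream. Expected accuracy: skeleton end erosion and staircase
inflation each contribute a few percent, so classifications are reliable
when the true tube length sits ≥ 15 % away from the diameter boundary;
inside that band the automatic call can go either way and manual
correction is the arbiter.

## Correction semantics

Corrections are an ordered list of (point, category, action) edits,
category ∈ {total, germinated}, action ∈ {add, remove}. Add-total
appends a manual grain; remove-total deletes the nearest detection within
the match radius (15 px ≈ one grain radius), taking any germinated mark
with it; add-germinated marks the nearest grain within the radius (or
creates a manual germinated grain if none is near); remove-germinated
clears the mark but keeps the grain. Germinated marks attach to grains,
which structurally enforces n_germinated ≤ n_total — the invariant the
percentage formula assumes. Equidistant matches break ties by smallest
row then smallest column, so replaying an edit list is deterministic. A
remove that matches nothing is reported, not raised; what an interactive
tool should do with such a click is genuinely ambiguous, and a report
keeps the batch run alive while preserving the information.

## Statistics

Per image: percent = 100 · n_germinated / n_total, undefined (and
flagged) when the image has no grains. Per sample: the arithmetic mean
over its images' defined percents; images with undefined percent are
excluded and counted separately. Between two groups of per-sample means:

    t  = (m̄_a − m̄_b) / √(s²_a/n_a + s²_b/n_b)
    df = (s²_a/n_a + s²_b/n_b)² / [(s²_a/n_a)²/(n_a−1) + (s²_b/n_b)²/(n_b−1)]

with variances on n−1 denominators and a two-sided p-value from the
Student-t CDF via the regularized incomplete beta function
P(|T| ≥ t) = I_{df/(df+t²)}(df/2, ½). Two constant groups with equal
means report t = 0, p = 1. Two-sided p-values are the conservative
default; medians accompany means because germination distributions are
typically skewed. No multiple-testing correction is applied to the
pairwise table — consumers comparing many conditions should adjust
downstream. The implementation agrees with a 50-digit mpmath evaluation
of the closed forms to better than six significant figures in the
test suite, and its null rejection rate at α = 0.05 calibrates to
0.05 ± 0.01 over 10⁴ simulated same-distribution pairs.

The test unit is the per-sample mean (one droplet = one sample); the
`aggregate` helper takes an image→sample→condition map, and mapping each
image to its own sample yields per-image units instead.

## Synthetic fields

The generator emulates a 5× brightfield view: a 1040×1392 field holding
Poisson(50) grains (hard-edged discs, radius ~N(14, 2) truncated at 8 px,
grey level 90 on background 220 in all three channels — grey objects so
the blue-channel convention is exercised without inventing pollen
coloration), additive Gaussian noise (σ = 8 by default), and optionally a
radial illumination fall-off. A configurable fraction of grains bears a
tube: a unit-step random-walk stroke of width 3 px whose heading drifts
by at most 0.05 rad/step, attached at the grain boundary, with true arc
length recorded as a per-grain uniform multiple of the grain diameter
(default interval 0.5–2.0). The ground-truth germinated flag follows the
length rule (tube > diameter), so a grain with a short tube is
truth-negative. Placement is rejection sampling against an occupancy
mask keeping a 4-px gap between components; tube paths that would leave
the field, curl back to their own grain, or pass within (width + 2) px of
their own earlier course are redrawn, keeping strokes non-self-merging so
skeleton length remains a valid proxy for arc length. One seeded
generator drives every draw: identical specs give bit-identical images
and truth.

What the generator does not model — and hence what passing tests do not
show about real micrographs: out-of-focus grains, uneven staining,
overlapping tubes from neighbouring grains, tube branching or bursting,
debris, and the drop-edge aggregation gradient of real droplets (real
counting protocols avoid those regions; the generator simply does not
produce them). Results on synthetic fields bound the algorithmic error,
not the biological one.

## Problem sizes in the standard checks

The bundled checks run 20 clean and 20 noisy full-size fields end to end,
16 smaller (360×480) single-factor fields spanning the tube-length-factor
range, 1,000 random edit sequences, 10⁴ simulated null pairs, and
50–100 rasterized-ellipse comparisons — sizes chosen so the whole suite
completes in about a minute while every claim is exercised at full image
scale where it matters.

## Known limitations

- Clumped grains are counted as one (or zero, if elongated) by design;
  the correction layer is the intended remedy.
- The fixed threshold assumes the study's illumination conventions; no
  adaptive thresholding or illumination correction is attempted.
- Automated tube scoring is undefined territory when tubes from different
  grains touch (components merge); the nearest-centroid rule is a
  deterministic convention, not a claim about biology.
- Eccentricity's absolute error is large for near-circular regions (see
  above); do not use the estimator to discriminate eccentricities below
  ~0.2 at these resolutions.
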