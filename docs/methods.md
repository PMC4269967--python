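# Methods

This note documents the models and procedures implemented in
`papnuclei`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic test bed does and
does not demonstrate.

## Problem and pipeline

Cervical cytology samples are screened by segmenting cell nuclei and
classifying their morphology. When two or more nuclei overlap in
projection they merge into one dark region; downstream morphometry then
operates on a compound object and misjudges it. `papnuclei` detects
such regions *unsupervised*: no labelled training set exists for most
laboratories' staining and imaging conditions, so the method relies on
geometry and intensity structure alone, in three stages —
boundary extraction, a five-feature descriptor, and two-cluster
classification.

## Stage 1 — boundary extraction

**Cell-cluster gate.** The RGB image is converted to HSV and pixels
with hue in the closed band [0.2, 0.7] are kept. Cytoplasmic material
falls in this band; the pale background and most reddish blood/artifact
pixels do not. Gating uses hue only — saturation and value are
ignored, which keeps the gate exposure-independent but means a fully
desaturated image (hue undefined, represented as 0) gates to empty.
The raw mask is closed with a 5-px disk and hole-filled so each cluster
is a solid blob; both are configurable. Both band endpoints are
included (closed interval) for determinism.

**Grayscale.** Fixed BT.601 luma (0.299, 0.587, 0.114), rounded
half-up, so the conversion is bit-exact across platforms.

**Gradient and edge curves.** Nuclei are among the darkest structures
and their walls produce the strongest intensity gradients against the
cytoplasm. The Sobel gradient magnitude (x/y kernels combined in
quadrature, borders replicated) is normalised by its maximum and
thresholded with hysteresis: keep pixels ≥ low that connect to a pixel
≥ high, with high = 0.4 and low = 0.4·high by default. The selected
ridge band is thinned (topology-preserving skeletonisation) to
1-px-wide curves.

Two deliberate choices here:

- *Ridge extraction instead of a second edge-detection pass.* Running a
  full Canny detector **on** the gradient-magnitude raster marks the
  two flanks of every gradient ridge and yields doubled, concentric
  contours per nucleus wall. Hysteresis selection of the ridge band
  followed by thinning extracts the single ridge centreline, which is
  what the nucleus wall is. The 0.4 threshold plays the same role as a
  Canny high threshold.
- *No pre-smoothing of the magnitude by default* (`canny_sigma = 0`).
  Smoothing blends the wall ridge with the interior radial intensity
  ramp of the nucleus and drags the extracted contour 2–3 px inward
  (mask Tanimoto against a clean rasterised disk drops from ≈0.97 to
  ≈0.76 at σ=1). Noise robustness comes from the hysteresis step
  instead. The parameter remains exposed for noisier material.

**Contour filtering.** 8-connected edge components outside a size
window ([20, 5000] pixels at the 1280×960 reference scale, scaled by
image area) are dropped; components that enclose no interior pixel
(open arcs) are dropped; then each surviving contour is reduced to a
simple closed curve. Spur pixels (≤1 neighbour) are pruned to fixpoint.
Junction pixels (>2 neighbours) are test-removed: a removal is accepted
only if the contour stays one 8-connected component and every
previously enclosed interior pixel stays enclosed, and removals of
non-wall pixels (pixels not touching both interior and exterior —
whisker stubs and chord shortcuts) are tried before wall pixels. This
preserves the enclosing wall exactly while deleting attachments; naive
"still closed" pruning lets the curve re-route through skeleton-bubble
chords and collapse. Components that degenerate below 8 px are dropped
with a log entry. Finally each contour is filled, regions whose
centroid lies outside the cell-cluster mask or whose area is below 50
px² (reference scale) are discarded, labels are assigned in raster-scan
order of centroids, and region masks are kept pairwise disjoint.

Splitting a merged overlapped region into its constituent nuclei is
explicitly out of scope; the pipeline *detects* overlap, it does not
resolve it.

## Stage 2 — five-feature descriptor

Per region, in fixed column order:

| # | feature | definition | direction under overlap |
|---|---------|------------|--------------------------|
| 1 | eccentricity | √(1 − b²/a²), a,b from second central moments of the filled mask | increases |
| 2 | axis_ratio | a/b (major/minor), ≥ 1 | increases |
| 3 | diameter_ratio | √(4·Area/π) / (P_n/π) | departs from the digital-disk baseline |
| 4 | n_minima | count of 8-connected grayscale local minima inside the region | increases |
| 5 | max_minima_dist | maximum pairwise Euclidean distance between minima (0 for ≤1) | increases |

P_n is literally the number of region pixels with at least one
4-neighbour outside the region. Note that for an ideal digital disk
this pixel count is ≈ 4√2·r, not 2πr, so a circle's diameter_ratio
baseline is π/(2√2) ≈ 1.11 rather than 1; tests compare against this
baseline. A degenerate 1-px-wide region clamps eccentricity to 1−1e−9
with a warning.

**Local minima.** A pixel is a minimum when strictly darker than all 8
neighbours; a connected constant-intensity plateau counts once (at the
plateau pixel nearest its centroid) when every in-region neighbour of
the plateau is strictly brighter — a strict-only rule would silently
drop flat-bottomed valleys, common after 8-bit quantisation. Only
pixels whose full 8-neighbourhood lies inside the region are eligible,
so wall-adjacent artefacts cannot vote. Regions smaller than 9 px
return no minima, with a warning.

`features.local_minima` operates on raw 8-bit values by default (the
literal definition). The *pipeline* default applies a 1-px Gaussian
first (`minima_sigma = 1.0`): a single nucleus's valley has a radius of
~10 px, while raw strict minima also count single-pixel sensor noise;
at noise σ = 2 gray levels those noise minima inflate n_minima for
single nuclei and dilute the texture-feature separation (observed FCM
precision 0.75 raw vs 1.0 smoothed on the synthetic sweep). 1 px is far
below the valley scale, so the smoothing removes noise minima without
merging genuine valleys. Set `minima_sigma = 0` to recover the literal
behaviour.

**Standardisation.** Features 4–5 span tens of units while features
1–3 are order one, so Euclidean clustering on raw values would be
dominated by texture. Descriptors are z-scored per column before
clustering by default; `--no-standardize` disables this.

## Stage 3 — clustering

Both methods are implemented in full (they are the decision mechanism,
not a convenience):

- **k-means** (Lloyd): assign to nearest centroid, recompute means;
  the within-cluster sum of squares is non-increasing per iteration.
  k-means++ seeding, 10 restarts, best objective kept; an emptied
  cluster is re-seeded at the point farthest from its assigned
  centroid. Tests verify the returned objective equals the exhaustive
  optimum over all bipartitions of 8 points and matches scikit-learn's
  inertia on blobs.
- **Fuzzy c-means** (Bezdek): memberships
  u_ij = 1/Σ_k (d_ij/d_ik)^{2/(m−1)}, centroids as u^m-weighted means,
  iterated until the largest absolute membership change < 1e−5 (or 300
  iterations). Fuzzifier m = 2.0, the canonical choice; m → 1 recovers
  hard clustering (verified at m = 1.05 against k-means). A point
  coinciding with a centroid receives membership 1 there (standard
  singularity rule). Converged memberships are self-consistent with
  the closed-form update at machine precision by construction.

**Naming the clusters.** The method never learns which cluster is
"overlapped"; the rule is: the cluster whose centroid has the larger
n_minima coordinate (ties: max_minima_dist, then axis_ratio) is
overlapped — overlap creates extra intensity valleys, so this direction
is part of the model, not a fitted quantity. Monotone z-scoring makes
the rule space-independent. If all three coordinates tie, the fit is
rejected as indistinguishable rather than guessed.

## Evaluation

- **Tanimoto / Jaccard** between binary masks: Nc/(Na+Nb+Nc); two empty
  masks compare as 1 with a warning.
- **Object matching**: greedy best-Tanimoto one-to-one; a truth object
  is *located* when its match reaches 0.5. Mean/std are over located
  matches.
- **Classification**: overlapped is the positive class; precision,
  recall, F1 with zero denominators reported as 0 plus a warning.
- **Feature significance**: per-feature |m₁−m₂|/√(s₁²/n₁ + s₂²/n₂)
  (independent two-sample signal-to-noise, after Weiss & Indurkhya);
  zero pooled variance with distinct means reports +inf.

## Synthetic scenes

`SceneSpec` defaults define the evaluation conditions: 1280×960 frames,
17 single nuclei plus 3 overlapped pairs (20 objects, 15% overlapped),
nucleus semi-major axes 14–24 px with axis ratios 1.0–1.3, pair centre
distance 0.6 of the summed radii along the centre line, gray levels
30 (nucleus centre) / 150 (cytoplasm) / 230 (background), Gaussian
noise σ = 1 by default (the evaluation sweep cycles σ = 0, 1, 2).

Rendering choices: each nucleus is a radial quadratic ramp from the
centre value to the rim value (midway to cytoplasm), so a single
nucleus has exactly one valley by construction; an overlapped pair is
the pixelwise minimum of two ramps, so both valley bottoms persist and
the union outline is flattened/irregular. Cytoplasm fades to the
background over a 10-px linear ramp, so the cluster rim produces only a
weak gradient that stays below the hysteresis threshold — in real
samples, too, the cytoplasm/background transition is far weaker than
the nucleus wall. Colour is synthesised with fixed small-chroma channel
offsets: cytoplasmic pixels (g−5, g+3, g+1) (hue 0.458), background
(g+4, g−2, g−1) (hue 0.972), so the 8-bit luma equals the target gray
raster exactly and the hue gate recovers the cluster support exactly.
All randomness (geometry in placement order, then pixel noise) comes
from one seeded generator; a scene is a pure function of its spec.
Placement enforces a 10-px clearance between object bounding circles
and raises a capacity error after 500 failed attempts per object.

**What the synthetic bed does not show.** Real Pap smears have
chromatin texture, stain variability, blood, mucus, folded cytoplasm
and out-of-focus blur; the generator models none of these. Passing the
synthetic sweep demonstrates the pipeline's internal correctness —
every stage, end to end, with exact ground truth — not clinical-grade
performance on slides. Published figures from real material (≈87% of
nuclei located, mask Tanimoto ≈0.73, F-scores ≈0.77–0.79) are not
reproducible here because the underlying image sets and observer
ground truth are not deposited; the synthetic numbers are expected to
be higher and are quality bars for the implementation, not claims
about real data.

## Acceptance sweep

`scripts/acceptance.py --seed S` generates ten scenes with seeds
S … S+9 and noise σ cycling (0, 1, 2), runs the pipeline per scene,
pools all region descriptors (as one would cluster a whole study set),
fits FCM and k-means once on the pool, and reports: located fraction
and mean/std mask Tanimoto over located matches; precision/recall/F1
for both methods against the generator's classes (regions without a
matched truth object are excluded from scoring since their class is
undefined, but still participate in clustering); and the fraction of
regions on which the two methods agree. Ten 1280×960 scenes run in
≈15 s on one CPU.

## Known limitations

- Junction pruning is O(candidates × component size) per contour;
  fine for nucleus-scale curves, not meant for image-scale meshes.
- The hue gate assumes stained material in the 0.2–0.7 band;
  grayscale or unusually stained input gates to empty (reported as a
  warning, not an error).
- With fewer than two valid regions no clustering is possible; all
  regions are reported as single with a warning.
- The overlap call is relative: in an image containing *only*
  overlapped (or only single) nuclei, two-cluster partitioning will
  still split the population and mislabel one half. The method is
  designed for whole-sample region populations where both classes are
  present.
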