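# papnuclei

Unsupervised detection of **overlapping cell nuclei** in Pap smear
(cervical cytology) micrographs.

Overlapping nuclei appear in projection as a single merged dark region
and are a major source of segmentation and classification errors in
automated cervical screening. `papnuclei` implements a three-stage,
fully unsupervised pipeline that flags candidate nucleus regions as
*overlapped* or *single* without any training data:

1. **Boundary extraction.** The RGB sample is hue-gated (HSV hue in
   [0.2, 0.7]) to isolate cytoplasmic cell clusters, converted to 8-bit
   grayscale, and the Sobel gradient magnitude |∇I| = √(Gx² + Gy²) is
   computed. Nucleus walls sit on ridges of |∇I|; hysteresis
   thresholding (high threshold 0.4 of the normalised magnitude) plus
   thinning extracts them as 1-px closed curves, which are then size
   filtered, closed-contour filtered, freed of spurs/bifurcations, and
   filled into candidate regions restricted to the cell clusters.
2. **Five-feature descriptor** per region (three shape, two texture):
   eccentricity e = √(1 − b²/a²) of the moment-matched ellipse, axis
   ratio a/b, the ratio of equivalent diameter √(4·Area/π) to the
   perimeter-implied diameter P_n/π, the number of 8-connected grayscale
   local minima inside the region, and the maximum pairwise Euclidean
   distance between those minima. Overlap flattens regions, makes their
   outline wavy, and produces multiple intensity valleys — all five
   features move in a known direction.
3. **Two-cluster classification** of the descriptors with k-means
   (Lloyd, minimising within-cluster sum of squares) or fuzzy c-means
   (memberships u_ij = 1/Σ_k (d_ij/d_ik)^{2/(m−1)}, centroids as
   u^m-weighted means, fuzzifier m = 2). The cluster whose centroid has
   the larger local-minima coordinate is called *overlapped*; the
   membership of the winning cluster is the call's confidence.

Because no public ground-truthed overlapping-nuclei image set is
bundled, the package ships a first-class **synthetic scene generator**
(`papnuclei.synthetic_data`) that renders light-background scenes with
hue-correct cytoplasmic clusters and dark elliptical nuclei whose
radial intensity profiles produce exactly one valley per single nucleus
and two or more per overlapped pair — with exact instance masks and
class labels for every object. Evaluation utilities provide the
Tanimoto (Jaccard) mask similarity Nc/(Na+Nb+Nc), precision/recall/F1
for the overlap calls, object-level greedy matching, and the
Weiss–Indurkhya independent-feature significance score.

## Worked example

```sh
papnuclei simulate --width 640 --height 480 --n-single 6 --n-overlap 2 \
    --noise-sigma 1 --seed 7 --out scene
papnuclei run scene/scene.png --out run --seed 0
papnuclei evaluate --calls run/calls.csv --truth scene/truth.json \
    --pred-mask run/labeled_mask.png --truth-mask scene/instance_mask.png \
    --out report.json
```

The scene contains 8 ground-truth objects (6 single nuclei, 2
overlapped pairs, each pair one merged object). `run` reports
`8 regions -> run` and writes one descriptor row per region
(`run/features.csv`):

```
label,eccentricity,axis_ratio,diameter_ratio,n_minima,max_minima_dist,valid
1,0.74393402548138854,1.4964390658368816,1.0755158218640002,3,20.880613017821101,True
2,0.37839569219178881,1.0803290108060331,1.1463552068731324,1,0,True
```

Region 1 is elongated (eccentricity 0.74), has 3 intensity minima
spread 20.9 px apart — an overlapped pair. Region 2 is nearly round
with a single valley — a single nucleus. The fuzzy c-means calls
(`run/calls.csv`) agree, with membership confidences:

```
label,predicted,confidence
1,overlapped,0.941170195929027
2,single,0.988616527110185
```

`report.json` scores the run against the generator's truth: all 8
objects located (`located_fraction: 1.0`), mean mask Tanimoto 0.962,
and a perfect overlap classification (Tp=2, Tn=6, Fp=Fn=0, F1=1.0).

The same stages are available as a library:

```python
from papnuclei import SceneSpec, generate_scene, run_pipeline, match_regions

rgb, truth = generate_scene(SceneSpec(n_single=17, n_overlap=3, rng_seed=0))
result = run_pipeline(rgb)                  # regions, features, calls
match = match_regions(result.regions, truth)
```

A pre-segmented mask (e.g. human-drawn nuclei) can bypass segmentation
entirely: `papnuclei run image.png --mask nuclei_mask.png` runs features
and clustering on the provided regions (semi-automated mode).

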