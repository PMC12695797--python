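# Methods

`orchardvision` implements an unsupervised apple-detection and 3D-localization
pipeline for orchard robotics, together with a synthetic stereo scene
generator that provides exact ground truth for every stage. This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic evaluation does and does not demonstrate.

## Pipeline model

The pipeline is: denoise → HSI conversion → enhanced K-Means segmentation →
morphological cleanup and instance separation → multi-feature fusion scoring →
(optionally) stereo block matching and triangulation.

### Preprocessing

Images are smoothed with a Gaussian (σ = 1 px) then median filtered (3 × 3)
per channel, and converted to HSI. Hue uses the circular definition
H = atan2(√3·(G−B), 2R−G−B) mapped to [0, 360). A single-quadrant arctan
cannot distinguish green (120°) from blue (240°); the circular form can. It
differs from the hexagonal HSV hue by at most ≈1.12° (they agree exactly at
multiples of 60°), which is why the hue-oracle tests use a 1.2° band rather
than machine precision. Saturation is 1 − min(R,G,B)/mean(R,G,B), intensity
mean(R,G,B)/255; zero-chroma pixels carry the sentinel hue 0 with
saturation 0. Grayscale uses BT.601 weights.

### Clustering features

Segmentation clusters per-pixel features with K-Means. The default feature
vector is two-dimensional:

* **re-centred hue** — hue minus the apple hue reference (0° for red fruit,
  100° for green), wrapped to (−180°, 180°], so the red variety's 0°/360°
  wrap becomes a single linear mode at 0;
* **scaled saturation** — 30 × S, i.e. saturation expressed in
  degree-equivalent units.

Saturation is included because it is brightness-invariant and carries
fruit/canopy contrast (≈0.8–0.9 vs ≈0.45) with noise *independent* of the
hue noise. At night the chroma of every surface drops, so the per-pixel hue
noise grows to several degrees and hue alone no longer separates green fruit
(≈100°) from foliage (≈122°) reliably; the saturation channel restores the
margin. Setting `cluster.saturation_scale: 0` restores hue-only clustering.

### Adaptive initial centres

Each pixel i is scored by local feature homogeneity,

    score(i) = P(i) · Σ_{j ∈ N(i)} 1 / (‖F(i) − F(j)‖_w + ε),

with N(i) a 5 × 5 spatial window and ε = 10⁻³ guarding zero distances.
Centres are chosen greedily: the highest-scoring pixel, then the
highest-scoring pixel at least `min_separation` (default 20
degree-equivalents) away in feature space, and so on. Scoring runs on a
stride-2 subsample of the image — modes of a megapixel frame are located
just as well at quarter density.

`P(i)` is a candidate-set indicator (exposed as `candidate_mask`). The
pipeline applies the restriction once per frame: one centre is always
seeded *inside the apple hue gate* (within `hue_gate` = 10° of the
reference), as the per-channel median of the gated pixels — when fruit is
present, gated pixels are mostly fruit surface, so the median sits on the
fruit mode and is robust to the stray boundary and noise pixels that a
single density peak can land on. Fruit pixels are a few percent of an
orchard frame, and without this restriction all k centres can land in the
(much larger) canopy mode, after which Lloyd iterations cannot recover a
fruit cluster. If an image has fewer than k separable modes the
selection degrades gracefully to k−1, then k−2; a frame with no pixels near
the reference hue yields an empty foreground (e.g. a foliage-only view).

k defaults to 3 (fruit, canopy, canopy shadow/highlight).

### Lloyd iterations and the foreground

Assignment uses the weighted Euclidean distance
D(x,y) = sqrt(Σ_m w_m (F_m(x) − F_m(y))²); the square root is monotone, so
assignments match the squared-distance form exactly. Iterations stop when
the largest centre movement falls below 10⁻⁴ feature units or after 100
rounds; the weighted within-cluster sum of squares is non-increasing by
construction and is recorded per iteration. Distance accumulation is done
in float32 (the step is memory-bandwidth bound at 1080p); objectives are
reduced in float64. An emptied cluster is re-seeded at the point farthest
from its nearest centre. Ties break toward the lower cluster index, so
results are deterministic and independent of pixel ordering.

The foreground is the union of clusters whose centre lies within `hue_gate`
of the reference hue (the flagged foreground label is the nearest). A gate
of 10° rejects the lower tail of the canopy distribution (which sits ≈20°
from the green-apple reference) while tolerating the few degrees of centre
drift seen at night.

### Morphology and instance separation

The binary foreground is opened then closed with a disc (radius 2 px) and
components smaller than `min_area` are dropped; `min_area` is specified at
a 1920 × 1080 reference scale (50 px²) and scaled by image area. Boundary
extraction is mask AND NOT erode(mask).

Touching fruits are separated by a watershed on the negated Euclidean
distance transform. The EDT is smoothed with a 1-px Gaussian first: the
medial axis of an elongated blob is a flat ridge whose rasterized plateau
would otherwise seed several markers for one fruit. Markers are distance
maxima at least 6 px apart; any component left without a marker keeps its
own maximum, so no component is ever lost. Per-fruit IoU (the CRR metric)
is computed against these separated instances, since per-fruit overlap is
only meaningful on instance masks.

### Fusion scoring

Each candidate region is scored with the convex combination

    T = α₁·H + α₂·GLCM + α₃·Shape,   α = (0.5, 0.3, 0.2),

and kept when T ≥ 0.6. H is 1 − min(|Δhue|, 60°)/60° of the region's mean
hue against the reference; GLCM is the co-occurrence homogeneity (distance
1, four angles averaged, 16 gray levels) of the region's window; Shape is
the circularity 4π·area/perimeter². Colour gets the largest weight because
it is the pipeline's primary cue; the weights and threshold are exposed in
the configuration. Regions with equivalent radius below
`fusion.min_radius` (8 px at the evaluation scale) are rejected — smaller
blobs at the working distances are sensor noise, not fruit.

Perimeters are measured on the marching-squares contour polygon subsampled
at every third vertex. The raw contour length overestimates smooth shapes
by the staircase factor (a disc of radius 20 would score ≈0.87
circularity); the subsampled polygon measures discs within ~2–3% of 2πr and
squares within ~3% of 4a, so circularity behaves like its continuous
definition (disc ≈ 0.95–0.99, square ≈ 0.81, thin streak < 0.2).

Each accepted region yields a detection with a hue-membership-weighted
centroid and a radius from a Kåsa algebraic circle fit to the region
boundary (falling back to the equal-area radius when the fit is degenerate
or off by more than 3× from it).

### Stereo localization

For a rectified pair, dense block matching minimizes the mean absolute
difference (SAD) over an 11 × 11 block along the same row across
disparities [0, 64], with three validity checks: a texture gate (flat cost
curves are unmatchable), rejection of zero-disparity winners (no physical
depth), and a left-right consistency check (±1 px). Sub-pixel refinement
uses the three-point *equiangular* (V-shape) fit: the SAD cost of a
translated signal is piecewise linear near its minimum, for which the
V-fit is the consistent estimator — a parabola exhibits ≈0.1 px
pixel-locking bias there, which alone would exceed the sub-0.1% clean
depth-error regime this system works in; the V-fit keeps the bias near
0.04 px.

A fruit's disparity is the median of valid per-pixel disparities over its
*exclusive* surface: its instance region minus every other detection's
fitted circle (dilated 2 px). The exclusion matters because the watershed
boundary between an occluded fruit and its (nearer) occluder follows the
distance-transform ridge, not the true circular boundary, so the occluded
fruit's cell contains slices of occluder surface whose disparity would
drag the median toward the occluder's depth. Measured disparities are
further restricted to the physical working band
(`min_disparity` = 16 px ≈ 2.6 m at f = 700 px, B = 60 mm).

Two occlusion pathologies are handled explicitly rather than silently:

* **Right-view occlusion.** When a nearer fruit hides a farther one in the
  right image, the hidden fruit's pixels match the occluder's surface
  (both are apple-coloured) and its measured disparity echoes the
  occluder's. The signature is a pair of left-view-overlapping detections
  with near-equal measured disparity. The hidden fruit's true surface
  usually survives as a coherent *deeper* mode in its disparity samples
  (≥15% of samples, IQR < 2 px); the deep mode is adopted only when it
  places the fruit geometrically under the neighbour's right-image
  footprint — otherwise the deep samples are third-fruit contamination and
  the dominant mode stands.
* **Unresolved mixtures.** A detection whose disparity samples remain
  strongly bimodal after the pair logic (typically an unsplit two-fruit
  cell) reports *no* 3D position. An unmeasurable depth is reported as
  missing, never as a guess.

Depth follows as Z = f·B/d, and metric coordinates as
X = (col − c_x)·Z/f, Y = (row − c_y)·Z/f in the left-camera frame (X
right, Y down, Z forward; 0-based row/col pixels). Invalid regions of a
dense depth map can be filled by `fill_occluded_depth`, which interpolates
each hole linearly from the ring of valid pixels around it (nearest-valid
fallback outside the interpolation hull).

### Depth-validation protocol

Planar targets carrying a band-limited random texture (sums of 2-D cosines
with 5–20 px periods) are rendered at 800/900/1000/1100 mm; the right view
is the same analytic texture shifted by the exact disparity, so it carries
no resampling error. The band's lower limit keeps every component's period
well below the working disparities (a near-periodic texture at the
disparity scale makes matching ambiguous). Disparity is read at six
interior points per distance as the median of valid sub-pixel disparities
in an 11-px window, with every matching window kept clear of the left
border where no counterpart exists. A Gaussian perturbation (σ
configurable; 0.2 px in the headline protocol) models per-measurement
jitter; the perturbations are the first draws of the seeded generator so
they are independent of rendering internals. Noise-free, the protocol's
maximum relative depth error is below 0.1%.

With σ = 0.2 px the statistic "max over 24 points of relative depth error"
has median ≈1.0% across seeds (at 1100 mm one σ of disparity noise is
already 0.52% of depth), so reproducing a 0.97% bound under these noise
conditions succeeds for roughly half of the random seeds. This is a
property of the protocol's noise model, not of the matcher; the noise-free
accuracy above is the matcher's own contribution.

## Evaluation metrics

* **RA** = 100·TP/(TP+FN) with greedy nearest-first centroid matching; a
  detection may match a truth fruit whose centre lies within 1.0× the
  fruit's radius; each truth fruit matches at most once; ties break to the
  lower detection index.
* **MCD** = mean matched-centroid deviation as a percentage of the image
  diagonal (the percentage makes it resolution-free).
* **CRR** = percentage of truth fruits whose best instance-mask IoU against
  the true disc reaches 0.5 (equality counts).
* **Precision/recall/F1/AP** — single class; AP integrates the all-point
  interpolated precision-recall curve over the detection-score sweep.
* **Angle stability** — sample standard deviation (ddof = 1) of RA across
  replicate batches per simulated camera angle; the synthetic generator
  models viewing angle as fruit foreshortening (axis ratio cos θ).

## Synthetic scene generator

Scenes emulate the statistics that stress this kind of pipeline: red
(hue ≈ 0°) or green (hue ≈ 100°) fruit over a green canopy (hue ≈ 122°)
built from smoothed noise fields plus a few hundred leaf-like elliptical
blobs; radial shading with a per-fruit light direction; a deterministic
per-fruit surface speckle sampled in fruit-local coordinates so both stereo
views see the same texture at sub-pixel-consistent positions; day/noon/
night global brightness (×1.0/×1.1/×0.45) with per-scene brightness jitter;
additive Gaussian pixel noise per view; fruit drawn far-to-near so nearer
fruit occludes farther fruit consistently in both views. The right view
re-renders each fruit at its exact disparity f·B/Z, so triangulating the
true disparity recovers the assigned depth to machine precision.

Placement draws radius, depth and eccentricity independently; a
configurable fraction of fruit (default 25%) is placed deliberately
overlapping an earlier fruit with a pairwise overlap drawn up to
`max_overlap` (overlap = lens area over the smaller disc's area — the
per-pair, smaller-disc convention), and all placements are rejected beyond
`max_overlap`. Rendering is fully determined by (spec, seed) through one
PCG64 generator: identical inputs give bit-identical scenes.

Default study conditions (the "evaluation scale"): 960 × 540 frames with
fruit radii 13–30 px and depths 800–1700 mm — a half-scale rendition of a
1920 × 1080 orchard camera with 25–60 px fruit. Every reported metric (RA,
CRR, MCD%, relative depth error) is a scale-free ratio, and the rig
(f = 700 px, B = 60 mm) keeps the depth band in the same 25–52 px disparity
range as at full scale. Headline protocols: 50 stereo scenes with 5–15
apples each, alternating day/night lighting and red/green varieties,
brightness jitter ±20%, rotation jitter ±15°, noise σ = 4 (detection, MCD,
3D error); 40 scenes per overlap bin {0.1 … 0.5} (CRR); 6 points per
distance at 800–1100 mm (depth).

**What passing does not show.** The generator renders fruit as shaded
ellipses, not photorealistic apples: there is no leaf-level occluder
geometry (foliage never partially covers a fruit), no specular highlights
or lens distortion, no wind blur, and fruit size is independent of depth.
Hue distributions are narrower than a real orchard's. Results on these
scenes demonstrate the pipeline's geometric and statistical behaviour
(occlusion handling, lighting invariance of the hue channel, triangulation
accuracy), not field performance.

## Known limitations

* A fruit hidden in the right view with too little surviving surface
  reports no 3D fix (by design); a robot would re-observe from a different
  pose.
* Fruit sandwiched between two occluders can defeat the watershed
  separation; the merged cell then counts one false negative and, when its
  disparity samples stay bimodal, reports no depth.
* The fusion gate cannot reject a smooth, round, apple-coloured distractor
  — colour, texture and shape are exactly its cues.
* Green-on-green separation rests on a ≈20° hue gap plus a saturation gap;
  canopies whose saturation matches the fruit would require a third
  feature (e.g. intensity texture).
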