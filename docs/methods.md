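# Methods

## The measurement problem

Honey-bee subspecies identification traditionally relies on manually
placed wing landmarks and Procrustes superimposition. `beevein` instead
treats the venation network as a graph: after segmentation and thinning,
junctions and endpoints become nodes, vein segments become weighted
edges, and a fixed 45-dimensional statistic of that graph is the
phenotype. Graph statistics are invariant to rotation and translation,
need no point correspondences, and capture continuous gradients in
hybrids. Groups are then discovered by hierarchical clustering with an
adaptive dendrogram cut rather than a preset cluster count.

## Synthetic wings and what they do (and do not) model

`beevein.synthetic` renders vein networks from analytic curves so that
the exact mask, junction coordinates, endpoint coordinates and damage
labels are known. Longitudinal veins are quadratic Bézier profiles
branching from a short vertical basal stalk at separated attachment
points; cross-veins are straight chords between consecutive veins.
Ground-truth junctions are the pairwise analytic curve intersections,
deduplicated at 2 px to match the detector's merge semantics.

Two design choices deserve explanation:

* **A basal stalk, not a single fan point.** Curves through one point
  fuse into a solid wedge at any finite stroke width; thinning then forks
  them at stroke-dependent positions that no analytic ground truth can
  predict. Attachments separated along a stalk are T-junctions the
  raster actually realizes, which is what makes the generator a usable
  oracle for the junction detector (≥ 90% of analytic junctions recovered
  within 3 px; counts agree within ±10%).
* **Stereotyped venation.** Real venation is homologous: wings of one
  lineage carry essentially the same vein plan, and within-lineage
  intersection-density spread is a few percent of the mean, far below the
  between-lineage contrasts. The generator mirrors this: a wing carries
  round(rate × pairs) cross-veins spread evenly over the pairs, each in
  an evenly spaced span slot with small positional jitter, and the wing
  shape (bow) varies in a narrow conserved range. Only geometry jitter
  distinguishes wings of one regime. With independently random (Poisson,
  uniform-position) cross-veins, within-regime phenotype variance exceeds
  the between-regime gaps and no method could separate the regimes —
  the stereotyped model is both the more realistic one and the one under
  which separability claims are meaningful.

The three study regimes (`STUDY_REGIMES`) fix n_longitudinal = 5/6/7 and
cross_vein_rate = 0.5/1.2/2.0 (sparse/medium/dense), emulating the
lineage-level density gradient. Degradation adds a linear illumination
ramp (amplitude 0.12 by default), Gaussian noise (σ = 0.03), 10 dust
impulses of 1–2 px radius, and optional blur; injected damage is either a
wedge-shaped tear from the wing margin or an opaque occluding blob.

What the generator does **not** model: photorealistic membrane texture,
species-accurate Comstock–Needham vein identities, perspective and lens
distortion, or the long-tailed quality variation of field photography.
Passing tests demonstrate that the algorithms are correct and that the
pipeline separates venation phenotypes whose contrasts resemble the
lineage gradient; they do not certify accuracy on any particular
photographic dataset, which remains a matter of per-source calibration.

## Calibration profiles

All preprocessing parameters live in a `CalibrationProfile`. The default
profile carries the values calibrated for high-resolution wing
photographs (Gaussian σ 1.5 / 5×5; NLM h 7, 29-px patch, 42-px search
window; CLAHE 2.2 / 20×20; threshold block 33 / offset 9.1; 5×5 closing,
2×2 opening, 10-px component floor). The shipped `synthetic_desk`
profile was tuned once on representative synthetic wings, exactly as the
calibration protocol prescribes for a new imaging source: a narrower
Gaussian (σ 0.6), a lighter NLM neighborhood (7-px patch, 15-px window),
a larger threshold offset (26/255, trimming the blur halo around 3-px
strokes), and a 60-px component floor (dust specks reach ~13 px at this
scale while true vein fragments span 50+ px). Profiles are matched to
images by zero-normalized cross-correlation of 256-bin histograms.

Numerical conventions: images are float in [0, 1]; 8-bit-scale parameters
(NLM h, threshold offset) are divided by 255 internally; the NLM search
window w maps to scikit-image's patch_distance (w−1)/2; the CLAHE clip
limit follows the 8-bit convention and is divided by 256 for
scikit-image's fractional convention. The morphology chain ends with one
extra sweep of sub-minimum components because opening can shear small
fragments off larger ones, and the output contract (no component below
the floor) must hold unconditionally.

PCA alignment computes the principal axis of foreground pixel
coordinates, rotates it vertical about the centroid, and resolves the
180° ambiguity by placing the heavier half on top; covariance eigenvalue
gaps below 1e-6 are treated as isotropic (no rotation). The pipeline
leaves alignment off by default: the features are rotation-invariant and
synthetic wings are already standardized; the flag exists for real
photograph collections with varying orientation.

## Junction detection and graph building

Thinning is the classical two-subiteration Zhang–Suen rule set,
implemented in-repo (vectorized) and verified against an independently
written pixel-by-pixel implementation. Borders are padded with
background. Note one classical property: components at the 2×2-pixel
scale can be erased entirely; the segmentation stage never produces them
(component floor ≥ 10 px).

The hit-or-miss bank contains 10 base 3×3 patterns closed under 90°
rotation (34 distinct kernels): the orthogonal and diagonal crosses
(4-fold symmetric, strict background), and the four 3-arm topologies
whose arms are pairwise non-adjacent on the 8-neighbor ring (orthogonal
T, diagonal T, two mixed Y forms), each in a strict-background variant
and a corner-tolerant variant (background required only at non-arm
orthogonal positions). The non-adjacency constraint is what separates
junctions from thinning artifacts: staircase pixels of shallow curves
always carry an adjacent neighbor pair and match no kernel.

For landmark detection the bank is the detector. For graph building,
skeleton pixels with crossing number ≥ 3 (three 0→1 transitions around
the ring) that the bank does not cover are added as tracing anchors, so a
shallow fork can never orphan a branch. Junction pixels within 4 px merge
by union-find transitive closure into centroid nodes; endpoints (exactly
one neighbor) are their own nodes. Tracing walks unvisited skeleton
pixels between node pixels with two disambiguation rules found necessary
in practice: a pixel of the walk's own junction cluster only terminates a
genuine loop (path > 3 px), and among multiple continuations the walk
prefers pixels not adjacent to its previous position (the adjacent ones
are corner pixels of another branch). Leftover pixels adjacent to traced
structure are redundant staircase debris and are dropped; isolated cycles
get a synthetic node and a self-loop. Arc length is the chain metric
(1 per axial step, √2 per diagonal step); for edges between merged
clusters it can fall short of the centroid-to-centroid distance by up to
the merge radius.

## The 45 features

`density` (junction nodes / vein pixels); `seg_{mean,var,skew,kurt}`
(population moments of arc lengths); `cent_{deg,btw,clo,eig}_{...}`
(moments of per-node centralities: raw multigraph degree; betweenness
weighted by arc length, normalized per component; closeness with the
Wasserman–Faust component correction; eigenvector centrality from an
exact symmetric eigendecomposition per component, isolated nodes 0);
`glob_{nodes,edges,diam,apl,cc,assort}_{...}` (moments across connected
components of node count, edge count, weighted diameter, weighted average
path length, transitivity, degree assortativity). Per-component
statistics are used because skeletons of noisy images are routinely
disconnected; a single-component graph yields (value, 0, 0, 0) per
metric. All moments are population moments with explicit zero conventions
for empty sets and zero variance; shortest-path quantities use arc-length
weights while degree, clustering and assortativity use unweighted
structure (lengths matter for distances, not for local connectivity
counts). Undefined assortativity (regular components) is reported as 0.

## Anomaly filtering

The convolutional autoencoder is implemented directly on NumPy: strided
5×5 convolutions with ReLU, a 128-dim linear latent projection, and a
resize-convolution decoder (nearest-neighbor upsampling + stride-1
convolution, the standard checkerboard-free alternative to transposed
convolution), trained with Adam (lr 1e-3, β 0.9/0.999), learning-rate
halving after 5 stagnant epochs, early stopping (patience 10, delta
0.001), MSE loss. The full-scale layer plan uses widths
(32, 64, 128, 256, 512) at 256×256; the desk preset (8, 16, 32) at 64×64
trains on a ~100-image cohort in about two minutes on one CPU and is the
default for synthetic cohorts. Flagging uses the 3σ rule: error strictly
above μ + 3σ of the cohort's error distribution.

Division of labor, measured at desk scale: the reconstruction error
reliably flags **additive** artifacts (occluding blobs score ~30% above
clean wings) but not **subtractive** damage — a torn wedge is replaced by
easy-to-reconstruct background and can score below clean wings. Tears
are instead caught by the isolation forest on the 45 features, where
missing veins shift density and topology strongly. The combined filter
(either stage flags) reaches ≥ 0.8 recall on 10% injected tears and
occlusions while flagging ~2% of clean wings. The forest flags the top
⌈contamination · n⌉ scores deterministically; when screening a cohort
with a known injected-damage fraction the contamination is set to that
fraction, while the default 0.7% reflects routine screening of
predominantly clean collections.

## Clustering

Features are z-scored before Ward linkage: the raw columns span five
orders of magnitude, and unscaled Euclidean distances are dominated by
the single largest-variance column. Ward linkage follows the
Lance–Williams recurrence (delegated to scipy; verified against a
brute-force implementation on small fixtures to 1e-9).

Two adaptive-cut criteria are exposed. The **inconsistency coefficient**
(h − h̄)/σ_h with a depth-limited neighborhood (itself plus descendant
merges up to `depth` levels; ddof-1 standard deviation; 0 for
neighborhoods smaller than 2 or with zero spread) is the default for
`adaptive_cut` and matches scipy's `inconsistent`/`fcluster` exactly.
Note its dynamic range: with depth-2 neighborhoods (≤ 3 merges) the
coefficient is bounded near 1.15, and near √m for m-merge neighborhoods
generally — published threshold sweeps in the tens are only meaningful on
the **raw-height** scale, the second criterion, where a merge is broken
when its Ward height exceeds the threshold. `cluster_features` (and the
pipeline) therefore default to the height criterion with a
dendrogram-derived coarse grid (19 values spanning the height range)
followed by a refinement pass around the best coarse value — the familiar
coarse-then-refined sweep. Threshold selection averages silhouette /
Davies–Bouldin / Calinski–Harabasz over 5 seeded folds (degenerate folds
contribute −1 / +∞ / 0), maximizing silhouette with DBI then CH as
tie-breaks; because Ward heights grow like the square root of cluster
sizes, a fold of m samples is cut at the threshold rescaled by √(m/n).

On the reference study conditions (3 regimes × 50 degraded wings,
isolation-forest pre-filter at the default contamination), the search
selects k = 3 with silhouette ≈ 0.8 and adjusted Rand index 1.0 against
the true regimes, and the silhouette profile across thresholds is
unimodal with a broad plateau at k = 3.

## Problem sizes and determinism

Default synthetic images are 384×512 (large enough for the 20×20 CLAHE
grid and 33-px threshold blocks); cohort experiments use 40–50 wings per
regime; the autoencoder's desk preset is 64×64 with ≤ 30 epochs. Every
random choice flows from a single integer seed through
`numpy.random.default_rng`; identical spec + seed reproduces
byte-identical images, features and cluster labels.

## Known limitations

* Calibration transfer: the desk profile is tuned for the synthetic
  source; real collections need their own profile rows, and histogram
  matching only helps if a similar source was calibrated.
* The per-component reading of the global network statistics makes them
  sensitive to stray components; the component floor controls this but
  heavily fragmented skeletons will still inflate their spread.
* The desk-scale autoencoder cannot flag subtractive damage on its own
  (see above); at photographic resolution with the full-width plan this
  asymmetry should shrink but has not been measured here.
* Inconsistency-coefficient cutting is brittle when subtrees are very
  uniform (tiny σ_h explodes the coefficient on benign merges); the
  height criterion is the robust default, and the coefficient remains
  available for comparability.
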