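# beevein

Label-free morphometrics of honey-bee wing venation. Forewing vein
networks are heritable taxonomic markers: evolutionary lineages of *Apis
mellifera* differ in vein intersection density and branching complexity.
`beevein` turns a wing photograph into a quantitative venation phenotype
and discovers morphological groups without landmarks, labels, or genetic
data:

1. **Calibrated segmentation** — two-stage denoising (Gaussian blur σ=1.5,
   5×5 kernel, then non-local means with h=7, 29-px patches inside a 42-px
   search window), CLAHE (clip 2.2, 20×20 grid), optional PCA rotation
   alignment, adaptive Gaussian thresholding (33-px blocks, offset 9.1 on
   the 8-bit scale), and morphological refinement (5×5 closing, 2×2
   opening, removal of components under 10 px). Parameters live in
   per-imaging-source calibration profiles matched to new images by
   normalized cross-correlation of grayscale histograms
   (`configs/filter_params.csv`).
2. **Skeleton graphs** — Zhang–Suen thinning to a 1-px skeleton; junctions
   located by hit-or-miss transforms with a bank of 3×3 kernels (10 base
   patterns, 34 after rotational closure), merged by 4-px centroid
   averaging; vein segments traced pixel-by-pixel with the chain metric
   (1 / √2 per step) as arc length.
3. **A 45-dimensional feature vector** — intersection density (junctions
   per vein pixel), four population moments of segment lengths, sixteen
   centrality moments (degree, betweenness, closeness, eigenvector), and
   twenty-four global network statistics (node count, edge count,
   diameter, average path length, clustering coefficient, assortativity
   across connected components).
4. **Two-stage anomaly filtering** — a convolutional autoencoder flags
   images whose reconstruction error exceeds μ + 3σ; an isolation forest
   (100 trees, contamination 0.7% by default) flags structural outliers in
   feature space. An image is removed iff either stage flags it.
5. **Adaptive hierarchical clustering** — Ward linkage on standardized
   Euclidean distances; the dendrogram is cut where merges become
   inconsistent with their neighborhood, by the coefficient
   (h − h̄)/σ_h or by raw merge height, with the threshold selected by a
   5-fold grid search over silhouette / Davies–Bouldin /
   Calinski–Harabasz scores.

A synthetic wing generator (`beevein.synthetic`) renders vein networks
from analytic curves with exact ground-truth masks, junction coordinates
and damage labels, so every stage is testable without photographic data.

## Worked example

```
$ python examples/03_features_and_clustering.py
adaptive cut at threshold 10.9: k=3, silhouette 0.80, ARI vs true regimes 1.00
 cluster  size  density_mean  density_sd
       0    20      0.001070    0.000045
       1    20      0.001714    0.000066
       2    20      0.002457    0.000046
```

Sixty degraded synthetic wings from three venation regimes (sparse /
medium / dense) go through the full image pipeline; the adaptive cut finds
exactly three clusters that match the true regimes perfectly (adjusted
Rand index 1.00) with a silhouette of 0.80, and the per-cluster
intersection-density profile reproduces the sparse → dense gradient the
regimes encode. The other scripts in `examples/` demonstrate the
generator (`01`), segmentation + graph extraction (`02`), and the
two-stage anomaly filter (`04`).

The same pipeline is available from the shell:

```
beevein simulate --out cohort --n-per-regime 20 --seed 1
beevein run --input-dir cohort/images --output-dir results \
    --profiles-csv configs/filter_params.csv --seed 1
```

which persists masks, skeletons, graphs, the feature table, the anomaly
report, cluster labels and a run manifest.

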