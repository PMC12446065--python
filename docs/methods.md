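# Methods

## Data model and the FSC ratio

Events are an n × p matrix of channel values with per-channel roles (marker,
scatter area/height/width, derived) and per-event metadata. Marker channels
are variance-stabilized per marker (arcsinh with a configurable cofactor,
default 150, or a logicle transform inverted numerically from its
biexponential closed form); scatter channels are never transformed.

The multiplet-indicative feature is `fsc_ratio_raw = FSC-A / FSC-H`. Events
with FSC-H ≤ 0 (electronic artifacts) are excluded rather than clipped — the
ratio is undefined there and clipping would fabricate multiplet-like values.
Because the ratio (≈1–2) and transformed marker values (≈0–6) live on
different scales, a scaled copy is derived for clustering: a linear map of
the ratio's robust range (0.1/99.9 percentiles) onto the pooled marker
channels' robust range (default), or a monotone quantile map. Both are
strictly increasing, so event ordering by raw ratio is preserved exactly,
and the ratio derivation is invariant to common rescaling of FSC-A and
FSC-H.

CSV channel-value exports (header row, comma-separated) and a minimal
FCS 3.0/3.1 list-mode reader/writer (float data types) are supported; rows
with missing or non-numeric channel values are dropped and counted.

## Thresholding suite

All histogram methods operate on an equal-width histogram with ≥ 1000 bins
spanning the data range (data-driven min/max; the rightmost bin is closed).
A cut index t assigns bins 0..t to the low class; the reported threshold is
the bin edge `edges[t+1]`, in data units.

- **Otsu**: minimizes within-class weighted variance (equivalently maximizes
  `w0·w1·(μ0−μ1)²`) by exhaustive scan over all B−1 cuts.
- **IsoData** (Ridler–Calvard): fixed point of t = (mean below + mean
  above)/2, started at the median bin.
- **Intermodes**: 3-point moving-average smoothing until exactly two local
  maxima remain; cut midway between the peaks.
- **Rényi entropy**: maximizes `H_α(low) + H_α(high)` with
  `H_α = log(Σ(p/P)^α)/(1−α)`; α is a parameter (default 2; α→1 recovers the
  Kapur maximum-Shannon-entropy rule). The three-estimate ImageJ-style
  combination is not used because its spacing constants are hard-wired for
  256-bin histograms.
- **Li** (minimum cross entropy): iterates
  `t ← (μ_low−μ_high)/(ln μ_low − ln μ_high)`; the histogram is shifted so
  the lowest bin center is positive (one bin width) and shifted back, since
  the iteration requires positive support.
- **Shanbhag**: fuzzy-information balance — each class's information is a
  membership-weighted sum with membership fading by cumulative distance from
  the cut; the cut minimizing |I_low − I_high| wins.
- **Huang**: minimizes total Shannon fuzziness with membership
  `u = 1/(1+|c−μ_class|/range)`.
- **Mean**: arithmetic mean of the raw values.
- **Triangle**: chord from the histogram peak to the far end of the longer
  tail (mirrored if needed); the bin furthest below the chord is the cut.
- **k-means (k=2)** and **2-component GMM** operate on raw values (seeded,
  10 restarts); the k-means threshold is the midpoint of the two centers,
  the GMM threshold the weighted-density crossing between the component
  means, solved from the quadratic in closed form (variance-weighted
  midpoint if no crossing lies between the means).

Numerical conventions: iterative methods stop after 1000 iterations
(10000 smoothing passes for Intermodes) or at absolute tolerance 1e-8,
raising a convergence error that carries the last iterate; constant or
single-bin-mass inputs raise a degenerate-distribution error; thresholds
always lie within the data range.

**Tie-breaking.** With ≥1000 bins, the empty-bin gap between separated
modes makes every cut inside the gap produce the identical partition, so
scan-based objectives tie exactly over a contiguous plateau. The median
tied cut is returned: deterministic, and it places the threshold mid-gap
rather than at the sample maximum of the lower mode.

## Detection pipeline

Features: transformed markers, scatter channels, scaled FSC ratio; each
z-scored before PCA (mixed-unit features require it). Defaults follow the
workflow the package implements: PCA with n_features − 1 components; SNN
graph over the k = 20 nearest neighbors with Jaccard weights
(`|kNN_i ∩ kNN_j| / |kNN_i ∪ kNN_j|`, self excluded) pruned at 1/15;
Louvain communities at resolution 1.0 (Leiden, k-means and a k-means +
hierarchical-metaclustering alternative are available); a single clustering
run is used in the pipeline, consensus over repeated runs being a
benchmarking device. UMAP (30 neighbors, min cosine distance 0.3) is
provided for visualization only and never feeds classification.

**Sketching.** Datasets larger than `sketch_size` (default 50 000) are
subsampled by leverage scores: row leverages of the top-q (q ≤ 16)
randomized-SVD factorization of the standardized feature matrix, sampled
without replacement via the Gumbel top-k trick. Outlying rare
subpopulations have high leverage and are retained at a rate exceeding
their abundance — the relevant property here, since interacting cells are
rare. Cluster labels are extended to unsketched events with linear
discriminant analysis; when the pooled within-class scatter is singular the
covariance is shrunk diagonally (λ = 1e-4·trace/d, floored in the fully
degenerate case) and the linear rule applied directly. Sketched events keep
their original cluster labels.

**Cluster classification.** Per cluster, the fraction of events with scaled
ratio strictly above the threshold is computed; the cluster is *multiplet*
iff that fraction exceeds `majority_cutoff` (default 0.5, strict — a
cluster exactly at the cutoff stays singlet). Events in multiplet clusters
are extracted and the reduce→SNN→cluster chain re-run on that subset alone
(components recomputed on the subset) to resolve interaction types.

**Bimodality guard.** Every thresholding method returns *some* cut even
when the ratio distribution contains no multiplet mode, and singlet
populations with elevated pulse-shape ratios would then be flagged
wholesale. The pipeline therefore computes Ashman's
`D = |μ_hi−μ_lo| / sqrt((σ_lo²+σ_hi²)/2)` between the two classes the cut
induces. Splitting a single bell-shaped distribution yields D ≤ ~2.64 at
any cut position (the value is attained for a Gaussian and is remarkably
stable empirically), whereas a detached multiplet mode drives D well above
3. Below the floor (default 2.9) the threshold is declared unusable and no
cluster is called multiplet. The guard assumes the singlet ratio core is
bell-shaped — true for pulse-shape ratios by construction — and is a
pipeline-level safeguard; the per-cluster majority rule itself is exposed
unchanged.

Fixed seeds make the full chain bit-reproducible (sketch, community
detection and the stochastic threshold methods are all seeded;
reference mode is single-threaded).

## Annotation

Marker enrichment per cluster c and marker m against the pooled remaining
clusters:

```
raw(c,m) = sign(MED_c − MED_ref) · (|MED_c − MED_ref| + IQR_ref/IQR_c − 1)
```

then rescaled so the largest magnitude in the profile is 10 (identical
distributions score 0; a zero cluster IQR caps the spread term, default
100). The spread statistic (IQR) and the positivity cutoff (default 2.0 on
the ±10 scale) are parameters; the cutoff replaces expert judgment to keep
the pipeline automatable and is deliberately surfaced.

A cell type is detected when *all* markers of its defining combination are
enriched; nested definitions resolve to the most specific type (CD3+CD4 →
"CD4 T", not "T"). Interacting clusters whose detected types are pairwise
mutually exclusive (their markers share an exclusivity group) are labeled
with the alphabetically ordered partner combination ("A\*B", "A\*B\*C" for
triplets — which require ≥ 3 exclusive positive markers; >3-plex
composition is not resolved). Clusters enriched for one lineage only are
excluded as possible homotypic pairs; clusters matching no rule are
excluded as ambiguous. Annotation is a pure function of the profile and
panel.

## Interaction statistics

Frequencies are reported per sample under three normalizations: among all
retained ("live, high-quality") events — operationalized as events
surviving loading/transform filters and not in excluded clusters; as shares
of all interacting events (summing to 1 per sample); or as harmonic-mean
enrichments `e_AB = f_AB / H(f_A, f_B)`. Zero denominators yield NaN
(undefined), never 0. For triplets the generalized harmonic mean
`H(f_A,f_B,f_C) = 3/(1/f_A+1/f_B+1/f_C)` is provided as a natural
extension.

Supporting statistics: Fisher's exact test (two-sided, exact hypergeometric
p) with Haldane–Anscombe-corrected odds ratios (correction flagged in the
output); per-interaction log2 fold changes between conditions with a
pseudocount defaulting to half the smallest nonzero frequency; PCA-space
Euclidean distances from a reference-state centroid scaled so the farthest
sample is 1; seeded k-means (50 restarts, best within-cluster SS) for
temporal profiles; Benjamini–Hochberg (default) or Bonferroni adjustment.

## Synthetic data

Each population has an abundance, log-normal marker intensities (positive
markers: median 5000, σ_log 0.35; background: median 30, σ_log 0.8, arcsinh
cofactor 150 — placing positives ≈4 transformed units above background),
log-normal FSC-A (lymphocytes ≈0.9e5, monocytes 1.6e5; CV 0.3, broad enough
that a multiplet is not recognizable from summed area alone) and a singlet
pulse-shape ratio ≈ N(1.05, 0.02) (monocytes 1.07; in the confounder
variant N(1.18, 0.15), overlapping the multiplet range the way large
myeloid cells do). Multiplets sum their contributors' marker and
scatter-area signals; the combined height is
`max(H_i) + α·(ΣH_i − max(H_i))` with α = 0.1 — an explicit stand-in for
coincident-cell pulse formation, parameterizing how sub-additive the height
is so tests can sweep difficulty. Multiplicative Gaussian noise (2%) is
applied to all channels; contributing types are recorded exactly in the
truth label.

Pair composition follows the enrichment statistic's null: the rate of
unordered pair (A,B) is proportional to `λ_AB · H(p_A, p_B)` (λ = 1 unless
targeted; homotypic pairs included). With `doublet_rate="auto"` the total
pair mass is set self-consistently (d = s·Σw with s the singlet fraction),
which makes the ground-truth enrichment of every pair exactly its λ in
expectation — the basis of the recovery tests; a fixed doublet rate keeps
the composition but rescales the total. Default conditions: 4 populations
(T 40%, B 20%, NK 15%, monocytes 25%), 5% doublets, no triplets.

What the simulator does **not** emulate: spectral spillover/unmixing
residuals, autofluorescence structure, debris and dead cells, acquisition
drift, or instrument electronics beyond the α-rule. Passing tests therefore
demonstrate the pipeline's logic under a faithful but idealized generative
model, not performance on raw instrument files.

The shape-based debris filter for segmented images excludes objects with
major axis length outside [15, 40] px, circularity `4π·area/perimeter²`
below 0.7, or area outside [100, 1000] px (any criterion suffices).

## Problem sizes and runtime

Test and acceptance runs use 1e5-event simulations with 15 000-event
sketches for end-to-end checks, 4e4 events for the high-scatter-confounder
comparisons, 20 × 1e5 composition draws for enrichment recovery, and
exhaustive enumeration of all 2×2 tables with total ≤ 40 for the Fisher
oracle; these sizes give stable estimates (enrichment means reproducible to
±0.005) while the whole suite runs in a few minutes on one CPU.

## Known limitations

- Heterotypic annotation requires mutually exclusive markers; interactions
  between types sharing all panel markers are invisible, and homotypic
  interactions are excluded by design rather than resolved.
- The bimodality guard assumes a bell-shaped singlet-ratio core; strongly
  skewed or multi-shouldered singlet ratio distributions could defeat it in
  either direction (the floor is configurable).
- The MEM profile rescaling is per-profile; scores are comparable within a
  clustering, not across datasets.
- FCS support covers list-mode float data only (no integer types, analysis
  segments, or multi-dataset files).
- The enrichment null models pair formation, not conjugate stability; e_AB
  near 1 does not distinguish "no preference" from balanced opposing
  effects.
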