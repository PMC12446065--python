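# picflow

Detection, annotation and enrichment statistics for **physically interacting
cells (PICs)** in multiparameter flow cytometry.

Two or more cells in stable physical contact pass the cytometer's laser as a
*single* event. Standard practice discards such "doublets" during gating, but
for immunologists they are the signal: conjugates of T cells with B cells,
antigen-presenting cells or tumor cells report ongoing immune interactions.
`picflow` identifies these events among singlets, labels which cell types are
interacting, and quantifies whether an interaction occurs more often than
expected by chance.

## The model in brief

**FSC ratio.** A cytometric pulse has an area (FSC-A) and a peak height
(FSC-H). When several cells traverse the laser as one event the area grows
roughly additively while the height is sub-additive, so the ratio

```
fsc_ratio = FSC-A / FSC-H
```

sits near the instrument's pulse-shape floor (≈1) for singlets and rises for
multiplets. A histogram-thresholding suite (Otsu by default; IsoData,
Intermodes, Rényi entropy, Li, Shanbhag, Huang, Mean, Triangle, k-means
(k=2) and a 2-component Gaussian mixture are also implemented) cuts the
ratio distribution, using ≥ 1000 histogram bins.

**Cluster-level classification.** A global ratio cut misclassifies singlet
populations with unusual pulse shapes — classically large myeloid cells.
`picflow` therefore clusters events on markers + scatter + scaled FSC ratio
(leverage-score sketch → PCA with n−1 components → shared-nearest-neighbor
graph, k = 20, Jaccard weights → Louvain communities → linear-discriminant
label projection to all events) and calls a whole cluster *multiplet* only
when the majority of its events exceed the threshold. Events in multiplet
clusters are extracted and re-clustered for a refined characterization.

**Annotation.** Interacting clusters are annotated from **mutually exclusive
lineage markers**: co-enrichment of CD19 with CD3/CD4 inside one cluster
indicates a B cell bound to a CD4 T cell ("B\*CD4 T"). Enrichment is scored
by marker-enrichment modeling (signed median shift plus IQR ratio against
the pooled remaining clusters, scaled to ±10). Clusters enriched for a
single lineage may be homotypic pairs and are excluded.

**Enrichment statistic.** For cell types A, B with singlet frequencies
`f_A`, `f_B` and observed interaction frequency `f_AB`, the expected rate is
the harmonic mean of the partner frequencies and the enrichment is the
observed/expected ratio:

```
E_AB = H(f_A, f_B) = 2 f_A f_B / (f_A + f_B)        e_AB = f_AB / E_AB
```

`H` tends strongly toward the rarer partner (`E_AB ≈ 2 f_B` when
`f_A ≫ f_B`) yet still increases with the abundant partner's frequency
(`∂E_AB/∂f_A = 2 f_B² / (f_A+f_B)² > 0`). Under pairing proportional to the
expected rate, `e_AB = 1`; values above 1 mark preferential interaction.

A fully parameterized synthetic-cytometry simulator (log-normal marker
intensities, population-specific scatter, sub-additive multiplet pulse
heights, exact ground-truth labels) makes every stage testable without
instrument data.

## Worked example

```python
from picflow import (PipelineConfig, run_pic_pipeline, compute_fsc_ratio,
                     transform_intensities, default_panel, default_spec,
                     simulate_cytometry, classification_metrics, mem_scores,
                     annotate_clusters)

panel = default_panel()                      # T/B/NK/Mono, one lineage marker each
spec = default_spec(doublet_rate=0.05)       # 5% cell-cell multiplets
events = simulate_cytometry(spec, 50000, seed=1)
events = compute_fsc_ratio(transform_intensities(events, panel))

result = run_pic_pipeline(events, PipelineConfig(sketch_size=10000, seed=1))
print(f"threshold (Otsu, scaled ratio): {result.threshold.threshold:.3f}")
print(f"interacting events: {result.report['n_interacting']} / {result.report['n_events']}")

truth = events.meta["truth_label"].to_numpy()
scores = classification_metrics(truth, result.event_class)
print(f"singlet/multiplet F1 vs ground truth: {scores['f1_multiplet']:.3f}")

sub = events.subset(result.interacting_index)
profile = mem_scores(sub, result.interacting_result.labels, list(panel.channel_to_marker))
annotations = annotate_clusters(profile, panel, positivity_cutoff=2.0)
print(annotations[annotations["class"] == "annotated"]["label"].value_counts().to_string())
```

prints

```
threshold (Otsu, scaled ratio): 2.247
interacting events: 2504 / 50000
singlet/multiplet F1 vs ground truth: 1.000
label
B*NK       1
Mono*NK    1
Mono*T     1
NK*T       1
B*Mono     1
B*T        1
```

i.e. the pipeline recovers the simulated 5% interacting compartment
essentially perfectly and resolves one interacting cluster per heterotypic
type pair (homotypic clusters are excluded by design).

The same workflow is available from the shell:

```
picflow simulate --n 100000 --doublet-rate 0.05 --seed 7 --out synth.csv
picflow detect --input synth.csv --sketch 20000 --threshold-method otsu --seed 7 --out results/
picflow annotate --input synth.csv --clusters results/
```

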