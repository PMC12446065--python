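"""Sketch → PCA → SNN graph → community detection → label projection →
cluster-level singlet/multiplet classification.

The pipeline clusters events on cell-type markers, scatter channels and the
scaled FSC ratio, then calls a whole cluster "multiplet" when the majority of
its events sit above an automatically determined FSC-ratio threshold.  This
cluster-level rule outperforms cutting events one by one because singlet
populations with atypically high or broad scatter pulses (classically
monocytes and other myeloid cells) form their own clusters and are rescued,
instead of leaking across a global cut.

Large datasets are subsampled with a leverage-score sketch that over-retains
rare subpopulations; cluster labels are extended from the sketch to all
events with a linear discriminant classifier.  Events landing in multiplet
clusters are extracted and the same chain re-run on them alone for a refined
characterization of the interacting compartment.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import EventTable, RATIO_SCALED
from .thresholding import ThresholdResult, compute_threshold

__all__ = [
    "PipelineConfig",
    "ClusterResult",
    "PipelineResult",
    "sketch_events",
    "reduce_dimensions",
    "build_snn_graph",
    "cluster_events",
    "project_labels",
    "classify_clusters",
    "run_pic_pipeline",
    "embed_map",
]


@dataclass
class PipelineConfig:
    """Knobs of the detection pipeline.

    ``n_components=None`` means one fewer than the number of features; the
    SNN graph uses ``k_neighbors`` nearest neighbors with Jaccard weights
    pruned at ``snn_prune``; ``majority_cutoff`` is the fraction of
    above-threshold events needed (strictly) to call a cluster multiplet.
    """

    sketch_size: int = 50000
    sketch_method: str = "leverage_sketch"
    n_components: int | None = None
    k_neighbors: int = 20
    clustering: str = "louvain"
    resolution: float = 1.0
    snn_prune: float = 1.0 / 15.0
    threshold_method: str = "otsu"
    threshold_bins: int = 1000
    majority_cutoff: float = 0.5
    umap_neighbors: int = 30
    umap_min_dist: float = 0.3
    umap_metric: str = "cosine"
    min_bimodality: float = 2.9
    seed: int = 0


@dataclass
class ClusterResult:
    """Per-event cluster ids plus a per-cluster summary table."""

    labels: np.ndarray
    features_used: list[str]
    per_cluster: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class PipelineResult:
    cluster_result: ClusterResult
    interacting_result: ClusterResult | None
    threshold: ThresholdResult
    event_class: np.ndarray          # per-event "singlet"/"multiplet"
    interacting_index: np.ndarray    # indices of events in multiplet clusters
    report: dict


# --------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def sketch_events(events: EventTable, target_n: int, method: str = "leverage_sketch",
                  seed: int = 0, features: list[str] | None = None) -> np.ndarray:
    """Select ``target_n`` distinct event indices for clustering.

    ``leverage_sketch`` samples without replacement with probability
    proportional to statistical leverage in a randomized low-rank projection
    of the standardized feature matrix, so small outlying subpopulations
    (rare cell types, multiplets) are retained at a rate exceeding their
    abundance.  ``uniform`` is plain random subsampling.
    """
    if events.n_events == 0:
        raise ValueError("empty event table")
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    n = events.n_events
    if target_n >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    if method == "uniform":
        return np.sort(rng.choice(n, size=target_n, replace=False))
    if method != "leverage_sketch":
        raise ValueError(f"unknown sketch method {method!r}")

    if features is None:
        features = events.channels_by_role("marker", "scatter_area", "scatter_height",
                                           "scatter_width", "derived")
    x = _standardize(events.matrix(features))
    q = min(x.shape[1], 16)
    from sklearn.utils.extmath import randomized_svd

    u, _, _ = randomized_svd(x, n_components=q, random_state=int(seed) % (2 ** 31))
    leverage = np.einsum("ij,ij->i", u, u)
    leverage = np.maximum(leverage, 1e-12)
    # Gumbel top-k trick == sampling without replacement ∝ leverage
    keys = np.log(leverage) + rng.gumbel(size=n)
    return np.sort(np.argpartition(-keys, target_n)[:target_n])


def reduce_dimensions(events_or_matrix, features: list[str] | None = None,
                      n_components: int | None = None):
    """Per-channel z-score then PCA.

    Returns ``(scores, loadings, explained_variance)``; loadings are the
    orthonormal principal axes (components x features).  ``n_components``
    defaults to n_features - 1 and may not exceed n_features.
    """
    if isinstance(events_or_matrix, EventTable):
        if features is None:
            raise ValueError("features required with an EventTable input")
        x = events_or_matrix.matrix(features)
    else:
        x = np.asarray(events_or_matrix, dtype=float)
    d = x.shape[1]
    if n_components is None:
        n_components = d - 1
    if not 1 <= n_components <= d:
        raise ValueError(f"n_components must be in [1, {d}], got {n_components}")
    from sklearn.decomposition import PCA

    xs = _standardize(x)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(xs)
    return scores, pca.components_, pca.explained_variance_


def build_snn_graph(scores: np.ndarray, k_neighbors: int = 20, prune: float = 1.0 / 15.0):
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Nodes are events; for every pair appearing in each other's k-NN
    neighborhoods the weight is ``|kNN_i ∩ kNN_j| / |kNN_i ∪ kNN_j|``
    (self excluded); edges with weight <= ``prune`` are removed.  Returns a
    symmetric ``scipy.sparse.csr_matrix``.
    """
    import scipy.sparse as sp
    from sklearn.neighbors import NearestNeighbors

    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_events={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    neigh = idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sp.csr_matrix((np.ones(n * k_neighbors), (rows, neigh.ravel())), shape=(n, n))
    shared = adj @ adj.T  # shared[i, j] = |kNN_i ∩ kNN_j|
    shared = shared.tocoo()
    jac = shared.data / (2.0 * k_neighbors - shared.data)
    mask = (jac > prune) & (shared.row != shared.col)
    graph = sp.csr_matrix((jac[mask], (shared.row[mask], shared.col[mask])), shape=(n, n))
    return graph.maximum(graph.T)


def _to_igraph(graph):
    import igraph as ig
    import scipy.sparse as sp

    coo = sp.triu(graph, k=1).tocoo()
    g = ig.Graph(n=graph.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    g.es["weight"] = coo.data.tolist()
    return g


def cluster_events(graph, method: str = "louvain", resolution: float = 1.0,
                   seed: int = 0, n_iterations: int = 2,
                   scores: np.ndarray | None = None) -> ClusterResult:
    """Partition the SNN graph into communities.

    ``louvain`` (igraph multilevel) and ``leiden`` use modularity with the
    given resolution; ``kmeans`` and ``flowsom_like`` (k-means pre-clustering
    followed by hierarchical meta-clustering of the centroids) operate on the
    PCA ``scores`` instead of the graph.  Seeded, hence deterministic.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if method in ("kmeans", "flowsom_like"):
        if scores is None:
            raise ValueError(f"method {method!r} requires scores")
        from sklearn.cluster import AgglomerativeClustering, KMeans

        if method == "kmeans":
            k = max(2, int(round(10 * resolution)))
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(scores)
        else:
            k_pre = min(max(20, scores.shape[0] // 100), 100, scores.shape[0])
            km = KMeans(n_clusters=k_pre, n_init=3, random_state=seed).fit(scores)
            n_meta = max(2, int(round(10 * resolution)))
            meta = AgglomerativeClustering(n_clusters=min(n_meta, k_pre)).fit_predict(
                km.cluster_centers_)
            labels = meta[km.labels_]
        return ClusterResult(np.asarray(labels), [], params={"method": method, "seed": seed})

    if graph is None or graph.shape[0] == 0:
        raise ValueError("empty graph")
    g = _to_igraph(graph)
    if method == "louvain":
        import igraph as ig

        state = _random.Random(int(seed))
        ig.set_random_number_generator(state)
        try:
            part = g.community_multilevel(weights="weight" if g.ecount() else None,
                                          resolution=resolution)
        finally:
            ig.set_random_number_generator(_random)
        labels = np.asarray(part.membership)
        modularity = part.modularity
    elif method == "leiden":
        import leidenalg as la

        part = la.find_partition(g, la.RBConfigurationVertexPartition,
                                 weights="weight" if g.ecount() else None,
                                 resolution_parameter=resolution,
                                 n_iterations=n_iterations, seed=int(seed))
        labels = np.asarray(part.membership)
        modularity = g.modularity(labels, weights="weight" if g.ecount() else None)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return ClusterResult(labels, [], params={"method": method, "resolution": resolution,
                                             "seed": seed, "modularity": float(modularity)})


def project_labels(sketch_features: np.ndarray, sketch_labels: np.ndarray,
                   all_features: np.ndarray, sketch_index: np.ndarray | None = None):
    """Extend sketch cluster labels to every event with an LDA classifier.

    Trains linear discriminant analysis on the sketched events; unsketched
    events get the classifier prediction, sketched events keep their original
    labels (when ``sketch_index`` is given).  Falls back to a shrinkage
    estimator of the within-class scatter when it is singular.
    Returns ``(labels, info)``.
    """
    sketch_labels = np.asarray(sketch_labels)
    classes, counts = np.unique(sketch_labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 members each")
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    x = np.asarray(sketch_features, dtype=float)
    all_x = np.asarray(all_features, dtype=float)
    d = x.shape[1]
    # pooled within-class scatter rank decides whether shrinkage is needed
    sw = np.zeros((d, d))
    for cl in classes:
        xc = x[sketch_labels == cl]
        xc = xc - xc.mean(axis=0)
        sw += xc.T @ xc
    singular = np.linalg.matrix_rank(sw) < d
    if singular:
        # diagonal shrinkage of the pooled covariance (floored for the
        # fully degenerate zero-scatter case), then the usual linear rule
        cov = sw / max(len(x) - len(classes), 1)
        lam = max(1e-4 * np.trace(cov) / d, 1e-8 * max(np.abs(x).max() ** 2, 1.0))
        cov = cov + lam * np.eye(d)
        inv = np.linalg.inv(cov)
        means = np.stack([x[sketch_labels == cl].mean(axis=0) for cl in classes])
        priors = counts / counts.sum()
        disc = all_x @ inv @ means.T - 0.5 * np.einsum("kd,dj,kj->k", means, inv, means) \
            + np.log(priors)
        labels = classes[np.argmax(disc, axis=1)]
    else:
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(x, sketch_labels)
        labels = lda.predict(all_x)
    if sketch_index is not None:
        labels[np.asarray(sketch_index)] = sketch_labels
    return labels, {"shrinkage_fallback": bool(singular)}


def classify_clusters(labels: np.ndarray, fsc_ratio: np.ndarray,
                      threshold: ThresholdResult | float,
                      majority_cutoff: float = 0.5,
                      features_used: list[str] | None = None) -> ClusterResult:
    """Call each cluster singlet or multiplet by its above-threshold fraction.

    A cluster is "multiplet" iff the fraction of its events with FSC ratio
    strictly above the threshold exceeds ``majority_cutoff`` (strict
    inequality: a cluster sitting exactly at the cutoff stays singlet).
    """
    labels = np.asarray(labels)
    fsc_ratio = np.asarray(fsc_ratio, dtype=float)
    thr = threshold.threshold if isinstance(threshold, ThresholdResult) else float(threshold)
    rows = []
    for cl in np.unique(labels):
        in_cluster = labels == cl
        frac = float(np.mean(fsc_ratio[in_cluster] > thr))
        rows.append({
            "cluster_id": cl,
            "n_events": int(in_cluster.sum()),
            "frac_above_threshold": frac,
            "class": "multiplet" if frac > majority_cutoff else "singlet",
        })
    per_cluster = pd.DataFrame(rows).set_index("cluster_id")
    return ClusterResult(labels, features_used or [], per_cluster,
                         params={"threshold": thr, "majority_cutoff": majority_cutoff})


def _cluster_chain(features_matrix: np.ndarray, config: PipelineConfig, seed: int):
    """reduce → SNN → cluster on an already-sketched feature matrix."""
    n, d = features_matrix.shape
    n_comp = config.n_components or max(1, min(d - 1, n - 1))
    n_comp = min(n_comp, d, n - 1)
    scores, _, _ = reduce_dimensions(features_matrix, n_components=n_comp)
    k = min(config.k_neighbors, n - 1)
    graph = build_snn_graph(scores, k_neighbors=k, prune=config.snn_prune)
    result = cluster_events(graph, method=config.clustering, resolution=config.resolution,
                            seed=seed, scores=scores)
    return scores, result


def run_pic_pipeline(events: EventTable, config: PipelineConfig | None = None) -> PipelineResult:
    """Full detection chain on a transformed event table with derived FSC ratio.

    Steps: threshold the scaled FSC ratio; sketch; PCA (n_features - 1
    components); SNN graph (k=20); community detection; LDA projection of
    cluster labels to all events; majority-rule cluster classification;
    extraction and re-clustering of the interacting compartment.  The whole
    chain is deterministic for a fixed seed.
    """
    config = config or PipelineConfig()
    if RATIO_SCALED not in events.channel_names:
        raise ValueError("run compute_fsc_ratio first (fsc_ratio_scaled channel missing)")
    features = events.channels_by_role("marker", "scatter_area", "scatter_height",
                                       "scatter_width")
    features = features + [RATIO_SCALED]
    ratio = events.channel(RATIO_SCALED)
    threshold = compute_threshold(ratio, method=config.threshold_method,
                                  n_bins=config.threshold_bins, seed=config.seed)
    # Every thresholding method returns *some* cut even when the ratio
    # distribution has no multiplet mode at all.  Ashman's D between the two
    # classes the cut induces detects this: splitting a single bell-shaped
    # distribution yields D <= ~2.64 at any cut, while a detached multiplet
    # mode drives D well above 3.  Below the floor the threshold is declared
    # unusable and no cluster is called multiplet.
    lo = ratio[ratio <= threshold.threshold]
    hi = ratio[ratio > threshold.threshold]
    if len(lo) > 1 and len(hi) > 1:
        ashman_d = abs(hi.mean() - lo.mean()) / np.sqrt((lo.var() + hi.var()) / 2.0)
    else:
        ashman_d = 0.0
    threshold_usable = ashman_d >= config.min_bimodality

    report = {"n_events": events.n_events, "features": features,
              "threshold": threshold.threshold, "threshold_method": config.threshold_method,
              "ashman_d": float(ashman_d), "threshold_usable": bool(threshold_usable),
              "config": asdict(config)}

    x_all = events.matrix(features)
    sketch_idx = sketch_events(events, config.sketch_size, config.sketch_method,
                               seed=config.seed, features=features)
    report["n_sketched"] = int(len(sketch_idx))
    x_sketch = x_all[sketch_idx]
    _, sketch_result = _cluster_chain(x_sketch, config, config.seed)

    if len(sketch_idx) < events.n_events:
        labels, proj_info = project_labels(x_sketch, sketch_result.labels, x_all, sketch_idx)
        report["lda"] = proj_info
    else:
        labels = sketch_result.labels

    cluster_result = classify_clusters(labels, ratio, threshold,
                                       config.majority_cutoff, features)
    if not threshold_usable:
        cluster_result.per_cluster["class"] = "singlet"
    cluster_result.params.update(sketch_result.params)
    multiplet_ids = cluster_result.per_cluster.index[
        cluster_result.per_cluster["class"] == "multiplet"]
    event_class = np.where(np.isin(labels, multiplet_ids), "multiplet", "singlet")
    interacting_index = np.flatnonzero(event_class == "multiplet")
    report["n_interacting"] = int(len(interacting_index))
    report["n_singlet"] = int(events.n_events - len(interacting_index))

    interacting_result = None
    if len(interacting_index) > config.k_neighbors + 1:
        x_int = x_all[interacting_index]
        if len(interacting_index) > config.sketch_size:
            sub = events.subset(interacting_index)
            idx2 = sketch_events(sub, config.sketch_size, config.sketch_method,
                                 seed=config.seed + 1, features=features)
            _, int_sketch = _cluster_chain(x_int[idx2], config, config.seed + 1)
            int_labels, _ = project_labels(x_int[idx2], int_sketch.labels, x_int, idx2)
        else:
            _, int_sketch = _cluster_chain(x_int, config, config.seed + 1)
            int_labels = int_sketch.labels
        interacting_result = classify_clusters(int_labels, ratio[interacting_index],
                                               threshold, config.majority_cutoff, features)
        interacting_result.params.update(int_sketch.params)
    elif len(interacting_index) == 0:
        import warnings

        warnings.warn("no multiplet cluster found; interacting result is empty")

    return PipelineResult(cluster_result, interacting_result, threshold,
                          event_class, interacting_index, report)


def embed_map(scores: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """2-D UMAP embedding of the PCA scores, for visualization only."""
    config = config or PipelineConfig()
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < config.umap_neighbors + 1:
        raise ValueError(f"need at least umap_neighbors+1={config.umap_neighbors + 1} events")
    import warnings

    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_neighbors=config.umap_neighbors,
                            min_dist=config.umap_min_dist,
                            metric=config.umap_metric,
                            random_state=int(config.seed) % (2 ** 31))
        return reducer.fit_transform(scores)
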