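"""Ground-truth-labeled synthetic cytometry data and benchmarking utilities.

The simulator emulates a multi-population singlet landscape (log-normal
marker intensities, population-specific forward/side scatter) plus multiplet
events formed by coincident or conjugated cells: fluorescence and scatter
*area* signals of the contributors add, while the pulse *height* is
sub-additive — the combined FSC-H is ``max(H_i) + alpha * (sum(H_i) -
max(H_i))`` with a small alpha, which is what drives the FSC ratio of
multiplets above that of singlets.  Every multiplet's contributing types are
recorded in the truth label, so any threshold/clustering configuration can
be scored against exact ground truth.

Multiplet composition follows the harmonic-mean pairing model: the rate of
unordered pair (A, B) is proportional to ``lambda_AB * H(p_A, p_B)``, the
null of the interaction-enrichment statistic (lambda = 1 everywhere means
e_AB = 1; a targeted pair with lambda = 3 has ground-truth enrichment 3
when the total pair mass is left at its self-consistent "auto" value).

Also here: the shape-based debris filter used on segmented brightfield
images, and F1/ARI scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable, PanelSpec, infer_channel_roles
from .stats import harmonic_mean

__all__ = [
    "Population",
    "SyntheticSpec",
    "simulate_composition",
    "simulate_cytometry",
    "default_spec",
    "default_panel",
    "debris_filter",
    "classification_metrics",
    "run_benchmark",
    "truth_is_multiplet",
]


@dataclass
class Population:
    """One singlet population: abundance, log-normal marker signals and
    scatter pulse statistics.

    ``markers`` maps marker name -> (median, sigma_log) of the raw signal;
    markers not listed fall back to the autofluorescence background.
    ``ratio_mean``/``ratio_sd`` set the population's singlet FSC-A/FSC-H
    pulse-shape ratio (slightly above 1 on real instruments; larger and
    broader for big, granular cells such as monocytes).
    """

    name: str
    abundance: float
    markers: dict[str, tuple[float, float]]
    fsc_a_mean: float = 1.0e5
    fsc_a_cv: float = 0.15
    ssc_a_mean: float = 0.5e5
    ssc_a_cv: float = 0.25
    ratio_mean: float = 1.05
    ratio_sd: float = 0.02


@dataclass
class SyntheticSpec:
    """Generative description of a synthetic cytometry experiment.

    ``doublet_rate``/``triplet_rate`` are event fractions; ``"auto"`` for
    the doublet rate uses the self-consistent mass of the harmonic pairing
    model so the ground-truth enrichment of every pair equals its lambda.
    ``targeted_pairs`` maps an unordered type pair to an enrichment factor.
    ``height_alpha`` controls how sub-additive the combined FSC-H is.
    """

    populations: list[Population]
    doublet_rate: float | str = 0.05
    triplet_rate: float = 0.0
    pairing_model: str = "random_proportional"
    targeted_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    include_homotypic: bool = True
    height_alpha: float = 0.1
    noise_sd: float = 0.02
    background: tuple[float, float] = (30.0, 0.8)

    def __post_init__(self) -> None:
        total = sum(p.abundance for p in self.populations)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"population abundances must sum to 1, got {total}")
        if self.pairing_model not in ("random_proportional", "targeted"):
            raise ValueError(f"unknown pairing model {self.pairing_model!r}")
        if self.pairing_model == "targeted" and not self.targeted_pairs:
            raise ValueError("targeted pairing requires targeted_pairs")
        for rate in (self.triplet_rate,) + (() if self.doublet_rate == "auto"
                                            else (self.doublet_rate,)):
            if not 0 <= float(rate) < 1:
                raise ValueError("rates must be in [0, 1)")

    @property
    def marker_names(self) -> list[str]:
        names: list[str] = []
        for p in self.populations:
            for m in p.markers:
                if m not in names:
                    names.append(m)
        return names

    def pair_weights(self) -> dict[tuple[str, str], float]:
        """Unordered pair rates lambda_AB * H(p_A, p_B) (unnormalized)."""
        weights = {}
        for pa, pb in itertools.combinations_with_replacement(self.populations, 2):
            if pa.name == pb.name and not self.include_homotypic:
                continue
            key = tuple(sorted((pa.name, pb.name)))
            lam = self.targeted_pairs.get(key, self.targeted_pairs.get(key[::-1], 1.0))
            weights[key] = lam * harmonic_mean(pa.abundance, pb.abundance)
        return weights


def _doublet_mass(spec: SyntheticSpec) -> tuple[dict, float]:
    """Per-pair probabilities and total doublet fraction.

    "auto": total pair mass w_sum * s with singlet fraction s solving
    s = 1 - triplet_rate - s * w_sum, so the realized f_AB equals
    lambda_AB * H(f_A, f_B) in expectation and e_AB = lambda_AB exactly.
    """
    weights = spec.pair_weights()
    w_sum = sum(weights.values())
    if spec.doublet_rate == "auto":
        s = (1.0 - spec.triplet_rate) / (1.0 + w_sum)
        d_total = s * w_sum
    else:
        d_total = float(spec.doublet_rate)
    probs = {k: v / w_sum * d_total for k, v in weights.items()}
    return probs, d_total


def simulate_composition(spec: SyntheticSpec, n_events: int, seed: int = 0) -> pd.DataFrame:
    """Draw only the event compositions (no signals): one row per event with
    columns ``kind`` ("singlet"/"doublet"/"triplet"), ``members`` (sorted
    tuple of contributing population names) and ``truth_label``."""
    rng = np.random.default_rng(seed)
    pair_probs, d_total = _doublet_mass(spec)
    pairs = list(pair_probs)
    categories = pairs + ["__triplet__", "__singlet__"]
    p = np.array([pair_probs[k] for k in pairs]
                 + [spec.triplet_rate, 1.0 - d_total - spec.triplet_rate])
    if p[-1] < 0:
        raise ValueError("doublet + triplet rates exceed 1")
    draws = rng.choice(len(categories), size=n_events, p=p)
    pop_names = [pop.name for pop in spec.populations]
    abundances = np.array([pop.abundance for pop in spec.populations])
    rows = []
    for d in draws:
        cat = categories[d]
        if cat == "__singlet__":
            name = pop_names[rng.choice(len(pop_names), p=abundances)]
            rows.append(("singlet", (name,), f"singlet:{name}"))
        elif cat == "__triplet__":
            members = tuple(sorted(pop_names[i] for i in
                                   rng.choice(len(pop_names), size=3, p=abundances)))
            rows.append(("triplet", members, "triplet:" + ",".join(members)))
        else:
            members = tuple(sorted(cat))
            rows.append(("doublet", members, "doublet:" + ",".join(members)))
    return pd.DataFrame(rows, columns=["kind", "members", "truth_label"])


def _draw_singlet_signals(pop: Population, n: int, markers: list[str],
                          background: tuple[float, float], rng) -> dict[str, np.ndarray]:
    out = {}
    for m in markers:
        med, sig = pop.markers.get(m, background)
        out[m] = rng.lognormal(np.log(med), sig, size=n)
    fsc_a = pop.fsc_a_mean * rng.lognormal(0.0, pop.fsc_a_cv, size=n)
    ratio = np.maximum(rng.normal(pop.ratio_mean, pop.ratio_sd, size=n), 1.0)
    out["FSC-A"] = fsc_a
    out["FSC-H"] = fsc_a / ratio
    out["SSC-A"] = pop.ssc_a_mean * rng.lognormal(0.0, pop.ssc_a_cv, size=n)
    return out


def simulate_cytometry(spec: SyntheticSpec, n_events: int, seed: int = 0) -> EventTable:
    """Simulate a raw (untransformed) event table with exact truth labels.

    Singlets are drawn per population; a multiplet's marker and scatter-area
    signals are the sums over its contributors while FSC-H follows the
    sub-additive alpha-rule, so the multiplet FSC ratio is stochastically
    larger than either contributor's.  Multiplicative Gaussian noise of
    relative magnitude ``noise_sd`` is applied to every channel.
    """
    rng = np.random.default_rng(seed)
    comp = simulate_composition(spec, n_events, seed=int(rng.integers(2 ** 31)))
    markers = spec.marker_names
    channels = markers + ["FSC-A", "FSC-H", "SSC-A"]
    values = np.zeros((n_events, len(channels)))
    pop_by_name = {p.name: p for p in spec.populations}

    member_lists = comp["members"].to_numpy()
    n_members = np.array([len(m) for m in member_lists])
    # draw each contributing cell, then combine per event
    flat_names = [name for members in member_lists for name in members]
    event_of_cell = np.repeat(np.arange(n_events), n_members)
    flat_names = np.array(flat_names)
    cell_signals = np.zeros((len(flat_names), len(channels)))
    for name, pop in pop_by_name.items():
        mask = flat_names == name
        if not mask.any():
            continue
        sig = _draw_singlet_signals(pop, int(mask.sum()), markers, spec.background, rng)
        for j, ch in enumerate(channels):
            cell_signals[mask, j] = sig[ch]

    h_col = channels.index("FSC-H")
    # areas and marker signals add across contributors
    for j, ch in enumerate(channels):
        if j == h_col:
            continue
        np.add.at(values[:, j], event_of_cell, cell_signals[:, j])
    # FSC-H: max + alpha * (sum - max)
    h = cell_signals[:, h_col]
    h_sum = np.zeros(n_events)
    np.add.at(h_sum, event_of_cell, h)
    h_max = np.zeros(n_events)
    np.maximum.at(h_max, event_of_cell, h)
    values[:, h_col] = h_max + spec.height_alpha * (h_sum - h_max)

    if spec.noise_sd > 0:
        values *= 1.0 + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.maximum(values, 1e-6)

    meta = pd.DataFrame({"truth_label": comp["truth_label"].to_numpy(),
                         "sample_id": "synthetic"})
    roles = infer_channel_roles(channels)
    for m in markers:
        roles[m] = "marker"
    return EventTable(values, channels, roles, meta)


def truth_is_multiplet(truth_labels) -> np.ndarray:
    """Boolean mask: True for doublet/triplet/multiplet truth labels."""
    return np.array([not str(t).startswith("singlet") for t in truth_labels])


# --------------------------------------------------------------------------
# default study conditions

def default_spec(doublet_rate: float | str = 0.05, high_scatter_confounder: bool = False,
                 targeted_pairs: dict | None = None, triplet_rate: float = 0.0) -> SyntheticSpec:
    """PBMC-like landscape: T, B, NK and monocytes with one lineage marker
    each (plus CD45 on all).  With ``high_scatter_confounder`` the monocytes
    get a high and broad pulse-shape ratio that overlaps the doublet range,
    emulating the myeloid singlets that a global FSC-ratio cut misclassifies.
    """
    hi, lo = (5000.0, 0.35), (30.0, 0.8)
    mono_ratio = (1.18, 0.15) if high_scatter_confounder else (1.07, 0.025)
    # broad scatter pulses (CV ~0.3, as in real cytometry) mean a multiplet
    # is not recognizable from its summed area alone — the pulse shape
    # (FSC ratio) carries that information
    pops = [
        Population("T", 0.40, {"CD45": hi, "CD3": hi}, fsc_a_mean=0.9e5, fsc_a_cv=0.3),
        Population("B", 0.20, {"CD45": hi, "CD19": hi}, fsc_a_mean=0.85e5, fsc_a_cv=0.3),
        Population("NK", 0.15, {"CD45": hi, "CD56": hi}, fsc_a_mean=0.95e5, fsc_a_cv=0.3),
        Population("Mono", 0.25, {"CD45": hi, "CD33": hi, "HLA-DR": hi},
                   fsc_a_mean=1.6e5, fsc_a_cv=0.3, ssc_a_mean=1.2e5, ssc_a_cv=0.35,
                   ratio_mean=mono_ratio[0], ratio_sd=mono_ratio[1]),
    ]
    # make sure every population draws every marker (background for negatives)
    for p in pops:
        for m in ("CD45", "CD3", "CD19", "CD56", "CD33", "HLA-DR"):
            p.markers.setdefault(m, lo)
    return SyntheticSpec(pops, doublet_rate=doublet_rate, triplet_rate=triplet_rate,
                         pairing_model="targeted" if targeted_pairs else "random_proportional",
                         targeted_pairs=targeted_pairs or {})


def default_panel() -> PanelSpec:
    """Panel matching ``default_spec``: identity channel map, one defining
    lineage marker per cell type, a single mutual-exclusivity group and
    arcsinh (cofactor 150) transforms."""
    markers = ["CD45", "CD3", "CD19", "CD56", "CD33", "HLA-DR"]
    return PanelSpec(
        channel_to_marker={m: m for m in markers},
        celltype_markers={"T": {"CD3"}, "B": {"CD19"}, "NK": {"CD56"}, "Mono": {"CD33"}},
        exclusivity_groups=[{"CD3", "CD19", "CD56", "CD33"}],
        transforms={m: ("arcsinh", 150.0) for m in markers},
    )


# --------------------------------------------------------------------------
# debris filter and metrics

def debris_filter(shapes: pd.DataFrame,
                  major_axis_range: tuple[float, float] = (15.0, 40.0),
                  circularity_min: float = 0.7,
                  area_range: tuple[float, float] = (100.0, 1000.0)) -> pd.Series:
    """Keep/exclude flags for segmented objects based on shape.

    An object is excluded if ANY criterion fires: major axis length outside
    [15, 40] px, circularity (4*pi*area/perimeter^2) below 0.7, or area
    outside [100, 1000] px.  Returns a boolean keep mask aligned with the
    input; a ``circularity`` column is added to ``shapes`` in place.
    """
    for col in ("area", "perimeter", "major_axis_length"):
        if col not in shapes.columns:
            raise ValueError(f"missing column {col!r}")
    if (shapes["perimeter"] <= 0).any() or (shapes["area"] <= 0).any():
        raise ValueError("area and perimeter must be positive")
    circ = 4.0 * np.pi * shapes["area"] / shapes["perimeter"] ** 2
    shapes["circularity"] = circ
    keep = (
        shapes["major_axis_length"].between(*major_axis_range)
        & (circ >= circularity_min)
        & shapes["area"].between(*area_range)
    )
    return keep.rename("keep")


def classification_metrics(truth, predicted) -> dict:
    """F1 for the multiplet class, macro F1 and ARI against ground truth.

    ``truth`` may be truth-label strings (reduced to singlet/multiplet for
    the F1s) or already-binary labels matching ``predicted``'s vocabulary.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("label vectors must have equal length")
    from sklearn.metrics import adjusted_rand_score, f1_score

    t_bin = np.where(truth_is_multiplet(truth), "multiplet", "singlet") \
        if truth.dtype.kind in "UO" and any(":" in str(t) for t in truth) else truth.astype(str)
    p_bin = predicted.astype(str)
    return {
        "f1_multiplet": float(f1_score(t_bin, p_bin, pos_label="multiplet",
                                       labels=["singlet", "multiplet"], average="binary",
                                       zero_division=0)),
        "macro_f1": float(f1_score(t_bin, p_bin, average="macro", zero_division=0)),
        "ari": float(adjusted_rand_score(t_bin, p_bin)),
    }


def run_benchmark(events: EventTable, threshold_methods=("otsu",),
                  clustering_methods=("louvain",), n_iterations: int = 1,
                  seed: int = 0, config=None) -> pd.DataFrame:
    """Score threshold-only and cluster-based singlet/multiplet calls.

    For every (threshold method, iteration) the direct event-level cut of
    the scaled FSC ratio is always scored as the baseline; every (threshold
    x clustering) configuration is run through the full pipeline.  Requires
    truth labels; returns a tidy per-iteration results table.
    """
    from .io import RATIO_SCALED
    from .pipeline import PipelineConfig, run_pic_pipeline
    from .thresholding import compute_threshold

    if "truth_label" not in events.meta.columns:
        raise ValueError("ground-truth labels required for benchmarking")
    truth = events.meta["truth_label"].to_numpy()
    ratio = events.channel(RATIO_SCALED)
    base = config or PipelineConfig()
    rows = []
    for it in range(n_iterations):
        it_seed = seed + it
        for tm in threshold_methods:
            thr = compute_threshold(ratio, method=tm, n_bins=base.threshold_bins,
                                    seed=it_seed)
            pred = np.where(ratio > thr.threshold, "multiplet", "singlet")
            rows.append({"iteration": it, "mode": "threshold_only", "threshold_method": tm,
                         "clustering": "", "threshold": thr.threshold, "seed": it_seed,
                         **classification_metrics(truth, pred)})
            for cm in clustering_methods:
                cfg = PipelineConfig(**{**base.__dict__, "threshold_method": tm,
                                        "clustering": cm, "seed": it_seed})
                result = run_pic_pipeline(events, cfg)
                rows.append({"iteration": it, "mode": "cluster_based",
                             "threshold_method": tm, "clustering": cm,
                             "threshold": result.threshold.threshold, "seed": it_seed,
                             **classification_metrics(truth, result.event_class)})
    return pd.DataFrame(rows)
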