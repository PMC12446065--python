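"""Cluster annotation from marker-enrichment profiles.

Singlet clusters are labeled with the cell type whose defining marker
combination is enriched.  Interacting (multiplet) clusters are labeled with
the unordered combination of cell types whose *mutually exclusive* lineage
markers are simultaneously enriched — e.g. CD19 together with CD3 and CD4
inside one cluster indicates a B cell bound to a CD4 T cell, written
"B*CD4 T" (partners sorted alphabetically, since cytometry cannot order
them).  Clusters enriched for markers of a single lineage may be homotypic
pairs or cells about to divide and are excluded, as are clusters matching no
rule.

Enrichment uses a marker-enrichment-modeling (MEM) style score per cluster
and marker: the signed median shift against the pooled remaining clusters
plus the reference/cluster IQR ratio minus one, scaled so the largest
magnitude in the profile is 10.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import EventTable, PanelSpec

__all__ = ["mem_scores", "annotate_clusters"]


def mem_scores(events: EventTable, labels, markers: list[str],
               spread_cap: float = 100.0, scale_to: float = 10.0) -> pd.DataFrame:
    """Marker-enrichment score per (cluster, marker) against all other clusters.

    raw(c, m) = sign(MED_c - MED_ref) * (|MED_c - MED_ref| + IQR_ref/IQR_c - 1)

    with the reference distribution pooled over every other cluster.  A zero
    cluster IQR caps the spread term at ``spread_cap``.  The raw matrix is
    scaled so ``max |score| == scale_to`` (identical distributions score 0).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters for a pooled reference")
    x = events.matrix(markers)
    scores = np.zeros((len(clusters), len(markers)))
    for i, cl in enumerate(clusters):
        mask = labels == cl
        own = x[mask]
        ref = x[~mask]
        med_own = np.median(own, axis=0)
        med_ref = np.median(ref, axis=0)
        iqr_own = np.subtract(*np.percentile(own, [75, 25], axis=0))
        iqr_ref = np.subtract(*np.percentile(ref, [75, 25], axis=0))
        if np.any(iqr_ref == 0):
            raise ValueError("zero spread in reference distribution")
        with np.errstate(divide="ignore"):
            spread = np.where(iqr_own > 0, iqr_ref / iqr_own, spread_cap)
        spread = np.minimum(spread, spread_cap)
        delta = med_own - med_ref
        scores[i] = np.sign(delta) * (np.abs(delta) + spread - 1.0)
    max_abs = np.abs(scores).max()
    if max_abs > 0:
        scores = scores / max_abs * scale_to
    scores = np.clip(scores, -scale_to, scale_to)
    return pd.DataFrame(scores, index=pd.Index(clusters, name="cluster_id"), columns=markers)


def _detected_celltypes(enriched: set[str], panel: PanelSpec) -> dict[str, set[str]]:
    """Cell types whose full defining marker set is enriched; keep only the
    most specific ones (drop types whose marker set is a strict subset of
    another detected type's, so CD3+CD4 reads as CD4 T, not T and CD4 T)."""
    detected = {ct: set(ms) for ct, ms in panel.celltype_markers.items()
                if set(ms) <= enriched}
    keep = {}
    for ct, ms in detected.items():
        if any(ms < other for o_ct, other in detected.items() if o_ct != ct):
            continue
        keep[ct] = ms
    return keep


def _mutually_exclusive(ms_a: set[str], ms_b: set[str], panel: PanelSpec) -> bool:
    """True if some marker of A and some marker of B share an exclusivity group."""
    for group in panel.exclusivity_groups:
        if (ms_a & group) and (ms_b & group) and not (ms_a & ms_b & group):
            return True
    return False


def annotate_clusters(profile: pd.DataFrame, panel: PanelSpec,
                      positivity_cutoff: float = 2.0,
                      compartment: str = "interacting") -> pd.DataFrame:
    """Turn a MEM profile into cluster annotations.

    ``compartment="singlet"``: each cluster gets the single most specific
    cell type whose defining markers all score above the cutoff (ties broken
    by total marker score); no match -> excluded/"ambiguous".

    ``compartment="interacting"``: the cluster is labeled "A*B" (or
    "A*B*C"...) from the detected cell types that are pairwise mutually
    exclusive.  One detected type -> excluded/"homotypic" (could be a
    homotypic pair); none -> excluded/"ambiguous".

    Pure function of the profile and panel; deterministic.
    """
    if compartment == "interacting" and not panel.exclusivity_groups:
        raise ValueError("panel defines no exclusivity groups")
    rows = []
    for cluster_id, row in profile.iterrows():
        enriched = {m for m in profile.columns if row[m] >= positivity_cutoff}
        detected = _detected_celltypes(enriched, panel)
        if compartment == "singlet":
            if not detected:
                rows.append((cluster_id, "excluded", "", "ambiguous"))
                continue
            best = max(detected, key=lambda ct: (sum(row[m] for m in detected[ct]), ct))
            rows.append((cluster_id, "annotated", best, ""))
            continue
        # interacting compartment
        types = sorted(detected)
        exclusive = [ct for ct in types
                     if any(_mutually_exclusive(detected[ct], detected[o], panel)
                            for o in types if o != ct)]
        if len(exclusive) >= 2:
            rows.append((cluster_id, "annotated", "*".join(sorted(exclusive)), ""))
        elif len(types) >= 1:
            rows.append((cluster_id, "excluded", "", "homotypic"))
        else:
            rows.append((cluster_id, "excluded", "", "ambiguous"))
    return pd.DataFrame(rows, columns=["cluster_id", "class", "label", "reason"]
                        ).set_index("cluster_id")
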