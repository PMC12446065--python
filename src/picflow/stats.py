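"""Interaction frequencies, harmonic-mean enrichment, and cohort statistics.

For cell types A and B with singlet fractions ``f_A``, ``f_B`` (among all
live, high-quality events) and observed interaction fraction
``f_AB = O_AB``, the expected interaction rate is the harmonic mean

    E_AB = H(f_A, f_B) = 2 f_A f_B / (f_A + f_B)

and the enrichment is ``e_AB = O_AB / E_AB``.  The harmonic mean tends
strongly toward the smaller of the two frequencies (E_AB ≈ 2 f_B when
f_A >> f_B), so the expected rate of an interaction involving a rare
partner is governed by that partner — yet E_AB still increases with the
abundant partner's frequency (∂E_AB/∂f_A = 2 f_B² / (f_A+f_B)² > 0).
Under pairing proportional to that expected rate, e_AB = 1; e_AB > 1 marks
preferential interaction.

Also here: Fisher's exact test with Haldane–Anscombe-corrected odds ratios,
condition log2 fold changes, PCA distances from a reference state, and
seeded k-means for temporal profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "harmonic_mean",
    "expected_rate",
    "interaction_frequencies",
    "enrichment_monotonicity_check",
    "fisher_odds_ratio",
    "condition_log2fc",
    "pca_distance_summary",
    "temporal_kmeans",
    "adjust_pvalues",
]


def harmonic_mean(*fracs: float) -> float:
    """H(f_1..f_k) = k / sum(1/f_i).  For k=2 this is the expected
    interaction rate; k>=3 is the natural generalization used for triplets."""
    fracs = np.asarray(fracs, dtype=float)
    if np.any(fracs <= 0):
        return np.nan
    return float(len(fracs) / np.sum(1.0 / fracs))


expected_rate = harmonic_mean


def interaction_frequencies(events: pd.DataFrame,
                            normalization: str = "harmonic_enrichment") -> pd.DataFrame:
    """Per-sample interaction frequencies under one of three normalizations.

    ``events`` must carry one row per event with columns ``sample_id``,
    ``kind`` in {"singlet", "interaction", "excluded"} and ``label`` (cell
    type for singlets, "A*B" partner combination for interactions); excluded
    events do not count toward any denominator.

    - ``of_all_events``: f_AB among all retained events;
    - ``of_all_interactions``: share within interacting events (sums to 1
      per sample);
    - ``harmonic_enrichment``: adds singlet fractions of both partners, the
      harmonic-mean expected rate E_AB and the enrichment e_AB = f_AB/E_AB.

    Frequencies with a zero denominator are NaN (undefined), never 0.
    """
    required = {"sample_id", "kind", "label"}
    if not required <= set(events.columns):
        raise ValueError(f"events must have columns {sorted(required)}")
    if normalization not in ("of_all_events", "of_all_interactions", "harmonic_enrichment"):
        raise ValueError(f"unknown normalization {normalization!r}")
    meta_cols = [c for c in ("condition", "timepoint") if c in events.columns]
    rows = []
    for sample, grp in events.groupby("sample_id", sort=True):
        retained = grp[grp["kind"] != "excluded"]
        n_total = len(retained)
        inter = retained[retained["kind"] == "interaction"]
        singlets = retained[retained["kind"] == "singlet"]
        singlet_frac = (singlets["label"].value_counts() / n_total) if n_total else pd.Series()
        meta = {c: grp[c].iloc[0] for c in meta_cols}
        for label, count in inter["label"].value_counts().items():
            row = {"sample_id": sample, "interaction": label, "count": int(count), **meta}
            if normalization == "of_all_interactions":
                row["frequency"] = count / len(inter) if len(inter) else np.nan
            else:
                f_ab = count / n_total if n_total else np.nan
                row["frequency"] = f_ab
                if normalization == "harmonic_enrichment":
                    partners = label.split("*")
                    fs = [float(singlet_frac.get(p, 0.0)) for p in partners]
                    e_exp = harmonic_mean(*fs)
                    row.update({f"f_{chr(65 + i)}": f for i, f in enumerate(fs)})
                    row["E"] = e_exp
                    row["enrichment"] = f_ab / e_exp if e_exp and not np.isnan(e_exp) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def enrichment_monotonicity_check(f_a_grid, f_b: float, tol: float = 1e-6) -> bool:
    """Verify ∂E_AB/∂f_A > 0 on a grid by central finite differences.

    Compares the analytic derivative ``2 f_B² / (f_A + f_B)²`` with the
    numerical one and checks strict positivity; returns True when both hold.
    """
    f_a = np.asarray(f_a_grid, dtype=float)
    if np.any(f_a <= 0) or f_b <= 0:
        raise ValueError("frequencies must be positive")
    h = 1e-6 * np.maximum(f_a, 1e-3)
    e = lambda fa: 2.0 * fa * f_b / (fa + f_b)
    numeric = (e(f_a + h) - e(f_a - h)) / (2 * h)
    analytic = 2.0 * f_b ** 2 / (f_a + f_b) ** 2
    return bool(np.all(analytic > 0) and np.all(np.abs(numeric - analytic) < tol
                                                + 1e-4 * np.abs(analytic)))


def fisher_odds_ratio(table) -> dict:
    """Two-sided Fisher's exact test with a Haldane–Anscombe odds ratio.

    ``table`` is a 2x2 array ``[[a, b], [c, d]]`` of nonnegative integer
    counts.  OR = (a·d)/(b·c); when any cell is zero, 0.5 is added to every
    cell for the OR (flagged via ``"haldane_corrected"``).  The p-value is
    the exact two-sided hypergeometric tail sum at fixed margins.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(np.asarray(table, dtype=float) < 0):
            raise ValueError("counts must be nonnegative integers")
        t = np.asarray(table, dtype=int)
        if not np.allclose(t, np.asarray(table, dtype=float)):
            raise ValueError("counts must be integers")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("row and column sums must be positive")
    from scipy.stats import fisher_exact

    _, p = fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    corrected = bool((t == 0).any())
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return {"odds_ratio": float(odds), "log2_or": float(np.log2(odds)),
            "p_two_sided": float(p), "haldane_corrected": corrected}


def condition_log2fc(freqs: pd.DataFrame, contrast: tuple[str, str],
                     pseudocount: float | None = None) -> pd.DataFrame:
    """Per-interaction log2 fold change between two conditions.

    ``freqs`` is long-format with columns ``interaction``, ``condition``,
    ``frequency`` (plus optional ``sample_id``).  The fold change is
    ``log2((x_t + eps) / (x_c + eps))`` with the pseudocount defaulting to
    half the smallest nonzero frequency; replicate-wise values are summarized
    as mean and standard deviation per interaction.  Swapping the contrast
    negates every value.
    """
    treat, ctrl = contrast
    for cond in contrast:
        if cond not in set(freqs["condition"]):
            raise ValueError(f"condition {cond!r} not present")
    if pseudocount is None:
        nonzero = freqs.loc[freqs["frequency"] > 0, "frequency"]
        pseudocount = float(nonzero.min()) / 2.0 if len(nonzero) else 1e-9
    rows = []
    for interaction, grp in freqs.groupby("interaction", sort=True):
        x_t = grp.loc[grp["condition"] == treat, "frequency"].to_numpy(dtype=float)
        x_c = grp.loc[grp["condition"] == ctrl, "frequency"].to_numpy(dtype=float)
        if len(x_t) == 0 or len(x_c) == 0:
            continue
        if len(x_t) == len(x_c):
            lfc = np.log2(x_t + pseudocount) - np.log2(x_c + pseudocount)
        else:  # unbalanced replication: contrast the condition means
            lfc = np.array([np.log2(x_t.mean() + pseudocount)
                            - np.log2(x_c.mean() + pseudocount)])
        rows.append({"interaction": interaction, "log2fc": float(np.mean(lfc)),
                     "log2fc_sd": float(np.std(lfc, ddof=1)) if len(lfc) > 1 else 0.0,
                     "n_pairs": int(len(lfc)), "pseudocount": pseudocount})
    return pd.DataFrame(rows).set_index("interaction")


def pca_distance_summary(freq_matrix: pd.DataFrame, reference: list) -> pd.Series:
    """Scaled Euclidean distance of every sample from a reference state.

    Projects the samples x features frequency matrix into PCA space,
    measures each sample's distance to the centroid of the ``reference``
    samples, and scales by the maximum so the farthest sample is exactly 1
    (all zero when every sample is identical).
    """
    if len(freq_matrix) < 2:
        raise ValueError("need >= 2 samples")
    reference = list(reference)
    if not reference:
        raise ValueError("reference sample set is empty")
    from sklearn.decomposition import PCA

    x = freq_matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if np.allclose(x, 0):
        return pd.Series(0.0, index=freq_matrix.index)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    ref_mask = freq_matrix.index.isin(reference)
    if not ref_mask.any():
        raise ValueError("no reference sample found in the matrix index")
    centroid = scores[ref_mask].mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    if dist.max() > 0:
        dist = dist / dist.max()
    return pd.Series(dist, index=freq_matrix.index)


def temporal_kmeans(profiles: pd.DataFrame, k: int = 7, seed: int = 0,
                    n_restarts: int = 50) -> pd.Series:
    """Seeded k-means on feature profiles (rows), standardized per column.

    Runs ``n_restarts`` initializations and keeps the best within-cluster
    sum of squares; assignments are deterministic given the seed.
    """
    x = profiles.to_numpy(dtype=float)
    if k >= x.shape[0]:
        raise ValueError(f"k={k} must be < number of profiles {x.shape[0]}")
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2 ** 31))
    labels = km.fit_predict(xs)
    out = pd.Series(labels, index=profiles.index, name="cluster")
    out.attrs["inertia"] = float(km.inertia_)
    return out


def adjust_pvalues(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini–Hochberg default, "bonferroni"
    available), applied per contrast family by the caller."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method=method)[1]
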