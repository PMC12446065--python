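"""Harmonic-mean enrichment identities, Fisher/odds-ratio oracle, contrasts,
PCA distances and temporal k-means."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from picflow.stats import (condition_log2fc, enrichment_monotonicity_check,
                           fisher_odds_ratio, harmonic_mean,
                           interaction_frequencies, pca_distance_summary,
                           temporal_kmeans)


def _events_from_counts(singlets: dict, interactions: dict, other: int = 0,
                        sample="s1", condition=None) -> pd.DataFrame:
    rows = []
    for label, n in singlets.items():
        rows += [{"sample_id": sample, "kind": "singlet", "label": label}] * n
    for label, n in interactions.items():
        rows += [{"sample_id": sample, "kind": "interaction", "label": label}] * n
    rows += [{"sample_id": sample, "kind": "singlet", "label": "other"}] * other
    df = pd.DataFrame(rows)
    if condition is not None:
        df["condition"] = condition
    return df


class TestHarmonicEnrichment:
    def test_worked_count_example(self):
        """100 events: 40 A singlets, 10 B, 16 A*B doublets, 34 other
        => f_A=0.40, f_B=0.10, f_AB=0.16, E=0.16, e=1.0 exactly."""
        ev = _events_from_counts({"A": 40, "B": 10}, {"A*B": 16}, other=34)
        out = interaction_frequencies(ev, "harmonic_enrichment").set_index("interaction")
        row = out.loc["A*B"]
        assert row["f_A"] == 0.40 and row["f_B"] == 0.10
        assert row["frequency"] == 0.16
        assert row["E"] == pytest.approx(2 * 0.4 * 0.1 / 0.5, abs=1e-15)
        assert row["enrichment"] == pytest.approx(1.0, abs=1e-12)

    def test_share_normalization_sums_to_one_per_sample(self):
        ev = pd.concat([
            _events_from_counts({"A": 30}, {"A*B": 5, "A*C": 7, "B*C": 2}, sample="s1"),
            _events_from_counts({"A": 20}, {"A*B": 3, "B*C": 9}, sample="s2"),
        ])
        out = interaction_frequencies(ev, "of_all_interactions")
        sums = out.groupby("sample_id")["frequency"].sum()
        assert sums.to_numpy() == pytest.approx([1.0, 1.0])

    def test_rare_partner_limit(self):
        """f_A >> f_B: E -> 2 f_B with relative deviation f_B/(f_A+f_B)."""
        f_a, f_b = 0.5, 0.0005
        e = harmonic_mean(f_a, f_b)
        assert e == pytest.approx(0.0005 / 0.5005 * 2 * f_a, rel=1e-12)
        rel_dev = (2 * f_b - e) / (2 * f_b)
        assert rel_dev == pytest.approx(f_b / (f_a + f_b), rel=1e-9)

    def test_diagonal_point(self):
        assert harmonic_mean(0.3, 0.3) == pytest.approx(0.3)

    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_harmonic_mean_bounds(self, f_a, f_b):
        e = harmonic_mean(f_a, f_b)
        assert min(f_a, f_b) <= e + 1e-15
        assert e <= 2 * min(f_a, f_b) + 1e-15

    def test_zero_denominator_is_nan_not_zero(self):
        ev = _events_from_counts({}, {"A*B": 3})  # no singlets at all
        out = interaction_frequencies(ev, "harmonic_enrichment").set_index("interaction")
        assert np.isnan(out.loc["A*B", "enrichment"])

    def test_monotonicity_check_passes_on_grid(self):
        assert enrichment_monotonicity_check(np.linspace(0.1, 0.9, 100), 0.1)

    def test_monotonicity_check_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            enrichment_monotonicity_check([0.0, 0.5], 0.1)

    def test_enrichment_invariant_to_subsampling(self):
        rng = np.random.default_rng(0)
        ev = _events_from_counts({"A": 4000, "B": 1000}, {"A*B": 1600}, other=3400)
        full = interaction_frequencies(ev).set_index("interaction").loc["A*B", "enrichment"]
        sub_es = []
        for seed in range(20):
            sub = ev.sample(frac=0.3, random_state=seed)
            out = interaction_frequencies(sub).set_index("interaction")
            sub_es.append(out.loc["A*B", "enrichment"])
        assert np.mean(sub_es) == pytest.approx(full, rel=0.05)


def _fisher_p_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration of same-margin tables."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)
    probs = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((x, comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_cross_product_arithmetic(self):
        out = fisher_odds_ratio([[10, 90], [10, 990]])
        assert out["odds_ratio"] == pytest.approx(11.0)
        assert out["log2_or"] == pytest.approx(np.log2(11.0), abs=1e-9)

    def test_no_association(self):
        out = fisher_odds_ratio([[5, 5], [5, 5]])
        assert out["odds_ratio"] == 1.0
        assert out["p_two_sided"] == pytest.approx(1.0)

    def test_zero_cell_haldane_corrected(self):
        out = fisher_odds_ratio([[0, 10], [10, 10]])
        assert out["haldane_corrected"] is True
        assert out["odds_ratio"] == pytest.approx(0.5 * 10.5 / (10.5 * 10.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_odds_ratio([[1, -2], [3, 4]])

    def test_p_matches_enumeration_on_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 8, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = fisher_odds_ratio([[a, b], [c, d]])["p_two_sided"]
            assert ours == pytest.approx(_fisher_p_oracle(a, b, c, d), rel=1e-8)


class TestLog2FC:
    def _freqs(self):
        return pd.DataFrame({
            "interaction": ["A*B"] * 4 + ["A*C"] * 4,
            "condition": ["treated", "treated", "control", "control"] * 2,
            "frequency": [0.08, 0.08, 0.02, 0.02, 0.05, 0.05, 0.05, 0.05],
        })

    def test_equal_frequencies_zero(self):
        out = condition_log2fc(self._freqs(), ("treated", "control"))
        assert out.loc["A*C", "log2fc"] == pytest.approx(0.0)

    def test_fourfold_change_approx_two(self):
        out = condition_log2fc(self._freqs(), ("treated", "control"), pseudocount=1e-9)
        assert out.loc["A*B", "log2fc"] == pytest.approx(2.0, abs=1e-6)

    def test_antisymmetry_under_contrast_swap(self):
        fwd = condition_log2fc(self._freqs(), ("treated", "control"))
        rev = condition_log2fc(self._freqs(), ("control", "treated"))
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            condition_log2fc(self._freqs(), ("treated", "vehicle"))


class TestPcaDistance:
    def test_identical_samples_all_zero(self):
        m = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        d = pca_distance_summary(m, reference=["a"])
        assert (d == 0).all()

    def test_planted_shift_orders_groups(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.1, (5, 6))
        shifted = base + 3.0
        m = pd.DataFrame(np.r_[base, shifted],
                         index=[f"r{i}" for i in range(5)] + [f"s{i}" for i in range(5)])
        d = pca_distance_summary(m, reference=[f"r{i}" for i in range(5)])
        assert d[:5].mean() < d[5:].mean()
        assert d.max() == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca_distance_summary(pd.DataFrame([[1.0, 2.0]]), reference=[0])


class TestTemporalKmeans:
    def test_recovers_planted_profile_shapes(self):
        rng = np.random.default_rng(3)
        shapes = np.array([[0, 1, 2, 3], [3, 2, 1, 0], [0, 3, 0, 3]], dtype=float)
        rows, truth = [], []
        for k, s in enumerate(shapes):
            for _ in range(10):
                rows.append(s + rng.normal(0, 0.05, 4))
                truth.append(k)
        prof = pd.DataFrame(rows)
        labels = temporal_kmeans(prof, k=3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k1_wcss_equals_total_ss(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.normal(size=(20, 3)))
        labels = temporal_kmeans(prof, k=1, seed=0)
        assert labels.nunique() == 1
        x = prof.to_numpy()
        xs = (x - x.mean(0)) / x.std(0)
        assert labels.attrs["inertia"] == pytest.approx(((xs - xs.mean(0)) ** 2).sum())

    def test_restarts_never_worse_than_single_run(self):
        rng = np.random.default_rng(5)
        prof = pd.DataFrame(rng.normal(size=(60, 5)))
        best = temporal_kmeans(prof, k=7, seed=1, n_restarts=50).attrs["inertia"]
        single = temporal_kmeans(prof, k=7, seed=1, n_restarts=1).attrs["inertia"]
        assert best <= single + 1e-9

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            temporal_kmeans(pd.DataFrame(np.zeros((5, 2))), k=5)
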