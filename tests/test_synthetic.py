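"""Simulator bookkeeping, multiplet signal construction, debris filter and
scoring metrics."""

import numpy as np
import pandas as pd
import pytest

from picflow.io import RATIO_RAW, compute_fsc_ratio
from picflow.synthetic import (SyntheticSpec, classification_metrics, debris_filter,
                               default_spec, simulate_composition, simulate_cytometry,
                               truth_is_multiplet)


class TestSimulator:
    def test_zero_doublet_rate_all_singlets(self):
        ev = simulate_cytometry(default_spec(doublet_rate=0.0), 2000, seed=0)
        assert not truth_is_multiplet(ev.meta["truth_label"]).any()

    def test_doublet_fraction_within_binomial_error(self):
        n, rate = 100000, 0.05
        ev = simulate_composition(default_spec(doublet_rate=rate), n, seed=1)
        observed = (ev["kind"] == "doublet").mean()
        sd = np.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) < 3 * sd

    def test_contributors_recorded_exactly(self):
        ev = simulate_composition(default_spec(doublet_rate=0.2, triplet_rate=0.05),
                                  5000, seed=2)
        sizes = ev["members"].apply(len)
        assert (sizes[ev["kind"] == "singlet"] == 1).all()
        assert (sizes[ev["kind"] == "doublet"] == 2).all()
        assert (sizes[ev["kind"] == "triplet"] == 3).all()
        for label, members in zip(ev["truth_label"], ev["members"]):
            assert label.split(":")[1].split(",") == list(members)

    @pytest.mark.parametrize("alpha", [0.0, 0.1, 0.3])
    def test_doublet_ratio_exceeds_singlet_ratio(self, alpha):
        spec = default_spec(doublet_rate=0.2)
        spec.height_alpha = alpha
        ev = compute_fsc_ratio(simulate_cytometry(spec, 20000, seed=3), "none")
        ratio = ev.channel(RATIO_RAW)
        mult = truth_is_multiplet(ev.meta["truth_label"])
        assert ratio[mult].mean() > ratio[~mult].mean()

    def test_seeded_determinism(self):
        spec = default_spec()
        e1 = simulate_cytometry(spec, 1000, seed=9)
        e2 = simulate_cytometry(spec, 1000, seed=9)
        np.testing.assert_array_equal(e1.values, e2.values)
        assert (e1.meta["truth_label"] == e2.meta["truth_label"]).all()

    def test_bad_abundances_rejected(self):
        pops = default_spec().populations
        pops[0].abundance = 0.9
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticSpec(pops)


class TestDebrisFilter:
    def test_perfect_circle_kept(self):
        r = 10.0
        shapes = pd.DataFrame({"area": [np.pi * r ** 2], "perimeter": [2 * np.pi * r],
                               "major_axis_length": [2 * r]})
        keep = debris_filter(shapes)
        assert shapes["circularity"].iloc[0] == pytest.approx(1.0)
        assert keep.iloc[0]

    @pytest.mark.parametrize("col,val", [
        ("area", 50.0),              # below the 100-pixel floor
        ("area", 1500.0),            # above the 1000-pixel ceiling
        ("major_axis_length", 10.0),
        ("major_axis_length", 50.0),
    ])
    def test_any_single_criterion_excludes(self, col, val):
        base = {"area": 314.16, "perimeter": 62.83, "major_axis_length": 20.0}
        base[col] = val
        assert not debris_filter(pd.DataFrame([base])).iloc[0]

    def test_low_circularity_excluded(self):
        # circularity = 4*pi*300/80^2 ~ 0.59 < 0.7, all else in range
        shapes = pd.DataFrame({"area": [300.0], "perimeter": [80.0],
                               "major_axis_length": [25.0]})
        keep = debris_filter(shapes)
        assert shapes["circularity"].iloc[0] < 0.7
        assert not keep.iloc[0]

    def test_nonpositive_perimeter_rejected(self):
        with pytest.raises(ValueError):
            debris_filter(pd.DataFrame({"area": [10.0], "perimeter": [0.0],
                                        "major_axis_length": [20.0]}))


class TestMetrics:
    def test_perfect_prediction(self):
        truth = ["singlet:T", "doublet:B,T", "singlet:B"]
        pred = ["singlet", "multiplet", "singlet"]
        m = classification_metrics(truth, pred)
        assert m["f1_multiplet"] == 1.0 and m["ari"] == 1.0

    def test_closed_form_counts(self):
        # TP=2, FP=1, FN=1 -> precision = recall = 2/3 -> F1 = 2/3
        truth = ["multiplet"] * 3 + ["singlet"] * 3
        pred = ["multiplet", "multiplet", "singlet", "multiplet", "singlet", "singlet"]
        assert classification_metrics(truth, pred)["f1_multiplet"] == pytest.approx(2 / 3)

    def test_matches_contingency_oracle_on_random_labels(self):
        rng = np.random.default_rng(0)
        truth = rng.choice(["singlet", "multiplet"], 500, p=[0.8, 0.2])
        pred = rng.choice(["singlet", "multiplet"], 500, p=[0.7, 0.3])
        m = classification_metrics(truth, pred)
        tp = np.sum((truth == "multiplet") & (pred == "multiplet"))
        fp = np.sum((truth == "singlet") & (pred == "multiplet"))
        fn = np.sum((truth == "multiplet") & (pred == "singlet"))
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert m["f1_multiplet"] == pytest.approx(f1)
        # ARI from the pair-counting contingency formula
        from scipy.special import comb

        ct = pd.crosstab(truth, pred).to_numpy()
        n = ct.sum()
        sum_ij = sum(comb(x, 2) for x in ct.ravel())
        sum_a = sum(comb(x, 2) for x in ct.sum(1))
        sum_b = sum(comb(x, 2) for x in ct.sum(0))
        expected = sum_a * sum_b / comb(n, 2)
        ari = (sum_ij - expected) / (0.5 * (sum_a + sum_b) - expected)
        assert m["ari"] == pytest.approx(ari)

    def test_random_labels_ari_near_zero(self):
        rng = np.random.default_rng(1)
        aris = []
        for _ in range(10):
            truth = rng.choice(["singlet", "multiplet"], 1000)
            pred = rng.choice(["singlet", "multiplet"], 1000)
            aris.append(classification_metrics(truth, pred)["ari"])
        assert abs(np.mean(aris)) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(["singlet"], ["singlet", "multiplet"])


class TestBenchmark:
    def test_single_iteration_deterministic_row(self, easy_events):
        from picflow.pipeline import PipelineConfig
        from picflow.synthetic import run_benchmark

        cfg = PipelineConfig(sketch_size=4000)
        t1 = run_benchmark(easy_events, ("otsu",), ("louvain",), 1, seed=5, config=cfg)
        t2 = run_benchmark(easy_events, ("otsu",), ("louvain",), 1, seed=5, config=cfg)
        assert len(t1) == 2  # threshold-only baseline + cluster-based row
        pd.testing.assert_frame_equal(t1, t2)

    def test_cluster_based_beats_threshold_only_with_confounder(self, confounder_events):
        from picflow.pipeline import PipelineConfig
        from picflow.synthetic import run_benchmark

        cfg = PipelineConfig(sketch_size=6000)
        table = run_benchmark(confounder_events, ("otsu",), ("louvain",), 1, seed=6,
                              config=cfg).set_index("mode")
        assert table.loc["cluster_based", "f1_multiplet"] \
            > table.loc["threshold_only", "f1_multiplet"]

    def test_requires_truth_labels(self, easy_events):
        from picflow.synthetic import run_benchmark

        stripped = easy_events.subset(np.arange(100))
        stripped.meta = stripped.meta.drop(columns=["truth_label"])
        with pytest.raises(ValueError, match="truth"):
            run_benchmark(stripped)
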