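import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from priontx import (
    CountMatrix,
    GeneRecord,
    SimulationConfig,
    ThresholdConfig,
    call_degs,
    classify_patterns,
    estimate_depth,
    feature_breakdown,
    generate_network,
    normalize_counts,
    sample_outlier_screen,
    simulate_counts,
    summarize_overlap,
)
from priontx.deg import calls_to_frame, direction_map

from conftest import make_calls


class TestEstimateDepth:
    @pytest.mark.parametrize(
        "n, l, g, expected",
        [
            (12, 10, 120, 1.0),
            (15e6, 50, 12.07e6, 62.1),
            (18e6, 50, 12.07e6, 74.6),
        ],
    )
    def test_fold_coverage(self, n, l, g, expected):
        assert estimate_depth(n, l, g) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            estimate_depth(0, 50, 1e6)


class TestNormalizeCounts:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=["g1", "g2", "g3"])
        cm = CountMatrix(df, {"a": "wt", "b": "prion"})
        sf, _ = normalize_counts(cm)
        assert np.allclose(sf, 1.0)

    def test_exact_doubling_gives_factor_ratio_two(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=["g1", "g2", "g3"])
        cm = CountMatrix(df, {"a": "wt", "b": "prion"})
        sf, normed = normalize_counts(cm)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.allclose(normed["a"], normed["b"])

    def test_recovers_planted_library_size_factor(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(3, 1, size=2000)
        a = rng.poisson(mu)
        b = rng.poisson(3 * mu)
        df = pd.DataFrame({"a": a, "b": b}, index=[f"g{i}" for i in range(2000)])
        cm = CountMatrix(df, {"a": "wt", "b": "prion"})
        sf, _ = normalize_counts(cm)
        assert sf["b"] / sf["a"] == pytest.approx(3.0, rel=0.05)

    def test_fallback_warns_without_all_positive_gene(self):
        df = pd.DataFrame({"a": [10, 0], "b": [0, 10]}, index=["g1", "g2"])
        cm = CountMatrix(df, {"a": "wt", "b": "prion"})
        with pytest.warns(UserWarning, match="total-count"):
            normalize_counts(cm)


class TestCallDegs:
    def test_identical_groups_yield_no_degs(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=200)
        cols = {f"prion_{i}": base for i in range(1, 4)} | {
            f"wt_{i}": base for i in range(1, 4)
        }
        cond = {c: ("prion" if c.startswith("prion") else "wt") for c in cols}
        cm = CountMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(200)]), cond)
        calls = call_degs(cm, "prion_vs_wt")
        assert all(c.direction == "unchanged" for c in calls)

    def test_cutoff_semantics_require_both_conditions(self):
        # significance alone is not enough: |log2FC| must exceed the cutoff
        cfg = ThresholdConfig(alpha_adj=0.001, lfc_cut=1.0)
        from priontx.types import DEGCall

        up = DEGCall("g", "prion_vs_wt", 1.2, 1e-5, 5e-4, "up")
        assert up.direction == "up"
        # the caller must never emit "up" when log2fc <= cutoff at any p
        rng = np.random.default_rng(3)
        mu = rng.lognormal(5, 1, size=300)
        cols = {}
        for i in range(1, 4):
            cols[f"wt_{i}"] = rng.poisson(mu)
            cols[f"prion_{i}"] = rng.poisson(mu * 1.6)  # strong but < 2-fold
        cond = {c: ("prion" if c.startswith("prion") else "wt") for c in cols}
        cm = CountMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(300)]), cond)
        for c in call_degs(cm, "prion_vs_wt", cfg):
            if c.direction == "up":
                assert c.log2fc > 1.0 and c.p_adj < 0.001

    def test_two_replicates_required(self, toy_counts):
        cm = toy_counts.subset_samples(["wt_1", "prion_1", "prion_2"])
        with pytest.raises(ValueError, match="replicates"):
            call_degs(cm, "prion_vs_wt")

    def test_all_zero_gene_reported_untested(self):
        df = pd.DataFrame(
            {"wt_1": [5, 0], "wt_2": [6, 0], "prion_1": [5, 0], "prion_2": [7, 0]},
            index=["g1", "gzero"],
        )
        cm = CountMatrix(df, {"wt_1": "wt", "wt_2": "wt", "prion_1": "prion", "prion_2": "prion"})
        calls = {c.gene_id: c for c in call_degs(cm, "prion_vs_wt")}
        assert np.isnan(calls["gzero"].p_raw)
        assert calls["gzero"].direction == "unchanged"

    def test_bh_adjustment_invariants(self, planted_config):
        edges = generate_network(planted_config)
        cm, _ = simulate_counts(planted_config, edges)
        calls = [c for c in call_degs(cm, "prion_vs_wt") if not np.isnan(c.p_raw)]
        df = calls_to_frame(calls).sort_values("p_raw")
        assert (df.p_adj.to_numpy() >= df.p_raw.to_numpy() - 1e-12).all()
        assert df.p_adj.is_monotonic_increasing
        assert df.p_adj.max() <= 1.0

    def test_planted_targets_recovered(self, planted_config):
        edges = generate_network(planted_config)
        cm, gt = simulate_counts(planted_config, edges)
        dm = direction_map(call_degs(cm, "prion_vs_wt"))
        truth = {g: d for g, d in gt.direction["prion"].items() if d != "none"}
        assert len(truth) >= 30
        correct = sum(dm[g] == d for g, d in truth.items())
        assert correct / len(truth) >= 0.9
        null_genes = [g for g, d in gt.direction["prion"].items() if d == "none"]
        false_calls = sum(dm[g] != "unchanged" for g in null_genes)
        assert false_calls / len(null_genes) <= 0.01


class TestOutlierScreen:
    def test_tight_replicates_none_flagged(self, toy_counts):
        keep, embedding = sample_outlier_screen(toy_counts)
        assert all(keep.values())
        assert embedding.shape == (9, 2)

    def test_noisy_replicate_flagged(self):
        cfg = SimulationConfig(n_genes=1000, n_tfs=5, library_size=1e6, seed=21)
        edges = generate_network(cfg)
        cm, _ = simulate_counts(cfg, edges)
        counts = cm.counts.copy()
        rng = np.random.default_rng(5)
        # corrupt one replicate with strong independent noise
        noisy = counts["prion_2"].to_numpy() * rng.lognormal(0, 1.0, size=len(counts))
        counts["prion_2"] = np.round(noisy).astype(np.int64)
        cm2 = CountMatrix(counts, cm.condition_of, cm.replicate_of)
        keep, _ = sample_outlier_screen(cm2)
        assert keep == {s: s != "prion_2" for s in cm2.samples}

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [3, 4]}, index=["g1", "g2"])
        cm = CountMatrix(df, {"a": "wt", "b": "wt"})
        with pytest.raises(ValueError):
            sample_outlier_screen(cm)


class TestPatternsAndOverlap:
    def test_opposite_pattern(self):
        prion = make_calls({"g1": "up", "g2": "unchanged"})
        deletion = make_calls({"g1": "down", "g2": "unchanged"}, "deletion_vs_wt")
        assignments, counts = classify_patterns(prion, deletion)
        assert assignments == {"g1": ("up", "down")}
        assert counts[("up", "down")] == 1

    def test_double_unchanged_not_assigned(self):
        prion = make_calls({"g1": "unchanged"})
        deletion = make_calls({"g1": "unchanged"}, "deletion_vs_wt")
        assignments, counts = classify_patterns(prion, deletion)
        assert assignments == {}
        assert sum(counts.values()) == 0

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            classify_patterns(make_calls({"g1": "up"}), make_calls({"g2": "up"}, "deletion_vs_wt"))

    def test_partition_sums_to_union(self, planted_config):
        edges = generate_network(planted_config)
        cm, _ = simulate_counts(planted_config, edges)
        calls_p = call_degs(cm, "prion_vs_wt")
        calls_d = call_degs(cm, "deletion_vs_wt")
        assignments, counts = classify_patterns(calls_p, calls_d)
        degs_p = {c.gene_id for c in calls_p if c.direction != "unchanged"}
        degs_d = {c.gene_id for c in calls_d if c.direction != "unchanged"}
        assert sum(counts.values()) == len(degs_p | degs_d) == len(assignments)

    def test_aggregated_tf_shared_targets_fall_in_double_down(self):
        # a TF aggregated in the prion strain and deleted-path-affected in
        # the deletion strain: its activator targets go down in both
        cfg = SimulationConfig(
            n_genes=800, n_tfs=5, mean_out_degree=15, activator_fraction=1.0,
            library_size=2e6,
            planted_tf_aggregated={"prion": ["G0001"]},
            planted_tf_down={"deletion": ["G0001"]},
            seed=13,
        )
        edges = generate_network(cfg)
        cm, gt = simulate_counts(cfg, edges)
        assignments, _ = classify_patterns(
            call_degs(cm, "prion_vs_wt"), call_degs(cm, "deletion_vs_wt")
        )
        targets = {e.target_id for e in edges if e.tf_id == "G0001"}
        patterns = {assignments[g] for g in targets if g in assignments}
        # ground-truth propagation: no target may flip up in either strain
        assert patterns <= {("down", "down"), ("down", "unchanged"), ("unchanged", "down")}
        both_called = [g for g in targets if assignments.get(g) == ("down", "down")]
        assert len(both_called) > len(targets) / 2

    def test_identical_sets_full_overlap(self):
        s = {"a", "b", "c"}
        out = summarize_overlap(s, s)
        assert out["pct_of_a"] == out["pct_of_b"] == 100.0
        assert out["n_union"] == 3

    @given(
        a=st.sets(st.integers(0, 60), max_size=40),
        b=st.sets(st.integers(0, 60), max_size=40),
    )
    @settings(max_examples=200, deadline=None)
    def test_overlap_matches_brute_force(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        out = summarize_overlap(a, b)
        assert out["n_intersection"] == len(a & b)
        assert out["n_union"] == len(a | b)
        assert out["n_a"] + out["n_b"] - out["n_intersection"] == out["n_union"]


class TestFeatureBreakdown:
    def _annotation(self, genes, fclass="ORF"):
        return [GeneRecord(g, g, "chrI", fclass) for g in genes]

    def test_all_orf_single_column(self):
        assignments = {"g1": ("up", "up"), "g2": ("down", "unchanged")}
        table = feature_breakdown(assignments, self._annotation(["g1", "g2"]))
        assert list(table.columns) == ["ORF"]
        assert table.to_numpy().sum() == 2

    def test_snorna_repression_shape(self):
        # a snoRNA-heavy deletion-repressed class: 40 snoRNA genes in the
        # (unchanged, down) pattern produce a single dominating cell
        assignments = {f"sno{i}": ("unchanged", "down") for i in range(40)}
        assignments["orf1"] = ("up", "up")
        ann = self._annotation([f"sno{i}" for i in range(40)], "snoRNA") + self._annotation(["orf1"])
        table = feature_breakdown(assignments, ann)
        assert table.loc["unchanged/down", "snoRNA"] == 40
        assert table.to_numpy().sum() == 41

    def test_unannotated_gene_rejected(self):
        with pytest.raises(ValueError, match="unannotated"):
            feature_breakdown({"gX": ("up", "up")}, self._annotation(["g1"]))
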