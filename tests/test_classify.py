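"""Filtering, backbone classification, and branch-length statistics."""

import math

import numpy as np
import pytest

from phyloconflict import treeio as T
from phyloconflict.classify import (
    LineageMap,
    TopologyClass,
    build_records,
    classification_summary,
    classify_topology,
    compare_groups,
    divergence_branch_length,
    estimate_internal_branch,
    evolutionary_rate,
    filter_consistent,
    filter_support,
)
from phyloconflict.simulate import (
    MSCSimConfig,
    expected_backbone_freqs,
    random_nni,
    simulate_gene_trees,
    simulate_strategy_pair,
)

TREE1_NWK = "((((a1,a2),(d1,d2)),(r1,r2)),out);"
TREE2_NWK = "((((a1,a2),(r1,r2)),(d1,d2)),out);"
UNCLASS_NWK = "((((a1,d1),(a2,d2)),(r1,r2)),out);"


class TestLineageMap:
    def test_tsv_round_trip(self, lm7, tmp_path):
        path = tmp_path / "lm.tsv"
        lm7.to_tsv(path)
        back = LineageMap.from_tsv(path)
        assert back.mapping == lm7.mapping
        assert back.display_names == lm7.display_names

    def test_rejects_bad_maps(self):
        with pytest.raises(ValueError):
            LineageMap({"a": "L1", "b": "L2", "o": "OUT"})  # L3 empty
        with pytest.raises(ValueError):
            LineageMap({"a": "L1", "b": "L2", "c": "L3"})  # no outgroup
        with pytest.raises(ValueError):
            LineageMap({"a": "L9", "b": "L2", "c": "L3", "o": "OUT"})


class TestFilters:
    def test_same_topology_different_lengths_consistent(self):
        a = T.parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        b = T.parse_newick("((a:9,b:9):9,(c:9,d:9):9);")
        assert filter_consistent(a, b) == (True, False)

    def test_nni_pair_inconsistent(self):
        a = T.parse_newick("((a,b),(c,d));")
        b = T.parse_newick("((a,c),(b,d));")
        assert filter_consistent(a, b)[0] is False

    def test_single_strategy_passes_with_flag(self):
        a = T.parse_newick("((a,b),(c,d));")
        assert filter_consistent(a, None) == (True, True)

    def test_rejection_rate_tracks_perturbation_rate(self):
        p = 0.3
        cfg = MSCSimConfig(n1=2, n2=2, n3=1, n_genes=500, nni_fraction=p, seed=5)
        trees_a, trees_b, truth = simulate_strategy_pair(cfg)
        rejected = sum(
            not filter_consistent(ta, tb)[0]
            for (_, ta), (_, tb) in zip(trees_a, trees_b)
        )
        se = math.sqrt(p * (1 - p) / 500)
        assert abs(rejected / 500 - p) < 3 * se
        # and rejections are exactly the perturbed genes (one NNI always
        # changes a binary unrooted topology)
        assert rejected == int(truth.perturbed.sum())

    @pytest.mark.parametrize(
        "supports,threshold,expect",
        [((90, 70), 80, True), ((75, 75), 80, False), ((100, 100), 99.9, True)],
    )
    def test_support_filter_boundary(self, supports, threshold, expect):
        nwk = f"(((a,b){supports[0]},c){supports[1]},d);"
        assert filter_support(T.parse_newick(nwk), threshold) is expect

    def test_support_filter_statistics_and_errors(self):
        t = T.parse_newick("((((a,b)60,c)90,d)90,e);")
        assert filter_support(t, 80, "mean") is True  # mean 80
        assert filter_support(t, 80, "median") is True
        assert filter_support(t, 80, "minimum") is False
        with pytest.raises(T.TreeError):
            filter_support(T.parse_newick("((a,b),c);"), 80)


class TestClassification:
    @pytest.mark.parametrize(
        "nwk,expected",
        [
            (TREE1_NWK, TopologyClass.TREE1),
            (TREE2_NWK, TopologyClass.TREE2),
            (UNCLASS_NWK, TopologyClass.UNCLASSIFIED),
            ("((((d1,d2),(r1,r2)),(a1,a2)),out);", TopologyClass.TREE3),
        ],
    )
    def test_hand_written_examples(self, lm7, nwk, expected):
        assert classify_topology(T.parse_newick(nwk), lm7) is expected

    def test_invariant_to_child_order_lengths_and_rooting_position(self, lm7):
        variants = [
            "(out,(((a2,a1),(d2,d1)),(r2,r1)));",
            "((((a1:5,a2:1):9,(d1:2,d2:2):1):3,(r1:1,r2:1):4):2,out:9);",
            "((r1,r2),(((a1,a2),(d1,d2)),out));",  # rooted elsewhere
        ]
        for nwk in variants:
            assert classify_topology(T.parse_newick(nwk), lm7) is TopologyClass.TREE1

    def test_backbone_polytomy_unclassified(self, lm7):
        nwk = "(((a1,a2),(d1,d2),(r1,r2)),out);"
        assert classify_topology(T.parse_newick(nwk), lm7) is TopologyClass.UNCLASSIFIED

    def test_missing_taxon_errors(self, lm7):
        with pytest.raises(T.TreeError, match="a2"):
            classify_topology(T.parse_newick("(((a1,(d1,d2)),(r1,r2)),out);"), lm7)

    def test_minor_classes_symmetric_under_pure_ils(self, lm4):
        cfg = MSCSimConfig(n_genes=5000, internal_t=0.5, seed=23)
        trees, _ = simulate_gene_trees(cfg)
        classes = [classify_topology(t, lm4) for _, t in trees]
        n2 = classes.count(TopologyClass.TREE2)
        n3 = classes.count(TopologyClass.TREE3)
        p_minor = expected_backbone_freqs(0.5)[1]
        se = math.sqrt(p_minor * (1 - p_minor) / 5000)
        assert abs(n2 / 5000 - n3 / 5000) < 3 * math.sqrt(2) * se

    def test_unclassified_grows_as_lineage_depth_shrinks(self):
        fracs = []
        for depth in (3.0, 1.0, 0.3):
            cfg = MSCSimConfig(
                n1=3, n2=3, n3=2, n_genes=400, internal_t=1.0,
                lineage_depth=depth, seed=29,
            )
            _, truth = simulate_gene_trees(cfg)
            fracs.append((truth.true_class == "UNCLASSIFIED").mean())
        assert fracs[0] < fracs[1] < fracs[2]


class TestBranchStats:
    def test_divergence_single_internal_branch(self, lm7):
        nwk = "((((a1,a2):0.1,(d1,d2):0.1):0.25,(r1,r2):0.3):0.05,out:1);"
        assert divergence_branch_length(T.parse_newick(nwk), lm7) == pytest.approx(0.25)

    def test_divergence_zero_length_segment(self, lm7):
        nwk = "((((a1,a2):0.1,(d1,d2):0.1):0.0,(r1,r2):0.3):0.05,out:1);"
        assert divergence_branch_length(T.parse_newick(nwk), lm7) == 0.0

    def test_divergence_undefined_for_unclassified(self, lm7):
        t = T.parse_newick(
            "((((a1:1,d1:1):1,(a2:1,d2:1):1):1,(r1:1,r2:1):1):1,out:1);"
        )
        with pytest.raises(T.TreeError):
            divergence_branch_length(t, lm7)

    def test_divergence_matches_simulator_bookkeeping(self, lm4):
        """The classifier's node1-node2 path equals the simulator's own record
        of the internal coalescent segment, gene by gene."""
        cfg = MSCSimConfig(n_genes=300, internal_t=1.0, seed=31)
        trees, truth = simulate_gene_trees(cfg)
        checked = 0
        for (_, tree), row in zip(trees, truth.itertuples()):
            if row.true_class == "UNCLASSIFIED" or math.isnan(row.true_divergence):
                continue
            assert divergence_branch_length(tree, lm4) == pytest.approx(
                row.true_divergence, abs=1e-9
            )
            checked += 1
        assert checked > 200

    def test_evolutionary_rate(self):
        t = T.parse_newick("((a:1,b:2):3,c:4);")
        assert evolutionary_rate(t) == pytest.approx(10 / 3)
        assert evolutionary_rate(t, "total") == pytest.approx(10.0)
        zero = T.parse_newick("((a:0,b:0):0,c:0);")
        assert evolutionary_rate(zero) == 0.0

    def test_rate_scales_homogeneously(self):
        t = T.parse_newick("((a:1,b:2):3,c:4);")
        scaled = T.parse_newick("((a:2.5,b:5):7.5,c:10);")
        assert evolutionary_rate(scaled) == pytest.approx(2.5 * evolutionary_rate(t))


class TestCompareGroups:
    def test_identical_groups_null(self):
        out = compare_groups({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        row = out.iloc[0]
        assert row.statistic == 0.0 and row.p_value == 1.0

    def test_separated_groups_tiny_p(self, rng):
        a = list(rng.normal(0, 1, 50))
        b = list(rng.normal(5, 1, 50))
        assert compare_groups({"A": a, "B": b}).iloc[0].p_value < 1e-10

    def test_undersized_group_skipped_with_nan(self):
        out = compare_groups({"A": [1.0], "B": [1.0, 2.0, 3.0]})
        assert math.isnan(out.iloc[0].p_value)

    def test_type_i_error_calibrated(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            a = list(rng.normal(0, 1, 20))
            b = list(rng.normal(0, 1, 20))
            hits += compare_groups({"A": a, "B": b}).iloc[0].p_value < 0.05
        assert abs(hits / reps - 0.05) < 0.02


class TestSummary:
    def test_all_one_class(self, lm7):
        genes = [(f"g{i}", T.parse_newick(TREE1_NWK), None) for i in range(10)]
        records = build_records(genes, lm7, support_threshold=0)
        # hand-written trees carry no supports: support filter is inapplicable
        summary = classification_summary(records)
        tree1 = summary[summary.category == "TREE1"].iloc[0]
        assert tree1["count"] == 10 and tree1.proportion == 1.0

    def test_proportions_over_four_classes(self, lm7):
        nwk_by_class = {
            TopologyClass.TREE1: TREE1_NWK,
            TopologyClass.TREE2: TREE2_NWK,
            TopologyClass.TREE3: "((((d1,d2),(r1,r2)),(a1,a2)),out);",
            TopologyClass.UNCLASSIFIED: UNCLASS_NWK,
        }
        counts = {"TREE1": 4, "TREE2": 1, "TREE3": 2, "UNCLASSIFIED": 3}
        genes = []
        for cls, c in counts.items():
            for i in range(c):
                genes.append((f"{cls}_{i}", T.parse_newick(nwk_by_class[TopologyClass(cls)]), None))
        summary = classification_summary(build_records(genes, lm7))
        for cls, c in counts.items():
            row = summary[summary.category == cls].iloc[0]
            assert row["count"] == c and row.proportion == pytest.approx(c / 10)
        props = summary[summary.category.str.startswith(("TREE", "UNCL"))].proportion
        assert props.sum() == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classification_summary([])


def test_estimate_internal_branch_inverts_closed_form():
    for t in (0.5, 1.0, 2.0):
        p_disc = 2 * expected_backbone_freqs(t)[1]
        assert estimate_internal_branch(p_disc) == pytest.approx(t)
    with pytest.raises(ValueError):
        estimate_internal_branch(0.9)


def test_random_nni_changes_topology(rng):
    from conftest import random_trees

    for tree in random_trees(30, seed=37):
        perturbed = random_nni(tree, rng)
        assert T.rf_distance(tree, perturbed) > 0
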