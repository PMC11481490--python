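"""Coalescent simulator: determinism, validity, and closed-form agreement."""

import math

import numpy as np
import pytest

from phyloconflict import treeio as T
from phyloconflict.classify import classify_topology
from phyloconflict.simulate import (
    FIXTURE_PRESETS,
    MSCSimConfig,
    SiteSimConfig,
    expected_backbone_freqs,
    make_fixture,
    simulate_gene_trees,
    simulate_site_patterns,
    species_tree_for,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MSCSimConfig(n1=0).validate()
        with pytest.raises(ValueError):
            MSCSimConfig(n_genes=0).validate()
        with pytest.raises(ValueError):
            MSCSimConfig(introgression=("L1", "L1", 0.2)).validate()
        with pytest.raises(ValueError):
            MSCSimConfig(introgression=("L1", "L2", 1.5)).validate()
        with pytest.raises(ValueError):
            SiteSimConfig(t1=2.0, t2=1.0).validate()

    def test_species_tree_matches_taxa(self):
        cfg = MSCSimConfig(n1=3, n2=2, n3=2)
        sp = species_tree_for(cfg)
        assert sp.leaf_names() == frozenset(
            sum(cfg.taxa().values(), [])
        )


class TestGeneTrees:
    def test_deterministic_under_seed(self):
        cfg = MSCSimConfig(n1=2, n2=2, n3=1, n_genes=25, seed=97)
        a, truth_a = simulate_gene_trees(cfg)
        b, truth_b = simulate_gene_trees(cfg)
        assert [T.write_newick(t) for _, t in a] == [T.write_newick(t) for _, t in b]
        assert truth_a.equals(truth_b)

    def test_trees_are_valid_and_ultrametric(self):
        cfg = MSCSimConfig(n1=3, n2=2, n3=2, n_genes=50, seed=101)
        trees, _ = simulate_gene_trees(cfg)
        for _, tree in trees:
            # round-trips through Newick and validates
            back = T.parse_newick(T.write_newick(tree))
            assert back.leaf_names() == tree.leaf_names()
            depths = []

            def depth(nd, acc):
                acc += nd.length or 0.0
                if nd.is_leaf:
                    depths.append(acc)
                for c in nd.children:
                    depth(c, acc)

            depth(tree.root, 0.0)
            assert max(depths) - min(depths) < 1e-9

    def test_deep_internal_branch_kills_discordance(self, lm4):
        cfg = MSCSimConfig(n_genes=1000, internal_t=10.0, seed=103)
        _, truth = simulate_gene_trees(cfg)
        assert (truth.true_class == "TREE1").mean() >= 0.99

    def test_star_tree_gives_thirds(self, lm4):
        cfg = MSCSimConfig(n_genes=10_000, internal_t=0.0, seed=107)
        _, truth = simulate_gene_trees(cfg)
        se = math.sqrt((1 / 3) * (2 / 3) / 10_000)
        for cls in ("TREE1", "TREE2", "TREE3"):
            assert abs((truth.true_class == cls).mean() - 1 / 3) < 3 * se

    def test_truth_table_agrees_with_classifier(self, lm7):
        """Event-bookkeeping truth equals tree-based classification on
        multi-taxon trees (including non-monophyly cases)."""
        cfg = MSCSimConfig(
            n1=2, n2=2, n3=2, n_genes=300, internal_t=0.5, lineage_depth=1.0, seed=109
        )
        trees, truth = simulate_gene_trees(cfg)
        relabel = dict(
            zip(["L1_1", "L1_2", "L2_1", "L2_2", "L3_1", "L3_2", "OUT"],
                ["a1", "a2", "d1", "d2", "r1", "r2", "out"])
        )
        for (_, tree), expected in zip(trees, truth.true_class):
            for leaf in tree.leaves():
                leaf.name = relabel[leaf.name]
            assert str(classify_topology(tree, lm7)) == expected

    def test_introgression_biases_toward_donor_pair(self):
        cfg = MSCSimConfig(
            n_genes=4000, internal_t=1.0, introgression=("L3", "L2", 0.4), seed=113
        )
        _, truth = simulate_gene_trees(cfg)
        assert truth.introgressed.mean() == pytest.approx(0.4, abs=0.03)
        # pulse reroutes L2 through L3: TREE3 (L2+L3 sisters) inflated
        n2 = (truth.true_class == "TREE2").sum()
        n3 = (truth.true_class == "TREE3").sum()
        assert n3 > 2 * n2

    def test_supports_track_branch_lengths(self):
        cfg = MSCSimConfig(n1=3, n2=3, n3=2, n_genes=80, seed=127, support_sd=4.0)
        trees, _ = simulate_gene_trees(cfg)
        short, long_ = [], []
        for _, tree in trees:
            for nd in tree.internal_nodes(exclude_root=True):
                (long_ if nd.length > 0.3 else short if nd.length < 0.03 else []).append(
                    nd.support
                )
        assert np.mean(long_) > 90
        assert np.mean(short) < np.mean(long_) - 20


class TestSitePatterns:
    def test_byte_identical_under_seed(self, tmp_path):
        cfg = SiteSimConfig(n_sites=2000, gamma=0.2, seed=131)
        a = simulate_site_patterns(cfg)
        b = simulate_site_patterns(cfg)
        pa, pb = tmp_path / "a.fasta", tmp_path / "b.fasta"
        a.to_fasta(pa)
        b.to_fasta(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_every_site_biallelic(self):
        aln = simulate_site_patterns(SiteSimConfig(n_sites=3000, seed=137))
        arr = np.array([list(aln.sequences[n]) for n in ("P1", "P2", "P3", "O")])
        for col in arr.T:
            assert len(set(col)) == 2

    def test_null_pattern_symmetry(self):
        from phyloconflict.dstat import count_patterns

        aln = simulate_site_patterns(SiteSimConfig(n_sites=80_000, gamma=0.0, seed=139))
        abba, baba = count_patterns(aln)
        a, b = abba.sum(), baba.sum()
        # under exchangeability of P1/P2, ABBA and BABA counts are binomial halves
        assert abs(a - b) / math.sqrt(a + b) < 3.5


class TestMsprimeCrossCheck:
    def test_quartet_frequencies_match_msprime(self):
        """Independent-oracle check: an msprime version of the same
        demography yields the same major-topology frequency."""
        import msprime

        t1, t2, t3 = 1.0, 2.0, 3.0
        demography = msprime.Demography()
        # haploid populations of size 1: one generation = one coalescent unit
        for name in ("P1", "P2", "P3", "O", "A12", "A123", "R"):
            demography.add_population(name=name, initial_size=1.0)
        demography.add_population_split(time=t1, derived=["P1", "P2"], ancestral="A12")
        demography.add_population_split(time=t2, derived=["A12", "P3"], ancestral="A123")
        demography.add_population_split(time=t3, derived=["A123", "O"], ancestral="R")
        reps = msprime.sim_ancestry(
            samples={"P1": 1, "P2": 1, "P3": 1, "O": 1},
            demography=demography,
            ploidy=1,
            num_replicates=3000,
            random_seed=7,
        )
        major = 0
        for ts in reps:
            tree = ts.first()
            t01 = tree.time(tree.mrca(0, 1))
            major += t01 < tree.time(tree.mrca(0, 2)) and t01 < tree.time(tree.mrca(1, 2))
        p_hat = major / 3000
        p_expected = 1 - (2 / 3) * math.exp(-(t2 - t1))
        se = math.sqrt(p_expected * (1 - p_expected) / 3000)
        assert abs(p_hat - p_expected) < 3 * se

        cfg = MSCSimConfig(n_genes=3000, internal_t=t2 - t1, lineage_depth=t1, seed=149)
        _, truth = simulate_gene_trees(cfg)
        p_mine = (truth.true_class == "TREE1").mean()
        assert abs(p_mine - p_expected) < 3 * se


class TestFixtures:
    def test_unknown_preset_lists_options(self, tmp_path):
        with pytest.raises(ValueError, match="mini-ntf"):
            make_fixture("nope", tmp_path)

    @pytest.mark.parametrize("preset", sorted(FIXTURE_PRESETS))
    def test_bundles_are_complete_and_loadable(self, preset, tmp_path):
        import pandas as pd

        from phyloconflict.classify import LineageMap
        from phyloconflict.dstat import GroupedAlignment, read_popmap

        paths = make_fixture(preset, tmp_path / preset, seed=3)
        trees_a = T.read_tree_file(paths["trees_a"])
        trees_b = T.read_tree_file(paths["trees_b"])
        assert len(trees_a) == len(trees_b) == FIXTURE_PRESETS[preset]["msc"].n_genes
        lm = LineageMap.from_tsv(paths["lineage_map"])
        with open(paths["species_tree"]) as fh:
            sp = T.parse_newick(fh.read())
        assert sp.leaf_names() == lm.taxa == trees_a[0][1].leaf_names()
        GroupedAlignment.from_fasta(paths["alignment"], read_popmap(paths["popmap"]))
        truth = pd.read_csv(paths["truth"], sep="\t")
        assert len(truth) == len(trees_a)
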