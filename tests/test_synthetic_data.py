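"""Synthetic-data generator: trees, accelerations, sequence evolution."""

import math

import numpy as np
import pytest
from scipy import stats

import mitosignal as ms
from mitosignal.codon_tools import INVERTEBRATE_MITO, translate
from mitosignal.synthetic_data import (
    AT_RICH_FREQS,
    GeneSpec,
    LineageAcceleration,
    SimulationConfig,
    apply_lineage_rate,
    make_dataset,
    paper_like_config,
    simulate_gene,
    simulate_tree,
)
from mitosignal.tree_metrics import read_newick, root_to_tip, write_newick


class TestSimulateTree:
    def test_edge_count_rooted_binary(self, rng):
        tree = simulate_tree(4, 0.2, rng)
        edges = [
            e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None
        ]
        assert len(edges) == 2 * 4 - 2  # rooted binary: 2n-2 edges
        assert len(tree.leaf_nodes()) == 4

    def test_root_to_tip_equals_depth_exactly(self, rng):
        for depth in (0.1, 0.2, 0.5):
            tree = simulate_tree(10, depth, rng)
            for leaf in tree.leaf_node_iter():
                assert leaf.distance_from_root() == pytest.approx(depth, rel=1e-9)

    def test_mean_depth_over_seeds(self):
        # rescaling makes every draw hit the configured depth
        depths = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tree = simulate_tree(6, 0.2, rng)
            depths.append(tree.leaf_nodes()[0].distance_from_root())
        assert abs(np.mean(depths) - 0.2) < 0.05 * 0.2

    def test_same_seed_same_newick(self):
        t1 = simulate_tree(8, 0.2, np.random.default_rng(5))
        t2 = simulate_tree(8, 0.2, np.random.default_rng(5))
        assert write_newick(t1) == write_newick(t2)

    def test_terminal_branch_conditioning(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tree = simulate_tree(10, 0.2, rng, min_terminal_frac=0.7)
            longest = max(l.edge.length for l in tree.leaf_node_iter())
            assert longest >= 0.7 * 0.2


class TestApplyLineageRate:
    def test_factor_one_is_identity(self, rng):
        tree = simulate_tree(6, 0.2, rng)
        out = apply_lineage_rate(tree, ["t01"], 1.0)
        assert write_newick(out) == write_newick(tree)

    def test_single_tip_scales_terminal_branch_only(self, rng):
        tree = simulate_tree(6, 0.2, rng)
        before = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        out = apply_lineage_rate(tree, ["t03"], 5.0)
        after = {l.taxon.label: l.edge.length for l in out.leaf_node_iter()}
        assert after["t03"] == pytest.approx(5 * before["t03"])
        for t in before:
            if t != "t03":
                assert after[t] == pytest.approx(before[t])
        # internal edges untouched: total change equals the terminal change
        total_before = sum(e.length or 0 for e in tree.preorder_edge_iter())
        total_after = sum(e.length or 0 for e in out.preorder_edge_iter())
        assert total_after - total_before == pytest.approx(4 * before["t03"])

    def test_clade_path_scaling_raises_root_to_tip(self):
        tree = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        tree.is_rooted = True
        out = apply_lineage_rate(tree, ["C", "D"], 3.0)
        div = root_to_tip(out, outgroup="A")
        # C path from A's attachment: 0.1 (AB->root merged with root->CD) + 3*0.1
        assert div["C"] == pytest.approx(0.2 + 0.3)
        assert div["B"] == pytest.approx(0.1)

    def test_empty_taxon_set_rejected(self, rng):
        tree = simulate_tree(5, 0.2, rng)
        with pytest.raises(ValueError, match="empty"):
            apply_lineage_rate(tree, [], 2.0)


class TestSimulateGene:
    def test_zero_branch_lengths_give_identical_rows(self):
        tree = read_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = simulate_gene(tree, 120, seed=3)
        seqs = {s for _, s in aln.rows}
        assert len(seqs) == 1

    def test_jc_expected_p_distance(self):
        """Two-leaf tree of total length 0.3 under JC:
        E[p] = (3/4)(1 - exp(-4t/3)) = 0.2473."""
        tree = read_newick("(A:0.15,B:0.15);")
        ps = []
        for seed in range(50):
            aln = simulate_gene(tree, 10000, model="jc", seed=seed)
            a, b = aln.rows[0][1], aln.rows[1][1]
            ps.append(sum(x != y for x, y in zip(a, b)) / len(a))
        expected = 0.75 * (1 - math.exp(-4 * 0.3 / 3))
        assert np.mean(ps) == pytest.approx(expected, abs=0.01)

    def test_composition_converges_to_equilibrium(self):
        tree = read_newick("(A:0.5,B:0.5);")
        aln = simulate_gene(tree, 99999, model="hky", freqs=AT_RICH_FREQS, seed=11)
        seq = aln.rows[0][1] + aln.rows[1][1]
        counts = [seq.count(b) for b in "ACGT"]
        chi2, p = stats.chisquare(counts, [f * len(seq) for f in AT_RICH_FREQS])
        assert p > 1e-4  # no gross deviation from the configured frequencies

    def test_avoid_stops_keeps_gene_translatable(self):
        tree = read_newick("((A:0.4,B:0.4):0.2,(C:0.4,D:0.4):0.2);")
        aln = simulate_gene(tree, 300, seed=9, avoid_stops=True)
        for _, seq in aln.rows:
            protein = translate(seq)
            assert "*" not in protein

    def test_determinism_under_seed(self):
        tree = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        a1 = simulate_gene(tree, 200, seed=4)
        a2 = simulate_gene(tree, 200, seed=4)
        assert a1.rows == a2.rows


class TestMakeDataset:
    def test_rate_multiplier_doubles_p_distance(self):
        genes = (GeneSpec("slow", 6000, 1.0), GeneSpec("fast", 6000, 2.0))
        ratios = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_taxa=6, depth=0.05, genes=genes, model="jc", seed=seed, outgroup=None
            )
            alns, _ = make_dataset(cfg)

            def mean_p(aln):
                seqs = [s for _, s in aln.rows]
                ps = [
                    sum(x != y for x, y in zip(a, b)) / len(a)
                    for i, a in enumerate(seqs)
                    for b in seqs[i + 1 :]
                ]
                return np.mean(ps)

            ratios.append(mean_p(alns[1]) / mean_p(alns[0]))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_masked_pairs_absent(self):
        genes = (GeneSpec("g1", 300, 1.0), GeneSpec("g2", 300, 1.0))
        cfg = SimulationConfig(
            n_taxa=5, genes=genes, missing=(("t02", "g2"),), seed=1, outgroup=None
        )
        alns, _ = make_dataset(cfg)
        assert "t02" in alns[0].taxa
        assert "t02" not in alns[1].taxa

    def test_truth_effective_trees_scaled_by_multiplier(self):
        genes = (GeneSpec("g1", 300, 1.0), GeneSpec("g2", 300, 2.5))
        cfg = SimulationConfig(n_taxa=5, genes=genes, seed=2, outgroup=None)
        _, truth = make_dataset(cfg)
        base = sum(e.length or 0 for e in truth.tree.preorder_edge_iter())
        fast = sum(e.length or 0 for e in truth.gene_trees["g2"].preorder_edge_iter())
        assert fast == pytest.approx(2.5 * base)

    def test_accelerated_taxon_crosses_screen_threshold(self):
        """A x5-accelerated lineage at depth 0.2 exceeds 0.5 subst/site
        root-to-tip in the true tree; background taxa stay at 0.2."""
        genes = (GeneSpec("g1", 300, 1.0),)
        for seed in range(10):
            cfg = SimulationConfig(
                n_taxa=10,
                genes=genes,
                accelerations=(LineageAcceleration(factor=5.0),),
                seed=seed,
            )
            _, truth = make_dataset(cfg)
            (accel,) = truth.accelerated_taxa
            gene_tree = truth.gene_trees["g1"]
            gene_tree.is_rooted = True
            for leaf in gene_tree.leaf_node_iter():
                d = leaf.distance_from_root()
                if leaf.taxon.label == accel:
                    assert d > 0.5
                else:
                    assert d <= 0.2 + 1e-9

    def test_rna_genes_carry_rna_alphabet(self):
        genes = (GeneSpec("cox1", 300, 1.0), GeneSpec("rrnS", 200, 1.0, coding=False))
        cfg = SimulationConfig(n_taxa=5, genes=genes, seed=3, outgroup=None)
        alns, _ = make_dataset(cfg)
        assert alns[0].alphabet == "dna"
        assert alns[1].alphabet == "rna"

    def test_dataset_determinism(self):
        cfg = paper_like_config(seed=5)
        a1, _ = make_dataset(cfg)
        a2, _ = make_dataset(cfg)
        assert all(x.rows == y.rows for x, y in zip(a1, a2))

    def test_paper_like_preset_shape(self):
        cfg = paper_like_config()
        assert cfg.n_taxa == 17
        assert len(cfg.genes) == 13
        rates = {g.name: g.rate for g in cfg.genes}
        assert rates["cox1"] > 2.0  # the fast barcode gene
        assert sum(f for f, b in zip(cfg.freqs, "ACGT") if b in "AT") == pytest.approx(0.75)


class TestScaleFactorConsistency:
    def test_bias_shrinks_with_gene_length(self):
        """The pipeline's scale-factor estimate converges to the simulated
        multiplier as the gene grows (1 kb vs 9 kb)."""
        import mitosignal as ms

        errs = {999: [], 9000: []}
        for L in errs:
            for seed in range(3):
                genes = tuple(
                    [GeneSpec("probe", L, 2.0)]
                    + [GeneSpec(f"bg{i}", 2001, 1.0) for i in range(6)]
                )
                cfg = SimulationConfig(
                    n_taxa=8, depth=0.15, genes=genes, model="jc",
                    freqs=(0.25, 0.25, 0.25, 0.25), seed=seed, outgroup=None,
                )
                alns, _ = make_dataset(cfg)
                # reference from the rate-1 background genes only, so the
                # reference scale is independent of the probe's length
                acfg = ms.AssessmentConfig(genes=tuple(alns[1:]), k=3, seed=seed)
                _, ref = ms.build_reference(acfg)
                scores = {s.gene: s for s in ms.score_genes([alns[0]], ref, acfg)}
                errs[L].append(abs(scores["probe"].scale_factor - 2.0))
        assert np.mean(errs[9000]) < np.mean(errs[999]) + 0.02
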