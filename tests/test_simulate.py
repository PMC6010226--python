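"""Coalescent synthesizer: species trees, gene trees, sequences, bundles."""

import math

import numpy as np
import pytest

from specdelim.alignments import read_alignment, split_by_clade
from specdelim.distances import p_distance
from specdelim.gmyc import tree_from_string
from specdelim.registry import load_site_table, registry_totals
from specdelim.simulate import (
    ClockModel,
    SimulationConfig,
    calibrated_species_tree,
    evolve_sequences,
    simulate_dataset,
    simulate_gene_trees,
    simulate_species_tree,
)


class TestClockModel:
    def test_prior_interval_spans_published_divergence_rates(self):
        lo, hi = ClockModel().prior_interval()
        assert lo <= 0.020 and hi >= 0.026  # 2.0-2.6% divergence per My


class TestSpeciesTree:
    def test_single_species_degenerate(self):
        newick, ages = simulate_species_tree(1, 0.5, seed=1)
        assert newick.startswith("sp1:") and ages == []

    def test_reproducible_under_seed(self):
        a = simulate_species_tree(5, 0.3, seed=11)
        b = simulate_species_tree(5, 0.3, seed=11)
        assert a == b

    def test_expected_lineage_growth(self):
        # E[K(t)] = exp(rate * t) for a pure-birth process
        rate, t, reps = 0.8, 2.0, 1000
        rng = np.random.default_rng(99)
        counts = []
        for _ in range(reps):
            newick, _ = simulate_species_tree(0, rate, seed=rng, duration=t)
            counts.append(newick.count("sp"))
        mean = np.mean(counts)
        expected = math.exp(rate * t)
        se = np.std(counts, ddof=1) / math.sqrt(reps)
        assert abs(mean - expected) <= 3 * se

    def test_min_split_rescaling(self):
        newick, ages = calibrated_species_tree(6, 1.5, seed=3, min_split_my=2.0)
        assert min(ages) >= 2.0 - 1e-9
        # still parseable and ultrametric
        tree = tree_from_string(newick)
        assert tree.n_tips == 6


class TestGeneTrees:
    def test_pairwise_coalescent_depth_matches_theta(self):
        # two samples, one species: expected pairwise distance = theta,
        # i.e. expected TMRCA = theta / (2 * rate)
        theta, rate, reps = 0.01, 0.011, 300
        depths = []
        for i in range(reps):
            gt = simulate_gene_trees(
                "sp1:1.0;", theta, 2, seed=500 + i, markers={"ITS2": 1.0}
            )
            tree = tree_from_string(gt["ITS2"][0])
            depths.append(tree.height[tree.root])
        mean = np.mean(depths)
        expected = theta / (2 * rate)
        se = np.std(depths, ddof=1) / math.sqrt(reps)
        assert abs(mean - expected) <= 3 * se

    def test_mito_coalesces_faster_than_nuclear(self):
        depths = {"COI": [], "ITS2": []}
        for i in range(150):
            gt = simulate_gene_trees("sp1:1.0;", 0.01, 2, seed=9000 + i)
            for marker in depths:
                tree = tree_from_string(gt[marker][0])
                depths[marker].append(tree.height[tree.root])
        assert np.mean(depths["COI"]) < np.mean(depths["ITS2"])

    def test_one_sample_per_species_congruence_at_deep_divergence(self):
        # divergences ~20x theta: gene tree should match the species tree
        congruent = 0
        reps = 40
        for i in range(reps):
            newick, _ = calibrated_species_tree(3, 0.3, seed=i, min_split_my=4.0)
            gt = simulate_gene_trees(newick, 0.008, 1, seed=10_000 + i)
            tree = tree_from_string(gt["COI"][0])
            # topology check via the shallower pair of the species tree
            sp = tree_from_string(newick)
            pair = min(
                (v for v in sp.internal_nodes()),
                key=lambda v: sp.height[v],
            )
            sp_pair = {label.split("_")[0] if "_" in label else label
                       for label in sp.tipset(pair)}
            gene_pair_node = min(
                (v for v in tree.internal_nodes()), key=lambda v: tree.height[v]
            )
            gene_pair = {f"sp{label.rsplit('_', 1)[1]}"
                         for label in tree.tipset(gene_pair_node)}
            if gene_pair == sp_pair:
                congruent += 1
        assert congruent >= 0.9 * reps

    def test_specimen_ids_carry_clade_suffix(self):
        gt = simulate_gene_trees("(sp1:1.0,sp2:1.0);", 0.008, 3, seed=4)
        _, mapping = gt["COI"]
        for sid, sp in mapping.items():
            assert sid.rsplit("_", 1)[1] == sp[2:]


class TestSequences:
    def test_zero_branch_lengths_identical(self):
        aln = evolve_sequences("(a_1:0.0,b_1:0.0):0.0;", 100, seed=3)
        assert aln.rows[0][1] == aln.rows[1][1]

    def test_no_indels_means_no_gaps(self):
        aln = evolve_sequences("(a_1:1.0,b_1:1.0);", 200, indel_rate=0.0, seed=5)
        assert "-" not in aln.rows[0][1] + aln.rows[1][1]

    def test_indel_process_produces_gaps(self):
        aln = evolve_sequences(
            "(a_1:4.0,b_1:4.0);", 300, indel_rate=0.01, seed=8
        )
        assert any("-" in seq for _, seq in aln.rows)
        assert len({len(seq) for _, seq in aln.rows}) == 1  # still aligned

    def test_jc_expected_p_distance(self):
        # JC closed form at pairwise divergence d: E[p] = 3/4 (1 - e^{-4d/3})
        d = 0.1
        clock = ClockModel(rate=d / 2.0)  # branch of 1 My per tip
        length, reps = 400, 120
        observed = []
        for i in range(reps):
            aln = evolve_sequences(
                "(a_1:1.0,b_1:1.0);", length, clock=clock, model="jc", seed=2000 + i
            )
            observed.append(p_distance(aln.rows[0][1], aln.rows[1][1]))
        expected = 0.75 * (1 - math.exp(-4 * d / 3))
        se = np.std(observed, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(observed) - expected) <= 3 * se


class TestDataset:
    def test_bundle_parseable_by_upstream_modules(self, small_dataset, tmp_path):
        small_dataset.write(tmp_path)
        coi = read_alignment(tmp_path / "coi.fasta")
        assert len(coi) == len(small_dataset.true_partition)
        clades = split_by_clade(coi)
        assert set(clades) == {sp[2:] for sp in small_dataset.true_partition.values()}
        sites = load_site_table(tmp_path / "sites.csv")
        n_sites, n_specimens, dmin, dmax = registry_totals(sites)
        assert n_specimens == len(small_dataset.true_partition)
        assert dmin >= 8 and dmax <= 4380

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = dict(K=3, seed=17, n_per_species=3)
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        simulate_dataset(SimulationConfig(**cfg)).write(a_dir)
        simulate_dataset(SimulationConfig(**cfg)).write(b_dir)
        for name in ("coi.fasta", "its2.fasta", "sites.csv", "truth.json"):
            assert (a_dir / name).read_bytes() == (b_dir / name).read_bytes()

    def test_within_species_diversity_near_theta(self, small_dataset):
        theta = small_dataset.config.theta
        coi = small_dataset.alignments["COI"]
        clades = split_by_clade(coi)
        dists = []
        for aln in clades.values():
            rows = aln.rows
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    dists.append(p_distance(rows[i][1], rows[j][1]))
        # mitochondrial marker: quarter effective size -> theta / 4, with
        # broad coalescent variance; just require the right order of magnitude
        assert 0.0 < np.mean(dists) < 4 * theta

    def test_true_partition_consistent_across_markers(self, small_dataset):
        for marker, aln in small_dataset.alignments.items():
            for sid in aln.ids:
                assert sid in small_dataset.true_partition

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(K=0)
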