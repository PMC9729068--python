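"""Structured-coalescent simulator against the analytic theory."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from migsci.densities import mscm_density, msci_density
from migsci.klfit import phi0
from migsci.params import (
    MSciParams,
    ScenarioSpec,
    msci_two_species_network,
    preset_scenario,
    two_species_network,
)
from migsci.params import _fig7_ghost_intro
from migsci.simulate import (
    CompiledNetwork,
    GeneTree,
    GeneTreeNode,
    MultilocusDataset,
    evolve_sequences_jc,
    pairwise_diff_counts,
    simulate_dataset,
    simulate_gene_tree,
    write_fasta,
    write_gene_trees,
    write_phylip,
)


def _pair_times(network, n_rep, seed):
    cn = CompiledNetwork(network)
    rng = np.random.default_rng(seed)
    return np.array(
        [cn.simulate(rng).mrca_age("A_1", "B_1") for _ in range(n_rep)]
    )


class TestGeneTreeSimulation:
    def test_isolation_means_no_coalescence_before_divergence(self, im_params):
        p = dataclasses.replace(im_params, M=0.0)
        ts = _pair_times(two_species_network(p, 1), 500, 1)
        assert np.all(ts > p.tau_R)

    def test_msci_lineage_takes_donor_path_with_probability_phi(self, msci_truth):
        cn = CompiledNetwork(msci_two_species_network(msci_truth, samples=1))
        rng = np.random.default_rng(2)
        N = 10000
        hits = 0
        for _ in range(N):
            tree = cn.simulate(rng)
            (tip,) = [t for t in tree.tips() if t.name == "B_1"]
            if any(lab == "S" for _, lab in tip.pop_path):
                hits += 1
        phat = hits / N
        se = np.sqrt(msci_truth.phi * (1 - msci_truth.phi) / N)
        assert abs(phat - msci_truth.phi) < 3.5 * se

    @pytest.mark.parametrize(
        "name", ["fig1-im", "fig1-iim", "fig1-sc"]
    )
    def test_ks_against_analytic_density(self, name):
        p = preset_scenario(name).mscm
        ts = _pair_times(two_species_network(p, 1), 20000, 3)
        ks = stats.kstest(ts, mscm_density(p).cdf)
        assert ks.pvalue > 0.01

    def test_ks_against_msci_density(self, msci_truth):
        ts = _pair_times(msci_two_species_network(msci_truth, 1), 20000, 4)
        ks = stats.kstest(ts, msci_density(msci_truth).cdf)
        assert ks.pvalue > 0.01

    def test_msci_phi_zero_mean_matches_isolation(self, msci_truth):
        p = dataclasses.replace(msci_truth, phi=0.0)
        ts = _pair_times(msci_two_species_network(p, 1), 20000, 5)
        expected = p.tau_R + p.theta_R / 2
        se = (p.theta_R / 2) / np.sqrt(len(ts))
        assert abs(ts.mean() - expected) < 3 * se

    @pytest.mark.parametrize("name", ["fig1-iim", "fig1-sc"])
    def test_migration_event_frequency_matches_phi0(self, name):
        """With one pair and one-way gene flow the B lineage jumps at most
        once, so the mean migration count equals the migrant proportion
        1 - exp(-w * dtau)."""
        p = preset_scenario(name).mscm
        cn = CompiledNetwork(two_species_network(p, 1))
        rng = np.random.default_rng(6)
        N = 10000
        m = np.array([cn.simulate(rng).n_migrations for _ in range(N)])
        assert set(np.unique(m)) <= {0, 1}
        target = phi0(p.M, p.delta_tau, p.theta_B)
        se = np.sqrt(target * (1 - target) / N)
        assert abs(m.mean() - target) < 3.5 * se

    def test_ghost_donor_representation_is_equivalent(self):
        """Writing the introgression bridge as an unsampled ghost species
        leaves the sampled pairwise coalescent process unchanged."""
        net_a = _fig7_ghost_intro(with_ghost_tip=False)
        net_b = _fig7_ghost_intro(with_ghost_tip=True)
        sam = {"A": 1, "B": 1, "C": 0, "D": 0}
        t_a = _pair_times(
            dataclasses.replace(net_a, samples=sam), 4000, 7
        )
        t_b = _pair_times(
            dataclasses.replace(net_b, samples={**sam, "U": 0}), 4000, 8
        )
        assert stats.ks_2samp(t_a, t_b).pvalue > 0.01

    def test_multispecies_preset_runs(self):
        net = preset_scenario("fig4-C").network
        tree = simulate_gene_tree(net, np.random.default_rng(0))
        assert len(tree.tips()) == 16  # 4 species x 4 samples
        ages = tree.coalescent_ages()
        assert len(ages) == 15
        assert all(a <= b for a, b in zip(ages, ages[1:]))


class TestSequences:
    def test_zero_branch_lengths_give_identical_sequences(self, rng):
        root = GeneTreeNode(
            "", 0.0, [GeneTreeNode("a", 0.0), GeneTreeNode("b", 0.0)]
        )
        aln = evolve_sequences_jc(GeneTree(root), 500, rng)
        assert np.array_equal(aln["a"], aln["b"])

    def test_pair_divergence_matches_jc_expectation(self, rng):
        t = 0.02
        root = GeneTreeNode(
            "", t, [GeneTreeNode("a", 0.0), GeneTreeNode("b", 0.0)]
        )
        tree = GeneTree(root)
        n, reps = 2000, 50
        fracs = []
        for _ in range(reps):
            aln = evolve_sequences_jc(tree, n, rng)
            fracs.append(np.mean(aln["a"] != aln["b"]))
        # total path between the tips is 2t, matching p(t) of the theory
        expected = 0.75 * (1 - np.exp(-8 * t / 3))
        se = np.sqrt(expected * (1 - expected) / (n * reps))
        assert abs(np.mean(fracs) - expected) < 4 * se

    def test_long_branch_saturates_at_three_quarters(self, rng):
        root = GeneTreeNode(
            "", 100.0, [GeneTreeNode("a", 0.0), GeneTreeNode("b", 0.0)]
        )
        aln = evolve_sequences_jc(GeneTree(root), 20000, rng)
        frac = np.mean(aln["a"] != aln["b"])
        assert abs(frac - 0.75) < 0.02

    def test_pairwise_diff_counts_examples(self):
        a = np.array([0, 0, 0, 0], dtype=np.int8)
        b = np.array([0, 0, 0, 3], dtype=np.int8)
        assert pairwise_diff_counts({"a": a, "b": b}, "a", "b").x == 1
        assert pairwise_diff_counts({"a": a, "b": a}, "a", "b").x == 0
        with pytest.raises(ValueError):
            pairwise_diff_counts({"a": a, "b": b[:3]}, "a", "b")


class TestDatasets:
    def test_fixed_seed_reproduces_dataset(self, im_params):
        sc = ScenarioSpec("t", L=30, S=2, n=100, mscm=im_params)
        d1 = simulate_dataset(sc, seed=9, emit="alignments")
        d2 = simulate_dataset(sc, seed=9, emit="alignments")
        for a1, a2 in zip(d1.alignments, d2.alignments):
            assert sorted(a1) == sorted(a2)
            for k in a1:
                assert np.array_equal(a1[k], a2[k])

    def test_growing_L_preserves_earlier_loci(self, im_params):
        small = ScenarioSpec("t", L=10, S=1, n=100, mscm=im_params)
        big = ScenarioSpec("t", L=25, S=1, n=100, mscm=im_params)
        c1 = simulate_dataset(small, seed=9, emit="counts").counts
        c2 = simulate_dataset(big, seed=9, emit="counts").counts
        assert c2[:10] == c1

    def test_shapes(self, im_params):
        sc = ScenarioSpec("t", L=250, S=1, n=250, mscm=im_params)
        ds = simulate_dataset(sc, seed=1, emit="alignments")
        assert len(ds.alignments) == 250
        for aln in ds.alignments[:5]:
            assert sorted(aln) == ["A_1", "B_1"]
            assert all(len(v) == 250 for v in aln.values())

    def test_counts_mode_matches_alignment_mode_distribution(self, im_params):
        """Drawing x ~ Binomial(n, p(t)) is distributionally identical to
        evolving JC sequences on the two-tip tree."""
        sc = ScenarioSpec("t", L=4000, S=1, n=400, mscm=im_params)
        xa = [
            pairwise_diff_counts(a, "A_1", "B_1").x
            for a in simulate_dataset(sc, seed=3, emit="alignments").alignments
        ]
        xc = [c.x for c in simulate_dataset(sc, seed=4, emit="counts").counts]
        assert stats.ks_2samp(xa, xc).pvalue > 0.01

    def test_writers(self, tmp_path, im_params):
        sc = ScenarioSpec("t", L=3, S=1, n=60, mscm=im_params)
        ds = simulate_dataset(sc, seed=2, emit="both", keep_trees=True)
        write_phylip(ds, tmp_path / "loci.phy")
        write_fasta(ds.alignments[0], tmp_path / "locus0.fa")
        write_gene_trees(ds.trees, tmp_path / "trees.nwk")
        phy = (tmp_path / "loci.phy").read_text().splitlines()
        assert phy[0] == "2 60"
        fa = (tmp_path / "locus0.fa").read_text()
        assert fa.startswith(">A_1\n")
        assert set(fa.splitlines()[1]) <= set("ACGT")
        nwk = (tmp_path / "trees.nwk").read_text().splitlines()
        assert len(nwk) == 3 and all(line.endswith(";") for line in nwk)
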