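"""Generator contracts: meiosis model, transmission, variance structure."""

import numpy as np
import pytest

from pedqtl import sim
from pedqtl.core import ConfigError, GenotypeMatrix, Pedigree


def _one_marker_map():
    cfg = sim.SimulationConfig(lg_lengths=[1.0], n_markers_per_lg=1)
    return cfg, sim.make_genetic_map(cfg)


class TestFounders:
    def test_smallest_instance_is_homozygous_biallelic(self):
        cfg, gmap = _one_marker_map()
        cfg.n_founders = 2
        g = sim.simulate_founders(cfg, gmap, seed=0)
        assert g.calls.shape == (2, 1)
        assert set(g.calls.ravel()) <= {0, 1}

    def test_same_seed_reproduces_matrix(self):
        cfg = sim.SimulationConfig(n_founders=20, lg_lengths=[50.0], n_markers_per_lg=30)
        gmap = sim.make_genetic_map(cfg)
        a = sim.simulate_founders(cfg, gmap, seed=7)
        b = sim.simulate_founders(cfg, gmap, seed=7)
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_allele_frequency_matches_binomial_sampling(self):
        # 10,000 founders at frequency 0.3: observed within 3 binomial SEs
        cfg, gmap = _one_marker_map()
        cfg.n_founders = 10_000
        g = sim.simulate_founders(cfg, gmap, seed=3, founder_freqs=np.array([0.3]))
        freq = g.calls.mean()
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(freq - 0.3) < 3 * se

    def test_empty_map_rejected(self):
        cfg = sim.SimulationConfig()
        gmap = sim.make_genetic_map(sim.SimulationConfig(lg_lengths=[1.0], n_markers_per_lg=1))
        empty = sim.GeneticMap(gmap.table.iloc[0:0])
        with pytest.raises(ConfigError):
            sim.simulate_founders(cfg, empty, seed=0)


class TestGamete:
    def test_zero_distance_cotransmits(self):
        cfg = sim.SimulationConfig(lg_lengths=[0.0], n_markers_per_lg=2)
        gmap = sim.make_genetic_map(cfg)
        haps = np.array([[0, 0], [1, 1]], dtype=np.int8)
        gametes = sim.simulate_gamete(haps, gmap, seed=1, n=2000)
        assert (gametes[:, 0] == gametes[:, 1]).all()

    def test_haldane_recombinant_fraction_at_10cm(self, two_marker_map):
        # r = (1 - exp(-0.2)) / 2 = 0.09063
        haps = np.array([[0, 0], [1, 1]], dtype=np.int8)
        n = 100_000
        gametes = sim.simulate_gamete(haps, two_marker_map, seed=2, n=n)
        rec = (gametes[:, 0] != gametes[:, 1]).mean()
        r = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(r * (1 - r) / n)
        assert abs(rec - r) < 3 * se

    def test_independent_assortment_across_linkage_groups(self):
        cfg = sim.SimulationConfig(lg_lengths=[1.0, 1.0], n_markers_per_lg=1)
        gmap = sim.make_genetic_map(cfg)
        haps = np.array([[0, 0], [1, 1]], dtype=np.int8)
        n = 100_000
        gametes = sim.simulate_gamete(haps, gmap, seed=3, n=n)
        rec = (gametes[:, 0] != gametes[:, 1]).mean()
        assert abs(rec - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_inbred_parent_shortcut_and_het_rejection(self, two_marker_map):
        g = sim.simulate_gamete(np.array([1, 0], dtype=np.int8), two_marker_map, seed=0, n=5)
        np.testing.assert_array_equal(g, np.tile([1, 0], (5, 1)))
        with pytest.raises(ConfigError):
            sim.simulate_gamete(np.array([1, 2], dtype=np.int8), two_marker_map, seed=0)


class TestPedigreeLines:
    def _setup(self, seed=0, n_markers=40):
        cfg = sim.SimulationConfig(
            n_founders=4, lg_lengths=[100.0], n_markers_per_lg=n_markers
        )
        gmap = sim.make_genetic_map(cfg)
        founders = sim.simulate_founders(cfg, gmap, seed=seed)
        return cfg, gmap, founders

    def test_child_of_identical_founders_is_identical(self):
        cfg, gmap, founders = self._setup()
        calls = founders.calls.copy()
        calls[1] = calls[0]
        founders = GenotypeMatrix(list(founders.accession_ids), list(founders.marker_ids), calls)
        ped = Pedigree([("f01", None, None), ("f02", None, None), ("c", "f01", "f02")])
        sub = founders.subset_accessions(["f01", "f02"])
        geno = sim.simulate_pedigree_lines(ped, sub, gmap, seed=5)
        np.testing.assert_array_equal(geno.calls[geno.accession_index("c")], calls[0])

    def test_transmission_closure_to_tagged_founder_alleles(self):
        cfg, gmap, founders = self._setup(seed=2)
        ped = sim.build_breeding_pedigree(4, 20, seed=2)
        geno, origins = sim.simulate_pedigree_lines(
            ped, founders, gmap, seed=3, return_origins=True
        )
        for i in range(geno.n_accessions):
            np.testing.assert_array_equal(
                geno.calls[i], founders.calls[origins[i], np.arange(geno.n_markers)]
            )

    def test_full_sib_kinship_exceeds_unrelated(self):
        # identity-by-descent: sibs share transmitted founder segments
        sib_sims, unrel_sims = [], []
        ped = Pedigree(
            [("f01", None, None), ("f02", None, None), ("f03", None, None),
             ("f04", None, None), ("s1", "f01", "f02"), ("s2", "f01", "f02")]
        )
        for rep in range(1000):
            cfg = sim.SimulationConfig(
                n_founders=4, lg_lengths=[100.0], n_markers_per_lg=30
            )
            gmap = sim.make_genetic_map(cfg)
            founders = sim.simulate_founders(cfg, gmap, seed=rep * 2)
            geno = sim.simulate_pedigree_lines(ped, founders, gmap, seed=rep * 2 + 1)
            s1 = geno.calls[geno.accession_index("s1")]
            s2 = geno.calls[geno.accession_index("s2")]
            f3 = geno.calls[geno.accession_index("f03")]
            f4 = geno.calls[geno.accession_index("f04")]
            sib_sims.append((s1 == s2).mean())
            unrel_sims.append((f3 == f4).mean())
        assert np.mean(sib_sims) > np.mean(unrel_sims)

    def test_cyclic_pedigree_rejected_on_construction(self):
        with pytest.raises(Exception):
            Pedigree([("a", "b", None), ("b", "a", None)])


class TestPhenotypes:
    def test_zero_variance_no_qtl_gives_constant_mu(self, two_marker_map):
        cfg = sim.SimulationConfig(
            qtl_spec=[], kernel_locus=None, var_genotype=0, var_environment=0,
            var_residual=0, n_environments=3, mu=64.0,
            lg_lengths=[10.0], n_markers_per_lg=2,
        )
        geno = GenotypeMatrix(["a1", "a2"], ["m1", "m2"], np.zeros((2, 2), dtype=np.int8))
        table = sim.simulate_phenotypes(geno, cfg, two_marker_map, seed=0)
        assert (table.table["value"] == 64.0).all()

    def test_noiseless_qtl_effect_is_exact_class_difference(self, two_marker_map):
        cfg = sim.SimulationConfig(
            qtl_spec=[("LG1", 0.0, 2.0)], kernel_locus=None, var_genotype=0,
            var_environment=7.3, var_residual=0, n_environments=2,
            lg_lengths=[10.0], n_markers_per_lg=2,
        )
        geno = GenotypeMatrix(
            ["a1", "a2"], ["m1", "m2"], np.array([[0, 0], [1, 0]], dtype=np.int8)
        )
        table = sim.simulate_phenotypes(geno, cfg, two_marker_map, seed=1)
        cell = table.env_means("FlYd")
        diff = cell.loc["a2"] - cell.loc["a1"]
        np.testing.assert_allclose(diff.to_numpy(), 2.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigError):
            sim.SimulationConfig(var_residual=-1.0)


class TestDHPopulation:
    def test_population_size_and_homozygosity(self, two_marker_map):
        p1 = np.array([0, 1], dtype=np.int8)
        p2 = np.array([1, 0], dtype=np.int8)
        pop = sim.simulate_dh_population(p1, p2, 160, two_marker_map, seed=0)
        assert pop.genotypes.n_accessions == 160
        assert set(pop.genotypes.calls.ravel()) <= {0, 1}

    def test_allele_frequency_half_at_polymorphic_markers(self):
        cfg = sim.SimulationConfig(lg_lengths=[50.0] * 2, n_markers_per_lg=5)
        gmap = sim.make_genetic_map(cfg)
        p1 = np.zeros(10, dtype=np.int8)
        p2 = np.ones(10, dtype=np.int8)
        pop = sim.simulate_dh_population(p1, p2, 10_000, gmap, seed=4)
        freq = pop.genotypes.calls.mean(axis=0)
        se = np.sqrt(0.25 / 10_000)
        assert (np.abs(freq - 0.5) < 3 * se).all()

    def test_shared_allele_marker_stays_monomorphic(self, two_marker_map):
        p1 = np.array([1, 1], dtype=np.int8)
        p2 = np.array([1, 0], dtype=np.int8)
        pop = sim.simulate_dh_population(p1, p2, 500, two_marker_map, seed=5)
        assert (pop.genotypes.calls[:, 0] == 1).all()

    def test_fully_monomorphic_cross_warns(self, two_marker_map):
        p = np.array([1, 0], dtype=np.int8)
        with pytest.warns(UserWarning, match="monomorphic"):
            sim.simulate_dh_population(p, p, 10, two_marker_map, seed=6)


class TestContigTriplet:
    def test_zero_divergence_gives_identical_sequences(self):
        t = sim.simulate_contig_triplet(400, 0.0, 200, seed=0)
        seqs = list(t.sequences.values())
        assert seqs[0] == seqs[1] == seqs[2]
        genome, offset, ref, alt = t.target_snp
        assert t.sequences[genome][offset] == ref

    def test_pairwise_differences_match_binomial_rate(self):
        t = sim.simulate_contig_triplet(1000, 0.03, 500, seed=1)
        a, b = t.sequences["A"], t.sequences["B"]
        diff = sum(x != y for x, y in zip(a, b))
        se = np.sqrt(1000 * 0.03 * 0.97)
        assert abs(diff - 30) < 3 * se

    def test_snp_readable_back_with_stated_alleles(self):
        t = sim.simulate_contig_triplet(600, 0.05, 300, alleles=("T", "C"), seed=2)
        genome, offset, ref, alt = t.target_snp
        assert (offset, ref, alt) == (300, "T", "C")
        assert t.allele_sequence("C")[300] == "C"

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ConfigError):
            sim.simulate_contig_triplet(400, 0.5, 200, seed=0)


def test_study_panel_structure(study_panel):
    panel = study_panel
    assert panel.genotypes.n_accessions == 65
    assert panel.phenotypes.table["environment"].nunique() == 9
    assert set(panel.kernel_type.unique()) <= {0, 1}
    # missing calls present (imputation is exercised) but never at QTL markers
    assert (panel.genotypes.calls == -1).any()
    for m in panel.qtl_markers:
        assert (panel.genotypes.column(m) != -1).all()
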