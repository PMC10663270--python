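import numpy as np
import pandas as pd
import pytest

from rggsim import genome
from rggsim.genome import ConfigurationError


class TestGeneticMap:
    def test_total_length_and_qtl_distribution(self, rng):
        gmap = genome.build_genetic_map(20, 2145.5, (204, 349), 1000, rng)
        assert gmap.total_cM == pytest.approx(2145.5)
        assert gmap.n_qtl == 1000
        # at least one QTL per chromosome
        for c in range(gmap.n_chrom):
            assert gmap.qtl_mask[gmap.chrom_slice(c)].sum() >= 1
        for c in range(gmap.n_chrom):
            assert np.all(np.diff(gmap.positions[c]) > 0)

    def test_single_chromosome_identity(self, rng):
        gmap = genome.build_genetic_map(1, 100.0, (10, 10), 5, rng)
        assert gmap.n_chrom == 1
        assert gmap.chrom_lengths[0] == pytest.approx(100.0)

    def test_too_many_qtl_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            genome.build_genetic_map(2, 100.0, (5, 5), 50, rng)

    def test_haldane_closed_form(self):
        # 50 cM -> (1 - exp(-1)) / 2
        assert genome.haldane(50.0) == pytest.approx(0.3161, abs=5e-5)

    def test_map_round_trip(self, small_map, tmp_path):
        rows = []
        for c in range(small_map.n_chrom):
            sl = small_map.chrom_slice(c)
            for p, q in zip(small_map.positions[c], small_map.qtl_mask[sl]):
                rows.append({"chrom": c, "position_cM": p, "is_qtl": int(q)})
        path = tmp_path / "map.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        loaded = genome.load_genetic_map(path)
        assert loaded.n_loci == small_map.n_loci
        assert loaded.n_qtl == small_map.n_qtl


class TestFounders:
    def test_maf_floor_and_inbreeding(self, founders):
        freq = founders.allele_freq()
        assert np.all(np.minimum(freq, 1 - freq) >= 0.05)
        assert np.all(founders.heterozygosity() <= 0.0625)

    def test_maf_validation(self, small_map, rng):
        with pytest.raises(ConfigurationError):
            genome.simulate_founders(10, small_map, maf_min=0.6, rng=rng)
        with pytest.raises(ConfigurationError):
            genome.simulate_founders(1, small_map, rng=rng)

    def test_heterozygosity_of_random_diploids(self, small_map):
        # sampling two haplotypes at p = 0.3 gives ~2p(1-p) heterozygosity
        rng = np.random.default_rng(3)
        p = 0.3
        h = (rng.random((4000, 2)) < p).astype(int)
        frac_het = (h[:, 0] != h[:, 1]).mean()
        assert frac_het == pytest.approx(2 * p * (1 - p), abs=0.02)

    def test_genotype_matrix_round_trip(self, founders, tmp_path):
        dos = founders.dosages()
        df = pd.DataFrame(dos, index=founders.ids)
        path = tmp_path / "geno.csv"
        df.to_csv(path)
        loaded = genome.load_founders(path, founders.gmap)
        assert np.array_equal(loaded.dosages(), dos)


class TestQTLEffects:
    def test_variance_rescaling_exact(self, small_map, founders, rng):
        eff = genome.sample_qtl_effects(small_map, 6.3, founders, rng)
        bv = founders.qtl_dosages() @ eff.phi_G
        assert bv.var(ddof=0) == pytest.approx(6.3, abs=1e-6)

    def test_zero_target_gives_zero_effects(self, small_map, founders, rng):
        eff = genome.sample_qtl_effects(small_map, 0.0, founders, rng)
        assert np.all(eff.phi_G == 0)

    def test_breeding_value_is_linear_dot_product(self, small_map, founders, rng):
        eff = genome.sample_qtl_effects(small_map, 2.0, founders, rng)
        theta = founders.qtl_dosages().astype(float)
        explicit = np.array([float(np.dot(row, eff.phi_G)) for row in theta])
        assert np.allclose(genome.breeding_values(theta, eff.phi_G), explicit)


class TestMeiosis:
    def test_recombination_matches_haldane(self):
        gmap = genome.GeneticMap(np.array([100.0]),
                                 [np.array([25.0, 75.0])],
                                 np.array([True, True]))
        rng = np.random.default_rng(0)
        haps = np.zeros((100000, 2, 2), np.int8)
        haps[:, 0, :] = 1  # doubly heterozygous, phase known
        g = genome.gametes_batch(haps, gmap, rng)
        rec = (g[:, 0] != g[:, 1]).mean()
        assert rec == pytest.approx(genome.haldane(50.0), abs=0.01)

    def test_selfing_homozygote_is_identity(self, small_map, founders, rng):
        ind = genome.Individual("x", founders.haplotypes[0], small_map)
        for child in genome.self_progeny(ind, 3, rng):
            assert np.array_equal(child.haplotypes.sum(0), ind.haplotypes.sum(0))

    def test_gametes_conserve_parental_alleles(self, small_map, founders, rng):
        a = genome.Individual("a", founders.haplotypes[0], small_map)
        b = genome.Individual("b", founders.haplotypes[1], small_map)
        f1 = genome.cross(a, b, rng)
        g = genome.gametes_batch(f1.haplotypes[None].repeat(200, 0), small_map, rng)
        lo = np.minimum(f1.haplotypes[0], f1.haplotypes[1])
        hi = np.maximum(f1.haplotypes[0], f1.haplotypes[1])
        assert np.all(g >= lo) and np.all(g <= hi)

    def test_mismatched_parents_rejected(self, small_map, founders, rng):
        a = genome.Individual("a", founders.haplotypes[0], small_map)
        b = genome.Individual("b", founders.haplotypes[1][:, :10], small_map)
        with pytest.raises(ConfigurationError):
            genome.cross(a, b, rng)

    def test_heterozygosity_halves_per_selfing_generation(self, small_map, founders):
        # F1 fully heterozygous at differing loci; F4 keeps ~1/8 of them
        rng = np.random.default_rng(11)
        a = genome.Individual("a", founders.haplotypes[0], small_map)
        b = genome.Individual("b", founders.haplotypes[1], small_map)
        diff = founders.haplotypes[0, 0] != founders.haplotypes[1, 0]
        fracs = []
        for _ in range(400):
            f1 = genome.cross(a, b, rng)
            f2 = genome.self_progeny(f1, 1, rng)[0]
            line = genome.develop_line(f2, rng)
            het = line.haplotypes[0] != line.haplotypes[1]
            fracs.append(het[diff].mean())
        assert np.mean(fracs) == pytest.approx(1 / 8, abs=0.02)

    def test_develop_line_homozygous_f2_unchanged(self, small_map, founders, rng):
        f2 = genome.Individual("f2", founders.haplotypes[2], small_map)
        line = genome.develop_line(f2, rng)
        assert np.array_equal(line.haplotypes.sum(0), f2.haplotypes.sum(0))

    def test_family_mean_near_midparent(self, small_map, founders):
        rng = np.random.default_rng(21)
        eff = genome.sample_qtl_effects(small_map, 4.0, founders, rng)
        devs = []
        for i in range(120):
            a = genome.Individual("a", founders.haplotypes[2 * (i % 25)], small_map)
            b = genome.Individual("b", founders.haplotypes[2 * (i % 25) + 1], small_map)
            f1 = genome.cross(a, b, rng)
            f2s = genome.self_progeny(f1, 12, rng)
            fam = np.mean([f.qtl_dosage() @ eff.phi_G for f in f2s])
            mid = 0.5 * (a.qtl_dosage() + b.qtl_dosage()) @ eff.phi_G
            devs.append(fam - mid)
        assert np.mean(devs) == pytest.approx(0.0, abs=0.25)


class TestGRM:
    def test_hand_computed_toy(self):
        M = np.array([[0, 2, 1, 0],
                      [2, 0, 1, 2],
                      [1, 1, 2, 1.0]])
        p = M.mean(0) / 2
        W = M - 2 * p
        expected = W @ W.T / (2 * np.sum(p * (1 - p)))
        assert np.allclose(genome.genomic_relationship(M), expected)

    def test_identical_inbred_lines_share_diagonal(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 2, 50) * 2
        M = np.vstack([base, base, 2 - base])
        G = genome.genomic_relationship(M)
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_monomorphic_input_rejected(self):
        with pytest.raises(ConfigurationError):
            genome.genomic_relationship(np.full((4, 6), 2.0))

    def test_inbred_diagonal_about_twice_outbred(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, 300)
        inbred = 2 * (rng.random((80, 300)) < p).astype(float)
        hw = ((rng.random((80, 300)) < p).astype(float)
              + (rng.random((80, 300)) < p).astype(float))
        d_in = np.diag(genome.genomic_relationship(inbred)).mean()
        d_out = np.diag(genome.genomic_relationship(hw)).mean()
        assert d_in / d_out == pytest.approx(2.0, rel=0.1)
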