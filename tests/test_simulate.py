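"""Simulator statistics: founder draws, meiosis, pedigree truth bookkeeping."""
import numpy as np
import pytest

from pedtrace.simulate import (ChromSpec, ConfigError, Cross, PedigreeOrderError,
                               PedigreeSpec, default_backcross_spec, meiosis,
                               run_pedigree, simulate_founders)


def _spec(seed=0, length=1_000_000, density=1e-3, morgans=1.0, poly=0.5,
          edges=(), nodes=("A", "B")):
    return PedigreeSpec(nodes=list(nodes), edges=list(edges),
                        genome=[ChromSpec("chr1", length, morgans)],
                        snp_density=density, polymorphism_rate=poly, seed=seed)


class TestFounders:
    def test_site_count_poisson(self):
        # ~1000 expected sites; 3 SD of the Poisson mean
        haps = simulate_founders(_spec(seed=3))
        n = len(haps[0].positions)
        assert abs(n - 1000) <= 3 * np.sqrt(1000)

    def test_homozygous_and_shared_positions(self):
        haps = simulate_founders(_spec(seed=1))
        by_founder = {h.founder_id: h for h in haps}
        assert set(by_founder) == {"A", "B"}
        np.testing.assert_array_equal(by_founder["A"].positions,
                                      by_founder["B"].positions)
        assert set(np.unique(by_founder["A"].alleles)) <= {0, 1}

    def test_zero_polymorphism_identical_founders(self):
        haps = simulate_founders(_spec(seed=2, poly=0.0))
        a, b = (h.alleles for h in haps)
        np.testing.assert_array_equal(a, b)

    def test_divergence_matches_rate(self):
        haps = simulate_founders(_spec(seed=4, density=5e-3, poly=0.3))
        a, b = (h.alleles for h in haps)
        rate = np.mean(a != b)
        assert abs(rate - 0.3) < 3 * np.sqrt(0.3 * 0.7 / len(a))

    def test_same_seed_bit_identical(self):
        h1 = simulate_founders(_spec(seed=5))
        h2 = simulate_founders(_spec(seed=5))
        for x, y in zip(h1, h2):
            np.testing.assert_array_equal(x.alleles, y.alleles)
            np.testing.assert_array_equal(x.positions, y.positions)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            _spec(density=0.0)
        with pytest.raises(ConfigError):
            PedigreeSpec(nodes=["A"], edges=[], genome=[], snp_density=1e-3)


class TestMeiosis:
    def _parent(self, n_sites, het=True, seed=0):
        rng = np.random.default_rng(seed)
        h0 = rng.integers(0, 2, n_sites).astype(np.int8)
        h1 = rng.integers(0, 2, n_sites).astype(np.int8) if het else h0.copy()
        o0 = [(0, 1_000_000, "A")]
        o1 = [(0, 1_000_000, "B" if het else "A")]
        pos = np.sort(rng.choice(np.arange(1, 1_000_001), n_sites, replace=False))
        return (h0, h1), (o0, o1), pos

    def test_crossover_mean_poisson(self):
        # 2-Morgan chromosome, 1000 meioses: Monte-Carlo check of the mean
        haps, origins, pos = self._parent(200)
        rng = np.random.default_rng(11)
        counts = [len(meiosis(haps, origins, pos, 1_000_000, 2.0, rng)[2])
                  for _ in range(1000)]
        sem = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 2.0) <= 3 * sem

    def test_zero_genetic_length_intact_copy(self):
        haps, origins, pos = self._parent(100)
        rng = np.random.default_rng(1)
        gamete, segs, xs = meiosis(haps, origins, pos, 1_000_000, 0.0, rng)
        assert len(xs) == 0
        assert any(np.array_equal(gamete, h) for h in haps)
        assert segs in (origins[0], origins[1])

    def test_homozygous_parent_gamete_identical(self):
        haps, origins, pos = self._parent(100, het=False)
        rng = np.random.default_rng(2)
        gamete, _, _ = meiosis(haps, origins, pos, 1_000_000, 3.0, rng)
        np.testing.assert_array_equal(gamete, haps[0])

    def test_negative_length_rejected(self):
        haps, origins, pos = self._parent(10)
        with pytest.raises(ConfigError):
            meiosis(haps, origins, pos, 1_000_000, -1.0, np.random.default_rng(0))


class TestPedigree:
    def test_truth_tiles_chromosome(self, small_sim):
        for mosaic in small_sim.truth.values():
            for cspec in small_sim.spec.genome:
                for hap in mosaic.segments[cspec.name]:
                    assert hap[0][0] == 0
                    assert hap[-1][1] == cspec.length_bp
                    for (s1, e1, _), (s2, e2, _) in zip(hap, hap[1:]):
                        assert e1 == s2  # no gaps, no overlaps

    def test_truth_fractions_sum_to_one(self, small_sim):
        for mosaic in small_sim.truth.values():
            fr = mosaic.diploid_fractions(small_sim.spec.genome)
            assert abs(sum(fr.values()) - 1.0) < 1e-9

    def test_same_seed_reproducible(self):
        spec = default_backcross_spec(seed=9, chrom_length_bp=200_000)
        gm1 = run_pedigree(spec).genotype_matrix()
        gm2 = run_pedigree(spec).genotype_matrix()
        np.testing.assert_array_equal(gm1.calls, gm2.calls)

    def test_child_before_parent_rejected(self):
        with pytest.raises(PedigreeOrderError):
            PedigreeSpec(nodes=["A", "B", "C", "D"],
                         edges=[Cross("A", "C", "D"), Cross("A", "B", "C")],
                         genome=[ChromSpec("chr1", 1000, 1.0)])

    def test_bc1_recurrent_fraction_75pct(self):
        # Monte-Carlo oracle: truth-level recurrent-parent fraction of a BC1
        # averages 75% (one homolog fully recurrent, the other half)
        fracs = []
        for seed in range(500):
            spec = PedigreeSpec(
                nodes=["D", "R", "F1", "BC1"],
                edges=[Cross("D", "R", "F1"), Cross("R", "F1", "BC1")],
                genome=[ChromSpec("chr1", 10_000_000, 1.0),
                        ChromSpec("chr2", 10_000_000, 1.0)],
                snp_density=1e-5, seed=seed)
            sim = run_pedigree(spec)
            fracs.append(sim.truth["BC1"].diploid_fractions(spec.genome)["R"])
        sem = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.75) <= 3 * sem

    def test_selfing_halves_heterozygosity(self):
        # F1 selfed 6 generations keeps ~(1/2)^6 of the F1 heterozygosity
        hets6, hets0 = [], []
        for seed in range(40):
            for n_self, acc in ((0, hets0), (6, hets6)):
                spec = PedigreeSpec(
                    nodes=["A", "B", "F"],
                    edges=[Cross("A", "B", "F", n_selfing=n_self)],
                    genome=[ChromSpec("chr1", 1_000_000, 1.0)],
                    snp_density=2e-3, seed=seed)
                sim = run_pedigree(spec)
                acc.append(sim.lines["F"].heterozygosity())
        expected = np.mean(hets0) / 2 ** 6
        sem = np.std(hets6, ddof=1) / np.sqrt(len(hets6))
        assert abs(np.mean(hets6) - expected) <= 3 * sem + 1e-4

    def test_selfing_monotonically_reduces_heterozygosity(self):
        means = []
        for n_self in (0, 1, 2, 4):
            hets = []
            for seed in range(15):
                spec = PedigreeSpec(
                    nodes=["A", "B", "F"],
                    edges=[Cross("A", "B", "F", n_selfing=n_self)],
                    genome=[ChromSpec("chr1", 1_000_000, 1.0)],
                    snp_density=1e-3, seed=100 + seed)
                hets.append(run_pedigree(spec).lines["F"].heterozygosity())
            means.append(np.mean(hets))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_vcf_and_truth_bed_written(self, small_sim, tmp_path):
        vcf = tmp_path / "sim.vcf"
        small_sim.write_vcf(str(vcf))
        beds = small_sim.write_truth_beds(str(tmp_path))
        assert vcf.exists() and len(beds) == 2 * len(small_sim.lines)
        first = open(beds[0]).readline().split("\t")
        assert len(first) == 4 and first[1] == "0"
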