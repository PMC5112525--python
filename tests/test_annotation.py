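"""Feature classification and coding-effect calls against translation oracles."""
import numpy as np
import pytest
from Bio.Seq import Seq

from pedtrace.annotation import (RefMismatchError, annotation_summary,
                                 chromosome_shares, classify_coding_effect,
                                 classify_feature, nonsyn_syn_ratio,
                                 summary_from_counts)
from pedtrace.io import GeneIndex, GeneModel, VariantSite
from pedtrace.synthdata import simulate_gene_models


@pytest.fixture()
def toy_index():
    # + strand: exon1 1001-1500 (UTR5 1001-1100, CDS 1101-1500),
    #           intron 1501-2000, exon2 2001-3000 (CDS 2001-2800, UTR3 2801-3000)
    g = GeneModel("g1", "chr1", "+", 1001, 3000,
                  exons=[(1001, 1500), (2001, 3000)],
                  cds=[(1101, 1500), (2001, 2800)],
                  utr5=[(1001, 1100)], utr3=[(2801, 3000)], coding_ok=True)
    return GeneIndex([g])


@pytest.mark.parametrize("pos,expected", [
    (1501, "splice_site"),   # 1 bp into the intron
    (2000, "splice_site"),   # last intron base
    (1700, "intron"),
    (1050, "utr5"),
    (2900, "utr3"),
    (1200, "exon"),
    (500, "promoter"),       # within 2000 bp upstream of TSS 1001
    (50_000, "intergenic"),
])
def test_feature_classification(toy_index, pos, expected):
    feature, gene = classify_feature("chr1", pos, toy_index)
    assert feature == expected
    assert (gene is None) == (expected == "intergenic")


def test_promoter_only_outside_genebodies():
    # overlapping gene body beats the other gene's promoter region
    ga = GeneModel("a", "chr1", "+", 1000, 5000, exons=[(1000, 5000)])
    gb = GeneModel("b", "chr1", "+", 6000, 9000, exons=[(6000, 9000)])
    index = GeneIndex([ga, gb])
    feature, gene = classify_feature("chr1", 4500, index)  # in a, upstream of b
    assert (feature, gene) == ("exon", "a")


def test_feature_classification_matches_brute_force():
    index, _ = simulate_gene_models({"chrZ": 60_000}, genes_per_chrom=8, seed=5)
    genes = list(index)
    rng = np.random.default_rng(6)
    for pos in rng.integers(1, 60_000, size=400):
        pos = int(pos)
        got, _ = classify_feature("chrZ", pos, index, promoter_bp=2000, splice_bp=2)
        # independent re-derivation from the raw gene structures
        labels = []
        for g in genes:
            if not (g.start <= pos <= g.end):
                continue
            lab = None
            for (s1, e1), (s2, _) in zip(g.exons, g.exons[1:]):
                if e1 < pos < s2:
                    lab = ("splice_site" if pos - e1 <= 2 or s2 - pos <= 2
                           else "intron")
            if lab is None:
                if any(s <= pos <= e for s, e in g.utr5):
                    lab = "utr5"
                elif any(s <= pos <= e for s, e in g.utr3):
                    lab = "utr3"
                elif any(s <= pos <= e for s, e in g.cds):
                    lab = "exon"
                else:
                    lab = "intron"
            labels.append(lab)
        if labels:
            prio = {"splice_site": 5, "utr5": 4, "utr3": 4, "exon": 3, "intron": 2}
            expect = max(labels, key=lambda x: prio[x])
        elif any(g.in_promoter(pos, 2000) for g in genes):
            expect = "promoter"
        else:
            expect = "intergenic"
        assert got == expect, pos


class TestCodingEffect:
    def _gene_and_fasta(self, cds_seq, strand="+"):
        """Single-exon gene at 101..; genomic sequence carries cds_seq."""
        genomic = cds_seq if strand == "+" else str(Seq(cds_seq).reverse_complement())
        chrom = "N" * 100 + genomic + "N" * 50
        start, end = 101, 100 + len(genomic)
        gene = GeneModel("g", "chr1", strand, start, end, exons=[(start, end)],
                         cds=[(start, end)], coding_ok=True)
        return gene, {"chr1": chrom}, start, end

    def test_synonymous_gly_to_gly(self):
        gene, fa, start, _ = self._gene_and_fasta("ATGGGATAA")
        # GGA -> GGG at codon position 3
        site = VariantSite("chr1", start + 5, "A", "G")
        assert classify_coding_effect(site, gene, fa) == "synonymous"

    def test_stop_gain_tgg_to_tga(self):
        gene, fa, start, _ = self._gene_and_fasta("ATGTGGTAA")
        site = VariantSite("chr1", start + 5, "G", "A")
        assert classify_coding_effect(site, gene, fa) == "stop_gain"

    def test_stop_loss_taa_to_caa(self):
        gene, fa, start, _ = self._gene_and_fasta("ATGGGATAA")
        site = VariantSite("chr1", start + 6, "T", "C")
        assert classify_coding_effect(site, gene, fa) == "stop_loss"

    def test_nonsynonymous_minus_strand(self):
        gene, fa, start, _ = self._gene_and_fasta("ATGGCATAA", strand="-")
        # transcript offset 4 = middle of codon GCA (Ala); on the minus
        # strand it maps to genomic position end-4 with complemented bases.
        site_pos = gene.end - 4
        ref = fa["chr1"][site_pos - 1]
        assert ref == "G"  # complement of transcript 'C'
        site = VariantSite("chr1", site_pos, "G", "A")  # transcript C->T: GTA (Val)
        assert classify_coding_effect(site, gene, fa) == "nonsynonymous"

    def test_ref_mismatch_raises(self):
        gene, fa, start, _ = self._gene_and_fasta("ATGGGATAA")
        site = VariantSite("chr1", start + 5, "C", "G")  # FASTA has A
        with pytest.raises(RefMismatchError):
            classify_coding_effect(site, gene, fa)

    def test_matches_whole_protein_translation_oracle(self):
        # every CDS position of a randomized multi-gene fixture, both strands
        from pedtrace.annotation import cds_sequence
        index, genomes = simulate_gene_models({"chrO": 40_000},
                                              genes_per_chrom=6, seed=9)
        rng = np.random.default_rng(10)
        n_checked = 0
        for gene in index:
            cds_positions = [p for s, e in gene.cds for p in range(s, e + 1)]
            for pos in rng.choice(cds_positions, size=30, replace=False):
                pos = int(pos)
                ref = genomes["chrO"][pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                site = VariantSite("chrO", pos, ref, alt)
                got = classify_coding_effect(site, gene, genomes)
                # oracle: translate full ref and alt CDS and diff the proteins
                alt_genome = {"chrO": genomes["chrO"][:pos - 1] + alt
                              + genomes["chrO"][pos:]}
                p_ref = str(Seq(cds_sequence(gene, genomes)).translate())
                p_alt = str(Seq(cds_sequence(gene, alt_genome)).translate())
                if p_ref == p_alt:
                    expect = "synonymous"
                else:
                    diffs = [(a, b) for a, b in zip(p_ref, p_alt) if a != b]
                    a, b = diffs[0]
                    expect = ("stop_gain" if b == "*" else
                              "stop_loss" if a == "*" else "nonsynonymous")
                assert got == expect, f"{gene.gene_id}:{pos}"
                n_checked += 1
        assert n_checked >= 150


class TestSummaries:
    def test_percentages_sum_to_100(self):
        summ = summary_from_counts({"intergenic": 55, "exon": 30, "intron": 15})
        assert sum(summ["feature_pct"].values()) == pytest.approx(100.0)

    def test_ratio_excludes_stops_and_handles_zero(self):
        summ = summary_from_counts({"exon": 10},
                                   {"nonsynonymous": 6, "synonymous": 4,
                                    "stop_gain": 100})
        assert summ["nonsyn_syn_ratio"] == pytest.approx(1.5)
        assert np.isnan(nonsyn_syn_ratio(5, 0))
        assert nonsyn_syn_ratio(0, 5) == 0.0

    def test_annotation_summary_from_table(self):
        import pandas as pd
        df = pd.DataFrame({"feature": ["exon", "exon", "intron"],
                           "coding_effect": ["synonymous", "nonsynonymous",
                                             "none"]})
        summ = annotation_summary(df)
        assert summ["feature_pct"]["intron"] == pytest.approx(100 / 3)
        assert summ["nonsyn_syn_ratio"] == pytest.approx(1.0)

    def test_chromosome_shares(self):
        shares = chromosome_shares({"c1": 30, "c2": 70})
        assert shares == {"c1": 30.0, "c2": 70.0}
        with pytest.raises(ValueError):
            chromosome_shares({})
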