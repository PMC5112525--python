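"""Synthetic companions to the pedigree simulator.

Generators for the non-genotype inputs the pipeline consumes: gene models
with a matching reference sequence, long-form expression tables with
planted differentially expressed genes, and promoter sequences with
planted TF-binding motifs.  Everything carries explicit truth so every
downstream stage is testable without external data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import DEFAULT_CONTRASTS, DROUGHT, WELL_WATERED, contrast_label
from .io import GeneIndex, GeneModel
from .motifs import BASES, Pwm
from .simulate import PedigreeSpec


# ---------------------------------------------------------------------------
# gene models + reference sequence
# ---------------------------------------------------------------------------

def simulate_gene_models(chrom_lengths: dict[str, int], genes_per_chrom: int = 20,
                         seed: int = 0, snp_positions: dict[str, np.ndarray] | None = None
                         ) -> tuple[GeneIndex, dict[str, str]]:
    """Random 2-exon protein-coding gene models and a matching genome.

    Genes are laid out non-overlapping on alternating strands with UTRs,
    a CDS whose length is a multiple of 3, and an intact ORF
    (ATG ... stop, no internal stops) so coding effects are well defined.
    If ``snp_positions`` is given (1-based, per chromosome), the reference
    base at each SNP site is forced to 'A' so simulator VCFs (REF=A, ALT=T)
    are consistent with the sequence.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 10)))
    genomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    for chrom, length in chrom_lengths.items():
        seq = rng.choice(list(BASES), size=length)
        if snp_positions is not None and chrom in snp_positions:
            seq[snp_positions[chrom] - 1] = "A"
        # gene slots spaced over the chromosome
        slot = length // (genes_per_chrom + 1)
        for k in range(genes_per_chrom):
            anchor = slot * (k + 1)
            strand = "+" if k % 2 == 0 else "-"
            utr5_len = int(rng.integers(50, 150))
            utr3_len = int(rng.integers(50, 150))
            cds1 = int(rng.integers(30, 120)) * 3 // 2
            intron = int(rng.integers(80, 300))
            cds_total = int(rng.integers(60, 180)) * 3
            cds1 = min(cds1, cds_total - 3)
            cds2 = cds_total - cds1
            gene_id = f"G{chrom}_{k:03d}"
            if strand == "+":
                g_start = anchor
                e1_start = g_start
                e1_end = g_start + utr5_len + cds1 - 1
                e2_start = e1_end + intron + 1
                e2_end = e2_start + cds2 + utr3_len - 1
                cds = [(g_start + utr5_len, e1_end), (e2_start, e2_start + cds2 - 1)]
                exons = [(e1_start, e1_end), (e2_start, e2_end)]
                g_end = e2_end
            else:
                g_end = anchor + utr5_len + cds1 + intron + cds2 + utr3_len
                e2_end = g_end
                e2_start = g_end - utr5_len - cds1 + 1
                e1_end = e2_start - intron - 1
                e1_start = e1_end - (cds2 + utr3_len) + 1
                cds = [(e1_start + utr3_len, e1_end), (e2_start, e2_end - utr5_len)]
                exons = [(e1_start, e1_end), (e2_start, e2_end)]
                g_start = e1_start
            if g_end >= length - 1 or g_start < 1:
                continue
            gm = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                           start=g_start, end=g_end, exons=exons, cds=cds,
                           coding_ok=True)
            _write_orf(seq, gm, rng, snp_positions.get(chrom) if snp_positions else None)
            # UTRs derive from exon minus CDS
            from .io import _subtract
            utr = _subtract(exons, cds)
            if strand == "+":
                gm.utr5 = [iv for iv in utr if iv[1] < cds[0][0]]
                gm.utr3 = [iv for iv in utr if iv[0] > cds[-1][1]]
            else:
                gm.utr5 = [iv for iv in utr if iv[0] > cds[-1][1]]
                gm.utr3 = [iv for iv in utr if iv[1] < cds[0][0]]
            genes.append(gm)
        genomes[chrom] = "".join(seq)
    return GeneIndex(genes), genomes


_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def _write_orf(seq: np.ndarray, gene: GeneModel, rng: np.random.Generator,
               snp_pos: np.ndarray | None) -> None:
    """Overwrite the genomic bases of a gene's CDS with an intact ORF.

    Bases at SNP sites (forced to 'A') are preserved; codons are re-drawn
    until no internal stop emerges, which the 'A' constraint cannot block
    (AAA is never a stop).
    """
    n = sum(e - s + 1 for s, e in gene.cds)
    # genomic coordinates of the CDS in transcript orientation
    coords: list[int] = []
    for s, e in gene.cds:
        coords.extend(range(s, e + 1))
    if gene.strand == "-":
        coords = coords[::-1]
    frozen = set(snp_pos.tolist()) if snp_pos is not None else set()

    def put(tx_idx: int, base: str) -> None:
        g = coords[tx_idx]
        if g in frozen:
            return
        seq[g - 1] = base if gene.strand == "+" else base.translate(_COMP)

    def get(tx_idx: int) -> str:
        g = coords[tx_idx]
        b = str(seq[g - 1])
        return b if gene.strand == "+" else b.translate(_COMP)

    for b, base in zip(range(3), "ATG"):
        put(b, base)
    for ci in range(1, n // 3 - 1):
        for _ in range(10):
            codon = "".join(get(3 * ci + k) for k in range(3))
            if codon not in _STOPS:
                break
            k = int(rng.integers(3))
            put(3 * ci + k, str(rng.choice(list("ACG"))))
    # terminal stop codon; TAA survives frozen-'A' positions
    for k, base in enumerate("TAA"):
        put(n - 3 + k, base)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Planted DEG membership per (variety, contrast)."""

    up: dict[tuple[str, str], set[str]]
    down: dict[tuple[str, str], set[str]]


def simulate_expression(gene_ids: list[str], varieties: list[str],
                        n_up: int = 8, n_down: int = 6, seed: int = 0,
                        base_fpkm: float = 20.0) -> tuple[pd.DataFrame, pd.DataFrame,
                                                          ExpressionTruth]:
    """Long-form FPKM table + per-contrast p-values with planted DEGs.

    For each variety and each default contrast, ``n_up``/``n_down`` genes
    are planted with fold changes beyond the 2x threshold and p-values
    below 0.05; every other gene gets a sub-threshold fold change or a
    non-significant p-value.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    sides = sorted({s for pair in DEFAULT_CONTRASTS for s in pair})
    fpkm_rows = []
    p_rows = []
    truth = ExpressionTruth({}, {})
    for variety in varieties:
        base = pd.Series(rng.lognormal(np.log(base_fpkm), 0.5, len(gene_ids)),
                         index=gene_ids)
        levels = {side: base * rng.lognormal(0, 0.05, len(gene_ids))
                  for side in sides}
        for num, den in DEFAULT_CONTRASTS:
            label = contrast_label(num, den)
            chosen = rng.choice(gene_ids, size=n_up + n_down, replace=False)
            up, down = set(chosen[:n_up]), set(chosen[n_up:])
            truth.up[(variety, label)] = up
            truth.down[(variety, label)] = down
            for g in up:
                levels[num].loc[g] = levels[den].loc[g] * rng.uniform(2.5, 8.0)
            for g in down:
                levels[num].loc[g] = levels[den].loc[g] / rng.uniform(2.5, 8.0)
            for g in gene_ids:
                planted = g in up or g in down
                p = rng.uniform(0.0001, 0.03) if planted else rng.uniform(0.2, 0.99)
                p_rows.append(dict(gene_id=g, variety=variety, contrast=label,
                                   p_value=p))
        for side in sides:
            cond, time = side
            for g in gene_ids:
                fpkm_rows.append(dict(gene_id=g, variety=variety, condition=cond,
                                      time_point=time,
                                      fpkm=float(levels[side].loc[g])))
    return pd.DataFrame(fpkm_rows), pd.DataFrame(p_rows), truth


# ---------------------------------------------------------------------------
# promoters with planted motifs
# ---------------------------------------------------------------------------

def toy_pwms(seed: int = 0) -> list[Pwm]:
    """Three sharp 8-bp toy motifs named after drought-responsive TF families."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 12)))
    fams = ["ERF", "WRKY", "bHLH"]
    out = []
    for i, fam in enumerate(fams):
        L = 8
        counts = np.full((4, L), 1.0)
        cons = rng.integers(0, 4, size=L)
        counts[cons, np.arange(L)] = 97.0  # strongly informative columns
        out.append(Pwm(f"MT{i + 1:04d}", fam, counts))
    return out


def simulate_promoters(gene_ids: list[str], pwms: list[Pwm],
                       planted: dict[str, list[str]] | None = None,
                       length: int = 300, seed: int = 0,
                       plant_fraction: float = 0.5) -> tuple[dict[str, str],
                                                             dict[str, set[str]]]:
    """Random promoter sequences with motif consensi planted in a subset.

    Returns (gene -> sequence, gene -> set of planted motif ids).  If
    ``planted`` is not given, each motif is planted in a random
    ``plant_fraction`` of the genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    if planted is None:
        planted = {}
        for pwm in pwms:
            n = max(1, int(round(plant_fraction * len(gene_ids))))
            for g in rng.choice(gene_ids, size=n, replace=False):
                planted.setdefault(str(g), []).append(pwm.motif_id)
    by_id = {p.motif_id: p for p in pwms}
    seqs: dict[str, str] = {}
    truth: dict[str, set[str]] = {}
    for g in gene_ids:
        seq = rng.choice(list(BASES), size=length)
        truth[g] = set()
        for mid in planted.get(g, []):
            pwm = by_id[mid]
            off = int(rng.integers(0, length - pwm.length + 1))
            seq[off:off + pwm.length] = list(pwm.consensus())
            truth[g].add(mid)
        seqs[g] = "".join(seq)
    return seqs, truth
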