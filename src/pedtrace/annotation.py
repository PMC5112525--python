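"""SNP functional annotation: genomic feature and coding effect.

Each SNP receives exactly one feature label.  Within a gene the priority is
splice_site > UTR (5'/3') > exon (CDS) > intron; promoter applies only to
SNPs outside every gene body; everything else is intergenic.  Coding
effects (synonymous / nonsynonymous / stop_gain / stop_loss) are called by
substituting the alternate allele into the reference codon in transcript
orientation and translating under the standard nuclear code.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import GeneIndex, GeneModel, GenotypeMatrix, VariantSite, fetch_seq

FEATURES = ("intergenic", "promoter", "intron", "exon", "utr5", "utr3", "splice_site")
EFFECTS = ("synonymous", "nonsynonymous", "stop_gain", "stop_loss", "none")

# priority when a SNP hits annotations of one or several genes (high wins)
_PRIORITY = {"splice_site": 5, "utr5": 4, "utr3": 4, "exon": 3, "intron": 2}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class RefMismatchError(ValueError):
    """VCF ref allele disagrees with the reference FASTA."""


@dataclass
class SnpAnnotation:
    site: VariantSite
    feature: str
    coding_effect: str = "none"
    gene_id: str | None = None


def _feature_within_gene(pos: int, gene: GeneModel, splice_bp: int) -> str | None:
    """Sub-feature of a position inside a gene span, or None if outside."""
    if not gene.contains(pos):
        return None
    exons = gene.exons
    # introns = gaps between consecutive exons
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        if e1 < pos < s2:
            if pos - e1 <= splice_bp or s2 - pos <= splice_bp:
                return "splice_site"
            return "intron"
    for s, e in gene.utr5:
        if s <= pos <= e:
            return "utr5"
    for s, e in gene.utr3:
        if s <= pos <= e:
            return "utr3"
    for s, e in gene.cds:
        if s <= pos <= e:
            return "exon"
    for s, e in exons:
        if s <= pos <= e:
            return "exon"  # exonic but non-coding transcript
    return "intron"  # inside span, outside representative-transcript exons


def classify_feature(chrom: str, pos: int, index: GeneIndex,
                     promoter_bp: int = 2000,
                     splice_bp: int = 2) -> tuple[str, str | None]:
    """Feature label (and gene id where applicable) for one position."""
    best: tuple[int, str, str] | None = None  # (priority, feature, gene_id)
    for g in index.genes_at(chrom, pos):
        feat = _feature_within_gene(pos, g, splice_bp)
        if feat is None:
            continue
        cand = (_PRIORITY[feat], feat, g.gene_id)
        if best is None or cand[0] > best[0]:
            best = cand
    if best is not None:
        return best[1], best[2]
    prom = index.promoter_genes_at(chrom, pos, promoter_bp)
    if prom:
        return "promoter", prom[0].gene_id
    return "intergenic", None


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS (transcript orientation)."""
    if gene.strand == "+":
        off = 0
        for s, e in gene.cds:
            if s <= pos <= e:
                return off + pos - s
            off += e - s + 1
    else:
        off = 0
        for s, e in reversed(gene.cds):
            if s <= pos <= e:
                return off + e - pos
            off += e - s + 1
    return None


def cds_sequence(gene: GeneModel, fasta) -> str:
    """Spliced CDS in transcript orientation (reverse-complemented on −)."""
    parts = [fetch_seq(fasta, gene.chrom, s, e) for s, e in gene.cds]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def classify_coding_effect(site: VariantSite, gene: GeneModel, fasta,
                           _cds_cache: dict | None = None) -> str:
    """Coding effect of a CDS SNP under the standard codon table."""
    if not gene.coding_ok:
        return "none"
    off = _cds_offset(gene, site.pos)
    if off is None:
        return "none"
    ref_base = fetch_seq(fasta, site.chrom, site.pos, site.pos)
    if ref_base != site.ref:
        raise RefMismatchError(
            f"{site.chrom}:{site.pos}: VCF ref {site.ref} != FASTA {ref_base}")
    if _cds_cache is not None and gene.gene_id in _cds_cache:
        cds = _cds_cache[gene.gene_id]
    else:
        cds = cds_sequence(gene, fasta)
        if _cds_cache is not None:
            _cds_cache[gene.gene_id] = cds
    alt = site.alt if gene.strand == "+" else site.alt.translate(_COMPLEMENT)
    ci = off // 3
    within = off % 3
    codon = cds[3 * ci:3 * ci + 3]
    if len(codon) < 3:
        return "none"
    alt_codon = codon[:within] + alt + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_ref != "*" and aa_alt == "*":
        return "stop_gain"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_loss"
    return "nonsynonymous"


def annotate_sites(gm: GenotypeMatrix, index: GeneIndex, fasta=None,
                   promoter_bp: int = 2000, splice_bp: int = 2) -> pd.DataFrame:
    """Annotate every site of a genotype matrix.

    Coding effects are computed only when a reference FASTA is supplied;
    otherwise exonic SNPs carry effect 'none'.
    """
    rows = []
    cache: dict[str, str] = {}
    sites = gm.sites
    for j in range(gm.n_sites):
        site = VariantSite(sites.at[j, "chrom"], int(sites.at[j, "pos"]),
                           sites.at[j, "ref"], sites.at[j, "alt"])
        feature, gene_id = classify_feature(site.chrom, site.pos, index,
                                            promoter_bp, splice_bp)
        effect = "none"
        if feature == "exon" and fasta is not None and gene_id is not None:
            effect = classify_coding_effect(site, index.genes[gene_id], fasta, cache)
        rows.append(dict(chrom=site.chrom, pos=site.pos, ref=site.ref,
                         alt=site.alt, feature=feature, coding_effect=effect,
                         gene_id=gene_id))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def nonsyn_syn_ratio(n_nonsyn: int, n_syn: int) -> float:
    """Nonsyn/Syn ratio; stop mutations are excluded by the caller's counts."""
    if n_syn == 0:
        return float("nan")
    return n_nonsyn / n_syn


def summary_from_counts(feature_counts: dict[str, int],
                        effect_counts: dict[str, int] | None = None) -> dict:
    """Percentages per feature and the Nonsyn/Syn ratio from pre-tabulated counts.

    Stop-gain/stop-loss variants are excluded from both sides of the ratio.
    """
    total = sum(feature_counts.values())
    if total == 0:
        raise ValueError("empty annotation set")
    out = {
        "total_snps": total,
        "feature_counts": dict(feature_counts),
        "feature_pct": {k: 100.0 * v / total for k, v in feature_counts.items()},
    }
    if effect_counts is not None:
        out["effect_counts"] = dict(effect_counts)
        out["nonsyn_syn_ratio"] = nonsyn_syn_ratio(
            effect_counts.get("nonsynonymous", 0), effect_counts.get("synonymous", 0))
    return out


def annotation_summary(annotations: pd.DataFrame) -> dict:
    """Summary (feature percentages, Nonsyn/Syn ratio) of an annotation table."""
    if annotations.empty:
        raise ValueError("empty annotation set")
    feat = annotations["feature"].value_counts().to_dict()
    eff = annotations.loc[annotations["coding_effect"] != "none",
                          "coding_effect"].value_counts().to_dict()
    return summary_from_counts(feat, eff)


def chromosome_shares(counts: dict[str, int]) -> dict[str, float]:
    """Per-chromosome SNP share (percent of the genome-wide total)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no SNPs counted")
    return {c: 100.0 * v / total for c, v in counts.items()}
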