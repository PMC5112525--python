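"""Specific inherited-allele tracing.

A *specific allele* in the offspring is a homozygous genotype identical to
at least one donor-side parent's genotype but different from the recurrent
parent's — evidence of donor introgression at that site.  Traced sites are
assigned to genes (gene body or promoter) and checked for concordance with
the reconstructed ancestry mosaic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ancestry import SHARED_SEP, BlockMosaic
from .io import GeneIndex, GenotypeMatrix, HET, MISSING, VariantSite


@dataclass
class AlleleTraceRecord:
    site: VariantSite
    offspring_call: int
    recurrent_call: int
    matching_donors: list[str]
    gene_hits: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, genebody|promoter)


def trace_specific_alleles(gm: GenotypeMatrix, offspring: str, recurrent: str,
                           donors: Sequence[str]) -> list[AlleleTraceRecord]:
    """Find sites where the offspring matches a donor but not the recurrent parent.

    A site qualifies iff offspring, recurrent and at least one donor are all
    homozygous non-missing, offspring differs from recurrent, and offspring
    equals that donor.  All matching donors are recorded.
    """
    donors = list(donors)
    if offspring in donors or recurrent in donors:
        raise ValueError("donors must be disjoint from offspring/recurrent")
    off = gm.calls_for(offspring)
    rec = gm.calls_for(recurrent)
    don = np.stack([gm.calls_for(d) for d in donors])

    hom = lambda x: (x != MISSING) & (x != HET)  # noqa: E731
    base = hom(off) & hom(rec) & (off != rec)
    match = hom(don) & (don == off[None, :])
    qualifies = base & match.any(axis=0)

    idx = np.nonzero(qualifies)[0]
    sites = gm.sites
    records = []
    for j in idx:
        records.append(AlleleTraceRecord(
            site=VariantSite(sites.at[j, "chrom"], int(sites.at[j, "pos"]),
                             sites.at[j, "ref"], sites.at[j, "alt"]),
            offspring_call=int(off[j]),
            recurrent_call=int(rec[j]),
            matching_donors=[d for k, d in enumerate(donors) if match[k, j]],
        ))
    return records


def assign_to_genes(records: list[AlleleTraceRecord], index: GeneIndex,
                    promoter_bp: int = 2000) -> pd.DataFrame:
    """Attach gene hits to traced records and summarise per gene.

    Gene body = within the gene span (inclusive); promoter = within
    ``promoter_bp`` upstream of the TSS (strand-aware), exclusive of any
    gene body hit of the *same* gene.  A SNP may hit multiple genes.
    Returns the gene-level summary (distinct genes with >= 1 traced SNP).
    """
    gene_rows: dict[str, dict] = {}
    for rec in records:
        hits: list[tuple[str, str]] = []
        for g in index.genes_at(rec.site.chrom, rec.site.pos):
            hits.append((g.gene_id, "genebody"))
        body_ids = {gid for gid, _ in hits}
        for g in index.promoter_genes_at(rec.site.chrom, rec.site.pos, promoter_bp):
            if g.gene_id not in body_ids:
                hits.append((g.gene_id, "promoter"))
        rec.gene_hits = hits
        for gid, loc in hits:
            row = gene_rows.setdefault(gid, dict(gene_id=gid, n_snps=0,
                                                 locations=set(), donors=set()))
            row["n_snps"] += 1
            row["locations"].add(loc)
            row["donors"].update(rec.matching_donors)
    summary = pd.DataFrame(
        [dict(gene_id=r["gene_id"], n_snps=r["n_snps"],
              locations=",".join(sorted(r["locations"])),
              donors=",".join(sorted(r["donors"])))
         for r in gene_rows.values()]
    )
    if len(summary):
        summary = summary.sort_values("gene_id").reset_index(drop=True)
    return summary


@dataclass
class ConcordanceResult:
    fraction: float          # NaN when not applicable
    n_concordant: int
    n_in_blocks: int
    n_outside_blocks: int
    per_chrom: dict[str, float]

    @property
    def applicable(self) -> bool:
        return np.isfinite(self.fraction)


def concordance_with_mosaic(records: list[AlleleTraceRecord],
                            mosaic: BlockMosaic) -> ConcordanceResult:
    """Fraction of traced sites lying in a block whose origin matches a donor.

    Sites falling outside any assigned block are excluded from the
    denominator and counted separately.
    """
    n_in = n_conc = n_out = 0
    per_chrom_in: dict[str, int] = {}
    per_chrom_conc: dict[str, int] = {}
    for rec in records:
        origin = mosaic.origin_at(rec.site.chrom, rec.site.pos - 1)
        if origin is None:
            n_out += 1
            continue
        n_in += 1
        per_chrom_in[rec.site.chrom] = per_chrom_in.get(rec.site.chrom, 0) + 1
        if set(origin.split(SHARED_SEP)) & set(rec.matching_donors):
            n_conc += 1
            per_chrom_conc[rec.site.chrom] = per_chrom_conc.get(rec.site.chrom, 0) + 1
    frac = n_conc / n_in if n_in else np.nan
    per_chrom = {c: per_chrom_conc.get(c, 0) / n for c, n in per_chrom_in.items()}
    return ConcordanceResult(frac, n_conc, n_in, n_out, per_chrom)


def records_to_frame(records: list[AlleleTraceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(chrom=r.site.chrom, pos=r.site.pos, ref=r.site.ref, alt=r.site.alt,
              offspring_call=r.offspring_call, recurrent_call=r.recurrent_call,
              donors=",".join(r.matching_donors),
              gene_hits=";".join(f"{g}:{loc}" for g, loc in r.gene_hits))
         for r in records]
    )
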