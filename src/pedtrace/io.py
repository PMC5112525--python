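"""Readers, writers and in-memory containers for variant and gene-model data.

The genotype matrix is the substrate of every diversity and tracing
computation in the package: samples x biallelic SNP sites, with calls coded
as small integers.  Gene models are parsed from GFF3 into a light per-gene
record (one representative transcript each) with an interval index for
point queries.

Coordinate conventions: everything user-facing is 1-based inclusive
(VCF/GFF convention) except BED output, which is 0-based half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

# genotype call codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_HOMOZYGOUS = (HOM_REF, HOM_ALT)


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


class GffFormatError(ValueError):
    """Raised when a GFF3 file cannot be parsed into gene models."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")


class GenotypeMatrix:
    """Samples x sites matrix of genotype calls.

    Parameters
    ----------
    samples
        Ordered sample labels.
    sites
        DataFrame with columns chrom, pos, ref, alt; grouped by chromosome
        and sorted by position within each chromosome, no duplicate
        (chrom, pos).
    calls
        int8 array of shape (n_samples, n_sites) with values in
        {HOM_REF, HET, HOM_ALT, MISSING}.
    """

    def __init__(self, samples: Sequence[str], sites: pd.DataFrame, calls: np.ndarray):
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample labels")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(sites)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(samples)} samples x {len(sites)} sites"
            )
        sites = sites.reset_index(drop=True)
        # grouped chromosomes, sorted positions, unique (chrom, pos)
        chroms = sites["chrom"].to_numpy()
        pos = sites["pos"].to_numpy()
        seen: set[str] = set()
        order: list[str] = []
        prev = None
        for c in chroms:
            if c != prev:
                if c in seen:
                    raise ValueError(f"sites for chromosome {c} are not contiguous")
                seen.add(c)
                order.append(c)
                prev = c
        for c in order:
            p = pos[chroms == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions on {c} not strictly increasing")
        self.samples = samples
        self.sites = sites
        self.calls = calls
        self.chroms: list[str] = order
        self._sample_idx = {s: i for i, s in enumerate(samples)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_idx[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in matrix ({self.samples})") from None

    def calls_for(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites.loc[self.sites["chrom"] == chrom, "pos"].to_numpy()

    def subset(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(list(samples), self.sites.copy(), self.calls[idx])

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites)"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNPs are kept; multiallelic sites and indels are skipped
    and counted in the log.  Missing genotypes (``./.``) become MISSING;
    the phase separator is ignored.
    """
    import pysam

    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no sample columns")

    recs = {"chrom": [], "pos": [], "ref": [], "alt": []}
    calls_cols: list[np.ndarray] = []
    n_multi = n_indel = 0
    bases = {"A", "C", "G", "T"}
    try:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in bases or alt not in bases:
                n_indel += 1
                continue
            col = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    col[i] = int(sum(gt))
            recs["chrom"].append(rec.chrom)
            recs["pos"].append(rec.pos)
            recs["ref"].append(ref)
            recs["alt"].append(alt)
            calls_cols.append(col)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: malformed record: {exc}") from exc
    if n_multi or n_indel:
        log.info(
            "read_vcf(%s): skipped %d multiallelic and %d indel/non-SNP records",
            path, n_multi, n_indel,
        )
    sites = pd.DataFrame(recs)
    calls = (
        np.stack(calls_cols, axis=1)
        if calls_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, sites, calls)


def write_vcf(gm: GenotypeMatrix, path: str,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCFv4.2 with a diploid GT field per sample."""
    code_to_gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    if contig_lengths is None:
        contig_lengths = {
            c: int(gm.positions(c).max()) if len(gm.positions(c)) else 1
            for c in gm.chroms
        }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pedtrace\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        chrom = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        ref = gm.sites["ref"].to_numpy()
        alt = gm.sites["alt"].to_numpy()
        for j in range(gm.n_sites):
            gts = "\t".join(code_to_gt[int(v)] for v in gm.calls[:, j])
            fh.write(f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Gene models / GFF3
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 1-based inclusive


@dataclass
class GeneModel:
    """One gene with a single representative (longest-CDS) transcript."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    coding_ok: bool = True

    @property
    def tss(self) -> int:
        """Transcription start site: gene start on +, gene end on −."""
        return self.start if self.strand == "+" else self.end

    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_promoter(self, pos: int, promoter_bp: int) -> bool:
        """Within promoter_bp upstream of the TSS (strand-aware), outside the gene body."""
        if self.strand == "+":
            return self.tss - promoter_bp <= pos < self.tss
        return self.tss < pos <= self.tss + promoter_bp


class GeneIndex:
    """Interval-indexed collection of gene models supporting point queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
        self._promoter_trees: dict[int, dict[str, IntervalTree]] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((self.genes[iv.data] for iv in tree.at(pos)),
                      key=lambda g: g.gene_id)

    def promoter_genes_at(self, chrom: str, pos: int, promoter_bp: int) -> list[GeneModel]:
        trees = self._promoter_trees.get(promoter_bp)
        if trees is None:
            trees = {}
            for g in self.genes.values():
                if g.strand == "+":
                    lo, hi = g.tss - promoter_bp, g.tss - 1
                else:
                    lo, hi = g.tss + 1, g.tss + promoter_bp
                if hi >= max(lo, 1):
                    trees.setdefault(g.chrom, IntervalTree()).addi(max(lo, 1), hi + 1, g.gene_id)
            self._promoter_trees[promoter_bp] = trees
        tree = trees.get(chrom)
        if tree is None:
            return []
        return sorted((self.genes[iv.data] for iv in tree.at(pos)),
                      key=lambda g: g.gene_id)


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Interval-list subtraction a \\ b (1-based inclusive)."""
    out: list[Interval] = []
    for s, e in a:
        pieces = [(s, e)]
        for bs, be in b:
            nxt: list[Interval] = []
            for ps, pe in pieces:
                if be < ps or bs > pe:
                    nxt.append((ps, pe))
                    continue
                if ps < bs:
                    nxt.append((ps, bs - 1))
                if be < pe:
                    nxt.append((be + 1, pe))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


def read_gff3(path: str) -> GeneIndex:
    """Parse gene/mRNA/exon/CDS features into a :class:`GeneIndex`.

    One representative transcript per gene (longest total CDS).  UTRs are
    derived as exon minus CDS, split 5'/3' by strand.  A CDS whose length is
    not a multiple of 3 flags the gene as non-annotatable for coding effect
    (``coding_ok=False``) rather than failing.
    """
    import gffutils

    try:
        db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:
        raise GffFormatError(f"{path}: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        best_exons: list[Interval] = []
        best_cds: list[Interval] = []
        if transcripts:
            best_len = -1
            for t in sorted(transcripts, key=lambda t: t.id):
                cds = [(c.start, c.end) for c in db.children(t, featuretype="CDS")]
                clen = sum(e - s + 1 for s, e in cds)
                if clen > best_len:
                    best_len = clen
                    best_cds = cds
                    best_exons = [(x.start, x.end) for x in db.children(t, featuretype="exon")]
        else:
            best_cds = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
            best_exons = [(x.start, x.end) for x in db.children(gene, featuretype="exon")]
        exons = _merge_intervals(best_exons) or [(gene.start, gene.end)]
        cds = _merge_intervals(best_cds)
        utr = _subtract(exons, cds) if cds else []
        if gene.strand == "+":
            cds_start = cds[0][0] if cds else None
            utr5 = [iv for iv in utr if cds_start and iv[1] < cds_start]
            utr3 = [iv for iv in utr if cds_start and iv[0] > cds[-1][1]]
        else:
            cds_end = cds[-1][1] if cds else None
            utr5 = [iv for iv in utr if cds_end and iv[0] > cds_end]
            utr3 = [iv for iv in utr if cds_end and iv[1] < cds[0][0]]
        coding_ok = bool(cds) and sum(e - s + 1 for s, e in cds) % 3 == 0
        if cds and not coding_ok:
            log.warning("gene %s: CDS length not divisible by 3; "
                        "coding effects will not be annotated", gene.id)
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end,
            exons=exons, cds=cds, utr5=utr5, utr3=utr3, coding_ok=coding_ok,
        ))
    return GeneIndex(genes)


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS rows, one transcript per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            mrna_id = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\tpedtrace\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tpedtrace\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mrna_id};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tpedtrace\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"Parent={mrna_id}\n")
            for k, (s, e) in enumerate(g.cds):
                fh.write(f"{g.chrom}\tpedtrace\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                         f"ID={mrna_id}.cds;Parent={mrna_id}\n")


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def fetch_seq(fasta, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end] (1-based inclusive) from a pyfaidx Fasta or a dict of strings."""
    if end < start:
        return ""
    seg = fasta[chrom][start - 1:end]
    return (seg.seq if hasattr(seg, "seq") else str(seg)).upper()


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
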