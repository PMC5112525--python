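"""Promoter extraction, PWM scanning and TF–target network construction.

Promoters are the 3 kb upstream of the TSS (strand-aware, truncated at
chromosome ends).  JASPAR-style position-frequency matrices are converted
to log-odds with a pseudocount and scanned over both strands; hits at or
above a configurable fraction of the maximum attainable score become
TF-family → target-gene network edges.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, fetch_seq

log = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Position weight matrix built from a 4 x L count matrix (rows A,C,G,T)."""

    motif_id: str
    tf_family: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("counts must be 4 x L with L >= 4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """log2 of pseudocounted column frequencies over the background."""
        col_tot = self.counts.sum(axis=0) + 4 * self.pseudocount
        freq = (self.counts + self.pseudocount) / col_tot
        return np.log2(freq / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def read_jaspar(path: str, families: dict[str, str] | None = None) -> list[Pwm]:
    """Read PFMs from a JASPAR plain-text file.

    The motif *name* field is used as the TF family unless an explicit
    motif_id -> family mapping is supplied.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        fam = (families or {}).get(m.matrix_id) or m.name or m.matrix_id
        out.append(Pwm(m.matrix_id, fam, counts))
    return out


def write_jaspar(pwms: list[Pwm], path: str) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.tf_family}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{int(v):6d}" for v in p.counts[i])
                fh.write(f"{b} [{row} ]\n")


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

@dataclass
class Promoter:
    gene_id: str
    seq: str  # 5'->3', ending immediately upstream of the TSS
    requested_bp: int
    truncated: bool

    @property
    def length(self) -> int:
        return len(self.seq)


def extract_promoter(gene: GeneModel, fasta, length: int = 3000) -> Promoter:
    """Strand-aware promoter: [TSS−L, TSS) on +, (TSS, TSS+L] reverse-complemented on −."""
    chrom_len = len(fasta[gene.chrom])
    if gene.strand == "+":
        start = max(1, gene.tss - length)
        end = gene.tss - 1
        seq = fetch_seq(fasta, gene.chrom, start, end) if end >= start else ""
    else:
        start = gene.tss + 1
        end = min(chrom_len, gene.tss + length)
        seq = revcomp(fetch_seq(fasta, gene.chrom, start, end)) if end >= start else ""
    truncated = len(seq) < length
    if len(seq) == 0:
        log.warning("gene %s: TSS at chromosome edge, zero-length promoter",
                    gene.gene_id)
    return Promoter(gene.gene_id, seq, length, truncated)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i


def scan_pwm(seq: str, pwm: Pwm,
             threshold_fraction: float = 0.8) -> list[tuple[int, str, float]]:
    """All hits (offset, strand, score) with score >= threshold_fraction * max.

    Both strands are scanned; windows containing N (or any non-ACGT
    character) are skipped; overlapping hits are all reported.  The offset
    is the 0-based window start in ``seq`` regardless of strand.
    """
    L = pwm.length
    if len(seq) < L:
        return []
    enc = _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    wins = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (wins >= 0).all(axis=1)
    lo = pwm.log_odds()
    lo_rc = lo[::-1, ::-1]  # reverse-complement matrix
    cols = np.arange(L)
    safe = np.where(wins >= 0, wins, 0)
    fwd = lo[safe, cols].sum(axis=1)
    rev = lo_rc[safe, cols].sum(axis=1)
    thr = threshold_fraction * pwm.max_score()
    hits = []
    for off in np.nonzero(valid)[0]:
        if fwd[off] >= thr:
            hits.append((int(off), "+", float(fwd[off])))
        if rev[off] >= thr:
            hits.append((int(off), "-", float(rev[off])))
    return hits


@dataclass
class NetworkEdge:
    tf_family: str
    motif_id: str
    target_gene: str
    hit_position: int  # offset relative to TSS, negative upstream
    strand: str
    score: float


def build_network(promoters: dict[str, Promoter], pwms: list[Pwm],
                  threshold_fraction: float = 0.8
                  ) -> tuple[list[NetworkEdge], pd.DataFrame]:
    """Scan every promoter with every PWM; return edges and a per-family summary.

    The summary counts distinct target genes with at least one hit per TF
    family.  Hit positions are reported relative to the TSS (negative,
    upstream), computed from the promoter's actual length.
    """
    edges: list[NetworkEdge] = []
    for gene_id in sorted(promoters):
        prom = promoters[gene_id]
        for pwm in pwms:
            for off, strand, score in scan_pwm(prom.seq, pwm, threshold_fraction):
                edges.append(NetworkEdge(pwm.tf_family, pwm.motif_id, gene_id,
                                         off - prom.length, strand, score))
    by_family: dict[str, set[str]] = {}
    for e in edges:
        by_family.setdefault(e.tf_family, set()).add(e.target_gene)
    summary = pd.DataFrame(
        [dict(tf_family=f, n_target_genes=len(g)) for f, g in sorted(by_family.items())]
    )
    return edges, summary


def edges_to_frame(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in edges],
                        columns=["tf_family", "motif_id", "target_gene",
                                 "hit_position", "strand", "score"])


def edges_to_sif(edges: list[NetworkEdge], path: str) -> None:
    """SIF-style TSV: tf_family <tab> binds <tab> target_gene (unique rows)."""
    seen = sorted({(e.tf_family, e.target_gene) for e in edges})
    with open(path, "w") as fh:
        for fam, gene in seen:
            fh.write(f"{fam}\tbinds\t{gene}\n")
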