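"""Scoring reconstructions against simulator truth.

The offspring of a backcross program is diploid: in regions where its two
homologous chromosome copies descend from different founders, a
genotype-based caller cannot (and need not) separate them.  Agreement is
therefore scored per base pair as: the called block origin matches the
truth origin of *either* homolog at that position.
"""
from __future__ import annotations

import numpy as np

from .ancestry import SHARED_SEP, BlockMosaic
from .simulate import ChromSpec, Segment, TruthMosaic
from .tracing import AlleleTraceRecord


def _origin_at(segs: list[Segment], pos: int) -> str | None:
    for s, e, o in segs:
        if s <= pos < e:
            return o
    return None


def truth_agreement(mosaic: BlockMosaic, truth: TruthMosaic) -> float:
    """Fraction of assigned genome length whose called origin matches truth.

    Positions are evaluated on the union of block and truth breakpoints,
    so the computation is exact, not sampled.
    """
    matched = assigned = 0
    for chrom in mosaic.chrom_lengths:
        hap0, hap1 = truth.segments[chrom]
        cuts = sorted({b for b in
                       [s for seg in hap0 for s in seg[:2]]
                       + [s for seg in hap1 for s in seg[:2]]
                       + [x for blk in mosaic.blocks if blk.chrom == chrom
                          for x in (blk.start, blk.end)]})
        for lo, hi in zip(cuts, cuts[1:]):
            called = mosaic.origin_at(chrom, lo)
            if called is None:
                continue
            assigned += hi - lo
            origins = {_origin_at(hap0, lo), _origin_at(hap1, lo)}
            # shared two-origin calls ("A|B") match only when every member
            # is present among the homolog truth origins
            if set(called.split(SHARED_SEP)) <= origins:
                matched += hi - lo
    return matched / assigned if assigned else np.nan


def truth_contributions(truth: TruthMosaic, genome: list[ChromSpec]) -> dict[str, float]:
    """Founder fractions from truth, averaged over both homologs."""
    return truth.diploid_fractions(genome)


def traced_truth_concordance(records: list[AlleleTraceRecord],
                             truth: TruthMosaic) -> float:
    """Fraction of traced sites inside a truth segment of a matching donor.

    A site is concordant when either homolog's truth origin at that
    position is among the record's matching donors.
    """
    if not records:
        return np.nan
    n_conc = 0
    for rec in records:
        origins = set(truth.origins_at(rec.site.chrom, rec.site.pos - 1))
        if origins & set(rec.matching_donors):
            n_conc += 1
    return n_conc / len(records)
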