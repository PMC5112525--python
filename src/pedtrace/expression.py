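"""Differential-expression filtering and integration with traced alleles.

This module *filters* expression tables, it does not test them: FPKM
values and per-contrast p-values are consumed as given (the upstream
quantification/testing pipeline is out of scope).  A gene is a DEG for a
contrast when its pseudocounted fold change strictly exceeds the threshold
and its p-value is strictly below the cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WELL_WATERED = "well_watered"
DROUGHT = "drought"
TIME_POINTS = ("T1", "T2", "T3")

Side = tuple[str, str]  # (condition, time_point)


def contrast_label(numerator: Side, denominator: Side) -> str:
    return f"{numerator[0]}_{numerator[1]}_vs_{denominator[0]}_{denominator[1]}"


#: the three stated contrasts whose union gives "total DEGs" per variety:
#: drought vs well-watered at T1, then successive drought time points.
DEFAULT_CONTRASTS: list[tuple[Side, Side]] = [
    ((DROUGHT, "T1"), (WELL_WATERED, "T1")),
    ((DROUGHT, "T2"), (DROUGHT, "T1")),
    ((DROUGHT, "T3"), (DROUGHT, "T2")),
]


@dataclass
class DegSet:
    variety: str
    contrast: str
    up: set[str]
    down: set[str]

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")

    @property
    def all(self) -> set[str]:
        return self.up | self.down


def _fpkm_series(expr: pd.DataFrame, variety: str, side: Side) -> pd.Series:
    cond, time = side
    sel = expr[(expr["variety"] == variety) & (expr["condition"] == cond)
               & (expr["time_point"] == time)]
    if sel.empty:
        raise ValueError(f"no expression records for {variety}/{cond}/{time}")
    return sel.set_index("gene_id")["fpkm"]


def call_degs(expr: pd.DataFrame, pvalues: pd.DataFrame, variety: str,
              numerator: Side, denominator: Side, fc_threshold: float = 2.0,
              p_threshold: float = 0.05, pseudocount: float = 0.1) -> DegSet:
    """DEG call for one contrast: fold change > fc_threshold and p < p_threshold.

    ``expr`` is long-form (gene_id, variety, condition, time_point, fpkm);
    ``pvalues`` is (gene_id, variety, contrast, p_value) with the contrast
    labelled by :func:`contrast_label`.  Missing p-values are an error.
    """
    label = contrast_label(numerator, denominator)
    a = _fpkm_series(expr, variety, numerator)
    b = _fpkm_series(expr, variety, denominator)
    genes = a.index.intersection(b.index)
    psel = pvalues[(pvalues["variety"] == variety) & (pvalues["contrast"] == label)]
    pmap = psel.set_index("gene_id")["p_value"]
    missing = genes.difference(pmap.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} genes lack a p-value for contrast {label} "
            f"(e.g. {sorted(missing)[:3]}); this module filters, it does not test")
    fc = (a.loc[genes] + pseudocount) / (b.loc[genes] + pseudocount)
    p = pmap.loc[genes]
    sig = p < p_threshold
    up = set(genes[(fc > fc_threshold) & sig])
    down = set(genes[(1.0 / fc > fc_threshold) & sig])
    return DegSet(variety, label, up, down)


def total_degs(deg_sets: Sequence[DegSet]) -> DegSet:
    """Union over contrasts (per variety): the 'total DEGs' of a variety.

    A gene up in one contrast and down in another is kept on both lists'
    union-before-dedup; to preserve the up/down split it is assigned to the
    side of its first occurrence in contrast order.
    """
    if not deg_sets:
        raise ValueError("no DEG sets given")
    variety = deg_sets[0].variety
    up: set[str] = set()
    down: set[str] = set()
    for ds in deg_sets:
        if ds.variety != variety:
            raise ValueError("total_degs mixes varieties")
        up |= ds.up - down
        down |= ds.down - up
    return DegSet(variety, "total", up, down)


def common_deg_total(a: DegSet, b: DegSet) -> int:
    """Common DEGs between two varieties: |up∩up| + |down∩down|."""
    return len(a.up & b.up) + len(a.down & b.down)


def venn_counts(named_sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Exclusive-region counts of a 2- or 3-way Venn diagram.

    Keys are '+'-joined sorted member names; counts are of genes belonging
    to exactly that combination of sets.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(*(named_sets[n] for n in names if n not in combo), set())
            out["+".join(combo)] = len(inside - outside)
    return out


def log2_stress_ratio(expr: pd.DataFrame, gene: str, variety: str, time: str,
                      pseudocount: float = 0.1) -> float:
    """log2((FPKM drought + pc) / (FPKM well-watered + pc)) at one time point."""
    d = _fpkm_series(expr, variety, (DROUGHT, time))
    w = _fpkm_series(expr, variety, (WELL_WATERED, time))
    return float(np.log2((d.loc[gene] + pseudocount) / (w.loc[gene] + pseudocount)))


def intersect_with_traced_genes(deg_sets: Sequence[DegSet],
                                traced_summary: pd.DataFrame) -> pd.DataFrame:
    """Genes that are both DEGs and carry specific inherited alleles.

    Returns one row per gene with the contrast(s) and direction in which it
    is differentially expressed and the donor/location provenance from the
    traced-gene summary.
    """
    if traced_summary.empty:
        return pd.DataFrame(columns=["gene_id", "contrasts", "donors", "locations"])
    traced = traced_summary.set_index("gene_id")
    rows: dict[str, dict] = {}
    for ds in deg_sets:
        for direction, genes in (("up", ds.up), ("down", ds.down)):
            for g in genes & set(traced.index):
                row = rows.setdefault(g, dict(gene_id=g, contrasts=set(),
                                              donors=traced.at[g, "donors"],
                                              locations=traced.at[g, "locations"]))
                row["contrasts"].add(f"{ds.contrast}:{direction}")
    out = pd.DataFrame(
        [dict(gene_id=r["gene_id"], contrasts=";".join(sorted(r["contrasts"])),
              donors=r["donors"], locations=r["locations"])
         for r in rows.values()]
    )
    if len(out):
        out = out.sort_values("gene_id").reset_index(drop=True)
    return out
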