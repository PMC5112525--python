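"""Pairwise genetic similarity (1 − π) between lines.

π here is the Nei–Li-style genotype diversity: the proportion of compared
SNP sites at which two lines carry different genotypes.  For inbred lines
the genotype-level and haplotype-level readings coincide at homozygous
sites; heterozygous sites are handled by an explicit policy.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, HET, MISSING

log = logging.getLogger(__name__)

HET_POLICIES = ("exclude", "half-difference")


def pair_diff_valid(a: np.ndarray, b: np.ndarray,
                    het_policy: str = "exclude") -> tuple[np.ndarray, np.ndarray]:
    """Per-site difference weight and validity mask for two call vectors.

    ``exclude``: only sites where both calls are homozygous and non-missing
    are compared; the difference weight is 0/1.
    ``half-difference``: all non-missing pairs compared; a het-vs-hom pair
    counts half a difference (expected allele-sharing distance).
    """
    if het_policy not in HET_POLICIES:
        raise ValueError(f"unknown het_policy {het_policy!r}")
    if het_policy == "exclude":
        valid = (a != MISSING) & (b != MISSING) & (a != HET) & (b != HET)
        diff = ((a != b) & valid).astype(float)
    else:
        valid = (a != MISSING) & (b != MISSING)
        diff = np.where(valid, np.abs(a.astype(float) - b.astype(float)) / 2.0, 0.0)
    return diff, valid


@dataclass
class SimilarityMatrix:
    samples: list[str]
    values: np.ndarray      # similarity = 1 - pi; NaN where undefined
    n_compared: np.ndarray  # per-pair count of sites used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f",
                               index_label="sample")


def pairwise_similarity(gm: GenotypeMatrix, het_policy: str = "exclude",
                        min_sites: int = 100) -> SimilarityMatrix:
    """Similarity index 1 − π for every pair of samples.

    π = (# sites with differing genotypes) / (# sites where both calls are
    usable under het_policy), pooled genome-wide.  Pairs with fewer than
    ``min_sites`` usable sites are reported as undefined (NaN).
    """
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    vals = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    np.fill_diagonal(vals, 1.0)
    np.fill_diagonal(counts, gm.n_sites)
    for i in range(n):
        for j in range(i + 1, n):
            diff, valid = pair_diff_valid(gm.calls[i], gm.calls[j], het_policy)
            nv = int(valid.sum())
            counts[i, j] = counts[j, i] = nv
            if nv == 0:
                warnings.warn(f"no comparable sites for pair "
                              f"({gm.samples[i]}, {gm.samples[j]}); similarity undefined")
                continue
            pi = float(diff.sum()) / nv
            if nv < min_sites:
                log.warning("pair (%s, %s): only %d comparable sites "
                            "(< min_sites=%d); similarity flagged undefined",
                            gm.samples[i], gm.samples[j], nv, min_sites)
                continue
            vals[i, j] = vals[j, i] = 1.0 - pi
    return SimilarityMatrix(list(gm.samples), vals, counts)
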