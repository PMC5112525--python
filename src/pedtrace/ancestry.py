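"""Haplotype-block ancestry reconstruction from window diversity statistics.

The core statistic: in sliding windows along the genome, Dpair is the
genotype diversity between a descendant and one candidate ancestor and
Darv the average diversity over all unordered sample pairs in the matrix.
The *diversity-decreased level* (Darv − Dpair)/Darv approaches 1 inside
genomic blocks the descendant inherited from that ancestor and stays low
elsewhere.  Per-ancestor thresholds are fitted from the bimodal
distribution of the decrease values (two-component Gaussian mixture);
windows are assigned to the ancestor passing its threshold with maximal
decrease, uncertain stretches are apportioned between their flanking
blocks, and per-ancestor genome contribution fractions are reported.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .io import GenotypeMatrix
from .similarity import pair_diff_valid

log = logging.getLogger(__name__)

UNCERTAIN = "uncertain"


class InsufficientWindowsError(ValueError):
    """Too few informative windows to fit a threshold."""


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------

@dataclass
class WindowGrid:
    """Sliding windows (0-based half-open) over a genome."""

    windows: list[tuple[str, int, int]]
    window_bp: int
    step_bp: int
    min_snps: int
    chrom_lengths: dict[str, int]


def make_window_grid(chrom_lengths: Mapping[str, int], window_bp: int = 100_000,
                     step_bp: int = 10_000, min_snps: int = 10) -> WindowGrid:
    if window_bp <= 0 or step_bp <= 0 or min_snps < 1:
        raise ValueError("window_bp, step_bp must be positive; min_snps >= 1")
    wins = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            wins.append((chrom, start, min(start + window_bp, length)))
            start += step_bp
    return WindowGrid(wins, window_bp, step_bp, min_snps, dict(chrom_lengths))


# ---------------------------------------------------------------------------
# window diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityProfile:
    """Per-window, per-candidate-ancestor diversity statistics.

    ``table`` columns: chrom, start, end, ancestor, d_pair, d_arv, decrease,
    n_snps, informative.  A window is informative for an ancestor when the
    descendant–ancestor pair has at least ``grid.min_snps`` comparable
    sites and Darv > 0.
    """

    descendant: str
    ancestors: list[str]
    grid: WindowGrid
    table: pd.DataFrame

    def decreases(self, ancestor: str) -> np.ndarray:
        t = self.table
        sel = t[(t["ancestor"] == ancestor) & t["informative"]]
        return sel["decrease"].to_numpy()


def window_diversity(gm: GenotypeMatrix, grid: WindowGrid, descendant: str,
                     ancestors: Sequence[str],
                     het_policy: str = "exclude") -> DiversityProfile:
    """Compute Dpair, Darv and the diversity-decreased level per window.

    Dpair uses the same site-counting rules as the similarity module;
    Darv is the mean of the pairwise diversities over *all* unordered
    sample pairs present in ``gm`` (restrict the matrix first to control
    which samples enter the average).
    """
    d_idx = gm.sample_index(descendant)
    for a in ancestors:
        gm.sample_index(a)
    n = gm.n_samples
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    anc_pair_idx = {a: pairs.index(tuple(sorted((d_idx, gm.sample_index(a)))))
                    for a in ancestors}

    rows: list[dict] = []
    for chrom in {c for c, _, _ in grid.windows}:
        mask = gm.chrom_mask(chrom)
        pos = gm.sites.loc[mask, "pos"].to_numpy()
        cdiff = np.zeros((len(pairs), len(pos) + 1))
        cvalid = np.zeros((len(pairs), len(pos) + 1))
        for k, (i, j) in enumerate(pairs):
            diff, valid = pair_diff_valid(gm.calls[i][mask], gm.calls[j][mask],
                                          het_policy)
            cdiff[k, 1:] = np.cumsum(diff)
            cvalid[k, 1:] = np.cumsum(valid)
        for (wc, s, e) in grid.windows:
            if wc != chrom:
                continue
            lo = np.searchsorted(pos, s + 1, side="left")
            hi = np.searchsorted(pos, e, side="right")
            dsum = cdiff[:, hi] - cdiff[:, lo]
            vsum = cvalid[:, hi] - cvalid[:, lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                pis = np.where(vsum > 0, dsum / np.maximum(vsum, 1), np.nan)
            defined = vsum > 0
            d_arv = float(np.mean(pis[defined])) if defined.any() else np.nan
            for a in ancestors:
                k = anc_pair_idx[a]
                n_snps = int(vsum[k])
                d_pair = float(pis[k]) if defined[k] else np.nan
                informative = (n_snps >= grid.min_snps and np.isfinite(d_arv)
                               and d_arv > 0 and np.isfinite(d_pair))
                decrease = (d_arv - d_pair) / d_arv if informative else np.nan
                rows.append(dict(chrom=chrom, start=s, end=e, ancestor=a,
                                 d_pair=d_pair, d_arv=d_arv, decrease=decrease,
                                 n_snps=n_snps, informative=informative))
    table = pd.DataFrame(rows).sort_values(["chrom", "start", "ancestor"],
                                           kind="stable").reset_index(drop=True)
    return DiversityProfile(descendant, list(ancestors), grid, table)


# ---------------------------------------------------------------------------
# bimodal thresholding
# ---------------------------------------------------------------------------

@dataclass
class ThresholdFit:
    threshold: float
    unimodal: bool
    means: tuple[float, float] | None = None
    stds: tuple[float, float] | None = None
    weights: tuple[float, float] | None = None
    n_values: int = 0


def bimodal_threshold(values: np.ndarray, min_windows: int = 50,
                      delta: float = 0.1, min_weight: float = 0.05,
                      fallback: float = 0.5, seed: int = 0) -> ThresholdFit:
    """Fit a 2-component Gaussian mixture and return the decision boundary.

    When the fitted components are not separable (means closer than
    ``delta`` or one weight below ``min_weight``), the distribution is
    flagged unimodal and a fixed fallback threshold is used.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_windows:
        raise InsufficientWindowsError(
            f"{len(values)} informative windows < required {min_windows}")
    if np.ptp(values) == 0:
        log.info("all decrease values identical; using fallback threshold %.3f", fallback)
        return ThresholdFit(fallback, True, n_values=len(values))

    # reg_covar keeps a point-mass mode (e.g. decrease exactly 1 inside
    # every inherited block) from collapsing the decision boundary onto it
    gmm = GaussianMixture(n_components=2, covariance_type="full",
                          init_params="k-means++", n_init=1,
                          random_state=seed, reg_covar=1e-3)
    gmm.fit(values.reshape(-1, 1))
    order = np.argsort(gmm.means_.ravel())
    m = gmm.means_.ravel()[order]
    v = gmm.covariances_.ravel()[order]
    w = gmm.weights_.ravel()[order]
    fit = ThresholdFit(np.nan, False, (float(m[0]), float(m[1])),
                       (float(np.sqrt(v[0])), float(np.sqrt(v[1]))),
                       (float(w[0]), float(w[1])), len(values))
    if (m[1] - m[0]) < delta or w.min() < min_weight:
        log.info("decrease distribution effectively unimodal "
                 "(means %.3f/%.3f, weights %.2f/%.2f); fallback threshold %.3f",
                 m[0], m[1], w[0], w[1], fallback)
        fit.unimodal = True
        fit.threshold = fallback
        return fit

    def _log_diff(x: float) -> float:
        lo0 = np.log(w[0]) - 0.5 * np.log(2 * np.pi * v[0]) - (x - m[0]) ** 2 / (2 * v[0])
        lo1 = np.log(w[1]) - 0.5 * np.log(2 * np.pi * v[1]) - (x - m[1]) ** 2 / (2 * v[1])
        return lo0 - lo1

    if _log_diff(m[0]) > 0 > _log_diff(m[1]):
        fit.threshold = float(brentq(_log_diff, m[0], m[1]))
    else:  # pathological overlap: fall back to the midpoint of the means
        fit.threshold = float(0.5 * (m[0] + m[1]))
    return fit


def fit_thresholds(profile: DiversityProfile, min_windows: int = 50,
                   delta: float = 0.1, min_weight: float = 0.05,
                   fallback: float = 0.5, seed: int = 0) -> dict[str, ThresholdFit]:
    """Per-ancestor threshold fits from the profile's decrease distributions."""
    return {a: bimodal_threshold(profile.decreases(a), min_windows=min_windows,
                                 delta=delta, min_weight=min_weight,
                                 fallback=fallback, seed=seed)
            for a in profile.ancestors}


# ---------------------------------------------------------------------------
# block calling
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    chrom: str
    start: int  # 0-based half-open
    end: int
    origin: str
    mean_decrease: float = np.nan
    n_windows: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BlockMosaic:
    descendant: str
    blocks: list[HaplotypeBlock]
    chrom_lengths: dict[str, int]
    unassigned_chroms: list[str] = field(default_factory=list)

    def origin_at(self, chrom: str, pos_bp: int) -> str | None:
        for b in self.blocks:
            if b.chrom == chrom and b.start <= pos_bp < b.end:
                return b.origin
        return None

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for b in self.blocks:
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.origin}\t"
                         f"{b.mean_decrease:.4f}\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.blocks])


SHARED_SEP = "|"


def _assign_windows(profile: DiversityProfile, thresholds: Mapping[str, float],
                    tie_margin: float) -> pd.DataFrame:
    """Per-window origin label.

    Best passing ancestor wins; when the top two passing ancestors lie
    within the tie margin the window is labelled with the *pair*
    ("A|B", sorted) — in a diploid descendant such shared windows arise in
    residual heterozygous regions where each homolog genuinely descends
    from a different ancestor, or where two ancestors are locally
    identical by state.  Windows where no ancestor passes are 'uncertain'.
    """
    t = profile.table
    rows = []
    for (chrom, s, e), grp in t.groupby(["chrom", "start", "end"], sort=False):
        passing = []
        for _, r in grp.iterrows():
            if r["informative"] and r["decrease"] > thresholds[r["ancestor"]]:
                passing.append((r["decrease"], r["ancestor"]))
        if not passing:
            label = UNCERTAIN
        else:
            passing.sort(reverse=True)
            if len(passing) > 1 and passing[0][0] - passing[1][0] < tie_margin:
                label = SHARED_SEP.join(sorted((passing[0][1], passing[1][1])))
            else:
                label = passing[0][1]
        rows.append(dict(chrom=chrom, start=s, end=e, label=label))
    return pd.DataFrame(rows)


def call_blocks(profile: DiversityProfile, thresholds: Mapping[str, "ThresholdFit | float"],
                tie_margin: float = 0.05) -> BlockMosaic:
    """Assign windows to ancestors and merge them into haplotype blocks.

    Overlapping windows are resolved on the step-sized tiling by plurality
    vote of the windows covering each tile.  Uncertain runs strictly
    between two determinate blocks are split at their midpoint and
    apportioned half to each; uncertain runs touching a chromosome end are
    attached to their single determinate neighbour.  A chromosome that is
    entirely uncertain is reported unassigned.
    """
    thr = {a: (v.threshold if isinstance(v, ThresholdFit) else float(v))
           for a, v in thresholds.items()}
    for a in profile.ancestors:
        if a not in thr:
            raise ValueError(f"no threshold supplied for ancestor {a}")
    win_assign = _assign_windows(profile, thr, tie_margin)
    step = profile.grid.step_bp
    blocks: list[HaplotypeBlock] = []
    unassigned: list[str] = []

    for chrom, length in profile.grid.chrom_lengths.items():
        n_tiles = int(np.ceil(length / step))
        votes: list[dict[str, int]] = [dict() for _ in range(n_tiles)]
        sub = win_assign[win_assign["chrom"] == chrom]
        for _, r in sub.iterrows():
            t0 = r["start"] // step
            t1 = int(np.ceil(r["end"] / step))
            for t in range(t0, min(t1, n_tiles)):
                votes[t][r["label"]] = votes[t].get(r["label"], 0) + 1
        labels = []
        for t in range(n_tiles):
            if not votes[t]:
                labels.append(UNCERTAIN)
                continue
            best = max(votes[t].values())
            top = sorted(lab for lab, c in votes[t].items() if c == best)
            labels.append(top[0] if len(top) == 1 else UNCERTAIN)
        # merge tiles into runs
        runs: list[list] = []  # [start_bp, end_bp, label]
        for t, lab in enumerate(labels):
            s, e = t * step, min((t + 1) * step, length)
            if runs and runs[-1][2] == lab:
                runs[-1][1] = e
            else:
                runs.append([s, e, lab])
        det = [r for r in runs if r[2] != UNCERTAIN]
        if not det:
            warnings.warn(f"chromosome {chrom} entirely uncertain; left unassigned")
            unassigned.append(chrom)
            continue
        # apportion uncertain runs into neighbours
        resolved: list[list] = []
        for k, run in enumerate(runs):
            if run[2] != UNCERTAIN:
                resolved.append(list(run))
                continue
            prev_lab = resolved[-1][2] if resolved else None
            next_lab = next((r[2] for r in runs[k + 1:] if r[2] != UNCERTAIN), None)
            if prev_lab is None and next_lab is None:
                continue  # unreachable: det is non-empty
            if prev_lab is None:
                resolved.append([run[0], run[1], next_lab])
            elif next_lab is None:
                resolved[-1][1] = run[1]
            else:
                mid = (run[0] + run[1]) // 2
                resolved[-1][1] = mid
                resolved.append([mid, run[1], next_lab])
        # merge adjacent same-origin runs into blocks
        merged: list[list] = []
        for run in resolved:
            if merged and merged[-1][2] == run[2] and merged[-1][1] == run[0]:
                merged[-1][1] = run[1]
            else:
                merged.append(list(run))
        tab = profile.table
        for s, e, lab in merged:
            sel = tab[(tab["chrom"] == chrom)
                      & tab["ancestor"].isin(lab.split(SHARED_SEP))
                      & tab["informative"]]
            centers = (sel["start"] + sel["end"]) / 2
            inside = sel[(centers >= s) & (centers < e)]
            blocks.append(HaplotypeBlock(
                chrom, int(s), int(e), lab,
                mean_decrease=float(inside["decrease"].mean()) if len(inside) else np.nan,
                n_windows=int(len(inside))))
    return BlockMosaic(profile.descendant, blocks, dict(profile.grid.chrom_lengths),
                       unassigned)


# ---------------------------------------------------------------------------
# contributions
# ---------------------------------------------------------------------------

@dataclass
class ContributionReport:
    descendant: str
    fractions: dict[str, float]  # over assigned genome length
    assigned_bp: int
    unassigned_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ancestor": list(self.fractions),
             "fraction": list(self.fractions.values())})


def contribution_fractions(mosaic: BlockMosaic) -> ContributionReport:
    """Per-ancestor fraction of the assigned genome length.

    Shared two-origin blocks ("A|B") contribute half their length to each
    member.  Fractions are over assigned length only; unassigned length
    (entirely uncertain chromosomes) is disclosed separately.
    """
    per_origin: dict[str, float] = {}
    for b in mosaic.blocks:
        members = b.origin.split(SHARED_SEP)
        for m in members:
            per_origin[m] = per_origin.get(m, 0.0) + b.length / len(members)
    assigned = int(round(sum(per_origin.values())))
    if assigned == 0:
        raise ValueError(f"no assigned genome length for {mosaic.descendant}")
    total = sum(mosaic.chrom_lengths.values())
    fractions = {o: v / assigned for o, v in sorted(per_origin.items())}
    return ContributionReport(mosaic.descendant, fractions, assigned, total - assigned)
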