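"""Backcross-pedigree simulator with exact ancestry truth.

Models an inbred-line breeding program: fully homozygous founders, crosses
and selfing generations, meiosis under the Haldane model (crossover count
Poisson in the genetic length, positions uniform, no interference).  Every
gamete's founder-of-origin mosaic is tracked exactly, so each simulated
line carries a per-homolog truth mosaic against which ancestry
reconstruction and allele tracing can be scored.

The default pedigree mirrors a three-founder program: two upland donors
crossed and selfed into a donor line, then backcrossed into a recurrent
elite parent and selfed — the structure used to breed the drought-resistant
rice maintainer lines this package was designed around.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

log = logging.getLogger(__name__)

Segment = tuple[int, int, str]  # (start_bp, end_bp, founder) 0-based half-open


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PedigreeOrderError(ValueError):
    """A cross references a line before both its parents exist."""


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length_bp: int
    morgans: float

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ConfigError(f"chromosome {self.name}: length must be positive")
        if self.morgans < 0:
            raise ConfigError(f"chromosome {self.name}: genetic length must be >= 0")


@dataclass(frozen=True)
class Cross:
    """mother x father -> child, followed by n_selfing selfing generations."""

    mother: str
    father: str
    child: str
    n_selfing: int = 0


@dataclass
class PedigreeSpec:
    """Full description of a simulated breeding program."""

    nodes: list[str]
    edges: list[Cross]
    genome: list[ChromSpec]
    snp_density: float = 1e-3
    polymorphism_rate: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.genome:
            raise ConfigError("genome must contain at least one chromosome")
        if self.snp_density <= 0:
            raise ConfigError("snp_density must be positive")
        if not 0 <= self.polymorphism_rate <= 0.5:
            raise ConfigError("polymorphism_rate must lie in [0, 0.5] "
                              "(pairwise divergence of binary alleles)")
        children = [e.child for e in self.edges]
        if len(set(children)) != len(children):
            raise ConfigError("a line may be produced by only one cross")
        known = set(self.founders)
        for e in self.edges:
            if e.mother not in known or e.father not in known:
                raise PedigreeOrderError(
                    f"cross producing {e.child}: parent(s) not yet defined "
                    f"({e.mother}, {e.father})")
            if e.child in known:
                raise ConfigError(f"line {e.child} defined twice")
            known.add(e.child)

    @property
    def founders(self) -> list[str]:
        children = {e.child for e in self.edges}
        return [n for n in self.nodes if n not in children]


@dataclass(frozen=True)
class FounderHaplotype:
    """Homozygous founder haplotype on one chromosome (alleles coded 0/1)."""

    founder_id: str
    chrom: str
    positions: np.ndarray
    alleles: np.ndarray

    def __post_init__(self):
        if len(self.positions) != len(self.alleles):
            raise ValueError("positions and alleles lengths differ")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class TruthMosaic:
    """Per-homolog founder-of-origin segments for one line.

    ``segments[chrom]`` is a pair of segment lists (one per homologous
    chromosome copy); each list tiles [0, length_bp) with half-open
    (start, end, founder) intervals.
    """

    line_id: str
    segments: dict[str, tuple[list[Segment], list[Segment]]]

    def origins_at(self, chrom: str, pos_bp: int) -> tuple[str, str]:
        out = []
        for hap in self.segments[chrom]:
            for s, e, o in hap:
                if s <= pos_bp < e:
                    out.append(o)
                    break
        return tuple(out)  # type: ignore[return-value]

    def diploid_fractions(self, genome: Sequence[ChromSpec]) -> dict[str, float]:
        """Founder genome fractions averaged over both homologs."""
        total = 2 * sum(c.length_bp for c in genome)
        acc: dict[str, float] = {}
        for cspec in genome:
            for hap in self.segments[cspec.name]:
                for s, e, o in hap:
                    acc[o] = acc.get(o, 0.0) + (e - s)
        return {o: v / total for o, v in acc.items()}


@dataclass
class Individual:
    """Internal diploid state: per chromosome, two allele arrays + origin mosaics."""

    line_id: str
    haps: dict[str, tuple[np.ndarray, np.ndarray]]
    origins: dict[str, tuple[list[Segment], list[Segment]]]

    def heterozygosity(self) -> float:
        n = het = 0
        for h0, h1 in self.haps.values():
            n += len(h0)
            het += int(np.sum(h0 != h1))
        return het / n if n else 0.0


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def _allele_one_prob(polymorphism_rate: float) -> float:
    # solve 2 p (1-p) = rate so pairwise founder divergence equals the rate
    return 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * polymorphism_rate))


def simulate_founders(spec: PedigreeSpec) -> list[FounderHaplotype]:
    """Draw shared SNP positions and independent homozygous founder haplotypes.

    Site counts per chromosome are Poisson(snp_density * length); positions
    uniform.  Each founder's allele at a site is an independent Bernoulli
    draw with success probability p solved from 2p(1-p) = polymorphism_rate,
    so any two founders differ at a site with exactly the configured rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    p = _allele_one_prob(spec.polymorphism_rate)
    out: list[FounderHaplotype] = []
    for cspec in spec.genome:
        n = rng.poisson(spec.snp_density * cspec.length_bp)
        # uniform positions, deduplicated (collision loss is negligible at
        # the densities this simulator targets)
        pos = np.unique(rng.integers(1, cspec.length_bp + 1, size=n))
        for fid in spec.founders:
            alleles = (rng.random(len(pos)) < p).astype(np.int8)
            out.append(FounderHaplotype(fid, cspec.name, pos, alleles))
    return out


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _clip_segments(segs: list[Segment], lo: int, hi: int) -> list[Segment]:
    out = []
    for s, e, o in segs:
        if e <= lo or s >= hi:
            continue
        out.append((max(s, lo), min(e, hi), o))
    return out


def _merge_adjacent(segs: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segs:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def meiosis(hap_pair: tuple[np.ndarray, np.ndarray],
            origin_pair: tuple[list[Segment], list[Segment]],
            positions: np.ndarray, length_bp: int, morgans: float,
            rng: np.random.Generator) -> tuple[np.ndarray, list[Segment], np.ndarray]:
    """One meiosis on one chromosome under the Haldane model.

    Returns the gamete allele array, its origin mosaic, and the crossover
    positions (bp).  Crossover count ~ Poisson(morgans); positions uniform
    on [0, length_bp); the starting homolog is chosen with probability 1/2.
    """
    if morgans < 0:
        raise ConfigError("genetic length must be >= 0")
    n_x = rng.poisson(morgans)
    xs = np.sort(rng.uniform(0, length_bp, size=n_x))
    start = int(rng.integers(2))
    # sites strictly after a crossover switch homolog; positions are 1-based
    hap_idx = (start + np.searchsorted(xs, positions - 0.5)) % 2
    gamete = np.where(hap_idx == 0, hap_pair[0], hap_pair[1]).astype(np.int8)
    bounds = [0.0, *xs.tolist(), float(length_bp)]
    segs: list[Segment] = []
    for k in range(len(bounds) - 1):
        lo, hi = int(np.ceil(bounds[k])), int(np.ceil(bounds[k + 1]))
        if hi <= lo:
            continue
        active = (start + k) % 2
        segs.extend(_clip_segments(origin_pair[active], lo, hi))
    return gamete, _merge_adjacent(segs), xs


def simulate_meiosis(parent: Individual, chrom: ChromSpec, positions: np.ndarray,
                     seed: int) -> tuple[np.ndarray, list[Segment], np.ndarray]:
    """Convenience wrapper running one seeded meiosis for one chromosome."""
    rng = np.random.default_rng(np.random.SeedSequence((seed,)))
    return meiosis(parent.haps[chrom.name], parent.origins[chrom.name],
                   positions, chrom.length_bp, chrom.morgans, rng)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    spec: PedigreeSpec
    site_positions: dict[str, np.ndarray]
    lines: dict[str, Individual]
    truth: dict[str, TruthMosaic]

    def genotype_matrix(self, samples: Sequence[str] | None = None) -> GenotypeMatrix:
        samples = list(samples) if samples is not None else list(self.lines)
        recs = {"chrom": [], "pos": [], "ref": [], "alt": []}
        cols = []
        for cspec in self.spec.genome:
            pos = self.site_positions[cspec.name]
            recs["chrom"].extend([cspec.name] * len(pos))
            recs["pos"].extend(pos.tolist())
            recs["ref"].extend(["A"] * len(pos))
            recs["alt"].extend(["T"] * len(pos))
            block = np.empty((len(samples), len(pos)), dtype=np.int8)
            for i, s in enumerate(samples):
                h0, h1 = self.lines[s].haps[cspec.name]
                block[i] = h0 + h1  # 0/1/2 == HOM_REF/HET/HOM_ALT
            cols.append(block)
        calls = np.concatenate(cols, axis=1) if cols else np.empty((len(samples), 0), np.int8)
        if self.spec.missing_rate > 0:
            rng = np.random.default_rng(np.random.SeedSequence((self.spec.seed, 2)))
            mask = rng.random(calls.shape) < self.spec.missing_rate
            calls = np.where(mask, np.int8(MISSING), calls)
        return GenotypeMatrix(samples, pd.DataFrame(recs), calls)

    def write_vcf(self, path: str, samples: Sequence[str] | None = None) -> None:
        from .io import write_vcf
        gm = self.genotype_matrix(samples)
        write_vcf(gm, path, {c.name: c.length_bp for c in self.spec.genome})

    def write_truth_beds(self, outdir: str) -> list[str]:
        import os
        paths = []
        for line_id, mosaic in self.truth.items():
            for hap in (0, 1):
                p = os.path.join(outdir, f"{line_id}.hap{hap}.bed")
                with open(p, "w") as fh:
                    for cspec in self.spec.genome:
                        for s, e, o in mosaic.segments[cspec.name][hap]:
                            fh.write(f"{cspec.name}\t{s}\t{e}\t{o}\n")
                paths.append(p)
        return paths


def run_pedigree(spec: PedigreeSpec,
                 founders: Sequence[FounderHaplotype] | None = None) -> SimulationResult:
    """Run the breeding program and record exact ancestry truth.

    Each cross performs two independent meioses (one per parent); each
    selfing generation performs two meioses on the current individual
    (single-seed descent).  Per-meiosis random substreams are derived from
    (spec.seed, 1, event_counter) so adding lines later never reshuffles
    earlier ones.
    """
    if founders is None:
        founders = simulate_founders(spec)
    by_chrom: dict[str, np.ndarray] = {}
    by_founder: dict[str, dict[str, np.ndarray]] = {f: {} for f in spec.founders}
    for fh in founders:
        if fh.founder_id not in by_founder:
            raise ConfigError(f"haplotype for unknown founder {fh.founder_id}")
        prev = by_chrom.get(fh.chrom)
        if prev is not None and not np.array_equal(prev, fh.positions):
            raise ConfigError(f"founders disagree on site positions for {fh.chrom}")
        by_chrom[fh.chrom] = fh.positions
        by_founder[fh.founder_id][fh.chrom] = fh.alleles

    lines: dict[str, Individual] = {}
    truth: dict[str, TruthMosaic] = {}
    for fid in spec.founders:
        haps = {}
        origins = {}
        for cspec in spec.genome:
            a = by_founder[fid][cspec.name]
            haps[cspec.name] = (a.copy(), a.copy())
            origins[cspec.name] = ([(0, cspec.length_bp, fid)], [(0, cspec.length_bp, fid)])
        lines[fid] = Individual(fid, haps, origins)
        truth[fid] = TruthMosaic(fid, origins)

    counter = 0

    def _gamete(parent: Individual, cspec: ChromSpec):
        nonlocal counter
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1, counter)))
        counter += 1
        return meiosis(parent.haps[cspec.name], parent.origins[cspec.name],
                       by_chrom[cspec.name], cspec.length_bp, cspec.morgans, rng)

    def _offspring(line_id: str, mother: Individual, father: Individual) -> Individual:
        haps = {}
        origins = {}
        for cspec in spec.genome:
            g0, s0, _ = _gamete(mother, cspec)
            g1, s1, _ = _gamete(father, cspec)
            haps[cspec.name] = (g0, g1)
            origins[cspec.name] = (s0, s1)
        return Individual(line_id, haps, origins)

    for edge in spec.edges:
        if edge.mother not in lines or edge.father not in lines:
            raise PedigreeOrderError(f"cross producing {edge.child}: parents missing")
        child = _offspring(edge.child, lines[edge.mother], lines[edge.father])
        for g in range(edge.n_selfing):
            child = _offspring(edge.child, child, child)
        lines[edge.child] = child
        truth[edge.child] = TruthMosaic(edge.child, child.origins)

    return SimulationResult(spec, by_chrom, lines, truth)


# ---------------------------------------------------------------------------
# default study pedigree
# ---------------------------------------------------------------------------

DONOR_GP1 = "MaWanNuo"
DONOR_GP2 = "IRAT109"
RECURRENT = "HanFengB"
DONOR_LINE = "HuHan3"
OFFSPRING = "HuHan2B"


def default_backcross_spec(seed: int = 0, n_chrom: int = 2,
                           chrom_length_bp: int = 10_000_000,
                           morgans_per_chrom: float = 1.0,
                           snp_density: float = 1e-3,
                           polymorphism_rate: float = 0.5,
                           missing_rate: float = 0.0) -> PedigreeSpec:
    """Default three-founder backcross program.

    Two donor grandparents are crossed and the F1 selfed for three
    generations into the donor line; the donor is crossed to the recurrent
    parent, backcrossed once into the recurrent parent (BC1) and selfed for
    two generations into the offspring line — the structure of a
    donor-introgression maintainer-breeding program.
    """
    genome = [ChromSpec(f"chr{i + 1}", chrom_length_bp, morgans_per_chrom)
              for i in range(n_chrom)]
    edges = [
        Cross(DONOR_GP2, DONOR_GP1, DONOR_LINE, n_selfing=3),
        Cross(RECURRENT, DONOR_LINE, "BC0", n_selfing=0),
        Cross(RECURRENT, "BC0", OFFSPRING, n_selfing=2),
    ]
    nodes = [DONOR_GP1, DONOR_GP2, RECURRENT, DONOR_LINE, "BC0", OFFSPRING]
    return PedigreeSpec(nodes=nodes, edges=edges, genome=genome,
                        snp_density=snp_density,
                        polymorphism_rate=polymorphism_rate,
                        missing_rate=missing_rate, seed=seed)
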