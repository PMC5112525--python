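"""End-to-end orchestration: simulate → similarity → ancestry → trace →
annotate → DE-filter → motif scan → integrate.

Each stage writes its outputs before the next starts, so any stage can be
re-run from persisted inputs.  A JSON manifest records parameters, seed
and package versions to make runs reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import (call_blocks, contribution_fractions, fit_thresholds,
                       make_window_grid, window_diversity)
from .annotation import annotate_sites, annotation_summary
from .expression import (DEFAULT_CONTRASTS, call_degs, common_deg_total,
                         intersect_with_traced_genes, total_degs)
from .io import read_gff3, read_vcf, write_fasta, write_gff3
from .motifs import (Promoter, build_network, edges_to_frame, edges_to_sif,
                     extract_promoter, read_jaspar, write_jaspar)
from .similarity import pairwise_similarity
from .simulate import (DONOR_GP1, DONOR_GP2, DONOR_LINE, OFFSPRING, RECURRENT,
                       default_backcross_spec, run_pedigree)
from .synthdata import simulate_expression, simulate_gene_models, toy_pwms
from .tracing import (assign_to_genes, concordance_with_mosaic,
                      records_to_frame, trace_specific_alleles)

log = logging.getLogger(__name__)


class ConfigValidationError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All paths, sample roles and numeric parameters of a pipeline run.

    When ``vcf`` is None the built-in backcross simulator supplies every
    input (genotypes, gene models, reference sequence, expression tables
    and PWMs), with the default study roles.
    """

    outdir: str = "pedtrace_out"
    # input paths (all optional; None -> simulated)
    vcf: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    expression: str | None = None
    pvalues: str | None = None
    pwms: str | None = None
    # sample roles
    offspring: str | None = None
    recurrent: str | None = None
    donors: list[str] = field(default_factory=list)
    ancestors: list[str] = field(default_factory=list)  # candidate block origins
    panel: list[str] = field(default_factory=list)      # samples entering Darv
    varieties: list[str] = field(default_factory=list)  # expression varieties
    # ancestry parameters
    window_bp: int = 100_000
    step_bp: int = 10_000
    min_snps: int = 10
    tie_margin: float = 0.05
    fallback_threshold: float = 0.5
    het_policy: str = "exclude"
    min_sites: int = 100
    # tracing / annotation parameters
    promoter_bp: int = 2000
    splice_bp: int = 2
    # expression parameters
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    pseudocount: float = 0.1
    # motif parameters
    promoter_length: int = 3000
    threshold_fraction: float = 0.8
    # simulation scale (used when vcf is None)
    sim_n_chrom: int = 2
    sim_chrom_length: int = 1_000_000
    sim_snp_density: float = 1e-3
    sim_polymorphism: float = 0.5
    sim_genes_per_chrom: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("vcf", "gff3", "fasta", "expression", "pvalues", "pwms"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise ConfigValidationError(f"{name} path does not exist: {p}")
        if self.vcf is not None:
            if not self.offspring or not self.recurrent or not self.donors:
                raise ConfigValidationError(
                    "offspring, recurrent and donors roles are required with a user VCF")
        roles = [self.offspring, self.recurrent, *self.donors]
        named = [r for r in roles if r]
        if len(set(named)) != len(named):
            raise ConfigValidationError("sample roles must reference distinct samples")
        if not (0 < self.threshold_fraction <= 1):
            raise ConfigValidationError("threshold_fraction must be in (0, 1]")
        for name in ("window_bp", "step_bp", "min_snps", "promoter_bp",
                     "promoter_length"):
            if getattr(self, name) <= 0:
                raise ConfigValidationError(f"{name} must be positive")
        if not (0 <= self.p_threshold <= 1):
            raise ConfigValidationError("p_threshold must be in [0, 1]")

    @classmethod
    def from_ini(cls, path: str, **overrides) -> "PipelineConfig":
        """Read a flat sectioned key=value config file; kwargs override file values."""
        import configparser

        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for section in cp.sections():
            for key, raw in cp.items(section):
                if key not in fields:
                    raise ConfigValidationError(f"unknown config key: {key}")
                kwargs[key] = _coerce(raw, fields[key])
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _coerce(raw: str, f: dataclasses.Field):
    t = f.type
    if "list" in str(t):
        return [s.strip() for s in raw.split(",") if s.strip()]
    if "int" in str(t):
        return int(raw)
    if "float" in str(t):
        return float(raw)
    return raw


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the run manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "pedtrace_version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    ctx: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("similarity", _stage_similarity),
        ("ancestry", _stage_ancestry),
        ("trace", _stage_trace),
        ("annotate", _stage_annotate),
        ("de-filter", _stage_de_filter),
        ("scan-motifs", _stage_scan_motifs),
        ("integrate", _stage_integrate),
    ]
    for name, fn in stages:
        log.info("[%s] starting", name)
        try:
            outputs = fn(config, ctx)
        except Exception as exc:
            _write_manifest(manifest, config.outdir)
            raise PipelineStageError(name, exc) from exc
        manifest["stages"][name] = outputs
        log.info("[%s] done: %s", name, sorted(outputs.get("files", [])))
    _write_manifest(manifest, config.outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _out(config: PipelineConfig, name: str) -> str:
    return os.path.join(config.outdir, name)


def _to_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, ctx: dict) -> dict:
    if config.vcf is not None:
        ctx["vcf"] = config.vcf
        ctx["gff3"], ctx["fasta"] = config.gff3, config.fasta
        ctx["expression"], ctx["pvalues"] = config.expression, config.pvalues
        ctx["pwms_path"] = config.pwms
        return {"skipped": "user inputs supplied"}
    spec = default_backcross_spec(
        seed=config.seed, n_chrom=config.sim_n_chrom,
        chrom_length_bp=config.sim_chrom_length,
        snp_density=config.sim_snp_density,
        polymorphism_rate=config.sim_polymorphism)
    sim = run_pedigree(spec)
    ctx["sim"] = sim
    vcf_path = _out(config, "simulated.vcf")
    sim.write_vcf(vcf_path)
    bed_paths = sim.write_truth_beds(config.outdir)
    ctx["vcf"] = vcf_path
    # matching gene models + reference sequence
    chrom_lengths = {c.name: c.length_bp for c in spec.genome}
    index, genomes = simulate_gene_models(
        chrom_lengths, genes_per_chrom=config.sim_genes_per_chrom,
        seed=config.seed, snp_positions=sim.site_positions)
    gff_path, fa_path = _out(config, "genes.gff3"), _out(config, "genome.fa")
    write_gff3(index, gff_path)
    write_fasta(genomes, fa_path)
    ctx["gff3"], ctx["fasta"] = gff_path, fa_path
    # toy expression for offspring + recurrent parent
    gene_ids = sorted(g.gene_id for g in index)
    varieties = [OFFSPRING, RECURRENT]
    fpkm, pvals, _ = simulate_expression(gene_ids, varieties, seed=config.seed)
    expr_path, pval_path = _out(config, "expression.tsv"), _out(config, "pvalues.tsv")
    _to_tsv(fpkm, expr_path)
    _to_tsv(pvals, pval_path)
    ctx["expression"], ctx["pvalues"] = expr_path, pval_path
    # toy PWMs
    pwm_path = _out(config, "motifs.jaspar")
    write_jaspar(toy_pwms(seed=config.seed), pwm_path)
    ctx["pwms_path"] = pwm_path
    # default study roles
    config.offspring = config.offspring or OFFSPRING
    config.recurrent = config.recurrent or RECURRENT
    config.donors = config.donors or [DONOR_GP1, DONOR_GP2, DONOR_LINE]
    config.ancestors = config.ancestors or [RECURRENT, DONOR_GP1, DONOR_GP2]
    config.panel = config.panel or [DONOR_GP1, DONOR_GP2, DONOR_LINE,
                                    RECURRENT, OFFSPRING]
    config.varieties = config.varieties or varieties
    return {"files": [vcf_path, gff_path, fa_path, expr_path, pval_path,
                      pwm_path, *bed_paths]}


def _stage_similarity(config: PipelineConfig, ctx: dict) -> dict:
    gm = read_vcf(ctx["vcf"])
    ctx["gm"] = gm
    sm = pairwise_similarity(gm, het_policy=config.het_policy,
                             min_sites=config.min_sites)
    path = _out(config, "similarity.tsv")
    sm.to_tsv(path)
    ctx["similarity"] = sm
    return {"files": [path]}


def _stage_ancestry(config: PipelineConfig, ctx: dict) -> dict:
    gm = ctx["gm"]
    panel = config.panel or gm.samples
    sub = gm.subset(panel)
    chrom_lengths = {c: int(gm.positions(c).max()) for c in gm.chroms}
    if "sim" in ctx:
        chrom_lengths = {c.name: c.length_bp for c in ctx["sim"].spec.genome}
    grid = make_window_grid(chrom_lengths, config.window_bp, config.step_bp,
                            config.min_snps)
    ancestors = config.ancestors or [config.recurrent, *config.donors]
    profile = window_diversity(sub, grid, config.offspring, ancestors,
                               het_policy=config.het_policy)
    thresholds = fit_thresholds(profile, fallback=config.fallback_threshold,
                                seed=config.seed)
    mosaic = call_blocks(profile, thresholds, tie_margin=config.tie_margin)
    report = contribution_fractions(mosaic)
    bed = _out(config, "ancestry_blocks.bed")
    mosaic.to_bed(bed)
    tsv = _out(config, "contributions.tsv")
    _to_tsv(report.to_frame(), tsv)
    js = _out(config, "contributions.json")
    with open(js, "w") as fh:
        json.dump({"descendant": report.descendant,
                   "fractions": report.fractions,
                   "assigned_bp": report.assigned_bp,
                   "unassigned_bp": report.unassigned_bp}, fh, indent=2)
    ctx["mosaic"], ctx["contributions"] = mosaic, report
    return {"files": [bed, tsv, js],
            "thresholds": {a: t.threshold for a, t in thresholds.items()}}


def _stage_trace(config: PipelineConfig, ctx: dict) -> dict:
    gm = ctx["gm"]
    records = trace_specific_alleles(gm, config.offspring, config.recurrent,
                                     config.donors)
    index = read_gff3(ctx["gff3"]) if ctx.get("gff3") else None
    ctx["gene_index"] = index
    if index is not None:
        summary = assign_to_genes(records, index, promoter_bp=config.promoter_bp)
    else:
        summary = pd.DataFrame(columns=["gene_id", "n_snps", "locations", "donors"])
    conc = concordance_with_mosaic(records, ctx["mosaic"])
    snp_path, gene_path = _out(config, "traced_snps.tsv"), _out(config, "traced_genes.tsv")
    _to_tsv(records_to_frame(records), snp_path)
    _to_tsv(summary, gene_path)
    ctx["records"], ctx["traced_summary"] = records, summary
    return {"files": [snp_path, gene_path],
            "n_traced_snps": len(records),
            "n_traced_genes": int(len(summary)),
            "mosaic_concordance": None if not conc.applicable else conc.fraction}


def _stage_annotate(config: PipelineConfig, ctx: dict) -> dict:
    if ctx.get("gene_index") is None:
        return {"skipped": "no gene models supplied"}
    from pyfaidx import Fasta
    fasta = Fasta(ctx["fasta"]) if ctx.get("fasta") else None
    ann = annotate_sites(ctx["gm"], ctx["gene_index"], fasta,
                         promoter_bp=config.promoter_bp,
                         splice_bp=config.splice_bp)
    path = _out(config, "snp_annotations.tsv")
    _to_tsv(ann, path)
    summ = annotation_summary(ann)
    js = _out(config, "annotation_summary.json")
    with open(js, "w") as fh:
        json.dump(summ, fh, indent=2, default=str)
    ctx["annotations"] = ann
    return {"files": [path, js],
            "nonsyn_syn_ratio": summ.get("nonsyn_syn_ratio")}


def _stage_de_filter(config: PipelineConfig, ctx: dict) -> dict:
    if not ctx.get("expression"):
        return {"skipped": "no expression table supplied"}
    expr = pd.read_csv(ctx["expression"], sep="\t")
    pvals = pd.read_csv(ctx["pvalues"], sep="\t")
    rows = []
    per_variety: dict[str, list] = {}
    for variety in config.varieties:
        sets = [call_degs(expr, pvals, variety, num, den,
                          fc_threshold=config.fc_threshold,
                          p_threshold=config.p_threshold,
                          pseudocount=config.pseudocount)
                for num, den in DEFAULT_CONTRASTS]
        per_variety[variety] = sets
        for ds in sets:
            for direction, genes in (("up", ds.up), ("down", ds.down)):
                for g in sorted(genes):
                    rows.append(dict(variety=variety, contrast=ds.contrast,
                                     direction=direction, gene_id=g))
    degs_path = _out(config, "degs.tsv")
    _to_tsv(pd.DataFrame(rows, columns=["variety", "contrast", "direction",
                                        "gene_id"]), degs_path)
    totals = {v: total_degs(sets) for v, sets in per_variety.items()}
    ctx["deg_sets"] = per_variety
    ctx["deg_totals"] = totals
    out = {"files": [degs_path],
           "n_total_degs": {v: len(t.all) for v, t in totals.items()}}
    if len(totals) == 2:
        a, b = totals.values()
        out["common_deg_total"] = common_deg_total(a, b)
    return out


def _stage_scan_motifs(config: PipelineConfig, ctx: dict) -> dict:
    if not ctx.get("pwms_path") or ctx.get("gene_index") is None or not ctx.get("fasta"):
        return {"skipped": "PWMs, gene models and FASTA all required"}
    from pyfaidx import Fasta
    fasta = Fasta(ctx["fasta"])
    pwms = read_jaspar(ctx["pwms_path"])
    # scan promoters of the offspring's total DEGs (fall back to all genes)
    genes = None
    if ctx.get("deg_totals") and config.offspring in ctx["deg_totals"]:
        genes = sorted(ctx["deg_totals"][config.offspring].all)
    index = ctx["gene_index"]
    if not genes:
        genes = sorted(index.genes)
    promoters: dict[str, Promoter] = {}
    for g in genes:
        if g in index.genes:
            promoters[g] = extract_promoter(index.genes[g], fasta,
                                            length=config.promoter_length)
    edges, summary = build_network(promoters, pwms,
                                   threshold_fraction=config.threshold_fraction)
    hits_path = _out(config, "tfbs_hits.tsv")
    _to_tsv(edges_to_frame(edges), hits_path)
    sif_path = _out(config, "network.sif")
    edges_to_sif(edges, sif_path)
    summ_path = _out(config, "tfbs_summary.tsv")
    _to_tsv(summary, summ_path)
    ctx["network_edges"] = edges
    return {"files": [hits_path, sif_path, summ_path],
            "n_edges": len(edges),
            "n_genes_with_tfbs": len({e.target_gene for e in edges})}


def _stage_integrate(config: PipelineConfig, ctx: dict) -> dict:
    if "deg_sets" not in ctx or "traced_summary" not in ctx:
        return {"skipped": "needs DEG sets and traced genes"}
    sets = ctx["deg_sets"].get(config.offspring, [])
    inter = intersect_with_traced_genes(sets, ctx["traced_summary"])
    path = _out(config, "traced_degs.tsv")
    _to_tsv(inter, path)
    n_net = 0
    if ctx.get("network_edges") is not None and len(inter):
        net_genes = {e.target_gene for e in ctx["network_edges"]}
        n_net = int(sum(g in net_genes for g in inter["gene_id"]))
    return {"files": [path], "n_traced_degs": int(len(inter)),
            "n_traced_degs_in_network": n_net}
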