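"""Trace specific inherited alleles to genes and annotate SNP effects.

A specific allele is an offspring genotype identical to a donor-side
parent but different from the recurrent parent — direct evidence of
introgression.  Traced SNPs are assigned to gene bodies / promoters, and
all SNPs are classified by feature and coding effect against synthetic
gene models and reference sequence.
"""
from pedtrace.annotation import annotate_sites, annotation_summary
from pedtrace.evaluate import traced_truth_concordance
from pedtrace.simulate import OFFSPRING, RECURRENT, default_backcross_spec, run_pedigree
from pedtrace.synthdata import simulate_gene_models
from pedtrace.tracing import assign_to_genes, trace_specific_alleles

spec = default_backcross_spec(seed=1, n_chrom=2, chrom_length_bp=2_000_000)
sim = run_pedigree(spec)
gm = sim.genotype_matrix()

records = trace_specific_alleles(gm, OFFSPRING, RECURRENT,
                                 donors=["MaWanNuo", "IRAT109"])
conc = traced_truth_concordance(records, sim.truth[OFFSPRING])
print(f"{len(records)} specific inherited alleles traced "
      f"(truth concordance {conc:.3f})")

index, genomes = simulate_gene_models(
    {c.name: c.length_bp for c in spec.genome}, genes_per_chrom=40, seed=1,
    snp_positions=sim.site_positions)
summary = assign_to_genes(records, index, promoter_bp=2000)
print(f"{len(summary)} genes carry a traced SNP in the gene body or "
      f"within 2 kb of the promoter")

ann = annotate_sites(gm, index, genomes)
summ = annotation_summary(ann)
print("\nSNP feature distribution:")
for feat, pct in sorted(summ["feature_pct"].items(), key=lambda kv: -kv[1]):
    print(f"  {feat:12s} {pct:6.2f}%")
if "nonsyn_syn_ratio" in summ:
    print(f"Nonsyn/Syn ratio (stop variants excluded): "
          f"{summ['nonsyn_syn_ratio']:.2f}")
print("\nMost SNPs fall in intergenic space; exonic SNPs split into "
      "synonymous and amino-acid-changing classes.")
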