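"""DEG filtering, promoter motif scanning and allele-DEG integration.

The DEG filter keeps genes with fold change > 2 and p < 0.05 per
contrast; promoters of DEGs are scanned with position weight matrices to
build a TF-family -> target network, and DEGs carrying specific inherited
alleles are intersected with it.
"""
from pedtrace.expression import (DEFAULT_CONTRASTS, call_degs, common_deg_total,
                                 contrast_label, log2_stress_ratio, total_degs)
from pedtrace.motifs import Promoter, build_network
from pedtrace.synthdata import simulate_expression, simulate_promoters, toy_pwms

genes = [f"LOC_Os{i:02d}g{i * 137 % 100:05d}" for i in range(60)]
fpkm, pvals, truth = simulate_expression(genes, ["HuHan2B", "HanFengB"], seed=2)

totals = {}
for variety in ("HuHan2B", "HanFengB"):
    sets = [call_degs(fpkm, pvals, variety, num, den)
            for num, den in DEFAULT_CONTRASTS]
    totals[variety] = total_degs(sets)
    print(f"{variety}: {len(totals[variety].up)} up / "
          f"{len(totals[variety].down)} down total DEGs")
print(f"common DEGs between varieties: "
      f"{common_deg_total(totals['HuHan2B'], totals['HanFengB'])} "
      f"(|up ∩ up| + |down ∩ down|)")

g0 = sorted(totals["HuHan2B"].up)[0]
lfc = log2_stress_ratio(fpkm, g0, "HuHan2B", "T1")
print(f"log2 FPKM(drought)/FPKM(watered) at T1 for {g0}: {lfc:+.2f}")

pwms = toy_pwms(seed=2)  # ERF / WRKY / bHLH toy motifs
deg_genes = sorted(totals["HuHan2B"].all)
seqs, planted = simulate_promoters(deg_genes, pwms, length=300, seed=2)
promoters = {g: Promoter(g, s, 300, False) for g, s in seqs.items()}
edges, summary = build_network(promoters, pwms, threshold_fraction=0.8)
print(f"\nTFBS network: {len(edges)} hits, "
      f"{len({e.target_gene for e in edges})} DEGs with at least one TFBS")
print(summary.to_string(index=False))
print("\nEach row counts DEGs whose promoter contains a predicted binding "
      "site of that TF family — the skeleton of a drought-response "
      "regulatory network.")
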