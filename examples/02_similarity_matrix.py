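"""Pairwise genetic similarity (1 − π) between the pedigree lines.

π is the fraction of compared SNP sites at which two lines carry
different genotypes; 1 − π is the similarity index used to quantify how
much of an offspring's genome tracks each ancestor.
"""
from pedtrace.similarity import pairwise_similarity
from pedtrace.simulate import default_backcross_spec, run_pedigree

spec = default_backcross_spec(seed=1, n_chrom=2, chrom_length_bp=2_000_000)
sim = run_pedigree(spec)
gm = sim.genotype_matrix(["MaWanNuo", "IRAT109", "HuHan3", "HanFengB",
                          "HuHan2B"])

sm = pairwise_similarity(gm, het_policy="exclude", min_sites=100)
print(sm.to_frame().round(3))
print("\nThe offspring (HuHan2B analogue) is most similar to the recurrent "
      "parent (HanFengB analogue); unrelated founders sit near 1 - "
      "polymorphism rate = 0.5.")
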