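# Methods

This note documents the models, parameters and numerical choices behind
`pedtrace`, and what the synthetic-data generator does and does not
emulate.

## Pedigree simulator

**Genetic model.** Founders are fully homozygous (inbred lines). Meiosis
follows the Haldane model: the crossover count per chromosome is
Poisson-distributed with mean equal to the chromosome's genetic length in
Morgans, crossover positions are uniform, and there is no interference.
The starting homolog is chosen with probability 1/2. This is the simplest
defensible meiosis model for a breeding simulator; interference would
slightly reduce the variance of block lengths but not their expectation.

**Founder genotypes.** SNP site counts per chromosome are
Poisson(density × length) with uniform positions (deduplicated; collision
loss is negligible at the targeted densities). Each founder's allele at a
site is an independent Bernoulli draw with success probability *p* solved
from 2*p*(1−*p*) = polymorphism rate, so that any two founders differ at
a site with exactly the configured rate. The default rate 0.5 is the
maximum attainable for binary alleles and gives the strongest ancestry
signal; it can be lowered to stress-test callers on more related
founders.

**Truth bookkeeping.** Every gamete's founder-of-origin mosaic is carried
through each meiosis exactly (crossover breakpoints intersected with the
parent's segment lists), so each simulated line has a per-homolog truth
mosaic that tiles every chromosome. Truth BED files are written per
homolog (`<line>.hap0.bed` / `<line>.hap1.bed`) because the two homolog
mosaics overlap and cannot share one 4-column BED.

**Randomness.** One global seed; each meiosis consumes its own substream
derived from (seed, stage, event counter), so extending a pedigree never
reshuffles the lines already simulated. With the seed fixed, all outputs
(VCF, BEDs, tables) are byte-identical across runs.

**Default program.** Two donor grandparents → F1 → 3 selfing generations
→ donor line; donor × recurrent → BC1 (one backcross) → 2 selfing
generations → offspring. Genome: 2 chromosomes × 10 Mb at 1 SNP/kb.
Genetic length defaults to 1.0 Morgan per chromosome — a typical
chromosome-scale map length that yields a handful of crossovers over the
~6 effective meioses of the program, i.e. realistic block sizes relative
to the 100-kb analysis window.

**What the simulator does not emulate.** No phenotypic selection during
breeding (real programs select, which inflates donor content around
target loci), no mutation, no genotyping error beyond an optional uniform
missing-data rate, no segregation distortion, and founder alleles are
i.i.d. across sites (no linkage disequilibrium within founders). Passing
tests therefore demonstrate correctness of the reconstruction machinery
under a clean inheritance model, not robustness to array/sequencing
artefacts or to selection-skewed pedigrees.

## Similarity (1 − π)

π between two lines is the fraction of compared SNP sites with different
genotypes, pooled genome-wide. Heterozygous calls are excluded by default
(`het_policy="exclude"`): the lines this tool targets are inbred, and
haplotype-level identity is ambiguous at heterozygous genotypes. The
alternative `half-difference` policy scores het-vs-hom pairs as half a
difference (expected allele-sharing distance). Missing calls are excluded
pairwise, maximising informative sites per pair; pairs with fewer than
`min_sites` (default 100) comparable sites are reported undefined rather
than noisy.

## Ancestry reconstruction

**Windows.** Sliding windows, default 100 kb with 10-kb step and at least
`min_snps = 10` informative sites. The defaults are chosen so that
rice-scale SNP densities (a few SNPs per kb) give on the order of a
hundred sites per window; all three are configurable.

**Statistic.** Per window and candidate ancestor:
Dpair = diversity between descendant and ancestor (same counting rules as
the similarity module); Darv = mean of the pairwise diversities over all
unordered pairs of the sample panel (restrict the genotype matrix to
control which samples enter the average); decrease =
(Darv − Dpair)/Darv, computed only where Darv > 0. Windows with too few
sites are marked uninformative, never NaN-propagated.

**Thresholds.** The decrease values of a descendant–ancestor pair are
bimodal: a mode near 1 (windows inherited from that ancestor) and a
background mode. A two-component Gaussian mixture is fitted by EM
(deterministic k-means++ initialisation from a fixed seed; `reg_covar =
1e-3` so a point mass at decrease = 1 cannot collapse the decision
boundary onto itself), and the threshold is the equal-posterior decision
boundary between the two components (bracketed root between the means).
If the component means are closer than δ = 0.1 or either weight is below
0.05, the distribution is declared unimodal and a fixed fallback
threshold (default 0.5) is used and logged. Thresholds are fitted per
ancestor, not globally, because decrease scales differ with
ancestor relatedness.

**Assignment and blocks.** A window is assigned to the ancestor that
passes its threshold with maximal decrease. When the top two passing
ancestors lie within the tie margin (default 0.05) the window is labelled
with the *pair* ("A|B"): in a diploid descendant such windows arise in
residual heterozygous regions where each homolog genuinely descends from
a different ancestor (with the het-excluding counting rules, the
comparable sites in such regions match both ancestors, driving both
decreases to ≈1), or where two ancestors are locally identical by state.
Shared blocks count half their length toward each member — without this,
apportioning them to flanking blocks mis-assigns up to the descendant's
entire residual-het fraction of the genome. Windows where *no* ancestor
passes are "uncertain"; overlapping windows are resolved on the
step-sized tiling by plurality vote; uncertain runs strictly between two
determinate blocks are split at the midpoint and apportioned half to
each, runs touching a chromosome end attach to their single neighbour,
and a chromosome that is entirely uncertain is reported unassigned.
Contribution fractions are over assigned length, with unassigned length
disclosed separately.

**Scoring against truth.** Agreement is measured per base pair of
assigned genome: a called origin matches if it equals the truth origin of
either homolog (for shared calls: if every member of the pair appears
among the homolog origins). A genotype-based caller cannot, and need not,
say which homolog carries which origin.

## Allele tracing

A site qualifies as a specific inherited allele iff offspring, recurrent
parent and at least one donor are homozygous and non-missing, the
offspring differs from the recurrent parent, and equals that donor.
Heterozygous sites are excluded: origin is ambiguous there, and the
target lines are inbred. All matching donors are recorded per site
(grandparents and intermediate donor lines share alleles, so matches are
reported per donor rather than collapsed). Gene assignment uses the gene
body (span-inclusive) and a promoter window (default 2 000 bp upstream of
the TSS, strand-aware) — deliberately independent of the 3 000-bp window
used for TFBS scanning; both are configurable.

## SNP annotation

Exactly one feature per SNP. Within a gene the priority is splice site
(within `splice_bp = 2` bp of an intron end, the GT–AG dinucleotides) >
UTR > exon (CDS) > intron; across overlapping genes the highest-priority
feature wins; promoter applies only outside all gene bodies; everything
else is intergenic. One representative transcript per gene (longest total
CDS). Coding effects substitute the alternate allele into the reference
codon in transcript orientation (reverse-complemented on the minus
strand) and translate under the standard nuclear code; a CDS whose length
is not a multiple of 3 flags the gene non-annotatable rather than
failing, and a VCF/FASTA reference mismatch is a hard error naming the
site. The Nonsyn/Syn ratio excludes stop-gain/stop-loss variants from
both numerator and denominator.

## Expression filtering

This module filters, it does not test: FPKM values and per-contrast
p-values are consumed as given. A gene is up-regulated for a contrast
when (FPKM_num + pc)/(FPKM_den + pc) > 2 and p < 0.05 (strict
inequalities; pseudocount pc = 0.1 guards zeros, also in the log2
drought/watered ratios). The standard contrasts are drought vs
well-watered at T1, then successive drought time points (T2 vs T1, T3 vs
T2); "total DEGs" of a variety is the union over the three contrasts, and
the common-DEG count between two varieties is |up ∩ up| + |down ∩ down|.

## Promoter motif scanning

Promoters are the 3 000 bp upstream of the TSS, strand-aware, truncated
at chromosome ends with the actual length reported. JASPAR-style count
matrices become log-odds scores with pseudocount 0.8 and a uniform
background by default; both strands are scanned; windows containing N are
skipped; a hit requires score ≥ 0.8 × the maximum attainable score
(relative threshold — no p-value calibration is attempted), and
overlapping hits are all reported. Hit positions are reported relative to
the TSS (negative upstream). Network edges exist purely from sequence;
expression may annotate but never creates edges.

## Synthetic companions

The generator also supplies: non-overlapping two-exon gene models with
intact ORFs and a matching reference sequence (reference bases at SNP
sites forced to 'A' so simulator VCFs are consistent); long-form
expression tables with DEGs planted beyond the 2×/0.05 thresholds and
everything else kept sub-threshold; and random promoters with motif
consensi planted in a known subset. Each generator returns its planted
truth so recovery is exactly checkable. These toys exercise the
*filtering and scanning logic*; they do not emulate read-level noise,
expression covariance, or composition biases of real promoters.

## Problem sizes in the shipped tests

The test suite and acceptance script run the default study at 2 × 10 Mb
with ~20 000 SNPs over 10 replicate seeds, 1 000 meioses for the
crossover statistic and 500 truth-only replicates for the BC1 recovery
statistic — sizes at which every Monte-Carlo check resolves its 3-SE
tolerance in seconds while exercising the same code paths as a
genome-scale run.

## Known limitations

* Contributions are over assigned genome only; the unassigned remainder
  is disclosed but not allocated.
* Whether Darv should average over all pairs or only parent–descendant
  pairs is a modelling choice; all unordered pairs is the default, and
  the panel is caller-controlled.
* Block boundaries are resolved to about one window length; no HMM
  smoothing is applied (by design).
* The DEG stage trusts upstream p-values; no multiple-testing correction
  is added because the filter is deliberately the published-style
  fold-change + p cut.
* PWM hits use a relative-score cutoff; absolute binding affinity and
  chromatin context are out of scope.
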