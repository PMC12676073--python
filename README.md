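# homeocomp

Homoeolog transcriptional-compensation analysis for polyploid wheat
mutant lines.

Given gene-level expression counts and annotated point mutations from
EMS-mutagenised (TILLING) lines, the package

- calls SNV consequences (stop-gained / synonymous / missense) against
  gene models and a genome, or accepts pre-annotated VCFs;
- applies the mutation-filtering cascade (PTC or synonymous, homozygous
  in the mutant, member of a homoeolog group, absent from wild type) and
  resolves per-(line, group) mutation contexts;
- runs a self-contained negative-binomial differential-expression test
  (median-of-ratios normalization, moment dispersion with trend
  shrinkage, Wald test, Benjamini–Hochberg FDR);
- flags *transcriptional compensation*: homoeolog groups in which at
  least one non-mutated homoeolog is significantly upregulated in the
  mutant, summarised per line and pooled over unique groups, with a
  chi-squared comparison of the PTC and synonymous classes;
- classifies wild-type homoeolog expression-bias categories by nearest
  ideal point in TPM-share space (seven triad categories; three dyad
  categories for tetraploid data);
- computes Pfaffl-ratio relative expression from qPCR Ct tables with a
  genotype ANOVA.

A synthetic-data generator (`homeocomp.synthetic`) produces counts,
variants (VCF), homoeolog groups, gene models (GFF3 + FASTA) and a
ground-truth table with configurable NMD-like downregulation and true
compensation rates, so every stage is testable without external data.

## CLI

```sh
# generate fixtures with known truth
homeocomp simulate --ploidy hexaploid --n-groups 100 --compensation-rate 0.3 \
    --seed 1 --out fixtures/

# full pipeline: variants -> DE -> compensation -> bias -> report.json
homeocomp run-all --dir fixtures/ --out results/ --alpha 0.05

# or stage by stage (byte-identical intermediates)
homeocomp annotate --vcf fixtures/variants.vcf --groups fixtures/groups.tsv \
    --gff3 fixtures/genes.gff3 --fasta fixtures/genome.fa --out assignments.tsv
homeocomp de --counts fixtures/counts.tsv --samples fixtures/samples.tsv \
    --line mut1 --out de_mut1.tsv
homeocomp compensate --assignments assignments.tsv --groups fixtures/groups.tsv \
    --de-dir . --out comp/
homeocomp bias --counts fixtures/counts.tsv --samples fixtures/samples.tsv \
    --gff3 fixtures/genes.gff3 --groups fixtures/groups.tsv --out bias.tsv
homeocomp qpcr --ct-table ct.tsv --reference GAPDH --calibrator WT --out qpcr/
```

All file formats are plain text: counts and sample sheets as TSV,
variants as VCF v4.2, gene models as GFF3 with a FASTA genome, homoeolog
groups as a four-column TSV (`group_id, gene_A, gene_B, gene_D`; empty
`gene_D` marks a dyad).

## Notes

- The DE module is a simplified NB Wald pipeline validated by simulation
  calibration (null rejection rate, p-value uniformity), not a bit-exact
  DESeq2 reimplementation; externally produced DE tables can be
  substituted at the `compensate` stage.
- The chi-squared class comparison uses Yates continuity correction by
  default (`--no-yates` to disable).
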