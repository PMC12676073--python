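"""SNV consequence calling and the mutation-filtering cascade.

The cascade keeps variants that (i) are predicted to cause a premature
termination codon (PTC, i.e. stop_gained) or a synonymous change, (ii) are
homozygous-alt in a mutant line, (iii) fall in a gene that belongs to a
homoeolog group, and (iv) are absent from the wild-type control (which
removes cultivar-specific SNPs).  Surviving variants become per-line
mutation assignments, which are then grouped into analyzable (line, group)
contexts with exactly one mutated homoeolog.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam
from Bio.Seq import Seq

from .genomodel import GeneModel, GroupTable, cds_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PTC",
    "SYNONYMOUS",
    "MISSENSE",
    "NON_CODING",
    "OTHER",
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "VariantRecord",
    "MutationAssignment",
    "MutationContext",
    "GroupAssignment",
    "read_vcf",
    "write_vcf",
    "call_consequence",
    "filter_mutations",
    "assign_groups",
]

# consequence classes
PTC = "PTC"
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NON_CODING = "non_coding"
OTHER = "other"

# genotype classes
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

_NUCS = set("ACGT")

#: VEP-style consequence terms accepted from pre-annotated VCFs.
VEP_TERMS = {
    "stop_gained": PTC,
    "synonymous_variant": SYNONYMOUS,
    "missense_variant": MISSENSE,
    "intergenic_variant": NON_CODING,
    "intron_variant": NON_CODING,
}
_TO_VEP = {PTC: "stop_gained", SYNONYMOUS: "synonymous_variant",
           MISSENSE: "missense_variant", NON_CODING: "intergenic_variant",
           OTHER: "coding_sequence_variant"}


class CdsFrameError(ValueError):
    """CDS length of a gene model is not divisible by three."""


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic SNV with one genotype per declared sample."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    genotypes: Mapping[str, str]  # sample -> HOM_REF/HET/HOM_ALT/MISSING
    consequence: str | None = None  # optional pre-annotated class

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"{self.chrom}:{self.pos}: only single-nucleotide ref/alt "
                f"supported (got {self.ref!r}>{self.alt!r})"
            )
        if self.ref.upper() not in _NUCS or self.alt.upper() not in _NUCS:
            raise ValueError(f"{self.chrom}:{self.pos}: non-ACGT allele")
        for sample, gt in self.genotypes.items():
            if gt not in (HOM_REF, HET, HOM_ALT, MISSING):
                raise ValueError(
                    f"{self.chrom}:{self.pos}: bad genotype {gt!r} for "
                    f"sample {sample!r}"
                )


@dataclass(frozen=True)
class MutationAssignment:
    """A retained homozygous PTC/synonymous variant attached to a gene."""

    line: str
    gene: str
    group_id: str
    subgenome: str
    consequence: str  # PTC or SYNONYMOUS
    cds_pos: int  # 0-based offset of the change within the spliced CDS

    def __post_init__(self) -> None:
        if self.consequence not in (PTC, SYNONYMOUS):
            raise ValueError(
                f"assignment consequence must be PTC or synonymous, "
                f"got {self.consequence!r}"
            )


@dataclass(frozen=True)
class MutationContext:
    """An analyzable (line, group) context: exactly one mutated homoeolog."""

    line: str
    group_id: str
    mutation_class: str  # PTC or SYNONYMOUS
    mutated_gene: str
    mutated_subgenome: str


@dataclass
class GroupAssignment:
    """Result of grouping assignments into per-(line, group) contexts."""

    contexts: list[MutationContext]
    excluded_multi: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_multi)


# ---------------------------------------------------------------------------
# Consequence calling


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def call_consequence(
    variant: VariantRecord, model: GeneModel, genome: Mapping[str, str]
) -> str:
    """Classify a SNV against a gene model using the standard genetic code.

    Positions outside the CDS are ``non_coding``.  Within the CDS the
    affected codon is translated before and after the substitution: a new
    stop where the reference had none is ``PTC``; an unchanged amino acid is
    ``synonymous``; a changed amino acid is ``missense``; loss of the stop
    or start codon (including a stop replaced by a different stop) is
    ``other``.
    """
    if variant.chrom != model.chrom:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} not on model chromosome "
            f"{model.chrom!r}"
        )
    offset = model.cds_offset(variant.pos)
    if offset is None:
        return NON_CODING
    if not model.frame_complete:
        raise CdsFrameError(
            f"{model.gene_id}: CDS length {model.cds_length} not divisible by 3"
        )
    cds = cds_sequence(model, genome)
    ref_base = variant.ref.upper()
    alt_base = variant.alt.upper()
    if model.strand == "-":
        ref_base = str(Seq(ref_base).complement())
        alt_base = str(Seq(alt_base).complement())
    if cds[offset] != ref_base:
        raise ValueError(
            f"{model.gene_id}: reference mismatch at CDS offset {offset}: "
            f"CDS has {cds[offset]!r}, variant implies {ref_base!r}"
        )
    codon_idx = offset // 3
    within = offset % 3
    old_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    new_codon = old_codon[:within] + alt_base + old_codon[within + 1 :]
    old_aa = _translate(old_codon)
    new_aa = _translate(new_codon)
    if old_aa == "*":
        # stop retained (synonymous-at-stop) or stop lost: both excluded
        return OTHER
    if codon_idx == 0 and old_codon == "ATG" and new_codon != "ATG":
        return OTHER
    if new_aa == "*":
        return PTC
    if new_aa == old_aa:
        return SYNONYMOUS
    return MISSENSE


# ---------------------------------------------------------------------------
# Filtering cascade


class _GeneLocator:
    """Map genomic positions to gene models via per-chromosome sorted spans."""

    def __init__(self, models: Mapping[str, GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[tuple[int, str]]]] = {}
        for gene_id, model in models.items():
            start, end = model.span
            self._by_chrom.setdefault(model.chrom, ([], []))
            starts, spans = self._by_chrom[model.chrom]
            spans.append((start, end, gene_id))
        for chrom, (starts, spans) in self._by_chrom.items():
            spans.sort()
            starts[:] = [s for s, _, _ in spans]

    def find(self, chrom: str, pos: int) -> str | None:
        if chrom not in self._by_chrom:
            return None
        starts, spans = self._by_chrom[chrom]
        idx = bisect_right(starts, pos) - 1
        if idx < 0:
            return None
        start, end, gene_id = spans[idx]
        return gene_id if start <= pos <= end else None


def _line_genotype(
    variant: VariantRecord, samples: list[str]
) -> str:
    """Collapse per-sample genotypes of one line into a single class."""
    gts = {variant.genotypes.get(s, MISSING) for s in samples}
    if gts == {HOM_ALT}:
        return HOM_ALT
    if gts == {HOM_REF}:
        return HOM_REF
    if MISSING in gts and len(gts) == 1:
        return MISSING
    return HET


def filter_mutations(
    variants: Iterable[VariantRecord],
    groups: GroupTable,
    models: Mapping[str, GeneModel],
    genome: Mapping[str, str] | None,
    lines: Mapping[str, str],
    wt_line: str,
    *,
    use_annotated: bool = False,
    on_missing_wt: str = "error",
) -> list[MutationAssignment]:
    """Apply the variant-filtering cascade and return mutation assignments.

    A variant is retained iff its consequence is PTC or synonymous, it is
    homozygous-alt in a mutant line, its gene belongs to a homoeolog group,
    and the wild-type line is homozygous-ref.  ``lines`` maps VCF sample
    names to line ids; ``wt_line`` names the wild-type line.  With
    ``use_annotated`` the pre-annotated consequence on each record is
    trusted instead of calling against ``genome``; otherwise ``genome`` is
    required.  ``on_missing_wt`` is ``"error"`` (default) or ``"drop"``.
    """
    if on_missing_wt not in ("error", "drop"):
        raise ValueError(f"on_missing_wt must be 'error' or 'drop'")
    if not use_annotated and genome is None:
        raise ValueError("genome required unless use_annotated=True")

    line_samples: dict[str, list[str]] = {}
    for sample, line in lines.items():
        line_samples.setdefault(line, []).append(sample)
    if wt_line not in line_samples:
        raise ValueError(f"wild-type line {wt_line!r} has no samples")
    mutant_lines = [l for l in line_samples if l != wt_line]

    locator = _GeneLocator(models)
    assignments: list[MutationAssignment] = []
    n_in = n_no_gene = n_consequence = n_group = n_not_hom = n_wt = 0
    for variant in variants:
        n_in += 1
        gene_id = locator.find(variant.chrom, variant.pos)
        if gene_id is None:
            logger.debug("variant %s:%d in no gene, dropped",
                         variant.chrom, variant.pos)
            n_no_gene += 1
            continue
        model = models[gene_id]
        if use_annotated:
            consequence = variant.consequence
            if consequence is None:
                raise ValueError(
                    f"variant {variant.chrom}:{variant.pos} lacks the "
                    f"annotated consequence required by use_annotated=True"
                )
        else:
            consequence = call_consequence(variant, model, genome)
        if consequence not in (PTC, SYNONYMOUS):
            n_consequence += 1
            continue
        membership = groups.lookup(gene_id)
        if membership is None:
            n_group += 1
            continue
        group_id, subgenome = membership
        wt_gt = _line_genotype(variant, line_samples[wt_line])
        if wt_gt == MISSING:
            if on_missing_wt == "error":
                raise ValueError(
                    f"variant {variant.chrom}:{variant.pos} has no wild-type "
                    f"genotype"
                )
            n_wt += 1
            continue
        if wt_gt != HOM_REF:
            n_wt += 1
            continue
        cds_pos = model.cds_offset(variant.pos)
        retained_any = False
        for line in mutant_lines:
            if _line_genotype(variant, line_samples[line]) != HOM_ALT:
                continue
            retained_any = True
            assignments.append(
                MutationAssignment(
                    line=line,
                    gene=gene_id,
                    group_id=group_id,
                    subgenome=subgenome,
                    consequence=consequence,
                    cds_pos=cds_pos,
                )
            )
        if not retained_any:
            n_not_hom += 1
    logger.info(
        "filter_mutations: %d in, %d no-gene, %d consequence-filtered, "
        "%d not-in-group, %d WT-filtered, %d not-homozygous, %d assignments",
        n_in, n_no_gene, n_consequence, n_group, n_wt, n_not_hom,
        len(assignments),
    )
    return _dedupe(assignments)


def _dedupe(assignments: list[MutationAssignment]) -> list[MutationAssignment]:
    """One assignment per (line, gene); PTC beats synonymous, then 5'-most."""
    best: dict[tuple[str, str], MutationAssignment] = {}
    for a in assignments:
        key = (a.line, a.gene)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            continue
        rank = lambda x: (0 if x.consequence == PTC else 1, x.cds_pos)
        if rank(a) < rank(cur):
            best[key] = a
    return list(best.values())


def assign_groups(assignments: Iterable[MutationAssignment]) -> GroupAssignment:
    """Group assignments into analyzable per-(line, group) contexts.

    A context is analyzable iff exactly one homoeolog of the group carries a
    qualifying mutation in that line; (line, group) pairs with more than one
    mutated homoeolog are excluded and counted, regardless of class mix
    (so a group with a PTC in one homoeolog and a synonymous change in
    another never enters the synonymous set).
    """
    by_context: dict[tuple[str, str], list[MutationAssignment]] = {}
    for a in assignments:
        by_context.setdefault((a.line, a.group_id), []).append(a)
    contexts: list[MutationContext] = []
    excluded: list[tuple[str, str]] = []
    for (line, group_id), members in sorted(by_context.items()):
        mutated_genes = {a.gene for a in members}
        if len(mutated_genes) > 1:
            logger.debug(
                "(line=%s, group=%s): %d mutated homoeologs, excluded",
                line, group_id, len(mutated_genes),
            )
            excluded.append((line, group_id))
            continue
        (a,) = members
        contexts.append(
            MutationContext(
                line=line,
                group_id=group_id,
                mutation_class=a.consequence,
                mutated_gene=a.gene,
                mutated_subgenome=a.subgenome,
            )
        )
    return GroupAssignment(contexts=contexts, excluded_multi=excluded)


# ---------------------------------------------------------------------------
# VCF I/O


def _classify_gt(allele_indices, alt_index: int) -> str:
    if allele_indices is None or any(i is None for i in allele_indices):
        return MISSING
    hits = sum(1 for i in allele_indices if i == alt_index)
    if hits == len(allele_indices):
        return HOM_ALT
    if hits > 0:
        return HET
    return HOM_REF


def read_vcf(
    path: str | Path,
    *,
    csq_key: str = "CSQ",
    csq_field: int = 1,
) -> list[VariantRecord]:
    """Read SNVs from a VCF (v4.2, plain text or bgzipped).

    Multi-allelic sites are split, one record per alt allele.  When the
    ``csq_key`` INFO field is present its ``csq_field``-th ``|``-separated
    component is mapped from VEP-style terms to internal consequence
    classes.  Non-SNV alleles are skipped with a debug log.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    logger.debug("non-SNV allele at %s:%d skipped",
                                 rec.chrom, rec.pos)
                    continue
                consequence = None
                if csq_key in rec.info:
                    raw = rec.info[csq_key]
                    if isinstance(raw, tuple):
                        raw = raw[alt_index - 1] if alt_index - 1 < len(raw) else raw[0]
                    parts = str(raw).split("|")
                    term = parts[csq_field] if len(parts) > csq_field else parts[0]
                    consequence = VEP_TERMS.get(term, OTHER)
                genotypes = {
                    s: _classify_gt(rec.samples[s].get("GT"), alt_index)
                    for s in samples
                }
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotypes=genotypes,
                        consequence=consequence,
                    )
                )
    return records


_GT_TO_VCF = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    *,
    contigs: Mapping[str, int] | None = None,
    csq_key: str = "CSQ",
) -> None:
    """Write SNVs as a plain-text VCF v4.2 with GT and a VEP-like CSQ INFO."""
    records = list(records)
    samples: list[str] = []
    for rec in records:
        for s in rec.genotypes:
            if s not in samples:
                samples.append(s)
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                handle.write(f"##contig=<ID={name},length={length}>\n")
        handle.write(
            f'##INFO=<ID={csq_key},Number=.,Type=String,'
            f'Description="Consequence annotation: Allele|Consequence">\n'
        )
        handle.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            info = "."
            if rec.consequence is not None:
                term = _TO_VEP.get(rec.consequence, rec.consequence)
                info = f"{csq_key}={rec.alt}|{term}"
            gts = "\t".join(
                _GT_TO_VCF[rec.genotypes.get(s, MISSING)] for s in samples
            )
            handle.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                f"{info}\tGT\t{gts}\n"
            )
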