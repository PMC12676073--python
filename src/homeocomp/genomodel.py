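"""Homoeolog group tables and gene models.

Homoeolog groups map a group id to one gene per subgenome: triads (A/B/D)
in hexaploid material, dyads (A/B) in tetraploid material.  Gene models
carry the ordered CDS intervals needed for consequence calling.

Coordinates follow the GFF3 convention (1-based, inclusive) at the file
boundary; everything exposed by :func:`cds_offset` downstream is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

SUBGENOMES = ("A", "B", "D")

__all__ = [
    "HomoeologGroup",
    "GroupTable",
    "GeneModel",
    "read_groups",
    "write_groups",
    "read_genome",
    "write_genome",
    "read_gene_models",
    "write_gene_models",
    "cds_sequence",
]


class GroupTableError(ValueError):
    """Raised for malformed homoeolog group tables."""


@dataclass(frozen=True)
class HomoeologGroup:
    """A strict 1:1(:1) homoeolog group."""

    group_id: str
    members: Mapping[str, str]  # subgenome -> gene id

    def __post_init__(self) -> None:
        if not 2 <= len(self.members) <= 3:
            raise GroupTableError(
                f"group {self.group_id!r}: expected 2 or 3 members, "
                f"got {len(self.members)}"
            )
        for sub in self.members:
            if sub not in SUBGENOMES:
                raise GroupTableError(
                    f"group {self.group_id!r}: unknown subgenome {sub!r}"
                )
        genes = list(self.members.values())
        if len(set(genes)) != len(genes):
            raise GroupTableError(
                f"group {self.group_id!r}: duplicate gene id within group"
            )

    @property
    def cardinality(self) -> str:
        return "triad" if len(self.members) == 3 else "dyad"

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.members[s] for s in SUBGENOMES if s in self.members)


class GroupTable:
    """A set of homoeolog groups with a total gene -> (group, subgenome) lookup."""

    def __init__(self, groups: Iterable[HomoeologGroup]):
        self.groups: dict[str, HomoeologGroup] = {}
        self._gene_index: dict[str, tuple[str, str]] = {}
        for group in groups:
            if group.group_id in self.groups:
                raise GroupTableError(f"duplicate group id {group.group_id!r}")
            for sub, gene in group.members.items():
                if gene in self._gene_index:
                    other, _ = self._gene_index[gene]
                    raise GroupTableError(
                        f"gene {gene!r} appears in groups {other!r} and "
                        f"{group.group_id!r}"
                    )
                self._gene_index[gene] = (group.group_id, sub)
            self.groups[group.group_id] = group

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups.values())

    def __contains__(self, group_id: str) -> bool:
        return group_id in self.groups

    def __getitem__(self, group_id: str) -> HomoeologGroup:
        return self.groups[group_id]

    def lookup(self, gene_id: str) -> tuple[str, str] | None:
        """Return (group_id, subgenome) for a member gene, else None."""
        return self._gene_index.get(gene_id)

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupTable) and self.groups == other.groups


def read_groups(path: str | Path) -> GroupTable:
    """Read a homoeolog group TSV (group_id, gene_A, gene_B, gene_D).

    An empty gene_D column yields a dyad.  Duplicate gene ids across groups,
    malformed rows and groups with fewer than two members are rejected.
    """
    path = Path(path)
    groups: list[HomoeologGroup] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["group_id", "gene_A", "gene_B", "gene_D"]
        if header != expected:
            raise GroupTableError(
                f"{path}: expected header {expected!r}, got {header!r}"
            )
        for lineno, raw in enumerate(handle, start=2):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise GroupTableError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            group_id, *genes = fields
            members = {
                sub: gene
                for sub, gene in zip(SUBGENOMES, genes)
                if gene.strip()
            }
            if len(members) < 2:
                raise GroupTableError(
                    f"{path}:{lineno}: group {group_id!r} has fewer than 2 members"
                )
            groups.append(HomoeologGroup(group_id, members))
    return GroupTable(groups)


def write_groups(table: GroupTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("group_id\tgene_A\tgene_B\tgene_D\n")
        for group in table:
            row = [group.group_id] + [
                group.members.get(sub, "") for sub in SUBGENOMES
            ]
            handle.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Gene models


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model.

    ``cds`` holds 1-based inclusive genomic intervals sorted by genomic
    start; transcript orientation is resolved by :func:`cds_sequence`.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        intervals = sorted(self.cds)
        object.__setattr__(self, "cds", tuple(intervals))
        last_end = 0
        for start, end in intervals:
            if start < 1 or end < start:
                raise ValueError(
                    f"{self.gene_id}: invalid CDS interval ({start}, {end})"
                )
            if start <= last_end:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
            last_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds)

    @property
    def frame_complete(self) -> bool:
        return self.cds_length % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic position ``pos`` within the spliced CDS,
        in transcript orientation; None when the position is not in the CDS."""
        offset = 0
        for start, end in self.cds:
            if start <= pos <= end:
                genomic_offset = offset + (pos - start)
                if self.strand == "+":
                    return genomic_offset
                return self.cds_length - 1 - genomic_offset
            offset += end - start + 1
        return None


def cds_sequence(model: GeneModel, genome: Mapping[str, str]) -> str:
    """Spliced CDS of ``model`` in transcript orientation.

    Minus-strand models are reverse-complemented so the returned string
    starts at the annotated start codon.
    """
    try:
        chrom_seq = genome[model.chrom]
    except KeyError:
        raise KeyError(f"{model.gene_id}: chromosome {model.chrom!r} not in genome")
    _, end = model.span
    if end > len(chrom_seq):
        raise ValueError(
            f"{model.gene_id}: CDS extends to {end} beyond chromosome "
            f"{model.chrom!r} length {len(chrom_seq)}"
        )
    parts = [chrom_seq[start - 1 : stop] for start, stop in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a (possibly line-wrapped, multi-record) FASTA into a dict."""
    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon/CDS).

    CDS features are grouped per gene via their mRNA parent; one transcript
    per gene is assumed (the first mRNA wins, others are logged and skipped).
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    cds_by_mrna: dict[str, list] = {}
    with open(path) as handle:
        for raw in handle:
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {raw!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attributes = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            if ftype == "gene":
                gene_id = attributes["ID"]
                genes[gene_id] = {"chrom": chrom, "strand": strand}
            elif ftype == "mRNA":
                parent = attributes["Parent"]
                if parent in set(mrna_to_gene.values()):
                    logger.debug("extra transcript %s for gene %s skipped",
                                 attributes["ID"], parent)
                    continue
                mrna_to_gene[attributes["ID"]] = parent
            elif ftype == "CDS":
                parent = attributes["Parent"]
                cds_by_mrna.setdefault(parent, []).append(
                    (int(start), int(end))
                )
    models: dict[str, GeneModel] = {}
    for mrna, gene_id in mrna_to_gene.items():
        intervals = cds_by_mrna.get(mrna)
        if not intervals:
            continue
        info = genes[gene_id]
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=info["chrom"],
            strand=info["strand"],
            cds=tuple(sorted(intervals)),
        )
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 with gene/mRNA/exon/CDS rows."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene_id in sorted(models):
            model = models[gene_id]
            start, end = model.span
            base = f"{model.chrom}\thomeocomp"
            handle.write(
                f"{base}\tgene\t{start}\t{end}\t.\t{model.strand}\t.\t"
                f"ID={gene_id}\n"
            )
            mrna_id = f"{gene_id}.1"
            handle.write(
                f"{base}\tmRNA\t{start}\t{end}\t.\t{model.strand}\t.\t"
                f"ID={mrna_id};Parent={gene_id}\n"
            )
            # phase bookkeeping for CDS rows, in transcript orientation
            intervals = list(model.cds)
            ordered = intervals if model.strand == "+" else intervals[::-1]
            phase = 0
            phases = {}
            for s, e in ordered:
                phases[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e) in enumerate(intervals, start=1):
                handle.write(
                    f"{base}\texon\t{s}\t{e}\t.\t{model.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
                handle.write(
                    f"{base}\tCDS\t{s}\t{e}\t.\t{model.strand}\t"
                    f"{phases[(s, e)]}\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )
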