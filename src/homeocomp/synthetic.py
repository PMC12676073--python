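"""Synthetic experiment generator with known ground truth.

Emits everything the downstream stages consume — a count matrix, a variant
table, homoeolog group definitions, gene models with a matching genome —
plus the simulated truth, so the whole pipeline is testable without
external data.  Groups are triads (hexaploid) or dyads (tetraploid); a
configurable fraction carry an EMS-style (G>A / C>T) homozygous mutation
in exactly one homoeolog, split into a PTC class (downregulated by an
NMD-like fold in the mutant) and a synonymous class.  A configurable
fraction of PTC groups are truly compensated: their non-mutated homoeologs
are upregulated by a fixed fold.  Counts are negative-binomial with
variance = mu + dispersion * mu^2.

The same seed always produces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexp import CountMatrix
from .genomodel import (
    GeneModel,
    GroupTable,
    HomoeologGroup,
    write_gene_models,
    write_genome,
    write_groups,
)
from .variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    PTC,
    SYNONYMOUS,
    VariantRecord,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "simulate_experiment",
    "write_fixtures",
    "read_truth",
]

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
)

# (reference codon, offset within codon, ref base, alt base) — all EMS
# transitions (G>A or C>T on the coding strand) with the stated outcome.
_PTC_TEMPLATES = (
    ("TGG", 1, "G", "A"),  # TGG -> TAG, Trp -> stop
    ("TGG", 2, "G", "A"),  # TGG -> TGA, Trp -> stop
    ("CAG", 0, "C", "T"),  # CAG -> TAG, Gln -> stop
    ("CAA", 0, "C", "T"),  # CAA -> TAA, Gln -> stop
    ("CGA", 0, "C", "T"),  # CGA -> TGA, Arg -> stop
)
_SYN_TEMPLATES = (
    ("CTG", 2, "G", "A"),  # Leu -> Leu
    ("GTG", 2, "G", "A"),  # Val -> Val
    ("GCC", 2, "C", "T"),  # Ala -> Ala
    ("ACC", 2, "C", "T"),  # Thr -> Thr
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

NONE_CLASS = "none"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulated experiment; invalid fields are reported
    by name via :meth:`validate` (called by :func:`simulate_experiment`)."""

    ploidy_mode: str = "hexaploid"
    n_groups: int = 100
    n_replicates: int = 3
    baseline_mean_log2_range: tuple[float, float] = (6.0, 10.0)
    nb_dispersion: float = 0.05
    library_size_factors: tuple[float, ...] | None = None
    ptc_fraction: float = 0.5
    syn_fraction: float = 0.25
    nmd_fold: float = 0.1
    compensation_rate: float = 0.0
    compensation_fold: float = 2.0
    syn_compensation_rate: float = 0.0
    wt_shared_snp_rate: float = 0.0
    heterozygous_rate: float = 0.0
    line_id: str = "mut1"
    min_codons: int = 40
    max_codons: int = 80
    seed: int = 0

    @property
    def subgenomes(self) -> tuple[str, ...]:
        return ("A", "B", "D") if self.ploidy_mode == "hexaploid" else ("A", "B")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_replicates

    def validate(self) -> None:
        if self.ploidy_mode not in ("hexaploid", "tetraploid"):
            raise ValueError(f"ploidy_mode: got {self.ploidy_mode!r}")
        if not (isinstance(self.n_groups, int) and self.n_groups > 0):
            raise ValueError(f"n_groups: must be a positive integer")
        if not (isinstance(self.n_replicates, int) and self.n_replicates > 0):
            raise ValueError("n_replicates: must be a positive integer")
        lo, hi = self.baseline_mean_log2_range
        if not lo <= hi:
            raise ValueError("baseline_mean_log2_range: low must be <= high")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion: must be >= 0")
        if self.library_size_factors is not None:
            if len(self.library_size_factors) != self.n_samples:
                raise ValueError(
                    f"library_size_factors: expected {self.n_samples} values"
                )
            if any(s <= 0 for s in self.library_size_factors):
                raise ValueError("library_size_factors: must be positive")
        for name in ("ptc_fraction", "syn_fraction", "compensation_rate",
                     "syn_compensation_rate", "wt_shared_snp_rate",
                     "heterozygous_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {value}")
        if self.ptc_fraction + self.syn_fraction > 1.0 + 1e-12:
            raise ValueError("ptc_fraction + syn_fraction: must be <= 1")
        if not 0.0 < self.nmd_fold <= 1.0:
            raise ValueError(f"nmd_fold: must be in (0, 1], got {self.nmd_fold}")
        if self.compensation_fold < 1.0:
            raise ValueError("compensation_fold: must be >= 1")
        if not 3 <= self.min_codons <= self.max_codons:
            raise ValueError("min_codons/max_codons: need 3 <= min <= max")


@dataclass
class SimulatedExperiment:
    """Outputs of :func:`simulate_experiment`."""

    config: SimulationConfig
    counts: CountMatrix
    variants: list[VariantRecord]
    groups: GroupTable
    models: dict[str, GeneModel]
    genome: dict[str, str]
    truth: pd.DataFrame  # one row per group


def _genomic_position(model: GeneModel, cds_offset: int) -> int:
    """Inverse of GeneModel.cds_offset for in-CDS offsets."""
    genomic_offset = (
        cds_offset if model.strand == "+" else model.cds_length - 1 - cds_offset
    )
    for start, end in model.cds:
        width = end - start + 1
        if genomic_offset < width:
            return start + genomic_offset
        genomic_offset -= width
    raise IndexError(f"{model.gene_id}: CDS offset {cds_offset} out of range")


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    chrom_offset: int,
    n_codons: int,
    override: tuple[int, str] | None,
) -> tuple[GeneModel, str, int]:
    """Lay one gene down at ``chrom_offset`` (0-based); returns the model,
    the genomic locus sequence and the next free offset.

    ``override`` optionally replaces the codon at a given index with a
    fixed codon (used to stage mutation sites).
    """
    codons = [_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons - 2)]
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    cds_codons = ["ATG"] + codons + [stop]
    if override is not None:
        idx, codon = override
        cds_codons[idx] = codon
    cds = "".join(cds_codons)

    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(1, len(cds)), n_exons - 1, replace=False)) \
        if n_exons > 1 else []
    bounds = [0, *map(int, cuts), len(cds)]
    exon_lengths = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    intron_lengths = [int(rng.integers(20, 51)) for _ in range(n_exons - 1)]
    strand = "+" if rng.random() < 0.5 else "-"

    # locus in transcript orientation: exons interleaved with introns
    pieces = []
    pos = 0
    for i, elen in enumerate(exon_lengths):
        pieces.append(cds[pos : pos + elen])
        pos += elen
        if i < n_exons - 1:
            intron = "".join(
                "ACGT"[j] for j in rng.integers(0, 4, intron_lengths[i])
            )
            pieces.append(intron)
    locus_tx = "".join(pieces)
    locus = locus_tx if strand == "+" else locus_tx.translate(_COMPLEMENT)[::-1]
    locus_len = len(locus)
    start_1based = chrom_offset + 1

    # exon positions within the transcript-oriented locus
    intervals = []
    cursor = 0
    for i, elen in enumerate(exon_lengths):
        tx_start = cursor
        tx_end = cursor + elen  # half-open in locus_tx coordinates
        if strand == "+":
            intervals.append((start_1based + tx_start, start_1based + tx_end - 1))
        else:
            intervals.append(
                (
                    start_1based + locus_len - tx_end,
                    start_1based + locus_len - tx_start - 1,
                )
            )
        cursor = tx_end + (intron_lengths[i] if i < n_exons - 1 else 0)

    model = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, cds=tuple(sorted(intervals))
    )
    return model, locus, chrom_offset + locus_len + 50  # 50 bp spacer


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a complete synthetic experiment from ``config``.

    The mutant line carries exactly one focal EMS mutation per affected
    group, placed so that the generator's intended consequence (PTC or
    synonymous) is independently recoverable from the emitted gene models
    and genome.  Counts are NB draws with mean
    baseline * genotype effect * library size factor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subs = config.subgenomes
    n = config.n_groups

    # class assignment: first ptc groups, then syn, rest untouched — via a
    # seeded permutation so classes are not position-correlated
    n_ptc = int(round(config.ptc_fraction * n))
    n_syn = int(round(config.syn_fraction * n))
    n_syn = min(n_syn, n - n_ptc)
    order = rng.permutation(n)
    classes = np.array([NONE_CLASS] * n, dtype=object)
    classes[order[:n_ptc]] = PTC
    classes[order[n_ptc : n_ptc + n_syn]] = SYNONYMOUS

    mutated_sub = rng.integers(0, len(subs), n)
    compensated = np.zeros(n, dtype=bool)
    compensated[classes == PTC] = (
        rng.random((classes == PTC).sum()) < config.compensation_rate
    )
    compensated[classes == SYNONYMOUS] = (
        rng.random((classes == SYNONYMOUS).sum()) < config.syn_compensation_rate
    )

    groups: list[HomoeologGroup] = []
    models: dict[str, GeneModel] = {}
    chrom_seqs: dict[str, list[str]] = {f"chr{s}": [] for s in subs}
    chrom_offsets: dict[str, int] = {f"chr{s}": 0 for s in subs}
    variants: list[VariantRecord] = []
    truth_rows = []
    gene_order: list[str] = []

    for g in range(n):
        group_id = f"hg{g + 1:04d}"
        members = {}
        mut_sub = subs[mutated_sub[g]]
        cls = str(classes[g])
        mutated_gene = ""
        for sub in subs:
            gene_id = f"{group_id}_{sub}"
            members[sub] = gene_id
            gene_order.append(gene_id)
            chrom = f"chr{sub}"
            n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
            override = None
            template = None
            if cls != NONE_CLASS and sub == mut_sub:
                templates = _PTC_TEMPLATES if cls == PTC else _SYN_TEMPLATES
                template = templates[rng.integers(0, len(templates))]
                codon_idx = int(rng.integers(1, n_codons - 1))
                override = (codon_idx, template[0])
            model, locus, next_offset = _build_gene(
                rng,
                gene_id,
                chrom,
                chrom_offsets[chrom],
                n_codons,
                override,
            )
            chrom_seqs[chrom].append(locus + "N" * 50)
            chrom_offsets[chrom] = next_offset
            models[gene_id] = model
            if template is not None:
                mutated_gene = gene_id
                codon_idx, _ = override
                _, within, ref_cds, alt_cds = template
                cds_offset = 3 * codon_idx + within
                pos = _genomic_position(model, cds_offset)
                if model.strand == "+":
                    ref, alt = ref_cds, alt_cds
                else:
                    ref = ref_cds.translate(_COMPLEMENT)
                    alt = alt_cds.translate(_COMPLEMENT)
                mut_gt = (
                    HET if rng.random() < config.heterozygous_rate else HOM_ALT
                )
                wt_gt = (
                    HOM_ALT
                    if rng.random() < config.wt_shared_snp_rate
                    else HOM_REF
                )
                variants.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        genotypes={"WT": wt_gt, config.line_id: mut_gt},
                        consequence=cls,
                    )
                )
        groups.append(HomoeologGroup(group_id, members))
        folds = {}
        for sub in subs:
            fold = 1.0
            if cls == PTC and sub == mut_sub:
                fold = config.nmd_fold
            elif cls != NONE_CLASS and compensated[g] and sub != mut_sub:
                fold = config.compensation_fold
            folds[sub] = fold
        truth_rows.append(
            {
                "group_id": group_id,
                "mutation_class": cls,
                "mutated_subgenome": mut_sub if cls != NONE_CLASS else "",
                "mutated_gene": mutated_gene,
                "compensated": bool(compensated[g]) if cls != NONE_CLASS else False,
                **{f"fold_{sub}": folds[sub] for sub in subs},
            }
        )

    truth = pd.DataFrame(truth_rows)
    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}

    # ----- counts -----
    n_genes = len(gene_order)
    sample_names = [f"WT_{r + 1}" for r in range(config.n_replicates)] + [
        f"{config.line_id}_{r + 1}" for r in range(config.n_replicates)
    ]
    genotypes = ["WT"] * config.n_replicates + [config.line_id] * config.n_replicates
    size_factors = (
        np.asarray(config.library_size_factors, dtype=float)
        if config.library_size_factors is not None
        else np.ones(config.n_samples)
    )
    lo, hi = config.baseline_mean_log2_range
    baseline = 2.0 ** rng.uniform(lo, hi, n_genes)
    fold_lookup = {}
    for row in truth_rows:
        for sub in subs:
            fold_lookup[f"{row['group_id']}_{sub}"] = row[f"fold_{sub}"]
    genotype_fold = np.array([fold_lookup[g] for g in gene_order])
    mean = baseline[:, None] * np.where(
        np.array(genotypes) == "WT", 1.0, genotype_fold[:, None]
    )
    mean = mean * size_factors[None, :]
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(shape, shape / (shape + mean))
    else:
        counts = rng.poisson(mean)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_order, name="gene_id"), columns=sample_names
    )
    samples_df = pd.DataFrame(
        {
            "genotype": genotypes,
            "replicate": list(range(1, config.n_replicates + 1)) * 2,
        },
        index=pd.Index(sample_names, name="sample"),
    )
    matrix = CountMatrix(counts=counts_df, samples=samples_df)

    return SimulatedExperiment(
        config=config,
        counts=matrix,
        variants=variants,
        groups=GroupTable(groups),
        models=models,
        genome=genome,
        truth=truth,
    )


def write_fixtures(experiment: SimulatedExperiment, directory: str | Path) -> dict[str, Path]:
    """Write all outputs as plain-text fixtures that round-trip through the
    package readers; returns the mapping of artefact name to path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "variants": directory / "variants.vcf",
        "groups": directory / "groups.tsv",
        "gene_models": directory / "genes.gff3",
        "genome": directory / "genome.fa",
        "truth": directory / "truth.tsv",
    }
    experiment.counts.to_tsv(paths["counts"], paths["samples"])
    contigs = {name: len(seq) for name, seq in experiment.genome.items()}
    write_vcf(experiment.variants, paths["variants"], contigs=contigs)
    write_groups(experiment.groups, paths["groups"])
    write_gene_models(experiment.models, paths["gene_models"])
    write_genome(experiment.genome, paths["genome"])
    experiment.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(
        path, sep="\t", dtype={"mutated_subgenome": str, "mutated_gene": str}
    )
    truth["mutated_subgenome"] = truth["mutated_subgenome"].fillna("")
    truth["mutated_gene"] = truth["mutated_gene"].fillna("")
    return truth
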