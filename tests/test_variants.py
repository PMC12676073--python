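import numpy as np
import pytest
from Bio.Seq import Seq

from homeocomp import variants as V
from homeocomp.genomodel import GeneModel
from homeocomp.synthetic import SimulationConfig, simulate_experiment
from homeocomp.variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MISSENSE,
    NON_CODING,
    OTHER,
    PTC,
    SYNONYMOUS,
    MutationAssignment,
    VariantRecord,
    assign_groups,
    call_consequence,
    filter_mutations,
)


def snv(chrom, pos, ref, alt, wt=HOM_REF, mut=HOM_ALT, consequence=None):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes={"WT": wt, "mut1": mut},
        consequence=consequence,
    )


class TestCallConsequence:
    """Single-codon examples; the codon positions assume a plain
    single-exon plus-strand model starting at position 1."""

    def model(self, cds):
        return GeneModel("g", "chr1", "+", ((1, len(cds)),))

    def test_tgg_to_tag_is_ptc(self):
        # Trp codon gaining a stop via G>A
        cds = "ATGTGGTAA"
        variant = snv("chr1", 5, "G", "A")
        assert call_consequence(variant, self.model(cds), {"chr1": cds}) == PTC

    def test_cag_to_tag_is_ptc(self):
        # Gln codon gaining a stop via C>T
        cds = "ATGCAGTAA"
        variant = snv("chr1", 4, "C", "T")
        assert call_consequence(variant, self.model(cds), {"chr1": cds}) == PTC

    def test_ctg_to_cta_synonymous(self):
        cds = "ATGCTGTAA"
        variant = snv("chr1", 6, "G", "A")
        assert (
            call_consequence(variant, self.model(cds), {"chr1": cds})
            == SYNONYMOUS
        )

    def test_missense(self):
        cds = "ATGGATTAA"  # Asp -> Asn via G>A
        variant = snv("chr1", 4, "G", "A")
        assert (
            call_consequence(variant, self.model(cds), {"chr1": cds})
            == MISSENSE
        )

    def test_outside_cds_non_coding(self):
        cds = "ATGTGGTAA"
        genome = {"chr1": cds + "GGGG"}
        variant = snv("chr1", 11, "G", "A")
        assert call_consequence(variant, self.model(cds), genome) == NON_CODING

    def test_stop_to_stop_is_other(self):
        cds = "ATGTGGTAG"  # TAG -> TAA: a different stop
        variant = snv("chr1", 9, "G", "A")
        assert call_consequence(variant, self.model(cds), {"chr1": cds}) == OTHER

    def test_start_loss_is_other(self):
        cds = "ATGTGGTAA"
        variant = snv("chr1", 3, "G", "A")
        assert call_consequence(variant, self.model(cds), {"chr1": cds}) == OTHER

    def test_frame_error_flags_model(self):
        model = GeneModel("gX", "chr1", "+", ((1, 10),))
        variant = snv("chr1", 5, "G", "A")
        with pytest.raises(V.CdsFrameError, match="gX"):
            call_consequence(variant, model, {"chr1": "ATGTGGTAAG"})

    def test_reference_mismatch_detected(self):
        cds = "ATGTGGTAA"
        variant = snv("chr1", 5, "C", "T")
        with pytest.raises(ValueError, match="mismatch"):
            call_consequence(variant, self.model(cds), {"chr1": cds})


def oracle_consequence(variant, model, genome):
    """Independent oracle: translate the full spliced CDS before and after
    the substitution and compare the proteins."""
    from homeocomp.genomodel import cds_sequence

    # brute-force genomic position -> CDS offset, walking every CDS base
    positions = []
    for start, end in model.cds:
        positions.extend(range(start, end + 1))
    if model.strand == "-":
        positions = positions[::-1]
    if variant.pos not in positions:
        return NON_CODING
    offset = positions.index(variant.pos)
    cds = cds_sequence(model, genome)
    alt = variant.alt
    if model.strand == "-":
        alt = str(Seq(alt).complement())
    new_cds = cds[:offset] + alt + cds[offset + 1 :]
    old_protein = str(Seq(cds).translate())
    new_protein = str(Seq(new_cds).translate())
    i = offset // 3
    if old_protein[i] == "*":
        return OTHER
    if i == 0 and cds[:3] == "ATG" and new_cds[:3] != "ATG":
        return OTHER
    if any(n == "*" and o != "*" for o, n in zip(old_protein, new_protein)):
        return PTC
    if new_protein == old_protein:
        return SYNONYMOUS
    return MISSENSE


class TestConsequenceOracle:
    def test_oracle_equivalence_random_snvs(self, small_experiment):
        """call_consequence agrees with full-CDS translation on >= 1000
        random SNVs over random (simulated) gene models."""
        rng = np.random.default_rng(7)
        genome = small_experiment.genome
        models = list(small_experiment.models.values())
        n_checked = 0
        while n_checked < 1000:
            model = models[rng.integers(0, len(models))]
            start, end = model.span
            pos = int(rng.integers(start, end + 1))
            ref = genome[model.chrom][pos - 1]
            if ref not in "ACGT":
                continue
            alt = "ACGT"[rng.integers(0, 4)]
            if alt == ref:
                continue
            variant = snv(model.chrom, pos, ref, alt)
            assert call_consequence(variant, model, genome) == oracle_consequence(
                variant, model, genome
            ), f"{model.gene_id} {pos} {ref}>{alt}"
            n_checked += 1


def toy_setup(tmp_path):
    """Two triads on one chromosome with hand-placed codons."""
    from homeocomp.genomodel import GroupTable, HomoeologGroup

    #            gene a1: ATG TGG TAA  (PTC-able at pos 5 G>A)
    #            gene b1: ATG CTG TAA  (synonymous at pos 15+6 G>A)
    chrom = "ATGTGGTAA" + "N" + "ATGCTGTAA" + "N" + "ATGGATTAA"
    genome = {"c": chrom}
    models = {
        "a1": GeneModel("a1", "c", "+", ((1, 9),)),
        "b1": GeneModel("b1", "c", "+", ((11, 19),)),
        "d1": GeneModel("d1", "c", "+", ((21, 29),)),
    }
    groups = GroupTable([HomoeologGroup("g1", {"A": "a1", "B": "b1", "D": "d1"})])
    return genome, models, groups


class TestFilterMutations:
    lines = {"WT": "WT", "mut1": "mut1"}

    def test_retained_ptc(self, tmp_path):
        genome, models, groups = toy_setup(tmp_path)
        out = filter_mutations(
            [snv("c", 5, "G", "A")], groups, models, genome, self.lines, "WT"
        )
        assert len(out) == 1
        a = out[0]
        assert (a.line, a.gene, a.group_id, a.subgenome, a.consequence) == (
            "mut1", "a1", "g1", "A", PTC,
        )
        assert a.cds_pos == 4

    def test_wt_shared_removed(self, tmp_path):
        genome, models, groups = toy_setup(tmp_path)
        out = filter_mutations(
            [snv("c", 5, "G", "A", wt=HOM_ALT)],
            groups, models, genome, self.lines, "WT",
        )
        assert out == []

    def test_heterozygous_removed(self, tmp_path):
        genome, models, groups = toy_setup(tmp_path)
        out = filter_mutations(
            [snv("c", 5, "G", "A", mut=HET)],
            groups, models, genome, self.lines, "WT",
        )
        assert out == []

    def test_missense_removed(self, tmp_path):
        genome, models, groups = toy_setup(tmp_path)
        out = filter_mutations(
            [snv("c", 24, "G", "A")], groups, models, genome, self.lines, "WT"
        )
        assert out == []

    def test_intergenic_dropped_silently(self, tmp_path):
        genome, models, groups = toy_setup(tmp_path)
        out = filter_mutations(
            [snv("c", 10, "G", "A"), snv("c", 5, "G", "A")],
            groups, models, genome, self.lines, "WT",
        )
        assert [a.gene for a in out] == ["a1"]

    def test_missing_wt_genotype_errors_by_default(self, tmp_path):
        genome, models, groups = toy_setup(tmp_path)
        rec = snv("c", 5, "G", "A", wt=MISSING)
        with pytest.raises(ValueError, match="wild-type"):
            filter_mutations([rec], groups, models, genome, self.lines, "WT")
        assert filter_mutations(
            [rec], groups, models, genome, self.lines, "WT",
            on_missing_wt="drop",
        ) == []

    def test_monotone_subset(self, tmp_path):
        genome, models, groups = toy_setup(tmp_path)
        records = [
            snv("c", 5, "G", "A"),
            snv("c", 16, "G", "A"),
            snv("c", 24, "G", "A"),
            snv("c", 5, "G", "A", wt=HOM_ALT),
        ]
        out = filter_mutations(records, groups, models, genome, self.lines, "WT")
        genes_in = {"a1", "b1", "d1"}
        assert {a.gene for a in out} <= genes_in
        assert len(out) <= len(records)

    def test_annotated_consequence_path(self, tmp_path):
        genome, models, groups = toy_setup(tmp_path)
        rec = snv("c", 5, "G", "A", consequence=PTC)
        out = filter_mutations(
            [rec], groups, models, None, self.lines, "WT", use_annotated=True
        )
        assert len(out) == 1 and out[0].consequence == PTC


class TestAssignGroups:
    def make(self, line, gene, group, sub, cls, pos=0):
        return MutationAssignment(line, gene, group, sub, cls, pos)

    def test_single_ptc_context(self):
        result = assign_groups([self.make("l1", "a1", "g1", "A", PTC)])
        assert len(result.contexts) == 1
        ctx = result.contexts[0]
        assert ctx.mutation_class == PTC
        assert ctx.mutated_subgenome == "A"

    def test_two_mutated_homoeologs_excluded(self):
        result = assign_groups(
            [
                self.make("l1", "a1", "g1", "A", PTC),
                self.make("l1", "b1", "g1", "B", PTC),
            ]
        )
        assert result.contexts == []
        assert result.excluded_multi == [("l1", "g1")]

    def test_ptc_and_synonymous_mix_excluded_entirely(self):
        result = assign_groups(
            [
                self.make("l1", "a1", "g1", "A", PTC),
                self.make("l1", "b1", "g1", "B", SYNONYMOUS),
            ]
        )
        assert result.contexts == []
        assert result.n_excluded == 1

    def test_same_group_two_lines_two_contexts(self):
        result = assign_groups(
            [
                self.make("l1", "a1", "g1", "A", PTC),
                self.make("l2", "a1", "g1", "A", PTC),
            ]
        )
        assert len(result.contexts) == 2
        assert {c.line for c in result.contexts} == {"l1", "l2"}
        assert {c.group_id for c in result.contexts} == {"g1"}


class TestTruthRecovery:
    def test_clean_synthetic_recovery(self):
        config = SimulationConfig(
            n_groups=80, ptc_fraction=0.4, syn_fraction=0.4,
            wt_shared_snp_rate=0.0, heterozygous_rate=0.0, seed=9,
        )
        exp = simulate_experiment(config)
        assignments = filter_mutations(
            exp.variants, exp.groups, exp.models, exp.genome,
            {"WT": "WT", "mut1": "mut1"}, "WT",
        )
        grouped = assign_groups(assignments)
        got = {
            (c.group_id, c.mutated_subgenome, c.mutation_class)
            for c in grouped.contexts
        }
        truth = exp.truth[exp.truth.mutation_class != "none"]
        want = {
            (r.group_id, r.mutated_subgenome, r.mutation_class)
            for r in truth.itertuples()
        }
        assert got == want

    def test_wt_shared_saturation(self):
        config = SimulationConfig(
            n_groups=30, ptc_fraction=0.5, syn_fraction=0.5,
            wt_shared_snp_rate=1.0, seed=9,
        )
        exp = simulate_experiment(config)
        assert len(exp.variants) == 30
        assignments = filter_mutations(
            exp.variants, exp.groups, exp.models, exp.genome,
            {"WT": "WT", "mut1": "mut1"}, "WT",
        )
        assert assignments == []


class TestVcfRoundTrip:
    def test_read_back_equals_written(self, small_experiment, tmp_path):
        from homeocomp.variants import read_vcf, write_vcf

        path = tmp_path / "v.vcf"
        write_vcf(small_experiment.variants, path)
        back = read_vcf(path)
        assert sorted(back, key=lambda r: (r.chrom, r.pos)) == sorted(
            small_experiment.variants, key=lambda r: (r.chrom, r.pos)
        )
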