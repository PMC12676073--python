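"""End-to-end orchestration: variants -> DE -> compensation -> bias.

The stages communicate through TSV intermediates (so externally produced
DE results can be substituted) and the run ends in a single versioned JSON
report.  Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compensation, diffexp, expression_bias, variants as variants_mod
from .diffexp import CountMatrix, DEResult, de_table
from .genomodel import read_gene_models, read_genome, read_groups
from .variants import MutationContext

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts_path: str | Path
    samples_path: str | Path
    variants_path: str | Path
    groups_path: str | Path
    gff3_path: str | Path | None = None
    fasta_path: str | Path | None = None
    out_dir: str | Path = "homeocomp_out"
    ploidy_mode: str = "hexaploid"
    wt_line: str = "WT"
    alpha: float = 0.05
    yates: bool = True
    bias_min_tpm: float = expression_bias.DEFAULT_MIN_TPM
    use_annotated_consequence: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        required = [self.counts_path, self.samples_path, self.variants_path,
                    self.groups_path]
        if not self.use_annotated_consequence:
            if self.gff3_path is None or self.fasta_path is None:
                raise ValueError(
                    "gff3_path and fasta_path are required unless "
                    "use_annotated_consequence is set"
                )
        for path in required + [self.gff3_path, self.fasta_path]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(str(path))


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return decorate


@_stage("variants")
def _stage_variants(config: PipelineConfig, counts: CountMatrix):
    groups = read_groups(config.groups_path)
    models = read_gene_models(config.gff3_path) if config.gff3_path else {}
    genome = read_genome(config.fasta_path) if config.fasta_path else None
    records = variants_mod.read_vcf(config.variants_path)
    if not records:
        raise ValueError("variant table is empty")
    vcf_lines = set()
    for rec in records:
        vcf_lines.update(rec.genotypes)
    line_map = {s: s for s in vcf_lines}
    assignments = variants_mod.filter_mutations(
        records,
        groups,
        models,
        genome,
        line_map,
        config.wt_line,
        use_annotated=config.use_annotated_consequence,
    )
    grouped = variants_mod.assign_groups(assignments)
    logger.info(
        "variants: %d records, %d assignments, %d contexts, %d multi-mutated "
        "groups excluded",
        len(records), len(assignments), len(grouped.contexts), grouped.n_excluded,
    )
    return groups, models, assignments, grouped


@_stage("diffexp")
def _stage_diffexp(config: PipelineConfig, counts: CountMatrix, lines: list[str]):
    results: dict[str, list[DEResult]] = {}
    for line in lines:
        results[line] = diffexp.run_de(
            counts, line, config.wt_line, alpha=config.alpha
        )
        n_sig = sum(1 for r in results[line] if r.status != diffexp.NO_CHANGE)
        logger.info("diffexp: line %s, %d/%d genes significant",
                    line, n_sig, len(results[line]))
    return results

@_stage("compensation")
def _stage_compensation(config, groups, grouped, de_results):
    calls = []
    for context in grouped.contexts:
        if context.line not in de_results:
            logger.debug("context line %s has no expression data", context.line)
            continue
        per_gene = {r.gene: r for r in de_results[context.line]}
        calls.append(
            compensation.call_group(context, groups[context.group_id], per_gene)
        )
    if not calls:
        raise ValueError("no analyzable (line, group) contexts")
    summary = compensation.summarize(calls)
    try:
        comparison = compensation.compare_classes(summary, yates=config.yates)
    except ValueError as exc:
        logger.warning("class comparison skipped: %s", exc)
        comparison = None
    return calls, summary, comparison


@_stage("expression_bias")
def _stage_bias(config: PipelineConfig, counts: CountMatrix, groups, models):
    if not models:
        logger.warning("no gene models; skipping TPM-based bias classification")
        return []
    lengths = {gene_id: m.cds_length for gene_id, m in models.items()}
    known = [g for g in counts.counts.index if g in lengths]
    tpm = expression_bias.tpm_from_counts(
        counts.counts.loc[known], pd.Series(lengths)
    )
    wt_samples = counts.condition_samples(config.wt_line)
    expected_dim = 3 if config.ploidy_mode == "hexaploid" else 2
    rows = []
    for group in groups:
        if len(group.members) != expected_dim:
            raise ValueError(
                f"group {group.group_id} has {len(group.members)} members; "
                f"{config.ploidy_mode} mode expects {expected_dim}"
            )
        vector = expression_bias.bias_vector(
            group, tpm, wt_samples, min_tpm=config.bias_min_tpm
        )
        if vector.classifiable:
            category = expression_bias.classify_bias(vector)
            label, distance, tie = category.label, category.distance, category.tie
        else:
            label, distance, tie = "not_classifiable", np.nan, False
        rows.append(
            {
                "group_id": group.group_id,
                **{
                    f"share_{sub}": share
                    for sub, share in zip(vector.subgenomes, vector.shares)
                },
                "total_tpm": vector.total_tpm,
                "category": label,
                "distance": distance,
                "tie": tie,
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write intermediates plus the JSON report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        counts = CountMatrix.from_tsv(config.counts_path, config.samples_path)
    except Exception as exc:
        raise PipelineError("counts", str(exc)) from exc

    groups, models, assignments, grouped = _stage_variants(config, counts)
    lines = sorted(
        {c.line for c in grouped.contexts}
        & {g for g in counts.genotypes() if g != config.wt_line}
    )
    if not lines:
        raise PipelineError(
            "diffexp", "no mutant line is present in both variants and counts"
        )
    de_results = _stage_diffexp(config, counts, lines)
    calls, summary, comparison = _stage_compensation(
        config, groups, grouped, de_results
    )
    bias_rows = _stage_bias(config, counts, groups, models)

    # ---- intermediates ----
    pd.DataFrame(
        [
            {
                "line": a.line,
                "gene_id": a.gene,
                "group_id": a.group_id,
                "subgenome": a.subgenome,
                "consequence": a.consequence,
                "cds_pos": a.cds_pos,
            }
            for a in assignments
        ]
    ).to_csv(out_dir / "assignments.tsv", sep="\t", index=False)
    for line, results in de_results.items():
        de_table(results).to_csv(out_dir / f"de_{line}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "line": c.line,
                "group_id": c.group_id,
                "mutation_class": c.mutation_class,
                "mutated_subgenome": c.mutated_subgenome,
                "mutated_status": c.mutated_status,
                "homoeolog_statuses": ";".join(
                    f"{sub}:{status}"
                    for sub, status in sorted(c.homoeolog_statuses.items())
                ),
                "compensated": c.compensated,
                "evaluable": c.evaluable,
            }
            for c in calls
        ]
    ).to_csv(out_dir / "calls.tsv", sep="\t", index=False)
    if bias_rows:
        pd.DataFrame(bias_rows).to_csv(out_dir / "bias.tsv", sep="\t", index=False)

    bias_distribution: dict[str, int] = {}
    for row in bias_rows:
        bias_distribution[row["category"]] = (
            bias_distribution.get(row["category"], 0) + 1
        )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "ploidy_mode": config.ploidy_mode,
            "alpha": config.alpha,
            "yates": config.yates,
            "wt_line": config.wt_line,
            "seed": config.seed,
        },
        "n_variants_assigned": len(assignments),
        "n_contexts": len(grouped.contexts),
        "n_multi_mutated_excluded": grouped.n_excluded,
        "compensation": summary.to_dict(),
        "class_comparison": (
            {
                "statistic": comparison.statistic,
                "pvalue": comparison.pvalue,
                "dof": comparison.dof,
                "table": list(map(list, comparison.table)),
                "yates": comparison.yates,
                "low_expected": comparison.low_expected,
            }
            if comparison is not None
            else None
        ),
        "bias_distribution": dict(sorted(bias_distribution.items())),
    }
    with open(out_dir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report
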