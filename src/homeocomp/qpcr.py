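"""Pfaffl-ratio relative expression from qPCR Ct values.

Relative expression of a target transcript against a reference transcript
(e.g. GAPDH) is E_target^dCt(target) / E_ref^dCt(reference), where dCt is
the mean Ct of the calibrator genotype minus the sample's Ct, and E is the
primer efficiency (1 < E <= 2, with 2 meaning perfect doubling).  The
genotype effect on relative expression is tested by one-way fixed-effects
ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "pfaffl_ratio",
    "pfaffl_table",
    "genotype_effect_test",
    "read_ct_table",
]

CT_COLUMNS = ["sample", "genotype", "target", "ct", "efficiency"]


def _check_efficiency(e: float, name: str) -> None:
    if not 1.0 < e <= 2.0:
        raise ValueError(f"{name} efficiency must be in (1, 2], got {e}")


def pfaffl_ratio(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """Efficiency-corrected expression ratio E_t^dCt_t / E_ref^dCt_ref."""
    _check_efficiency(e_target, "target")
    _check_efficiency(e_ref, "reference")
    return e_target**dct_target / e_ref**dct_ref


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


def pfaffl_table(
    ct_table: pd.DataFrame,
    reference_target: str,
    calibrator_genotype: str,
) -> pd.DataFrame:
    """Per-sample Pfaffl ratios for every non-reference target.

    Technical replicates (duplicate rows per sample/target) are averaged to
    one Ct per biological sample before the ratio is formed.  dCt uses the
    calibrator genotype's mean Ct per target.
    """
    table = ct_table.copy()
    averaged = (
        table.groupby(["sample", "genotype", "target"], sort=False)
        .agg(ct=("ct", "mean"), efficiency=("efficiency", "first"))
        .reset_index()
    )
    targets = [t for t in averaged["target"].unique() if t != reference_target]
    if reference_target not in set(averaged["target"]):
        raise ValueError(f"reference target {reference_target!r} not in table")
    calib = averaged[averaged["genotype"] == calibrator_genotype]
    if calib.empty:
        raise ValueError(f"no rows for calibrator genotype {calibrator_genotype!r}")
    calib_ct = calib.groupby("target")["ct"].mean()

    ref = averaged[averaged["target"] == reference_target].set_index("sample")
    rows = []
    for target in targets:
        sub = averaged[averaged["target"] == target]
        for _, row in sub.iterrows():
            sample = row["sample"]
            if sample not in ref.index:
                raise ValueError(
                    f"sample {sample!r} lacks reference target measurements"
                )
            dct_t = calib_ct[target] - row["ct"]
            dct_r = calib_ct[reference_target] - ref.loc[sample, "ct"]
            ratio = pfaffl_ratio(
                row["efficiency"], dct_t, ref.loc[sample, "efficiency"], dct_r
            )
            rows.append(
                {
                    "sample": sample,
                    "genotype": row["genotype"],
                    "target": target,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    pvalue: float


def genotype_effect_test(
    ratios_by_genotype: Mapping[str, Sequence[float]]
) -> AnovaResult:
    """One-way fixed-effects ANOVA of relative expression on genotype."""
    groups = {g: np.asarray(v, dtype=float) for g, v in ratios_by_genotype.items()}
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 genotypes")
    for genotype, values in groups.items():
        if values.size < 2:
            raise ValueError(f"genotype {genotype!r} has < 2 replicates")
    f_stat, pvalue = stats.f_oneway(*groups.values())
    n = sum(v.size for v in groups.values())
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=len(groups) - 1,
        df_within=n - len(groups),
        pvalue=float(pvalue),
    )
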