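"""Homoeolog expression-bias categories by nearest ideal point.

The WT relative expression of a homoeolog group (TPM shares summing to 1)
is assigned to the category whose ideal point is nearest in Euclidean
distance.  Triads use seven categories (balanced, one dominant and one
suppressed per subgenome); dyads use the tetraploid modification with
three categories and ideal ratios 0.5:0.5 (balanced) and 1:0 (dominant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomodel import HomoeologGroup, SUBGENOMES

__all__ = [
    "BiasVector",
    "BiasCategory",
    "ideal_points",
    "tpm_from_counts",
    "bias_vector",
    "classify_bias",
]

NORMALIZATION_TOL = 1e-8
#: groups whose summed WT TPM is at or below this are not classifiable
DEFAULT_MIN_TPM = 0.5


@dataclass(frozen=True)
class BiasVector:
    """Relative WT expression of one homoeolog group."""

    group_id: str
    shares: tuple[float, ...]  # one share per subgenome, sums to 1
    subgenomes: tuple[str, ...]
    total_tpm: float
    classifiable: bool = True

    def __post_init__(self) -> None:
        if len(self.shares) not in (2, 3):
            raise ValueError("bias vector must have 2 or 3 components")
        if len(self.shares) != len(self.subgenomes):
            raise ValueError("one subgenome label per component required")
        if self.classifiable and abs(sum(self.shares) - 1.0) > 1e-6:
            raise ValueError(
                f"group {self.group_id!r}: shares sum to {sum(self.shares)}"
            )


@dataclass(frozen=True)
class BiasCategory:
    label: str
    distance: float
    tie: bool = False


def ideal_points(n: int) -> list[tuple[str, np.ndarray]]:
    """Ordered (label, point) pairs for triads (n=3) or dyads (n=2).

    The order fixes tie-breaking: balanced first, then dominant A/B(/D),
    then suppressed A/B/D (triads only).
    """
    if n == 3:
        pts = [("Balanced", np.full(3, 1 / 3))]
        for i, sub in enumerate(SUBGENOMES):
            point = np.zeros(3)
            point[i] = 1.0
            pts.append((f"{sub}.dominant", point))
        for i, sub in enumerate(SUBGENOMES):
            point = np.full(3, 0.5)
            point[i] = 0.0
            pts.append((f"{sub}.suppressed", point))
        return pts
    if n == 2:
        return [
            ("Balanced", np.array([0.5, 0.5])),
            ("A.dominant", np.array([1.0, 0.0])),
            ("B.dominant", np.array([0.0, 1.0])),
        ]
    raise ValueError("only 2- or 3-homoeolog groups supported")


def tpm_from_counts(
    counts: pd.DataFrame, effective_lengths: Mapping[str, float] | pd.Series
) -> pd.DataFrame:
    """Transcripts-per-million from counts and per-gene effective lengths.

    Per sample: rate = count / length, TPM = 1e6 * rate / sum(rates); every
    column therefore sums to 1e6 (when the sample has any counts).
    """
    lengths = pd.Series(effective_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing effective lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    return rates.div(totals.where(totals > 0, np.nan), axis=1) * 1e6


def bias_vector(
    group: HomoeologGroup,
    tpm: pd.DataFrame,
    wt_samples: Sequence[str],
    *,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> BiasVector:
    """Mean WT TPM per homoeolog, normalized to shares summing to 1.

    Groups whose summed mean TPM does not exceed ``min_tpm`` (including
    all-zero groups) are marked not classifiable.
    """
    subs = tuple(s for s in SUBGENOMES if s in group.members)
    genes = [group.members[s] for s in subs]
    missing = [g for g in genes if g not in tpm.index]
    if missing:
        raise KeyError(f"group {group.group_id!r}: genes missing from TPM: {missing}")
    means = tpm.loc[genes, list(wt_samples)].mean(axis=1).to_numpy(dtype=float)
    total = float(means.sum())
    if total <= min_tpm:
        return BiasVector(
            group_id=group.group_id,
            shares=tuple(0.0 for _ in subs),
            subgenomes=subs,
            total_tpm=total,
            classifiable=False,
        )
    return BiasVector(
        group_id=group.group_id,
        shares=tuple(means / total),
        subgenomes=subs,
        total_tpm=total,
    )


def classify_bias(vector: BiasVector, *, tol: float = 1e-9) -> BiasCategory:
    """Assign the nearest ideal-point category to a normalized bias vector.

    Exact distance ties (within ``tol``) set the tie flag and resolve by
    the fixed category order of :func:`ideal_points`.
    """
    if not vector.classifiable:
        raise ValueError(
            f"group {vector.group_id!r} is not classifiable (low expression)"
        )
    shares = np.asarray(vector.shares, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-6:
        raise ValueError("bias vector is not normalized")
    best_label, best_distance, tie = None, np.inf, False
    for label, point in ideal_points(shares.size):
        distance = float(np.linalg.norm(shares - point))
        if distance < best_distance - tol:
            best_label, best_distance, tie = label, distance, False
        elif abs(distance - best_distance) <= tol:
            tie = True
    return BiasCategory(label=best_label, distance=best_distance, tie=tie)
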