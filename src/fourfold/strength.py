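"""The selection-strength statistic F_pi on fourfold-degenerate codon groups.

Under a pure mutational pressure with stationary nucleotide distribution pi,
the third-position usage within any 4FD group equals pi exactly (the codon
stationary factorizes over positions). Selection at the amino-acid level
perturbs this; F_pi quantifies the perturbation as the pi-normalized absolute
deviation of the within-group relative usage from pi,

    F_pi|s = sum_i |pi_i - pi^sel(s_i) / pi^sel(s)| / pi_i,

summed over the four third-position nucleotides i, and F_pi is the sum of
F_pi|s over the five groups (Ala, Gly, Pro, Thr, Val). F_pi is 0 if and only
if selection leaves the relative usage of every group at the mutational
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .codons import NUCLEOTIDES, CODON_INDEX
from .genetic_codes import GeneticCode, FourfoldGroup, fourfold_groups
from .mutation import StationaryDistribution
from .selection import CodonStationary

__all__ = ["SelectionStrengthResult", "DegenerateGroupError", "fpi_group", "fpi_total"]


class DegenerateGroupError(ValueError):
    """A 4FD group is unreachable (zero stationary frequency) under the chain."""


@dataclass(frozen=True)
class SelectionStrengthResult:
    """Per-group and total selection strength for one (code, pressure) pair."""

    per_group: Mapping[str, float]
    total: float
    code_id: int
    pi: StationaryDistribution
    provenance: dict = field(default_factory=dict, compare=False)


def fpi_group(
    pi: StationaryDistribution, stat: CodonStationary, group: FourfoldGroup
) -> float:
    """Selection strength F_pi|s for a single 4FD group (nonnegative)."""
    members = [CODON_INDEX[group.members[n]] for n in NUCLEOTIDES]
    group_total = float(stat.freq[members].sum())
    if group_total <= 0.0:
        raise DegenerateGroupError(
            f"group {group.amino_acid} ({group.prefix}N) has zero stationary "
            "frequency under the chain"
        )
    if np.any(pi.vec <= 0):
        raise ValueError("every pi_i must be positive")
    relative = stat.freq[members] / group_total
    return float((np.abs(pi.vec - relative) / pi.vec).sum())


def fpi_total(
    pi: StationaryDistribution,
    stat: CodonStationary,
    code: GeneticCode,
    provenance: dict | None = None,
) -> SelectionStrengthResult:
    """Total selection strength F_pi = sum over the five 4FD groups.

    Raises
    ------
    DegenerateGroupError
        Naming the first unreachable group, if any.
    """
    per = {}
    for group in fourfold_groups(code):
        per[group.amino_acid] = fpi_group(pi, stat, group)
    return SelectionStrengthResult(
        per_group=per,
        total=float(sum(per.values())),
        code_id=code.id,
        pi=pi,
        provenance=provenance or {},
    )
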