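"""Codon counting on coding sequences and the observed-usage statistic F.

F is the sequence-level analogue of F_pi: for each 4FD group s the observed
relative third-position usage o(s_i)/o(s) is compared with an expected
frequency e_i, defined as the average relative usage of nucleotide i across
the five groups,

    e_i = (1/5) * sum_s o(s_i) / o(s),
    f_s = sum_i |e_i - o(s_i)/o(s)| / e_i,       F = sum_s f_s.

Reading frames are taken as annotated (position 1 of each record); codons
containing non-ACGT symbols are skipped and tallied, trailing partial codons
are dropped with a warning, and stop codons are counted in the usage table
but never enter F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .codons import CODONS, CODON_INDEX, NUCLEOTIDES
from .genetic_codes import GeneticCode, fourfold_groups

__all__ = [
    "CodonUsage",
    "FResult",
    "EmptyGroupError",
    "count_codons",
    "f_statistic",
    "f_from_group_counts",
    "usage_table",
]

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


class EmptyGroupError(ValueError):
    """A 4FD group has no observed codons; F is undefined."""


@dataclass(frozen=True)
class CodonUsage:
    counts: Mapping[str, int]
    code_id: int
    n_sequences: int
    n_codons_counted: int
    n_codons_skipped: int
    n_internal_stops: int = 0


@dataclass(frozen=True)
class FResult:
    e: Mapping[str, float]
    per_group: Mapping[str, float]
    total: float


def _iter_records(source) -> Iterable[SeqRecord]:
    if isinstance(source, (str, Path)):
        yield from SeqIO.parse(str(source), "fasta")
    elif hasattr(source, "read"):
        yield from SeqIO.parse(source, "fasta")
    else:
        yield from source


def count_codons(source, code: GeneticCode) -> CodonUsage:
    """Count in-frame codons from FASTA (path, handle or SeqRecord iterable).

    Input is case-insensitive and U is mapped to T. Internal stop codons
    (under ``code``) are counted and reported as a QC tally but do not
    invalidate the record.
    """
    counts = {c: 0 for c in CODONS}
    n_seq = n_counted = n_skipped = n_internal_stops = 0
    for rec in _iter_records(source):
        seq = str(rec.seq).upper().replace("U", "T")
        n_seq += 1
        remainder = len(seq) % 3
        if remainder:
            logger.warning(
                "record %s length %d is not a multiple of 3; dropping %d "
                "trailing nucleotide(s)", rec.id, len(seq), remainder
            )
            seq = seq[: len(seq) - remainder]
        n_codons = len(seq) // 3
        for k in range(n_codons):
            codon = seq[3 * k : 3 * k + 3]
            if set(codon) <= _VALID:
                counts[codon] += 1
                n_counted += 1
                if code.assignment[codon] == "Stop" and k < n_codons - 1:
                    n_internal_stops += 1
            else:
                n_skipped += 1
    if n_seq == 0:
        raise ValueError("no FASTA records in input")
    if n_internal_stops:
        logger.warning("%d internal stop codon(s) observed", n_internal_stops)
    return CodonUsage(
        counts=counts,
        code_id=code.id,
        n_sequences=n_seq,
        n_codons_counted=n_counted,
        n_codons_skipped=n_skipped,
        n_internal_stops=n_internal_stops,
    )


def f_from_group_counts(group_counts: Mapping[str, Sequence[float]]) -> FResult:
    """F from per-group third-position counts (keys: group label -> 4 counts
    in A, C, G, T order). Exposed separately so restricted or synthetic group
    sets can be scored directly."""
    labels = list(group_counts)
    mat = np.array([np.asarray(group_counts[g], dtype=float) for g in labels])
    if mat.shape != (len(labels), 4):
        raise ValueError("each group needs exactly 4 third-position counts")
    totals = mat.sum(axis=1)
    for lbl, tot in zip(labels, totals):
        if tot <= 0:
            raise EmptyGroupError(f"group {lbl} has no observed codons")
    rel = mat / totals[:, None]
    e = rel.mean(axis=0)
    if e.min() <= 0.0:
        raise ValueError(
            "expected frequency e_i is zero for some nucleotide; F is undefined"
        )
    per = {
        lbl: float((np.abs(e - rel[k]) / e).sum()) for k, lbl in enumerate(labels)
    }
    return FResult(
        e={n: float(e[i]) for i, n in enumerate(NUCLEOTIDES)},
        per_group=per,
        total=float(sum(per.values())),
    )


def f_statistic(usage: CodonUsage, code: GeneticCode) -> FResult:
    """The observed-usage deviation statistic F over the five 4FD groups."""
    group_counts = {}
    for group in fourfold_groups(code):
        group_counts[group.amino_acid] = [
            usage.counts[group.members[n]] for n in NUCLEOTIDES
        ]
    return f_from_group_counts(group_counts)


def usage_table(usage: CodonUsage, code: GeneticCode, path: str | Path) -> None:
    """Write the 64-row TSV usage table (codon, count, amino_acid)."""
    with Path(path).open("w") as fh:
        fh.write("codon\tcount\tamino_acid\n")
        for c in CODONS:
            fh.write(f"{c}\t{usage.counts[c]}\t{code.assignment[c]}\n")
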