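"""Synthetic coding sequences and Monte-Carlo codon evolution.

The CDS generator emulates the statistical structure the F statistic
consumes: codons are drawn i.i.d. from a 64-way distribution assembled from
(i) per-group third-position simplexes for the five 4FD groups, optionally
skewed toward one nucleotide by a mixing weight delta, and (ii) a background
distribution over the remaining sense codons. Records never contain internal
stop codons and each ends with a stop codon valid under the chosen code;
lengths are 10 + geometric codons. Real coding sequences couple group usages
through shared mutational pressure and gene-level selection; the generator
keeps the groups independent, which isolates the averaging behavior of the
expected-frequency vector e.

``simulate_codon_evolution`` runs independent per-site Markov chains under a
codon transition matrix and is used to cross-validate the deterministic
stationary solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import CODONS, CODON_INDEX, NUCLEOTIDES
from .genetic_codes import GeneticCode, FOURFOLD_PREFIXES, get_code, fourfold_groups
from .mutation import CodonTransitionMatrix
from .usage import FResult, f_from_group_counts

__all__ = ["UsageSpec", "InfeasibleSpecError", "generate_cds", "simulate_codon_evolution"]


class InfeasibleSpecError(ValueError):
    """The spec cannot be realized (e.g. no stop codon to terminate records)."""


def _as_simplex(values: Sequence[float] | Mapping[str, float]) -> np.ndarray:
    if isinstance(values, Mapping):
        v = np.array([values[n] for n in NUCLEOTIDES], dtype=float)
    else:
        v = np.asarray(values, dtype=float)
    if v.shape != (4,) or v.min() < 0 or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("third-position usage must be a 4-simplex over A,C,G,T")
    return v


@dataclass(frozen=True)
class UsageSpec:
    """Target codon usage for the synthetic-CDS generator.

    ``group_third_position`` maps each 4FD amino acid to a third-position
    simplex (A, C, G, T order); ``background`` distributes the non-4FD sense
    mass over the remaining sense codons; ``fourfold_weight`` is the total
    probability of drawing a 4FD codon (split equally among the five groups).
    ``delta`` mixes each group simplex toward ``skew_toward``:
    ``(1 - delta) * simplex + delta * e_toward``.
    """

    code_id: int
    group_third_position: Mapping[str, Sequence[float]]
    background: Mapping[str, float] | None = None
    fourfold_weight: float = 0.4
    delta: float = 0.0
    skew_toward: str = "A"

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 0.75:
            raise ValueError("delta must lie in [0, 0.75]")
        if not 0.0 < self.fourfold_weight < 1.0:
            raise ValueError("fourfold_weight must lie in (0, 1)")
        if set(self.group_third_position) != set(FOURFOLD_PREFIXES):
            raise ValueError("need a simplex for each of Ala, Gly, Pro, Thr, Val")

    @classmethod
    def uniform(
        cls, code_id: int, delta: float = 0.0, skew_toward: str = "A"
    ) -> "UsageSpec":
        """Uniform third-position usage in every group, optionally skewed."""
        return cls(
            code_id=code_id,
            group_third_position={aa: [0.25] * 4 for aa in FOURFOLD_PREFIXES},
            delta=delta,
            skew_toward=skew_toward,
        )

    def skewed_simplex(self, amino_acid: str) -> np.ndarray:
        base = _as_simplex(self.group_third_position[amino_acid])
        if self.delta == 0.0:
            return base
        toward = np.zeros(4)
        toward[NUCLEOTIDES.index(self.skew_toward)] = 1.0
        return (1.0 - self.delta) * base + self.delta * toward

    def codon_distribution(self) -> np.ndarray:
        """The 64-way codon probability vector the generator draws from."""
        code = get_code(self.code_id)
        probs = np.zeros(64)
        fourfold_codons: set[str] = set()
        for aa, prefix in FOURFOLD_PREFIXES.items():
            simplex = self.skewed_simplex(aa)
            for k, n in enumerate(NUCLEOTIDES):
                probs[CODON_INDEX[prefix + n]] = self.fourfold_weight / 5.0 * simplex[k]
                fourfold_codons.add(prefix + n)
        rest = [
            c
            for c in CODONS
            if c not in fourfold_codons and code.assignment[c] != "Stop"
        ]
        if self.background is None:
            back = np.full(len(rest), 1.0 / len(rest))
        else:
            if set(self.background) != set(rest):
                raise ValueError(
                    "background must cover exactly the non-4FD sense codons"
                )
            back = np.array([self.background[c] for c in rest], dtype=float)
            if back.min() < 0 or abs(back.sum() - 1.0) > 1e-9:
                raise ValueError("background must be a probability distribution")
        for c, b in zip(rest, back):
            probs[CODON_INDEX[c]] = (1.0 - self.fourfold_weight) * b
        return probs

    def analytic_f(self) -> FResult:
        """F computed exactly from the (skewed) target simplexes."""
        return f_from_group_counts(
            {aa: self.skewed_simplex(aa) for aa in FOURFOLD_PREFIXES}
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "code_id": self.code_id,
            "group_third_position": {
                aa: list(map(float, _as_simplex(v)))
                for aa, v in self.group_third_position.items()
            },
            "background": dict(self.background) if self.background else None,
            "fourfold_weight": self.fourfold_weight,
            "delta": self.delta,
            "skew_toward": self.skew_toward,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "UsageSpec":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def generate_cds(
    spec: UsageSpec,
    n_sequences: int,
    mean_length_codons: int,
    seed: int,
    return_tally: bool = False,
):
    """Generate synthetic CDS records with multinomial codon usage.

    Lengths are ``10 + Geometric`` with the requested mean; each record ends
    with a stop codon drawn uniformly from the code's stops. Byte-identical
    output for identical seeds. With ``return_tally=True`` also returns the
    exact codon tally of the emitted records (stop codons included).
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if mean_length_codons < 10:
        raise ValueError("mean_length_codons must be >= 10")
    code = get_code(spec.code_id)
    stops = code.stop_codons
    if not stops:
        raise InfeasibleSpecError(
            f"code {code.id} ({code.name}) has no stop codons; records cannot "
            "be terminated"
        )
    rng = np.random.default_rng(seed)
    probs = spec.codon_distribution()
    tally = {c: 0 for c in CODONS}
    records = []
    excess = mean_length_codons - 10
    for k in range(n_sequences):
        if excess > 0:
            length = 10 + rng.geometric(1.0 / (excess + 1)) - 1
        else:
            length = 10
        draws = rng.choice(64, size=length, p=probs)
        stop = stops[rng.integers(len(stops))]
        codons = [CODONS[i] for i in draws] + [stop]
        for c in codons:
            tally[c] += 1
        records.append(
            SeqRecord(
                Seq("".join(codons)),
                id=f"synth_{k:06d}",
                description=f"synthetic CDS code={code.id} delta={spec.delta}",
            )
        )
    if return_tally:
        return records, tally
    return records


def simulate_codon_evolution(
    m_sel: CodonTransitionMatrix,
    n_sites: int,
    steps: int,
    seed: int,
    initial: Sequence[float] | None = None,
) -> np.ndarray:
    """Monte-Carlo codon evolution: independent per-site chains under m_sel.

    Sites start from ``initial`` (default: uniform over the 64 codons).
    Returns the aggregate codon frequencies at each step, shape
    ``(steps + 1, 64)``. Rows are clipped at 0 and renormalized before
    sampling to absorb sub-ulp negative diagonals.
    """
    if n_sites < 1 or steps < 1:
        raise ValueError("need n_sites >= 1 and steps >= 1")
    rng = np.random.default_rng(seed)
    start = (
        np.full(64, 1.0 / 64.0)
        if initial is None
        else np.asarray(initial, dtype=float)
    )
    rows = np.clip(m_sel.m, 0.0, None)
    rows = rows / rows.sum(axis=1, keepdims=True)
    counts = rng.multinomial(n_sites, start / start.sum())
    freqs = np.empty((steps + 1, 64))
    freqs[0] = counts / n_sites
    for t in range(1, steps + 1):
        new_counts = np.zeros(64, dtype=np.int64)
        for state in np.flatnonzero(counts):
            new_counts += rng.multinomial(counts[state], rows[state])
        counts = new_counts
        freqs[t] = counts / n_sites
    return freqs
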