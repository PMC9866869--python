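"""Amino-acid-level selection and the combined mutation-selection codon chain.

Selection is modeled as an acceptance probability for each amino-acid
substitution, derived from Grantham's physicochemical distance matrix
(composition, polarity, molecular volume; range 5-215). The default
conversion is the linear complement of the normalized distance,
``a(x, y) = 1 - D(x, y) / D_max``, so identical residues are always accepted
and the most dissimilar pair (Cys-Trp) is never accepted; substitutions
gaining or losing a stop codon receive the floor acceptance (default 0, the
lowest possible). The conversion is a strategy hook: any callable mapping a
distance array to acceptances in [0, 1] can be substituted.

The combined codon chain multiplies each off-diagonal mutational transition
by the acceptance of the implied amino-acid change and returns the removed
mass to the diagonal (rejected mutations leave the codon unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .codons import AMINO_ACIDS_3, AA_INDEX, AA1_TO_AA3, STOP, STOP_INDEX
from .genetic_codes import GeneticCode, FourfoldGroup
from .mutation import CodonTransitionMatrix

__all__ = [
    "AcceptanceMatrix",
    "CodonStationary",
    "MultipleRecurrentClassesError",
    "grantham_distance",
    "grantham_matrix",
    "build_acceptance_matrix",
    "combined_codon_matrix",
    "stationary_distribution",
    "combined_stationary",
]


class MultipleRecurrentClassesError(ValueError):
    """The chain has several closed communicating classes."""

    def __init__(self, classes: list[list[int]]):
        self.classes = classes
        super().__init__(
            f"chain has {len(classes)} closed communicating classes "
            f"(sizes {[len(c) for c in classes]}); the stationary distribution "
            "is not unique"
        )


_GRANTHAM: np.ndarray | None = None


def grantham_matrix() -> np.ndarray:
    """The 20x20 Grantham distance matrix, alphabetical 3-letter order."""
    global _GRANTHAM
    if _GRANTHAM is None:
        path = resources.files("fourfold.data") / "grantham.tsv"
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            if tuple(header) != AMINO_ACIDS_3:
                raise ValueError("grantham.tsv residue order is corrupted")
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
        _GRANTHAM = np.array(rows, dtype=float)
        _GRANTHAM.setflags(write=False)
    return _GRANTHAM


def _residue_index(residue: str) -> int:
    r = AA1_TO_AA3.get(residue, residue)
    try:
        return AA_INDEX[r]
    except KeyError:
        raise KeyError(f"unknown residue {residue!r}") from None


def grantham_distance(x: str, y: str) -> float:
    """Grantham distance between two amino acids (1- or 3-letter codes)."""
    return float(grantham_matrix()[_residue_index(x), _residue_index(y)])


def linear_acceptance(distances: np.ndarray) -> np.ndarray:
    """Default conversion: ``1 - D / D_max`` (monotone, onto [0, 1])."""
    return 1.0 - distances / distances.max()


@dataclass(frozen=True)
class AcceptanceMatrix:
    """21x21 substitution-acceptance probabilities (20 amino acids + stop).

    Rows/columns follow :data:`fourfold.codons.AMINO_ACIDS_3` with the stop
    signal last. Diagonal entries are 1 (synonymous changes always accepted,
    including stop-to-stop); every entry involving stop equals ``stop_floor``.
    """

    a: np.ndarray
    d_max: float
    stop_floor: float

    def __post_init__(self) -> None:
        self.a.setflags(write=False)

    def of(self, x: str, y: str) -> float:
        ix = STOP_INDEX if x == STOP else _residue_index(x)
        iy = STOP_INDEX if y == STOP else _residue_index(y)
        return float(self.a[ix, iy])

    def codon_expansion(self, code: GeneticCode) -> np.ndarray:
        """64x64 lookup ``a[meaning(c), meaning(c')]`` under ``code``."""
        idx = np.array(code.aa_codes)
        return self.a[np.ix_(idx, idx)]


def build_acceptance_matrix(
    stop_floor: float = 0.0,
    conversion: Callable[[np.ndarray], np.ndarray] = linear_acceptance,
    strict: bool = True,
) -> AcceptanceMatrix:
    """Convert Grantham distances into an acceptance matrix.

    Parameters
    ----------
    stop_floor : float
        Acceptance for substitutions gaining or losing a stop signal. The
        default 0 is the lowest possible probability; with ``strict=True``
        (default) the floor must not exceed the smallest amino-acid-pair
        acceptance, preserving the "least accepted" semantics. ``strict=False``
        permits any value in [0, 1] (used e.g. to switch stop selection off
        entirely with a floor of 1).
    conversion : callable
        Maps the 20x20 distance matrix to acceptances in [0, 1]; must return
        1 on the diagonal.
    """
    d = grantham_matrix()
    a20 = np.asarray(conversion(d), dtype=float)
    if a20.shape != (20, 20):
        raise ValueError("conversion must return a 20x20 matrix")
    if a20.min() < 0 or a20.max() > 1 or not np.allclose(np.diag(a20), 1.0):
        raise ValueError("conversion must map into [0, 1] with unit diagonal")
    off_min = float(a20[~np.eye(20, dtype=bool)].min())
    if not 0.0 <= stop_floor <= 1.0:
        raise ValueError("stop_floor must lie in [0, 1]")
    if strict and stop_floor > off_min + 1e-12:
        raise ValueError(
            f"stop_floor {stop_floor} exceeds the smallest amino-acid-pair "
            f"acceptance {off_min:.4g}; pass strict=False to allow this"
        )
    a = np.empty((21, 21))
    a[:20, :20] = a20
    a[20, :] = stop_floor
    a[:, 20] = stop_floor
    a[20, 20] = 1.0  # stop-to-stop is synonymous
    return AcceptanceMatrix(a=a, d_max=float(d.max()), stop_floor=float(stop_floor))


def combined_codon_matrix(
    m: CodonTransitionMatrix, acceptance: AcceptanceMatrix, code: GeneticCode
) -> CodonTransitionMatrix:
    """Apply amino-acid selection to a mutational codon chain.

    Off-diagonal transitions are multiplied by the acceptance of the implied
    amino-acid (or stop) change; rejected probability mass stays on the
    diagonal, so rows still sum to 1.
    """
    a64 = acceptance.codon_expansion(code)
    ms = m.m * a64
    np.fill_diagonal(ms, 0.0)
    np.fill_diagonal(ms, 1.0 - ms.sum(axis=1))
    return CodonTransitionMatrix(m=ms)


@dataclass(frozen=True)
class CodonStationary:
    """Stationary distribution of a codon chain with group accessors."""

    freq: np.ndarray

    def __post_init__(self) -> None:
        self.freq.setflags(write=False)

    def group_freq(self, group: FourfoldGroup) -> float:
        from .codons import CODON_INDEX

        return float(sum(self.freq[CODON_INDEX[c]] for c in group.codons))

    def member_freq(self, group: FourfoldGroup, nucleotide: str) -> float:
        from .codons import CODON_INDEX

        return float(self.freq[CODON_INDEX[group.members[nucleotide]]])


def _closed_classes(m: np.ndarray, tol: float = 0.0) -> list[np.ndarray]:
    """Closed communicating classes of a stochastic matrix."""
    adj = csr_matrix(m > tol)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for k in range(n_comp):
        members = np.flatnonzero(labels == k)
        outside = np.setdiff1d(np.arange(m.shape[0]), members, assume_unique=True)
        if m[np.ix_(members, outside)].max(initial=0.0) <= tol:
            closed.append(members)
    return closed


def _solve_on(m: np.ndarray, members: np.ndarray) -> np.ndarray:
    sub = m[np.ix_(members, members)]
    n = len(members)
    lhs = sub.T - np.eye(n)
    lhs[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    try:
        v = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        v, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    full = np.zeros(m.shape[0])
    full[members] = v
    return full


def stationary_distribution(m: CodonTransitionMatrix) -> CodonStationary:
    """Unique stationary distribution via a direct dense linear solve.

    The recurrent class is identified by strong-connectivity analysis;
    transient states get frequency 0. Deterministic — no random number
    generation.

    Raises
    ------
    MultipleRecurrentClassesError
        If more than one closed communicating class exists (e.g. a combined
        chain whose stop codons, with a floor of 0, form their own closed
        class — use :func:`combined_stationary` for that case).
    """
    closed = _closed_classes(m.m)
    if len(closed) != 1:
        raise MultipleRecurrentClassesError([c.tolist() for c in closed])
    return CodonStationary(freq=_solve_on(m.m, closed[0]))


def combined_stationary(
    m_sel: CodonTransitionMatrix, code: GeneticCode
) -> CodonStationary:
    """Stationary distribution of a combined chain, stop-aware.

    With a stop floor of 0 the stop codons exchange no probability with the
    sense codons and form a separate closed class; the meaningful stationary
    distribution is then the one supported on the sense class, with stop
    frequencies exactly 0. With a positive floor the full 64-state chain is
    irreducible and this reduces to :func:`stationary_distribution`.
    """
    stops = np.array(code.stop_indices, dtype=int)
    if stops.size:
        sense = np.array(code.sense_indices, dtype=int)
        no_exchange = (
            m_sel.m[np.ix_(sense, stops)].max(initial=0.0) == 0.0
            and m_sel.m[np.ix_(stops, sense)].max(initial=0.0) == 0.0
        )
        if no_exchange:
            closed = _closed_classes(m_sel.m[np.ix_(sense, sense)])
            if len(closed) != 1:
                raise MultipleRecurrentClassesError(
                    [sense[c].tolist() for c in closed]
                )
            return CodonStationary(freq=_solve_on(m_sel.m, sense[closed[0]]))
    return stationary_distribution(m_sel)
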