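"""Nucleotide mutational pressures with prescribed stationary distributions.

A mutational pressure is a continuous-time Markov generator Q on {A,C,G,T}
under the unrestricted (UNREST) model: all 12 off-diagonal rates free. The
package parameterizes the family of generators with a *prescribed* stationary
distribution pi by flux decomposition: the probability flux matrix
``F[i,j] = pi[i] * Q[i,j]`` must have equal row and column sums (flux balance
at every nucleotide), and every such nonnegative F splits into

* a symmetric part S (6 free parameters, one per unordered nucleotide pair),
  which alone yields a reversible (detailed-balance) chain, and
* a circulation part on a cycle basis of the complete graph K4 (3 free
  parameters), which carries all irreversibility.

``Q[i,j] = F[i,j] / pi[i]`` then has stationary distribution pi *by
construction*, with no rejection sampling; the decomposition is surjective
onto the stationarity-constrained UNREST family up to overall scale. Scale is
fixed by normalizing the expected substitution rate ``-sum_i pi_i Q[i,i]``
to 1.

Generators are lifted to discrete time by uniformization, ``P = I + Q/lam``
with ``lam = max_i |Q[i,i]|`` (a configurable multiplier allows lazier
chains), and to codons by the positional tensor product, which permits
simultaneous changes at several codon positions with product probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codons import NUCLEOTIDES, NUC_INDEX, CODONS

__all__ = [
    "StationaryDistribution",
    "FluxParams",
    "NucleotideRateMatrix",
    "NucleotideTransitionMatrix",
    "CodonTransitionMatrix",
    "NegativeFluxError",
    "ZeroGeneratorError",
    "EmptyGridError",
    "enumerate_stationary_grid",
    "flux_to_rates",
    "sample_rate_matrix",
    "uniformize",
    "codon_mutation_matrix",
    "NUCLEOTIDE_PAIRS",
    "CYCLE_BASIS",
]

#: unordered nucleotide pairs indexing the 6 symmetric flux parameters
NUCLEOTIDE_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)
)  # AC, AG, AT, CG, CT, GT

#: fundamental cycles of K4 for the spanning tree {A-C, A-G, A-T}; each
#: circulation parameter adds directed flux along its cycle's edges
CYCLE_BASIS: tuple[tuple[tuple[int, int], ...], ...] = (
    ((1, 2), (2, 0), (0, 1)),  # C->G->A->C
    ((1, 3), (3, 0), (0, 1)),  # C->T->A->C
    ((2, 3), (3, 0), (0, 2)),  # G->T->A->G
)


class NegativeFluxError(ValueError):
    """Circulation magnitudes exceed the symmetric flux on some edge."""


class ZeroGeneratorError(ValueError):
    """All fluxes are zero; the degenerate generator is rejected."""


class EmptyGridError(ValueError):
    """The requested lattice admits no stationary distribution."""


class StationaryDistribution:
    """A strictly positive nucleotide frequency vector summing to 1.

    Stored internally in ``ACGT`` order. ``from_atcg`` accepts the
    ``(A, T, C, G)`` order conventional for composition tables.
    """

    __slots__ = ("vec",)

    def __init__(self, freqs: Mapping[str, float] | Sequence[float]):
        if isinstance(freqs, Mapping):
            vec = np.array([freqs[n] for n in NUCLEOTIDES], dtype=float)
        else:
            vec = np.asarray(freqs, dtype=float)
        if vec.shape != (4,):
            raise ValueError("a stationary distribution has exactly 4 frequencies")
        if not np.all(vec > 0):
            raise ValueError("every nucleotide frequency must be positive")
        if abs(vec.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies must sum to 1 (got {vec.sum()!r})")
        self.vec = vec
        self.vec.setflags(write=False)

    @classmethod
    def from_atcg(cls, a: float, t: float, c: float, g: float) -> "StationaryDistribution":
        return cls({"A": a, "T": t, "C": c, "G": g})

    def of(self, nucleotide: str) -> float:
        return float(self.vec[NUC_INDEX[nucleotide]])

    def as_array(self) -> np.ndarray:
        """Frequencies in ``ACGT`` order."""
        return self.vec

    def as_atcg(self) -> tuple[float, float, float, float]:
        return (self.of("A"), self.of("T"), self.of("C"), self.of("G"))

    @property
    def at_content(self) -> float:
        return self.of("A") + self.of("T")

    @property
    def gc_content(self) -> float:
        return self.of("G") + self.of("C")

    def __eq__(self, other) -> bool:
        return isinstance(other, StationaryDistribution) and np.array_equal(
            self.vec, other.vec
        )

    def __hash__(self) -> int:
        return hash(self.vec.tobytes())

    def __repr__(self) -> str:
        a, t, c, g = self.as_atcg()
        return f"StationaryDistribution(A={a:g}, T={t:g}, C={c:g}, G={g:g})"


@dataclass(frozen=True)
class FluxParams:
    """The 9 free parameters of the flux decomposition."""

    sym: tuple[float, ...]   # 6 symmetric edge fluxes, order NUCLEOTIDE_PAIRS
    circ: tuple[float, ...]  # 3 signed cycle circulations, order CYCLE_BASIS

    def as_array(self) -> np.ndarray:
        return np.array(self.sym + self.circ, dtype=float)

    @classmethod
    def from_array(cls, params: Sequence[float]) -> "FluxParams":
        p = np.asarray(params, dtype=float)
        if p.shape != (9,):
            raise ValueError("expected 9 flux parameters (6 symmetric + 3 circulation)")
        return cls(sym=tuple(p[:6]), circ=tuple(p[6:]))


@dataclass(frozen=True)
class NucleotideRateMatrix:
    """UNREST generator with prescribed stationary distribution."""

    q: np.ndarray
    pi: StationaryDistribution
    params: FluxParams

    def __post_init__(self) -> None:
        self.q.setflags(write=False)

    def stationarity_residual(self) -> float:
        """``max_j |sum_i pi_i q_ij|`` — 0 for exact stationarity."""
        return float(np.abs(self.pi.vec @ self.q).max())


@dataclass(frozen=True)
class NucleotideTransitionMatrix:
    """Uniformized nucleotide transition matrix ``P = I + Q/lam``."""

    p: np.ndarray
    lam: float
    pi: StationaryDistribution

    def __post_init__(self) -> None:
        self.p.setflags(write=False)


@dataclass(frozen=True)
class CodonTransitionMatrix:
    """Row-stochastic 64x64 codon transition matrix (lexicographic order)."""

    m: np.ndarray
    codon_order: tuple[str, ...] = CODONS

    def __post_init__(self) -> None:
        self.m.setflags(write=False)
        if self.m.shape != (64, 64):
            raise ValueError("codon transition matrix must be 64x64")


def enumerate_stationary_grid(
    lo: float = 0.05, hi: float = 0.85, step: float = 0.01
) -> list[StationaryDistribution]:
    """All stationary distributions on the step lattice, in deterministic order.

    Enumeration is exact integer arithmetic on step counts — no floating-point
    accumulation can exclude or duplicate lattice points. Tuples are ordered
    lexicographically in (A, T, C, G) counts. The default lattice has 91,881
    members.
    """
    if not (0 < lo < hi < 1):
        raise ValueError("need 0 < lo < hi < 1")
    if step <= 0:
        raise ValueError("step must be positive")
    span = round((hi - lo) / step)
    if span < 0 or abs(span * step - (hi - lo)) > 1e-9:
        raise ValueError("(hi - lo) must be an integer multiple of step")
    # coordinates are lo + k*step; summing to 1 needs k1+..+k4 = total
    total_f = (1.0 - 4.0 * lo) / step
    total = round(total_f)
    if total < 0 or abs(total - total_f) > 1e-9:
        raise EmptyGridError(
            f"no (A,T,C,G) tuple on the lattice [{lo}, {hi}] step {step} sums to 1"
        )
    # integer nano-units keep coordinates exactly on the decimal lattice
    lo_n, step_n = round(lo * 1e9), round(step * 1e9)

    def coord(k: int) -> float:
        return (lo_n + k * step_n) / 1e9

    out: list[StationaryDistribution] = []
    for a in range(min(span, total) + 1):
        for t in range(min(span, total - a) + 1):
            for c in range(min(span, total - a - t) + 1):
                g = total - a - t - c
                if 0 <= g <= span:
                    out.append(
                        StationaryDistribution.from_atcg(
                            coord(a), coord(t), coord(c), coord(g)
                        )
                    )
    if not out:
        raise EmptyGridError(
            f"no (A,T,C,G) tuple on the lattice [{lo}, {hi}] step {step} sums to 1"
        )
    return out


def _flux_matrix(params: FluxParams) -> np.ndarray:
    f = np.zeros((4, 4))
    for (i, j), s in zip(NUCLEOTIDE_PAIRS, params.sym):
        f[i, j] += s
        f[j, i] += s
    for cycle, w in zip(CYCLE_BASIS, params.circ):
        for i, j in cycle:
            f[i, j] += w
            f[j, i] -= w
    return f


def flux_to_rates(
    sym_flux: Sequence[float],
    circ: Sequence[float],
    pi: StationaryDistribution,
) -> NucleotideRateMatrix:
    """Build the UNREST generator from flux parameters.

    Stationarity of ``pi`` holds by flux balance; the generator is scaled to
    one expected substitution per site per unit time.

    Raises
    ------
    NegativeFluxError
        If a circulation exceeds the symmetric flux on some edge.
    ZeroGeneratorError
        If all fluxes vanish.
    """
    params = FluxParams(sym=tuple(map(float, sym_flux)), circ=tuple(map(float, circ)))
    if len(params.sym) != 6 or len(params.circ) != 3:
        raise ValueError("need 6 symmetric fluxes and 3 circulations")
    if any(s < 0 for s in params.sym):
        raise NegativeFluxError("symmetric fluxes must be nonnegative")
    f = _flux_matrix(params)
    if f.min() < -1e-15:
        i, j = np.unravel_index(np.argmin(f), f.shape)
        raise NegativeFluxError(
            f"net flux {NUCLEOTIDES[i]}->{NUCLEOTIDES[j]} is negative "
            f"({f[i, j]:.3g}); reduce circulation magnitudes"
        )
    total = f.sum()
    if total <= 0:
        raise ZeroGeneratorError("all fluxes are zero")
    f = f / total  # expected substitutions per site per unit time = 1
    q = f / pi.vec[:, None]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return NucleotideRateMatrix(q=q, pi=pi, params=params)


def repair_params(params: np.ndarray) -> np.ndarray:
    """Project parameters onto the feasible (nonnegative-flux) region.

    Symmetric fluxes are clipped at zero; circulations are shrunk by the
    largest factor in [0, 1] keeping every edge flux nonnegative (bisection).
    """
    p = np.asarray(params, dtype=float).copy()
    p[:6] = np.maximum(p[:6], 0.0)
    f = _flux_matrix(FluxParams.from_array(p))
    if f.min() >= -1e-15:
        return p
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        trial = p.copy()
        trial[6:] *= mid
        if _flux_matrix(FluxParams.from_array(trial)).min() >= 0.0:
            lo = mid
        else:
            hi = mid
    p[6:] *= lo
    return p


def sample_rate_matrix(
    pi: StationaryDistribution, rng_seed: int | np.random.Generator
) -> NucleotideRateMatrix:
    """Draw a random stationarity-constrained UNREST generator.

    Symmetric fluxes are uniform on [0, 1); circulations uniform on
    (-0.25, 0.25), shrunk if needed to keep fluxes nonnegative. The flux
    parameters are recorded on the result for reproducibility.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    while True:
        raw = np.concatenate([rng.random(6), (rng.random(3) - 0.5) * 0.5])
        p = repair_params(raw)
        if p[:6].sum() > 1e-9:
            params = FluxParams.from_array(p)
            return flux_to_rates(params.sym, params.circ, pi)


def uniformize(
    q: NucleotideRateMatrix, lam_multiplier: float = 1.0
) -> NucleotideTransitionMatrix:
    """Uniformize a generator: ``P = I + Q/lam``, ``lam = mult * max|q_ii|``.

    The tight default multiplier 1 puts the most probability mass on actual
    substitutions (the row attaining the maximum exit rate gets diagonal 0);
    larger multipliers give lazier chains with fewer simultaneous multi-site
    codon changes after the tensor lift.
    """
    if lam_multiplier < 1.0:
        raise ValueError("lam_multiplier below 1 would produce negative diagonals")
    lam = float(np.abs(np.diag(q.q)).max()) * lam_multiplier
    if lam == 0.0:
        raise ZeroGeneratorError("cannot uniformize the zero generator")
    p = np.eye(4) + q.q / lam
    return NucleotideTransitionMatrix(p=p, lam=lam, pi=q.pi)


def codon_mutation_matrix(p: NucleotideTransitionMatrix) -> CodonTransitionMatrix:
    """Lift a nucleotide transition matrix to codons by tensor product.

    ``m[c -> c'] = prod_k p[c_k -> c'_k]``: the three positions mutate
    independently in one step, so simultaneous multi-position changes occur
    with product probability. The stationary distribution is the product
    measure ``pi_{c1} pi_{c2} pi_{c3}``.
    """
    m = np.kron(np.kron(p.p, p.p), p.p)
    return CodonTransitionMatrix(m=m)
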