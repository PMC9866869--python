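"""Evolutionary-strategies search over rate-matrix space and grid sweeps.

For a fixed genetic code and stationary nucleotide distribution there are
infinitely many UNREST generators; the optimizer searches the 9-dimensional
flux parameterization (6 symmetric fluxes + 3 cycle circulations) for the
generator whose combined mutation-selection chain maximizes (or minimizes)
F_pi. The variant is an elitist (mu + lambda) evolution strategy with
log-normal self-adaptive per-coordinate step sizes; infeasible proposals are
repaired by projection onto the nonnegative-flux region, and proposals whose
chain degenerates (an unreachable 4FD group or an ill-conditioned stationary
solve) are discarded as infeasible offspring.

Because the symmetric fluxes alone produce reversible chains — for which
F_pi is exactly 0 — everything the optimizer can gain in the maximize
direction is carried by the circulation parameters, and the minimize
direction converges toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codons import CODON_INDEX, NUCLEOTIDES
from .genetic_codes import GeneticCode, FOURFOLD_PREFIXES
from .mutation import (
    FluxParams,
    StationaryDistribution,
    ZeroGeneratorError,
    repair_params,
)
from .selection import AcceptanceMatrix

__all__ = [
    "ESConfig",
    "OptimizationRecord",
    "FpiObjective",
    "optimize_fpi",
    "sweep_grid",
    "descriptive_stats",
    "percent_change",
    "SWEEP_COLUMNS",
]

_GROUP_MEMBER_IDX = np.array(
    [[CODON_INDEX[p + n] for n in NUCLEOTIDES] for p in FOURFOLD_PREFIXES.values()]
)


@dataclass(frozen=True)
class ESConfig:
    """Evolution-strategy settings.

    ``sigma0`` is the initial mutation step on the flux parameters (the total
    flux is scale-normalized, so steps are effectively relative). Defaults
    follow a robust textbook (mu + lambda) setup for a smooth 9-dimensional
    box-constrained objective.
    """

    mu: int = 10
    lambda_offspring: int = 40
    sigma0: float = 0.3
    generations: int = 300
    restarts: int = 5
    seed: int = 0
    direction: str = "max"

    def __post_init__(self) -> None:
        if self.mu < 1 or self.lambda_offspring < self.mu:
            raise ValueError("need mu >= 1 and lambda_offspring >= mu")
        if self.generations < 1 or self.restarts < 1:
            raise ValueError("need generations >= 1 and restarts >= 1")
        if self.direction not in ("min", "max"):
            raise ValueError("direction must be 'min' or 'max'")


@dataclass(frozen=True)
class OptimizationRecord:
    best_value: float
    best_params: FluxParams
    trace: tuple[float, ...]
    config: ESConfig
    code_id: int
    pi: StationaryDistribution


class FpiObjective:
    """Fast evaluation of F_pi for one (code, pi, acceptance) setting.

    Precomputes the 64x64 acceptance expansion, the sense-codon index and the
    group membership so that a single evaluation is a handful of dense numpy
    operations. Evaluations are pure: identical parameters give identical
    values.
    """

    def __init__(
        self,
        code: GeneticCode,
        pi: StationaryDistribution,
        acceptance: AcceptanceMatrix,
        lam_multiplier: float = 1.0,
    ):
        self.code = code
        self.pi = pi
        self.acceptance = acceptance
        self.lam_multiplier = lam_multiplier
        self._a64 = acceptance.codon_expansion(code)
        stops = np.array(code.stop_indices, dtype=int)
        sense = np.array(code.sense_indices, dtype=int)
        # with a floor of 0 the stop codons are isolated; solve on sense only
        if stops.size and acceptance.stop_floor == 0.0:
            self._solve_idx = sense
        else:
            self._solve_idx = np.arange(64)
        self._pi_vec = pi.as_array()
        # positions of the 20 group members inside the solve index
        lookup = -np.ones(64, dtype=int)
        lookup[self._solve_idx] = np.arange(len(self._solve_idx))
        self._members = lookup[_GROUP_MEMBER_IDX]
        if (self._members < 0).any():
            raise ValueError("a 4FD codon is excluded from the solve index")
        n = len(self._solve_idx)
        self._eye = np.eye(n)
        self._rhs = np.zeros(n)
        self._rhs[-1] = 1.0

    def evaluate(self, params: np.ndarray) -> float | None:
        """F_pi for repaired flux parameters, or None if degenerate."""
        fp = FluxParams.from_array(params)
        f = np.zeros((4, 4))
        s = np.asarray(fp.sym)
        f[([0, 0, 0, 1, 1, 2], [1, 2, 3, 2, 3, 3])] = s
        f[([1, 2, 3, 2, 3, 3], [0, 0, 0, 1, 1, 2])] = s
        w1, w2, w3 = fp.circ
        f[1, 2] += w1; f[2, 0] += w1; f[0, 1] += w1
        f[2, 1] -= w1; f[0, 2] -= w1; f[1, 0] -= w1
        f[1, 3] += w2; f[3, 0] += w2; f[0, 1] += w2
        f[3, 1] -= w2; f[0, 3] -= w2; f[1, 0] -= w2
        f[2, 3] += w3; f[3, 0] += w3; f[0, 2] += w3
        f[3, 2] -= w3; f[0, 3] -= w3; f[2, 0] -= w3
        total = f.sum()
        if total <= 0 or f.min() < -1e-12:
            return None
        f /= total
        q = f / self._pi_vec[:, None]
        np.fill_diagonal(q, 0.0)
        exit_rates = q.sum(axis=1)
        lam = exit_rates.max() * self.lam_multiplier
        if lam <= 0:
            return None
        p = q / lam
        np.fill_diagonal(p, 1.0 - exit_rates / lam)
        m = np.kron(np.kron(p, p), p)
        ms = m * self._a64
        np.fill_diagonal(ms, 0.0)
        np.fill_diagonal(ms, 1.0 - ms.sum(axis=1))
        sub = ms[np.ix_(self._solve_idx, self._solve_idx)]
        lhs = sub.T - self._eye
        lhs[-1, :] = 1.0
        try:
            v = np.linalg.solve(lhs, self._rhs)
        except np.linalg.LinAlgError:
            return None
        if v.min() < -1e-8:  # numerically unreliable near-reducible chain
            return None
        v = np.clip(v, 0.0, None)
        v /= v.sum()
        group = v[self._members]            # (5, 4)
        totals = group.sum(axis=1, keepdims=True)
        if totals.min() < 1e-12:
            return None
        rel = group / totals
        return float((np.abs(self._pi_vec - rel) / self._pi_vec).sum())


def _run_restart(
    objective: FpiObjective, cfg: ESConfig, rng: np.random.Generator, sign: float
) -> tuple[float, np.ndarray, list[float]]:
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(9.0))
    tau_prime = 1.0 / np.sqrt(2.0 * 9.0)
    population: list[tuple[float, np.ndarray, np.ndarray]] = []
    attempts = 0
    while len(population) < cfg.mu:
        attempts += 1
        if attempts > 200 * cfg.mu:
            raise ZeroGeneratorError("could not find a feasible initial population")
        raw = np.concatenate([rng.random(6), (rng.random(3) - 0.5) * 0.5])
        p = repair_params(raw)
        val = objective.evaluate(p)
        if val is not None:
            population.append((sign * val, p, np.full(9, cfg.sigma0)))
    population.sort(key=lambda t: -t[0])
    trace = [sign * population[0][0]]
    for _ in range(cfg.generations):
        offspring = []
        for _ in range(cfg.lambda_offspring):
            _, parent, sigma = population[rng.integers(cfg.mu)]
            sigma_new = sigma * np.exp(
                tau_prime * rng.standard_normal() + tau * rng.standard_normal(9)
            )
            sigma_new = np.clip(sigma_new, 1e-8, 2.0)
            child = repair_params(parent + sigma_new * rng.standard_normal(9))
            val = objective.evaluate(child)
            if val is not None:
                offspring.append((sign * val, child, sigma_new))
        # elitist (mu + lambda); stable sort keeps earlier-found on ties
        population = sorted(population + offspring, key=lambda t: -t[0])[: cfg.mu]
        trace.append(sign * population[0][0])
    best = population[0]
    return sign * best[0], best[1], trace


def optimize_fpi(
    code: GeneticCode,
    pi: StationaryDistribution,
    acceptance: AcceptanceMatrix,
    cfg: ESConfig,
    lam_multiplier: float = 1.0,
) -> OptimizationRecord:
    """Best-of-restarts ES search for extremal F_pi; reproducible from config.

    Each restart seeds its generator as ``(cfg.seed, restart_index)``, so two
    runs with the same config are bit-identical.
    """
    objective = FpiObjective(code, pi, acceptance, lam_multiplier)
    sign = 1.0 if cfg.direction == "max" else -1.0
    best_val: float | None = None
    best_params: np.ndarray | None = None
    best_trace: list[float] | None = None
    for restart in range(cfg.restarts):
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, restart])
        val, params, trace = _run_restart(objective, cfg, rng, sign)
        if best_val is None or sign * val > sign * best_val:
            best_val, best_params, best_trace = val, params, trace
    return OptimizationRecord(
        best_value=float(best_val),
        best_params=FluxParams.from_array(best_params),
        trace=tuple(best_trace),
        config=cfg,
        code_id=code.id,
        pi=pi,
    )


SWEEP_COLUMNS = (
    ["code_id", "A", "T", "C", "G", "direction", "Fpi"]
    + [f"sym_{i}" for i in range(6)]
    + [f"circ_{i}" for i in range(3)]
    + ["seed", "generations"]
)


def _derived_seed(master_seed: int, code_id: int, grid_index: int) -> int:
    """Deterministic per-(code, pressure) seed, kept below 2**31."""
    ss = np.random.SeedSequence([master_seed, code_id, grid_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def sweep_grid(
    codes: Sequence[GeneticCode],
    grid: Sequence[StationaryDistribution],
    acceptance: AcceptanceMatrix,
    cfg: ESConfig,
    directions: Sequence[str] = ("max",),
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Optimize F_pi for every (code, pressure, direction); resumable.

    Rows are keyed by (code_id, A, T, C, G, direction). When ``out_path``
    exists, already-computed rows are loaded and skipped; rows are appended
    and flushed after each optimization, so a partial file is always valid
    TSV.
    """
    if not codes or not grid:
        raise ValueError("codes and grid must be nonempty")
    done: set[tuple] = set()
    rows: list[list] = []
    path = Path(out_path) if out_path is not None else None
    if path is not None and path.exists():
        prev = pd.read_csv(path, sep="\t", float_precision="round_trip")
        rows = prev.values.tolist()
        done = {
            (int(r.code_id), round(r.A, 9), round(r.T, 9), round(r.C, 9),
             round(r.G, 9), r.direction)
            for r in prev.itertuples()
        }
    handle = None
    if path is not None:
        new_file = not path.exists()
        handle = path.open("a")
        if new_file:
            handle.write("\t".join(SWEEP_COLUMNS) + "\n")
            handle.flush()
    try:
        for code in codes:
            for gi, pi in enumerate(grid):
                a, t, c, g = pi.as_atcg()
                for direction in directions:
                    key = (code.id, round(a, 9), round(t, 9), round(c, 9),
                           round(g, 9), direction)
                    if key in done:
                        continue
                    seed = _derived_seed(cfg.seed, code.id, gi)
                    local = replace(cfg, seed=seed, direction=direction)
                    rec = optimize_fpi(code, pi, acceptance, local)
                    row = (
                        [code.id, a, t, c, g, direction, rec.best_value]
                        + list(rec.best_params.sym)
                        + list(rec.best_params.circ)
                        + [seed, cfg.generations]
                    )
                    rows.append(row)
                    if handle is not None:
                        handle.write("\t".join(map(str, row)) + "\n")
                        handle.flush()
    finally:
        if handle is not None:
            handle.close()
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def percent_change(value: float, reference: float) -> float:
    """Percent change relative to a reference value."""
    return 100.0 * (value - reference) / reference


def descriptive_stats(sweep: pd.DataFrame, reference_code: int = 1) -> pd.DataFrame:
    """Per-code min/median/max of optimized F_pi plus percent changes.

    Operates on the "max" direction rows if a direction column is present
    with both directions; the summary of each code is over its pressures.
    """
    df = sweep
    if "direction" in df.columns and df["direction"].nunique() > 1:
        df = df[df["direction"] == "max"]
    stats = (
        df.groupby("code_id")["Fpi"]
        .agg(min_Fpi="min", me_Fpi="median", max_Fpi="max")
        .reset_index()
    )
    if reference_code not in set(stats["code_id"]):
        raise ValueError(f"reference code {reference_code} is missing from the sweep")
    ref = stats.loc[stats["code_id"] == reference_code].iloc[0]
    for col in ("min_Fpi", "me_Fpi", "max_Fpi"):
        stats["pct_" + col] = percent_change(stats[col], ref[col])
    return stats
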