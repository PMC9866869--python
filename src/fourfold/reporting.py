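"""Statistical comparisons and summary tables for sweep results.

Covers the three report surfaces around the grid sweep: paired comparisons
of substitution rates between pressure sets (Wilcoxon signed-rank with
Benjamini-Hochberg correction across the 12 substitutions), extremal-
composition summaries per code, and rank-based comparisons of F / F_pi value
samples (Kruskal-Wallis with median ratio). All tables are pure functions of
their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .codons import NUCLEOTIDES
from .mutation import NucleotideRateMatrix

__all__ = [
    "RateComparisonResult",
    "compare_rates",
    "composition_summary",
    "distribution_comparison",
    "binned_median_table",
]

#: the 12 ordered substitutions i->j, row-major over ACGT
SUBSTITUTIONS: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in NUCLEOTIDES for b in NUCLEOTIDES if a != b
)


@dataclass(frozen=True)
class RateComparisonResult:
    per_substitution: Mapping[str, dict]
    alpha: float

    def significant(self) -> list[str]:
        return [
            k
            for k, v in self.per_substitution.items()
            if v["p_adjusted"] < self.alpha
        ]


def _rate_array(matrices: Sequence[NucleotideRateMatrix | np.ndarray]) -> np.ndarray:
    out = []
    for m in matrices:
        q = m.q if isinstance(m, NucleotideRateMatrix) else np.asarray(m, dtype=float)
        out.append([q[NUCLEOTIDES.index(a), NUCLEOTIDES.index(b)] for a, b in SUBSTITUTIONS])
    return np.array(out)


def compare_rates(
    min_pressures: Sequence[NucleotideRateMatrix | np.ndarray],
    max_pressures: Sequence[NucleotideRateMatrix | np.ndarray],
    alpha: float = 0.05,
) -> RateComparisonResult:
    """Paired signed-rank comparison of the 12 substitution rates.

    The two lists must be paired (same codes / pressure indices). For each
    substitution a two-sided Wilcoxon signed-rank test is applied to the
    paired differences (exact null for small samples without ties, normal
    approximation with continuity correction otherwise, scipy's default
    policy), then Benjamini-Hochberg adjustment across the 12 substitutions.
    """
    if len(min_pressures) != len(max_pressures):
        raise ValueError("paired inputs must have equal length")
    if len(min_pressures) < 6:
        raise ValueError("need at least 6 pairs for a meaningful signed-rank test")
    lo = _rate_array(min_pressures)
    hi = _rate_array(max_pressures)
    raw_p = []
    medians_lo = np.median(lo, axis=0)
    medians_hi = np.median(hi, axis=0)
    for k in range(12):
        diff = hi[:, k] - lo[:, k]
        if np.allclose(diff, 0.0):
            raw_p.append(1.0)
        else:
            raw_p.append(float(sps.wilcoxon(hi[:, k], lo[:, k]).pvalue))
    _, adj_p, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
    per = {}
    for k, (a, b) in enumerate(SUBSTITUTIONS):
        med_diff = medians_hi[k] - medians_lo[k]
        per[f"{a}->{b}"] = {
            "median_min": float(medians_lo[k]),
            "median_max": float(medians_hi[k]),
            "p_raw": float(raw_p[k]),
            "p_adjusted": float(adj_p[k]),
            "direction": "higher_in_max" if med_diff > 0 else (
                "higher_in_min" if med_diff < 0 else "equal"
            ),
        }
    return RateComparisonResult(per_substitution=per, alpha=alpha)


def composition_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-code extremal compositions: the pressures attaining min and max F_pi.

    Requires both directions in the sweep ("max" rows locate the maximizing
    pressure; among "max" rows the minimum over pressures locates the
    composition that minimizes the maximized strength).
    """
    if "direction" not in sweep.columns or set(sweep["direction"]) < {"max"}:
        raise ValueError("sweep must contain direction column with 'max' rows")
    rows = []
    for code_id, df in sweep[sweep["direction"] == "max"].groupby("code_id"):
        for which, idx in (("min", df["Fpi"].idxmin()), ("max", df["Fpi"].idxmax())):
            r = df.loc[idx]
            rows.append(
                {
                    "code_id": int(code_id),
                    "extremum": which,
                    "A": r["A"],
                    "T": r["T"],
                    "C": r["C"],
                    "G": r["G"],
                    "AT": r["A"] + r["T"],
                    "GC": r["G"] + r["C"],
                    "Fpi": r["Fpi"],
                }
            )
    return pd.DataFrame(rows)


def distribution_comparison(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> dict:
    """Kruskal-Wallis comparison of two value samples with median ratio."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if np.array_equal(np.sort(a), np.sort(b)):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(a, b)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "median_a": med_a,
        "median_b": med_b,
        "median_ratio": med_a / med_b if med_b != 0 else np.inf,
    }


def binned_median_table(
    sweep: pd.DataFrame, bin_edges: Sequence[float] = (0.0, 0.25, 0.45, 0.65, 1.0)
) -> pd.DataFrame:
    """Median maximized F_pi per code, binned by A+T content of the pressure."""
    df = sweep[sweep["direction"] == "max"] if "direction" in sweep.columns else sweep
    at = df["A"] + df["T"]
    rows = []
    for code_id, sub in df.groupby("code_id"):
        at_sub = sub["A"] + sub["T"]
        for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
            mask = (at_sub > lo) & (at_sub <= hi)
            if mask.sum():
                rows.append(
                    {
                        "code_id": int(code_id),
                        "AT_bin_low": lo,
                        "AT_bin_high": hi,
                        "n": int(mask.sum()),
                        "median_Fpi": float(sub.loc[mask, "Fpi"].median()),
                    }
                )
    return pd.DataFrame(rows)
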