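"""Count series over frames and inter-expression correlation coefficients.

For a micro-interaction expression *x*, C_x(t) is the number of matches in
frame *t*.  With ΔC_i = C_i − μ_i, the correlation between two expressions
is the normalised covariance

    C_{x−y} = ⟨ΔC_x · ΔC_y⟩ / sqrt(⟨ΔC_x²⟩ ⟨ΔC_y²⟩)

with ⟨·⟩ a population average over frames: fully correlated at 1.0,
uncorrelated at 0.0.  All means and standard deviations reported here are
population statistics (divide by T), matching the ensemble-average
notation; at trajectory lengths in the thousands the distinction from
sample statistics is negligible, but it is deliberate and documented.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import StatisticsError

__all__ = [
    "CountSeries",
    "correlation",
    "correlation_matrix",
    "summarize",
    "percentage_ratio",
    "cross_correlation_block",
]


@dataclass
class CountSeries:
    """Per-frame match counts for one expression."""

    name: str
    counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise StatisticsError("counts must be one-dimensional")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        """Population standard deviation of the per-frame counts."""
        return float(np.std(self.counts))


def correlation(x: CountSeries, y: CountSeries) -> float:
    """C_{x−y} as defined above; raises for constant series.

    A constant series has ⟨ΔC²⟩ = 0 and its correlation with anything is
    undefined — that is surfaced as an error, never silently set to 0.
    """
    if len(x) != len(y):
        raise StatisticsError(
            f"series lengths differ: {len(x)} ({x.name}) vs {len(y)} ({y.name})"
        )
    if len(x) < 2:
        raise StatisticsError("correlation requires at least two frames")
    dx = x.counts - np.mean(x.counts)
    dy = y.counts - np.mean(y.counts)
    var_x = float(np.mean(dx * dx))
    var_y = float(np.mean(dy * dy))
    if var_x == 0.0 or var_y == 0.0:
        constant = x.name if var_x == 0.0 else y.name
        raise StatisticsError(
            f"correlation undefined: series '{constant}' is constant"
        )
    c = float(np.mean(dx * dy) / np.sqrt(var_x * var_y))
    return max(-1.0, min(1.0, c))


def correlation_matrix(series: list[CountSeries]) -> pd.DataFrame:
    """Symmetric matrix of C_{x−y} over all expression pairs."""
    names = [s.name for s in series]
    n = len(series)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = correlation(series[i], series[j])
    return pd.DataFrame(out, index=names, columns=names)


def summarize(series: list[CountSeries]) -> pd.DataFrame:
    """One row per expression: mean μ and population SD σ, input order."""
    if not series:
        raise StatisticsError("no series to summarize")
    return pd.DataFrame(
        {
            "expression": [s.name for s in series],
            "mean": [s.mean for s in series],
            "sd": [s.sd for s in series],
        }
    )


def percentage_ratio(
    numerator_mean: float, denominator_mean: float, decimals: int = 1
) -> float:
    """100 × numerator/denominator, rounded half-away-from-zero.

    E.g. mean counts 1.69 of 113.50 → 1.5 (%); 418.90 of 581.28 → 72 (%).
    """
    if denominator_mean == 0:
        raise StatisticsError("percentage of a zero denominator")
    value = 100.0 * numerator_mean / denominator_mean
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def cross_correlation_block(
    hb_series: list[CountSeries], hp_series: list[CountSeries]
) -> pd.DataFrame:
    """All hydrogen-bond × hydrophobic pairwise correlations in one table."""
    if not hb_series or not hp_series:
        raise StatisticsError("both series sets must be non-empty")
    data = {
        hp.name: [correlation(hb, hp) for hb in hb_series] for hp in hp_series
    }
    return pd.DataFrame(data, index=[s.name for s in hb_series])
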