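"""Rank-based comparison of selection methods across datasets.

Given a methods x datasets grid of an error metric (lower is better), the
pipeline ranks the methods within each dataset (mid-ranks on ties),
averages the ranks, tests the omnibus null of no method differences with
the Friedman chi-square and its Iman–Davenport F correction,

    chi2_F = 12 N / (k(k+1)) * (sum_j Rbar_j^2 - k(k+1)^2 / 4)
    F_F    = (N - 1) chi2_F / (N(k-1) - chi2_F),

and follows up with Holm step-down tests of every method against a
control, using the large-sample normal statistic

    z_j = (Rbar_j - Rbar_control) / sqrt(k(k+1) / (6N)).

No tie-correction factor is applied to chi2_F (mid-ranks only), matching
the convention of the benchmark this package reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigError, DegenerateStatisticError


@dataclass
class RankTable:
    """Metric grid with per-dataset ranks and average ranks."""

    methods: list[str]
    datasets: list[str]
    metrics: np.ndarray  # k x Nd, lower = better
    ranks: np.ndarray  # k x Nd mid-ranks
    avg_ranks: np.ndarray  # length k

    @property
    def k(self) -> int:
        return len(self.methods)

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ranks, index=self.methods, columns=self.datasets)
        df["avg_rank"] = self.avg_ranks
        return df


def rank_methods(
    metrics: np.ndarray | pd.DataFrame,
    methods: list[str] | None = None,
    datasets: list[str] | None = None,
) -> RankTable:
    """Rank methods within each dataset, ascending, mid-ranks on ties."""
    if isinstance(metrics, pd.DataFrame):
        methods = methods or [str(m) for m in metrics.index]
        datasets = datasets or [str(d) for d in metrics.columns]
        metrics = metrics.to_numpy(dtype=float)
    metrics = np.asarray(metrics, dtype=float)
    if metrics.ndim != 2:
        raise ConfigError("metrics must be a 2-d methods x datasets grid")
    if not np.all(np.isfinite(metrics)):
        raise ConfigError("metrics contain NaN or infinite values")
    k, nd = metrics.shape
    methods = methods or [f"method{i+1}" for i in range(k)]
    datasets = datasets or [f"dataset{j+1}" for j in range(nd)]
    ranks = np.column_stack(
        [stats.rankdata(metrics[:, j], method="average") for j in range(nd)]
    )
    return RankTable(methods, datasets, metrics, ranks, ranks.mean(axis=1))


def friedman_chi2(avg_ranks: np.ndarray, n_datasets: int) -> float:
    """Friedman chi-square from the average ranks of k methods."""
    R = np.asarray(avg_ranks, dtype=float)
    k = R.size
    if k < 2 or n_datasets < 2:
        raise ConfigError("need k >= 2 methods and >= 2 datasets")
    return float(
        12.0 * n_datasets / (k * (k + 1)) * (np.sum(R**2) - k * (k + 1) ** 2 / 4.0)
    )


def iman_davenport(chi2: float, n_datasets: int, k: int) -> float:
    """Iman–Davenport F correction of the Friedman chi-square."""
    denom = n_datasets * (k - 1) - chi2
    if denom <= 0:
        raise DegenerateStatisticError(
            "N(k-1) - chi2 <= 0: Iman-Davenport statistic undefined"
        )
    return float((n_datasets - 1) * chi2 / denom)


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper critical value of the F(df1, df2) distribution at level alpha."""
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def holm_posthoc(
    avg_ranks: np.ndarray,
    n_datasets: int,
    k: int | None = None,
    control: int = 0,
    alpha: float = 0.1,
    methods: list[str] | None = None,
) -> pd.DataFrame:
    """Holm step-down comparison of every method against a control.

    Returns one row per method with z, raw two-sided normal p-value,
    Holm-adjusted p-value (non-decreasing in |z| order after step-down
    enforcement), and a rejection flag at ``alpha``.  The control's own
    row carries p = 1 and is excluded from the adjustment family.
    """
    R = np.asarray(avg_ranks, dtype=float)
    k = k or R.size
    if not 0 <= control < k:
        raise ConfigError("control index out of range")
    se = np.sqrt(k * (k + 1) / (6.0 * n_datasets))
    z = (R - R[control]) / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_raw[control] = 1.0

    others = [i for i in range(k) if i != control]
    m = len(others)
    order = sorted(others, key=lambda i: p_raw[i])
    p_holm = np.ones(k)
    running = 0.0
    for rank_pos, i in enumerate(order):
        running = max(running, (m - rank_pos) * p_raw[i])
        p_holm[i] = min(1.0, running)
    reject = p_holm <= alpha
    reject[control] = False

    names = methods or [f"method{i+1}" for i in range(k)]
    return pd.DataFrame(
        {
            "method": names,
            "avg_rank": R,
            "z": z,
            "p_raw": p_raw,
            "p_holm": p_holm,
            "reject": reject,
        }
    )


@dataclass
class ComparisonReport:
    """Bundle of the full rank -> omnibus -> post hoc pipeline."""

    table: RankTable
    chi2: float
    ff: float
    alpha: float
    f_crit: float
    significant: bool
    holm: pd.DataFrame


def compare_methods(
    metrics: pd.DataFrame | np.ndarray,
    control: int = 0,
    alpha: float = 0.1,
    methods: list[str] | None = None,
    datasets: list[str] | None = None,
    rank_precision: int | None = None,
) -> ComparisonReport:
    """Run the whole comparison pipeline on a metric grid.

    ``rank_precision`` optionally rounds the average ranks before the
    omnibus statistics, reproducing published values computed from ranks
    reported at fixed display precision.
    """
    table = rank_methods(metrics, methods, datasets)
    avg = table.avg_ranks
    if rank_precision is not None:
        avg = np.round(avg, rank_precision)
    chi2 = friedman_chi2(avg, table.n_datasets)
    ff = iman_davenport(chi2, table.n_datasets, table.k)
    crit = f_critical(alpha, table.k - 1, (table.k - 1) * (table.n_datasets - 1))
    holm = holm_posthoc(
        table.avg_ranks, table.n_datasets, table.k, control, alpha, table.methods
    )
    return ComparisonReport(table, chi2, ff, alpha, crit, ff > crit, holm)
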