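"""Predictive-performance scoring and rank-based method comparison.

Long-term predictions are scored with the relative root mean squared error

    ReRMSE = sqrt( sum_t (y_t - yhat_t)^2 / sum_t (y_t - ybar)^2 ),

the prediction error relative to the variability of the system variable in
the test data, which makes errors comparable across variables measured on
different scales. A mean predictor scores exactly 1.

Methods are compared across datasets with average ranks, the
Iman–Davenport-corrected Friedman test, and the Nemenyi or Bonferroni–Dunn
post-hoc critical distance CD = q_alpha * sqrt(k (k + 1) / (6 N)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import TimeSeriesDataset, Trajectory


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ReRMSE
# ---------------------------------------------------------------------------


def rermse(test: TimeSeriesDataset, traj: Trajectory, printed_variant: bool = False) -> float:
    """Relative root mean squared error of a trajectory on a test set.

    The denominator is the observed variability sum((y_t - ybar)^2); with
    ``printed_variant=True`` it is sum((ybar - yhat_t)^2) instead (a
    formulation that does not give the mean predictor a score of 1). With
    several endogenous variables the per-variable scores are averaged. A
    failed trajectory scores +inf.
    """
    if len(test) < 2:
        raise EvaluationError("ReRMSE needs at least 2 test points")
    if not traj.ok:
        return float("inf")
    scores = []
    for v in test.endogenous:
        y = test.values(v)
        y_hat = traj[v]
        mask = np.isfinite(y)
        y, y_hat = y[mask], y_hat[mask]
        if not np.all(np.isfinite(y_hat)):
            scores.append(float("inf"))
            continue
        y_bar = y.mean()
        denom = ((y_bar - y_hat) ** 2).sum() if printed_variant else ((y - y_bar) ** 2).sum()
        if denom == 0:
            raise EvaluationError(f"ReRMSE undefined: zero variance for {v!r} in test data")
        scores.append(float(np.sqrt(((y - y_hat) ** 2).sum() / denom)))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# error tables and ranks
# ---------------------------------------------------------------------------


def rank_row(errors) -> np.ndarray:
    """Ascending ranks (1 = smallest error); ties get averaged ranks."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise EvaluationError("cannot rank an empty row")
    return stats.rankdata(errors, method="average")


@dataclass
class ErrorTable:
    """Datasets (rows) x methods (columns) table of ReRMSE values."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise EvaluationError("error table has missing cells")

    @classmethod
    def from_csv(cls, path) -> "ErrorTable":
        return cls(pd.read_csv(path, index_col=0))

    @property
    def methods(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_datasets(self) -> int:
        return len(self.frame)

    def ranks(self) -> pd.DataFrame:
        """Per-dataset ranks of the methods (ascending, ties averaged)."""
        return self.frame.apply(lambda row: pd.Series(rank_row(row.values), index=row.index), axis=1)

    def average_ranks(self) -> pd.Series:
        return self.ranks().mean(axis=0)


def count_wins(tbl: ErrorTable, method: str, rivals) -> int:
    """Rows where *method*'s error is strictly smallest among it and *rivals*."""
    cols = [method] + [r for r in rivals if r != method]
    for c in cols:
        if c not in tbl.frame.columns:
            raise EvaluationError(f"unknown method column {c!r}")
    sub = tbl.frame[cols].to_numpy(dtype=float)
    others = sub[:, 1:]
    if others.shape[1] == 0:
        return int(len(sub))  # vacuous: a method always beats no rivals
    return int(np.sum(sub[:, 0] < others.min(axis=1)))


# ---------------------------------------------------------------------------
# Friedman test and post-hoc critical distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankComparison:
    average_ranks: pd.Series
    chi2_f: float  # Friedman statistic from average ranks
    f_stat: float | None  # Iman-Davenport corrected statistic
    p_value: float | None  # of the corrected F statistic
    critical_distance: float | None
    posthoc: str
    alpha: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        """Method pairs whose average-rank gap exceeds the critical distance."""
        if self.critical_distance is None:
            return []
        out = []
        names = list(self.average_ranks.index)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if abs(self.average_ranks[a] - self.average_ranks[b]) > self.critical_distance:
                    out.append((a, b))
        return out


def critical_value(k: int, alpha: float = 0.05, test: str = "nemenyi") -> float:
    """q_alpha for a post-hoc test over k methods.

    Nemenyi: the studentized-range quantile at infinite degrees of freedom
    divided by sqrt(2); Bonferroni-Dunn: the two-sided normal quantile at
    alpha / (k - 1) (k - 1 comparisons against a control).
    """
    if k < 2:
        raise EvaluationError("post-hoc tests need at least 2 methods")
    if test == "nemenyi":
        return float(stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2))
    if test == "bonferroni-dunn":
        return float(stats.norm.ppf(1 - alpha / (2 * (k - 1))))
    raise EvaluationError(f"unknown post-hoc test {test!r}")


def compare_methods(tbl: ErrorTable, alpha: float = 0.05, test: str = "nemenyi") -> RankComparison:
    """Friedman test (Iman-Davenport corrected) with a post-hoc critical distance.

    chi2_F = 12N / (k (k+1)) * (sum_j R_j^2 - k (k+1)^2 / 4)
    F      = (N - 1) chi2_F / (N (k - 1) - chi2_F)
    CD     = q_alpha * sqrt(k (k + 1) / (6 N))

    A degenerate (all-methods-identical) table yields chi2_F = 0 and no
    post-hoc distance.
    """
    k = len(tbl.methods)
    n = tbl.n_datasets
    if k < 2 or n < 2:
        raise EvaluationError("comparison needs at least 2 methods and 2 datasets")
    avg = tbl.average_ranks()
    chi2 = 12.0 * n / (k * (k + 1)) * (float((avg**2).sum()) * 1.0 - k * (k + 1) ** 2 / 4.0)
    chi2 = max(chi2, 0.0)
    if chi2 == 0.0:
        return RankComparison(avg, 0.0, None, None, None, test, alpha)
    denom = n * (k - 1) - chi2
    f_stat = (n - 1) * chi2 / denom if denom > 0 else float("inf")
    p = float(stats.f.sf(f_stat, k - 1, (k - 1) * (n - 1))) if np.isfinite(f_stat) else 0.0
    cd = critical_value(k, alpha, test) * np.sqrt(k * (k + 1) / (6.0 * n))
    return RankComparison(avg, chi2, f_stat, p, float(cd), test, alpha)


def plot_critical_difference(comparison: RankComparison, path) -> None:
    """Save a simple average-rank diagram with the critical-distance bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranks = comparison.average_ranks.sort_values()
    k = len(ranks)
    fig, ax = plt.subplots(figsize=(7, 1.2 + 0.45 * k))
    ax.set_xlim(0.5, k + 0.5)
    ax.set_ylim(-k - 1.5, 1.5)
    ax.spines[["left", "right", "bottom"]].set_visible(False)
    ax.xaxis.tick_top()
    ax.set_xlabel("average rank")
    ax.xaxis.set_label_position("top")
    ax.set_yticks([])
    for i, (name, r) in enumerate(ranks.items()):
        y = -(i + 1)
        ax.plot([r, r], [0, y], "k-", lw=0.8)
        ax.text(r, y - 0.15, f"{name} ({r:.2f})", ha="center", va="top", fontsize=9)
    if comparison.critical_distance is not None:
        x0 = float(ranks.iloc[0])
        ax.plot([x0, x0 + comparison.critical_distance], [0.8, 0.8], "r-", lw=2)
        ax.text(
            x0 + comparison.critical_distance / 2,
            1.0,
            f"CD = {comparison.critical_distance:.3f}",
            ha="center",
            fontsize=9,
            color="red",
        )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
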