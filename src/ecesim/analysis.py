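"""Population-genetic and fitness statistics.

Genetic variance is measured directly as H, the sum of Hamming distances over
all unordered pairs of genomes in a population (raw digit units; also
reported per-pair and per-individual). Fitness trajectories are summarized
per generation (mean and population-SD) and per population by the
coefficients of an ordinary-least-squares cubic of fitness on generation,
w = A + B x + C x^2 + D x^3. Factorial-grid summaries include the cost of
transcription error: the final-generation fitness lost relative to the tau=0
column at the same mutation rate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import QuaternaryGenome

__all__ = ["VarianceSummary", "TrendFit", "FitError", "hamming_contributions",
           "hamming_H", "fitness_summaries", "fit_cubic", "trend_table",
           "cost_of_tau", "grid_matrix"]


class FitError(Exception):
    """Raised when a regression design is rank-deficient."""


@dataclass(frozen=True)
class VarianceSummary:
    H: int
    n_pairs: int
    mean_pairwise: float
    genome_length: int
    generation: int | None = None
    condition: tuple[float, float] | None = None
    replicate: int | None = None


@dataclass(frozen=True)
class TrendFit:
    A: float
    B: float
    C: float
    D: float
    rss: float
    n: int

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D])


def _genome_matrix(genomes) -> np.ndarray:
    rows = [g.digits if isinstance(g, QuaternaryGenome) else np.asarray(g)
            for g in genomes]
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError("all genomes must have equal length")
    return np.stack(rows).astype(np.uint8)


def hamming_contributions(matrix: np.ndarray) -> np.ndarray:
    """Per-individual summed Hamming distance to all other rows.

    Uses per-position digit counts, O(n L) rather than O(n^2 L): at each
    position an individual differs from exactly (n - count of its own digit)
    others.
    """
    n, length = matrix.shape
    counts = np.stack([(matrix == v).sum(axis=0) for v in range(4)])
    matches = counts[matrix.astype(np.int64), np.arange(length)]
    return (n - matches).sum(axis=1)


def hamming_H(genomes, **context) -> VarianceSummary:
    """H = sum over unordered pairs of differing digit positions."""
    matrix = _genome_matrix(genomes)
    n, length = matrix.shape
    contrib = hamming_contributions(matrix)
    H = int(contrib.sum()) // 2
    n_pairs = n * (n - 1) // 2
    return VarianceSummary(H, n_pairs, H / n_pairs if n_pairs else 0.0,
                           length, **context)


def fitness_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-generation mean and SD of fitness.

    Groups by whichever of mu/tau/replicate/generation columns are present.
    The SD uses the population denominator n (every member of the population
    is observed, not sampled).
    """
    keys = [c for c in ("mu", "tau", "replicate", "generation")
            if c in table.columns]
    if "generation" not in keys:
        raise ValueError("table needs a 'generation' column")
    g = table.groupby(keys, sort=True)["fitness"]
    out = g.agg(mean_fitness="mean", sd_fitness=lambda s: s.std(ddof=0),
                n="size").reset_index()
    return out


def fit_cubic(x, y) -> TrendFit:
    """OLS fit of y on (1, x, x^2, x^3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 4:
        raise FitError("need at least 4 distinct x values for a cubic")
    X = np.vander(x, 4, increasing=True)
    coef, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise FitError("rank-deficient cubic design")
    rss = float(((y - X @ coef) ** 2).sum())
    return TrendFit(*map(float, coef), rss=rss, n=x.size)


def trend_table(table: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    """Cubic trend coefficients per population (condition x replicate).

    pooled=True regresses every individual's fitness on its generation (the
    default); pooled=False first averages fitness within generations.
    """
    keys = [c for c in ("mu", "tau", "replicate") if c in table.columns]
    rows = []
    grouped = table.groupby(keys) if keys else [((), table)]
    for key, sub in grouped:
        if pooled:
            fit = fit_cubic(sub["generation"], sub["fitness"])
        else:
            means = sub.groupby("generation")["fitness"].mean()
            fit = fit_cubic(means.index.to_numpy(), means.to_numpy())
        key = key if isinstance(key, tuple) else (key,)
        rows.append({**dict(zip(keys, key)), "A": fit.A, "B": fit.B,
                     "C": fit.C, "D": fit.D, "rss": fit.rss, "n": fit.n})
    return pd.DataFrame(rows)


def cost_of_tau(grid: pd.DataFrame,
                value: str = "mean_fitness") -> pd.DataFrame:
    """Fitness loss relative to the tau=0 baseline at the same mu.

    `grid` holds one row per (mu, tau[, replicate]) with a final-generation
    fitness column; replicates are averaged first. Returns tidy rows
    (mu, tau, loss) with loss(mu, tau) = value(mu, 0) - value(mu, tau).
    """
    cols = {"mu", "tau", value}
    if not cols.issubset(grid.columns):
        raise ValueError(f"grid needs columns {sorted(cols)}")
    means = grid.groupby(["mu", "tau"], sort=True)[value].mean().reset_index()
    base = means[means["tau"] == 0.0].set_index("mu")[value]
    if base.empty or not set(means["mu"]).issubset(base.index):
        raise ValueError("missing tau=0 baseline cell for some mu")
    means["loss"] = means["mu"].map(base) - means[value]
    return means[["mu", "tau", "loss"]]


def grid_matrix(tidy: pd.DataFrame, value: str) -> pd.DataFrame:
    """Wide (rows mu, columns tau) matrix for heatmap plotting."""
    return tidy.pivot_table(index="mu", columns="tau", values=value,
                            aggfunc="mean")
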