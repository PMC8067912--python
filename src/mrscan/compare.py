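"""Diagnostics comparing simulated and analytical scan matrices.

Matrices are normalized to grand mean one, log-transformed, and
compared by Pearson correlation — on all elements and on the row/column
marginal profiles.  Convergence curves record these correlations over a
grid of mutation counts M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import InconsistentInputsError, NonNormalizableError
from .mrs import marginal_profiles

#: fraction of nonpositive (log-excluded) entries above which a warning fires
EXCLUSION_WARN_FRACTION = 0.01


class LogExclusionWarning(UserWarning):
    """More than 1% of entries were excluded from the log transform."""


@dataclass
class ComparisonReport:
    """Correlations between a simulated and an analytical scan matrix."""

    normalized: bool
    pearson_R_matrix: float | None = None
    pearson_R_influence: float | None = None
    pearson_R_sensitivity: float | None = None
    n_excluded: int = 0
    convergence: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["comparison report (mean-1 normalized, log-transformed)"]
        if self.pearson_R_matrix is not None:
            lines.append(f"R_matrix      = {self.pearson_R_matrix:.4f}")
        if self.pearson_R_influence is not None:
            lines.append(f"R_col_profile = {self.pearson_R_influence:.4f}")
        if self.pearson_R_sensitivity is not None:
            lines.append(f"R_row_profile = {self.pearson_R_sensitivity:.4f}")
        if self.n_excluded:
            lines.append(f"excluded nonpositive entries: {self.n_excluded}")
        if self.convergence is not None:
            lines.append(self.convergence.to_string(index=False))
        return "\n".join(lines)


def normalize_mean_one(matrix: np.ndarray) -> np.ndarray:
    """Divide by the grand mean so the result averages exactly to one."""
    m = np.asarray(matrix, dtype=float)
    mean = m.mean()
    if not mean > 0:
        raise NonNormalizableError(f"grand mean is {mean}; cannot normalize")
    return m / mean


def log_pearson(a: np.ndarray, b: np.ndarray, exclude_diagonal: bool = False) -> float:
    """Pearson correlation of the elementwise logs of two positive arrays.

    Both inputs are first normalized to mean one (the correlation is
    invariant to positive rescaling of either input).  Nonpositive
    entries are excluded pairwise; if more than 1% of entries are
    dropped a :class:`LogExclusionWarning` is emitted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InconsistentInputsError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = normalize_mean_one(a)
    b = normalize_mean_one(b)
    if exclude_diagonal and a.ndim == 2 and a.shape[0] == a.shape[1]:
        off = ~np.eye(a.shape[0], dtype=bool)
        a, b = a[off], b[off]
    a, b = a.ravel(), b.ravel()
    mask = (a > 0) & (b > 0)
    n_excluded = int(a.size - mask.sum())
    if n_excluded > EXCLUSION_WARN_FRACTION * a.size:
        warnings.warn(
            f"{n_excluded}/{a.size} nonpositive entries excluded from "
            "log-correlation",
            LogExclusionWarning,
            stacklevel=2,
        )
    return float(pearsonr(np.log(a[mask]), np.log(b[mask])).statistic)


def compare_matrices(
    simulated: np.ndarray,
    analytical: np.ndarray,
    exclude_diagonal: bool = False,
) -> ComparisonReport:
    """Full report: matrix correlation plus both profile correlations."""
    sim = simulated.matrix if hasattr(simulated, "matrix") else np.asarray(simulated)
    ana = analytical.matrix if hasattr(analytical, "matrix") else np.asarray(analytical)
    p_sim = marginal_profiles(sim)
    p_ana = marginal_profiles(ana)
    return ComparisonReport(
        normalized=True,
        pearson_R_matrix=log_pearson(sim, ana, exclude_diagonal=exclude_diagonal),
        pearson_R_influence=log_pearson(p_sim.influence, p_ana.influence),
        pearson_R_sensitivity=log_pearson(p_sim.sensitivity, p_ana.sensitivity),
    )


def convergence_curve(
    analytical: np.ndarray,
    simulator,
    M_grid,
    seeds,
    exclude_diagonal: bool = False,
) -> ComparisonReport:
    """Correlation against the analytical matrix over a grid of M.

    ``simulator(M, seed)`` must return the simulated matrix.  The
    returned report carries a table with one row per (M, seed), sorted,
    with the matrix and both profile correlations.
    """
    M_grid = list(M_grid)
    if not M_grid:
        raise InconsistentInputsError("M grid is empty")
    if sorted(M_grid) != M_grid:
        raise InconsistentInputsError("M grid must be increasing")
    ana = analytical.matrix if hasattr(analytical, "matrix") else np.asarray(analytical)
    rows = []
    for M in M_grid:
        for seed in seeds:
            sim = simulator(M, seed)
            rep = compare_matrices(sim, ana, exclude_diagonal=exclude_diagonal)
            rows.append(
                {
                    "M": M,
                    "seed": seed,
                    "R_matrix": rep.pearson_R_matrix,
                    "R_row_profile": rep.pearson_R_sensitivity,
                    "R_col_profile": rep.pearson_R_influence,
                }
            )
    table = pd.DataFrame(rows).sort_values(["M", "seed"]).reset_index(drop=True)
    return ComparisonReport(normalized=True, convergence=table)
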