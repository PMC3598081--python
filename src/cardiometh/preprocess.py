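"""Signal-to-beta conversion, quantile normalization and sample QC.

Two-channel methylation arrays report a methylated (M) and an unmethylated
(U) fluorescence intensity per probe. The methylation fraction (beta value)
is M / (M + U + offset), with a small positive offset stabilising
low-intensity probes. Channels are quantile-normalized across samples before
beta computation so that every sample shares the same intensity
distribution, and samples whose overall intensity is an outlier are dropped
by a robust-z quality filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignalMatrix",
    "compute_beta",
    "quantile_normalize",
    "qc_filter",
    "signals_to_beta",
]

DEFAULT_BETA_OFFSET = 100.0  # Illumina-style stabilising constant, intensity units


@dataclass
class SignalMatrix:
    """Per-probe methylated/unmethylated channel intensities (probes x samples)."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.methylated.index.equals(self.unmethylated.index):
            raise ValueError("channel probe sets differ")
        if list(self.methylated.columns) != list(self.unmethylated.columns):
            raise ValueError("channel sample sets differ")
        if (self.methylated.to_numpy() < 0).any() or (
            self.unmethylated.to_numpy() < 0
        ).any():
            raise ValueError("negative intensities")

    @property
    def samples(self) -> list[str]:
        return list(self.methylated.columns)

    def total(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated

    def subset_samples(self, samples: list[str]) -> "SignalMatrix":
        return SignalMatrix(self.methylated[samples], self.unmethylated[samples])


def compute_beta(M, U, offset: float = DEFAULT_BETA_OFFSET):
    """Infinium-style beta value M / (M + U + offset), elementwise.

    Accepts scalars, arrays or DataFrames. Monotone increasing in M and
    decreasing in U; lies in [0, 1] whenever offset >= 0.
    """
    M_arr = np.asarray(M, dtype=float)
    U_arr = np.asarray(U, dtype=float)
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    if (M_arr < 0).any() or (U_arr < 0).any():
        raise ValueError("negative intensities")
    denom = M_arr + U_arr + offset
    if (denom == 0).any():
        raise ValueError("all-zero denominator: M + U + offset == 0")
    beta = M_arr / denom
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(beta, index=M.index, columns=M.columns)
    if np.isscalar(M) and np.isscalar(U):
        return float(beta)
    return beta


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column (sample) onto the common mean-quantile distribution.

    The reference distribution is the per-rank mean of the column-sorted
    values. Within a column, values are replaced by the reference value at
    their rank; tied values receive the mean of the reference values across
    their rank span, which makes the result independent of input row order.
    Idempotent up to floating-point tolerance.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values not allowed")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average reference values over tied spans
        sorted_vals = col[order]
        i = 0
        while i < len(sorted_vals):
            k = i
            while k + 1 < len(sorted_vals) and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                assigned[order[i : k + 1]] = ref[i : k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class QCReport:
    """Per-sample intensity statistics and pass/fail verdicts."""

    table: pd.DataFrame  # sample, mean_total_intensity, robust_z, passed
    z_threshold: float
    warnings: list[str] = field(default_factory=list)

    @property
    def passing(self) -> list[str]:
        return list(self.table.loc[self.table["passed"], "sample"])


def qc_filter(signals: SignalMatrix, z_threshold: float = 3.0) -> tuple[list[str], QCReport]:
    """Drop samples whose mean total intensity is a robust-z outlier.

    A sample fails when |mean(M+U) - median over samples| exceeds
    ``z_threshold`` robust z-units (median/MAD with the 1.4826 normal
    consistency factor). With a zero MAD, any deviation from the median
    fails. Returns the passing sample list plus a full report.
    """
    totals = signals.total().mean(axis=0)  # per sample
    if len(totals) < 3:
        raise ValueError("need at least 3 samples for QC")
    med = float(np.median(totals))
    mad = float(stats.median_abs_deviation(totals, scale="normal"))
    dev = np.abs(totals - med)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(dev == 0, 0.0, np.where(mad > 0, dev / mad, np.inf))
    passed = z <= z_threshold
    table = pd.DataFrame(
        {
            "sample": totals.index,
            "mean_total_intensity": totals.to_numpy(),
            "robust_z": z,
            "passed": passed,
        }
    ).reset_index(drop=True)
    warnings = [] if passed.any() else ["no samples passed QC"]
    return list(totals.index[passed]), QCReport(table, z_threshold, warnings)


def signals_to_beta(
    signals: SignalMatrix,
    offset: float = DEFAULT_BETA_OFFSET,
    normalize: bool = True,
    joint: bool = False,
) -> pd.DataFrame:
    """Quantile-normalize channels and convert to a beta matrix.

    Channels are normalized separately across samples by default; ``joint``
    stacks both channels into one matrix before normalization so they share
    a common reference distribution.
    """
    M, U = signals.methylated, signals.unmethylated
    if normalize:
        if joint:
            stacked = pd.concat([M, U], axis=0, keys=["M", "U"])
            norm = quantile_normalize(stacked)
            M, U = norm.loc["M"], norm.loc["U"]
        else:
            M, U = quantile_normalize(M), quantile_normalize(U)
    return compute_beta(M, U, offset=offset)
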