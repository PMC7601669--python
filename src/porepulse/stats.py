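"""Distribution, correlation, and regression diagnostics of event features.

Three diagnostics summarize an event table the way nanopore studies report
them: normalized density histograms of single features, the Pearson
correlation matrix of the five features, and an ordinary least-squares
regression of the relative blockade on the dwell time.  Density bins use
``d_i = f_i / (n * w_i)`` - counts relative to sample size and bin width -
so histograms from runs with different event counts are directly
comparable and integrate to one over the binned range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "DensityHistogram",
    "RegressionResult",
    "density_histogram",
    "correlation_matrix",
    "regress_blockade_on_dwell",
    "FEATURES_TWO",
    "FEATURES_FIVE",
    "DEFAULT_BLOCKADE_BIN_WIDTH",
    "DEFAULT_DWELL_BIN_WIDTH_S",
]

#: The classical feature pair and the full five-feature set.
FEATURES_TWO = ("rel_blockade", "dwell_s")
FEATURES_FIVE = ("rel_blockade", "dwell_s", "auc", "left_slope", "right_slope")

#: Conventional bin widths: 0.01 for the relative blockade, 200 us for the
#: dwell time (millisecond-scale events).
DEFAULT_BLOCKADE_BIN_WIDTH = 0.01
DEFAULT_DWELL_BIN_WIDTH_S = 200e-6


@dataclass(frozen=True)
class DensityHistogram:
    """Histogram with per-bin density ``d_i = f_i / (n * w_i)``."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    bin_width: float

    @property
    def density(self) -> np.ndarray:
        return self.counts / (self.n * self.bin_width)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares fit of one feature on another."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def density_histogram(
    values: np.ndarray,
    bin_width: float,
    range: tuple[float, float] | None = None,
) -> DensityHistogram:
    """Bin values into equal-width, left-closed bins anchored at zero.

    Bin edges are integer multiples of ``bin_width`` covering ``range`` (or
    the data range), which makes binning reproducible for positive-support
    features regardless of sample extremes.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    lo, hi = range if range is not None else (values.min(), values.max())
    first = np.floor(lo / bin_width)
    last = np.ceil(hi / bin_width)
    if last <= first:
        last = first + 1
    edges = np.arange(first, last + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return DensityHistogram(
        bin_edges=edges, counts=counts, n=values.size, bin_width=bin_width
    )


def correlation_matrix(
    table: pd.DataFrame, features: tuple[str, ...] = FEATURES_FIVE
) -> pd.DataFrame:
    """Pearson correlation matrix of the selected feature columns.

    Zero-variance columns yield ``NaN`` entries rather than a silent zero:
    an undefined correlation is not evidence of independence.
    """
    sub = table.loc[:, list(features)]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 events for correlations, got {len(sub)}")
    if not np.isfinite(sub.to_numpy()).all():
        raise ValueError("feature table contains non-finite values")
    return sub.corr(method="pearson")


def regress_blockade_on_dwell(
    table: pd.DataFrame,
    response: str = "rel_blockade",
    predictor: str = "dwell_s",
) -> RegressionResult:
    """OLS regression of the relative blockade on the dwell time.

    The returned R-squared equals the squared Pearson correlation of the
    two columns; a value far below one quantifies how little of the
    blockade-depth variation the dwell time explains.
    """
    if len(table) < 3:
        raise ValueError(f"need >= 3 events for a regression, got {len(table)}")
    x = table[predictor].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    fit = sp_stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=len(table),
    )
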