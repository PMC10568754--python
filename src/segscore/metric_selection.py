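"""PCA-based metric selection.

Given a table of image pairs (rows) by metric values (columns), principal
component analysis identifies the metrics carrying the most variance across
the compared segmentation models.  Components are retained up to a
cumulative explained-variance threshold (default 90%); each retained
component's absolute loading vector is weighted by its explained-variance
percentage, and a metric's importance is the sum of its weighted loadings
over the retained components.  The full component-by-metric weighted-loading
grid is also returned so a different aggregation (e.g. max) can be applied
by the caller.

Columns are mean-centered but *not* rescaled by default: the selection
statistic deliberately ranks metrics by how much variance they carry, and
rescaling every column to unit variance would erase exactly that signal.
Most segmentation metrics share the [0, 1] scale, so centering suffices;
``standardize=True`` is available for tables mixing incommensurate scales.

Missing values are handled explicitly: constant columns are dropped with a
warning, and rows containing undefined (NaN) cells are dropped complete-case
with the count reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class MetricImportance:
    """Result of :func:`pca_importance`.

    importance
        Per-metric importance score (sum of ``|loading| * variance%`` over
        the retained components), indexed by metric name.
    loading_grid
        Retained-component x metric grid of ``|loading| * variance%``.
    variance_ratios
        Explained-variance ratios of *all* components, non-increasing.
    retained_components
        Number of leading components whose cumulative ratio first reaches
        the threshold.
    dropped_columns, dropped_rows
        Constant columns removed, and count of incomplete rows removed.
    """

    importance: pd.Series
    loading_grid: pd.DataFrame
    variance_ratios: np.ndarray
    retained_components: int
    dropped_columns: list[str]
    dropped_rows: int


def pca_importance(
    table: pd.DataFrame,
    cum_variance_threshold: float = 0.9,
    standardize: bool = False,
) -> MetricImportance:
    """Rank metrics by PCA ``|loading| x explained-variance%`` importance."""
    if not 0.0 < cum_variance_threshold <= 1.0:
        raise ValueError("cum_variance_threshold must be in (0, 1]")
    df = pd.DataFrame(table).apply(pd.to_numeric)
    if df.shape[1] < 2 or len(df) < 2:
        raise ValueError(f"metric table needs >= 2 rows and >= 2 columns, got {df.shape}")
    n_rows_in = len(df)
    df = df.dropna(axis=0, how="any")
    dropped_rows = n_rows_in - len(df)

    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant metric columns before PCA: {constant}",
            stacklevel=2,
        )
        df = df.drop(columns=constant)

    if len(df) < 2 or df.shape[1] < 1:
        raise ValueError(
            f"PCA needs >= 2 complete rows and >= 1 non-constant column, "
            f"got {df.shape} after cleaning"
        )

    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        x = x / x.std(axis=0, ddof=0)

    pca = PCA(svd_solver="full")
    pca.fit(x)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    retained = int(np.searchsorted(cum, cum_variance_threshold) + 1)
    retained = min(retained, len(ratios))

    weighted = np.abs(pca.components_[:retained]) * (ratios[:retained, None] * 100.0)
    grid = pd.DataFrame(
        weighted,
        index=[f"PC{i + 1}" for i in range(retained)],
        columns=df.columns,
    )
    importance = grid.sum(axis=0)
    return MetricImportance(
        importance=importance,
        loading_grid=grid,
        variance_ratios=ratios,
        retained_components=retained,
        dropped_columns=constant,
        dropped_rows=dropped_rows,
    )


def select_top(imp: MetricImportance, k: int) -> list[str]:
    """Top-``k`` metric names by importance; ties broken alphabetically."""
    if k > len(imp.importance):
        raise ValueError(f"k={k} exceeds the {len(imp.importance)} available metrics")
    ranked = sorted(imp.importance.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]
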