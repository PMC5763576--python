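"""Correlation and principal-component views of the aging-marker panel.

The marker table has one row per donor×passage group and six columns:
mean cell area (μm²), PD/day, p16 and p21 expression (relative to a
loading control), SA-β-gal activity (RFU) and mean telomere length
(kbp).  Pearson correlations quantify how each marker tracks cell
enlargement; PCA (on standardized columns) visualizes the shared aging
axis — PC1 is oriented so the mean-cell-area loading is positive, which
places proliferation (PD/day) on the negative side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MARKER_COLUMNS

__all__ = ["MARKER_COLUMNS", "PCAResult", "pearson_matrix", "pca_markers", "heatmap_export"]


def pearson_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations of the marker columns.

    Requires at least three complete rows.  A constant column has no
    defined correlation: its entries are NaN and a warning is issued.
    """
    columns = columns or [c for c in MARKER_COLUMNS if c in table.columns]
    if len(columns) < 2:
        raise ValueError("need at least two marker columns")
    data = table[columns]
    if data.isna().any().any():
        raise ValueError("missing values in correlated columns")
    if len(data) < 3:
        raise ValueError("need at least 3 rows for correlation")
    constant = [c for c in columns if data[c].nunique() == 1]
    if constant:
        warnings.warn(f"constant columns, correlations undefined: {constant}", stacklevel=2)
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables × components
    scores: pd.DataFrame  # rows × components
    explained_variance_ratio: np.ndarray
    rank: int


def pca_markers(table: pd.DataFrame, columns: list[str] | None = None) -> PCAResult:
    """PCA of the standardized marker columns.

    Columns are centred and scaled to unit variance (ddof=1) before the
    decomposition; components are ordered by explained variance.  Sign
    convention: PC1 is oriented so the mean-cell-area loading (or, if
    absent, the first column's loading) is positive; later components
    orient their largest-magnitude loading positive.  Components beyond
    the numerical rank are flagged via ``rank``.
    """
    columns = columns or [c for c in MARKER_COLUMNS if c in table.columns]
    data = table[columns].to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 rows for PCA")
    if np.isnan(data).any():
        raise ValueError("missing values in marker columns")
    sd = data.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column; standardization undefined")
    z = (data - data.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2 / (data.shape[0] - 1)
    evr = var / var.sum()
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    loadings = vt.T  # columns are components
    scores = u * s
    anchor = columns.index("mean_cell_area") if "mean_cell_area" in columns else 0
    for k in range(loadings.shape[1]):
        pivot = loadings[anchor, k] if k == 0 else loadings[np.argmax(np.abs(loadings[:, k])), k]
        if pivot < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=columns, columns=comp_names),
        scores=pd.DataFrame(scores, columns=comp_names, index=table.index),
        explained_variance_ratio=evr,
        rank=rank,
    )


def heatmap_export(matrix: pd.DataFrame, path) -> None:
    """Circle-style correlation heat map (red positive, blue negative,
    circle radius proportional to |r|)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matrix.size == 0:
        raise ValueError("empty correlation matrix")
    names = list(matrix.index)
    n = len(names)
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * n, 1.0 + 0.8 * n))
    for i in range(n):
        for j in range(n):
            r = matrix.iloc[i, j]
            if np.isnan(r):
                continue
            color = "#c0392b" if r >= 0 else "#2e6da4"
            ax.add_patch(
                plt.Circle((j, n - 1 - i), 0.45 * min(abs(r), 1.0), color=color)
            )
    ax.set_xlim(-0.6, n - 0.4)
    ax.set_ylim(-0.6, n - 0.4)
    ax.set_xticks(range(n), names, rotation=45, ha="right")
    ax.set_yticks(range(n), names[::-1])
    ax.set_aspect("equal")
    ax.set_title("Pearson correlation")
    fig.tight_layout()
    fig.savefig(path, metadata=_stable_metadata(path))
    plt.close(fig)


def _stable_metadata(path) -> dict:
    """Strip timestamps so identical inputs give identical bytes."""
    suffix = str(path).lower()
    if suffix.endswith(".png"):
        return {"Software": "mscmorph"}
    if suffix.endswith(".svg"):
        return {"Date": None}
    return {}
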