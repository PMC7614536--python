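"""Mean-one normalisation, complete-case filtering, and covariance PCA.

Each metabolite column is rescaled so its mean is exactly one (putting
metabolites with very different absolute levels — 25(OH)D3 at tens of nM,
1,25(OH)2D3 at fractions of a nM — on a common footing without imposing
unit variance), rows with any missing required metabolite are removed, and
principal components are extracted from the sample covariance of the
centred, scaled matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "complete_case_filter",
    "mean_scale",
    "principal_components",
    "DEFAULT_PCA_METABOLITES",
]

# the panel used for the PCA: the four modelled metabolites plus 25(OH)D2.
# The identity of the fifth analyte is a configuration assumption.
DEFAULT_PCA_METABOLITES = ("c25_nM", "c3epi25_nM", "c125_nM", "c2425_nM", "c25D2_nM")


@dataclass(frozen=True)
class PCAResult:
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_fraction: np.ndarray
    scores: np.ndarray  # (n_subjects, n_components)
    centre: np.ndarray  # post-scaling column means subtracted before PCA
    scaling_factors: np.ndarray | None = field(default=None)


def complete_case_filter(table: pd.DataFrame, required) -> pd.DataFrame:
    """Keep only rows where every required metabolite is present and positive.

    Per-group surviving counts are recorded in
    ``result.attrs["complete_case_counts"]``.  An empty result warns rather
    than raising.
    """
    required = list(required)
    out = table
    if required:
        missing_cols = [c for c in required if c not in table.columns]
        if missing_cols:
            raise KeyError(f"required metabolite columns absent: {missing_cols}")
        mask = np.ones(len(table), dtype=bool)
        for c in required:
            v = table[c].to_numpy(dtype=float)
            mask &= ~np.isnan(v) & (v > 0.0)
        out = table[mask]
    out = out.copy()
    out.attrs = dict(table.attrs)
    if "group" in out.columns:
        out.attrs["complete_case_counts"] = out["group"].value_counts().to_dict()
    if len(out) == 0:
        warnings.warn("complete-case filter removed every row", stacklevel=2)
    return out


def mean_scale(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each column to mean exactly one.

    Returns ``(scaled, factors)`` with ``scaled[:, j] = factors[j] * matrix[:, j]``.
    Columns with non-positive mean cannot be normalised this way and raise.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x metabolites)")
    means = X.mean(axis=0)
    if np.any(~np.isfinite(means)) or np.any(means <= 0.0):
        raise ValueError("every column mean must be finite and > 0 for mean-one scaling")
    factors = 1.0 / means
    return X * factors, factors


def principal_components(scaled) -> PCAResult:
    """Covariance PCA of a (scaled) subjects x metabolites matrix.

    Columns are centred, the sample covariance eigendecomposed, components
    sorted by decreasing variance, and each loading's sign fixed so that its
    largest-magnitude element is positive.  Explained fractions are the
    eigenvalues over their total.
    """
    X = np.asarray(scaled, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    centre = X.mean(axis=0)
    Xc = X - centre
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    total = np.trace(cov)
    if total <= 0.0:
        raise ValueError("matrix has zero variance; PCA undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order].T
    # deterministic sign: largest-|.| element of each component positive
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0.0:
            loadings[i] = -loadings[i]
    scores = Xc @ loadings.T
    return PCAResult(
        loadings=loadings,
        explained_fraction=eigvals / eigvals.sum(),
        scores=scores,
        centre=centre,
    )
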