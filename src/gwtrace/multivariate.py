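"""Ordination of the wells × analytes concentration matrix.

Two classical descriptors of occurrence/distribution structure:

* PCA on the standardized (correlation-matrix) or centered (covariance)
  wells × analytes matrix, with explained-variance fractions;
* correspondence analysis (CA) of the non-negative matrix, i.e. the SVD of
  the standardized Pearson-residual matrix of the row/column profiles, whose
  total inertia equals χ²/n.

``prevalence_order`` gives the mass ranking the CA relay summarises —
for the study fixture: antimony > selenium > arsenic.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .datamodel import ANALYTES, OrdinationResult, ValidationError, WellSummary
from .summary import _per_well_means


def matrix_from_summaries(
    summaries: Iterable[WellSummary],
    analytes: Sequence[str] = ANALYTES,
    scope: str = "overall",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Assemble the wells × analytes matrix of per-well means (μg/L)."""
    summaries = list(summaries)
    cols = {a: _per_well_means(summaries, a, scope) for a in analytes}
    wells = sorted(next(iter(cols.values())), key=lambda w: (len(w), w))
    for a, per_well in cols.items():
        if set(per_well) != set(wells):
            raise ValidationError(f"analyte {a!r} does not cover all wells")
    X = np.array([[cols[a][w].mean for a in analytes] for w in wells])
    return X, wells, list(analytes)


def prevalence_order(
    summaries: Iterable[WellSummary], analytes: Sequence[str] = ANALYTES
) -> tuple[list[str], dict[str, float], bool]:
    """Rank analytes by total concentration mass across wells.

    Returns (ordered analytes, per-analyte totals, tie flag). Ties are broken
    alphabetically and flagged.
    """
    X, _wells, cols = matrix_from_summaries(summaries, analytes)
    totals = {a: float(X[:, j].sum()) for j, a in enumerate(cols)}
    order = sorted(totals, key=lambda a: (-totals[a], a))
    values = sorted(totals.values(), reverse=True)
    tie = any(np.isclose(values[i], values[i + 1]) for i in range(len(values) - 1))
    return order, totals, tie


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip component signs so each column's first nonzero entry is positive."""
    flipped = loadings.copy()
    for j in range(flipped.shape[1]):
        col = flipped[:, j]
        nonzero = np.flatnonzero(np.abs(col) > 1e-12)
        if nonzero.size and col[nonzero[0]] < 0:
            flipped[:, j] = -col
    return flipped


def pca(
    matrix: np.ndarray,
    standardize: bool = True,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> OrdinationResult:
    """PCA via eigendecomposition of the correlation (default) or covariance matrix.

    Rows are observations (wells), columns variables (analytes). Loadings are
    orthonormal with the first nonzero entry of each component positive;
    scores are the centered/scaled data projected on the loadings. Explained
    fractions are eigenvalues over their sum.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    if not np.isfinite(X).all():
        raise ValidationError("matrix entries must be finite")
    cols = list(col_labels) if col_labels is not None else [f"v{j}" for j in range(X.shape[1])]
    rows = list(row_labels) if row_labels is not None else [f"r{i}" for i in range(X.shape[0])]

    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValidationError(
                f"zero-variance column(s) under standardization: {[cols[j] for j in zero]}"
            )
        Xc = Xc / sd
        C = np.corrcoef(X, rowvar=False)
    else:
        C = np.cov(X, rowvar=False, ddof=1)

    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = _fix_signs(eigvec[:, order])
    scores = Xc @ loadings
    total = float(eigval.sum())
    return OrdinationResult(
        method="pca",
        row_labels=rows,
        col_labels=cols,
        row_coords=scores,
        col_coords=loadings * np.sqrt(eigval),  # biplot variable coordinates
        explained_fraction=eigval / total,
        total=total,
    )


def correspondence_analysis(
    matrix: np.ndarray,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> OrdinationResult:
    """Correspondence analysis of a non-negative wells × analytes matrix.

    SVD of S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2} where P is the matrix scaled
    to unit total, r and c its margins. Row/column principal coordinates are
    D^{-1/2} U Σ and D^{-1/2} V Σ; total inertia Σσ² equals χ²/n. All-zero
    rows are filtered out and reported; an all-zero matrix or all-zero column
    is rejected.
    """
    N = np.asarray(matrix, dtype=float)
    if N.ndim != 2:
        raise ValidationError("need a 2-D matrix")
    if (N < 0).any() or not np.isfinite(N).all():
        raise ValidationError("matrix entries must be finite and >= 0")
    rows = list(row_labels) if row_labels is not None else [f"r{i}" for i in range(N.shape[0])]
    cols = list(col_labels) if col_labels is not None else [f"v{j}" for j in range(N.shape[1])]
    if N.sum() == 0:
        raise ValidationError("all-zero matrix has no correspondence structure")

    keep = N.sum(axis=1) > 0
    filtered = [rows[i] for i in np.flatnonzero(~keep)]
    N = N[keep]
    rows = [r for r, k in zip(rows, keep) if k]
    if (N.sum(axis=0) == 0).any():
        zero_cols = [cols[j] for j in np.flatnonzero(N.sum(axis=0) == 0)]
        raise ValidationError(f"all-zero column(s): {zero_cols}")

    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(N.shape[0] - 1, N.shape[1] - 1)  # structural rank of the residuals
    U, sigma, Vt = U[:, :k], sigma[:k], Vt[:k]
    V = _fix_signs(Vt.T)
    # keep row/column coordinates consistent after the sign fix
    flip = np.sign(np.einsum("ij,ij->j", Vt.T, V))
    U = U * flip

    row_coords = (U * sigma) / np.sqrt(r)[:, None]
    col_coords = (V * sigma) / np.sqrt(c)[:, None]
    inertia = float((sigma**2).sum())
    if inertia == 0:
        explained = np.zeros(k)
        explained[:1] = 1.0 if k else explained[:1]
    else:
        explained = sigma**2 / inertia
    return OrdinationResult(
        method="ca",
        row_labels=rows,
        col_labels=cols,
        row_coords=row_coords,
        col_coords=col_coords,
        explained_fraction=explained,
        total=inertia,
        filtered_rows=filtered,
    )
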