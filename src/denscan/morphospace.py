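"""Missingness filtering, iterative-PCA imputation, and morphospace projection.

Most fossil crania are incomplete, so a PCA morphospace needs imputation. The
pipeline is:

1. filter measurements with more than 20% missing values, then specimens with
   more than 15% (both thresholds and the application order are configurable;
   a nonlinear-only variant uses a more permissive 30% measurement threshold);
2. impute the remaining holes by iterative PCA (EM-PCA): initialise missing
   cells at column means, then alternate rank-``n_components`` SVD
   reconstruction and refilling of the missing cells until convergence;
3. fit the PCA plane (centering, scaling and loadings) on the reference-group
   individuals only;
4. project the test subjects onto that plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .data import MeasurementClass, MeasurementMatrix

__all__ = [
    "PCAModel",
    "filter_missingness",
    "impute_iterative_pca",
    "fit_reference_pca",
    "project_test_subjects",
]


def filter_missingness(
    matrix: MeasurementMatrix,
    measurement_max_missing: float = 0.20,
    specimen_max_missing: float = 0.15,
    order: str = "MEASUREMENTS_FIRST",
    measurement_class: MeasurementClass | None = None,
) -> MeasurementMatrix:
    """Drop measurements/specimens whose missing fraction strictly exceeds the caps.

    ``order`` picks which axis is filtered first (MEASUREMENTS_FIRST is the
    main-analysis choice; SPECIMENS_FIRST retains more measurements).
    ``measurement_class`` optionally restricts the matrix to one class before
    filtering (the nonlinear-only morphospace variant).
    """
    if not (0 <= measurement_max_missing <= 1 and 0 <= specimen_max_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    m = matrix
    if measurement_class is not None:
        keep = [
            mid
            for mid in m.measurement_ids
            if m.measurement_class(mid) is measurement_class
        ]
        if not keep:
            raise ValueError(f"no measurements of class {measurement_class.value}")
        m = m.subset(measurement_ids=keep)

    def _drop_measurements(mat: MeasurementMatrix) -> MeasurementMatrix:
        frac = np.isnan(mat.values).mean(axis=0)
        keep = [mid for mid, f in zip(mat.measurement_ids, frac) if f <= measurement_max_missing]
        if not keep:
            raise ValueError("missingness filtering removed every measurement")
        return mat.subset(measurement_ids=keep)

    def _drop_specimens(mat: MeasurementMatrix) -> MeasurementMatrix:
        frac = np.isnan(mat.values).mean(axis=1)
        keep = [sid for sid, f in zip(mat.specimen_ids, frac) if f <= specimen_max_missing]
        if not keep:
            raise ValueError("missingness filtering removed every specimen")
        return mat.subset(specimen_ids=keep)

    order = order.upper()
    if order == "MEASUREMENTS_FIRST":
        return _drop_specimens(_drop_measurements(m))
    if order == "SPECIMENS_FIRST":
        return _drop_measurements(_drop_specimens(m))
    raise ValueError(f"unknown filtering order {order!r}")


def impute_iterative_pca(
    matrix: MeasurementMatrix,
    n_components: int = 2,
    scale: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
    regularization: float = 0.0,
) -> MeasurementMatrix:
    """Fill missing cells by iterative rank-truncated SVD reconstruction.

    Missing cells start at the column mean; each sweep standardises the
    current matrix (optionally), reconstructs it at rank ``n_components``, and
    rewrites only the missing cells with the reconstruction until the largest
    change falls below ``tol``. Observed cells are never altered.
    ``regularization`` shrinks the retained singular values toward the noise
    level (0 = plain EM-PCA).
    """
    X = matrix.values.copy()
    miss = np.isnan(X)
    if np.any(miss.all(axis=1)):
        bad = [s for s, m in zip(matrix.specimen_ids, miss.all(axis=1)) if m]
        raise ValueError(f"specimens with no observed values: {bad}")
    if np.any(miss.all(axis=0)):
        bad = [m_ for m_, m in zip(matrix.measurement_ids, miss.all(axis=0)) if m]
        raise ValueError(f"measurements with no observed values: {bad}")
    if not miss.any():
        return matrix.copy()
    n, p = X.shape
    n_components = min(n_components, n - 1, p)

    col_mean = np.nanmean(matrix.values, axis=0)
    X[miss] = np.take(col_mean, np.nonzero(miss)[1])

    converged = False
    for it in range(max_iter):
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0) if scale else np.ones(p)
        sd = np.where(sd == 0, 1.0, sd)
        Z = (X - mu) / sd
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        S_used = S[:n_components]
        if regularization > 0:
            noise = (
                np.mean(S[n_components:] ** 2) if S.size > n_components else 0.0
            )
            S_used = np.maximum(
                S_used - regularization * noise / np.maximum(S_used, 1e-12), 0.0
            )
        Z_hat = (U[:, :n_components] * S_used) @ Vt[:n_components]
        X_hat = Z_hat * sd + mu
        delta = np.max(np.abs(X[miss] - X_hat[miss])) if miss.any() else 0.0
        X[miss] = X_hat[miss]
        denom = max(np.max(np.abs(X[miss])), 1.0)
        if delta / denom < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"iterative PCA imputation did not converge in {max_iter} sweeps "
            f"(last relative change {delta / denom:.3g}); returning best iterate",
            stacklevel=2,
        )
    out = matrix.copy()
    out.values = X
    # observed cells untouched by construction
    return out


@dataclass
class PCAModel:
    """PCA plane fitted on reference individuals.

    ``mean`` and ``scale`` are the reference-set column centering/scaling
    (population SD, ddof=0); ``loadings`` is (n_components, n_measurements)
    with orthonormal rows, each row's largest-magnitude element made positive;
    ``explained_variance_ratio`` refers to the reference rows.
    """

    measurement_ids: list[str]
    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, values: np.ndarray) -> np.ndarray:
        Z = (np.asarray(values, dtype=float) - self.mean) / self.scale
        return Z @ self.loadings.T


def fit_reference_pca(
    matrix: MeasurementMatrix,
    reference_ids: Sequence[str],
    n_components: int = 2,
    scale: bool = True,
) -> PCAModel:
    """Fit centering, scaling and loadings on the reference rows of an imputed matrix."""
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference_ids must be nonempty")
    if len(reference_ids) < n_components:
        raise ValueError(
            f"{len(reference_ids)} reference rows cannot support "
            f"{n_components} components"
        )
    rows = np.array([matrix.row(s) for s in reference_ids], dtype=float)
    if np.isnan(rows).any():
        raise ValueError("matrix must be imputed before PCA fitting")
    mu = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=0) if scale else np.ones(rows.shape[1])
    sd = np.where(sd == 0, 1.0, sd)
    Z = (rows - mu) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.copy()
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    return PCAModel(
        measurement_ids=list(matrix.measurement_ids),
        mean=mu,
        scale=sd,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project_test_subjects(
    model: PCAModel,
    matrix: MeasurementMatrix,
    subject_ids: Sequence[str],
) -> np.ndarray:
    """Coordinates of subjects on the reference PCA plane (subjects × components)."""
    missing = [m for m in model.measurement_ids if m not in matrix._col]
    if missing:
        raise ValueError(f"matrix lacks model measurements: {missing}")
    cols = [matrix.col_index(m) for m in model.measurement_ids]
    rows = np.array(
        [matrix.values[matrix.row_index(s), cols] for s in subject_ids], dtype=float
    )
    if np.isnan(rows).any():
        raise ValueError("subjects must be imputed before projection")
    return model.transform(rows)
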