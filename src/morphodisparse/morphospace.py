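"""Scaling, PCA and species centroids: the morphospace construction.

The morphospace is built in two steps.  First the seven raw measurements are
z-scored column-wise (correlation-matrix convention, sample SD with the n-1
denominator), so each variable contributes unit variance regardless of its
absolute size in mm.  PCA of the z-scored matrix is then the
eigendecomposition of the correlation matrix of the raw data; with strongly
covarying wing elements, PC1 is the shared size axis.  Species centroids are
arithmetic means of conspecific rows in the z-scored space, and a second,
centroid-level PCA summarizes between-species structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateVariableError, DimensionMismatchError
from .io_core import MEASUREMENT_COLUMNS, MeasurementTable


@dataclass
class ScaledMatrix:
    """Column-wise z-scored data with the centering/scale used.

    ``values`` is (n_rows, p); ``center`` and ``scale`` (both length p, in
    mm) invert the transform: raw = values * scale + center.
    """

    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    row_labels: list[str]
    columns: tuple[str, ...]

    def inverse(self) -> np.ndarray:
        return self.values * self.scale + self.center


@dataclass
class PCAResult:
    """Eigendecomposition of a (centered) data matrix.

    loadings: (p, k) orthonormal; scores: (n, k), in SD units of the input;
    eigenvalues: non-increasing; variance_proportions sums to 1 over the
    retained axes.
    """

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    row_labels: list[str]
    columns: tuple[str, ...]

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.scores, index=self.row_labels, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.loadings, index=list(self.columns), columns=cols)

    def eigenvalue_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "axis": [f"PC{i + 1}" for i in range(self.n_axes)],
            "eigenvalue": self.eigenvalues,
            "proportion": self.variance_proportions,
            "cumulative": np.cumsum(self.variance_proportions),
        })


@dataclass
class CentroidSet:
    """Per-species mean vectors in the common z-scored measurement space."""

    values: np.ndarray          # (n_species, p)
    species: list[str]
    regions: list[str]
    columns: tuple[str, ...]

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, index=self.species, columns=list(self.columns))
        out.insert(0, "region", self.regions)
        return out


def zscale(table: MeasurementTable | pd.DataFrame) -> ScaledMatrix:
    """Z-score the measurement columns (sample SD, n-1 denominator)."""
    if isinstance(table, MeasurementTable):
        x = table.measurement_matrix()
        labels = table.data["specimen_id"].tolist()
        columns = MEASUREMENT_COLUMNS
    else:
        x = table.to_numpy(dtype=float)
        labels = [str(i) for i in table.index]
        columns = tuple(table.columns)
    if x.shape[0] < 2:
        raise DimensionMismatchError("need at least 2 rows to z-score")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(scale == 0)
    if dead.size:
        names = [columns[i] for i in dead]
        raise DegenerateVariableError(f"zero-variance column(s): {names}")
    return ScaledMatrix((x - center) / scale, center, scale, labels, columns)


def _pca_of_matrix(x: np.ndarray, row_labels, columns,
                   center: bool) -> PCAResult:
    """Eigendecomposition of the sample covariance of ``x``.

    The covariance is formed explicitly (p x p, tiny here) and decomposed
    with a symmetric-matrix routine.  Axes are sorted by decreasing
    eigenvalue and each loading column is oriented so its largest-magnitude
    element is positive, making the output deterministic across backends.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DimensionMismatchError(f"need a 2-D matrix with >=2 rows/cols, got {x.shape}")
    xc = x - x.mean(axis=0) if center else x
    cov = (xc.T @ xc) / (xc.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order]
    # deterministic sign convention
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = xc @ loadings
    total = eigvals.sum()
    props = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAResult(loadings, scores, eigvals, props, list(row_labels), tuple(columns))


def pca(scaled: ScaledMatrix) -> PCAResult:
    """PCA of z-scored data: the correlation-matrix PCA of the raw table."""
    return _pca_of_matrix(scaled.values, scaled.row_labels, scaled.columns,
                          center=True)


def species_centroids(scaled: ScaledMatrix, species_labels,
                      region_map: dict[str, str] | None = None) -> CentroidSet:
    """Arithmetic mean of conspecific rows in z-scored space.

    ``species_labels`` gives one species per row of ``scaled``; species
    order of first appearance is preserved.
    """
    labels = list(species_labels)
    if len(labels) != scaled.values.shape[0]:
        raise DimensionMismatchError("one species label per row required")
    order = list(dict.fromkeys(labels))
    idx = pd.Series(labels)
    means = np.vstack([scaled.values[(idx == sp).to_numpy()].mean(axis=0)
                       for sp in order])
    regions = [region_map.get(sp, "") if region_map else "" for sp in order]
    return CentroidSet(means, order, regions, scaled.columns)


def centroid_pca(centroids: CentroidSet, rescale: bool = False) -> PCAResult:
    """PCA of the species-centroid matrix.

    By default the centroid columns are centered but not re-standardized:
    the centroids already live in a common z-scored space, and re-scaling
    would distort between-species size structure.  ``rescale=True`` applies
    a second z-scoring to the centroid columns instead.
    """
    x = np.asarray(centroids.values, dtype=float)
    if x.shape[0] < 3:
        raise DimensionMismatchError("need at least 3 centroids")
    if rescale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateVariableError("zero-variance centroid column")
        x = (x - x.mean(axis=0)) / sd
    return _pca_of_matrix(x, centroids.species, centroids.columns, center=True)
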