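"""Distance-based disparity statistics and the dispersion permutation test.

Disparity is summarized at the species level: pairwise Euclidean distances
between species centroids in the z-scored measurement space, nearest/farthest
neighbor summaries per region, and a multivariate dispersion statistic — the
mean distance of species to their own regional centroid in a principal
coordinates (PCoA) embedding of the distance matrix, with the standard
correction for axes arising from negative eigenvalues (squared distances on
"imaginary" axes are subtracted).  A permutation null is built by jointly
permuting the rows and columns of the distance matrix (equivalently,
shuffling group membership over the fixed point configuration) and
recomputing the mean dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from .errors import (
    DimensionMismatchError,
    EmptyGroupError,
    SubsetTooSmallError,
)
from .morphospace import CentroidSet


@dataclass
class DistanceMatrix:
    """Symmetric species-by-species Euclidean distance matrix."""

    values: np.ndarray
    labels: list[str]
    regions: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionMismatchError(f"distance matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.labels):
            raise DimensionMismatchError("one label per row required")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DimensionMismatchError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12) or np.any(v < -1e-12):
            raise DimensionMismatchError("invalid distances (diagonal/negative)")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, labels) -> "DistanceMatrix":
        labels = list(labels)
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise DimensionMismatchError(f"unknown labels: {missing}")
        idx = np.array([pos[lab] for lab in labels])
        regions = ([self.regions[i] for i in idx] if self.regions is not None else None)
        return DistanceMatrix(self.values[np.ix_(idx, idx)], labels, regions)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(points: CentroidSet | np.ndarray,
                    labels=None, regions=None) -> DistanceMatrix:
    """Pairwise Euclidean distances over all supplied dimensions."""
    if isinstance(points, CentroidSet):
        coords = points.values
        labels = points.species
        regions = points.regions
    else:
        coords = np.asarray(points, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(coords.shape[0])]
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise DimensionMismatchError("need a 2-D array with at least 2 points")
    return DistanceMatrix(squareform(pdist(coords)), list(labels),
                          list(regions) if regions is not None else None)


@dataclass
class NeighborSummary:
    """Nearest/farthest neighbor distance summary for one species set.

    ``mean_nearest``/``mean_farthest`` average the per-species minimum and
    maximum off-diagonal distances; ``farthest`` is the single largest
    pairwise distance in the set; ``mean_pairwise`` averages the C(m,2)
    unordered pairs.
    """

    mean_nearest: float
    sd_nearest: float
    mean_pairwise: float
    farthest: float
    mean_farthest: float
    sd_farthest: float
    per_species_nearest: dict[str, float]
    per_species_farthest: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "mean_nearest": self.mean_nearest,
            "sd_nearest": self.sd_nearest,
            "mean_pairwise": self.mean_pairwise,
            "farthest": self.farthest,
            "mean_farthest": self.mean_farthest,
            "sd_farthest": self.sd_farthest,
        }


def neighbor_summary(dm: DistanceMatrix, subset=None) -> NeighborSummary:
    """Neighbor-distance summary, optionally restricted to ``subset``."""
    sub = dm.subset(subset) if subset is not None else dm
    m = sub.n
    if m < 2:
        raise SubsetTooSmallError("need at least 2 species")
    v = sub.values.copy()
    off = v[np.triu_indices(m, k=1)]
    np.fill_diagonal(v, np.inf)
    mins = v.min(axis=1)
    np.fill_diagonal(v, -np.inf)
    maxs = v.max(axis=1)
    sd = lambda a: float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    return NeighborSummary(
        mean_nearest=float(mins.mean()),
        sd_nearest=sd(mins),
        mean_pairwise=float(off.mean()),
        farthest=float(off.max()),
        mean_farthest=float(maxs.mean()),
        sd_farthest=sd(maxs),
        per_species_nearest=dict(zip(sub.labels, mins.tolist())),
        per_species_farthest=dict(zip(sub.labels, maxs.tolist())),
    )


@dataclass
class PCoAEmbedding:
    """Principal coordinates of a distance matrix.

    Axes from negative eigenvalues of the double-centered matrix are kept
    (scaled by sqrt(|eigenvalue|)) and flagged ``imaginary`` so dispersion
    distances can apply the subtractive correction.
    """

    coordinates: np.ndarray     # (m, a)
    eigenvalues: np.ndarray     # (a,), decreasing by absolute contribution
    imaginary: np.ndarray       # (a,) bool
    labels: list[str]

    @property
    def is_euclidean(self) -> bool:
        return not bool(self.imaginary.any())


def pcoa(dm: DistanceMatrix, eig_rel_tol: float = 1e-9) -> PCoAEmbedding:
    """Gower double-centering eigendecomposition of a distance matrix.

    Decomposes -1/2 * J D^2 J (J the centering matrix).  Eigenvalues with
    magnitude below ``eig_rel_tol`` times the largest are treated as zero
    and dropped; negative eigenvalues beyond tolerance yield imaginary axes.
    """
    d2 = dm.values ** 2
    m = dm.n
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(-eigvals)  # positive axes first, negative last
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = np.max(np.abs(eigvals)) if eigvals.size else 0.0
    keep = np.abs(eigvals) > eig_rel_tol * scale
    eigvals = eigvals[keep]
    eigvecs = eigvecs[:, keep]
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    return PCoAEmbedding(coords, eigvals, eigvals < 0, list(dm.labels))


@dataclass
class DispersionResult:
    """Observed multivariate dispersion, optional F, and permutation null."""

    observed_mean_dispersion: float
    group_means: dict[str, float]
    point_distances: dict[str, float]
    f_statistic: float | None
    null_dispersions: np.ndarray | None = None
    p_value: float | None = None
    n_reps: int = 0
    seed: int | None = None

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "observed_mean_dispersion": self.observed_mean_dispersion,
            "group_means": dict(self.group_means),
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }
        if self.null_dispersions is not None:
            out["null_summary"] = {
                "mean": float(self.null_dispersions.mean()),
                "sd": float(self.null_dispersions.std(ddof=1))
                if self.null_dispersions.size > 1 else 0.0,
                "min": float(self.null_dispersions.min()),
                "max": float(self.null_dispersions.max()),
            }
            if include_null:
                out["null_dispersions"] = self.null_dispersions.tolist()
        return out


def _group_arrays(labels, groups) -> np.ndarray:
    g = np.asarray([groups[lab] if isinstance(groups, dict) else groups[i]
                    for i, lab in enumerate(labels)])
    if len(g) != len(labels):
        raise DimensionMismatchError("one group per point required")
    return g


def _dispersion_distances(emb: PCoAEmbedding, group_vec: np.ndarray) -> np.ndarray:
    """Distance of each point to its own group centroid, with the
    negative-eigenvalue correction: d^2 = (real-axis squared distance) -
    (imaginary-axis squared distance), floored at 0."""
    real, imag = ~emb.imaginary, emb.imaginary
    d2 = np.empty(emb.coordinates.shape[0])
    for grp in np.unique(group_vec):
        idx = np.flatnonzero(group_vec == grp)
        if idx.size == 0:
            raise EmptyGroupError(f"group {grp!r} has no members")
        centroid = emb.coordinates[idx].mean(axis=0)
        delta2 = (emb.coordinates[idx] - centroid) ** 2
        d2[idx] = delta2[:, real].sum(axis=1) - delta2[:, imag].sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def _f_statistic(distances: np.ndarray, group_vec: np.ndarray) -> float | None:
    """One-way ANOVA F of the dispersion distances across groups; absent
    (None) when fewer than two groups, or any group has < 2 members."""
    groups = [distances[group_vec == g] for g in np.unique(group_vec)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return None
    return float(f_oneway(*groups).statistic)


def mean_dispersion(dm: DistanceMatrix, groups) -> DispersionResult:
    """Observed mean multivariate dispersion (no permutation null).

    ``groups`` maps point label -> group label (or is a sequence aligned
    with ``dm.labels``).  The statistic is the mean over all points of the
    distance to the own-group centroid in PCoA space.
    """
    emb = pcoa(dm)
    gvec = _group_arrays(dm.labels, groups)
    dist = _dispersion_distances(emb, gvec)
    return DispersionResult(
        observed_mean_dispersion=float(dist.mean()),
        group_means={str(g): float(dist[gvec == g].mean()) for g in np.unique(gvec)},
        point_distances=dict(zip(dm.labels, dist.tolist())),
        f_statistic=_f_statistic(dist, gvec),
    )


def permutation_test(dm: DistanceMatrix, groups, n_reps: int = 1000,
                     seed: int = 0, smoothing: bool = False) -> DispersionResult:
    """Permutation test of the mean dispersion against a shuffled null.

    Each replicate applies one uniform random permutation jointly to the
    rows and columns of the distance matrix — equivalently, shuffles group
    membership over the fixed point configuration (the PCoA embedding is
    permutation-invariant up to row order, so it is computed once).  The
    p-value is the plain proportion of null dispersions >= the observed
    one; ``smoothing=True`` uses (k+1)/(n+1) instead, so p can never be 0.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    observed = mean_dispersion(dm, groups)
    emb = pcoa(dm)
    gvec = _group_arrays(dm.labels, groups)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(dm.n)
        null[r] = _dispersion_distances(emb, gvec[perm]).mean()
    k = int(np.sum(null >= observed.observed_mean_dispersion - 1e-12))
    p = (k + 1) / (n_reps + 1) if smoothing else k / n_reps
    observed.null_dispersions = null
    observed.p_value = float(p)
    observed.n_reps = n_reps
    observed.seed = seed
    return observed
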