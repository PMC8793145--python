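"""PCA shape space over pooled particle ensembles.

Every particle is one point: its Fourier amplitude spectrum.  PCA on the
pooled feature matrix of all ensembles under comparison ranks the
correlated nanoscale features (spikes, lobes, roughness) that dominate the
variation, and each ensemble collapses to a cloud with a center of gravity
(its typical shape), a 95% confidence ellipse in the leading two
components, and a dispersity summary — the distribution of per-particle
distances to the center of gravity.

The basis is refit for each comparison on exactly the ensembles being
compared (coordinates are comparison-specific, not global).  Features are
centered but never per-feature standardized: harmonic amplitudes share
units, and standardizing would inflate high-frequency noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .contours import Contour, resample_contour
from .descriptors import FeatureVector, compute_descriptor, feature_vector

__all__ = [
    "ShapeEnsemble",
    "ensemble_from_contours",
    "ShapeSpaceModel",
    "EnsembleProjection",
    "ConfidenceEllipse",
    "DistancePDF",
    "fit_shape_space",
    "project_ensemble",
    "representative_particle",
    "confidence_ellipse",
    "ellipse_contains",
    "distance_pdf",
]


@dataclass
class ShapeEnsemble:
    """A named population of particle feature vectors (one synthesis batch,
    or one generator parameter set)."""

    label: str
    features: np.ndarray  # (n_particles, K)
    particle_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if len(self.particle_ids) != self.features.shape[0]:
            raise ValueError("particle_ids length must match feature rows")

    @classmethod
    def from_feature_vectors(cls, label: str, fvs: list[FeatureVector]) -> "ShapeEnsemble":
        ks = {fv.k for fv in fvs}
        if len(ks) != 1:
            raise ValueError(f"feature vectors have mixed K: {sorted(ks)}")
        return cls(
            label=label,
            features=np.vstack([fv.values for fv in fvs]),
            particle_ids=[fv.source_id or str(i) for i, fv in enumerate(fvs)],
        )

    @property
    def n_particles(self) -> int:
        return int(self.features.shape[0])

    @property
    def k(self) -> int:
        return int(self.features.shape[1])


@dataclass
class ShapeSpaceModel:
    """PCA basis: mean vector, orthonormal components ranked by variance,
    and explained-variance ratios summing to 1."""

    mean_vector: np.ndarray
    components: np.ndarray  # (n_components, K), rows orthonormal
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return int(self.mean_vector.shape[0])

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    def transform(self, features: np.ndarray, m: int | None = None) -> np.ndarray:
        m = self.n_components if m is None else m
        return (np.atleast_2d(features) - self.mean_vector) @ self.components[:m].T

    def inverse_transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(coords)
        return coords @ self.components[: coords.shape[1]] + self.mean_vector


@dataclass
class EnsembleProjection:
    """Per-particle coordinates of one ensemble in the leading m PCs, plus
    the ensemble's center of gravity (mean coordinate)."""

    label: str
    coords: np.ndarray  # (n_particles, m)
    particle_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def n_particles(self) -> int:
        return int(self.coords.shape[0])

    @property
    def m(self) -> int:
        return int(self.coords.shape[1])


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Coverage ellipse of a 2D Gaussian fit: center, semi-axes (a >= b),
    orientation of the major axis, and nominal coverage level."""

    center: np.ndarray
    semi_axes: tuple[float, float]
    angle_rad: float
    level: float


@dataclass
class DistancePDF:
    """Distances of each particle to its own center of gravity, with a
    Gaussian-KDE density on a regular grid (shape dispersity summary)."""

    distances: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def ensemble_from_contours(
    label: str, contours: list[Contour], n: int = 1024, k: int = 512
) -> ShapeEnsemble:
    """Resample, transform and featurize raw contours into an ensemble."""
    fvs = []
    for i, c in enumerate(contours):
        rc = resample_contour(c, n)
        fv = feature_vector(compute_descriptor(rc), k)
        fv.source_id = c.source_id or str(i)
        fvs.append(fv)
    return ShapeEnsemble.from_feature_vectors(label, fvs)


def fit_shape_space(ensembles: list[ShapeEnsemble]) -> ShapeSpaceModel:
    """Fit PCA on the pooled feature matrix of all given ensembles.

    Centering only, full SVD, all components kept.  Component signs follow
    a fixed convention — the entry of largest magnitude in each component
    is positive — so results are reproducible across runs and platforms.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    ks = {e.k for e in ensembles}
    if len(ks) != 1:
        raise ValueError(f"ensembles have mixed K: {sorted(ks)}")
    pooled = np.vstack([e.features for e in ensembles])
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 particles in total to fit a shape space")

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(pooled)
    components = pca.components_.copy()
    for i, comp in enumerate(components):
        j = np.argmax(np.abs(comp))
        if comp[j] < 0:
            components[i] = -comp
    return ShapeSpaceModel(
        mean_vector=pca.mean_.copy(),
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project_ensemble(model: ShapeSpaceModel, e: ShapeEnsemble, m: int = 3) -> EnsembleProjection:
    """Project one ensemble into the leading ``m`` principal components."""
    if e.k != model.k:
        raise ValueError(f"feature dimension mismatch: ensemble K={e.k}, model K={model.k}")
    if not 1 <= m <= model.n_components:
        raise ValueError(f"m must be in [1, {model.n_components}]")
    return EnsembleProjection(
        label=e.label,
        coords=model.transform(e.features, m=m),
        particle_ids=list(e.particle_ids),
    )


def representative_particle(p: EnsembleProjection) -> str:
    """Particle closest to the center of gravity — the ensemble's typical
    shape.  Ties go to the lowest particle index."""
    if p.n_particles == 0:
        raise ValueError("empty projection")
    d = np.linalg.norm(p.coords - p.centroid, axis=1)
    return p.particle_ids[int(np.argmin(d))]


def confidence_ellipse(p: EnsembleProjection, level: float = 0.95) -> ConfidenceEllipse:
    """Gaussian coverage ellipse of the first two coordinates.

    Built from the sample mean and covariance: semi-axes are
    sqrt(eigenvalue * q) with q the chi-square(2) quantile at ``level``,
    orientation from the leading eigenvector.  For truly Gaussian clouds
    the ellipse contains ``level`` of the points in expectation.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if p.n_particles < 3:
        raise ValueError("need >= 3 particles for a covariance ellipse")
    xy = p.coords[:, :2]
    if xy.shape[1] < 2:
        raise ValueError("need at least 2 coordinates for an ellipse")
    cov = np.cov(xy, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[-1], 1.0):
        raise ValueError("degenerate (collinear or identical) points: singular covariance")
    q = stats.chi2.ppf(level, df=2)
    a = float(np.sqrt(evals[1] * q))
    b = float(np.sqrt(evals[0] * q))
    major = evecs[:, 1]
    return ConfidenceEllipse(
        center=xy.mean(axis=0),
        semi_axes=(a, b),
        angle_rad=float(np.arctan2(major[1], major[0])),
        level=level,
    )


def ellipse_contains(ell: ConfidenceEllipse, points: np.ndarray) -> np.ndarray:
    """Boolean mask of which 2D points fall inside the ellipse."""
    pts = np.atleast_2d(points) - ell.center
    c, s = np.cos(ell.angle_rad), np.sin(ell.angle_rad)
    u = pts @ np.array([c, s])
    v = pts @ np.array([-s, c])
    a, b = ell.semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def distance_pdf(p: EnsembleProjection, m: int | None = None, n_grid: int = 512) -> DistancePDF:
    """Dispersity of an ensemble as the PDF of particle distances to the
    center of gravity.

    Euclidean distances in the first ``m`` coordinates (default: all that
    the projection carries), smoothed with a Gaussian KDE at the Silverman
    bandwidth and evaluated on ``n_grid`` points from 0 to
    max(distance) + 3 bandwidths.  Because distance has a hard boundary at
    zero, the evaluated density is renormalized on the grid so it
    integrates to one.
    """
    if p.n_particles < 20:
        raise ValueError("need >= 20 particles for a distance PDF")
    coords = p.coords if m is None else p.coords[:, :m]
    d = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    if np.allclose(d, 0.0):
        raise ValueError("degenerate distribution: all particles at the centroid")
    kde = stats.gaussian_kde(d, bw_method="silverman")
    bw = float(kde.factor * d.std(ddof=1))
    grid = np.linspace(0.0, d.max() + 3.0 * bw, n_grid)
    density = kde(grid)
    density = density / np.trapezoid(density, grid)
    return DistancePDF(distances=d, grid=grid, density=density, bandwidth=bw)
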