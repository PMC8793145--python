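"""Distribution overlap between two shape ensembles.

Two ensembles projected into the same shape space are compared by
projecting every particle onto the line joining the two centers of gravity
("coordinate X"), estimating each ensemble's 1D density along that line by
Gaussian KDE, and integrating the pointwise minimum of the two densities:

    OVL(f, g) = integral min(f(x), g(x)) dx  in [0, 1].

OVL reads directly as the fraction of particles common to both
distributions: 1 for identical ensembles, 0 for disjoint ones.  Two
ensembles are declared statistically independent shapes when their OVL
falls at or below a configurable threshold (default 0.05).  The
Bhattacharyya coefficient integral sqrt(f*g) is reported alongside as a
secondary similarity statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .shape_space import EnsembleProjection

__all__ = [
    "OverlapResult",
    "IndependenceReport",
    "projection_axis",
    "overlap_coefficient",
    "independence_test",
    "pairwise_overlap",
]

DEFAULT_INDEPENDENCE_THRESHOLD = 0.05


@dataclass
class OverlapResult:
    """Overlap coefficient between two projected ensembles, with the 1D
    densities behind it."""

    ovl: float
    bhattacharyya: float
    axis: np.ndarray  # unit vector from centroid(a) to centroid(b)
    origin: np.ndarray  # centroid(a)
    centroid_distance: float
    grid: np.ndarray
    pdf_a: np.ndarray
    pdf_b: np.ndarray
    labels: tuple[str, str]
    degenerate_axis: bool = False


@dataclass(frozen=True)
class IndependenceReport:
    """Outcome of the independence decision for one ensemble pair."""

    independent: bool
    ovl: float
    threshold: float
    centroid_distance: float
    labels: tuple[str, str]


def projection_axis(
    a: EnsembleProjection, b: EnsembleProjection
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Unit vector along the line joining the two centers of gravity.

    Returns ``(axis, origin, degenerate)`` with the origin at centroid(a).
    If the centroids coincide (within 1e-12) there is no defined
    inter-centroid line; the axis falls back to the first shape-space
    direction and the degenerate flag is set.
    """
    if a.m != b.m:
        raise ValueError(f"projections live in different spaces: m={a.m} vs m={b.m}")
    ca, cb = a.centroid, b.centroid
    delta = cb - ca
    dist = float(np.linalg.norm(delta))
    if dist < 1e-12:
        axis = np.zeros(a.m)
        axis[0] = 1.0
        return axis, ca, True
    return delta / dist, ca, False


def overlap_coefficient(
    a: EnsembleProjection,
    b: EnsembleProjection,
    n_grid: int = 512,
    min_particles: int = 20,
) -> OverlapResult:
    """Overlapping coefficient of two ensembles along the inter-centroid line.

    Both point clouds are projected onto the axis from
    :func:`projection_axis`; each 1D sample gets its own Gaussian KDE at the
    Silverman bandwidth, evaluated on a shared grid spanning the joint
    sample range padded by three times the larger bandwidth, so the
    pointwise minimum is well defined.  OVL is the trapezoidal integral of
    that minimum, clipped to [0, 1]; it is symmetric in its arguments.
    """
    for p in (a, b):
        if p.n_particles < min_particles:
            raise ValueError(
                f"ensemble {p.label!r} has {p.n_particles} particles; "
                f"need >= {min_particles} for a stable KDE"
            )
    axis, origin, degenerate = projection_axis(a, b)
    xa = (a.coords - origin) @ axis
    xb = (b.coords - origin) @ axis
    if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
        raise ValueError("degenerate (zero-variance) projection along the axis")

    kde_a = stats.gaussian_kde(xa, bw_method="silverman")
    kde_b = stats.gaussian_kde(xb, bw_method="silverman")
    bw_a = float(kde_a.factor * xa.std(ddof=1))
    bw_b = float(kde_b.factor * xb.std(ddof=1))
    pad = 3.0 * max(bw_a, bw_b)
    lo = min(xa.min(), xb.min()) - pad
    hi = max(xa.max(), xb.max()) + pad
    grid = np.linspace(lo, hi, n_grid)
    pdf_a = kde_a(grid)
    pdf_b = kde_b(grid)
    ovl = float(np.clip(np.trapezoid(np.minimum(pdf_a, pdf_b), grid), 0.0, 1.0))
    bc = float(np.clip(np.trapezoid(np.sqrt(pdf_a * pdf_b), grid), 0.0, 1.0))
    return OverlapResult(
        ovl=ovl,
        bhattacharyya=bc,
        axis=axis,
        origin=origin,
        centroid_distance=float(np.linalg.norm(b.centroid - a.centroid)),
        grid=grid,
        pdf_a=pdf_a,
        pdf_b=pdf_b,
        labels=(a.label, b.label),
        degenerate_axis=degenerate,
    )


def independence_test(
    r: OverlapResult, threshold: float = DEFAULT_INDEPENDENCE_THRESHOLD
) -> IndependenceReport:
    """Decide statistical shape independence: independent iff OVL <= threshold."""
    return IndependenceReport(
        independent=r.ovl <= threshold,
        ovl=r.ovl,
        threshold=threshold,
        centroid_distance=r.centroid_distance,
        labels=r.labels,
    )


def pairwise_overlap(projections: list[EnsembleProjection]) -> dict[tuple[str, str], float]:
    """OVL for every unordered pair of projections (same shape space)."""
    out: dict[tuple[str, str], float] = {}
    for i in range(len(projections)):
        for j in range(i + 1, len(projections)):
            a, b = projections[i], projections[j]
            out[(a.label, b.label)] = overlap_coefficient(a, b).ovl
    return out
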