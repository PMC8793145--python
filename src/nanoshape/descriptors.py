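"""Fourier shape descriptors of the radial signature.

Each resampled contour is reduced to the discrete Fourier coefficients of
its centroid-distance signature r(t), t = 0..N-1 — the same move by which a
periodic signal is decomposed into harmonics.  The transform convention is
fixed throughout the package: forward transform carries the 1/N factor, so

    c_k = (1/N) * sum_t r(t) * exp(-2*pi*i*k*t/N),      k = 0..N/2

and c_0 is the mean radius.  The feature vector used downstream is the
one-sided normalized amplitude spectrum

    a_k = 2*|c_k| / c_0,        k = 1..K,

which is translation- (centroid-relative), scale- (c_0 division),
rotation- and start-point- (magnitudes drop phase; canonical resampling
start) invariant.  A pure circle maps to the zero vector; a contour
r(theta) = 1 + 0.2*cos(5*theta) has a_5 = 0.2 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .contours import ResampledContour

__all__ = [
    "ShapeDescriptor",
    "FeatureVector",
    "compute_descriptor",
    "descriptor_from_signature",
    "feature_vector",
    "reconstruct_contour",
    "dominant_harmonic",
]


@dataclass
class ShapeDescriptor:
    """Complex radial-signature Fourier coefficients c_0..c_{N/2}."""

    coeffs: np.ndarray
    n: int
    mean_radius_nm: float
    centroid: np.ndarray
    source_id: str = ""

    def amplitude(self, k: int) -> float:
        """One-sided normalized amplitude 2|c_k|/c_0 of harmonic k >= 1."""
        return float(2.0 * np.abs(self.coeffs[k]) / self.coeffs[0].real)


@dataclass
class FeatureVector:
    """Real invariant magnitudes a_1..a_K (one-sided, c_0-normalized)."""

    values: np.ndarray
    source_id: str = ""

    @property
    def k(self) -> int:
        return int(self.values.shape[0])


def descriptor_from_signature(
    r: np.ndarray, centroid=(0.0, 0.0), source_id: str = ""
) -> ShapeDescriptor:
    """Transform a radial signature r(t) directly (forward-1/N rFFT)."""
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if not np.all(r > 0):
        raise ValueError("radial signature must be strictly positive")
    coeffs = np.fft.rfft(r) / n
    return ShapeDescriptor(
        coeffs=coeffs,
        n=n,
        mean_radius_nm=float(coeffs[0].real),
        centroid=np.asarray(centroid, dtype=float),
        source_id=source_id,
    )


def compute_descriptor(rc: ResampledContour) -> ShapeDescriptor:
    """Fourier-transform the centroid-distance signature of a contour.

    Translation invariance is by construction (distances are taken from the
    contour's own centroid).  Raises on a degenerate (zero-radius) contour.
    Non-star-shaped contours — where the boundary angle does not increase
    monotonically around the centroid, so the radial signature is not a
    single-valued function of angle — are flagged with a warning but still
    processed: the arc-length-parametrized signature remains well defined.
    """
    r = rc.radial_signature()
    if not np.all(r > 0):
        raise ValueError("degenerate contour: boundary passes through the centroid")
    d = rc.points - rc.centroid
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    if not (np.all(np.diff(theta) > 0) or np.all(np.diff(theta) < 0)):
        warnings.warn(
            f"contour {rc.source_id!r} is not star-shaped about its centroid; "
            "the radial signature folds back on itself",
            stacklevel=2,
        )
    return descriptor_from_signature(r, centroid=rc.centroid, source_id=rc.source_id)


def feature_vector(d: ShapeDescriptor, k: int = 512) -> FeatureVector:
    """Invariant amplitude spectrum a_1..a_K of a descriptor."""
    if not 1 <= k <= d.n // 2:
        raise ValueError(f"K must be in [1, N/2] = [1, {d.n // 2}]")
    c0 = d.coeffs[0].real
    if c0 <= 0:
        raise ValueError("descriptor has non-positive mean radius")
    vals = 2.0 * np.abs(d.coeffs[1 : k + 1]) / c0
    return FeatureVector(values=vals, source_id=d.source_id)


def dominant_harmonic(d: ShapeDescriptor) -> int:
    """Index k >= 1 of the largest-amplitude harmonic."""
    return int(np.argmax(np.abs(d.coeffs[1:]))) + 1


def reconstruct_contour(d: ShapeDescriptor, k_keep: int) -> ResampledContour:
    """Rebuild a contour from the first ``k_keep`` harmonics.

    The truncated signature is inverted (inverse rFFT with the matching
    N-factor) and re-embedded as a closed curve around the stored centroid
    on the canonical uniform angular grid theta_t = 2*pi*t/N.  ``k_keep=0``
    gives the mean-radius circle; ``k_keep=N/2`` reproduces the input
    signature to round-off.
    """
    if not 0 <= k_keep <= d.n // 2:
        raise ValueError(f"k_keep must be in [0, N/2] = [0, {d.n // 2}]")
    coeffs = d.coeffs.copy()
    coeffs[k_keep + 1 :] = 0.0
    r = np.fft.irfft(coeffs * d.n, n=d.n)
    theta = 2.0 * np.pi * np.arange(d.n) / d.n
    pts = d.centroid + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    closed = np.vstack([pts, pts[:1]])
    perimeter = float(np.hypot(*np.diff(closed, axis=0).T).sum())
    return ResampledContour(
        points=pts,
        perimeter_nm=perimeter,
        centroid=np.asarray(d.centroid, dtype=float),
        source_id=d.source_id,
    )
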