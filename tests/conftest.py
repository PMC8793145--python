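"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from nanoshape import (
    Contour,
    EnsembleParams,
    ShapeParams,
    ensemble_from_contours,
    generate_ensemble,
)


def circle_contour(radius: float = 30.0, n: int = 256, center=(0.0, 0.0)) -> Contour:
    theta = 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return Contour(points=pts, source_id="circle")


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture
def star_params() -> ShapeParams:
    return ShapeParams(
        base_radius_nm=30.0,
        n_spikes=5,
        spike_amplitude=0.55,
        spike_sharpness=0.45,
        angular_jitter=0.02,
        roughness=0.01,
        seed=3,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def small_ensemble(label: str, mean: ShapeParams, n: int, seed: int, k: int = 64):
    ep = EnsembleParams(
        mean=mean,
        cv={"base_radius_nm": 0.05, "spike_amplitude": 0.10, "spike_sharpness": 0.10},
        n_particles=n,
        seed=seed,
    )
    return ensemble_from_contours(label, generate_ensemble(ep), n=1024, k=k)
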