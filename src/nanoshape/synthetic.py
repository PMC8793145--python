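"""Parametric generator of branched-particle ensembles and renders.

Emulates the classic branched gold-nanoparticle families — stars (few long
arms), flowers (rounded lobes), urchins (many fine needles) and plain
spheres — as star-shaped polar curves

    r(theta) = R * (1 + A * sum_j g((theta - theta_j) / s) + rho * eta(theta))

with R the base radius, A the fractional spike amplitude, the n spike
centers theta_j equally spaced plus angular jitter, g a periodic von-Mises
bump exp(kappa * (cos(u) - 1)) with kappa = 1/s^2 (smaller s = sharper,
more urchin-like protrusions), and eta a smooth band-limited zero-mean
noise field scaled by the roughness rho.

An ensemble is a population of such particles whose parameters vary
particle-to-particle with stated coefficients of variation (lognormal for
positive parameters, rounded truncated normal for the spike count), seeded
hierarchically so any single particle is reproducible in isolation.
Ensembles can be rendered into noisy micrograph-like images (dark filled
particles, bright background, Gaussian noise, non-overlapping placement)
to exercise the full segmentation pipeline without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon as draw_polygon

from .contours import Contour, ParticleImage

__all__ = [
    "ShapeParams",
    "EnsembleParams",
    "Placement",
    "generate_contour",
    "generate_ensemble",
    "render_image",
    "render_ensemble",
    "PRESETS",
]

_N_THETA = 1024  # angular samples per generated contour
_NOISE_HARMONICS = 32  # band limit of the roughness field


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of one branched particle.

    base_radius_nm > 0; 0 <= spike_amplitude <= 0.9 (keeps r > 0);
    spike_sharpness > 0 in radians (bump angular half-width scale);
    angular_jitter: SD of spike placement noise in radians;
    roughness: RMS fractional amplitude of the broadband radial noise.
    """

    base_radius_nm: float = 30.0
    n_spikes: int = 0
    spike_amplitude: float = 0.0
    spike_sharpness: float = 0.3
    angular_jitter: float = 0.0
    roughness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius_nm <= 0:
            raise ValueError("base_radius_nm must be > 0")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if not 0.0 <= self.spike_amplitude <= 0.9:
            raise ValueError("spike_amplitude must be in [0, 0.9]")
        if self.spike_sharpness <= 0:
            raise ValueError("spike_sharpness must be > 0")
        if self.angular_jitter < 0 or self.roughness < 0:
            raise ValueError("angular_jitter and roughness must be >= 0")


@dataclass(frozen=True)
class EnsembleParams:
    """A particle population: mean shape parameters plus per-parameter
    coefficients of variation for particle-to-particle variability."""

    mean: ShapeParams = field(default_factory=ShapeParams)
    cv: dict = field(default_factory=dict)  # param name -> CV (>= 0)
    n_particles: int = 200
    seed: int = 0

    _CV_PARAMS = ("base_radius_nm", "spike_amplitude", "spike_sharpness", "n_spikes")

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        for name, v in self.cv.items():
            if name not in self._CV_PARAMS:
                raise ValueError(f"unknown cv parameter {name!r}; allowed: {self._CV_PARAMS}")
            if v < 0:
                raise ValueError("coefficients of variation must be >= 0")


@dataclass(frozen=True)
class Placement:
    """Ground-truth record of where one particle was drawn in an image."""

    particle_index: int
    center_px: tuple[float, float]  # (row, col)
    max_radius_px: float


def _radial_profile(p: ShapeParams, rng: np.random.Generator) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(_N_THETA) / _N_THETA
    r = np.ones(_N_THETA)
    if p.n_spikes > 0 and p.spike_amplitude > 0:
        centers = 2.0 * np.pi * np.arange(p.n_spikes) / p.n_spikes
        if p.angular_jitter > 0:
            centers = centers + rng.normal(0.0, p.angular_jitter, size=p.n_spikes)
        kappa = 1.0 / p.spike_sharpness**2
        # von-Mises bump, unit peak height at each spike center
        bumps = np.exp(kappa * (np.cos(theta[:, None] - centers[None, :]) - 1.0))
        r = r + p.spike_amplitude * bumps.sum(axis=1)
    if p.roughness > 0:
        # smooth periodic noise: random low-order Fourier series, unit RMS
        ks = np.arange(1, _NOISE_HARMONICS + 1)
        amp = rng.normal(size=ks.size) / np.sqrt(ks)  # mild red spectrum
        phase = rng.uniform(0.0, 2.0 * np.pi, size=ks.size)
        eta = np.sum(amp[None, :] * np.cos(ks[None, :] * theta[:, None] + phase[None, :]), axis=1)
        eta = eta / max(np.sqrt(np.mean(eta**2)), 1e-12)
        r = r + p.roughness * eta
    r = p.base_radius_nm * r
    if np.any(r <= 0):
        raise ValueError("parameter combination produced a non-positive radius")
    return r


def generate_contour(p: ShapeParams, rng: np.random.Generator | None = None) -> Contour:
    """Sample one particle outline at 1024 equally spaced angles.

    Deterministic given (params, seed): with no rng supplied, a fresh
    generator is derived from ``p.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    theta = 2.0 * np.pi * np.arange(_N_THETA) / _N_THETA
    r = _radial_profile(p, rng)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Contour(points=pts, source_id=f"gen-{p.seed}")


def _draw_particle_params(ep: EnsembleParams, child_seeds: np.ndarray) -> list[ShapeParams]:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(ep.seed), spawn_key=(0,)))
    out = []
    m = ep.mean
    for i in range(ep.n_particles):
        kw = {}
        for name in ("base_radius_nm", "spike_amplitude", "spike_sharpness"):
            mean_v = getattr(m, name)
            cv = ep.cv.get(name, 0.0)
            if cv > 0 and mean_v > 0:
                # lognormal with the requested mean and CV
                sigma2 = np.log(1.0 + cv**2)
                mu = np.log(mean_v) - sigma2 / 2.0
                v = float(rng.lognormal(mu, np.sqrt(sigma2)))
            else:
                v = mean_v
            kw[name] = v
        kw["spike_amplitude"] = min(kw["spike_amplitude"], 0.9)
        cv_n = ep.cv.get("n_spikes", 0.0)
        if cv_n > 0 and m.n_spikes > 0:
            n = int(round(rng.normal(m.n_spikes, cv_n * m.n_spikes)))
            kw["n_spikes"] = max(n, 0)
        else:
            kw["n_spikes"] = m.n_spikes
        out.append(
            replace(
                m,
                **kw,
                seed=int(child_seeds[i]),
            )
        )
    return out


def generate_ensemble(ep: EnsembleParams) -> list[Contour]:
    """Generate a particle population with stated particle-to-particle CV.

    Child seeds derive deterministically from ``ep.seed`` (SeedSequence
    spawning), so particle i of ensemble s is reproducible on its own via
    ``generate_contour(params_i)``.
    """
    ss = np.random.SeedSequence(entropy=int(ep.seed), spawn_key=(1,))
    child_seeds = ss.generate_state(ep.n_particles) % (2**31)
    plist = _draw_particle_params(ep, child_seeds)
    contours = []
    for i, p in enumerate(plist):
        c = generate_contour(p)
        c.source_id = f"{ep.seed}:{i}"
        contours.append(c)
    return contours


def render_image(
    contours: list[Contour],
    canvas_px: int = 768,
    pixel_size_nm: float = 1.0,
    noise_sd: float = 0.03,
    rng: np.random.Generator | None = None,
    margin_px: int = 5,
    max_tries: int = 200,
    image_id: str = "synthetic",
) -> tuple[ParticleImage, list[Placement]]:
    """Rasterize contours into a noisy micrograph-like field of view.

    Dark filled particles (intensity 0.15) on a bright background (0.85)
    plus additive Gaussian noise.  Particles are placed by rejection
    sampling so their bounding circles never overlap and keep at least
    ``margin_px`` from the border, mirroring well-spread imaging; failure
    to place within ``max_tries`` raises.  The returned placements are the
    ground truth for segmentation oracles.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    bg, fg = 0.85, 0.15
    img = np.full((canvas_px, canvas_px), bg)
    placements: list[Placement] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    for idx, c in enumerate(contours):
        centered = c.points - c.centroid
        rad_px = np.max(np.hypot(centered[:, 0], centered[:, 1])) / pixel_size_nm
        lo = rad_px + margin_px
        hi = canvas_px - 1 - rad_px - margin_px
        if hi <= lo:
            raise ValueError(f"particle {idx} does not fit the canvas with margins")
        for attempt in range(max_tries):
            row = rng.uniform(lo, hi)
            col = rng.uniform(lo, hi)
            ok = True
            for r0, c0, rp in placed:
                if np.hypot(row - r0, col - c0) <= rad_px + rp + 2:
                    ok = False
                    break
            if ok:
                break
        else:
            raise ValueError(f"could not place particle {idx} without overlap after {max_tries} tries")
        placed.append((row, col, rad_px))
        placements.append(Placement(idx, (row, col), float(rad_px)))
        rows = centered[:, 1] / pixel_size_nm + row
        cols = centered[:, 0] / pixel_size_nm + col
        rr, cc = draw_polygon(rows, cols, shape=img.shape)
        img[rr, cc] = fg
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return ParticleImage(pixels=img, pixel_size_nm=pixel_size_nm, id=image_id), placements


def render_ensemble(
    contours: list[Contour],
    per_image: int = 6,
    canvas_px: int = 768,
    pixel_size_nm: float = 1.0,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> list[tuple[ParticleImage, list[Placement]]]:
    """Split an ensemble over as many canvases as needed and render each."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(0, len(contours), per_image):
        batch = contours[i : i + per_image]
        out.append(
            render_image(
                batch,
                canvas_px=canvas_px,
                pixel_size_nm=pixel_size_nm,
                noise_sd=noise_sd,
                rng=rng,
                image_id=f"field-{i // per_image}",
            )
        )
    return out


def _load_presets() -> dict[str, EnsembleParams]:
    import importlib.resources

    import yaml

    out = {}
    root = importlib.resources.files(__package__) / "presets"
    for res in sorted(root.iterdir(), key=lambda r: r.name):
        if not res.name.endswith(".yaml"):
            continue
        d = yaml.safe_load(res.read_text())
        out[res.name[:-5]] = EnsembleParams(
            mean=ShapeParams(**d["mean"]),
            cv=d.get("cv", {}),
            n_particles=d.get("n_particles", 200),
            seed=d.get("seed", 0),
        )
    return out


#: Canonical branched-particle families, loaded from the shipped YAML
#: configs: stars carry a few long arms, flowers many rounded lobes,
#: urchins a dense coat of fine needles.
PRESETS: dict[str, EnsembleParams] = _load_presets()
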