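"""The parametric branched-particle generator and the image renderer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoshape import (
    EnsembleParams,
    ShapeParams,
    compute_descriptor,
    dominant_harmonic,
    ensemble_from_contours,
    fit_shape_space,
    generate_contour,
    generate_ensemble,
    overlap_coefficient,
    project_ensemble,
    render_image,
    resample_contour,
    segment_particles,
)
from nanoshape.synthetic import PRESETS


class TestGenerateContour:
    def test_no_spikes_no_roughness_is_a_circle(self):
        c = generate_contour(ShapeParams(base_radius_nm=25.0))
        r = np.hypot(*c.points.T)
        np.testing.assert_allclose(r, 25.0, atol=1e-12)

    def test_dominant_harmonic_equals_spike_count(self):
        p = ShapeParams(base_radius_nm=30, n_spikes=12, spike_amplitude=0.25,
                        spike_sharpness=0.2)
        d = compute_descriptor(resample_contour(generate_contour(p), 1024))
        assert dominant_harmonic(d) == 12

    def test_deterministic_given_seed(self):
        p = ShapeParams(base_radius_nm=30, n_spikes=7, spike_amplitude=0.3,
                        spike_sharpness=0.3, angular_jitter=0.05, roughness=0.05, seed=99)
        a = generate_contour(p)
        b = generate_contour(p)
        assert np.array_equal(a.points, b.points)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ShapeParams(base_radius_nm=-1)
        with pytest.raises(ValueError):
            ShapeParams(spike_amplitude=0.95)
        with pytest.raises(ValueError):
            ShapeParams(spike_sharpness=0.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n_spikes=st.integers(0, 30),
        amplitude=st.floats(0.0, 0.6),
        sharpness=st.floats(0.1, 0.9),
        seed=st.integers(0, 1000),
    )
    def test_radial_signature_always_positive(self, n_spikes, amplitude, sharpness, seed):
        p = ShapeParams(base_radius_nm=20, n_spikes=n_spikes, spike_amplitude=amplitude,
                        spike_sharpness=sharpness, angular_jitter=0.05,
                        roughness=0.05, seed=seed)
        c = generate_contour(p)
        assert np.all(np.hypot(*(c.points - c.centroid).T) > 0)


class TestGenerateEnsemble:
    def test_zero_cv_gives_identical_feature_vectors(self):
        mean = ShapeParams(base_radius_nm=30, n_spikes=5, spike_amplitude=0.4,
                           spike_sharpness=0.5)
        ep = EnsembleParams(mean=mean, cv={}, n_particles=5, seed=1)
        ens = ensemble_from_contours("e", generate_ensemble(ep), k=64)
        np.testing.assert_allclose(
            ens.features, np.tile(ens.features[0], (ens.n_particles, 1)), atol=1e-9
        )

    def test_hierarchical_seeding_reproduces_single_particle(self):
        ep = EnsembleParams(mean=PRESETS["star"].mean, cv=PRESETS["star"].cv,
                            n_particles=10, seed=33)
        contours = generate_ensemble(ep)
        again = generate_ensemble(ep)
        for a, b in zip(contours, again):
            assert np.array_equal(a.points, b.points)

    def test_unknown_cv_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown cv"):
            EnsembleParams(mean=ShapeParams(), cv={"bogus": 0.1})

    def test_same_params_independent_replicates_overlap(self):
        eps = [
            EnsembleParams(mean=PRESETS["flower"].mean, cv=PRESETS["flower"].cv,
                           n_particles=60, seed=s)
            for s in (5, 6)
        ]
        ens = [ensemble_from_contours(f"r{i}", generate_ensemble(ep), k=64)
               for i, ep in enumerate(eps)]
        model = fit_shape_space(ens)
        pa, pb = (project_ensemble(model, e, m=3) for e in ens)
        assert overlap_coefficient(pa, pb).ovl >= 0.8

    def test_star_and_urchin_families_are_distinct(self):
        ens = []
        for name, seed in (("star", 1), ("urchin", 2)):
            ep = EnsembleParams(mean=PRESETS[name].mean, cv=PRESETS[name].cv,
                                n_particles=60, seed=seed)
            ens.append(ensemble_from_contours(name, generate_ensemble(ep), k=64))
        model = fit_shape_space(ens)
        pa, pb = (project_ensemble(model, e, m=3) for e in ens)
        assert overlap_coefficient(pa, pb).ovl <= 0.05


class TestRenderImage:
    def test_single_contour_noise_free(self):
        c = generate_contour(ShapeParams(base_radius_nm=40, n_spikes=5,
                                         spike_amplitude=0.3, spike_sharpness=0.5))
        img, placements = render_image([c], canvas_px=256, noise_sd=0.0,
                                       rng=np.random.default_rng(0))
        assert len(placements) == 1
        assert len(np.unique(img.pixels)) == 2  # exactly background and foreground
        masks = segment_particles(img)
        assert len(masks) == 1

    def test_placement_failure_raises(self):
        big = generate_contour(ShapeParams(base_radius_nm=100.0))
        contours = [big] * 4  # four radius-100 disks cannot share a 256px canvas
        with pytest.raises(ValueError, match="place|fit"):
            render_image(contours, canvas_px=256, rng=np.random.default_rng(0))

    def test_roundtrip_recovers_dominant_harmonic(self):
        from nanoshape import extract_contour

        p = ShapeParams(base_radius_nm=60, n_spikes=12, spike_amplitude=0.2,
                        spike_sharpness=0.15, seed=2)
        c = generate_contour(p)
        img, _ = render_image([c], canvas_px=256, noise_sd=0.02,
                              rng=np.random.default_rng(3))
        masks = segment_particles(img)
        assert len(masks) == 1
        traced = extract_contour(masks[0], img.pixel_size_nm)
        d = compute_descriptor(resample_contour(traced, 1024))
        assert dominant_harmonic(d) == 12


def test_presets_cover_the_canonical_families():
    assert {"sphere", "star", "flower", "urchin"} <= set(PRESETS)
    assert PRESETS["urchin"].mean.n_spikes > PRESETS["flower"].mean.n_spikes > PRESETS["star"].mean.n_spikes
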