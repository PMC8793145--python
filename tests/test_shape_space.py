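"""Pooled PCA shape space, confidence ellipses, dispersity PDFs."""

import numpy as np
import pytest
from scipy import stats

from nanoshape import (
    EnsembleProjection,
    ShapeEnsemble,
    ShapeParams,
    confidence_ellipse,
    distance_pdf,
    ellipse_contains,
    fit_shape_space,
    project_ensemble,
    representative_particle,
)

from conftest import small_ensemble


def gaussian_ensemble(label, mean, cov_or_scale, n, seed, k=6):
    rng = np.random.default_rng(seed)
    mean_vec = np.zeros(k)
    mean_vec[: len(mean)] = mean
    if np.isscalar(cov_or_scale):
        feats = rng.normal(0, cov_or_scale, (n, k)) + mean_vec
    else:
        feats = rng.multivariate_normal(mean_vec[:2], cov_or_scale, n)
        feats = np.hstack([feats, np.zeros((n, k - 2))])
    return ShapeEnsemble(label=label, features=feats, particle_ids=[str(i) for i in range(n)])


class TestFit:
    def test_variance_ratios_sum_to_one(self):
        e = gaussian_ensemble("a", [0, 0], 1.0, 50, 0)
        model = fit_shape_space([e])
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_components_orthonormal(self):
        model = fit_shape_space([gaussian_ensemble("a", [0, 0], 1.0, 40, 1)])
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_line_embedded_data_is_rank_one(self):
        t = np.linspace(-1, 1, 30)
        direction = np.array([1.0, 2.0, -1.0, 0.5, 0.0, 3.0])
        feats = np.outer(t, direction)
        e = ShapeEnsemble("line", feats, [str(i) for i in range(30)])
        model = fit_shape_space([e])
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_pc1_aligns_with_cluster_displacement(self):
        v = np.array([3.0, -1.0, 2.0, 0.0, 1.0, -2.0])
        v = v / np.linalg.norm(v)
        a = gaussian_ensemble("a", [0, 0], 0.01, 100, 2)
        b = ShapeEnsemble("b", a.features + 5.0 * v, a.particle_ids)
        model = fit_shape_space([a, b])
        cosine = abs(model.components[0] @ v)
        assert cosine >= 0.99

    def test_sign_convention(self):
        model = fit_shape_space([gaussian_ensemble("a", [1, 2], 1.0, 60, 3)])
        for comp in model.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_too_few_particles(self):
        e = ShapeEnsemble("one", np.ones((1, 4)), ["p"])
        with pytest.raises(ValueError, match="2 particles"):
            fit_shape_space([e])


class TestProjection:
    def test_pooled_grand_mean_is_zero(self):
        ens = [gaussian_ensemble(s, [i, -i], 1.0, 40, i) for i, s in enumerate("abc")]
        model = fit_shape_space(ens)
        coords = np.vstack([project_ensemble(model, e, m=3).coords for e in ens])
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_full_rank_projection_is_lossless(self):
        e = gaussian_ensemble("a", [0, 1], 1.0, 40, 5)
        model = fit_shape_space([e])
        proj = project_ensemble(model, e, m=model.n_components)
        back = model.inverse_transform(proj.coords)
        np.testing.assert_allclose(back, e.features, atol=1e-9)

    def test_identical_particles_collapse_to_centroid(self):
        base = gaussian_ensemble("a", [0, 0], 1.0, 30, 6)
        model = fit_shape_space([base])
        same = ShapeEnsemble("same", np.tile(base.features[0], (5, 1)),
                             [str(i) for i in range(5)])
        proj = project_ensemble(model, same, m=2)
        np.testing.assert_allclose(proj.coords, np.tile(proj.coords[0], (5, 1)), atol=1e-12)
        np.testing.assert_allclose(proj.centroid, proj.coords[0], atol=1e-12)

    def test_dimension_mismatch(self):
        model = fit_shape_space([gaussian_ensemble("a", [0, 0], 1.0, 30, 7, k=6)])
        other = gaussian_ensemble("b", [0, 0], 1.0, 30, 8, k=5)
        with pytest.raises(ValueError, match="mismatch"):
            project_ensemble(model, other, m=2)


class TestRepresentative:
    def test_particle_at_centroid_wins(self):
        coords = np.array([[1.0, 1.0], [-1.0, -1.0], [0.0, 0.0], [1.0, -1.0], [-1.0, 1.0]])
        p = EnsembleProjection("e", coords, list("abcde"))
        assert representative_particle(p) == "c"

    def test_tie_goes_to_lower_index(self):
        coords = np.array([[1.0, 0.0], [-1.0, 0.0]])  # both at distance 1
        p = EnsembleProjection("e", coords, ["first", "second"])
        assert representative_particle(p) == "first"

    def test_singleton(self):
        p = EnsembleProjection("e", np.array([[2.0, 3.0]]), ["only"])
        assert representative_particle(p) == "only"

    def test_empty_errors(self):
        p = EnsembleProjection("e", np.empty((0, 2)), [])
        with pytest.raises(ValueError):
            representative_particle(p)


class TestConfidenceEllipse:
    def test_isotropic_gaussian_semi_axes_match_chi2_quantile(self):
        rng = np.random.default_rng(0)
        p = EnsembleProjection("g", rng.normal(size=(20000, 2)), None)
        p.particle_ids = [str(i) for i in range(20000)]
        ell = confidence_ellipse(p, level=0.95)
        expected = np.sqrt(stats.chi2.ppf(0.95, 2))  # ~2.448
        assert ell.semi_axes[0] == pytest.approx(expected, rel=0.02)
        assert ell.semi_axes[1] == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("level", [0.5, 0.9, 0.95])
    def test_coverage_matches_level_for_gaussian_clouds(self, level):
        rng = np.random.default_rng(42)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        pts = rng.multivariate_normal([1.0, -2.0], cov, size=10000)
        p = EnsembleProjection("g", pts, [str(i) for i in range(10000)])
        ell = confidence_ellipse(p, level=level)
        coverage = ellipse_contains(ell, pts).mean()
        assert coverage == pytest.approx(level, abs=0.015)

    def test_collinear_points_degenerate(self):
        t = np.linspace(0, 1, 30)
        p = EnsembleProjection("line", np.column_stack([t, 2 * t]),
                              [str(i) for i in range(30)])
        with pytest.raises(ValueError, match="degenerate|singular"):
            confidence_ellipse(p)

    def test_identical_points_degenerate(self):
        p = EnsembleProjection("same", np.ones((10, 2)), [str(i) for i in range(10)])
        with pytest.raises(ValueError):
            confidence_ellipse(p)

    def test_invalid_level(self):
        p = EnsembleProjection("g", np.random.default_rng(1).normal(size=(30, 2)),
                              [str(i) for i in range(30)])
        with pytest.raises(ValueError):
            confidence_ellipse(p, level=1.0)


class TestDistancePDF:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(3)
        p = EnsembleProjection("g", rng.normal(size=(200, 3)), [str(i) for i in range(200)])
        pdf = distance_pdf(p)
        assert np.all(pdf.density >= 0)
        assert np.trapezoid(pdf.density, pdf.grid) == pytest.approx(1.0, abs=1e-3)

    def test_isotropic_gaussian_distances_are_rayleigh(self):
        rng = np.random.default_rng(4)
        p = EnsembleProjection("g", rng.normal(size=(2000, 2)), [str(i) for i in range(2000)])
        pdf = distance_pdf(p, m=2)
        ks = stats.kstest(pdf.distances, stats.rayleigh.cdf).statistic
        assert ks <= 0.05

    def test_degenerate_distribution_errors(self):
        p = EnsembleProjection("same", np.ones((25, 3)), [str(i) for i in range(25)])
        with pytest.raises(ValueError, match="degenerate"):
            distance_pdf(p)

    def test_minimum_population(self):
        p = EnsembleProjection("few", np.random.default_rng(5).normal(size=(10, 3)),
                              [str(i) for i in range(10)])
        with pytest.raises(ValueError, match="20"):
            distance_pdf(p)


def test_replicate_batches_sit_closer_than_their_spread():
    """Two ensembles from the same generator parameters have centroids
    separated by less than either batch's mean distance-to-centroid."""
    mean = ShapeParams(base_radius_nm=30, n_spikes=5, spike_amplitude=0.4,
                       spike_sharpness=0.45, angular_jitter=0.02, roughness=0.01)
    a = small_ensemble("rep1", mean, n=40, seed=21)
    b = small_ensemble("rep2", mean, n=40, seed=22)
    model = fit_shape_space([a, b])
    pa = project_ensemble(model, a, m=3)
    pb = project_ensemble(model, b, m=3)
    sep = np.linalg.norm(pa.centroid - pb.centroid)
    spread_a = np.linalg.norm(pa.coords - pa.centroid, axis=1).mean()
    spread_b = np.linalg.norm(pb.coords - pb.centroid, axis=1).mean()
    assert sep < spread_a and sep < spread_b
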