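"""Osculating-paraboloid curvature estimation and robustification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sdsim as sd
from sdsim.curvature import (chauvenet_flags, curvatures_from_fit,
                             find_hot_spots, fit_osculating_paraboloid,
                             robust_curvature_field, total_curvature,
                             vertex_normal, vertex_normals, ParaboloidFit)
from sdsim.surfaces import SurfaceError, TriSurface


from tests_support import quadratic_patch


class TestNormals:
    def test_flat_sheet_normal_is_z(self):
        s = sd.make_flat_sheet((10, 10), 1.0, "no_flux")
        n = vertex_normal(s, s.n_vertices // 2)
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-12)

    def test_unit_length_everywhere(self, sphere10):
        norms = np.linalg.norm(vertex_normals(sphere10), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_sphere_normals_radial(self, sphere10):
        n = vertex_normals(sphere10)
        radial = sphere10.vertices / np.linalg.norm(sphere10.vertices, axis=1,
                                                    keepdims=True)
        angles = np.degrees(np.arccos(np.clip((n * radial).sum(1), -1, 1)))
        assert angles.max() < 2.0


class TestParaboloidFit:
    @pytest.mark.parametrize("abc", [(2.0, 0.0, 1.0), (1.0, -0.7, 0.4),
                                     (0.0, 0.0, 0.0), (-0.5, 0.3, -1.2)])
    def test_exact_recovery_of_model_class(self, abc):
        # coefficients are reported in the fit's own tangent frame, which
        # may be rotated against global (x, y); the frame-invariant content
        # of (a, b, c) -- H, K, i.e. the eigenvalues of the shape form --
        # must be recovered to machine precision
        a, b, c = abc
        s = quadratic_patch(a, b, c)
        fit = fit_osculating_paraboloid(s, 0, ring_order=1)
        assert fit.a + fit.c == pytest.approx(a + c, abs=1e-9)
        assert 4 * fit.a * fit.c - fit.b ** 2 \
            == pytest.approx(4 * a * c - b * b, abs=1e-9)
        want = np.sort(np.linalg.eigvalsh([[a, b / 2], [b / 2, c]]))
        got = np.sort(np.linalg.eigvalsh([[fit.a, fit.b / 2],
                                          [fit.b / 2, fit.c]]))
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_flat_neighbourhood_gives_zero(self):
        s = sd.make_flat_sheet((10, 10), 1.0, "no_flux")
        fit = fit_osculating_paraboloid(s, s.n_vertices // 2, 1)
        assert (fit.a, fit.b, fit.c) == pytest.approx((0, 0, 0), abs=1e-12)

    def test_sphere_K_within_5_percent(self, sphere10):
        i = sphere10.n_vertices // 2
        fit = fit_osculating_paraboloid(sphere10, i, 1)
        K = 4 * fit.a * fit.c - fit.b ** 2
        assert K == pytest.approx(0.01, rel=0.05)

    def test_degenerate_fit_flagged(self):
        # two-point ring cannot constrain three coefficients
        verts = np.array([[0, 0, 0], [1, 0, 1], [-1, 0, 1]], dtype=float)
        faces = np.array([[0, 1, 2]])
        fit = fit_osculating_paraboloid(TriSurface(verts, faces), 0, 1)
        assert fit.degenerate and (fit.a, fit.b, fit.c) == (0, 0, 0)


class TestCurvaturesFromFit:
    @pytest.mark.parametrize("abc,expected", [
        ((1.0, 0.0, 1.0), (2.0, 4.0, 2.0, 2.0, 2.0)),     # umbilic dome
        ((1.0, 0.0, -1.0), (0.0, -4.0, 2.0, -2.0, -2.0)), # saddle
        ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0, 0.0)),     # flat
    ])
    def test_printed_examples(self, abc, expected):
        fit = ParaboloidFit(*abc, vertex_id=0, ring_order=1, n_points=9)
        H, K, k1, k2, kg = curvatures_from_fit(fit)
        assert (H, K, k1, k2, kg) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), c=st.floats(-3, 3))
    def test_principal_curvature_identities(self, a, b, c):
        fit = ParaboloidFit(a, b, c, 0, 1, 9)
        H, K, k1, k2, kg = curvatures_from_fit(fit)
        assert k1 + k2 == pytest.approx(2 * H, abs=1e-9)
        if H * H - K >= 0:   # without clipping, kappa1*kappa2 == K
            assert k1 * k2 == pytest.approx(K, abs=max(1e-9, 1e-9 * abs(K)))
        assert kg ** 2 == pytest.approx(abs(K), rel=1e-9, abs=1e-12)
        assert np.sign(kg) == np.sign(K)


def chauvenet_oracle(values):
    """Brute-force evaluation of the printed criterion, element by element."""
    values = list(map(float, values))
    n = len(values)
    mu = sum(values) / n
    var = sum((x - mu) ** 2 for x in values) / (n - 1)
    sigma = math.sqrt(var)
    if sigma == 0:
        return [False] * n
    return [n * math.erfc(abs(x - mu) / sigma) < 0.5 for x in values]


class TestChauvenet:
    def test_all_equal_no_outliers(self):
        assert not chauvenet_flags([3.0] * 50).any()

    def test_single_extreme_flagged(self):
        values = [0.0] * 100 + [10.0]
        flags = chauvenet_flags(values)
        assert flags[-1] and flags[:-1].sum() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=200)
        values[:3] += rng.choice([-8, 8], size=3)
        np.testing.assert_array_equal(chauvenet_flags(values),
                                      chauvenet_oracle(values))

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=100)
        base = chauvenet_flags(values)
        np.testing.assert_array_equal(chauvenet_flags(3.5 * values - 12.0),
                                      base)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            chauvenet_flags([1.0])


class TestRobustField:
    def test_sphere_statistics(self, sphere10, sphere10_field):
        f = sphere10_field
        assert f.outlier_fraction_K < 0.05
        assert np.median(f.K) == pytest.approx(0.01, rel=0.05)

    def test_flat_sheet_zero_curvature(self):
        s = sd.make_flat_sheet((15, 15), 1.0, "no_flux")
        f = robust_curvature_field(s)
        assert np.abs(f.H).max() < 1e-8 and np.abs(f.K).max() < 1e-8

    def test_displaced_vertex_flagged_and_tempered(self, sphere10):
        v = sphere10.vertices.copy()
        i = 100
        v[i] *= 1.0 + 0.5 * 1.4 / 10.0   # push outward ~half an edge length
        f = robust_curvature_field(TriSurface(v, sphere10.faces))
        assert f.outlier_K[i]
        assert abs(f.K[i]) < abs(f.K1[i])

    def test_orientation_reversal(self, sphere10, sphere10_field):
        flipped = TriSurface(sphere10.vertices, sphere10.faces[:, ::-1])
        ff = robust_curvature_field(flipped)
        np.testing.assert_allclose(ff.H1, -sphere10_field.H1, atol=1e-10)
        np.testing.assert_allclose(ff.K1, sphere10_field.K1, atol=1e-10)

    def test_convergence_under_refinement(self, sphere10, sphere10_field):
        coarse = robust_curvature_field(sd.make_sphere(10.0, 2))
        err = lambda f: np.median(np.abs(f.K - 0.01))
        assert err(sphere10_field) < err(coarse)


class TestIntegralAndHotSpots:
    def test_gauss_bonnet_sphere(self, sphere10, sphere10_field):
        assert total_curvature(sphere10_field, sphere10) == pytest.approx(
            4 * np.pi, rel=0.05)

    def test_gauss_bonnet_torus(self, torus31, torus31_field):
        assert abs(total_curvature(torus31_field, torus31)) < 0.5

    def test_open_surface_rejected(self):
        s = sd.make_flat_sheet((10, 10), 1.0, "no_flux")
        f = robust_curvature_field(s)
        with pytest.raises(SurfaceError):
            total_curvature(f, s)

    def test_sphere_and_flat_have_no_hot_spots(self, sphere10, sphere10_field):
        assert len(find_hot_spots(sphere10_field, sphere10, -0.1)) == 0
        s = sd.make_flat_sheet((15, 15), 1.0, "no_flux")
        assert len(find_hot_spots(robust_curvature_field(s), s, -0.1)) == 0

    def test_torus_hot_spots_on_inner_equator(self, torus31, torus31_field):
        spots = find_hot_spots(torus31_field, torus31, k_threshold=-0.3,
                               min_separation=1.0)
        assert len(spots) > 0
        # analytic K = cos(t)/(r(R + r cos t)) is most negative at t = pi,
        # the inner equator, at radial distance R - r = 2 from the axis
        radial = np.hypot(torus31.vertices[spots, 0],
                          torus31.vertices[spots, 1])
        np.testing.assert_allclose(radial, 2.0, atol=0.05)
        K_inner = np.cos(np.pi) / (1.0 * (3.0 + np.cos(np.pi)))
        assert torus31_field.K[spots[0]] == pytest.approx(K_inner, rel=0.05)
        # sorted ascending, thinned by separation
        Ks = torus31_field.K[spots]
        assert np.all(np.diff(Ks) >= 0)

    def test_threshold_sign_checked(self, torus31, torus31_field):
        with pytest.raises(ValueError):
            find_hot_spots(torus31_field, torus31, 0.5)
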