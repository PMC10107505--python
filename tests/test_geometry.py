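"""Gyration-based size estimation and filling corrections."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import protherm as pt
from protherm.exceptions import GeometryError, InputError
from protherm.geometry import (
    CYL_LONGITUDINAL_FILLING_FACTOR,
    CYL_RADIAL_FILLING_FACTOR,
    SPHERE_FILLING_FACTOR,
)


def cloud(points, masses=None):
    points = np.asarray(points, dtype=float)
    if masses is None:
        masses = np.ones(len(points))
    return pt.PointCloud(positions=points, masses=masses)


class TestSphericalGyrationRadius:
    def test_symmetric_pair(self):
        c = cloud([[1.7, 0, 0], [-1.7, 0, 0]])
        assert pt.spherical_gyration_radius(c) == pytest.approx(1.7)

    def test_single_point_is_zero(self):
        assert pt.spherical_gyration_radius(cloud([[3.0, -2.0, 1.0]])) == 0.0

    def test_mass_weighting_changes_result(self):
        c = cloud([[1.0, 0, 0], [-3.0, 0, 0]], masses=[3.0, 1.0])
        # COM at 0; rg = sqrt((3*1 + 1*9)/4) = sqrt(3)
        assert pt.spherical_gyration_radius(c) == pytest.approx(math.sqrt(3))
        # unweighted: COM at -1, both atoms at distance 2
        assert pt.spherical_gyration_radius(c, mass_weighted=False) == (
            pytest.approx(2.0)
        )

    def test_uniform_sphere_sample_matches_moment_oracle(self):
        R = 1.3
        c = pt.uniform_shape_cloud(("sphere", R), 40000, seed=3)
        rg = pt.spherical_gyration_radius(c)
        # independent second-moment computation
        d = c.positions - c.positions.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum(d * d, axis=1)))
        assert rg == pytest.approx(oracle, rel=1e-12)
        # law of large numbers: rg -> R*sqrt(3/5)
        assert rg == pytest.approx(R * math.sqrt(3.0 / 5.0), rel=0.01)

    def test_empty_cloud_rejected(self):
        with pytest.raises(InputError):
            pt.PointCloud(positions=np.empty((0, 3)), masses=np.empty(0))

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InputError):
            pt.PointCloud(positions=[[0, 0, 0]], masses=[0.0])


class TestCylindricalGyrationSizes:
    def test_uniform_cylinder_sample(self):
        R, H = 1.0, 4.0
        c = pt.uniform_shape_cloud(("cylinder", R, H), 50000, seed=4)
        r_c, h_c, axis = pt.cylindrical_gyration_sizes(c)
        assert r_c == pytest.approx(R / math.sqrt(2), rel=0.01)
        assert h_c == pytest.approx(H / math.sqrt(3), rel=0.01)
        assert abs(axis[2]) == pytest.approx(1.0, abs=1e-2)

    def test_collinear_points_give_zero_radius(self):
        c = cloud([[0, 0, z] for z in np.linspace(-2, 2, 9)])
        r_c, h_c, axis = pt.cylindrical_gyration_sizes(c)
        assert r_c == 0.0
        assert h_c > 0.0
        assert np.allclose(np.abs(axis), [0, 0, 1])

    def test_coincident_points_rejected(self):
        c = cloud([[1.0, 1.0, 1.0]] * 5)
        with pytest.raises(GeometryError):
            pt.cylindrical_gyration_sizes(c)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            pt.cylindrical_gyration_sizes(cloud([[0, 0, 0], [1, 0, 0]]))

    def test_isotropic_sample_has_no_preferred_axis(self):
        # for an isotropic body all principal variances agree, so
        # r_c = sqrt(2)*sigma and h_c = 2*sigma regardless of the axis pick
        c = pt.uniform_shape_cloud(("sphere", 1.0), 40000, seed=5)
        r_c, h_c, _ = pt.cylindrical_gyration_sizes(c)
        assert r_c == pytest.approx(math.sqrt(2) * h_c / 2.0, rel=0.02)

    def test_axis_sign_convention_deterministic(self):
        c = pt.uniform_shape_cloud(("cylinder", 0.5, 3.0), 5000, seed=6)
        _, _, axis1 = pt.cylindrical_gyration_sizes(c)
        flipped = pt.PointCloud(positions=-c.positions, masses=c.masses)
        _, _, axis2 = pt.cylindrical_gyration_sizes(flipped)
        nz = np.nonzero(np.abs(axis1) > 1e-12)[0][0]
        assert axis1[nz] > 0 and axis2[np.nonzero(np.abs(axis2) > 1e-12)[0][0]] > 0


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gyration_quantities_invariant(self, seed):
        rng = np.random.default_rng(seed)
        c = pt.uniform_shape_cloud(("cylinder", 1.0, 3.0), 2000, seed=7)
        rot = Rotation.random(random_state=int(rng.integers(2**31)))
        shift = rng.normal(scale=10.0, size=3)
        moved = pt.PointCloud(
            positions=c.positions @ rot.as_matrix().T + shift,
            masses=c.masses,
        )
        assert pt.spherical_gyration_radius(moved) == pytest.approx(
            pt.spherical_gyration_radius(c), rel=1e-9
        )
        r1, h1, _ = pt.cylindrical_gyration_sizes(c)
        r2, h2, _ = pt.cylindrical_gyration_sizes(moved)
        assert r2 == pytest.approx(r1, rel=1e-9)
        assert h2 == pytest.approx(h1, rel=1e-9)


class TestFillingCorrection:
    def test_sphere_factor_and_volume(self):
        est = pt.ShapeEstimate(model="sphere", r_s=1.0)
        cor = pt.filling_correction(est)
        assert round(cor.R_s, 2) == 1.29
        assert cor.volume / est.gyration_volume() == pytest.approx(
            (5.0 / 3.0) ** 1.5
        )

    def test_cylinder_factors_and_volume(self):
        est = pt.ShapeEstimate(model="cylinder", r_c=1.0, h_c=1.0)
        cor = pt.filling_correction(est)
        assert cor.R_c == pytest.approx(math.sqrt(2))
        assert cor.H_c == pytest.approx(math.sqrt(3))
        assert cor.volume / est.gyration_volume() == pytest.approx(
            2.0 * math.sqrt(3)
        )

    def test_zero_radius_maps_to_zero(self):
        est = pt.ShapeEstimate(model="cylinder", r_c=0.0, h_c=1.0)
        assert pt.filling_correction(est).R_c == 0.0

    def test_idempotent(self):
        est = pt.filling_correction(pt.ShapeEstimate(model="sphere", r_s=2.0))
        again = pt.filling_correction(est)
        assert again.R_s == pytest.approx(est.R_s, rel=1e-15)
        assert again.volume == pytest.approx(est.volume, rel=1e-15)

    def test_corrected_constructor_back_fills_gyration(self):
        est = pt.ShapeEstimate(model="sphere", R_s=1.29)
        assert est.r_s == pytest.approx(1.29 / SPHERE_FILLING_FACTOR)
        cyl = pt.ShapeEstimate(model="cylinder", R_c=2.0, H_c=3.0)
        assert cyl.r_c == pytest.approx(2.0 / CYL_RADIAL_FILLING_FACTOR)
        assert cyl.h_c == pytest.approx(3.0 / CYL_LONGITUDINAL_FILLING_FACTOR)


class TestUniformCylinderRelations:
    def test_exact_arithmetic_case(self):
        r_s = pt.spherical_radius_of_uniform_cylinder(math.sqrt(2), math.sqrt(12))
        assert r_s == pytest.approx(math.sqrt(2))

    def test_disk_limit(self):
        r_s = pt.spherical_radius_of_uniform_cylinder(1.0, 1e-9)
        assert r_s == pytest.approx(1.0 / math.sqrt(2), rel=1e-9)

    def test_matches_monte_carlo_moments(self):
        R, H = 0.8, 2.5
        c = pt.uniform_shape_cloud(("cylinder", R, H), 60000, seed=8)
        assert pt.spherical_gyration_radius(c) == pytest.approx(
            pt.spherical_radius_of_uniform_cylinder(R, H), rel=0.01
        )

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(InputError):
            pt.spherical_radius_of_uniform_cylinder(0.0, 1.0)
        with pytest.raises(InputError):
            pt.sphere_cylinder_volume_ratio(1.0, -1.0)


class TestSphereCylinderVolumeRatio:
    def test_scale_invariance(self):
        a = 7.0
        assert pt.sphere_cylinder_volume_ratio(a * 1.1, a * 2.3) == (
            pytest.approx(pt.sphere_cylinder_volume_ratio(1.1, 2.3), rel=1e-12)
        )

    def test_minimum_against_dense_scan(self):
        # brute-force 1-D scan over the aspect ratio R_c/H_c
        x = np.logspace(-3, 3, 40001)
        vals = np.array([pt.sphere_cylinder_volume_ratio(xi, 1.0) for xi in x])
        k = int(np.argmin(vals))
        # analytic minimum sqrt(3) at aspect ratio 1/sqrt(3)
        assert vals[k] == pytest.approx(math.sqrt(3), rel=1e-6)
        assert x[k] == pytest.approx(1.0 / math.sqrt(3), rel=1e-3)
        assert np.all(vals >= vals[k])
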