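"""Eigenvalue machinery: prefactors, root solving, Biot relations, series."""

import math

import numpy as np
import pytest

import protherm as pt
from protherm.exceptions import DomainError, NoRootError
from protherm.hde import J0_FIRST_ZERO, GeometryModel, _biot_expr

MODELS = list(GeometryModel)


class TestPrefactor:
    @pytest.mark.parametrize(
        "model,expected",
        [
            (GeometryModel.SPHERE, 6.0 / math.pi**2),
            (GeometryModel.CYLINDER_RADIAL, 4.0 / J0_FIRST_ZERO**2),
            (GeometryModel.CYLINDER_LONGITUDINAL, 8.0 / math.pi**2),
        ],
    )
    def test_dirichlet_limit_closed_forms(self, model, expected):
        assert pt.prefactor(model, model.dirichlet_lambda) == pytest.approx(
            expected, abs=1e-10
        )
        assert model.min_prefactor == pytest.approx(expected, abs=1e-14)

    @pytest.mark.parametrize("model", MODELS)
    def test_small_lambda_limit_is_one(self, model):
        assert pt.prefactor(model, 1e-3) == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("model", MODELS)
    def test_strictly_decreasing_and_continuous(self, model):
        # A = 1 - lambda^4/c near zero, so the decrease is only resolvable
        # in float64 away from the origin; require strict monotonicity
        # there and non-increase (to roundoff) on the flat shoulder.
        lam = np.linspace(0.1, model.dirichlet_lambda, 2000)
        vals = pt.prefactor(model, lam)
        assert np.all(np.diff(vals) < 0.0)
        assert np.max(np.abs(np.diff(vals))) < 0.01  # no jumps on this grid
        shoulder = pt.prefactor(model, np.linspace(1e-4, 0.1, 200))
        assert np.all(np.diff(shoulder) <= 1e-11)
        assert np.all(shoulder <= 1.0 + 1e-12)

    @pytest.mark.parametrize("model", MODELS)
    def test_domain_errors(self, model):
        with pytest.raises(DomainError):
            pt.prefactor(model, 0.0)
        with pytest.raises(DomainError):
            pt.prefactor(model, model.dirichlet_lambda + 0.1)


class TestSolveLambda1:
    @pytest.mark.parametrize("model", MODELS)
    def test_roundtrip_100_random_prefactors(self, model, rng):
        a_min = model.min_prefactor
        As = rng.uniform(a_min + 1e-6, 1.0 - 1e-6, size=100)
        for A in As:
            lam = pt.solve_lambda1(model, A)
            assert 0.0 < lam < model.dirichlet_lambda
            assert pt.prefactor(model, lam) == pytest.approx(A, abs=1e-10)

    def test_boundary_continuity(self):
        lam = pt.solve_lambda1("sphere", 6.0 / math.pi**2 + 1e-9)
        assert lam == pytest.approx(math.pi, abs=1e-3)
        assert lam < math.pi

    @pytest.mark.parametrize(
        "model,A",
        [
            ("cylinder_longitudinal", 8.0 / math.pi**2),  # at the boundary
            ("sphere", 1.0),
            ("sphere", 1.2),
            ("sphere", 0.5),  # below the sphere Dirichlet prefactor
        ],
    )
    def test_out_of_range_prefactor_raises_with_interval(self, model, A):
        with pytest.raises(NoRootError, match="interval"):
            pt.solve_lambda1(model, A)

    def test_agrees_with_bisection_oracle(self):
        A = 0.9
        lo, hi = 1e-8, math.pi - 1e-8
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if pt.prefactor("sphere", mid) > A:
                lo = mid
            else:
                hi = mid
        assert pt.solve_lambda1("sphere", A) == pytest.approx(
            0.5 * (lo + hi), abs=1e-10
        )


class TestBiotRelation:
    def test_sphere_at_half_pi(self):
        assert pt.biot_relation("sphere", math.pi / 2) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_slab_at_quarter_pi(self):
        assert pt.biot_relation(
            "cylinder_longitudinal", math.pi / 4
        ) == pytest.approx(math.pi / 4, abs=1e-12)

    @pytest.mark.parametrize("model", MODELS)
    def test_vanishes_as_lambda_to_zero(self, model):
        assert pt.biot_relation(model, 1e-3) < 1e-5

    @pytest.mark.parametrize("model", MODELS)
    def test_strictly_increasing_on_principal_branch(self, model):
        lam = np.linspace(1e-3, model.dirichlet_lambda - 1e-6, 5000)
        vals = pt.biot_relation(model, lam)
        assert np.all(np.diff(vals) > 0.0)
        assert vals[-1] > 1e4  # diverges at the Dirichlet limit

    @pytest.mark.parametrize("model", MODELS)
    def test_domain_error_at_limit(self, model):
        with pytest.raises(DomainError):
            pt.biot_relation(model, model.dirichlet_lambda)
        with pytest.raises(DomainError):
            pt.biot_relation(model, -0.1)


class TestEigenSpectrum:
    @pytest.mark.parametrize(
        "model,limit_fn",
        [
            (GeometryModel.SPHERE, lambda n: n * math.pi),
            (
                GeometryModel.CYLINDER_LONGITUDINAL,
                lambda n: (2 * n - 1) * math.pi / 2,
            ),
        ],
    )
    def test_large_biot_approaches_dirichlet_eigenvalues(self, model, limit_fn):
        lams = pt.eigen_spectrum(model, 1e6, 4)
        for n, lam in enumerate(lams, start=1):
            assert lam == pytest.approx(limit_fn(n), abs=1e-4)

    def test_large_biot_radial_approaches_bessel_zeros(self):
        from scipy.special import jn_zeros

        lams = pt.eigen_spectrum("cylinder_radial", 1e6, 4)
        assert lams == pytest.approx(jn_zeros(0, 4), abs=1e-4)

    def test_sphere_roots_match_sign_change_scan(self):
        biot = 4.0
        grid = np.arange(1e-4, 5 * math.pi, 1e-4)
        f = _biot_expr(GeometryModel.SPHERE, grid) - biot
        crossings = []
        for i in np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]:
            lo, hi = grid[i], grid[i + 1]
            flo = _biot_expr(GeometryModel.SPHERE, lo) - biot
            if not (np.isfinite(flo) and np.isfinite(f[i + 1])):
                continue
            if flo > 0:  # pole crossing, not a root
                continue
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if _biot_expr(GeometryModel.SPHERE, mid) - biot < 0:
                    lo = mid
                else:
                    hi = mid
            crossings.append(0.5 * (lo + hi))
        lams = pt.eigen_spectrum("sphere", biot, len(crossings))
        assert lams == pytest.approx(np.asarray(crossings), abs=1e-8)

    @pytest.mark.parametrize("model", MODELS)
    @pytest.mark.parametrize("biot", [0.5, 4.0, 20.0])
    def test_mutually_consistent_with_biot_relation(self, model, biot):
        lams = pt.eigen_spectrum(model, biot, 8)
        assert np.all(np.diff(lams) > 0.0)
        for lam in lams:
            assert pt.biot_relation(
                model, lam, principal_branch=False
            ) == pytest.approx(biot, abs=1e-9)


class TestSeriesTemperature:
    @pytest.mark.parametrize("model", MODELS)
    def test_single_term_initial_value_below_one(self, model):
        assert pt.series_temperature(model, 4.0, 0.0, n_terms=1) < 1.0

    @pytest.mark.parametrize("model", MODELS)
    def test_many_term_initial_value_is_one(self, model):
        assert pt.series_temperature(model, 4.0, 0.0, n_terms=200) == (
            pytest.approx(1.0, abs=1e-3)
        )

    def test_monotone_nonincreasing_in_time(self):
        fo = np.linspace(0.0, 2.0, 200)
        vals = pt.series_temperature("sphere", 4.0, fo, n_terms=50)
        assert np.all(np.diff(vals) <= 0.0)
        assert np.all(vals > 0.0) and vals[0] <= 1.0 + 1e-9
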