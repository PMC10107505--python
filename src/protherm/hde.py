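"""Analytic solutions of the heat diffusion equation for simple geometries.

A homogeneous body initially at a uniform temperature relaxes toward a bath
held at a fixed temperature, with a Robin (third-kind) boundary condition
``-kappa dT/dn = G (T_surface - T_bath)`` encoding the interfacial thermal
conductance ``G``.  Separation of variables gives the volume-averaged,
normalized temperature as a series

    theta(t) = sum_n A_n exp(-lambda_n^2 * Fo),    Fo = D t / l^2,

where the eigenvalues ``lambda_n`` solve a geometry-specific transcendental
relation parameterized by the Biot number ``Bi = G l / kappa``, and the
coefficients ``A_n`` are the volume-average projections of the eigenmodes.
Three one-dimensional geometries are supported:

==========================  ===========================  =================
kind                        eigenvalue relation          Dirichlet limit
==========================  ===========================  =================
sphere                      1 - lam*cot(lam) = Bi        pi
cylinder_radial             lam*J1(lam)/J0(lam) = Bi     j_{0,1} ~ 2.40483
cylinder_longitudinal       lam*tan(lam) = Bi            pi/2
==========================  ===========================  =================

The single-term coefficient ``A_1`` is what an exponential fit of a
relaxation trace estimates; inverting it for ``lambda_1`` and combining with
the fitted rate yields the thermal conductivity and conductance (see
:mod:`protherm.transport`).
"""

from __future__ import annotations

import enum
import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1, jn_zeros

from .exceptions import DomainError, NoRootError

__all__ = [
    "GeometryModel",
    "prefactor",
    "solve_lambda1",
    "biot_relation",
    "eigen_spectrum",
    "series_temperature",
]

#: First zero of the 0th-order Bessel function of the first kind.
J0_FIRST_ZERO: float = float(jn_zeros(0, 1)[0])

#: Margin kept around poles / interval endpoints when bracketing roots.
_POLE_MARGIN = 1e-8


class GeometryModel(enum.Enum):
    """One-dimensional heat-conduction geometry.

    ``sphere`` resolves the radial direction of a ball, ``cylinder_radial``
    the radial direction of an infinite circular cylinder, and
    ``cylinder_longitudinal`` the axial direction of a finite cylinder
    (mathematically a slab of thickness H with symmetric cooling, so the
    characteristic length is the half-height H/2).
    """

    SPHERE = "sphere"
    CYLINDER_RADIAL = "cylinder_radial"
    CYLINDER_LONGITUDINAL = "cylinder_longitudinal"

    @property
    def dirichlet_lambda(self) -> float:
        """First eigenvalue in the infinite-conductance (Dirichlet) limit."""
        return {
            GeometryModel.SPHERE: math.pi,
            GeometryModel.CYLINDER_RADIAL: J0_FIRST_ZERO,
            GeometryModel.CYLINDER_LONGITUDINAL: math.pi / 2.0,
        }[self]

    @property
    def min_prefactor(self) -> float:
        """Smallest attainable single-term coefficient (Dirichlet limit)."""
        return {
            GeometryModel.SPHERE: 6.0 / math.pi**2,
            GeometryModel.CYLINDER_RADIAL: 4.0 / J0_FIRST_ZERO**2,
            GeometryModel.CYLINDER_LONGITUDINAL: 8.0 / math.pi**2,
        }[self]


def _coerce_model(model: "GeometryModel | str") -> GeometryModel:
    if isinstance(model, GeometryModel):
        return model
    return GeometryModel(model)


def _prefactor_expr(model: GeometryModel, lam):
    """Single-mode volume-average coefficient, no domain restriction.

    Valid at every eigenvalue branch; the public :func:`prefactor` restricts
    to the principal branch where the expression is monotone.  All three
    coefficients behave as A = 1 - lambda^4/c near zero (c = 525, 192, 45),
    where the closed forms lose ~8 digits to cancellation, so small
    eigenvalues are evaluated by that series instead.
    """
    lam = np.asarray(lam, dtype=float)
    small = lam < 0.01
    safe = np.where(small, 1.0, lam)
    if model is GeometryModel.SPHERE:
        s, c = np.sin(safe), np.cos(safe)
        out = 6.0 * (s - safe * c) ** 2 / (safe**3 * (safe - s * c))
        series_c = 525.0
    elif model is GeometryModel.CYLINDER_RADIAL:
        b0, b1 = j0(safe), j1(safe)
        out = 4.0 * b1**2 / (safe**2 * (b0**2 + b1**2))
        series_c = 192.0
    else:
        s = np.sin(safe)
        out = 4.0 * s**2 / (safe * (2.0 * safe + np.sin(2.0 * safe)))
        series_c = 45.0
    return np.where(small, 1.0 - lam**4 / series_c, out)


def prefactor(model: "GeometryModel | str", lam):
    """Single-term series coefficient A(lambda) on the principal branch.

    Parameters
    ----------
    model : GeometryModel or str
    lam : float or array_like
        Eigenvalue, ``0 < lam <= model.dirichlet_lambda``.

    Returns
    -------
    float or ndarray
        A(lam); continuous, strictly decreasing, with A -> 1 as lam -> 0+
        and A = ``model.min_prefactor`` at the Dirichlet limit.
    """
    model = _coerce_model(model)
    arr = np.asarray(lam, dtype=float)
    limit = model.dirichlet_lambda
    if np.any(arr <= 0.0) or np.any(arr > limit * (1.0 + 1e-12)):
        raise DomainError(
            f"prefactor({model.value}): lambda must lie in (0, {limit:.9g}]"
        )
    out = _prefactor_expr(model, np.minimum(arr, limit))
    return float(out) if np.isscalar(lam) else out


def solve_lambda1(model: "GeometryModel | str", A: float) -> float:
    """Invert the single-term coefficient for the first eigenvalue.

    Returns the unique ``lambda_1`` in ``(0, dirichlet_lambda)`` with
    ``prefactor(model, lambda_1) == A``, found by bracketed Brent iteration
    (the relation is strictly monotone on this interval, so bisection-style
    bracketing is safe where Newton steps would not be).

    Raises
    ------
    NoRootError
        If ``A`` is outside the open interval ``(min_prefactor, 1)`` — e.g.
        a fitted prefactor >= 1, which the truncated series cannot produce.
    """
    model = _coerce_model(model)
    a_min = model.min_prefactor
    if not (a_min < A < 1.0):
        raise NoRootError(
            f"no root: prefactor A={A:.6g} must lie in the open interval "
            f"({a_min:.6g}, 1) for model '{model.value}'"
        )
    limit = model.dirichlet_lambda
    # the prefactor expressions are regular at the Dirichlet endpoint, so
    # only a token margin is needed there (resolves A within ~1e-12 of A_min)
    lo, hi = _POLE_MARGIN, limit - 1e-13
    return float(
        brentq(
            lambda x: _prefactor_expr(model, x) - A,
            lo,
            hi,
            xtol=1e-14,
            rtol=8.9e-16,
            maxiter=200,
        )
    )


def _biot_expr(model: GeometryModel, lam):
    lam = np.asarray(lam, dtype=float)
    if model is GeometryModel.SPHERE:
        return 1.0 - lam / np.tan(lam)
    if model is GeometryModel.CYLINDER_RADIAL:
        return lam * j1(lam) / j0(lam)
    return lam * np.tan(lam)


def biot_relation(
    model: "GeometryModel | str", lam, principal_branch: bool = True
):
    """Biot number implied by an eigenvalue.

    ``Bi = 1 - lam*cot(lam)`` (sphere), ``lam*J1(lam)/J0(lam)`` (cylinder,
    radial) or ``lam*tan(lam)`` (cylinder, longitudinal).  On the principal
    branch the relation is strictly increasing from 0 (lam -> 0) to
    infinity (Dirichlet limit).

    With ``principal_branch=False`` the raw expression is evaluated on any
    branch (used to check higher eigenvalues for consistency); poles are
    still rejected.
    """
    model = _coerce_model(model)
    arr = np.asarray(lam, dtype=float)
    if np.any(arr <= 0.0):
        raise DomainError(f"biot_relation({model.value}): lambda must be > 0")
    if principal_branch and np.any(arr >= model.dirichlet_lambda - 1e-15):
        raise DomainError(
            f"biot_relation({model.value}): lambda must be below the "
            f"Dirichlet limit {model.dirichlet_lambda:.9g}"
        )
    out = _biot_expr(model, arr)
    if not np.all(np.isfinite(out)):
        raise DomainError(
            f"biot_relation({model.value}): evaluation at a pole"
        )
    return float(out) if np.isscalar(lam) else out


def _branch_interval(model: GeometryModel, n: int) -> tuple[float, float]:
    """Open interval containing the n-th root of the Biot relation (n >= 1)."""
    if model is GeometryModel.SPHERE:
        return ((n - 1) * math.pi, n * math.pi)
    if model is GeometryModel.CYLINDER_LONGITUDINAL:
        return ((n - 1) * math.pi, (n - 1) * math.pi + math.pi / 2.0)
    zeros = jn_zeros(0, n)
    lo = 0.0 if n == 1 else float(zeros[n - 2])
    return (lo, float(zeros[n - 1]))


def eigen_spectrum(
    model: "GeometryModel | str", biot: float, n_terms: int
) -> np.ndarray:
    """First ``n_terms`` eigenvalues for a given Biot number.

    Each branch of the transcendental relation contains exactly one root;
    roots are bracketed analytically (between consecutive poles) and refined
    by Brent's method to ~1e-12, never by unguarded Newton steps.
    """
    model = _coerce_model(model)
    if biot <= 0.0:
        raise DomainError("eigen_spectrum: Biot number must be > 0")
    if n_terms < 1:
        raise DomainError("eigen_spectrum: n_terms must be >= 1")
    roots = np.empty(n_terms)
    for i in range(n_terms):
        lo, hi = _branch_interval(model, i + 1)
        a = lo + _POLE_MARGIN * max(1.0, hi)
        b = hi - _POLE_MARGIN * max(1.0, hi)
        f = lambda x: _biot_expr(model, x) - biot  # noqa: E731
        roots[i] = brentq(f, a, b, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return roots


def series_temperature(
    model: "GeometryModel | str",
    biot: float,
    fourier,
    n_terms: int = 200,
):
    """Volume-averaged normalized temperature of the eigenfunction series.

    Parameters
    ----------
    model : GeometryModel or str
    biot : float
        Biot number ``G l / kappa`` (> 0).
    fourier : float or array_like
        Dimensionless time ``Fo = D t / l^2`` (>= 0).
    n_terms : int
        Number of series terms; the coefficients sum to 1, so theta(0) -> 1
        as ``n_terms`` grows while a single term gives theta(0) = A_1 < 1.

    Returns
    -------
    float or ndarray
        ``sum_n A_n exp(-lambda_n^2 Fo)``, in (0, 1], non-increasing in Fo.
    """
    model = _coerce_model(model)
    fo = np.asarray(fourier, dtype=float)
    if np.any(fo < 0.0):
        raise DomainError("series_temperature: Fourier number must be >= 0")
    lams = eigen_spectrum(model, biot, n_terms)
    coeffs = _prefactor_expr(model, lams)
    vals = np.exp(-np.outer(fo.ravel(), lams**2)) @ coeffs
    if fo.ndim == 0:
        return float(vals[0])
    return vals.reshape(fo.shape)
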