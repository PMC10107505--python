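"""Protein size estimation from atomic coordinates.

A protein is approximated as a homogeneous sphere or a homogeneous circular
cylinder.  The baseline size measures are gyration quantities — second
moments of the (mass-weighted) atomic positions about the center of mass:

* sphere: the ordinary radius of gyration ``r_s``;
* cylinder: ``r_c = sqrt(<u^2> + <v^2>)`` over the two transverse principal
  directions and ``h_c = 2*sqrt(<w^2>)`` along the symmetry axis, chosen so
  that a uniform solid cylinder of radius R and height H has exactly
  ``r_c = R/sqrt(2)`` and ``h_c = H/sqrt(3)``.

Because a uniform solid of the *actual* dimensions has larger extent than
its gyration moments suggest, "filling-corrected" dimensions rescale the
gyration sizes to the matching uniform solid:

    R_s = sqrt(5/3) * r_s,    R_c = sqrt(2) * r_c,    H_c = sqrt(3) * h_c.

These corrected dimensions are the physically meaningful surface radius /
height to use when interpreting interfacial conductance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import GeometryError, InputError

__all__ = [
    "PointCloud",
    "ShapeEstimate",
    "spherical_gyration_radius",
    "cylindrical_gyration_sizes",
    "filling_correction",
    "spherical_radius_of_uniform_cylinder",
    "sphere_cylinder_volume_ratio",
]

SPHERE_FILLING_FACTOR = math.sqrt(5.0 / 3.0)
CYL_RADIAL_FILLING_FACTOR = math.sqrt(2.0)
CYL_LONGITUDINAL_FILLING_FACTOR = math.sqrt(3.0)


@dataclass(frozen=True)
class PointCloud:
    """Atomic positions (nm) with per-atom masses (amu)."""

    positions: np.ndarray
    masses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        m = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise InputError("PointCloud: positions must be an (n, 3) array")
        if pos.shape[0] == 0:
            raise InputError("PointCloud: at least one atom required")
        if m.shape != (pos.shape[0],):
            raise InputError("PointCloud: need one mass per position")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(m)):
            raise InputError("PointCloud: non-finite coordinates or masses")
        if np.any(m <= 0.0):
            raise InputError("PointCloud: all masses must be > 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "masses", m)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def weights(self, mass_weighted: bool = True) -> np.ndarray:
        if mass_weighted:
            return self.masses / self.masses.sum()
        return np.full(len(self), 1.0 / len(self))

    def center_of_mass(self, mass_weighted: bool = True) -> np.ndarray:
        return self.weights(mass_weighted) @ self.positions


@dataclass(frozen=True)
class ShapeEstimate:
    """Sphere or cylinder dimensions for a protein, in nm.

    Gyration-based fields (``r_s`` or ``r_c``, ``h_c``) are always set for
    the chosen model; the filling-corrected fields (``R_s`` or ``R_c``,
    ``H_c``) are populated by :func:`filling_correction`.  ``volume`` is the
    model volume of the *corrected* solid when corrected fields are present,
    otherwise of the gyration-sized solid.
    """

    model: str  # "sphere" | "cylinder"
    r_s: float | None = None
    r_c: float | None = None
    h_c: float | None = None
    R_s: float | None = None
    R_c: float | None = None
    H_c: float | None = None
    axis: np.ndarray | None = None
    volume: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.model not in ("sphere", "cylinder"):
            raise InputError(f"unknown shape model '{self.model}'")
        for name in ("r_s", "r_c", "h_c", "R_s", "R_c", "H_c"):
            v = getattr(self, name)
            if v is not None and v < 0.0:
                raise InputError(f"ShapeEstimate: {name} must be >= 0")
        if self.model == "sphere" and self.r_s is None and self.R_s is None:
            raise InputError("sphere estimate needs r_s or R_s")
        if self.model == "cylinder" and (
            (self.r_c is None and self.R_c is None)
            or (self.h_c is None and self.H_c is None)
        ):
            raise InputError("cylinder estimate needs (r_c, h_c) or (R_c, H_c)")
        # Back-fill gyration sizes from corrected ones (exact inverses).
        if self.R_s is not None and self.r_s is None:
            object.__setattr__(self, "r_s", self.R_s / SPHERE_FILLING_FACTOR)
        if self.R_c is not None and self.r_c is None:
            object.__setattr__(self, "r_c", self.R_c / CYL_RADIAL_FILLING_FACTOR)
        if self.H_c is not None and self.h_c is None:
            object.__setattr__(
                self, "h_c", self.H_c / CYL_LONGITUDINAL_FILLING_FACTOR
            )
        if not self.volume:
            object.__setattr__(self, "volume", self._model_volume())

    def _model_volume(self) -> float:
        if self.model == "sphere":
            r = self.R_s if self.R_s is not None else self.r_s
            return 4.0 / 3.0 * math.pi * r**3
        r = self.R_c if self.R_c is not None else self.r_c
        h = self.H_c if self.H_c is not None else self.h_c
        return math.pi * r**2 * h

    @property
    def is_corrected(self) -> bool:
        if self.model == "sphere":
            return self.R_s is not None
        return self.R_c is not None and self.H_c is not None

    def gyration_volume(self) -> float:
        """Volume of the solid built from the gyration-based sizes."""
        if self.model == "sphere":
            return 4.0 / 3.0 * math.pi * self.r_s**3
        return math.pi * self.r_c**2 * self.h_c

    @classmethod
    def from_cloud(
        cls, cloud: PointCloud, model: str, mass_weighted: bool = True
    ) -> "ShapeEstimate":
        """Gyration-based estimate (no filling correction) from coordinates."""
        if model == "sphere":
            return cls(
                model="sphere",
                r_s=spherical_gyration_radius(cloud, mass_weighted),
            )
        r_c, h_c, axis = cylindrical_gyration_sizes(cloud, mass_weighted)
        return cls(model="cylinder", r_c=r_c, h_c=h_c, axis=axis)


def spherical_gyration_radius(
    cloud: PointCloud, mass_weighted: bool = True
) -> float:
    """Radius of gyration about the center of mass, in nm.

    ``sqrt(sum_i m_i |x_i - xbar|^2 / sum_i m_i)``; with
    ``mass_weighted=False`` all atoms count equally.
    """
    w = cloud.weights(mass_weighted)
    d = cloud.positions - cloud.center_of_mass(mass_weighted)
    return float(np.sqrt(w @ np.sum(d * d, axis=1)))


def _principal_moments(
    cloud: PointCloud, mass_weighted: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors of the position covariance."""
    w = cloud.weights(mass_weighted)
    d = cloud.positions - cloud.center_of_mass(mass_weighted)
    cov = (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)
    return np.maximum(evals, 0.0), evecs


def cylindrical_gyration_sizes(
    cloud: PointCloud, mass_weighted: bool = True
) -> tuple[float, float, np.ndarray]:
    """Gyration-like cylinder sizes ``(r_c, h_c, axis)`` in nm.

    The symmetry axis is the mass-weighted principal axis with the largest
    positional variance (sign fixed so its first nonzero component is
    positive); ``r_c`` collects the two transverse variances and
    ``h_c = 2*sqrt(<w^2>)`` the axial one, so a uniform solid cylinder
    (R, H) gives ``r_c = R/sqrt(2)``, ``h_c = H/sqrt(3)``.

    Clouds with zero total extent (all atoms coincident) are rejected;
    collinear clouds are allowed and return ``r_c = 0`` with the axis along
    the line.
    """
    if len(cloud) < 3:
        raise GeometryError(
            "cylindrical_gyration_sizes: need at least 3 atoms"
        )
    evals, evecs = _principal_moments(cloud, mass_weighted)
    if evals[2] <= 0.0:
        raise GeometryError(
            "cylindrical_gyration_sizes: degenerate cloud (zero extent)"
        )
    axis = evecs[:, 2].copy()
    nz = np.nonzero(np.abs(axis) > 1e-12)[0]
    if nz.size and axis[nz[0]] < 0.0:
        axis = -axis
    r_c = float(np.sqrt(evals[0] + evals[1]))
    h_c = float(2.0 * np.sqrt(evals[2]))
    return r_c, h_c, axis


def filling_correction(estimate: ShapeEstimate) -> ShapeEstimate:
    """Populate the filling-corrected dimensions of a shape estimate.

    ``R_s = sqrt(5/3) r_s`` (the homogeneous-sphere radius whose gyration
    radius is ``r_s``), ``R_c = sqrt(2) r_c``, ``H_c = sqrt(3) h_c``; the
    volume is recomputed from the corrected solid.  Idempotent: corrected
    fields are always recomputed from the gyration fields.
    """
    if estimate.model == "sphere":
        R_s = SPHERE_FILLING_FACTOR * estimate.r_s
        return replace(
            estimate,
            R_s=R_s,
            volume=4.0 / 3.0 * math.pi * R_s**3,
        )
    R_c = CYL_RADIAL_FILLING_FACTOR * estimate.r_c
    H_c = CYL_LONGITUDINAL_FILLING_FACTOR * estimate.h_c
    return replace(
        estimate, R_c=R_c, H_c=H_c, volume=math.pi * R_c**2 * H_c
    )


def spherical_radius_of_uniform_cylinder(R_c: float, H_c: float) -> float:
    """Gyration radius of a uniform solid cylinder (R_c, H_c).

    ``r_s^2 = R_c^2/2 + H_c^2/12`` from the second moments of a uniform
    cylinder about its center.
    """
    if R_c <= 0.0 or H_c <= 0.0:
        raise InputError(
            "spherical_radius_of_uniform_cylinder: dimensions must be > 0"
        )
    return math.sqrt(R_c**2 / 2.0 + H_c**2 / 12.0)


def sphere_cylinder_volume_ratio(R_c: float, H_c: float) -> float:
    """Volume of the gyration-matched sphere over the gyration-sized cylinder.

    For a uniform cylinder (R_c, H_c) the spherical gyration radius is
    ``r_s = sqrt(R_c^2/2 + H_c^2/12)`` while the cylindrical gyration sizes
    are ``r_c = R_c/sqrt(2)``, ``h_c = H_c/sqrt(3)``.  The ratio
    ``(4/3) pi r_s^3 / (pi r_c^2 h_c)`` depends only on ``R_c/H_c`` and
    measures how much a spherical model overestimates the volume of an
    elongated or flattened body.
    """
    if R_c <= 0.0 or H_c <= 0.0:
        raise InputError("sphere_cylinder_volume_ratio: dimensions must be > 0")
    r_s = spherical_radius_of_uniform_cylinder(R_c, H_c)
    v_sphere = 4.0 / 3.0 * math.pi * r_s**3
    v_cyl = math.pi * (R_c / CYL_RADIAL_FILLING_FACTOR) ** 2 * (
        H_c / CYL_LONGITUDINAL_FILLING_FACTOR
    )
    return v_sphere / v_cyl
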