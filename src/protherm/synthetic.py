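"""Synthetic relaxation traces and an independent finite-difference oracle.

The generator emulates the non-equilibrium relaxation protocol the analysis
pipeline is built for: a protein pre-heated to ~400 K is released into a
300 K bath and its volume-averaged temperature is recorded every picosecond
for ~100 ps, with the experiment repeated over independent replicates.
Ground-truth kappa and G are prescribed, so the full inverse pipeline can
be validated end to end.

Two forward models are provided:

* the analytic eigenfunction series (:func:`protherm.hde.series_temperature`);
* an explicit finite-difference solution of the one-dimensional heat
  diffusion equation with the Robin interface condition
  ``-kappa dT/dn = G (T_s - T_f)``, written independently of the series
  machinery so the two can check each other.

The bath is an infinite reservoir pinned at T_f — exactly the assumption
under which the inversion formulas hold, so recovery tests are well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InputError, SolverError
from .fitting import TemperatureTrace
from .geometry import PointCloud
from .hde import GeometryModel, series_temperature
from .transport import NM, PS, cp_per_molecule

__all__ = [
    "SyntheticSpec",
    "fd_theta_bar",
    "fd_relaxation",
    "generate_traces",
    "uniform_shape_cloud",
]

#: radial weight exponent of the 1-D Laplacian: r^p d/dr(r^p ...) ... p = 2, 1, 0
_WEIGHT_EXPONENT = {
    GeometryModel.SPHERE: 2,
    GeometryModel.CYLINDER_RADIAL: 1,
    GeometryModel.CYLINDER_LONGITUDINAL: 0,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth definition of a synthetic relaxation experiment.

    Lengths in nm, kappa in W/K/m, G in MW/K/m^2, Cp in kJ/mol/K (per mole
    of protein molecules), temperatures in K, times in ps.  ``height_nm``
    is required for the cylinder models.  ``radius_nm``/``height_nm`` are
    the dimensions of the homogeneous body itself (i.e. filling-basis).
    """

    model: GeometryModel
    kappa_true: float
    g_true: float
    radius_nm: float
    cp_kj_mol_k: float
    height_nm: float | None = None
    T_i: float = 400.0
    T_f: float = 300.0
    duration_ps: float = 100.0
    dt_ps: float = 1.0
    noise_sd_K: float = 2.0
    seed: int = 0
    n_replicates: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "model",
            self.model
            if isinstance(self.model, GeometryModel)
            else GeometryModel(self.model),
        )
        for name in ("kappa_true", "g_true", "radius_nm", "cp_kj_mol_k",
                     "duration_ps", "dt_ps"):
            if getattr(self, name) <= 0.0:
                raise InputError(f"SyntheticSpec: {name} must be > 0")
        if self.model is not GeometryModel.SPHERE and (
            self.height_nm is None or self.height_nm <= 0.0
        ):
            raise InputError("SyntheticSpec: cylinder models need height_nm > 0")
        if self.noise_sd_K < 0.0 or self.n_replicates < 1:
            raise InputError("SyntheticSpec: bad noise/replicate settings")
        if self.T_i == self.T_f:
            raise InputError("SyntheticSpec: T_i must differ from T_f")

    # -- derived physical quantities -----------------------------------

    @property
    def l_m(self) -> float:
        """Characteristic length: R (sphere, radial) or H/2 (longitudinal)."""
        if self.model is GeometryModel.CYLINDER_LONGITUDINAL:
            return self.height_nm / 2.0 * NM
        return self.radius_nm * NM

    @property
    def volume_m3(self) -> float:
        if self.model is GeometryModel.SPHERE:
            return 4.0 / 3.0 * math.pi * (self.radius_nm * NM) ** 3
        return math.pi * (self.radius_nm * NM) ** 2 * self.height_nm * NM

    @property
    def biot(self) -> float:
        return self.g_true * 1e6 * self.l_m / self.kappa_true

    @property
    def diffusivity_m2_s(self) -> float:
        """D = kappa / (Cp/V): volumetric heat capacity from Cp per molecule."""
        return self.kappa_true * self.volume_m3 / cp_per_molecule(
            self.cp_kj_mol_k
        )

    @property
    def tau1_ps(self) -> float:
        """First-mode decay time lambda_1^2 tau ... l^2/(D lambda_1^2), in ps."""
        from .hde import eigen_spectrum

        lam1 = eigen_spectrum(self.model, self.biot, 1)[0]
        return self.l_m**2 / (self.diffusivity_m2_s * lam1**2) / PS

    def times_ps(self) -> np.ndarray:
        return np.arange(0.0, self.duration_ps + 0.5 * self.dt_ps, self.dt_ps)

    def fourier(self, times_ps: np.ndarray) -> np.ndarray:
        return times_ps * PS * self.diffusivity_m2_s / self.l_m**2


def fd_theta_bar(
    model: GeometryModel | str,
    biot: float,
    fourier_out: np.ndarray,
    grid_n: int = 200,
    safety: float = 0.8,
    dt_max: float | None = None,
) -> np.ndarray:
    """Finite-difference volume-averaged normalized temperature.

    Solves ``d theta/d Fo = (1/r^p) d/dr (r^p d theta/dr)`` on r in [0, 1]
    (p = 2 sphere, 1 cylinder radial, 0 slab) with theta(r, 0) = 1, a
    symmetry condition at r = 0 and the Robin condition
    ``d theta/dr = -Bi * theta`` at r = 1 (ghost-node, second-order central
    differences), advanced by explicit Euler with a stability-bounded step.
    Returns the r^p-weighted average of theta at the requested Fourier
    numbers.  Deliberately independent of the eigenfunction series code.
    """
    model = GeometryModel(model) if not isinstance(model, GeometryModel) else model
    if grid_n < 100:
        raise InputError("fd_theta_bar: grid_n must be >= 100")
    if biot <= 0.0:
        raise DomainError("fd_theta_bar: Biot number must be > 0")
    fo_out = np.asarray(fourier_out, dtype=float)
    if np.any(fo_out < 0.0) or np.any(np.diff(fo_out) < 0.0):
        raise InputError("fd_theta_bar: Fourier samples must be sorted, >= 0")

    p = _WEIGHT_EXPONENT[model]
    h = 1.0 / grid_n
    r = np.arange(grid_n + 1) * h
    faces = (r[:-1] + 0.5 * h) ** p  # r^p at i+1/2, i = 0..N-1
    face_out = (1.0 + 0.5 * h) ** p  # ghost face beyond r = 1
    rw = r**p
    rw[0] = 1.0  # unused at the center (handled by the symmetry stencil)

    # Explicit-Euler stability: the operator's spectrum lies in
    # [-2*max|diag|, 0] (Gershgorin), so dt <= 1/max|diag|; the center
    # stencil has diagonal 2(p+1)/h^2 and the Robin node
    # ~ (2 + 2 h Bi face_out)/h^2.
    diag_max = max(2.0 * (p + 1), 2.0 + 2.0 * h * biot * face_out) / h**2
    dt = safety / diag_max
    if dt_max is not None:
        dt = min(dt, dt_max)  # optional cap below the stability bound

    theta = np.ones(grid_n + 1)
    dtheta = np.empty_like(theta)
    weights = rw.copy()
    weights[0] = 0.0 if p > 0 else 1.0
    norm = np.trapezoid(weights, dx=h)

    out = np.empty(fo_out.size)
    fo = 0.0
    j = 0
    # emit any samples at Fo = 0 before stepping
    while j < fo_out.size and fo_out[j] <= 0.0:
        out[j] = np.trapezoid(weights * theta, dx=h) / norm
        j += 1
    steps_done = 0
    # overflow during a blow-up is detected and reported explicitly below
    with np.errstate(over="ignore", invalid="ignore"):
        while j < fo_out.size:
            target = fo_out[j]
            n_steps = max(1, int(math.ceil((target - fo) / dt - 1e-12)))
            step = (target - fo) / n_steps
            for _ in range(n_steps):
                dtheta[1:-1] = (
                    faces[1:] * (theta[2:] - theta[1:-1])
                    - faces[:-1] * (theta[1:-1] - theta[:-2])
                ) / (h**2 * rw[1:-1])
                dtheta[0] = 2.0 * (p + 1) * (theta[1] - theta[0]) / h**2
                ghost = theta[-2] - 2.0 * h * biot * theta[-1]
                dtheta[-1] = (
                    face_out * (ghost - theta[-1])
                    - faces[-1] * (theta[-1] - theta[-2])
                ) / (h**2 * rw[-1])
                theta += step * dtheta
                steps_done += 1
                if steps_done % 5000 == 0 and not np.all(np.isfinite(theta)):
                    raise SolverError("fd_theta_bar: solution blew up")
            fo = target
            if not np.all(np.isfinite(theta)):
                raise SolverError("fd_theta_bar: solution blew up")
            out[j] = np.trapezoid(weights * theta, dx=h) / norm
            j += 1
    return out


def fd_relaxation(
    spec: SyntheticSpec, grid_n: int = 200, dt_solver: float | None = None
) -> TemperatureTrace:
    """Noise-free relaxation trace from the finite-difference solver.

    ``dt_solver`` (dimensionless Fourier step) may cap the internal step
    below the stability bound; the bound itself is always enforced.
    """
    times = spec.times_ps()
    fo = spec.fourier(times)
    theta = fd_theta_bar(
        spec.model, spec.biot, fo, grid_n=grid_n, dt_max=dt_solver
    )
    T = spec.T_f + (spec.T_i - spec.T_f) * theta
    return TemperatureTrace(times=times, temperatures=T, role="protein")


def generate_traces(
    spec: SyntheticSpec,
    method: str = "series",
    n_terms: int = 200,
    grid_n: int = 200,
) -> list[TemperatureTrace]:
    """Replicate traces: forward model + i.i.d. Gaussian temperature noise.

    All randomness flows from ``spec.seed`` through one generator, so a
    fixed spec reproduces byte-identical traces; ``noise_sd_K = 0`` makes
    every replicate identical.
    """
    times = spec.times_ps()
    fo = spec.fourier(times)
    if method == "series":
        theta = series_temperature(spec.model, spec.biot, fo, n_terms=n_terms)
    elif method == "fd":
        theta = fd_theta_bar(spec.model, spec.biot, fo, grid_n=grid_n)
    else:
        raise InputError(f"generate_traces: unknown method '{method}'")
    clean = spec.T_f + (spec.T_i - spec.T_f) * theta
    rng = np.random.default_rng(spec.seed)
    traces = []
    for k in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd_K, size=clean.size) \
            if spec.noise_sd_K > 0 else 0.0
        traces.append(
            TemperatureTrace(
                times=times,
                temperatures=clean + noise,
                role="protein",
                replicate_id=k,
            )
        )
    return traces


def uniform_shape_cloud(
    shape: tuple, n_points: int, seed: int = 0
) -> PointCloud:
    """Uniform-density point sample of a solid sphere or cylinder.

    ``shape`` is ``("sphere", R)`` or ``("cylinder", R, H)`` in nm.  Unit
    masses; deterministic given the seed.  Used as a fixture generator for
    the gyration estimators (a uniform sphere of radius R has gyration
    radius R*sqrt(3/5); a uniform cylinder gives r_c = R/sqrt(2),
    h_c = H/sqrt(3)).
    """
    if n_points < 10:
        raise InputError("uniform_shape_cloud: n_points must be >= 10")
    rng = np.random.default_rng(seed)
    kind = shape[0]
    if kind == "sphere":
        (_, R) = shape
        u = rng.random(n_points)
        radii = R * u ** (1.0 / 3.0)
        vec = rng.normal(size=(n_points, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        pos = vec * radii[:, None]
    elif kind == "cylinder":
        (_, R, H) = shape
        rad = R * np.sqrt(rng.random(n_points))
        phi = rng.random(n_points) * 2.0 * math.pi
        z = (rng.random(n_points) - 0.5) * H
        pos = np.column_stack([rad * np.cos(phi), rad * np.sin(phi), z])
    else:
        raise InputError(f"uniform_shape_cloud: unknown shape '{kind}'")
    return PointCloud(
        positions=pos, masses=np.ones(n_points), label=f"uniform-{kind}"
    )
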