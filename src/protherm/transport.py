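"""Thermal conductivity and interfacial conductance from fitted relaxation.

Given the exponential-fit parameters (A, B) of a normalized relaxation
trace and a size model for the protein, the chain is

    A  --(invert single-term coefficient)-->  lambda_1
    tau = lambda_1^2 / B
    kappa = (l^2 / tau) * (Cp / V)                  [W/K/m]
    G     = Bi(lambda_1) * kappa / l                [reported in MW/K/m^2]

with l the characteristic length (sphere radius, cylinder radius, or
cylinder half-height), V the model volume and Cp the per-molecule heat
capacity.  Heat capacities are supplied per mole of protein molecules
(kJ/mol/K) and divided by Avogadro's number internally.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from dataclasses import dataclass

from scipy.constants import N_A

from . import hde
from .exceptions import InputError, ProthermError
from .fitting import FitResult, TemperatureTrace, fit_trace
from .geometry import ShapeEstimate, filling_correction
from .hde import GeometryModel

__all__ = [
    "MaterialParams",
    "TransportResult",
    "cp_per_molecule",
    "thermal_conductivity",
    "thermal_conductance",
    "size_correction_factors",
    "flux_partition_correction",
    "analyze",
]

NM = 1e-9
PS = 1e-12


@dataclass(frozen=True)
class MaterialParams:
    """Protein material properties: Cp per mole of molecules (kJ/mol/K)."""

    cp_kj_mol_k: float
    shape: ShapeEstimate | None = None

    def __post_init__(self) -> None:
        if self.cp_kj_mol_k <= 0.0:
            raise InputError("MaterialParams: Cp must be > 0")


@dataclass
class TransportResult:
    """Full output of one relaxation analysis."""

    direction: str  # "sphere" | "radial" | "longitudinal"
    kappa: float  # W/K/m
    G: float  # MW/K/m^2
    biot: float
    lambda1: float
    size_basis: str  # "gyration" | "filling"
    l: float  # characteristic length, m
    D: float  # thermal diffusivity, m^2/s
    volume: float  # m^3
    tau_ps: float
    fit: FitResult

    def as_dict(self) -> dict:
        d = {
            "direction": self.direction,
            "size_basis": self.size_basis,
            "kappa_W_K_m": self.kappa,
            "G_MW_K_m2": self.G,
            "biot": self.biot,
            "lambda1": self.lambda1,
            "l_nm": self.l / NM,
            "D_m2_s": self.D,
            "volume_nm3": self.volume / NM**3,
            "tau_ps": self.tau_ps,
            "A": self.fit.A,
            "B_per_ps": self.fit.B,
            "T_i": self.fit.T_i,
            "T_f": self.fit.T_f,
            "residual_rms": self.fit.residual_rms,
        }
        return d


def cp_per_molecule(cp_kj_mol_k: float) -> float:
    """Convert a molar heat capacity (kJ/mol/K) to J/K per molecule."""
    if cp_kj_mol_k <= 0.0:
        raise InputError("cp_per_molecule: Cp must be > 0")
    return cp_kj_mol_k * 1e3 / N_A


def thermal_conductivity(
    fit: FitResult,
    lambda1: float,
    l_m: float,
    cp_molecule_j_k: float,
    volume_m3: float,
) -> float:
    """kappa = (l^2 / tau) * (Cp / V) in W/K/m, with tau = lambda_1^2 / B.

    ``fit.B`` is in 1/ps; all other inputs SI.
    """
    if lambda1 <= 0.0 or l_m <= 0.0 or cp_molecule_j_k <= 0.0 or volume_m3 <= 0.0:
        raise InputError("thermal_conductivity: all inputs must be > 0")
    if fit.B <= 0.0:
        raise InputError("thermal_conductivity: fitted rate B must be > 0")
    tau_s = lambda1**2 / fit.B * PS
    return l_m**2 / tau_s * cp_molecule_j_k / volume_m3


def thermal_conductance(
    model: GeometryModel | str,
    lambda1: float,
    kappa: float,
    l_m: float,
) -> float:
    """Interfacial conductance G = Bi(lambda_1) * kappa / l in MW/K/m^2."""
    if kappa <= 0.0 or l_m <= 0.0:
        raise InputError("thermal_conductance: kappa and l must be > 0")
    bi = hde.biot_relation(model, lambda1)
    return bi * kappa / l_m / 1e6


def size_correction_factors(model: GeometryModel | str) -> tuple[float, float]:
    """Exact ratios (corrected/gyration) for kappa and G at fixed (A, B).

    With the fit unchanged, switching from the gyration sizes to the
    filling-corrected ones rescales l and V, hence kappa ~ l^2/V and
    G ~ kappa/l, by closed-form factors:

    * sphere (l = R, V ~ R^3):      kappa x sqrt(3/5),  G x 3/5
    * cylinder radial (l = R):      kappa x 1/sqrt(3),  G x 1/sqrt(6)
    * cylinder longitudinal (l = H/2): kappa x sqrt(3)/2, G x 1/2
    """
    model = GeometryModel(model) if not isinstance(model, GeometryModel) else model
    if model is GeometryModel.SPHERE:
        return (math.sqrt(3.0 / 5.0), 3.0 / 5.0)
    if model is GeometryModel.CYLINDER_RADIAL:
        return (1.0 / math.sqrt(3.0), 1.0 / math.sqrt(6.0))
    return (math.sqrt(3.0) / 2.0, 0.5)


def flux_partition_correction(
    kappa_r: float,
    G_r: float,
    kappa_z: float,
    G_z: float,
    R: float,
    H: float,
) -> tuple[float, float, float, float]:
    """Share the total heat flux between the two cylinder directions.

    Analyzing each direction alone attributes the entire flux to it; if the
    radial and longitudinal contributions are proportional to the lateral
    and end-cap cross sections (2*pi*R*H : 2*pi*R^2 = H : R), the radial
    values should be multiplied by H/(H+R) and the longitudinal ones by
    R/(H+R).  Off by default in :func:`analyze` — reported values elsewhere
    in this package do not apply it.
    """
    if R <= 0.0 or H <= 0.0:
        raise InputError("flux_partition_correction: R and H must be > 0")
    f_r = H / (H + R)
    f_z = R / (H + R)
    return (kappa_r * f_r, G_r * f_r, kappa_z * f_z, G_z * f_z)


_DIRECTION = {
    GeometryModel.SPHERE: "sphere",
    GeometryModel.CYLINDER_RADIAL: "radial",
    GeometryModel.CYLINDER_LONGITUDINAL: "longitudinal",
}


@contextmanager
def _stage(name: str):
    """Tag computation errors with the pipeline stage they came from."""
    try:
        yield
    except ProthermError as exc:
        exc.args = (f"[stage: {name}] {exc.args[0] if exc.args else ''}",)
        raise


def _characteristic_sizes(
    shape: ShapeEstimate, model: GeometryModel, size_basis: str
) -> tuple[float, float]:
    """(l, V) in nm / nm^3 for the requested model and size basis."""
    if size_basis not in ("gyration", "filling"):
        raise InputError("size_basis must be 'gyration' or 'filling'")
    if model is GeometryModel.SPHERE:
        if shape.model != "sphere":
            raise InputError("sphere analysis needs a sphere ShapeEstimate")
        if size_basis == "filling":
            shape = filling_correction(shape)
            return shape.R_s, shape.volume
        return shape.r_s, shape.gyration_volume()
    if shape.model != "cylinder":
        raise InputError("cylinder analysis needs a cylinder ShapeEstimate")
    if size_basis == "filling":
        shape = filling_correction(shape)
        r, h, v = shape.R_c, shape.H_c, shape.volume
    else:
        r, h, v = shape.r_c, shape.h_c, shape.gyration_volume()
    if model is GeometryModel.CYLINDER_RADIAL:
        return r, v
    return h / 2.0, v


def analyze(
    trace: TemperatureTrace,
    shape: ShapeEstimate,
    model: GeometryModel | str,
    cp_kj_mol_k: float,
    size_basis: str = "filling",
    T_i: float | None = None,
    T_f: float | None = None,
    window: tuple[float, float] | None = None,
    bath: TemperatureTrace | None = None,
) -> TransportResult:
    """End-to-end analysis of one relaxation trace.

    Composes endpoint normalization, the exponential fit, the eigenvalue
    inversion and the conductivity/conductance formulas; every intermediate
    is recorded on the returned :class:`TransportResult`.  Errors from any
    stage carry a stage label.
    """
    model = GeometryModel(model) if not isinstance(model, GeometryModel) else model
    with _stage("geometry"):
        l_nm, v_nm3 = _characteristic_sizes(shape, model, size_basis)
    with _stage("fit"):
        fit = fit_trace(trace, T_i=T_i, T_f=T_f, window=window, bath=bath)
    with _stage("eigenvalue"):
        lam1 = hde.solve_lambda1(model, fit.A)
    l_m = l_nm * NM
    v_m3 = v_nm3 * NM**3
    with _stage("transport"):
        kappa = thermal_conductivity(
            fit, lam1, l_m, cp_per_molecule(cp_kj_mol_k), v_m3
        )
        G = thermal_conductance(model, lam1, kappa, l_m)
    tau_ps = lam1**2 / fit.B
    fit.tau1 = tau_ps
    return TransportResult(
        direction=_DIRECTION[model],
        kappa=kappa,
        G=G,
        biot=hde.biot_relation(model, lam1),
        lambda1=lam1,
        size_basis=size_basis,
        l=l_m,
        D=l_m**2 / (tau_ps * PS),
        volume=v_m3,
        tau_ps=tau_ps,
        fit=fit,
    )
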