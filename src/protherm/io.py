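"""File readers/writers and run configuration.

Supported formats: GROMACS-style ``.xvg`` two-column time/temperature
traces (``#``/``@`` comment lines), plain whitespace/CSV tables, PDB
coordinate files (via Biopython) and YAML run configurations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError, DataError
from .fitting import TemperatureTrace
from .geometry import PointCloud

__all__ = [
    "read_trace",
    "write_trace",
    "read_pdb",
    "RunConfig",
]

_WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "DOD"}

# Fallback masses (amu) for elements Biopython cannot resolve from the file.
_FALLBACK_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "FE": 55.845, "ZN": 65.38, "MG": 24.305, "CA": 40.078,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "MN": 54.938, "CU": 63.546,
}


def read_trace(
    path,
    columns: tuple[int, int] = (0, 1),
    role: str = "protein",
    replicate_id: int = 0,
) -> TemperatureTrace:
    """Read a time/temperature trace from an .xvg-dialect or plain text file.

    Lines starting with ``#`` or ``@`` are comments; remaining lines must
    contain at least ``max(columns)+1`` whitespace- (or comma-) separated
    numeric fields.  Times are assumed in ps, temperatures in K.

    Raises
    ------
    DataError
        On an empty file, a malformed row (reported with its line number),
        or non-monotonic times.
    """
    path = Path(path)
    tcol, ycol = columns
    times, temps = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            fields = line.replace(",", " ").split()
            try:
                times.append(float(fields[tcol]))
                temps.append(float(fields[ycol]))
            except (IndexError, ValueError) as exc:
                raise DataError(
                    f"{path}:{lineno}: cannot parse columns {columns} "
                    f"from {line!r}"
                ) from exc
    if not times:
        raise DataError(f"{path}: no data rows found")
    t = np.asarray(times)
    if t.size >= 2 and not np.all(np.diff(t) > 0.0):
        raise DataError(f"{path}: times are not strictly increasing")
    return TemperatureTrace(
        times=t,
        temperatures=np.asarray(temps),
        role=role,
        replicate_id=replicate_id,
    )


def write_trace(path, trace: TemperatureTrace, title: str = "") -> None:
    """Write a trace in the .xvg dialect (round-trips at full precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f'@    title "{title or trace.role}"\n')
        fh.write('@    xaxis  label "Time (ps)"\n')
        fh.write('@    yaxis  label "Temperature (K)"\n')
        fh.write(f"# role={trace.role} replicate={trace.replicate_id}\n")
        for t, T in zip(trace.times, trace.temperatures):
            fh.write(f"{t:.17g} {T:.17g}\n")


def read_pdb(
    path,
    include_waters: bool = False,
    label: str | None = None,
) -> PointCloud:
    """Read atomic coordinates and masses from a PDB file.

    All atoms present in the file are used (hydrogens included when
    present); water residues are skipped unless ``include_waters``.  For
    disordered atoms the highest-occupancy alternate location is kept
    (Biopython's default selection).  Coordinates are converted from
    Angstrom to nm; masses come from Biopython's element table, with a
    small fallback for elements it cannot resolve.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(label or path.stem, str(path))
    positions, masses = [], []
    for atom in structure.get_atoms():
        res = atom.get_parent()
        if not include_waters and res.get_resname().strip() in _WATER_RESNAMES:
            continue
        m = atom.mass
        if m is None or not np.isfinite(m) or m <= 0.0:
            elem = (atom.element or atom.get_name()[:1]).upper().strip()
            m = _FALLBACK_MASSES.get(elem)
            if m is None:
                raise DataError(
                    f"{path}: cannot assign a mass to atom "
                    f"{atom.get_full_id()}"
                )
        positions.append(atom.coord / 10.0)  # Angstrom -> nm
        masses.append(m)
    if not positions:
        raise DataError(f"{path}: no usable atoms found")
    return PointCloud(
        positions=np.asarray(positions),
        masses=np.asarray(masses),
        label=label or path.stem,
    )


@dataclass
class RunConfig:
    """Resolved settings for one analysis run; serialized for provenance."""

    model: str = "sphere"
    size_basis: str = "filling"
    cp_kj_mol_k: float | None = None
    T_i: float | None = None
    T_f: float | None = None
    window: tuple[float, float] | None = None
    boxes: tuple[float, ...] = (3.0, 4.0, 4.5)
    flux_partition: bool = False
    mass_weighted: bool = True
    include_waters: bool = False
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.model not in (
            "sphere", "radial", "longitudinal", "cylinder", "both"
        ):
            raise ConfigError(f"RunConfig: unknown model '{self.model}'")
        if self.size_basis not in ("gyration", "filling"):
            raise ConfigError(
                f"RunConfig: unknown size basis '{self.size_basis}'"
            )
        if self.cp_kj_mol_k is not None and self.cp_kj_mol_k <= 0.0:
            raise ConfigError("RunConfig: Cp must be > 0")
        if self.flux_partition and self.model not in ("cylinder", "both"):
            raise ConfigError(
                "RunConfig: flux partition needs both cylinder directions"
            )
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras.update(extras)
        if cfg.window is not None:
            cfg.window = tuple(cfg.window)
        cfg.boxes = tuple(cfg.boxes)
        return cfg.validate()

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, sort_keys=True)
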