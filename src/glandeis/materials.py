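"""Per-compartment electrical material properties.

Each tissue compartment is a linear dielectric conductor described by a
conductivity ``sigma`` (S/m) and a relative permittivity ``eps_r``; at
angular frequency ``ω = 2πf`` it carries the complex admittivity

    γ(f) = sigma + j·ω·ε0·eps_r   [S/m].

Membranes additionally carry a physical thickness (~8 nm) and enter the
field problem as a per-area thin-layer admittance γ_m / t_m rather than
as a meshed volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml
from scipy.constants import epsilon_0

__all__ = [
    "CompartmentMaterial",
    "MaterialTable",
    "default_materials",
    "load_materials",
    "save_materials",
    "admittivity",
]

COMPARTMENTS = (
    "cytoplasm",
    "membrane",
    "extracellular_fluid",
    "colloid",
    "connective_tissue",
    "fascia",
    "background",
)


def admittivity(sigma: float, eps_r: float, f: float) -> complex:
    """Complex admittivity sigma + j·2πf·ε0·eps_r at frequency f (Hz)."""
    return sigma + 2j * 3.141592653589793 * f * epsilon_0 * eps_r


@dataclass(frozen=True)
class CompartmentMaterial:
    """Electrical description of one tissue compartment."""

    name: str
    sigma: float  # S/m
    eps_r: float  # dimensionless
    thickness: float | None = None  # m; membranes only
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"{self.name}: sigma must be >= 0")
        if self.eps_r < 1:
            raise ValueError(f"{self.name}: eps_r must be >= 1")
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError(f"{self.name}: thickness must be > 0")

    def gamma(self, f: float) -> complex:
        return admittivity(self.sigma, self.eps_r, f)


class MaterialTable(dict):
    """name → :class:`CompartmentMaterial` mapping with a gamma() helper."""

    def gamma(self, name: str, f: float) -> complex:
        return self[name].gamma(f)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self]
        if missing:
            raise KeyError(f"material table missing compartments: {missing}")


def _table_from_mapping(data: Mapping[str, Mapping]) -> MaterialTable:
    table = MaterialTable()
    for name, props in data.items():
        table[name] = CompartmentMaterial(
            name=name,
            sigma=float(props["sigma"]),
            eps_r=float(props["eps_r"]),
            thickness=(
                float(props["thickness"]) if props.get("thickness") is not None else None
            ),
            provenance=str(props.get("provenance", "")),
        )
    return table


def load_materials(path: str | Path) -> MaterialTable:
    """Read a material table from a YAML file (name → sigma/eps_r/...)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _table_from_mapping(data)


def save_materials(table: MaterialTable, path: str | Path) -> None:
    data = {
        m.name: {
            "sigma": m.sigma,
            "eps_r": m.eps_r,
            **({"thickness": m.thickness} if m.thickness is not None else {}),
            **({"provenance": m.provenance} if m.provenance else {}),
        }
        for m in table.values()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def default_materials() -> MaterialTable:
    """Baseline material table shipped with the package.

    Literature-sourced defaults (see the YAML file for per-value
    provenance); the study holds these fixed and varies geometry only.
    """
    ref = resources.files("glandeis").joinpath("data/materials_default.yaml")
    with resources.as_file(ref) as path:
        return load_materials(path)
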