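"""Virtual tissue constructs: geometric models at the three spatial scales.

micro  — a periodic cuboid unit cell: one epithelial cell body separated
         from its neighbours by an extracellular-fluid gap dECS, with the
         8 nm membrane carried as a surface property of the cell boundary.
macro  — a block of bulk tissue under a four-electrode surface probe,
meso   — (thyroid only) a periodic packing of a spherical follicle
         (colloid core + single-cell-layer epithelial shell) in
         connective tissue of thickness dCT.
         optionally capped by a superficial fascia layer; the parathyroid
         gland is a finite block embedded in connective-tissue background.

All micro/meso lengths are µm, all macro lengths mm, as in the study's
parameter tables; solvers convert to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .materials import MaterialTable
from .parameters import ZCELL_UM

__all__ = [
    "MicroUnit",
    "MesoUnit",
    "MacroDomain",
    "ElectrodeLayout",
    "make_micro_unit",
    "make_meso_unit",
    "make_macro_domain",
]


@dataclass(frozen=True)
class MicroUnit:
    """Periodic cell-scale unit: cuboid cell body in extracellular fluid."""

    xcell: float  # µm
    ycell: float  # µm
    zcell: float  # µm
    dECS: float  # µm, extracellular gap between neighbouring cells
    materials: MaterialTable

    def __post_init__(self) -> None:
        for name in ("xcell", "ycell", "zcell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dECS < 0:
            raise ValueError("dECS must be >= 0")
        self.materials.require("cytoplasm", "membrane", "extracellular_fluid")

    @property
    def edge_lengths(self) -> tuple[float, float, float]:
        """Unit-cell edges (µm): cell dimension plus one full gap."""
        return (self.xcell + self.dECS, self.ycell + self.dECS, self.zcell + self.dECS)

    @property
    def cell_volume_fraction(self) -> float:
        x, y, z = self.edge_lengths
        return (self.xcell * self.ycell * self.zcell) / (x * y * z)


@dataclass(frozen=True)
class MesoUnit:
    """Periodic follicle-scale unit (thyroid only).

    A spherical follicle — colloid core wrapped in an epithelial shell
    one cell layer thick, whose admittivity comes from the homogenised
    micro unit — packed in connective tissue of thickness dCT.
    """

    dfollicle: float  # µm, follicle diameter
    shell_thickness: float  # µm, epithelial layer
    dCT: float  # µm, inter-follicle connective tissue
    materials: MaterialTable

    def __post_init__(self) -> None:
        if self.dfollicle <= 0 or self.shell_thickness <= 0 or self.dCT <= 0:
            raise ValueError("all follicle dimensions must be > 0")
        if self.dfollicle <= 2.0 * self.shell_thickness:
            raise ValueError(
                "follicle has no colloid core: dfollicle must exceed twice the "
                "epithelial shell thickness"
            )
        self.materials.require("colloid", "connective_tissue")

    @property
    def core_diameter(self) -> float:
        return self.dfollicle - 2.0 * self.shell_thickness

    @property
    def edge_length(self) -> float:
        """Cubic packing convention: unit-cell edge dfollicle + dCT (µm)."""
        return self.dfollicle + self.dCT


@dataclass(frozen=True)
class ElectrodeLayout:
    """Four circular surface electrodes of a tetrapolar probe.

    Collinear by default: drive (I1) and ground (V0) outermost, the two
    passives (V1, V2) inside, on a uniform pitch.  Positions are (x, y)
    mm on the tissue surface z = 0.
    """

    positions: Mapping[str, tuple[float, float]]  # mm
    radius: float  # mm

    def __post_init__(self) -> None:
        required = {"I1", "V0", "V1", "V2"}
        if set(self.positions) != required:
            raise ValueError(f"electrode positions must name exactly {required}")
        if self.radius <= 0:
            raise ValueError("electrode radius must be > 0")
        names = list(self.positions)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.separation(a, b) < 2.0 * self.radius:
                    raise ValueError(f"electrodes {a} and {b} overlap")

    @classmethod
    def collinear(cls, pitch: float = 1.5, radius: float = 0.25) -> "ElectrodeLayout":
        """Default probe: I1, V1, V2, V0 on a line at the given pitch (mm)."""
        xs = np.array([-1.5, -0.5, 0.5, 1.5]) * pitch
        return cls(
            positions={
                "I1": (xs[0], 0.0),
                "V1": (xs[1], 0.0),
                "V2": (xs[2], 0.0),
                "V0": (xs[3], 0.0),
            },
            radius=radius,
        )

    def separation(self, a: str, b: str) -> float:
        pa, pb = np.asarray(self.positions[a]), np.asarray(self.positions[b])
        d = float(np.hypot(*(pa - pb)))
        return d

    @property
    def footprint(self) -> float:
        """Outer span of the electrode array including radii (mm)."""
        xs = np.array([p[0] for p in self.positions.values()])
        ys = np.array([p[1] for p in self.positions.values()])
        return max(np.ptp(xs), np.ptp(ys)) + 2.0 * self.radius


@dataclass(frozen=True)
class MacroDomain:
    """Tissue-scale block under the tetrapolar probe.

    Thyroid: a half-space of homogenised follicular bulk.  Parathyroid: a
    gland block of extent ``dpara`` centred beneath the probe, embedded in
    connective-tissue background.  Either may be capped by a fascia layer
    of thickness ``dfascia`` spanning the whole top surface.

    ``bulk_gamma`` maps frequency (Hz) to the complex admittivity (S/m)
    of the homogenised gland tissue.
    """

    gland: str
    include_fascia: bool
    dfascia: float | None  # mm
    dpara: float | None  # mm, parathyroid gland extent
    layout: ElectrodeLayout
    bulk_gamma: Callable[[float], complex]
    materials: MaterialTable
    width: float = 50.0  # mm, lateral block size (x and y)
    depth: float = 25.0  # mm, block depth below the surface

    def __post_init__(self) -> None:
        if self.include_fascia:
            if self.dfascia is None or self.dfascia <= 0:
                raise ValueError("include_fascia requires dfascia > 0")
            self.materials.require("fascia")
        elif self.dfascia is not None:
            raise ValueError("dfascia supplied but include_fascia is false")
        if self.gland == "parathyroid":
            if self.dpara is None or self.dpara <= 0:
                raise ValueError("parathyroid domain requires dpara > 0")
            self.materials.require("background")
        if self.width < 2.0 * self.layout.footprint:
            raise ValueError("block much smaller than electrode footprint")


def make_micro_unit(
    sample: Mapping[str, float],
    materials: MaterialTable,
    gland: str = "thyroid",
) -> MicroUnit:
    """Build the cell-scale unit from one morphology draw.

    zcell is not varied in the study design and is fixed to the gland's
    mean cell dimension (isotropic baseline cell).
    """
    return MicroUnit(
        xcell=float(sample["xcell"]),
        ycell=float(sample["ycell"]),
        zcell=float(sample.get("zcell", ZCELL_UM[gland])),
        dECS=float(sample["dECS"]),
        materials=materials,
    )


def make_meso_unit(
    sample: Mapping[str, float],
    materials: MaterialTable,
    gland: str = "thyroid",
) -> MesoUnit:
    """Build the follicle-scale unit (thyroid only).

    The epithelial shell is one cell layer thick: the sampled ycell.
    """
    if gland != "thyroid":
        raise ValueError("the follicle scale exists only in thyroid tissue")
    return MesoUnit(
        dfollicle=float(sample["dfollicle"]),
        shell_thickness=float(sample["ycell"]),
        dCT=float(sample["dCT"]),
        materials=materials,
    )


def make_macro_domain(
    sample: Mapping[str, float],
    gland: str,
    include_fascia: bool,
    bulk_gamma: Callable[[float], complex],
    materials: MaterialTable,
    layout: ElectrodeLayout | None = None,
    width: float = 50.0,
    depth: float = 25.0,
) -> MacroDomain:
    """Build the tissue-scale domain from one morphology draw."""
    if layout is None:
        layout = ElectrodeLayout.collinear()
    dfascia = float(sample["dfascia"]) if include_fascia else None
    dpara = float(sample["dpara"]) if gland == "parathyroid" else None
    return MacroDomain(
        gland=gland,
        include_fascia=include_fascia,
        dfascia=dfascia,
        dpara=dpara,
        layout=layout,
        bulk_gamma=bulk_gamma,
        materials=materials,
        width=width,
        depth=depth,
    )
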