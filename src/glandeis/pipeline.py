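"""Micro → meso → macro orchestration: one 14-frequency spectrum per draw.

For each frequency the cell-scale unit is homogenised; for thyroid its
effective admittivity feeds the epithelial shell of the follicle-scale
unit, which is homogenised in turn; the resulting bulk admittivity
enters the tetrapolar tissue-scale solve.  Parathyroid has no follicle
scale: the cell-scale effective properties are the bulk directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import ElectrodeLayout, make_macro_domain, make_meso_unit, make_micro_unit
from .materials import MaterialTable, default_materials
from .parameters import StudyDesign
from .solver import effective_admittivity, tetrapolar_impedance

__all__ = [
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "SpectraSet",
    "simulate_spectrum",
    "run_substudy",
    "SimulationError",
    "SubstudyError",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """The 14-point measurement grid, 76 Hz to 625 kHz.

    The probe's exact intermediate frequencies are not published, so the
    default grid is log-uniform between the fixed endpoints; a custom
    14-point list can be supplied to substitute the true hardware list.
    """

    freqs: np.ndarray = field(
        default_factory=lambda: np.geomspace(76.0, 625000.0, 14)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        f = self.freqs
        if f.shape != (14,):
            raise ValueError("frequency grid must hold exactly 14 points")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not (np.isclose(f[0], 76.0) and np.isclose(f[-1], 625000.0)):
            raise ValueError("grid endpoints are fixed at 76 Hz and 625 kHz")

    def __len__(self) -> int:
        return 14

    def __iter__(self):
        return iter(self.freqs)


@dataclass
class ImpedanceSpectrum:
    """Complex transfer impedance on the measurement grid for one draw."""

    grid: FrequencyGrid
    Z: np.ndarray  # complex Ω, one per grid frequency
    sample_id: str
    gland: str
    include_fascia: bool

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=complex)
        if self.Z.shape != (len(self.grid),):
            raise ValueError("spectrum length must match the frequency grid")

    @property
    def re(self) -> np.ndarray:
        """Real part — the quantity used by all downstream analysis."""
        return self.Z.real


@dataclass
class SpectraSet:
    """All spectra of one sub-study (one per design row)."""

    spectra: list[ImpedanceSpectrum]
    design: StudyDesign | None = None

    def __post_init__(self) -> None:
        if self.design is not None and len(self.spectra) != self.design.n_samples:
            raise ValueError(
                f"{len(self.spectra)} spectra for a design of "
                f"{self.design.n_samples} rows"
            )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def to_long_dataframe(self, source: str = "fe") -> pd.DataFrame:
        rows = []
        for s in self.spectra:
            for f, zval in zip(s.grid, s.Z):
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "gland": s.gland,
                        "include_fascia": s.include_fascia,
                        "frequency_hz": f,
                        "re_z_ohm": zval.real,
                        "im_z_ohm": zval.imag,
                        "source": source,
                    }
                )
        return pd.DataFrame(rows)


class SimulationError(RuntimeError):
    """A multiscale solve failed; carries the frequency and scale."""

    def __init__(self, message: str, f: float, scale: str):
        super().__init__(f"{message} (at {f:g} Hz, {scale} scale)")
        self.f = f
        self.scale = scale


class SubstudyError(RuntimeError):
    """Partial sub-study failure: lists every failed row, drops none silently."""

    def __init__(self, failures: list[tuple[int, Exception]], partial: SpectraSet):
        rows = ", ".join(str(i) for i, _ in failures)
        super().__init__(f"{len(failures)} sample(s) failed: rows [{rows}]")
        self.failures = failures
        self.partial = partial


def simulate_spectrum(
    sample: Mapping[str, float],
    gland: str,
    include_fascia: bool,
    grid: FrequencyGrid | None = None,
    materials: MaterialTable | None = None,
    sample_id: str = "sample",
    resolution: str = "default",
    electrode_model: str = "disc",
    layout: ElectrodeLayout | None = None,
    cache: dict | None = None,
    include_membrane: bool = True,
) -> ImpedanceSpectrum:
    """Full multiscale forward solve of one morphology draw.

    ``cache`` (optional dict) memoises effective admittivities keyed by
    (scale, geometry values, f): micro/meso solves dominate batch cost
    and recur when draws share geometry.
    """
    grid = grid or FrequencyGrid()
    materials = materials if materials is not None else default_materials()
    micro = make_micro_unit(sample, materials, gland)
    meso = make_meso_unit(sample, materials, gland) if gland == "thyroid" else None

    zvals = np.empty(len(grid), dtype=complex)
    for k, f in enumerate(grid):
        try:
            key = ("micro", micro.xcell, micro.ycell, micro.zcell, micro.dECS, f,
                   resolution, include_membrane)
            if cache is not None and key in cache:
                g_micro = cache[key]
            else:
                g_micro = effective_admittivity(
                    micro, f, resolution=resolution, include_membrane=include_membrane
                )
                if cache is not None:
                    cache[key] = g_micro
        except Exception as exc:
            raise SimulationError(str(exc), f, "micro") from exc
        if meso is not None:
            try:
                key = ("meso", meso.dfollicle, meso.shell_thickness, meso.dCT, g_micro, f, resolution)
                if cache is not None and key in cache:
                    bulk = cache[key]
                else:
                    bulk = effective_admittivity(
                        meso, f, shell_gamma=g_micro, resolution=resolution
                    )
                    if cache is not None:
                        cache[key] = bulk
            except Exception as exc:
                raise SimulationError(str(exc), f, "meso") from exc
        else:
            bulk = g_micro
        try:
            domain = make_macro_domain(
                sample, gland, include_fascia, lambda _f, b=bulk: b, materials,
                layout=layout,
            )
            zvals[k] = tetrapolar_impedance(
                domain, f, resolution=resolution, electrode_model=electrode_model
            ).Z
        except Exception as exc:
            raise SimulationError(str(exc), f, "macro") from exc

    return ImpedanceSpectrum(
        grid=grid,
        Z=zvals,
        sample_id=sample_id,
        gland=gland,
        include_fascia=include_fascia,
    )


def run_substudy(
    design: StudyDesign,
    grid: FrequencyGrid | None = None,
    materials: MaterialTable | None = None,
    resolution: str = "default",
    mode: str = "fe",
    seed: int | None = None,
    cache: dict | None = None,
) -> SpectraSet:
    """One spectrum per design row.

    ``mode='fe'`` runs the full multiscale field solves; ``mode='surrogate'``
    substitutes the fast statistical surrogate (seconds for a whole
    design), which is what continuous-test and screening runs use.
    Failed rows are collected and reported together — never dropped.
    """
    grid = grid or FrequencyGrid()
    if mode == "surrogate":
        from .surrogate import run_substudy_surrogate

        return run_substudy_surrogate(
            design, grid=grid, seed=design.seed if seed is None else seed
        )
    if mode != "fe":
        raise ValueError(f"unknown mode {mode!r}")

    spectra: list[ImpedanceSpectrum] = []
    failures: list[tuple[int, Exception]] = []
    for i, sample in enumerate(design.iter_samples()):
        sid = f"{design.gland}_{'wf' if design.include_fascia else 'nf'}_{i:04d}"
        try:
            spectra.append(
                simulate_spectrum(
                    sample,
                    design.gland,
                    design.include_fascia,
                    grid=grid,
                    materials=materials,
                    sample_id=sid,
                    resolution=resolution,
                    cache=cache,
                )
            )
        except Exception as exc:
            failures.append((i, exc))
    if failures:
        raise SubstudyError(failures, SpectraSet(spectra=spectra, design=None))
    return SpectraSet(spectra=spectra, design=design)
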