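"""Fast statistical surrogate of the multiscale simulator, and an
in-vivo-like dataset emulator.

The surrogate is explicitly a test fixture, not a claim about tissue
physics: it maps a morphology draw to a single-dispersion spectrum

    Re Z(f) = R∞ + (R0 − R∞) / (1 + (f/fc)^(2α)),

with log-linear monotone links from each morphological parameter to the
plateaus (R0, R∞) and the characteristic frequency fc, chosen so the
qualitative input–output sign structure of the full field-solver
pipeline is reproduced: R0 falls with extracellular-space and follicle
size, fc rises with extracellular-space thickness, and a superficial
fascia layer acts as a conductive shunt that pulls R∞ down as dfascia
grows and compresses the thyroid/parathyroid contrast.  All
coefficients live in the two config blocks below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import StudyDesign, build_specs, lhs_sample
from .pipeline import FrequencyGrid, ImpedanceSpectrum, SpectraSet

__all__ = [
    "SurrogateModel",
    "surrogate_spectrum",
    "run_substudy_surrogate",
    "emulate_datasets",
    "THYROID_SURROGATE",
    "PARATHYROID_SURROGATE",
]


@dataclass(frozen=True)
class SurrogateModel:
    """Coefficient block linking morphology to dispersion parameters.

    ``r0``, ``rinf`` and ``fc`` map parameter names to log-scale slopes
    per standardised unit; ``sigma_*`` are log-normal parameter-noise
    standard deviations (unexplained morphological variance); the
    ``fascia_*`` constants implement the conductive-shunt action of a
    fascia layer of thickness dfascia (mm).
    """

    r0_base: float  # Ω, low-frequency plateau
    rinf_base: float  # Ω, high-frequency plateau
    fc_base: float  # Hz, characteristic (mid-dispersion) frequency
    alpha: float  # dispersion breadth, (0, 1]
    r0: Mapping[str, float]
    rinf: Mapping[str, float]
    fc: Mapping[str, float]
    sigma_r0: float = 0.10
    sigma_rinf: float = 0.05
    sigma_fc: float = 0.08
    fascia_g0: float = 0.001  # S/mm shunt on the low-frequency plateau
    fascia_ginf: float = 0.15  # S/mm shunt on the high-frequency plateau
    fascia_kf: float = 0.4  # 1/mm pull-down of fc

    def __post_init__(self) -> None:
        if not (self.r0_base > self.rinf_base > 0):
            raise ValueError("need R0 > Rinf > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 76 < self.fc_base < 625000:
            raise ValueError("fc must lie inside the measurement band")


THYROID_SURROGATE = SurrogateModel(
    r0_base=260.0,
    rinf_base=55.0,
    fc_base=10_000.0,
    alpha=0.85,
    r0={"dECS": -0.25, "dfollicle": -0.20, "xcell": 0.10, "ycell": 0.03, "dCT": 0.03},
    rinf={"dfollicle": 0.20, "xcell": -0.04},
    fc={"dECS": 0.35, "xcell": -0.18, "dfollicle": 0.12},
    fascia_kf=0.4,
)

PARATHYROID_SURROGATE = SurrogateModel(
    r0_base=360.0,
    rinf_base=130.0,
    fc_base=30_000.0,
    alpha=0.75,
    r0={"dECS": -0.30, "xcell": 0.18, "ycell": 0.08, "dpara": -0.03},
    rinf={"ycell": -0.25, "xcell": -0.06},
    fc={"dECS": 0.25, "ycell": -0.30, "xcell": -0.15},
    fascia_kf=2.0,
)

_MODELS = {"thyroid": THYROID_SURROGATE, "parathyroid": PARATHYROID_SURROGATE}


def _standardise(sample: Mapping[str, float], gland: str) -> dict[str, float]:
    """Scale-free parameter values: (x − centre) / spread per spec."""
    u = {}
    for spec in build_specs(gland, include_fascia=True):
        if spec.name not in sample:
            continue
        x = float(sample[spec.name])
        if spec.distribution == "normal":
            u[spec.name] = (x - spec.a) / spec.b
        else:
            u[spec.name] = (x - 0.5 * (spec.a + spec.b)) / (0.5 * (spec.b - spec.a))
    return u


def dispersion_parameters(
    sample: Mapping[str, float],
    gland: str,
    include_fascia: bool,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, float]:
    """(R0, Rinf, fc, alpha) for one draw; parameter noise via ``rng``."""
    model = _MODELS[gland]
    u = _standardise(sample, gland)

    def linked(base: float, coefs: Mapping[str, float], sd: float) -> float:
        lg = np.log(base) + sum(c * u.get(name, 0.0) for name, c in coefs.items())
        if rng is not None and sd > 0:
            lg += rng.normal(0.0, sd)
        return float(np.exp(lg))

    r0 = linked(model.r0_base, model.r0, model.sigma_r0)
    rinf = linked(model.rinf_base, model.rinf, model.sigma_rinf)
    fc = linked(model.fc_base, model.fc, model.sigma_fc)

    if include_fascia and "dfascia" in sample:
        d = float(sample["dfascia"])  # mm
        r0 = 1.0 / (1.0 / r0 + model.fascia_g0 * d)
        rinf = 1.0 / (1.0 / rinf + model.fascia_ginf * d)
        fc = fc / (1.0 + model.fascia_kf * d)

    rinf = min(rinf, 0.95 * r0)  # keep the fall well-posed
    fc = float(np.clip(fc, 150.0, 5e5))
    return r0, rinf, fc, model.alpha


def surrogate_spectrum(
    sample: Mapping[str, float],
    gland: str,
    include_fascia: bool,
    grid: FrequencyGrid | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    sample_id: str = "surrogate",
) -> ImpedanceSpectrum:
    """Single-dispersion surrogate spectrum for one morphology draw.

    ``noise_sd`` adds multiplicative log-normal measurement noise per
    frequency point (0 for clean simulator-like spectra).
    """
    grid = grid or FrequencyGrid()
    rng = np.random.default_rng(seed)
    r0, rinf, fc, alpha = dispersion_parameters(sample, gland, include_fascia, rng)
    f = np.asarray(list(grid))
    s = (f / fc) ** (2.0 * alpha)
    re = rinf + (r0 - rinf) / (1.0 + s)
    im = -(r0 - rinf) * (f / fc) ** alpha / (1.0 + s)
    z = re + 1j * im
    if noise_sd > 0:
        z = z * np.exp(rng.normal(0.0, noise_sd, size=f.size))
    return ImpedanceSpectrum(
        grid=grid, Z=z, sample_id=sample_id, gland=gland, include_fascia=include_fascia
    )


def run_substudy_surrogate(
    design: StudyDesign,
    grid: FrequencyGrid | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SpectraSet:
    """Surrogate spectra for every design row (deterministic in seed)."""
    grid = grid or FrequencyGrid()
    children = np.random.SeedSequence(seed).spawn(design.n_samples)
    spectra = []
    for i, (sample, child) in enumerate(zip(design.iter_samples(), children)):
        sid = f"{design.gland}_{'wf' if design.include_fascia else 'nf'}_{i:04d}"
        rng = np.random.default_rng(child)
        r0, rinf, fc, alpha = dispersion_parameters(
            sample, design.gland, design.include_fascia, rng
        )
        f = np.asarray(list(grid))
        s = (f / fc) ** (2.0 * alpha)
        z = (rinf + (r0 - rinf) / (1.0 + s)) + 1j * (
            -(r0 - rinf) * (f / fc) ** alpha / (1.0 + s)
        )
        if noise_sd > 0:
            z = z * np.exp(rng.normal(0.0, noise_sd, size=f.size))
        spectra.append(
            ImpedanceSpectrum(
                grid=grid,
                Z=z,
                sample_id=sid,
                gland=design.gland,
                include_fascia=design.include_fascia,
            )
        )
    return SpectraSet(spectra=spectra, design=design)


def emulate_datasets(
    n_thyroid: int = 53,
    n_parathyroid: int = 42,
    noise_sd: float = 0.05,
    seed: int = 0,
    residual_fascia_max: float = 0.2,
) -> tuple[SpectraSet, SpectraSet]:
    """In-vivo-like noisy datasets of the pilot study's sizes.

    Morphology is drawn from the study's distributions; instead of the
    full fascia prior, each measurement carries a random residual fascia
    thickness Uniform(0, ``residual_fascia_max``) mm, mimicking
    incomplete surgical removal of the superficial layer.  Set
    ``residual_fascia_max=0`` for perfectly cleaned glands.
    """
    if n_thyroid <= 0 or n_parathyroid <= 0:
        raise ValueError("both group sizes must be positive")
    out = []
    for gi, (gland, n) in enumerate((("thyroid", n_thyroid), ("parathyroid", n_parathyroid))):
        design = lhs_sample(
            build_specs(gland, include_fascia=True), n,
            seed=np.random.SeedSequence([seed, gi]).generate_state(1)[0] % (2**31),
            gland=gland, include_fascia=True,
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, gi, 1]))
        include_fascia = residual_fascia_max > 0
        samples = design.samples.copy()
        j = design.names.index("dfascia")
        if include_fascia:
            samples[:, j] = rng.uniform(1e-6, residual_fascia_max, size=n)
        spectra = []
        for i in range(n):
            sample = dict(zip(design.names, samples[i]))
            if not include_fascia:
                sample.pop("dfascia")
            spectra.append(
                surrogate_spectrum(
                    sample,
                    gland,
                    include_fascia,
                    seed=int(rng.integers(2**31)),
                    noise_sd=noise_sd,
                    sample_id=f"{gland}_invivo_{i:03d}",
                )
            )
        out.append(SpectraSet(spectra=spectra, design=None))
    return out[0], out[1]
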