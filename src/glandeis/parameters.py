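"""Morphological parameter space of the thyroid/parathyroid virtual-tissue study.

The study varies the geometric features of the two glands across three
spatial scales — cell (micro), follicle (meso, thyroid only) and tissue
(macro) — each described by a published probability distribution.  This
module holds those distributions and draws Latin-hypercube design
matrices over them: one sample per equiprobable stratum of every
marginal, with the column pairings randomly permuted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParameterSpec",
    "StudyDesign",
    "build_specs",
    "lhs_sample",
    "GLANDS",
    "ZCELL_UM",
]

GLANDS = ("thyroid", "parathyroid")

#: Fixed cell depth (zcell, µm) per gland: the mean cell dimension, so the
#: baseline cell is isotropic.  zcell is not varied in the study design.
ZCELL_UM = {"thyroid": 8.53, "parathyroid": 7.59}


@dataclass(frozen=True)
class ParameterSpec:
    """One morphological input parameter and its sampling distribution.

    Parameters
    ----------
    name : str
        Field-standard identifier (``xcell``, ``ycell``, ``dECS``,
        ``dfollicle``, ``dCT``, ``dfascia``, ``dpara``).
    scale : {'micro', 'meso', 'macro'}
        Spatial scale the parameter belongs to.
    distribution : {'uniform', 'normal'}
    a, b : float
        ``uniform``: minimum / maximum.  ``normal``: mean / standard
        deviation.
    units : str
        Length unit of the sampled values ('um' or 'mm').
    """

    name: str
    scale: str
    distribution: str
    a: float
    b: float
    units: str

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.scale not in ("micro", "meso", "macro"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.distribution == "uniform":
            if not self.a < self.b:
                raise ValueError(f"{self.name}: uniform requires a < b")
            if self.a <= 0:
                raise ValueError(f"{self.name}: uniform support must be positive")
        else:
            if self.b <= 0:
                raise ValueError(f"{self.name}: normal requires sd > 0")

    @property
    def mean(self) -> float:
        if self.distribution == "uniform":
            return 0.5 * (self.a + self.b)
        return self.a

    @property
    def truncation_floor(self) -> float:
        """Lower bound applied to normal draws so geometry stays meshable.

        The larger of the 0.1st percentile and 1% of the mean; uniform
        specs (already positive) are not truncated.
        """
        if self.distribution == "uniform":
            return self.a
        return max(stats.norm.ppf(1e-3, loc=self.a, scale=self.b), 0.01 * self.a)

    @property
    def _q_floor(self) -> float:
        """Probability mass below the truncation floor of a normal spec."""
        if self.distribution == "uniform":
            return 0.0
        return float(stats.norm.cdf(self.truncation_floor, loc=self.a, scale=self.b))

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Inverse CDF (left-truncated at the floor for normal specs).

        Truncation is applied by remapping the quantile into the kept
        mass, so stratified draws stay exactly stratified.
        """
        q = np.asarray(q, dtype=float)
        if self.distribution == "uniform":
            return stats.uniform.ppf(q, loc=self.a, scale=self.b - self.a)
        q_lo = self._q_floor
        return stats.norm.ppf(q_lo + q * (1.0 - q_lo), loc=self.a, scale=self.b)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF of the (truncated, for normal specs) sampling distribution."""
        x = np.asarray(x, dtype=float)
        if self.distribution == "uniform":
            return stats.uniform.cdf(x, loc=self.a, scale=self.b - self.a)
        q_lo = self._q_floor
        raw = stats.norm.cdf(x, loc=self.a, scale=self.b)
        return np.clip((raw - q_lo) / (1.0 - q_lo), 0.0, 1.0)

    @property
    def label(self) -> str:
        return f"{self.name} [{self.units}]"


# Published distributions.  (name, scale, distribution, a, b, units)
_THYROID_TABLE = [
    ("xcell", "micro", "normal", 8.53, 1.84, "um"),
    ("ycell", "micro", "normal", 8.53, 1.84, "um"),
    ("dECS", "micro", "uniform", 0.1, 0.5, "um"),
    ("dfollicle", "meso", "normal", 113.77, 63.13, "um"),
    ("dCT", "meso", "uniform", 0.8, 2.5, "um"),
    ("dfascia", "macro", "uniform", 0.025, 0.5, "mm"),
]

_PARATHYROID_TABLE = [
    ("xcell", "micro", "normal", 7.59, 1.45, "um"),
    ("ycell", "micro", "normal", 7.59, 1.45, "um"),
    ("dECS", "micro", "uniform", 0.4, 0.9, "um"),
    ("dfascia", "macro", "uniform", 0.025, 0.5, "mm"),
    ("dpara", "macro", "uniform", 3.0, 8.0, "mm"),
]


def build_specs(gland: str, include_fascia: bool = True) -> list[ParameterSpec]:
    """Parameter specs for one gland, optionally dropping the fascia layer.

    Thyroid varies six parameters (five without fascia); parathyroid five
    (four without fascia).  Excluding the superficial fascia compartment
    removes exactly the ``dfascia`` spec.
    """
    if gland == "thyroid":
        table = _THYROID_TABLE
    elif gland == "parathyroid":
        table = _PARATHYROID_TABLE
    else:
        raise ValueError(f"unknown gland {gland!r}; expected one of {GLANDS}")
    specs = [ParameterSpec(*row) for row in table]
    if not include_fascia:
        specs = [s for s in specs if s.name != "dfascia"]
    return specs


@dataclass
class StudyDesign:
    """A Latin-hypercube design matrix over one gland's parameter space."""

    gland: str
    include_fascia: bool
    specs: list[ParameterSpec]
    n_samples: int
    seed: int
    samples: np.ndarray  # (n_samples, len(specs)), each spec's own units

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (self.n_samples, len(self.specs)):
            raise ValueError(
                f"sample matrix shape {self.samples.shape} does not match "
                f"({self.n_samples}, {len(self.specs)})"
            )
        if not np.all(self.samples > 0):
            raise ValueError("all sampled lengths must be strictly positive")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=[s.label for s in self.specs])

    def iter_samples(self) -> Iterator[dict[str, float]]:
        """Yield each design row as a name → value mapping (spec units)."""
        for row in self.samples:
            yield dict(zip(self.names, row))

    # -- CSV + JSON-sidecar persistence ---------------------------------
    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "gland": self.gland,
            "include_fascia": self.include_fascia,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "StudyDesign":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        df = pd.read_csv(path)
        specs = build_specs(meta["gland"], meta["include_fascia"])
        expect = [s.label for s in specs]
        if list(df.columns) != expect:
            raise ValueError(f"design columns {list(df.columns)} != {expect}")
        return cls(
            gland=meta["gland"],
            include_fascia=meta["include_fascia"],
            specs=specs,
            n_samples=meta["n_samples"],
            seed=meta["seed"],
            samples=df.to_numpy(),
        )


def lhs_sample(
    specs: Sequence[ParameterSpec],
    n: int,
    seed: int,
    gland: str = "thyroid",
    include_fascia: bool | None = None,
) -> StudyDesign:
    """Draw an ``n``-run Latin hypercube over ``specs``.

    Each marginal's CDF is divided into ``n`` non-overlapping equiprobable
    intervals; one point is drawn uniformly inside each interval and
    mapped through the inverse CDF, and the rows of each column are then
    randomly permuted.  One seeded generator is consumed column-by-column
    in spec order, so the design is bit-reproducible from ``seed``.

    Normal marginals are left-truncated at the spec's truncation floor
    (the larger of the 0.1st percentile and 1% of the mean) so every
    length is strictly positive and meshable; truncation happens inside
    the inverse CDF, which keeps the stratification exact.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    specs = list(specs)
    if include_fascia is None:
        include_fascia = any(s.name == "dfascia" for s in specs)
    rng = np.random.default_rng(seed)
    cols = []
    for spec in specs:
        strata = (rng.permutation(n) + rng.uniform(size=n)) / n
        cols.append(spec.ppf(strata))
    return StudyDesign(
        gland=gland,
        include_fascia=include_fascia,
        specs=specs,
        n_samples=n,
        seed=seed,
        samples=np.column_stack(cols),
    )
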