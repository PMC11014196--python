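"""File formats and study configuration.

Tabular artifacts are CSV, reports JSON, configuration YAML.  The
spectra CSV is long-format — one row per (sample, frequency) — and the
same reader ingests externally deposited spectra after a documented
column mapping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import FrequencyGrid, ImpedanceSpectrum, SpectraSet

__all__ = [
    "SPECTRA_COLUMNS",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_features_csv",
    "read_features_csv",
    "write_prcc_report",
    "write_separability_report",
    "StudyConfig",
]

SPECTRA_COLUMNS = (
    "sample_id",
    "gland",
    "include_fascia",
    "frequency_hz",
    "re_z_ohm",
    "im_z_ohm",
)


def write_spectra_csv(spectra: SpectraSet, path: str | Path, source: str = "fe") -> None:
    """Long-format spectra CSV; values round-trip losslessly."""
    df = spectra.to_long_dataframe(source=source)
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectra_csv(
    path: str | Path, column_map: dict[str, str] | None = None
) -> SpectraSet:
    """Read a long-format spectra CSV into a :class:`SpectraSet`.

    ``column_map`` maps external column names to the canonical schema
    (e.g. ``{"freq": "frequency_hz", "Zre": "re_z_ohm"}``) so deposited
    datasets can be ingested without editing the file.  ``im_z_ohm`` may
    be absent (imaginary parts default to zero).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = set(SPECTRA_COLUMNS) - {"im_z_ohm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spectra CSV missing columns: {sorted(missing)}")
    if "im_z_ohm" not in df.columns:
        df["im_z_ohm"] = 0.0

    spectra = []
    ref_freqs: np.ndarray | None = None
    for sid, group in df.groupby("sample_id", sort=False):
        group = group.sort_values("frequency_hz")
        freqs = group["frequency_hz"].to_numpy(dtype=float)
        if ref_freqs is None:
            ref_freqs = freqs
        elif freqs.shape != ref_freqs.shape or not np.allclose(freqs, ref_freqs):
            raise ValueError(
                f"sample {sid!r}: frequency grid differs from the rest of the file"
            )
        if freqs.size != 14:
            raise ValueError(
                f"sample {sid!r}: expected 14 frequencies, found {freqs.size}"
            )
        grid = FrequencyGrid(freqs)
        z = group["re_z_ohm"].to_numpy(float) + 1j * group["im_z_ohm"].to_numpy(float)
        gland = str(group["gland"].iloc[0])
        fascia = bool(group["include_fascia"].iloc[0])
        spectra.append(
            ImpedanceSpectrum(
                grid=grid, Z=z, sample_id=str(sid), gland=gland, include_fascia=fascia
            )
        )
    if not spectra:
        raise ValueError("spectra CSV holds no samples")
    return SpectraSet(spectra=spectra, design=None)


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False, float_format="%.12g")


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"z1_ohm", "z14_ohm", "fmid_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"features CSV missing columns: {sorted(missing)}")
    return df


def write_prcc_report(results, path: str | Path, filtered: bool = True) -> None:
    """PRCC table mirroring the published sensitivity-table layout."""
    path = Path(path)
    table = results.filtered() if filtered else results.table
    if path.suffix == ".json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=2))
    else:
        table.to_csv(path, index=False, float_format="%.6g")


def write_separability_report(results, path: str | Path) -> None:
    Path(path).write_text(json.dumps(results.to_dict(), indent=2))


@dataclass
class StudyConfig:
    """Fully serialisable description of one study run."""

    glands: list[str] = field(default_factory=lambda: ["thyroid", "parathyroid"])
    include_fascia: list[bool] = field(default_factory=lambda: [True, False])
    n_samples: int = 100
    seed: int = 0
    mode: str = "surrogate"  # 'fe' or 'surrogate'
    resolution: str = "default"
    materials_path: str | None = None
    cv_folds: int = 20
    output_dir: str = "study_out"

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
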