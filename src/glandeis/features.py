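"""Spectrum indices: Z1, Z14 and the mid-dispersion frequency fmid.

Z1 and Z14 are the real impedances at the first (76 Hz) and last
(625 kHz) grid frequencies — before and after the β dispersion.  fmid is
the frequency at which the real impedance crosses the midpoint
(Z1 + Z14)/2, located by interpolation that is linear in impedance and
linear in log-frequency (the dispersion is symmetric on a log-f axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import ImpedanceSpectrum, SpectraSet

__all__ = [
    "SpectrumFeatures",
    "extract_features",
    "fmid_from_curve",
    "features_dataframe",
    "FlatSpectrumError",
]

FEATURE_NAMES = ("Z1", "Z14", "fmid")


class FlatSpectrumError(ValueError):
    """Z1 equals Z14: there is no dispersion and fmid is undefined."""


@dataclass(frozen=True)
class SpectrumFeatures:
    """The (Z1, Z14, fmid) triple parameterising one spectrum."""

    Z1: float  # Ω at the first grid frequency
    Z14: float  # Ω at the last grid frequency
    fmid: float  # Hz
    monotone: bool = True  # False if the crossing was not unique


def fmid_from_curve(freqs: np.ndarray, re_z: np.ndarray) -> tuple[float, bool]:
    """Mid-dispersion frequency of a real-impedance curve.

    Finds the first crossing (from the low-frequency side) of the
    midpoint between the endpoint impedances and interpolates its
    position log-linearly between the bracketing grid points.  Returns
    (fmid, monotone) where ``monotone`` is False when the curve crosses
    the midpoint more than once.
    """
    freqs = np.asarray(freqs, dtype=float)
    re_z = np.asarray(re_z, dtype=float)
    if freqs.size != re_z.size or freqs.size < 2:
        raise ValueError("need matching frequency and impedance arrays (n >= 2)")
    z_lo, z_hi = re_z[0], re_z[-1]
    if z_lo == z_hi:
        raise FlatSpectrumError("no dispersion: Z1 equals Z14, fmid undefined")
    mid = 0.5 * (z_lo + z_hi)

    # Work on the curve oriented as a fall; a rising curve is mirrored.
    curve = re_z if z_lo > z_hi else -re_z
    target = mid if z_lo > z_hi else -mid
    below = curve <= target
    crossings = np.nonzero(below[1:] & ~below[:-1])[0]
    if crossings.size == 0:
        # Endpoint-anchored curves always bracket the midpoint; only
        # exact grid-point hits at the ends can land here.
        idx = int(np.argmin(np.abs(curve - target)))
        return float(freqs[idx]), True
    i = int(crossings[0])
    monotone = crossings.size == 1 and bool(np.all(np.diff(curve) <= 0))
    if curve[i] == target:
        return float(freqs[i]), monotone
    t = (target - curve[i]) / (curve[i + 1] - curve[i])
    logf = np.log10(freqs)
    return float(10.0 ** (logf[i] + t * (logf[i + 1] - logf[i]))), monotone


def extract_features(spectrum: ImpedanceSpectrum) -> SpectrumFeatures:
    """Parameterise one spectrum as (Z1, Z14, fmid).

    Raises :class:`FlatSpectrumError` for flat spectra; non-monotone
    spectra use the first crossing from the low-frequency side and carry
    a warning.
    """
    re_z = spectrum.re
    freqs = np.asarray(list(spectrum.grid))
    fmid, monotone = fmid_from_curve(freqs, re_z)
    if not monotone:
        warnings.warn(
            f"spectrum {spectrum.sample_id}: non-monotone dispersion; "
            "fmid taken at the first midpoint crossing",
            stacklevel=2,
        )
    return SpectrumFeatures(
        Z1=float(re_z[0]), Z14=float(re_z[-1]), fmid=fmid, monotone=monotone
    )


def features_dataframe(spectra: SpectraSet) -> pd.DataFrame:
    """Feature table for a spectra set (one row per spectrum)."""
    rows = []
    for s in spectra:
        feat = extract_features(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "gland": s.gland,
                "include_fascia": s.include_fascia,
                "z1_ohm": feat.Z1,
                "z14_ohm": feat.Z14,
                "fmid_hz": feat.fmid,
            }
        )
    return pd.DataFrame(rows)
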