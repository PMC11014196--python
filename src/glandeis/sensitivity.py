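"""Global sensitivity: partial rank correlation coefficients (PRCC).

Each design input is rank-transformed together with each output index;
the PRCC is the Pearson correlation of the rank residuals after
regressing the input's ranks and the output's ranks on all other
inputs' ranks.  Significance uses the two-sided t approximation with
n − 2 − c degrees of freedom (c = number of controlled inputs), and the
association strength is binned on |PRCC| as low (< 0.4), medium
(0.4 – 0.7) and high (> 0.7); boundary values fall in the lower bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PRCCRecord",
    "prcc_analysis",
    "classify_association",
    "PRCCAnalysis",
    "PRCCResults",
]


@dataclass(frozen=True)
class PRCCRecord:
    """One input–output partial rank correlation."""

    input_name: str
    output_name: str
    prcc: float
    p_value: float
    level: str  # 'low' | 'medium' | 'high'


def classify_association(prcc: float) -> str:
    """Association-strength bin of a PRCC value (on |PRCC|)."""
    a = abs(prcc)
    if a > 1.0:
        raise ValueError("|PRCC| cannot exceed 1")
    if a <= 0.4:
        return "low"
    if a <= 0.7:
        return "medium"
    return "high"


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)  # ties → average ranks


def _partial_corr_ranks(rx: np.ndarray, ry: np.ndarray, rc: np.ndarray) -> float:
    """Pearson correlation of rank residuals, controlling for rc columns."""
    n = rx.shape[0]
    design = np.column_stack([np.ones(n), rc]) if rc.size else np.ones((n, 1))
    coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ coef_x
    ey = ry - design @ coef_y
    sx, sy = np.linalg.norm(ex), np.linalg.norm(ey)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (constant-rank) residuals; PRCC undefined")
    # guard against |r| drifting past 1 by a few ulps
    return float(np.clip(np.dot(ex, ey) / (sx * sy), -1.0, 1.0))


def prcc_analysis(
    inputs: pd.DataFrame,
    outputs: pd.DataFrame,
) -> list[PRCCRecord]:
    """PRCC of every input column against every output column.

    ``inputs`` is the design matrix (n rows × k inputs), ``outputs`` the
    per-sample spectrum indices aligned row for row.
    """
    if len(inputs) != len(outputs):
        raise ValueError("design rows and feature rows must align 1:1")
    n, k = inputs.shape
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} samples for {k} inputs")
    rx_all = _rank(inputs.to_numpy(dtype=float))
    records = []
    for out_name in outputs.columns:
        ry = _rank(outputs[out_name].to_numpy(dtype=float))
        for j, in_name in enumerate(inputs.columns):
            others = np.delete(np.arange(k), j)
            r = _partial_corr_ranks(rx_all[:, j], ry, rx_all[:, others])
            c = k - 1
            dof = n - 2 - c
            r_clip = min(max(r, -0.9999999999), 0.9999999999)
            t = r_clip * np.sqrt(dof / (1.0 - r_clip**2))
            p = 2.0 * stats.t.sf(abs(t), dof)
            records.append(
                PRCCRecord(
                    input_name=str(in_name),
                    output_name=str(out_name),
                    prcc=r,
                    p_value=float(p),
                    level=classify_association(r),
                )
            )
    return records


class PRCCAnalysis:
    """Sensitivity model over one sub-study's design and features.

    Parameters
    ----------
    design : pandas.DataFrame or StudyDesign
        The sampled input matrix.  A StudyDesign is converted with
        bare parameter names as columns.
    features : pandas.DataFrame
        Columns Z1, Z14, fmid (case-insensitive; the canonical feature
        CSV columns z1_ohm/z14_ohm/fmid_hz are also recognised).
    """

    _ALIASES = {"z1_ohm": "Z1", "z14_ohm": "Z14", "fmid_hz": "fmid"}

    def __init__(self, design, features: pd.DataFrame):
        if hasattr(design, "samples"):  # StudyDesign
            self.inputs = pd.DataFrame(design.samples, columns=design.names)
        else:
            self.inputs = pd.DataFrame(design)
        features = pd.DataFrame(features).rename(columns=self._ALIASES)
        keep = [c for c in ("Z1", "Z14", "fmid") if c in features.columns]
        if not keep:
            raise ValueError("features must contain Z1/Z14/fmid columns")
        self.outputs = features[keep].reset_index(drop=True)
        self.inputs = self.inputs.reset_index(drop=True)

    def fit(self) -> "PRCCResults":
        return PRCCResults(prcc_analysis(self.inputs, self.outputs))


class PRCCResults:
    """Fitted PRCC table with the report filters of the study."""

    def __init__(self, records: list[PRCCRecord]):
        self.records = records

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "output": r.output_name,
                    "input": r.input_name,
                    "prcc": r.prcc,
                    "p_value": r.p_value,
                    "level": r.level,
                }
                for r in self.records
            ]
        )

    def lookup(self, input_name: str, output_name: str) -> PRCCRecord:
        for r in self.records:
            if r.input_name == input_name and r.output_name == output_name:
                return r
        raise KeyError((input_name, output_name))

    def filtered(
        self, p_max: float = 0.001, min_abs_prcc: float = 0.3
    ) -> pd.DataFrame:
        """Report filter: keep p < p_max and |PRCC| ≥ min_abs_prcc.

        These are the defaults the published sensitivity tables use
        (p < 0.001; low associations below 0.3 suppressed).
        """
        t = self.table
        return t[(t.p_value < p_max) & (t.prcc.abs() >= min_abs_prcc)].reset_index(
            drop=True
        )

    def summary(self, filtered: bool = True) -> str:
        t = self.filtered() if filtered else self.table
        lines = ["PRCC sensitivity summary", "=" * 24]
        if t.empty:
            lines.append("(no associations pass the report filters)")
        t = t.assign(_strength=t.prcc.abs()).sort_values(
            ["output", "_strength"], ascending=[True, False]
        )
        for _, row in t.iterrows():
            lines.append(
                f"{row.output:>5s} ~ {row.input:<10s} PRCC {row.prcc:+.2f}  "
                f"p {row.p_value:.1e}  {row.level}"
            )
        return "\n".join(lines)
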