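"""Agreement statistics: Bland-Altman analysis and gate discrepancy.

Bland-Altman limits of agreement summarize paired measurements from two
methods: with differences d = a - b, the bias is mean(d), and the 95%
limits of agreement are mean(d) +/- 1.96 * SD(d) (sample SD, n-1
denominator, the Bland-Altman convention).

Gate discrepancy compares two sets of sample-gate positions on the same
images (e.g. autonomous tracker vs sonographer, or tracker vs ground
truth) and reports the per-axis absolute differences and the fraction of
pairs within a clinical threshold (default 2 mm per axis; Euclidean
optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgreementResult", "GateDiscrepancy", "bland_altman", "gate_discrepancy"]


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of paired measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


@dataclass(frozen=True)
class GateDiscrepancy:
    """Per-axis gate differences and within-threshold fractions."""

    d_lateral_mm: np.ndarray
    d_axial_mm: np.ndarray
    threshold_mm: float
    frac_lateral: float
    frac_axial: float
    frac_euclidean: float


def bland_altman(a, b, label: str = "") -> AgreementResult:
    """Bland-Altman agreement between paired measurement vectors.

    Differences are a - b; limits of agreement are mean +/- 1.96 sample
    SD.  Requires equal-length finite vectors with n >= 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired measurements must be equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("Bland-Altman analysis needs n >= 2 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("paired measurements must be finite")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return AgreementResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        n=a.size,
        label=label,
    )


def _gate_xy(g) -> np.ndarray:
    """Coerce gates (DataFrame with lateral_mm/axial_mm, or (n,2) array)."""
    if isinstance(g, pd.DataFrame):
        return g[["lateral_mm", "axial_mm"]].to_numpy(dtype=float)
    arr = np.asarray(g, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("gates must be an (n, 2) array of (lateral, axial) mm")
    return arr


def gate_discrepancy(gates_a, gates_b, threshold_mm: float = 2.0) -> GateDiscrepancy:
    """Lateral/axial gate differences and within-threshold fractions.

    ``gates_a`` and ``gates_b`` are paired (lateral, axial) positions in
    mm on the same image geometry.
    """
    xy_a = _gate_xy(gates_a)
    xy_b = _gate_xy(gates_b)
    if xy_a.shape != xy_b.shape:
        raise ValueError(
            f"gate sets must pair up: got {xy_a.shape[0]} vs {xy_b.shape[0]} gates"
        )
    if xy_a.shape[0] == 0:
        raise ValueError("empty gate sets")
    d = xy_a - xy_b
    d_lat = np.abs(d[:, 0])
    d_ax = np.abs(d[:, 1])
    d_eu = np.hypot(d[:, 0], d[:, 1])
    return GateDiscrepancy(
        d_lateral_mm=d_lat,
        d_axial_mm=d_ax,
        threshold_mm=threshold_mm,
        frac_lateral=float((d_lat <= threshold_mm).mean()),
        frac_axial=float((d_ax <= threshold_mm).mean()),
        frac_euclidean=float((d_eu <= threshold_mm).mean()),
    )
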