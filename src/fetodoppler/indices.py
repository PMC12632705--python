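"""Clinical Doppler indices and Hadlock-IV fetal weight estimation.

Umbilical-artery Doppler indices quantify downstream (placental)
vascular resistance from one cardiac cycle of the maximum-velocity
waveform:

* S/D ratio = PSV / EDV
* resistance index  RI = (PSV - EDV) / PSV
* pulsatility index PI = (PSV - EDV) / TAV

where PSV, EDV and TAV are the peak systolic, end diastolic, and
time-averaged velocities (cm/s).  All three are ratios of velocities and
therefore independent of the insonation angle.  The cerebroplacental
ratio CPR = PI(MCA) / PI(UA) quantifies fetal brain-sparing.

Absent end-diastolic flow (EDV <= 0) is a marker of severe placental
insufficiency.  In that regime the S/D ratio diverges, so it is reported
as NaN (an explicit absent-EDV marker) and excluded from aggregate
means, while RI remains well defined (1 at EDV = 0, > 1 for reversed
flow) and is retained.

Estimated fetal weight uses the Hadlock-IV regression on biparietal
diameter (BPD), head circumference (HC), abdominal circumference (AC)
and femur length (FL), all in cm:

    log10(EFW[g]) = 1.3596 - 0.00386 AC*FL + 0.0064 HC
                    + 0.00061 BPD*AC + 0.0424 AC + 0.174 FL
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "VelocitySummary",
    "DopplerIndices",
    "Biometry",
    "compute_sd_ratio",
    "compute_ri",
    "compute_pi",
    "compute_cpr",
    "hadlock_efw",
    "indices_from_summary",
]

#: Hadlock-IV regression coefficients (log10 grams; lengths in cm).
HADLOCK_INTERCEPT = 1.3596
HADLOCK_AC_FL = -0.00386
HADLOCK_HC = 0.0064
HADLOCK_BPD_AC = 0.00061
HADLOCK_AC = 0.0424
HADLOCK_FL = 0.174


@dataclass(frozen=True)
class VelocitySummary:
    """Per-cycle velocity summary (cm/s).

    ``edv`` may be 0 (absent end-diastolic flow) or negative (reversed).
    """

    psv: float
    edv: float
    tav: float | None = None


@dataclass(frozen=True)
class DopplerIndices:
    """Dimensionless Doppler indices; ``sd_ratio`` is NaN when EDV <= 0."""

    sd_ratio: float
    pi: float
    ri: float

    @property
    def edv_absent(self) -> bool:
        return math.isnan(self.sd_ratio)


@dataclass(frozen=True)
class Biometry:
    """Fetal biometric measurements in cm."""

    bpd: float
    hc: float
    ac: float
    fl: float


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def compute_sd_ratio(v: VelocitySummary) -> float:
    """Systolic-to-diastolic ratio PSV/EDV.

    Returns NaN (the absent-EDV marker) when EDV <= 0, where the ratio
    is undefined/divergent.  Raises ``ValueError`` on non-finite inputs.
    """
    psv = _require_finite("psv", v.psv)
    edv = _require_finite("edv", v.edv)
    if edv <= 0.0:
        return math.nan
    return psv / edv


def compute_ri(v: VelocitySummary) -> float:
    """Resistance index (PSV - EDV)/PSV; requires PSV > 0.

    Equals ``1 - 1/(S/D)`` for EDV > 0, exactly 1 at absent EDV, and
    exceeds 1 for reversed end-diastolic flow.
    """
    psv = _require_finite("psv", v.psv)
    edv = _require_finite("edv", v.edv)
    if psv <= 0.0:
        raise ValueError(f"psv must be > 0 for the resistance index, got {psv}")
    return (psv - edv) / psv


def compute_pi(v: VelocitySummary) -> float:
    """Pulsatility index (PSV - EDV)/TAV; requires TAV > 0."""
    psv = _require_finite("psv", v.psv)
    edv = _require_finite("edv", v.edv)
    if v.tav is None:
        raise ValueError("pulsatility index requires a time-averaged velocity")
    tav = _require_finite("tav", v.tav)
    if tav <= 0.0:
        raise ValueError(f"tav must be > 0 for the pulsatility index, got {tav}")
    return (psv - edv) / tav


def compute_cpr(pi_mca: float, pi_ua: float) -> float:
    """Cerebroplacental ratio: MCA pulsatility index over UA pulsatility index."""
    pi_mca = _require_finite("pi_mca", pi_mca)
    pi_ua = _require_finite("pi_ua", pi_ua)
    if pi_ua <= 0.0:
        raise ValueError(f"pi_ua must be > 0, got {pi_ua}")
    return pi_mca / pi_ua


def indices_from_summary(v: VelocitySummary) -> DopplerIndices:
    """All three Doppler indices from one velocity summary."""
    return DopplerIndices(
        sd_ratio=compute_sd_ratio(v),
        pi=compute_pi(v),
        ri=compute_ri(v),
    )


def hadlock_efw(b: Biometry) -> tuple[float, float]:
    """Hadlock-IV estimated fetal weight.

    Parameters
    ----------
    b
        Biometry in cm (BPD, HC, AC, FL), all >= 0.

    Returns
    -------
    (efw_g, log_weight)
        Estimated fetal weight in grams and the log10-weight regression
        value it was exponentiated from.
    """
    for name in ("bpd", "hc", "ac", "fl"):
        val = _require_finite(name, getattr(b, name))
        if val < 0:
            raise ValueError(f"{name} must be >= 0 cm, got {val}")
    log_weight = (
        HADLOCK_INTERCEPT
        + HADLOCK_AC_FL * b.ac * b.fl
        + HADLOCK_HC * b.hc
        + HADLOCK_BPD_AC * b.bpd * b.ac
        + HADLOCK_AC * b.ac
        + HADLOCK_FL * b.fl
    )
    return 10.0 ** log_weight, log_weight
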