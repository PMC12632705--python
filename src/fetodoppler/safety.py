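"""Acoustic-output calculators for ultrasound exposure assessment.

Hydrophone sensitivity conversions (dB re 1 V/uPa to V/Pa, capacitive
loading of the preamplifier chain), pulse intensity metrics (Isppa,
Ispta, peak rarefactional pressure), FDA-convention derating
(0.3 dB/(cm MHz) soft tissue), the mechanical index, and acoustic power
integration over the beam cross-section of a hydrophone plane scan.

Units: pressures in Pa (MPa where noted), intensities in W/cm^2,
frequencies in MHz for the carrier and Hz for the PRF, grid spacing in
mm, power in mW.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HydrophoneCalibration",
    "IntensityMetrics",
    "sensitivity_from_db",
    "loaded_sensitivity",
    "intensity_metrics",
    "derate",
    "mechanical_index",
    "power_from_plane",
]

DENSITY_KG_M3 = 1000.0
SOUND_SPEED_M_S = 1540.0
FDA_DERATING_DB_CM_MHZ = 0.3


@dataclass(frozen=True)
class HydrophoneCalibration:
    """Hydrophone + preamplifier chain calibration.

    ``mc_db``: end-of-cable open-circuit sensitivity in dB re 1 V/uPa;
    ``gain_db``: preamplifier gain; capacitances in pF (hydrophone,
    preamplifier, right-angle adapter).
    """

    mc_db: float
    gain_db: float = 20.0
    ch_pf: float = 70.0
    ca_pf: float = 7.0
    cc_pf: float = 1.6

    @property
    def mc(self) -> float:
        """Open-circuit sensitivity in V/Pa."""
        return sensitivity_from_db(self.mc_db)

    @property
    def ml(self) -> float:
        """Loaded sensitivity in V/Pa."""
        return loaded_sensitivity(
            self.mc, 10.0 ** (self.gain_db / 20.0), self.ch_pf, self.ca_pf, self.cc_pf
        )


@dataclass(frozen=True)
class IntensityMetrics:
    """Pulse intensity summary at one field point."""

    isppa_w_cm2: float
    ispta_w_cm2: float
    pr_mpa: float
    pulse_duration_s: float
    pii_j_cm2: float


def sensitivity_from_db(mc_db: float) -> float:
    """Convert dB re 1 V/uPa to V/Pa: 10^((mc_db + 120) / 20)."""
    if not math.isfinite(mc_db):
        raise ValueError("sensitivity in dB must be finite")
    return 10.0 ** ((mc_db + 120.0) / 20.0)


def loaded_sensitivity(
    mc: float, gain: float, ch_pf: float, ca_pf: float, cc_pf: float
) -> float:
    """Loaded sensitivity ML = G * MC * CH / (CH + CA + CC) in V/Pa.

    ``gain`` is the linear preamplifier gain; capacitances in pF
    (hydrophone, preamplifier, adapter), all > 0 except the loads which
    may be 0 in the unloaded limit.
    """
    if ch_pf <= 0 or ca_pf < 0 or cc_pf < 0:
        raise ValueError("capacitances must be positive (loads may be 0)")
    return gain * mc * ch_pf / (ch_pf + ca_pf + cc_pf)


def intensity_metrics(
    pressure_pa,
    sample_rate: float,
    prf: float,
    density: float = DENSITY_KG_M3,
    sound_speed: float = SOUND_SPEED_M_S,
    pulse_fraction: float = 0.9,
) -> IntensityMetrics:
    """Pulse intensity metrics from a single-pulse pressure waveform.

    Instantaneous intensity i = p^2 / (rho c).  The pulse window is the
    central ``pulse_fraction`` of the pulse intensity integral (PII);
    Isppa is the mean intensity over that window, Ispta = PII * PRF, and
    the peak rarefactional pressure is -min(p).
    """
    p = np.asarray(pressure_pa, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("pressure waveform must be a 1-D array of >= 2 samples")
    if density <= 0 or sound_speed <= 0:
        raise ValueError("density and sound speed must be > 0")
    if sample_rate <= 0 or prf <= 0:
        raise ValueError("sample_rate and prf must be > 0")
    dt = 1.0 / sample_rate
    i_w_cm2 = p**2 / (density * sound_speed) / 1e4  # W/m^2 -> W/cm^2
    pii = float(i_w_cm2.sum() * dt)
    if pii == 0.0:
        return IntensityMetrics(0.0, 0.0, float(-p.min() / 1e6), 0.0, 0.0)

    cum = np.cumsum(i_w_cm2) * dt
    tail = (1.0 - pulse_fraction) / 2.0
    t_lo = float(np.searchsorted(cum, tail * pii)) * dt
    t_hi = float(np.searchsorted(cum, (1.0 - tail) * pii) + 1) * dt
    pd_s = t_hi - t_lo
    isppa = pulse_fraction * pii / pd_s
    return IntensityMetrics(
        isppa_w_cm2=isppa,
        ispta_w_cm2=pii * prf,
        pr_mpa=float(-p.min() / 1e6),
        pulse_duration_s=pd_s,
        pii_j_cm2=pii,
    )


def derate(
    value: float,
    depth_cm: float,
    carrier_mhz: float,
    coeff_db_cm_mhz: float = FDA_DERATING_DB_CM_MHZ,
    kind: str = "intensity",
) -> float:
    """Derate a water-tank value to estimated in-tissue exposure.

    Attenuation A = coeff * depth * carrier dB; pressure scales by
    10^(-A/20), intensity by 10^(-A/10).
    """
    if depth_cm < 0:
        raise ValueError("depth must be >= 0 cm")
    a_db = coeff_db_cm_mhz * depth_cm * carrier_mhz
    if kind == "pressure":
        return value * 10.0 ** (-a_db / 20.0)
    if kind == "intensity":
        return value * 10.0 ** (-a_db / 10.0)
    raise ValueError("kind must be 'pressure' or 'intensity'")


def mechanical_index(pr_derated_mpa: float, carrier_mhz: float) -> float:
    """Mechanical index: derated peak rarefactional pressure / sqrt(f)."""
    if pr_derated_mpa < 0:
        raise ValueError("peak rarefactional pressure must be >= 0 MPa")
    if carrier_mhz <= 0:
        raise ValueError("carrier frequency must be > 0 MHz")
    return pr_derated_mpa / math.sqrt(carrier_mhz)


def power_from_plane(
    intensity_w_cm2, spacing_mm: float, cutoff_db: float = -26.2
) -> float:
    """Acoustic power (mW) integrated over a transverse plane scan.

    Sums intensity x pixel area over pixels whose intensity is at least
    ``cutoff_db`` relative to the plane peak (the beam cross-section).
    """
    grid = np.asarray(intensity_w_cm2, dtype=float)
    if grid.size == 0:
        raise ValueError("empty intensity grid")
    if spacing_mm <= 0:
        raise ValueError("grid spacing must be > 0 mm")
    peak = float(grid.max())
    if peak <= 0.0:
        warnings.warn("all-zero intensity plane: zero power")
        return 0.0
    mask = grid >= peak * 10.0 ** (cutoff_db / 10.0)
    area_cm2 = (spacing_mm**2) / 100.0
    return float(grid[mask].sum() * area_cm2 * 1000.0)
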