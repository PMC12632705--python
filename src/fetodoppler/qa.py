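"""Image quality-assurance metrics for phantom characterization.

Pixel spacing, full-width-at-half-maximum spatial resolution, dynamic
range from greyscale contrast targets, contrast-to-noise ratio, and
spectral-Doppler velocity accuracy against a known pump velocity.  CNR
and dynamic range operate on displayed (log-compressed) greyscale
images, not raw RF or I/Q data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "pixel_spacing",
    "fwhm_resolution",
    "cnr",
    "dynamic_range",
    "doppler_velocity_accuracy",
]


def pixel_spacing(
    depth: float,
    n_axial: int,
    n_lateral: int,
    width: float | None = None,
) -> tuple[float, float]:
    """Adjacent-pixel spacing (dy, dx) of a reconstructed image.

    dy = depth / (n_axial - 1); dx uses the lateral extent ``width``
    (defaulting to ``depth`` for a square field of view).
    """
    if n_axial < 2 or n_lateral < 2:
        raise ValueError("need >= 2 pixels per direction")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    lateral_extent = depth if width is None else width
    return depth / (n_axial - 1), lateral_extent / (n_lateral - 1)


def fwhm_resolution(
    profile, spacing: float, background: float | None = None
) -> float:
    """Full width at half maximum of a point-spread profile, in mm.

    ``background`` defaults to the median of the outer 10% of samples on
    each side (the profile tails).  The half-maximum crossings are
    located with sub-sample linear interpolation.  A profile whose
    maximum is ambiguous (two disjoint equal maxima) or not above
    background raises ``ValueError``.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 5:
        raise ValueError("profile must be a 1-D array of >= 5 samples")
    if background is None:
        k = max(1, p.size // 10)
        background = float(np.median(np.concatenate([p[:k], p[-k:]])))
    peak = float(p.max())
    if peak <= background:
        raise ValueError("no peak above background")
    maxima = np.nonzero(p == peak)[0]
    if np.any(np.diff(maxima) > 1):
        raise ValueError("ambiguous peak: disjoint equal maxima")
    half = background + 0.5 * (peak - background)

    left_peak, right_peak = maxima[0], maxima[-1]
    below_left = np.nonzero(p[:left_peak] < half)[0]
    below_right = np.nonzero(p[right_peak:] < half)[0]
    if below_left.size == 0 or below_right.size == 0:
        raise ValueError("peak not resolved: profile never drops below half maximum")
    i = below_left[-1]  # linear interpolation at the crossings
    x_left = i + (half - p[i]) / (p[i + 1] - p[i])
    j = right_peak + below_right[0]
    x_right = j - 1 + (half - p[j - 1]) / (p[j] - p[j - 1])
    return float((x_right - x_left) * spacing)


def cnr(img, inside_mask, outside_mask) -> float:
    """Contrast-to-noise ratio of a target region vs background.

    (mu_in - mu_out) / sqrt(sigma_in^2 + sigma_out^2) on displayed pixel
    intensities.  Returns NaN when both regions have zero variance.
    """
    img = np.asarray(img, dtype=float)
    m_in = np.asarray(inside_mask, dtype=bool)
    m_out = np.asarray(outside_mask, dtype=bool)
    if m_in.shape != img.shape or m_out.shape != img.shape:
        raise ValueError("masks must match the image shape")
    if not m_in.any() or not m_out.any():
        raise ValueError("masks must be nonempty")
    if np.any(m_in & m_out):
        raise ValueError("inside and outside masks must be disjoint")
    mu_in, mu_out = img[m_in].mean(), img[m_out].mean()
    var_in, var_out = img[m_in].var(), img[m_out].var()
    denom = np.sqrt(var_in + var_out)
    if denom == 0.0:
        return float("nan")
    return float((mu_in - mu_out) / denom)


def dynamic_range(target_means, nominal_contrasts) -> float:
    """Dynamic range (dB) from greyscale contrast targets.

    Least-squares line of grey value vs nominal contrast (dB),
    extrapolated to grey 255 and 0; the dynamic range is
    contrast(255) - contrast(0) = 255 / slope.
    """
    grey = np.asarray(target_means, dtype=float)
    contrast = np.asarray(nominal_contrasts, dtype=float)
    if grey.shape != contrast.shape or grey.size < 2:
        raise ValueError("need >= 2 paired (grey, contrast) targets")
    if np.ptp(contrast) == 0:
        raise ValueError("singular fit: all nominal contrasts equal")
    slope, _ = np.polyfit(contrast, grey, 1)
    if slope == 0:
        raise ValueError("singular fit: zero grey-vs-contrast slope")
    return float(255.0 / slope)


def doppler_velocity_accuracy(measured, nominal) -> pd.DataFrame:
    """Per-condition percent error of measured vs nominal velocities."""
    m = np.asarray(measured, dtype=float)
    n = np.asarray(nominal, dtype=float)
    if m.shape != n.shape or m.ndim != 1:
        raise ValueError("measured and nominal must be equal-length vectors")
    if np.any(n == 0):
        raise ValueError("nominal velocities must be nonzero")
    return pd.DataFrame(
        {
            "measured_cms": m,
            "nominal_cms": n,
            "percent_error": (m - n) / n * 100.0,
        }
    )
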