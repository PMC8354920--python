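"""Point-spread-function and motion-direction resolution estimation.

A printed reference line of known width ``b_line`` is scanned under the
sensor.  Modelling both the line and the system PSF as Gaussians, the
measured transit is their convolution, so the widths deconvolve as

    sigma_psf = sqrt(sigma_meas^2 - sigma_line^2)

with ``sigma_meas`` obtained from the counted full width at half maximum
(``FWHM = 2 sqrt(2 ln 2) sigma``) and ``sigma_line = b_line / 6`` (the
optical line width is taken to contain 6 sigma of the line's Gaussian
because of its steep edges).  Frames convert to length through
``k = v / f`` (stage speed over frame rate), in µm per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateProfileError,
    DomainError,
    NonPhysicalDeconvolutionError,
)

#: FWHM of a unit-σ Gaussian
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class LineScanProfile:
    """1-D intensity transit of the reference line, one sample per frame."""

    intensity: np.ndarray
    frame_rate: float = 111.0
    stage_speed: float = 200.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size < 5:
            raise DomainError("line-scan profile needs at least 5 samples")


@dataclass(frozen=True)
class PSFEstimate:
    """Gaussian widths of the resolution analysis, all in µm."""

    sigma_meas: float
    sigma_line: float
    sigma_psf: float
    n_fwhm: int
    k: float
    b_line: float

    @property
    def sigma_psf_mm(self) -> float:
        return self.sigma_psf / 1000.0


def pixel_scale(stage_speed: float, frame_rate: float) -> float:
    """µm travelled per frame, ``k = v / f``."""
    if stage_speed <= 0 or frame_rate <= 0:
        raise DomainError("stage_speed and frame_rate must both be > 0")
    return stage_speed / frame_rate


def sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian σ from its full width at half maximum."""
    if fwhm <= 0:
        raise DomainError("FWHM must be > 0")
    return fwhm / FWHM_FACTOR


def fwhm_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_fwhm`."""
    if sigma <= 0:
        raise DomainError("sigma must be > 0")
    return FWHM_FACTOR * sigma


def _baseline(intensity: np.ndarray) -> float:
    """Median of the first and last 10% of samples (≥ 1 sample each end)."""
    n_edge = max(1, intensity.size // 10)
    edges = np.concatenate([intensity[:n_edge], intensity[-n_edge:]])
    return float(np.median(edges))


def count_fwhm_pixels(
    profile: LineScanProfile | np.ndarray, *, interpolate: bool = False
) -> int | float:
    """Number of frames at or above half the peak's baseline-subtracted height.

    Polarity (dark line on bright background or the reverse) is detected by
    comparing the extremum against the baseline.  The default is a plain
    integer count of samples, no sub-pixel interpolation; ``interpolate=True``
    returns instead the fractional width between the linearly interpolated
    half-maximum crossings (used by the round-trip oracles).
    """
    intensity = (
        profile.intensity if isinstance(profile, LineScanProfile) else
        np.asarray(profile, dtype=float)
    )
    base = _baseline(intensity)
    signed = intensity - base
    if np.max(np.abs(signed)) == 0:
        raise DegenerateProfileError("profile has no peak above baseline")
    # auto-detect polarity: flip so the dominant extremum is positive
    if abs(signed.min()) > abs(signed.max()):
        signed = -signed
    peak = signed.max()
    if peak <= 0:
        raise DegenerateProfileError("profile has no peak above baseline")
    half = 0.5 * peak
    above = signed >= half
    if not interpolate:
        return int(np.count_nonzero(above))
    # fractional width between the outermost half-max crossings
    idx = np.flatnonzero(above)
    left, right = idx[0], idx[-1]
    x_left = float(left)
    if left > 0:
        y0, y1 = signed[left - 1], signed[left]
        x_left = left - (y1 - half) / (y1 - y0)
    x_right = float(right)
    if right < signed.size - 1:
        y0, y1 = signed[right], signed[right + 1]
        x_right = right + (y0 - half) / (y0 - y1)
    return float(x_right - x_left)


def estimate_psf(n_fwhm: float, k: float, b_line: float) -> PSFEstimate:
    """Deconvolve the system PSF width from a counted line transit.

    Parameters
    ----------
    n_fwhm:
        frames counted at full width half maximum.
    k:
        µm per frame (``pixel_scale``), kept an explicit input.
    b_line:
        optical width of the reference line in µm (contains 6σ of the
        line's Gaussian).
    """
    if n_fwhm < 1:
        raise DomainError("n_fwhm must be ≥ 1")
    if k <= 0:
        raise DomainError("k must be > 0")
    if b_line < 0:
        raise DomainError("b_line must be ≥ 0")
    sigma_meas = n_fwhm * k / FWHM_FACTOR
    sigma_line = b_line / 6.0
    if sigma_meas <= sigma_line:
        raise NonPhysicalDeconvolutionError(
            f"measured σ {sigma_meas:.3g} µm not wider than line σ "
            f"{sigma_line:.3g} µm; deconvolution impossible"
        )
    sigma_psf = float(np.sqrt(sigma_meas**2 - sigma_line**2))
    return PSFEstimate(
        sigma_meas=float(sigma_meas),
        sigma_line=float(sigma_line),
        sigma_psf=sigma_psf,
        n_fwhm=int(round(n_fwhm)) if float(n_fwhm).is_integer() else n_fwhm,
        k=float(k),
        b_line=float(b_line),
    )


def estimate_psf_from_profile(
    profile: LineScanProfile, k: float, b_line: float
) -> PSFEstimate:
    """Count the FWHM on a transit profile and deconvolve in one step."""
    n = count_fwhm_pixels(profile)
    return estimate_psf(n, k, b_line)


def simulate_line_transit(
    sigma_psf: float,
    b_line: float,
    k: float,
    *,
    phase: float = 0.5,
    depth: float = 0.8,
    background: float = 1.0,
    margin_factor: float = 14.0,
    fine_step: float = 1.0,
) -> LineScanProfile:
    """Forward-model a dark-line transit for round-trip validation.

    The line is a 6σ-truncated Gaussian of optical width ``b_line``
    (σ_line = b_line/6, support ±b_line/2), convolved with a Gaussian PSF of
    width ``sigma_psf``; the result is sampled every ``k`` µm at sub-sample
    offset ``phase`` (0.5 centres the peak midway between two frames, the
    least biased position for an integer count).  Returns a bright-background
    profile with the line as an absorption dip of relative ``depth``.
    """
    if sigma_psf <= 0 or b_line < 0 or k <= 0:
        raise DomainError("sigma_psf, k must be > 0 and b_line ≥ 0")
    sigma_line = b_line / 6.0
    half_span = margin_factor * max(sigma_psf, sigma_line, k)
    x = np.arange(-half_span, half_span + fine_step, fine_step)
    if b_line > 0:
        line = np.where(
            np.abs(x) <= b_line / 2.0,
            np.exp(-0.5 * (x / sigma_line) ** 2),
            0.0,
        )
    else:
        line = np.zeros_like(x)
        line[np.argmin(np.abs(x))] = 1.0
    psf = np.exp(-0.5 * (x / sigma_psf) ** 2)
    meas = np.convolve(line, psf, mode="same")
    meas /= meas.max()
    # push-broom sampling every k µm, peak centred between samples
    n_side = int(np.floor((half_span - phase * k) / k))
    samples = (np.arange(-n_side, n_side + 1) + phase) * k
    vals = np.interp(samples, x, meas)
    intensity = background * (1.0 - depth * vals)
    return LineScanProfile(intensity=intensity)
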