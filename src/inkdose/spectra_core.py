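"""Core data model for push-broom NIR hyperspectral cubes.

A cube is indexed ``(frame, spatial_px, wavelength)``: axis 0 is the stage
travel direction (one frame per line acquired), axis 1 the 320-pixel sensor
line across the travel direction, axis 2 the wavelength axis (930–1700 nm for
the instrument class modelled here).  Reflectance counts are converted to
absorbance against white/black reference spectra with the standard
reflectance-mode relation ``A = -log10((S - D) / (W - D))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import (
    BoundsError,
    ConfigError,
    DimensionError,
    DomainError,
    EmptySelectionError,
    InvalidReferenceError,
    RangeError,
)

NIR_RANGE_NM = (930.0, 1700.0)

#: ratio floor applied before the log so dead pixels stay finite
DEFAULT_RATIO_FLOOR = 1e-6

RAW_REFLECTANCE = "raw_reflectance"
ABSORBANCE = "absorbance"


@dataclass
class HyperspectralCube:
    """3-D spectral image plus acquisition geometry.

    Parameters
    ----------
    data:
        ``(n_frames, n_spatial, n_wavelengths)`` array, reflectance counts or
        absorbance units depending on ``mode``.
    wavelengths:
        strictly increasing grid in nm, one entry per spectral plane.
    frame_rate:
        acquisition rate in frames/s (instrument default 111).
    stage_speed:
        linear-stage speed in µm/s (instrument default 200).
    pixel_pitch_across:
        across-track pixel footprint in µm/px (instrument default 114).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    frame_rate: float = 111.0
    stage_speed: float = 200.0
    pixel_pitch_across: float = 114.0
    mode: str = RAW_REFLECTANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(f"cube data must be 3-D, got {self.data.ndim}-D")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise DimensionError(
                f"wavelength grid length {self.wavelengths.size} does not match "
                f"spectral axis {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DomainError("wavelength grid must be strictly increasing")
        if self.frame_rate <= 0:
            raise DomainError("frame_rate must be > 0")
        if self.stage_speed < 0:
            raise DomainError("stage_speed must be ≥ 0")
        if self.mode not in (RAW_REFLECTANCE, ABSORBANCE):
            raise ConfigError(f"unknown cube mode {self.mode!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_spatial(self) -> int:
        return self.data.shape[1]

    @property
    def n_wavelengths(self) -> int:
        return self.data.shape[2]

    @property
    def pixel_pitch_along(self) -> float:
        """Along-track pixel footprint in µm/px, v/f."""
        return self.stage_speed / self.frame_rate

    def spectra(self) -> np.ndarray:
        """Flattened ``(n_frames * n_spatial, n_wavelengths)`` view-copy."""
        return self.data.reshape(-1, self.n_wavelengths)

    def with_data(self, data: np.ndarray, **changes) -> "HyperspectralCube":
        """Copy of the cube with new data (and optional field changes)."""
        return replace(self, data=data, meta=dict(self.meta), **changes)


@dataclass
class ReferencePair:
    """White and black reference spectra.

    Stored per spatial pixel, shape ``(n_spatial, n_wavelengths)``; a single
    mean spectrum ``(n_wavelengths,)`` is accepted and broadcast across the
    sensor line.
    """

    white: np.ndarray
    black: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.atleast_2d(np.asarray(self.white, dtype=float))
        self.black = np.atleast_2d(np.asarray(self.black, dtype=float))

    def aligned(self, cube: HyperspectralCube) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast references against ``cube``'s (spatial, wavelength) axes."""
        target = (cube.n_spatial, cube.n_wavelengths)
        try:
            white = np.broadcast_to(self.white, target)
            black = np.broadcast_to(self.black, target)
        except ValueError as exc:
            raise DimensionError(
                f"references {self.white.shape} not alignable with cube "
                f"(spatial, wavelength) = {target}"
            ) from exc
        return white, black


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open frame/spatial ranges plus an inclusive wavelength window."""

    frame_range: tuple[int, int]
    spatial_range: tuple[int, int]
    wavelength_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        f0, f1 = self.frame_range
        s0, s1 = self.spatial_range
        if f0 >= f1 or s0 >= s1:
            raise BoundsError("ROI ranges must be non-empty half-open intervals")
        if self.wavelength_window is not None:
            lo, hi = self.wavelength_window
            if not lo < hi:
                raise BoundsError("wavelength window must satisfy λ_lo < λ_hi")


def compute_absorbance(
    raw: HyperspectralCube,
    refs: ReferencePair,
    *,
    ratio_floor: float = DEFAULT_RATIO_FLOOR,
) -> HyperspectralCube:
    """Convert a raw reflectance cube to absorbance.

    ``A = -log10((S - D) / (W - D))`` per pixel and wavelength, with the ratio
    clipped from below at ``ratio_floor`` so dead/dark pixels stay finite.
    The number of clipped elements is recorded in ``meta['n_clipped']``.
    """
    if raw.mode != RAW_REFLECTANCE:
        raise InvalidReferenceError("compute_absorbance expects a raw reflectance cube")
    white, black = refs.aligned(raw)
    denom = white - black
    if np.any(denom <= 0):
        raise InvalidReferenceError(
            "white reference must exceed black reference on every used pixel"
        )
    ratio = (raw.data - black[None, :, :]) / denom[None, :, :]
    n_clipped = int(np.count_nonzero(ratio < ratio_floor))
    absorb = -np.log10(np.clip(ratio, ratio_floor, None))
    out = raw.with_data(absorb, mode=ABSORBANCE)
    out.meta["n_clipped"] = n_clipped
    out.meta["ratio_floor"] = ratio_floor
    return out


def invert_absorbance(
    cube: HyperspectralCube, refs: ReferencePair
) -> HyperspectralCube:
    """Inverse transform ``S = D + (W - D)·10^(-A)`` (used by the simulator)."""
    if cube.mode != ABSORBANCE:
        raise InvalidReferenceError("invert_absorbance expects an absorbance cube")
    white, black = refs.aligned(cube)
    counts = black[None, :, :] + (white - black)[None, :, :] * 10.0 ** (-cube.data)
    return cube.with_data(counts, mode=RAW_REFLECTANCE)


def restrict_wavelengths(
    cube: HyperspectralCube, window: Sequence[float]
) -> HyperspectralCube:
    """Keep exactly the wavelengths λ with λ_lo ≤ λ ≤ λ_hi (order preserved)."""
    lo, hi = float(window[0]), float(window[1])
    sel = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not np.any(sel):
        raise EmptySelectionError(
            f"window [{lo}, {hi}] nm selects no wavelengths from grid "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
        )
    return cube.with_data(cube.data[:, :, sel], wavelengths=cube.wavelengths[sel])


def extract_roi(cube: HyperspectralCube, roi: RegionOfInterest) -> HyperspectralCube:
    """Crop the cube to an ROI; acquisition metadata is preserved."""
    f0, f1 = roi.frame_range
    s0, s1 = roi.spatial_range
    if f0 < 0 or s0 < 0 or f1 > cube.n_frames or s1 > cube.n_spatial:
        raise BoundsError(
            f"ROI frames [{f0},{f1}) spatial [{s0},{s1}) outside cube "
            f"{cube.n_frames}×{cube.n_spatial}"
        )
    out = cube.with_data(cube.data[f0:f1, s0:s1, :])
    if roi.wavelength_window is not None:
        out = restrict_wavelengths(out, roi.wavelength_window)
    return out


def nearest_wavelength_index(grid: np.ndarray, wavelength: float) -> int:
    """Index of the grid wavelength nearest the request; ties break low."""
    if wavelength < grid[0] or wavelength > grid[-1]:
        raise RangeError(
            f"wavelength {wavelength} nm outside grid [{grid[0]}, {grid[-1]}] nm"
        )
    dist = np.abs(grid - wavelength)
    # argmin returns the first (lower-wavelength) index on exact ties
    return int(np.argmin(dist))


def peak_intensity_image(cube: HyperspectralCube, wavelength: float) -> np.ndarray:
    """2-D (frame × spatial) image at the grid wavelength nearest the request.

    Used for background masking and for the peak-absorption display at
    1515 nm.
    """
    idx = nearest_wavelength_index(cube.wavelengths, wavelength)
    return cube.data[:, :, idx].copy()
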