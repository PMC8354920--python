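"""Per-pixel spectral pretreatments applied before calibration.

The default pipeline mirrors common reflectance-NIR practice for scatter-
affected samples: restrict to the informative window (1200–1600 nm), remove
multiplicative scatter with the standard normal variate transform, then take
a Savitzky-Golay derivative (order-2 polynomial, 35-point window) to strip
baseline offsets and sharpen band structure.  Steps are configurable and the
resolved configuration travels with every cube and model as a "preprocess
card" so train/predict consistency can be enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from . import spectra_core as sc
from .errors import ConfigError, LengthError, ZeroVarianceError

VALID_STEPS = ("restrict", "snv", "savgol")


@dataclass
class PreprocessConfig:
    """Resolved pretreatment settings.

    wavelength_window : (nm, nm)
        inclusive window kept before any statistic is computed (default
        1200–1600 nm so SNV statistics are confined to the modelled range).
    sg_order, sg_window, sg_deriv :
        Savitzky-Golay polynomial order (2), window length in points (35,
        odd) and derivative order (1).
    sg_delta :
        abscissa spacing used for derivative scaling; ``None`` means the
        cube's mean wavelength step in nm.
    pipeline_order :
        ordered step names from ``{"restrict", "snv", "savgol"}``; steps
        absent from the list are skipped.
    """

    wavelength_window: tuple[float, float] = (1200.0, 1600.0)
    sg_order: int = 2
    sg_window: int = 35
    sg_deriv: int = 1
    sg_delta: float | None = None
    apply_snv: bool = True
    pipeline_order: tuple[str, ...] = ("restrict", "snv", "savgol")

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ConfigError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_window <= self.sg_order:
            raise ConfigError("sg_window must exceed sg_order")
        if self.sg_deriv > self.sg_order:
            raise ConfigError("sg_deriv must not exceed sg_order")
        lo, hi = self.wavelength_window
        if not lo < hi:
            raise ConfigError("wavelength_window must satisfy λ_lo < λ_hi")
        unknown = set(self.pipeline_order) - set(VALID_STEPS)
        if unknown:
            raise ConfigError(f"unknown pipeline steps: {sorted(unknown)}")
        if not self.apply_snv:
            self.pipeline_order = tuple(
                s for s in self.pipeline_order if s != "snv"
            )

    def card(self) -> dict:
        """JSON-serialisable record of the resolved configuration."""
        return {
            "wavelength_window": [float(w) for w in self.wavelength_window],
            "sg_order": int(self.sg_order),
            "sg_window": int(self.sg_window),
            "sg_deriv": int(self.sg_deriv),
            "sg_delta": None if self.sg_delta is None else float(self.sg_delta),
            "apply_snv": bool(self.apply_snv),
            "pipeline_order": list(self.pipeline_order),
        }

    @classmethod
    def from_card(cls, card: dict) -> "PreprocessConfig":
        return cls(
            wavelength_window=tuple(card["wavelength_window"]),
            sg_order=card["sg_order"],
            sg_window=card["sg_window"],
            sg_deriv=card["sg_deriv"],
            sg_delta=card.get("sg_delta"),
            apply_snv=card.get("apply_snv", True),
            pipeline_order=tuple(card["pipeline_order"]),
        )


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale to unit sample sd (n−1)."""
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise LengthError("SNV needs a 1-D spectrum of length ≥ 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("SNV undefined for a constant spectrum")
    return (x - x.mean()) / sd


def _snv_matrix(spectra: np.ndarray) -> np.ndarray:
    """Vectorised SNV along the last axis; raises on any constant spectrum."""
    mean = spectra.mean(axis=-1, keepdims=True)
    sd = spectra.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.argwhere(sd[..., 0] == 0)
        raise ZeroVarianceError(
            f"SNV undefined for constant spectra at pixel(s) {bad[:5].tolist()}"
        )
    return (spectra - mean) / sd


def savitzky_golay(
    spectrum: np.ndarray,
    order: int = 2,
    window: int = 35,
    deriv: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation of one spectrum.

    Each interior point is the ``deriv``-th derivative at the centre of a
    local least-squares polynomial of the given order over the window.  Edge
    points come from the same-order polynomial fitted over the terminal full
    window and evaluated at the edge abscissae (no reflection padding, so no
    fabricated data enters the model).
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    if window <= order:
        raise ConfigError("window must exceed polynomial order")
    if x.shape[-1] < window:
        raise LengthError(
            f"spectrum length {x.shape[-1]} shorter than window {window}"
        )
    return savgol_filter(
        x, window_length=window, polyorder=order, deriv=deriv, delta=delta,
        axis=-1, mode="interp",
    )


def preprocess_cube(
    cube: sc.HyperspectralCube, cfg: PreprocessConfig
) -> sc.HyperspectralCube:
    """Apply the configured pretreatment chain to every pixel spectrum.

    Steps run in ``cfg.pipeline_order``; the resolved card is recorded in
    ``meta['preprocess']`` so prediction can verify train/predict parity.
    """
    if cube.mode != sc.ABSORBANCE:
        raise ConfigError("preprocess_cube expects an absorbance-mode cube")
    out = cube.with_data(cube.data.copy())
    for step in cfg.pipeline_order:
        if step == "restrict":
            out = sc.restrict_wavelengths(out, cfg.wavelength_window)
        elif step == "snv":
            out = out.with_data(_snv_matrix(out.data))
        elif step == "savgol":
            if cfg.sg_delta is not None:
                delta = cfg.sg_delta
            else:
                steps = np.diff(out.wavelengths)
                delta = float(steps.mean()) if steps.size else 1.0
            out = out.with_data(
                savitzky_golay(
                    out.data, cfg.sg_order, cfg.sg_window, cfg.sg_deriv, delta
                )
            )
    out.meta["preprocess"] = cfg.card()
    return out
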