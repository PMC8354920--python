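"""Pixel-wise concentration maps, dose integration and method comparison.

The fitted regression vector is applied to every preprocessed pixel spectrum
(`ŷ = y_mean + (x − x_mean)·β`), giving a frame × spatial map of API mass in
mg/px.  Summing the map over a printed-region mask yields the pattern dose,
which is compared against the printer's dispensed-volume estimate and the
external reference assay, with relative standard deviations across replicate
prints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .calibration import PLSModel
from .errors import EmptyRegionError, IncompatibleModelError
from .spectra_core import HyperspectralCube

#: single-drop mass at the printer's nominal settings: 415 pl × 250 mg/ml
NOMINAL_DROP_VOLUME_PL = 415.0
NOMINAL_INK_CONC_MG_ML = 250.0


@dataclass
class ConcentrationMap:
    """2-D field of predicted API mass per detector pixel.

    ``values`` are floored at zero (mass cannot be negative); the unfloored
    predictions are kept in ``raw_values`` so flooring bias stays observable.
    ``pixel_geometry`` is (along-track, across-track) µm/px.
    """

    values: np.ndarray
    mask: np.ndarray
    pixel_geometry: tuple[float, float]
    raw_values: np.ndarray | None = None
    floored_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise EmptyRegionError("mask shape must equal values shape")


@dataclass
class DoseEstimate:
    """Per-pattern dose summary with optional reference/printer comparisons."""

    pattern_id: str
    predicted_mass: float
    reference_mass: float | None = None
    printer_mass: float | None = None
    replicate_masses: list[float] = field(default_factory=list)

    @property
    def rsd(self) -> float | None:
        """Relative standard deviation (%) across replicates, n−1 sd."""
        return rsd_percent(self.replicate_masses)


def rsd_percent(values) -> float | None:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return None
    mean = values.mean()
    if mean == 0:
        return None
    return float(100.0 * values.std(ddof=1) / mean)


def predict_map(
    model: PLSModel,
    cube: HyperspectralCube,
    mask: np.ndarray | None = None,
) -> ConcentrationMap:
    """Apply the regression vector to every pixel of a preprocessed cube.

    The cube's preprocess card must match the model's; negatives are floored
    at zero with the floored fraction recorded.
    """
    card = cube.meta.get("preprocess")
    if model.preprocess_card is not None and card != model.preprocess_card:
        raise IncompatibleModelError(
            "cube preprocessing does not match the model's preprocess card"
        )
    flat = cube.spectra()
    raw = model.predict(flat).reshape(cube.n_frames, cube.n_spatial)
    floored_fraction = float(np.mean(raw < 0))
    values = np.maximum(raw, 0.0)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return ConcentrationMap(
        values=values,
        mask=mask,
        pixel_geometry=(cube.pixel_pitch_along, cube.pixel_pitch_across),
        raw_values=raw,
        floored_fraction=floored_fraction,
    )


def background_mask(
    image: np.ndarray,
    threshold: float | str = "otsu",
    *,
    min_size: int = 4,
) -> np.ndarray:
    """Segment printed-region pixels from an intensity image.

    ``threshold='otsu'`` picks the Otsu level; a float is used as a fixed
    cut.  Connected components smaller than ``min_size`` pixels are removed.
    An all-background image yields an empty mask with a warning, not an
    error.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise EmptyRegionError("mask source image must be finite")
    if image.max() == image.min():
        warnings.warn("image has no contrast; returning empty mask")
        return np.zeros_like(image, dtype=bool)
    level = threshold_otsu(image) if threshold == "otsu" else float(threshold)
    mask = image > level
    if min_size > 1:
        # drop connected components with fewer than min_size pixels
        mask = remove_small_objects(mask, max_size=min_size - 1)
    if not mask.any():
        warnings.warn("thresholding produced an empty mask")
    return mask


def integrate_dose(cmap: ConcentrationMap) -> float:
    """Total mass (mg) over the masked printed region."""
    if not cmap.mask.any():
        raise EmptyRegionError("dose integration over an empty mask")
    return float(cmap.values[cmap.mask].sum())


def printer_dose(
    n_drops: int,
    drop_volume_pl: float = NOMINAL_DROP_VOLUME_PL,
    ink_conc_mg_ml: float = NOMINAL_INK_CONC_MG_ML,
) -> float:
    """Dose implied by the printer's dispensed volume, in mg.

    ``n_drops × V_drop × c_ink``; 1 pl = 1e-9 ml, so the single-drop mass at
    nominal settings is 415e-9 ml × 250 mg/ml = 1.0375e-4 mg (103.75 ng).
    """
    if drop_volume_pl <= 0 or ink_conc_mg_ml <= 0:
        from .errors import DomainError

        raise DomainError("drop volume and ink concentration must be > 0")
    if n_drops < 0:
        from .errors import DomainError

        raise DomainError("n_drops must be ≥ 0")
    return n_drops * drop_volume_pl * 1e-9 * ink_conc_mg_ml


def compare_doses(estimates: list[DoseEstimate]) -> pd.DataFrame:
    """Tabulate predicted vs reference vs printer dose per pattern.

    Relative biases are in percent of the comparator; missing comparators
    leave the bias fields empty rather than failing.
    """
    if not estimates:
        raise EmptyRegionError("compare_doses needs at least one estimate")
    rows = []
    for est in estimates:
        row: dict = {
            "pattern_id": est.pattern_id,
            "predicted_mg": est.predicted_mass,
            "reference_mg": est.reference_mass,
            "printer_mg": est.printer_mass,
            "rsd_pct": est.rsd,
        }
        for name, other in (
            ("bias_vs_reference_pct", est.reference_mass),
            ("bias_vs_printer_pct", est.printer_mass),
        ):
            row[name] = (
                None
                if other in (None, 0)
                else 100.0 * (est.predicted_mass - other) / other
            )
        rows.append(row)
    return pd.DataFrame(rows)
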