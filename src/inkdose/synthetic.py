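"""Instrument-free generator for print patterns, deposits, cubes and maps.

Emulates the full measurement chain the analysis assumes:

* drop deposition — each printed drop lays down its sampled mass
  (volume × ink concentration) as a radially symmetric footprint with a
  center-high gradient and an optional coffee-ring annulus, on a fine
  (10 µm) raster; layers add linearly and per-drop mass closure is exact by
  construction (the discrete footprint kernel is normalised to sum to 1);
* NIR optics — Gaussian PSF blur, push-broom resampling to the detector
  grid (along-track pitch = stage speed / frame rate, across-track pitch =
  sensor pixel footprint), linear spectral mixing of substrate and API
  endmembers on an absorbance scale, per-pixel multiplicative scatter,
  conversion to reflectance counts against synthetic white/black
  references, additive detector noise;
* Raman mapping — a Lorentzian metformin band at 735 cm⁻¹ whose area is
  proportional to the mass inside each raster point's sampling footprint,
  on a sloped baseline, with replicate scans and additive noise;
* reference assay — ground-truth totals perturbed by multiplicative error
  with a quantification limit, standing in for HPLC.

Everything is deterministic given (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import spectra_core as sc
from .calibration import RamanMap
from .errors import ConfigError, DomainError

#: calibration-strip drop counts (spots along the stage direction)
DEFAULT_SPOT_DROPS = (10, 20, 30, 50, 100, 200, 300, 400, 500)


@dataclass(frozen=True)
class PrintPattern:
    """Printed layout: a calibration strip of spots or a multilayer square."""

    kind: str  # "calibration_strip" | "multilayer_square"
    spots: tuple[int, ...] = DEFAULT_SPOT_DROPS
    grid: tuple[int, int] = (17, 17)
    grid_spacing_um: float = 300.0
    n_layers: int = 1
    spot_pitch_um: float = 3200.0

    def __post_init__(self) -> None:
        if self.kind not in ("calibration_strip", "multilayer_square"):
            raise ConfigError(f"unknown pattern kind {self.kind!r}")
        if self.kind == "calibration_strip" and any(s <= 0 for s in self.spots):
            raise ConfigError("drop counts must be positive")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be ≥ 1")
        if self.grid_spacing_um <= 0 or self.spot_pitch_um <= 0:
            raise ConfigError("spacings must be > 0")


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition geometry and blur of the NIR push-broom imager.

    ``frame_binning`` co-adds that many successive raw frames into one
    stored line: the along-track pixel pitch grows by the factor and the
    per-line detector noise falls by its square root, exactly as when a
    slow stage (200 µm/s at 111 fps gives a 1.8 µm raw pitch) is binned to
    a coarser working grid.
    """

    psf_sigma_um: float = 154.0
    pixel_pitch_across_um: float = 114.0
    frame_rate: float = 111.0
    stage_speed_um_s: float = 200.0
    frame_binning: int = 1

    def __post_init__(self) -> None:
        if min(
            self.psf_sigma_um,
            self.pixel_pitch_across_um,
            self.frame_rate,
            self.stage_speed_um_s,
        ) <= 0:
            raise ConfigError("all optics parameters must be positive")
        if self.frame_binning < 1:
            raise ConfigError("frame_binning must be ≥ 1")

    @property
    def pitch_along_um(self) -> float:
        return self.stage_speed_um_s / self.frame_rate * self.frame_binning

    @property
    def effective_frame_rate(self) -> float:
        """Stored-line rate after binning, frames/s."""
        return self.frame_rate / self.frame_binning


@dataclass
class SpectralModel:
    """Linear mixing model on the absorbance scale.

    The substrate endmember is a broad, smoothly structured baseline
    (gelatin/TiO₂-like, overlapping water band near 1450 nm); the API
    endmember has its main band at 1515 nm.  ``mixing_coefficient`` converts
    areal API density into absorbance (AU per mg/mm², applied to pixel mass
    over pixel footprint so the optical response is independent of stage
    speed).  ``noise_sd`` is additive detector noise as a fraction of the
    background-subtracted signal; ``scatter_range`` bounds the per-pixel
    multiplicative scatter factor.
    """

    wavelengths: np.ndarray = dc_field(
        default_factory=lambda: np.arange(930.0, 1701.0, 5.0)
    )
    substrate_endmember: np.ndarray | None = None
    api_endmember: np.ndarray | None = None
    mixing_coefficient: float = 3.0
    noise_sd: float = 0.01
    scatter_range: tuple[float, float] = (0.97, 1.03)
    white_level: float = 30000.0
    black_level: float = 500.0

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        self.wavelengths = lam
        if self.substrate_endmember is None:
            self.substrate_endmember = (
                0.45
                + 0.25 * np.exp(-(((lam - 1450.0) / 70.0) ** 2))
                + 0.12 * np.exp(-(((lam - 1190.0) / 60.0) ** 2))
                + 0.10 * (lam - lam[0]) / (lam[-1] - lam[0])
            )
        if self.api_endmember is None:
            self.api_endmember = (
                np.exp(-(((lam - 1515.0) / 25.0) ** 2))
                + 0.30 * np.exp(-(((lam - 1210.0) / 35.0) ** 2))
            )
        self.substrate_endmember = np.asarray(self.substrate_endmember, float)
        self.api_endmember = np.asarray(self.api_endmember, float)
        if np.any(self.substrate_endmember < 0) or np.any(self.api_endmember < 0):
            raise ConfigError("endmembers must be non-negative")
        if self.mixing_coefficient <= 0:
            raise ConfigError("mixing_coefficient must be > 0")

    def references(self, n_spatial: int) -> sc.ReferencePair:
        """Synthetic white/black mean reference spectra (noise-free means)."""
        lam = self.wavelengths
        shape = 0.8 + 0.2 * np.exp(-(((lam - 1300.0) / 250.0) ** 2))
        white = np.broadcast_to(self.white_level * shape, (n_spatial, lam.size))
        black = np.full((n_spatial, lam.size), self.black_level)
        return sc.ReferencePair(white=white.copy(), black=black)


@dataclass(frozen=True)
class DepositionModel:
    """Per-drop mass and footprint statistics.

    Nominal drop volume 415 pl at 250 mg/ml ink (one drop = 103.75 ng API).
    ``center_excess`` ≥ 1 steepens the centre of the radial profile (a value
    of 1 gives a plain Gaussian); ``coffee_ring_fraction`` moves that share
    of each drop's mass into a rim annulus.
    """

    drop_volume_pl: float = 415.0
    drop_volume_sd_pl: float = 5.0
    ink_conc_mg_ml: float = 250.0
    drop_footprint_sigma_um: float = 150.0
    spot_spread_exponent: float = 0.25
    spot_spread_ref_drops: int = 10
    center_excess: float = 2.0
    coffee_ring_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.drop_volume_pl <= 0 or self.ink_conc_mg_ml <= 0:
            raise ConfigError("volume and concentration must be positive")
        if self.drop_volume_sd_pl < 0:
            raise ConfigError("volume sd must be ≥ 0")
        if self.center_excess < 1:
            raise ConfigError("center_excess must be ≥ 1")
        if not 0 <= self.coffee_ring_fraction <= 1:
            raise ConfigError("coffee_ring_fraction must be in [0, 1]")

    @property
    def mean_drop_mass_mg(self) -> float:
        return self.drop_volume_pl * 1e-9 * self.ink_conc_mg_ml

    def spot_sigma_um(self, n_drops: int) -> float:
        """Footprint σ of an n-drop puddle: drops printed on one position
        spread laterally, σ ∝ (n / n_ref)^exponent (sub-linear wetting)."""
        return self.drop_footprint_sigma_um * (
            max(n_drops, 1) / self.spot_spread_ref_drops
        ) ** self.spot_spread_exponent


@dataclass
class MassField:
    """Deposited API mass on a fine raster, mg per cell."""

    values: np.ndarray
    cell_um: float
    ground_truth: dict

    @property
    def total_mg(self) -> float:
        return float(self.values.sum())

    @property
    def extent_um(self) -> tuple[float, float]:
        return (
            self.values.shape[0] * self.cell_um,
            self.values.shape[1] * self.cell_um,
        )


def drop_kernel(
    dep: DepositionModel, cell_um: float, sigma_um: float | None = None
) -> np.ndarray:
    """Discrete single-drop footprint, normalised to sum exactly to 1.

    Radial profile: a mixture of a Gaussian of width ``drop_footprint_sigma``
    and (for ``center_excess`` > 1) a half-width Gaussian that steepens the
    centre, plus an optional rim annulus at 1.5 σ carrying the coffee-ring
    fraction.  Discrete normalisation makes per-drop mass closure exact.
    """
    sigma = dep.drop_footprint_sigma_um if sigma_um is None else sigma_um
    radius_cells = int(np.ceil(4.0 * sigma / cell_um))
    ax = (np.arange(-radius_cells, radius_cells + 1)) * cell_um
    r2 = ax[:, None] ** 2 + ax[None, :] ** 2
    w_core = 1.0 / dep.center_excess
    core = w_core * np.exp(-0.5 * r2 / sigma**2) + (1.0 - w_core) * np.exp(
        -0.5 * r2 / (sigma / 2.0) ** 2
    )
    core /= core.sum()
    kernel = (1.0 - dep.coffee_ring_fraction) * core
    if dep.coffee_ring_fraction > 0:
        r = np.sqrt(r2)
        ring = np.exp(-0.5 * ((r - 1.5 * sigma) / (0.3 * sigma)) ** 2)
        kernel += dep.coffee_ring_fraction * ring / ring.sum()
    return kernel / kernel.sum()


def _drop_masses(
    n_drops: int, dep: DepositionModel, rng: np.random.Generator
) -> np.ndarray:
    vol = dep.drop_volume_pl + dep.drop_volume_sd_pl * rng.standard_normal(n_drops)
    vol = np.clip(vol, 0.0, None)
    return vol * 1e-9 * dep.ink_conc_mg_ml


def deposit_mass_field(
    pattern: PrintPattern,
    dep: DepositionModel = DepositionModel(),
    seed: int = 0,
    *,
    cell_um: float = 10.0,
    margin_um: float = 2400.0,
) -> MassField:
    """Deposit a pattern onto a fine mass raster with exact mass closure.

    Returns the field plus ground truth: exact per-spot (or per-square)
    deposited totals and centre coordinates, for later validation.
    """
    rng = np.random.default_rng(seed)

    def place(
        values: np.ndarray, cx_um: float, cy_um: float, mass: float,
        kernel: np.ndarray,
    ) -> None:
        radius = kernel.shape[0] // 2
        if margin_um / cell_um < radius:
            raise ConfigError("margin_um must cover the footprint kernel")
        ix = int(round(cx_um / cell_um))
        iy = int(round(cy_um / cell_um))
        values[ix - radius : ix + radius + 1, iy - radius : iy + radius + 1] += (
            mass * kernel
        )

    if pattern.kind == "calibration_strip":
        n_spots = len(pattern.spots)
        nx = int(np.ceil((2 * margin_um + (n_spots - 1) * pattern.spot_pitch_um)
                         / cell_um))
        ny = int(np.ceil(2 * margin_um / cell_um))
        values = np.zeros((nx, ny))
        cy = ny * cell_um / 2.0
        spots_truth = []
        for i, n_drops in enumerate(pattern.spots):
            cx = margin_um + i * pattern.spot_pitch_um
            masses = _drop_masses(n_drops * pattern.n_layers, dep, rng)
            spot_kernel = drop_kernel(
                dep, cell_um, dep.spot_sigma_um(n_drops * pattern.n_layers)
            )
            place(values, cx, cy, float(masses.sum()), spot_kernel)
            spots_truth.append(
                {
                    "spot_id": i,
                    "n_drops": int(n_drops * pattern.n_layers),
                    "mass_mg": float(masses.sum()),
                    "center_um": (cx, cy),
                }
            )
        truth = {
            "kind": pattern.kind,
            "spots": spots_truth,
            "total_mg": float(values.sum()),
        }
    else:  # multilayer_square
        gx, gy = pattern.grid
        span_x = (gx - 1) * pattern.grid_spacing_um
        span_y = (gy - 1) * pattern.grid_spacing_um
        nx = int(np.ceil((2 * margin_um + span_x) / cell_um))
        ny = int(np.ceil((2 * margin_um + span_y) / cell_um))
        values = np.zeros((nx, ny))
        square_kernel = drop_kernel(dep, cell_um)
        total = 0.0
        for _layer in range(pattern.n_layers):
            masses = _drop_masses(gx * gy, dep, rng).reshape(gx, gy)
            total += float(masses.sum())
            for i in range(gx):
                for j in range(gy):
                    place(
                        values,
                        margin_um + i * pattern.grid_spacing_um,
                        margin_um + j * pattern.grid_spacing_um,
                        masses[i, j],
                        square_kernel,
                    )
        truth = {
            "kind": pattern.kind,
            "n_layers": pattern.n_layers,
            "n_drops": int(gx * gy * pattern.n_layers),
            "mass_mg": total,
            "center_um": (margin_um + span_x / 2.0, margin_um + span_y / 2.0),
            "extent_um": (span_x, span_y),
            "margin_um": margin_um,
            "total_mg": float(values.sum()),
        }
    truth["spot_pitch_um"] = pattern.spot_pitch_um
    truth["margin_um"] = margin_um
    return MassField(values=values, cell_um=cell_um, ground_truth=truth)


def blur_field(field: MassField, psf_sigma_um: float) -> np.ndarray:
    """Gaussian PSF blur of the deposit; conserves mass (sources sit far
    enough from the boundary that no blurred mass leaves the array)."""
    if psf_sigma_um <= 0:
        return field.values.copy()
    return gaussian_filter(
        field.values, sigma=psf_sigma_um / field.cell_um, mode="constant",
        truncate=4.0,
    )


def resample_to_pixels(
    blurred: np.ndarray, cell_um: float, pitch_along_um: float,
    pitch_across_um: float,
) -> np.ndarray:
    """Bin fine-raster mass into detector pixels (exact mass-conserving sums)."""
    if cell_um > min(pitch_along_um, pitch_across_um):
        raise DomainError("field raster must be finer than the pixel pitch")
    nx, ny = blurred.shape
    ix = (((np.arange(nx) + 0.5) * cell_um) // pitch_along_um).astype(int)
    iy = (((np.arange(ny) + 0.5) * cell_um) // pitch_across_um).astype(int)
    n_frames, n_spatial = ix[-1] + 1, iy[-1] + 1
    flat = ix[:, None] * n_spatial + iy[None, :]
    pix = np.bincount(
        flat.ravel(), weights=blurred.ravel(), minlength=n_frames * n_spatial
    )
    return pix.reshape(n_frames, n_spatial)


def render_cube(
    field: MassField,
    optics: OpticsConfig = OpticsConfig(),
    smodel: SpectralModel | None = None,
    seed: int = 0,
) -> tuple[sc.HyperspectralCube, sc.ReferencePair, dict]:
    """Image a deposited mass field through the synthetic NIR-HSI chain.

    Returns the raw reflectance cube, the reference pair used, and a truth
    record with the per-pixel mass map (after PSF blur and resampling) for
    validation.
    """
    smodel = smodel if smodel is not None else SpectralModel()
    rng = np.random.default_rng(seed)
    blurred = blur_field(field, optics.psf_sigma_um)
    pixel_mass = resample_to_pixels(
        blurred, field.cell_um, optics.pitch_along_um, optics.pixel_pitch_across_um
    )
    pixel_area_mm2 = optics.pitch_along_um * optics.pixel_pitch_across_um * 1e-6
    density = pixel_mass / pixel_area_mm2  # mg/mm²

    absorb = (
        smodel.substrate_endmember[None, None, :]
        + smodel.mixing_coefficient
        * density[:, :, None]
        * smodel.api_endmember[None, None, :]
    )
    lo, hi = smodel.scatter_range
    scatter = rng.uniform(lo, hi, size=density.shape)
    absorb = scatter[:, :, None] * absorb

    refs = smodel.references(n_spatial=density.shape[1])
    acube = sc.HyperspectralCube(
        data=absorb,
        wavelengths=smodel.wavelengths,
        frame_rate=optics.effective_frame_rate,
        stage_speed=optics.stage_speed_um_s,
        pixel_pitch_across=optics.pixel_pitch_across_um,
        mode=sc.ABSORBANCE,
    )
    raw = sc.invert_absorbance(acube, refs)
    if smodel.noise_sd > 0:
        # co-added lines average the per-frame noise down by √binning
        line_sd = smodel.noise_sd / np.sqrt(optics.frame_binning)
        signal = raw.data - smodel.black_level
        raw.data = raw.data + rng.normal(scale=line_sd * np.abs(signal))
    truth = {
        "pixel_mass_mg": pixel_mass,
        "total_mg": float(pixel_mass.sum()),
        "pitch_along_um": optics.pitch_along_um,
        "pitch_across_um": optics.pixel_pitch_across_um,
        "field_truth": field.ground_truth,
    }
    return raw, refs, truth


def render_raman_map(
    field: MassField,
    seed: int = 0,
    *,
    center_um: tuple[float, float] | None = None,
    xs_um: np.ndarray | None = None,
    ys_um: np.ndarray | None = None,
    bin_um: tuple[float, float] | None = None,
    spacing_um: float = 100.0,
    span_um: float = 1000.0,
    shift_axis: np.ndarray | None = None,
    n_replicates: int = 3,
    sampling_sigma_um: float = 150.0,
    band_center: float = 735.0,
    band_hwhm: float = 6.0,
    gain: float = 1.0e6,
    baseline: tuple[float, float] = (50.0, 0.02),
    noise_sd: float = 1.0,
    pixel_index: np.ndarray | None = None,
) -> RamanMap:
    """Map the deposit as Raman spectra on a raster.

    By default the raster is a ``span_um`` × ``span_um`` grid at
    ``spacing_um`` centred on ``center_um`` (1 × 1 mm at 100 µm unless
    overridden); explicit ``xs_um``/``ys_um`` centres lay the raster on an
    arbitrary grid (e.g. the NIR pixel grid).  Each point integrates the
    deposit over its sampling cell after a Gaussian smear of
    ``sampling_sigma_um`` (the mapper's effective sampling footprint), and
    emits a Lorentzian band at 735 cm⁻¹ whose area is ``gain`` × local mass,
    on a sloped baseline, with additive noise per replicate scan.
    """
    rng = np.random.default_rng(seed)
    if shift_axis is None:
        shift_axis = np.arange(95.0, 1500.0, 4.0)
    if center_um is None:
        ext = field.extent_um
        center_um = (ext[0] / 2.0, ext[1] / 2.0)
    if xs_um is None:
        n_side = int(round(span_um / spacing_um)) + 1
        offs = (np.arange(n_side) - (n_side - 1) / 2.0) * spacing_um
        xs_um = center_um[0] + offs
        ys_um = center_um[1] + offs
    xs_um = np.asarray(xs_um, dtype=float)
    ys_um = np.asarray(ys_um, dtype=float)
    if bin_um is None:
        dx = float(xs_um[1] - xs_um[0]) if xs_um.size > 1 else spacing_um
        dy = float(ys_um[1] - ys_um[0]) if ys_um.size > 1 else spacing_um
        bin_um = (dx, dy)

    smeared = (
        gaussian_filter(
            field.values, sigma=sampling_sigma_um / field.cell_um,
            mode="constant", truncate=4.0,
        )
        if sampling_sigma_um > 0
        else field.values
    )
    cell = field.cell_um
    nx, ny = smeared.shape
    col_cum = np.zeros((nx + 1, ny))
    np.cumsum(smeared, axis=0, out=col_cum[1:])
    full_cum = np.zeros((nx + 1, ny + 1))
    np.cumsum(col_cum, axis=1, out=full_cum[:, 1:])

    def box_mass(x0, x1, y0, y1) -> float:
        i0 = int(np.clip(np.round(x0 / cell), 0, nx))
        i1 = int(np.clip(np.round(x1 / cell), 0, nx))
        j0 = int(np.clip(np.round(y0 / cell), 0, ny))
        j1 = int(np.clip(np.round(y1 / cell), 0, ny))
        return float(
            full_cum[i1, j1] - full_cum[i0, j1] - full_cum[i1, j0]
            + full_cum[i0, j0]
        )

    points = [(x, y) for x in xs_um for y in ys_um]
    local_mass = np.array(
        [
            box_mass(
                x - bin_um[0] / 2.0, x + bin_um[0] / 2.0,
                y - bin_um[1] / 2.0, y + bin_um[1] / 2.0,
            )
            for x, y in points
        ]
    )

    nu = shift_axis
    lorentz = (band_hwhm / np.pi) / ((nu - band_center) ** 2 + band_hwhm**2)
    base = baseline[0] + baseline[1] * nu
    clean = base[None, :] + gain * local_mass[:, None] * lorentz[None, :]
    spectra = clean[None, :, :] + rng.normal(
        scale=noise_sd, size=(n_replicates, local_mass.size, nu.size)
    ) if noise_sd > 0 else np.repeat(clean[None, :, :], n_replicates, axis=0)

    return RamanMap(
        shift_axis=nu,
        intensities=spectra,
        x_um=np.array([p[0] for p in points]),
        y_um=np.array([p[1] for p in points]),
        pixel_index=pixel_index,
    )


def reference_doses(
    true_masses_mg: np.ndarray,
    error_sd_fraction: float = 0.01,
    seed: int = 0,
    *,
    loq_mg: float = 5.0e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-assay masses: truth × (1 + N(0, error_sd_fraction)).

    Returns (values, quantifiable) where ``quantifiable`` flags values at or
    above the assay's limit of quantification.
    """
    if error_sd_fraction < 0:
        raise ConfigError("error_sd_fraction must be ≥ 0")
    truth = np.asarray(true_masses_mg, dtype=float)
    rng = np.random.default_rng(seed)
    if error_sd_fraction == 0:
        values = truth.copy()
    else:
        values = truth * (1.0 + error_sd_fraction * rng.standard_normal(truth.shape))
    return values, values >= loq_mg
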