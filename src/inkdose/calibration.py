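"""Raman-stratified response construction and SIMPLS calibration.

The absolute dose scale comes from per-spot reference masses (an HPLC-like
external assay); Raman band maps (metformin band, 730–740 cm⁻¹) supply only
the *within-spot* distribution of that mass.  Per-pixel band integrals are
stratified into concentration regions, each pixel receives a concentration
proportional to its stratum's mean band intensity, and the allocation is
rescaled so the pixel masses of a spot sum exactly to the spot's reference
mass (mass closure).  A SIMPLS partial-least-squares model (de Jong's
algorithm, single response) then maps preprocessed pixel spectra to mg/px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigError,
    NoSignalError,
    RangeError,
    RankError,
)
from .spectra_core import HyperspectralCube

DEFAULT_RAMAN_BAND = (730.0, 740.0)
DEFAULT_MIN_DROPS = 50


@dataclass
class RamanMap:
    """Raster of Raman spectra over a mapped area.

    intensities : ``(n_replicates, n_points, n_shifts)``
    x_um, y_um  : raster-point centres in the sample plane
    pixel_index : optional ``(n_points, 2)`` (frame, spatial) coordinates in
                  the matching NIR cube, filled in by the simulator when the
                  raster is laid on the cube's pixel grid.
    """

    shift_axis: np.ndarray
    intensities: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    pixel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shift_axis = np.asarray(self.shift_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ConfigError("intensities must be (replicates, points, shifts)")
        if np.any(np.diff(self.shift_axis) <= 0):
            raise ConfigError("Raman shift axis must be strictly increasing")
        if self.intensities.shape[2] != self.shift_axis.size:
            raise ConfigError("shift axis length mismatch")

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[0]


@dataclass
class ResponseMatrix:
    """Per-pixel training concentrations for one printed spot."""

    pixel_index: np.ndarray  # (n, 2) int (frame, spatial)
    concentration: np.ndarray  # mg/px (non-negative unless signed weights requested)
    stratum_label: np.ndarray  # int per pixel
    spot_mass: float  # mg, the closure target


@dataclass
class PLSModel:
    """SIMPLS factorisation and regression vector for pixel-wise prediction.

    Prediction is ``ŷ = y_mean + (x − x_mean) · beta_slope``; ``beta`` with
    the intercept folded in is exposed for the classic augmented form.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    beta_slope: np.ndarray
    weights: np.ndarray  # R (p × A): X-weights s.t. T = Xc R
    x_loadings: np.ndarray  # P (p × A)
    y_loadings: np.ndarray  # q (A,)
    scores: np.ndarray  # T (n × A), orthonormal columns
    preprocess_card: dict | None = None

    @property
    def beta(self) -> np.ndarray:
        """Augmented coefficients: [intercept, slope...]."""
        intercept = self.y_mean - float(self.x_mean @ self.beta_slope)
        return np.concatenate([[intercept], self.beta_slope])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_mean + (X - self.x_mean) @ self.beta_slope


def raman_band_integral(
    shift_axis: np.ndarray,
    spectrum: np.ndarray,
    band: tuple[float, float] = DEFAULT_RAMAN_BAND,
) -> float:
    """Baseline-subtracted trapezoidal band area.

    The baseline is the straight line joining the spectrum values at the band
    endpoints (interpolated if the endpoints fall between grid points).
    """
    shift = np.asarray(shift_axis, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    lo, hi = float(band[0]), float(band[1])
    if lo < shift[0] or hi > shift[-1] or lo >= hi:
        raise RangeError(
            f"band [{lo}, {hi}] cm⁻¹ outside shift axis "
            f"[{shift[0]}, {shift[-1]}] cm⁻¹"
        )
    inside = (shift > lo) & (shift < hi)
    xs = np.concatenate([[lo], shift[inside], [hi]])
    ys = np.concatenate([
        [np.interp(lo, shift, y)], y[inside], [np.interp(hi, shift, y)]
    ])
    baseline = ys[0] + (ys[-1] - ys[0]) * (xs - lo) / (hi - lo)
    return float(np.trapezoid(ys - baseline, xs))


def band_integral_image(
    rmap: RamanMap, band: tuple[float, float] = DEFAULT_RAMAN_BAND
) -> np.ndarray:
    """Replicate-averaged band integral at every raster point."""
    mean_spec = rmap.intensities.mean(axis=0)  # (points, shifts)
    return np.array(
        [raman_band_integral(rmap.shift_axis, s, band) for s in mean_spec]
    )


def stratify_response(
    rmap: RamanMap,
    spot_mass: float,
    n_strata: int | None = 3,
    *,
    band: tuple[float, float] = DEFAULT_RAMAN_BAND,
    pixel_index: np.ndarray | None = None,
    clip_negative: bool = True,
) -> ResponseMatrix:
    """Allocate a spot's reference mass over pixels by Raman-band strata.

    Replicate-averaged band integrals are partitioned into ``n_strata``
    quantile strata; every pixel of a stratum receives a concentration
    proportional to the stratum's mean band integral, rescaled so the
    concentrations sum exactly to ``spot_mass``.  Ties at quantile
    boundaries go to the lower stratum.  ``n_strata=None`` (or ≥ the number
    of pixels) is the fine-stratification limit: allocation proportional to
    each pixel's own band integral.

    ``clip_negative`` floors allocation weights at zero (the default,
    guaranteeing non-negative concentrations); passing ``False`` keeps
    signed weights so that zero-mean measurement noise is not rectified
    into spurious rim mass — individual pixel responses may then be
    negative noise realisations while spot totals stay exact.
    """
    if spot_mass <= 0:
        raise ConfigError("spot_mass must be > 0")
    if n_strata is not None and n_strata < 1:
        raise ConfigError("n_strata must be ≥ 1")
    integrals = band_integral_image(rmap, band)
    if not np.any(integrals > 0):
        raise NoSignalError("Raman map has no positive band intensity")
    n = integrals.size

    if n_strata is None or n_strata >= n:
        labels = np.arange(n)
        weights = integrals.astype(float)
        if clip_negative:
            weights = np.maximum(weights, 0.0)
    else:
        # quantile edges; searchsorted side='left' sends boundary ties low
        qs = np.quantile(integrals, np.linspace(0, 1, n_strata + 1)[1:-1])
        labels = np.searchsorted(qs, integrals, side="left")
        weights = np.empty(n)
        for lab in np.unique(labels):
            mean_w = integrals[labels == lab].mean()
            weights[labels == lab] = max(mean_w, 0.0) if clip_negative else mean_w

    total = weights.sum()
    if total <= 0:
        raise NoSignalError("stratum weights sum to zero")
    conc = weights * (spot_mass / total)
    # enforce exact closure against accumulated rounding
    conc *= spot_mass / conc.sum()

    if pixel_index is None:
        pixel_index = rmap.pixel_index
    if pixel_index is None:
        pixel_index = np.stack(
            [np.arange(n, dtype=int), np.zeros(n, dtype=int)], axis=1
        )
    return ResponseMatrix(
        pixel_index=np.asarray(pixel_index, dtype=int),
        concentration=conc,
        stratum_label=np.asarray(labels, dtype=int),
        spot_mass=float(spot_mass),
    )


def assemble_training(
    cubes: list[HyperspectralCube],
    responses: list[ResponseMatrix],
    drop_counts: list[int] | None = None,
    *,
    min_drops: int = DEFAULT_MIN_DROPS,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Row-align preprocessed pixel spectra with their response concentrations.

    Spots whose drop count falls below ``min_drops`` (the reference method's
    quantification limit) are excluded and reported in the returned log.
    """
    if len(cubes) != len(responses):
        raise AlignmentError("need one response per cube")
    if drop_counts is not None and len(drop_counts) != len(cubes):
        raise AlignmentError("need one drop count per cube")
    X_rows, y_rows, excluded = [], [], []
    for i, (cube, resp) in enumerate(zip(cubes, responses)):
        if drop_counts is not None and drop_counts[i] < min_drops:
            excluded.append(
                {"spot": i, "n_drops": int(drop_counts[i]),
                 "reason": f"below inclusion threshold ({min_drops} drops)"}
            )
            continue
        idx = resp.pixel_index
        if (
            np.any(idx < 0)
            or np.any(idx[:, 0] >= cube.n_frames)
            or np.any(idx[:, 1] >= cube.n_spatial)
        ):
            raise AlignmentError(
                f"response pixel coordinates outside cube {i} "
                f"({cube.n_frames}×{cube.n_spatial})"
            )
        X_rows.append(cube.data[idx[:, 0], idx[:, 1], :])
        y_rows.append(resp.concentration)
    if not X_rows:
        raise NoSignalError("no spots retained for training")
    return np.vstack(X_rows), np.concatenate(y_rows), excluded


def fit_simpls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    preprocess_card: dict | None = None,
) -> PLSModel:
    """Fit a single-response PLS model with the SIMPLS algorithm.

    Successive weight vectors maximise covariance with the response; the
    cross-product vector is deflated against an orthonormal basis of the
    X-loadings so factors stay mutually orthogonal (de Jong's construction).
    Scores are normalised to unit length, which makes the y-loadings the
    regression coefficients of y on the scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise AlignmentError(f"X has {n} rows but y has {y.size}")
    if n_components < 1:
        raise ConfigError("n_components must be ≥ 1")
    if n <= n_components:
        raise RankError(
            f"need more rows ({n}) than components ({n_components})",
            achievable_rank=max(0, n - 1),
        )

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc
    ref_norm: float | None = None  # first component's score norm sets the scale

    R = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    V = np.zeros((p, n_components))

    for a in range(n_components):
        r = s.copy()
        t = Xc @ r
        t -= t.mean()
        norm_t = np.linalg.norm(t)
        if ref_norm is None and norm_t > 0 and np.isfinite(norm_t):
            ref_norm = norm_t
        tol = 0.0 if ref_norm is None else ref_norm * 1e-12
        if not np.isfinite(norm_t) or norm_t <= tol:
            raise RankError(
                f"rank deficiency: only {a} informative component(s) available, "
                f"{n_components} requested",
                achievable_rank=a,
            )
        t /= norm_t
        r /= norm_t
        p_a = Xc.T @ t
        q_a = float(yc @ t)
        v = p_a.copy()
        if a > 0:
            # double Gram-Schmidt pass keeps the loading basis orthonormal
            # to machine precision over many components
            v -= V[:, :a] @ (V[:, :a].T @ v)
            v -= V[:, :a] @ (V[:, :a].T @ v)
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        if a > 0:
            s = s - V[:, :a] @ (V[:, :a].T @ s)

        R[:, a], P[:, a], q[a], T[:, a], V[:, a] = r, p_a, q_a, t, v

    beta_slope = R @ q
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        beta_slope=beta_slope,
        weights=R,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        preprocess_card=preprocess_card,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_components_grid: list[int],
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Venetian-blind cross-validation of the component count.

    Fold assignment is systematic (``(i + offset) % n_folds`` over the row
    order) with the offset drawn from ``seed``, so the table is deterministic
    given the seed.  Returns RMSECV and the achievable rank per candidate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n_folds < 2:
        raise ConfigError("n_folds must be ≥ 2")
    if n_folds > n:
        raise ConfigError(f"n_folds ({n_folds}) exceeds number of rows ({n})")
    offset = int(np.random.default_rng(seed).integers(n_folds))
    folds = (np.arange(n) + offset) % n_folds

    rows = []
    for a in n_components_grid:
        press = 0.0
        rank_seen = a
        for f in range(n_folds):
            train, test = folds != f, folds == f
            try:
                model = fit_simpls(X[train], y[train], a)
            except RankError as err:
                rank_seen = min(rank_seen, err.achievable_rank or 0)
                model = fit_simpls(
                    X[train], y[train], max(1, err.achievable_rank or 1)
                )
            resid = y[test] - model.predict(X[test])
            press += float(resid @ resid)
        rows.append(
            {"n_components": a, "rmsecv": np.sqrt(press / n), "rank": rank_seen}
        )
    return pd.DataFrame(rows)
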