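"""Spectral reflectance indices and exhaustive two-band ratio-index scans.

A ratio spectral index (RSI) is ``R_l1 / R_l2``, the reflectance at one
wavelength divided by the reflectance at another.  Beyond a fixed catalog of
published indices, this module scans *every* ordered wavelength pair on the
acquisition grid, regresses a measured trait on each pair's RSI across the
sample set, and records the coefficient of determination — producing the
R-squared "contour map" used to discover the most informative band pair for
a trait (for pigments this typically straddles the chlorophyll red edge).

Reflectance at off-grid wavelengths (published indices cite odd nanometre
bands while field spectrometers record on an even grid) is obtained by
linear interpolation by default; a nearest-neighbour mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "RSI_CATALOG_PAIRS",
    "reflectance_at",
    "rsi",
    "compute_sri_catalog",
    "sri_table",
    "correlogram_scan",
    "top_pairs",
    "CorrelogramResult",
]

#: Ratio-index wavelength pairs (numerator nm, denominator nm) in the
#: published catalog.  The last two (744/640, 826/640) appear only in the
#: screening literature tables and are carried along as plain ratio indices.
RSI_CATALOG_PAIRS: tuple[tuple[int, int], ...] = (
    (710, 600), (730, 650), (676, 664), (672, 670), (678, 666), (894, 878),
    (824, 810), (810, 822), (654, 566), (546, 1132), (534, 750), (522, 750),
    (632, 608), (1140, 674), (616, 674), (610, 646), (622, 640), (648, 1120),
    (620, 618), (640, 616), (584, 650), (610, 650), (744, 640), (826, 640),
)


#: The wavelength selection (nm) historically used when restricting the
#: two-band scan to bands already represented in published indices; pass as
#: ``correlogram_scan(..., wavelengths=PUBLISHED_SCAN_WAVELENGTHS)``.
PUBLISHED_SCAN_WAVELENGTHS: tuple[int, ...] = (
    522, 534, 546, 550, 566, 584, 600, 608, 610, 616, 618, 620, 622, 632,
    640, 646, 648, 650, 654, 660, 664, 666, 670, 672, 674, 676, 678, 710,
    720, 730, 750, 760, 780, 810, 822, 824, 878, 894, 1120, 1132, 1140,
)


@dataclass
class Spectrum:
    """A single sample's reflectance curve on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")


def reflectance_at(spectrum: Spectrum, wavelength: float, mode: str = "linear") -> float:
    """Reflectance at ``wavelength`` (nm), interpolating between grid points.

    mode="linear" (default) interpolates linearly between the bracketing
    grid points; exact grid hits are returned exactly.  mode="nearest"
    snaps to the closest grid point.  Wavelengths outside the grid raise.
    """
    wl = spectrum.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside spectral coverage "
            f"[{wl[0]:g}, {wl[-1]:g}]"
        )
    if mode == "nearest":
        idx = int(np.argmin(np.abs(wl - wavelength)))
        return float(spectrum.reflectance[idx])
    if mode != "linear":
        raise ValueError(f"unknown lookup mode {mode!r}")
    return float(np.interp(wavelength, wl, spectrum.reflectance))


def rsi(spectrum: Spectrum, lam1: float, lam2: float, mode: str = "linear") -> float:
    """Ratio spectral index ``R_lam1 / R_lam2``.

    Returns NaN (with a logged reason) when the denominator reflectance is
    zero or negative.
    """
    num = reflectance_at(spectrum, lam1, mode=mode)
    den = reflectance_at(spectrum, lam2, mode=mode)
    if den <= 0:
        logger.warning("RSI(%g, %g): non-positive denominator reflectance; NaN", lam1, lam2)
        return float("nan")
    return num / den


def _nd(spectrum: Spectrum, lam1: float, lam2: float, mode: str) -> float:
    a = reflectance_at(spectrum, lam1, mode=mode)
    b = reflectance_at(spectrum, lam2, mode=mode)
    if a + b == 0:
        logger.warning("ND(%g, %g): zero denominator; NaN", lam1, lam2)
        return float("nan")
    return (a - b) / (a + b)


def compute_sri_catalog(spectrum: Spectrum, mode: str = "linear") -> dict[str, float]:
    """Evaluate the published spectral-index catalog on one spectrum.

    Covers all ratio pairs in :data:`RSI_CATALOG_PAIRS` plus
    NDVI = (R780-R660)/(R780+R660), the anthocyanin index
    NAI = (R760-R720)/(R760+R720), the greenness index GI = R554/R677 and
    the pigment-sensitive ripening monitoring index
    PRMI = (R750-R678)/R550.
    """
    out: dict[str, float] = {}
    for lam1, lam2 in RSI_CATALOG_PAIRS:
        out[f"RSI_{lam1},{lam2}"] = rsi(spectrum, lam1, lam2, mode=mode)
    out["NDVI"] = _nd(spectrum, 780, 660, mode)
    out["NAI"] = _nd(spectrum, 760, 720, mode)
    out["GI"] = rsi(spectrum, 554, 677, mode=mode)
    r550 = reflectance_at(spectrum, 550, mode=mode)
    if r550 <= 0:
        logger.warning("PRMI: non-positive R550; NaN")
        out["PRMI"] = float("nan")
    else:
        out["PRMI"] = (reflectance_at(spectrum, 750, mode=mode)
                       - reflectance_at(spectrum, 678, mode=mode)) / r550
    return out


def sri_table(spectra_df: pd.DataFrame, mode: str = "linear") -> pd.DataFrame:
    """Catalog indices for a wide spectra table (columns = wavelengths, nm)."""
    wl = np.asarray([float(c) for c in spectra_df.columns])
    rows = [
        compute_sri_catalog(Spectrum(wl, spectra_df.iloc[i].to_numpy(float)), mode=mode)
        for i in range(len(spectra_df))
    ]
    return pd.DataFrame(rows, index=spectra_df.index)


@dataclass
class CorrelogramResult:
    """R-squared grid over ordered wavelength pairs for one trait.

    ``r2_grid[i, j]`` is the coefficient of determination of the simple
    linear regression of the trait on RSI(wavelengths[i], wavelengths[j])
    across samples (rows = numerator axis, columns = denominator axis).
    Diagonal entries are NaN by convention (the index is the constant 1).
    The grid is *not* symmetric: trait ~ x and trait ~ 1/x generally give
    different R-squared.
    """

    trait: str
    wavelengths: np.ndarray
    r2_grid: np.ndarray
    n_samples: int
    best_pairs: list[tuple[float, float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        wl = [int(w) if float(w).is_integer() else w for w in self.wavelengths]
        return pd.DataFrame(self.r2_grid, index=wl, columns=wl)


def correlogram_scan(
    spectra_df: pd.DataFrame,
    trait: pd.Series,
    lambda_step: float | None = None,
    wavelengths=None,
    n_best: int = 20,
) -> CorrelogramResult:
    """Exhaustive two-band ratio-index scan against one trait.

    For every ordered pair (l1, l2) of grid wavelengths, the per-sample RSI
    ``R_l1 / R_l2`` is regressed (ordinary least squares, one predictor)
    against the trait and the R-squared is stored.  For a single-predictor
    OLS fit the R-squared equals the squared Pearson correlation, which is
    how the grid is computed (vectorized over numerator wavelengths).

    Parameters
    ----------
    spectra_df : DataFrame
        Wide spectra, one row per sample, columns = wavelengths in nm.
    trait : Series
        Trait values aligned to ``spectra_df`` rows (by position or index).
    lambda_step : float, optional
        Subsample the grid to this spacing (must be a multiple of the grid
        step).  Default: use the full grid.
    wavelengths : array-like, optional
        Explicit wavelength subset (overrides ``lambda_step``); each must be
        on the acquisition grid.
    n_best : int
        Number of ranked best pairs to attach to the result.

    Notes
    -----
    Samples with a missing trait or a non-positive denominator reflectance
    are dropped pairwise per regression; pairs with fewer than 3 usable
    samples, or whose RSI is constant across samples, get NaN.
    A constant trait raises ``ValueError``.
    """
    grid = np.asarray([float(c) for c in spectra_df.columns])
    y_full = np.asarray(trait, dtype=float)
    if len(y_full) != len(spectra_df):
        raise ValueError("trait length does not match number of spectra")
    if len(spectra_df) < 3:
        raise ValueError("need at least 3 samples for a correlogram scan")
    finite_y = y_full[np.isfinite(y_full)]
    if finite_y.size < 3 or np.ptp(finite_y) == 0:
        raise ValueError(f"trait {trait.name!r} is constant or too sparse")

    if wavelengths is not None:
        sel_wl = np.asarray(wavelengths, dtype=float)
        missing = [w for w in sel_wl if w not in grid]
        if missing:
            raise ValueError(f"wavelengths not on the grid: {missing}")
        sel = np.asarray([int(np.where(grid == w)[0][0]) for w in sel_wl])
    elif lambda_step is not None:
        step = float(np.diff(grid).min())
        ratio = lambda_step / step
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError(
                f"lambda_step {lambda_step} is not a multiple of the grid step {step}"
            )
        sel = np.arange(0, len(grid), int(round(ratio)))
    else:
        sel = np.arange(len(grid))

    wl = grid[sel]
    R = spectra_df.to_numpy(dtype=float)[:, sel]  # n x m
    m = len(wl)
    grid_r2 = np.full((m, m), np.nan)

    for j in range(m):
        den = R[:, j]
        valid = np.isfinite(y_full) & np.isfinite(den) & (den > 0)
        if valid.sum() < 3:
            continue
        X = R[valid] / den[valid, None]  # n_valid x m ratios
        y = y_full[valid]
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sxx = (xc ** 2).sum(axis=0)
        syy = float((yc ** 2).sum())
        sxy = xc.T @ yc
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(sxx > 0, (sxy ** 2) / (sxx * syy), np.nan)
        grid_r2[:, j] = r2
        # pairwise-complete fallback for numerators with missing reflectance
        for i in np.nonzero(~np.all(np.isfinite(X), axis=0))[0]:
            ok = np.isfinite(X[:, i])
            if ok.sum() < 3 or np.ptp(X[ok, i]) == 0 or np.ptp(y[ok]) == 0:
                grid_r2[i, j] = np.nan
                continue
            r = np.corrcoef(X[ok, i], y[ok])[0, 1]
            grid_r2[i, j] = r * r
    np.fill_diagonal(grid_r2, np.nan)

    result = CorrelogramResult(
        trait=str(trait.name) if trait.name is not None else "trait",
        wavelengths=wl,
        r2_grid=grid_r2,
        n_samples=int(np.isfinite(y_full).sum()),
    )
    result.best_pairs = top_pairs(result, n_best)
    return result


def top_pairs(result: CorrelogramResult, k: int) -> list[tuple[float, float, float]]:
    """The ``k`` highest-R-squared (numerator, denominator, R2) pairs.

    Ties are broken by smaller band separation ``|l1 - l2|``, then
    lexicographically by (l1, l2).  If fewer than ``k`` finite entries
    exist, all of them are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    wl = result.wavelengths
    ii, jj = np.nonzero(np.isfinite(result.r2_grid))
    entries = [
        (float(wl[i]), float(wl[j]), float(result.r2_grid[i, j])) for i, j in zip(ii, jj)
    ]
    entries.sort(key=lambda e: (-e[2], abs(e[0] - e[1]), e[0], e[1]))
    return entries[:k]
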