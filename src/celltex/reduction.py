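"""Reduce 2D detector frames to 1D traces.

Sector (cake) integration in (q, χ), azimuthal profiles over a q band,
small-angle line cuts, and local background subtraction.  Pixels are
assigned to the nearest bin center (no pixel splitting); the per-bin
statistic is a mean — solid-angle weighted by default — so sectors of
different areas are directly comparable.  Bins that receive no pixel are
flagged, not zero-filled.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptySectorError, InvalidInput
from .optics import QChiMap
from .profiles import Profile1D

__all__ = [
    "sector_profile",
    "azimuthal_profile",
    "cake",
    "gisaxs_line_cuts",
    "local_background_subtract",
    "BACKGROUND_BANDS",
]

#: Local-background q bands (1/Angstrom) for pole-figure correction,
#: registered per specimen and measurement mode.
BACKGROUND_BANDS: dict[str, tuple[float, float]] = {
    "onion_giwaxs": (0.5, 0.6),
    "arabidopsis_giwaxs": (0.6, 0.7),
    "moss_giwaxs": (0.6, 0.7),
    "onion_rocking": (2.0, 2.2),
    "arabidopsis_rocking": (1.8, 1.9),
    "moss_rocking": (0.7, 0.8),
}


def _nearest_bin(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Index of nearest bin center; −1 outside the outer half-bin edges."""
    if grid.size < 2:
        raise InvalidInput("grid needs at least two bins")
    edges = np.empty(grid.size + 1)
    edges[1:-1] = 0.5 * (grid[1:] + grid[:-1])
    edges[0] = grid[0] - (edges[1] - grid[0])
    edges[-1] = grid[-1] + (grid[-1] - edges[-2])
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[(values < edges[0]) | (values >= edges[-1])] = -1
    return idx


def _binned_mean(
    counts: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray | None,
    grid: np.ndarray,
    axis: str,
    meta: dict,
) -> Profile1D:
    """Weighted per-bin mean with Poisson uncertainties."""
    idx = _nearest_bin(values, grid)
    keep = idx >= 0
    idx, counts = idx[keep], counts[keep]
    nbins = grid.size
    n_pix = np.bincount(idx, minlength=nbins)
    if weights is None:
        sum_w = n_pix.astype(float)
        sum_wc = np.bincount(idx, weights=counts, minlength=nbins)
        sum_w2c = np.bincount(idx, weights=np.maximum(counts, 0.0), minlength=nbins)
    else:
        w = weights[keep]
        sum_w = np.bincount(idx, weights=w, minlength=nbins)
        sum_wc = np.bincount(idx, weights=w * counts, minlength=nbins)
        sum_w2c = np.bincount(idx, weights=w * w * np.maximum(counts, 0.0), minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(n_pix > 0, sum_wc / sum_w, np.nan)
        sigma = np.where(n_pix > 0, np.sqrt(sum_w2c) / sum_w, np.nan)
    return Profile1D(
        axis=axis, grid=grid, intensity=intensity, sigma=sigma, n_pixels=n_pix, meta=meta
    )


def sector_profile(
    frame: np.ndarray,
    qcmap: QChiMap,
    chi_range: tuple[float, float],
    q_grid: np.ndarray,
    fold: bool = False,
    weighted: bool = True,
) -> Profile1D:
    """Intensity vs q within a χ sector.

    ``fold=True`` additionally includes the mirrored sector (−hi, −lo), for
    combining both signed lobes of a nominally symmetric pattern.
    """
    lo, hi = chi_range
    if not (-90 <= lo < hi <= 90):
        raise InvalidInput("chi_range must satisfy -90 <= lo < hi <= 90")
    q_grid = np.asarray(q_grid, dtype=float)
    chi = qcmap.chi
    sel = qcmap.mask & (chi >= lo) & (chi <= hi)
    if fold:
        sel |= qcmap.mask & (chi >= -hi) & (chi <= -lo)
    if not np.any(sel):
        raise EmptySectorError(f"sector chi in ({lo}, {hi}) deg selected no pixels")
    meta = {"sector_chi_deg": (lo, hi), "fold": fold, "weighted": weighted}
    return _binned_mean(
        np.asarray(frame, dtype=float)[sel],
        qcmap.q[sel],
        qcmap.weight[sel] if weighted else None,
        q_grid,
        "q",
        meta,
    )


def azimuthal_profile(
    frame: np.ndarray,
    qcmap: QChiMap,
    q_band: tuple[float, float],
    chi_grid: np.ndarray,
    weighted: bool = True,
    q_sub_bins: int = 1,
) -> Profile1D:
    """Intensity vs χ within a q annulus; missing-wedge bins stay flagged.

    With ``q_sub_bins > 1`` the band is split into that many q slices, a
    weighted mean is formed per (slice, χ) cell, and the slices are then
    averaged with equal weight.  This decouples the profile from the pixel
    sampling density in q, which on a flat detector varies with χ near the
    missing-wedge rim and would otherwise skew band averages there.
    """
    lo, hi = q_band
    if not (0 <= lo < hi):
        raise InvalidInput("q_band must satisfy 0 <= lo < hi")
    if q_sub_bins < 1:
        raise InvalidInput("q_sub_bins must be >= 1")
    chi_grid = np.asarray(chi_grid, dtype=float)
    sel = qcmap.mask & (qcmap.q >= lo) & (qcmap.q <= hi)
    if not np.any(sel):
        raise EmptySectorError(f"q band ({lo}, {hi}) 1/A lies outside the detector")
    meta = {"q_band_invA": (lo, hi), "weighted": weighted, "q_sub_bins": q_sub_bins}
    counts = np.asarray(frame, dtype=float)[sel]
    chi = qcmap.chi[sel]
    weights = qcmap.weight[sel] if weighted else None
    if q_sub_bins == 1:
        return _binned_mean(counts, chi, weights, chi_grid, "chi", meta)

    q = qcmap.q[sel]
    edges = np.linspace(lo, hi, q_sub_bins + 1)
    slice_idx = np.clip(np.searchsorted(edges, q, side="right") - 1, 0, q_sub_bins - 1)
    stack_i, stack_v, stack_n = [], [], []
    for s in range(q_sub_bins):
        in_slice = slice_idx == s
        if not np.any(in_slice):
            continue
        p = _binned_mean(
            counts[in_slice],
            chi[in_slice],
            weights[in_slice] if weights is not None else None,
            chi_grid,
            "chi",
            {},
        )
        stack_i.append(p.intensity)
        stack_v.append(p.sigma)
        stack_n.append(p.n_pixels)
    intensity = np.vstack(stack_i)
    sigma = np.vstack(stack_v)
    n_pix = np.vstack(stack_n)
    present = n_pix > 0
    n_slices = present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(
            n_slices > 0,
            np.nansum(np.where(present, intensity, 0.0), axis=0) / np.maximum(n_slices, 1),
            np.nan,
        )
        err = np.where(
            n_slices > 0,
            np.sqrt(np.nansum(np.where(present, sigma**2, 0.0), axis=0))
            / np.maximum(n_slices, 1),
            np.nan,
        )
    return Profile1D(
        axis="chi",
        grid=chi_grid,
        intensity=mean,
        sigma=err,
        n_pixels=n_pix.sum(axis=0),
        meta=meta,
    )


def cake(
    frame: np.ndarray,
    qcmap: QChiMap,
    q_edges: np.ndarray,
    chi_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """2D (q, χ) rebinning: per-cell plain mean and contributing-pixel count.

    Plain (unweighted) means, so Σ_cells mean·n_pixels reproduces the total
    masked counts exactly when the edges cover the masked (q, χ) range
    (count conservation).
    """
    q_edges = np.asarray(q_edges, dtype=float)
    chi_edges = np.asarray(chi_edges, dtype=float)
    sel = qcmap.mask
    counts = np.asarray(frame, dtype=float)[sel]
    q = qcmap.q[sel]
    chi = qcmap.chi[sel]
    n, _, _ = np.histogram2d(q, chi, bins=[q_edges, chi_edges])
    total, _, _ = np.histogram2d(q, chi, bins=[q_edges, chi_edges], weights=counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / n, np.nan)
    return mean, n.astype(int)


def gisaxs_line_cuts(
    frame: np.ndarray,
    qcmap: QChiMap,
    direction: str,
    center_inv_a: float | None = None,
    width_inv_a: float = 0.005,
    grid: np.ndarray | None = None,
    weighted: bool = True,
) -> Profile1D:
    """Small-angle line cuts through a grazing-incidence frame.

    ``direction="vertical"`` — intensity vs q_z along a cut at
    q_y = 0.012 1/Å (default), width 0.005 1/Å.
    ``direction="horizontal"`` — intensity vs q_y at q_z = 0.03 1/Å.
    Defaults are overridable; all cut parameters land in the profile meta.
    """
    if direction not in ("vertical", "horizontal"):
        raise InvalidInput("direction must be 'vertical' or 'horizontal'")
    if direction == "vertical":
        center = 0.012 if center_inv_a is None else center_inv_a
        across, along = qcmap.q_xy, qcmap.q_z
        axis_name = "q_z"
    else:
        center = 0.03 if center_inv_a is None else center_inv_a
        across, along = qcmap.q_z, qcmap.q_xy
        axis_name = "q_y"
    sel = qcmap.mask & (np.abs(across - center) <= width_inv_a / 2.0)
    if not np.any(sel):
        raise EmptySectorError(
            f"{direction} cut at {center} 1/A (width {width_inv_a}) misses the detector"
        )
    values = along[sel]
    if grid is None:
        lo, hi = float(values.min()), float(values.max())
        grid = np.linspace(lo, hi, 200)
    meta = {
        "cut_direction": direction,
        "cut_center_invA": center,
        "cut_width_invA": width_inv_a,
        "cut_axis": axis_name,
    }
    return _binned_mean(
        np.asarray(frame, dtype=float)[sel],
        values,
        qcmap.weight[sel] if weighted else None,
        np.asarray(grid, dtype=float),
        "q",
        meta,
    )


def local_background_subtract(signal: Profile1D, background: Profile1D) -> Profile1D:
    """Pointwise χ-resolved background subtraction.

    Grids must match exactly.  Uncertainties add in quadrature; negative
    differences are retained (the estimator stays unbiased) and their count
    is recorded in the result metadata.
    """
    signal.require_same_grid(background)
    intensity = signal.intensity - background.intensity
    sigma = np.hypot(signal.sigma, background.sigma)
    n_pixels = np.minimum(signal.n_pixels, background.n_pixels)
    intensity = np.where(n_pixels > 0, intensity, np.nan)
    sigma = np.where(n_pixels > 0, sigma, np.nan)
    n_negative = int(np.sum(intensity[np.isfinite(intensity)] < 0))
    meta = dict(signal.meta)
    meta["background_meta"] = dict(background.meta)
    meta["n_negative_bins"] = n_negative
    return Profile1D(
        axis=signal.axis,
        grid=signal.grid.copy(),
        intensity=intensity,
        sigma=sigma,
        n_pixels=n_pixels,
        meta=meta,
    )
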