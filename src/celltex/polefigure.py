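"""χ-pole figures and texture/crystallinity metrics.

A complete orientation-distribution trace I(χ) on χ ∈ [−90°, 90°] is
assembled from two partial measurements: the GIWAXS branch (valid for
|χ| ≥ 7.5°, where the missing wedge does not bite) and the rocking-scan
branch (|χ| < 30°, which samples crystallites near the substrate normal).
The GIWAXS branch is scaled to match the rocking branch at χ = ±7.5° and
the two are stitched; in the 7.5°–30° overlap the GIWAXS branch is kept
(better off-specular statistics) and the rocking branch is used only
inside |χ| < 7.5°.

Texture metrics: the oriented fraction within ±χ₀ (sin χ hemisphere
weighting by default, flat optional), and the FWHM of the folded
distribution.  Crystallinity: the Segal height-based index transcribed to
q-space windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySectorError, InvalidInput, ScalingError
from .optics import BeamSpec, DetectorGeometry, QChiMap, build_qchi_map
from .profiles import Profile1D
from .reduction import azimuthal_profile, local_background_subtract
from .simulate import RockingSeries

__all__ = [
    "PoleFigure",
    "giwaxs_branch",
    "rocking_branch",
    "stitch",
    "oriented_fraction",
    "texture_width",
    "segal_ci",
]

#: Default q band of the cellulose 110 pair: 1.15 ± 0.16 1/Angstrom.
DEFAULT_Q_BAND = (0.99, 1.31)

#: Interpolation step (degrees) for folded-quadrature metrics.
_FINE_STEP_DEG = 0.01


@dataclass
class PoleFigure:
    """Stitched, background-corrected I(χ) with per-bin branch provenance."""

    chi_grid: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    branch: np.ndarray  # per-bin label: "giwaxs" | "rocking" | "overlap"
    scale_factor: float
    q_band: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chi_grid = np.asarray(self.chi_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not self.scale_factor > 0:
            raise InvalidInput("scale factor must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidInput("stitched pole figure must be finite everywhere")
        if self.branch.shape != self.chi_grid.shape:
            raise InvalidInput("branch labels must match the grid")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# q_band_invA: {self.q_band}\n")
            for key, value in sorted(self.meta.items()):
                fh.write(f"# {key}: {value}\n")
            fh.write(f"# scale_factor: {self.scale_factor:.8g}\n")
            fh.write("chi_deg,intensity,sigma,branch\n")
            for x, i, s, b in zip(self.chi_grid, self.intensity, self.sigma, self.branch):
                fh.write(f"{x:.6g},{i:.8g},{s:.8g},{b}\n")

    @classmethod
    def from_csv(cls, path) -> "PoleFigure":
        meta: dict = {}
        scale = 1.0
        q_band = DEFAULT_Q_BAND
        chi, inten, sig, br = [], [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("chi_deg"):
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].partition(":")
                    key, value = key.strip(), value.strip()
                    if key == "scale_factor":
                        scale = float(value)
                    elif key == "q_band_invA":
                        q_band = tuple(float(t) for t in value.strip("()").split(","))
                    else:
                        meta[key] = value
                    continue
                parts = line.split(",")
                chi.append(float(parts[0]))
                inten.append(float(parts[1]))
                sig.append(float(parts[2]))
                br.append(parts[3])
        return cls(
            chi_grid=np.array(chi),
            intensity=np.array(inten),
            sigma=np.array(sig),
            branch=np.array(br),
            scale_factor=scale,
            q_band=q_band,  # type: ignore[arg-type]
            meta=meta,
        )


# ------------------------------------------------------------------ branches
def giwaxs_branch(
    frame: np.ndarray,
    qcmap: QChiMap,
    chi_grid: np.ndarray,
    q_band: tuple[float, float] = DEFAULT_Q_BAND,
    background_band: tuple[float, float] = (0.5, 0.6),
    min_abs_chi_deg: float = 7.5,
    q_sub_bins: int = 8,
) -> Profile1D:
    """Background-corrected azimuthal profile, restricted to |χ| ≥ 7.5°.

    The signal band is averaged in q sub-slices (see
    :func:`celltex.reduction.azimuthal_profile`) so the χ-dependent pixel
    density near the missing-wedge rim does not skew the stitch point.
    """
    signal = azimuthal_profile(frame, qcmap, q_band, chi_grid, q_sub_bins=q_sub_bins)
    background = azimuthal_profile(frame, qcmap, background_band, chi_grid)
    n_filled = _fill_missing_bins(background, 90.0)
    corrected = local_background_subtract(signal, background)
    corrected.meta["background_bins_interpolated"] = n_filled
    inside = np.abs(corrected.grid) < min_abs_chi_deg
    corrected.intensity[inside] = np.nan
    corrected.sigma[inside] = np.nan
    corrected.n_pixels[inside] = 0
    corrected.meta.update(
        {"branch": "giwaxs", "q_band_invA": q_band, "min_abs_chi_deg": min_abs_chi_deg}
    )
    return corrected


def rocking_branch(
    series: RockingSeries,
    geometry: DetectorGeometry,
    beam: BeamSpec,
    chi_grid: np.ndarray,
    background_band: tuple[float, float] = (2.0, 2.2),
    max_abs_chi_deg: float = 30.0,
    q_sub_bins: int = 8,
) -> Profile1D:
    """Orientation trace near χ = 0 from a summed rocking series.

    Frames are summed over sample angles, azimuthally integrated over the
    series' q band with the map evaluated at the central rocking angle, and
    background-corrected with the rocking background band.
    """
    if len(series.frames) == 0:
        raise EmptySectorError("rocking series contains no frames")
    summed = series.summed()
    mid = float(np.mean(series.sample_angles_deg))
    qcmap = build_qchi_map(geometry, beam, incidence_deg=mid)
    signal = azimuthal_profile(summed, qcmap, series.q_band, chi_grid, q_sub_bins=q_sub_bins)
    background = azimuthal_profile(summed, qcmap, background_band, chi_grid)
    n_filled = _fill_missing_bins(background, max_abs_chi_deg)
    corrected = local_background_subtract(signal, background)
    corrected.meta["background_bins_interpolated"] = n_filled
    outside = np.abs(corrected.grid) > max_abs_chi_deg
    corrected.intensity[outside] = np.nan
    corrected.sigma[outside] = np.nan
    corrected.n_pixels[outside] = 0
    corrected.meta.update(
        {"branch": "rocking", "q_band_invA": series.q_band, "max_abs_chi_deg": max_abs_chi_deg}
    )
    return corrected


def _fill_missing_bins(profile: Profile1D, within_abs_chi: float) -> int:
    """Interpolate a smooth background trace across empty bins.

    The local-background q band sits at a different scattering angle than
    the signal band, so its own missing wedge can blank a few bins near
    χ = 0 that the signal band does cover.  The background is smooth in χ;
    fill those bins by linear interpolation from the valid ones (edge-held
    at the ends).  Returns the number of bins filled.
    """
    missing = (~profile.valid) & (np.abs(profile.grid) <= within_abs_chi)
    if not np.any(missing):
        return 0
    valid = profile.valid
    if not np.any(valid):
        raise EmptySectorError("background profile has no valid bins at all")
    profile.intensity[missing] = np.interp(
        profile.grid[missing], profile.grid[valid], profile.intensity[valid]
    )
    profile.sigma[missing] = np.interp(
        profile.grid[missing], profile.grid[valid], profile.sigma[valid]
    )
    profile.n_pixels[missing] = 1
    return int(np.sum(missing))


def _interp_valid(profile: Profile1D, chi_points: np.ndarray) -> np.ndarray:
    valid = profile.valid
    if not np.any(valid):
        raise EmptySectorError("profile has no valid bins to interpolate")
    return np.interp(chi_points, profile.grid[valid], profile.intensity[valid])


def stitch(
    giwaxs: Profile1D,
    rocking: Profile1D,
    match_chi_deg: float = 7.5,
) -> PoleFigure:
    """Stitch the two branches into a full [−90°, 90°] pole figure.

    The scale factor s = mean(rocking at ±χ_m) / mean(GIWAXS at ±χ_m)
    (interpolated at the match points, symmetric lobes averaged first)
    multiplies the GIWAXS branch.  |χ| < χ_m comes from the rocking branch;
    |χ| ≥ χ_m from the scaled GIWAXS branch.
    """
    giwaxs.require_same_grid(rocking)
    match_pts = np.array([-match_chi_deg, match_chi_deg])
    g_match = float(np.mean(_interp_valid(giwaxs, match_pts)))
    r_match = float(np.mean(_interp_valid(rocking, match_pts)))
    if g_match <= 0 or r_match <= 0:
        raise ScalingError(
            f"cannot scale branches: mean at ±{match_chi_deg} deg is "
            f"{g_match:.4g} (GIWAXS) / {r_match:.4g} (rocking)"
        )
    scale = r_match / g_match

    grid = giwaxs.grid
    use_rocking = np.abs(grid) < match_chi_deg
    intensity = np.where(use_rocking, rocking.intensity, scale * giwaxs.intensity)
    sigma = np.where(use_rocking, rocking.sigma, scale * giwaxs.sigma)
    branch = np.where(use_rocking, "rocking", "giwaxs").astype("<U8")

    # fall back to the other branch where the preferred one is missing
    swap = ~np.isfinite(intensity)
    alt = np.where(use_rocking, scale * giwaxs.intensity, rocking.intensity)
    alt_sigma = np.where(use_rocking, scale * giwaxs.sigma, rocking.sigma)
    intensity[swap] = alt[swap]
    sigma[swap] = alt_sigma[swap]
    branch[swap & np.isfinite(intensity)] = "overlap"
    if not np.all(np.isfinite(intensity)):
        bad = grid[~np.isfinite(intensity)]
        raise EmptySectorError(
            f"no branch covers chi = {np.array2string(bad, precision=1)} deg"
        )

    q_band = tuple(giwaxs.meta.get("q_band_invA", DEFAULT_Q_BAND))
    return PoleFigure(
        chi_grid=grid.copy(),
        intensity=intensity,
        sigma=sigma,
        branch=branch,
        scale_factor=scale,
        q_band=q_band,  # type: ignore[arg-type]
        meta={"match_chi_deg": match_chi_deg},
    )


# ------------------------------------------------------------------- metrics
def _fold(pf: PoleFigure) -> tuple[np.ndarray, np.ndarray]:
    """Folded |χ| profile on a fine grid, with a left/right asymmetry check."""
    finite = np.isfinite(pf.intensity)
    chi = pf.chi_grid[finite]
    intensity = pf.intensity[finite]
    fine = np.arange(0.0, 90.0 + _FINE_STEP_DEG / 2, _FINE_STEP_DEG)

    left_sel = chi <= 0
    right_sel = chi >= 0
    sides = []
    for sel, sign in ((left_sel, -1.0), (right_sel, 1.0)):
        if np.sum(sel) >= 2:
            x = sign * chi[sel]
            order = np.argsort(x)
            sides.append(np.interp(fine, x[order], intensity[sel][order]))
    if not sides:
        raise EmptySectorError("pole figure has no valid bins")
    folded = np.mean(sides, axis=0)
    if len(sides) == 2:
        denom = np.trapezoid(np.abs(folded), fine)
        if denom > 0:
            asym = np.trapezoid(np.abs(sides[0] - sides[1]), fine) / denom
            if asym > 0.2:
                warnings.warn(
                    f"pole figure left/right asymmetry {asym:.1%} exceeds 20%; "
                    "folded metrics may be biased",
                    stacklevel=3,
                )
    return fine, folded


def oriented_fraction(
    pf: PoleFigure,
    chi0_deg: float = 34.0,
    weighting: str = "sin_chi",
) -> float:
    """Fraction of the orientation distribution within ±χ₀.

    fraction = ∫₀^χ₀ I(χ) w(χ) dχ / ∫₀^90 I(χ) w(χ) dχ on the folded |χ|
    trace, with w = sin χ (hemisphere measure, default) or w = 1.
    Equals 1 exactly at χ₀ = 90° for any positive pole figure.
    """
    if not 0 < chi0_deg <= 90:
        raise InvalidInput("chi0 must lie in (0, 90] degrees")
    if weighting not in ("sin_chi", "flat"):
        raise InvalidInput("weighting must be 'sin_chi' or 'flat'")
    valid = np.isfinite(pf.intensity)
    if not np.any(valid & (np.abs(pf.chi_grid) <= chi0_deg)):
        raise EmptySectorError("no valid pole-figure bins inside the numerator range")
    fine, folded = _fold(pf)
    w = np.sin(np.radians(fine)) if weighting == "sin_chi" else np.ones_like(fine)
    integrand = folded * w
    inside = fine <= chi0_deg
    numerator = np.trapezoid(integrand[inside], fine[inside])
    denominator = np.trapezoid(integrand, fine)
    if denominator == 0:
        raise EmptySectorError("pole figure integrates to zero")
    return float(numerator / denominator)


def texture_width(pf: PoleFigure) -> float:
    """FWHM (degrees) of the folded I(χ) about its maximum.

    Linear interpolation between samples.  Returns NaN (a flagged result,
    not an exception) when no half-maximum crossing exists — e.g. for an
    isotropic distribution — or when the maximum sits at |χ| ≥ 45°.
    """
    fine, folded = _fold(pf)
    search = fine < 45.0
    i_max = int(np.argmax(np.where(search, folded, -np.inf)))
    peak = folded[i_max]
    if not np.isfinite(peak) or peak <= 0:
        return float("nan")
    half = peak / 2.0

    def crossing(indices) -> float | None:
        for j in indices:
            if folded[j] < half:
                x0, x1 = fine[j - 1], fine[j]
                y0, y1 = folded[j - 1], folded[j]
                if y0 == y1:
                    return x0
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
        return None

    right = crossing(range(i_max + 1, fine.size))
    if right is None:
        return float("nan")
    left = None
    for j in range(i_max, 0, -1):
        if folded[j - 1] < half:
            x0, x1 = fine[j - 1], fine[j]
            y0, y1 = folded[j - 1], folded[j]
            left = x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            break
    if left is None:
        # still above half at the fold axis: on signed chi the distribution
        # is above half from -right to +right
        return 2.0 * right
    return right - left


def segal_ci(profile: Profile1D) -> float:
    """Segal crystallinity index, percent, from a 1D q-space pattern.

    CI = 100·(I_200 − I_am)/I_200 with I_200 the maximum intensity in
    q ∈ [1.40, 1.70] 1/Å (the 200 reflection window) and I_am the minimum
    in q ∈ [1.10, 1.40] 1/Å (the amorphous valley).  These windows are the
    q-space transcription of Segal's Cu-Kα 2θ points (22.6° and ~18.7°),
    wavelength-independent by construction.
    """
    if profile.axis != "q":
        raise InvalidInput("Segal CI requires a q-axis profile")
    valid = profile.valid
    grid = profile.grid
    cry = valid & (grid >= 1.40) & (grid <= 1.70)
    amo = valid & (grid >= 1.10) & (grid <= 1.40)
    if not np.any(cry) or not np.any(amo):
        raise InvalidInput(
            "profile grid does not cover the Segal windows [1.10, 1.40] and [1.40, 1.70] 1/A"
        )
    i200 = float(np.max(profile.intensity[cry]))
    iam = float(np.min(profile.intensity[amo]))
    if i200 <= 0:
        raise InvalidInput("non-positive crystalline maximum; cannot form Segal CI")
    return 100.0 * (i200 - iam) / i200
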