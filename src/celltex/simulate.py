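"""Forward renderer: synthetic GIWAXS / rocking / transmission frames.

Generates 2D detector count arrays from a generative :class:`Scene` so the
whole reduction and pole-figure chain is testable without beamline data.
A scene composes crystalline phases (peak list + orientation texture +
scale), an isotropic amorphous halo, and a flat background; frames carry
independent Poisson counting noise controlled by one explicit integer seed.

The expected count at a pixel with reciprocal coordinates (q, χ) is

    exposure · Σ_phases [ scale · R_phase(q) · f_texture(χ) ] + halo(q) + bg

where R_phase is the Scherrer-broadened radial profile (unit-area peaks)
and f_texture the orientation density, normalized over the hemisphere with
the sin(χ) measure so that injected "fraction within ±χ₀" values have
unambiguous analytic values.

Rocking frames are rendered with the same exact map evaluated at the
rocked incidence angle θ_s, so a vertical pixel at the Bragg ring probes
crystallite tilt |θ_B − θ_s| exactly; summing a series over a small range
around θ_B samples the orientation density near χ = 0 and fills the
GIWAXS missing wedge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

from .crystal import PhasePeakSet, cellulose_phase, phase_radial_profile, wax_phase
from .errors import InvalidInput, UnknownPresetError
from .optics import BeamSpec, DetectorGeometry, build_qchi_map, build_transmission_map
from .crystal import _gaussian_area

__all__ = [
    "TextureModel",
    "ScenePhase",
    "Scene",
    "RockingSeries",
    "render_giwaxs",
    "render_rocking_series",
    "render_transmission",
    "scene_presets",
    "default_detector",
    "PRESET_NAMES",
]

#: Renderable width of the nominally delta-like in-plane wax texture.
WAX_TEXTURE_SIGMA_DEG = 4.0

_TEXTURE_KINDS = ("isotropic", "gaussian_out_of_plane", "delta_in_plane")


@lru_cache(maxsize=256)
def _gaussian_norm(sigma: float, center: float) -> float:
    """Hemisphere normalization 2π ∫ g(χ) sinχ dχ for a Gaussian density."""

    def integrand(chi_rad: float) -> float:
        chi_deg = math.degrees(chi_rad)
        return math.exp(-0.5 * ((chi_deg - center) / sigma) ** 2) * math.sin(chi_rad)

    value, _ = quad(integrand, 0.0, math.pi / 2.0, limit=200)
    return 2.0 * math.pi * value


@dataclass(frozen=True)
class TextureModel:
    """Orientation density of one phase over the pole hemisphere.

    ``isotropic`` — constant density 1/(2π) per steradian.
    ``gaussian_out_of_plane`` — Gaussian in χ about ``center_chi_deg``
    (default 0, the substrate normal), width ``sigma_chi_deg``.
    ``delta_in_plane`` — narrow Gaussian at χ = 90° (width 4°), the
    renderable stand-in for a true in-plane delta.
    """

    kind: str
    sigma_chi_deg: float | None = None
    center_chi_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _TEXTURE_KINDS:
            raise InvalidInput(f"texture kind must be one of {_TEXTURE_KINDS}")
        if self.kind == "gaussian_out_of_plane" and not (
            self.sigma_chi_deg is not None and self.sigma_chi_deg > 0
        ):
            raise InvalidInput("gaussian texture requires sigma_chi_deg > 0")

    def _params(self) -> tuple[float, float] | None:
        if self.kind == "gaussian_out_of_plane":
            return float(self.sigma_chi_deg), float(self.center_chi_deg)
        if self.kind == "delta_in_plane":
            return WAX_TEXTURE_SIGMA_DEG, 90.0
        return None

    def density(self, chi_deg) -> np.ndarray:
        """Orientation density per steradian at polar angle |χ| (degrees)."""
        chi = np.abs(np.asarray(chi_deg, dtype=float))
        params = self._params()
        if params is None:
            return np.full_like(chi, 1.0 / (2.0 * math.pi))
        sigma, center = params
        norm = _gaussian_norm(sigma, center)
        return np.exp(-0.5 * ((chi - center) / sigma) ** 2) / norm

    def fraction_within(self, chi0_deg: float) -> float:
        """Analytic fraction of crystallites with |χ| ≤ χ₀ (sin χ measure)."""
        if not 0 < chi0_deg <= 90:
            raise InvalidInput("chi0 must lie in (0, 90] degrees")
        params = self._params()
        if params is None:
            return 1.0 - math.cos(math.radians(chi0_deg))
        sigma, center = params

        def integrand(chi_rad: float) -> float:
            chi_deg = math.degrees(chi_rad)
            return math.exp(-0.5 * ((chi_deg - center) / sigma) ** 2) * math.sin(chi_rad)

        num, _ = quad(integrand, 0.0, math.radians(chi0_deg), limit=200)
        den, _ = quad(integrand, 0.0, math.pi / 2.0, limit=200)
        return num / den


@dataclass(frozen=True)
class ScenePhase:
    peaks: PhasePeakSet
    texture: TextureModel
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise InvalidInput("phase scale must be non-negative")


@dataclass
class Scene:
    """Generative description of everything that scatters.

    ``amorphous_halo`` is ``(center_q, fwhm_q, area)`` — an isotropic broad
    Gaussian in q — or None.  ``flat_background`` is a constant expected
    count per pixel; ``exposure`` scales every component linearly.
    """

    phases: list[ScenePhase] = field(default_factory=list)
    amorphous_halo: tuple[float, float, float] | None = None
    flat_background: float = 0.0
    exposure: float = 1.0

    def __post_init__(self) -> None:
        if self.exposure < 0 or self.flat_background < 0:
            raise InvalidInput("exposure and background must be non-negative")
        if not self.phases and self.amorphous_halo is None and self.flat_background == 0:
            # an all-empty scene is allowed only as an explicit degenerate case
            pass

    def isotropic_radiance(self, q: np.ndarray) -> np.ndarray:
        """χ-independent part: halo plus background (before exposure)."""
        out = np.full_like(np.asarray(q, dtype=float), float(self.flat_background))
        if self.amorphous_halo is not None:
            center, fwhm, area = self.amorphous_halo
            out = out + area * _gaussian_area(np.asarray(q, dtype=float), center, fwhm)
        return out

    def expected_counts(self, q: np.ndarray, chi_deg: np.ndarray) -> np.ndarray:
        """Noise-free expected counts at reciprocal coordinates (q, χ)."""
        q = np.asarray(q, dtype=float)
        mean = self.isotropic_radiance(q)
        for phase in self.phases:
            if phase.scale == 0:
                continue
            radial = phase_radial_profile(phase.peaks, q)
            mean = mean + phase.scale * radial * phase.texture.density(chi_deg)
        return self.exposure * mean


@dataclass
class RockingSeries:
    """Frames of a specular rocking scan with their sample angles."""

    sample_angles_deg: np.ndarray
    frames: list[np.ndarray]
    q_band: tuple[float, float]

    def __post_init__(self) -> None:
        self.sample_angles_deg = np.asarray(self.sample_angles_deg, dtype=float)
        if len(self.frames) != self.sample_angles_deg.size:
            raise InvalidInput("one frame per sample angle required")
        if self.sample_angles_deg.size >= 2 and not np.all(
            np.diff(self.sample_angles_deg) > 0
        ):
            raise InvalidInput("sample angles must be strictly increasing")

    def summed(self) -> np.ndarray:
        return np.sum(self.frames, axis=0)


def _check_seed(seed) -> None:
    if seed is not None and not isinstance(seed, (int, np.integer)):
        raise InvalidInput(f"seed must be an integer or None, got {type(seed).__name__}")


def render_giwaxs(
    scene: Scene,
    geometry: DetectorGeometry,
    beam: BeamSpec,
    seed: int | None = None,
    noiseless: bool = False,
) -> np.ndarray:
    """One GIWAXS frame; Poisson counts unless ``noiseless``."""
    _check_seed(seed)
    qcmap = build_qchi_map(geometry, beam)
    mean = scene.expected_counts(qcmap.q, qcmap.chi)
    mean = np.where(qcmap.mask, mean, 0.0)
    if noiseless:
        return mean
    rng = np.random.default_rng(seed)
    return rng.poisson(mean).astype(np.float64)


def render_rocking_series(
    scene: Scene,
    geometry: DetectorGeometry,
    beam: BeamSpec,
    theta_range_deg: tuple[float, float],
    n_frames: int,
    seed: int | None = None,
    q_band: tuple[float, float] = (0.99, 1.31),
    noiseless: bool = False,
) -> RockingSeries:
    """Specular rocking series: one frame per sample angle θ_s.

    Each frame is rendered with the exact grazing map at incidence θ_s, so
    crystallites tilted by ≈ θ_s − θ_B from the surface satisfy the Bragg
    condition near the specular direction.  A warning is logged if the
    angular range misses the Bragg angle of ``q_band``.
    """
    _check_seed(seed)
    lo, hi = theta_range_deg
    if not (0 < lo < hi < 20):
        raise InvalidInput("theta range must satisfy 0 < lo < hi < 20 degrees")
    if n_frames < 2:
        raise InvalidInput("need at least 2 rocking frames")
    theta_b = np.degrees(
        np.arcsin(np.array(q_band) / (2.0 * beam.k_a))
    )
    if hi < theta_b[0] or lo > theta_b[1]:
        import logging

        logging.getLogger(__name__).warning(
            "rocking range (%.2f, %.2f) deg excludes the Bragg angles "
            "(%.2f, %.2f) deg of the target band",
            lo,
            hi,
            theta_b[0],
            theta_b[1],
        )
    angles = np.linspace(lo, hi, n_frames)
    rng = np.random.default_rng(seed)
    frames = []
    for theta_s in angles:
        qcmap = build_qchi_map(geometry, beam, incidence_deg=float(theta_s))
        mean = scene.expected_counts(qcmap.q, qcmap.chi)
        mean = np.where(qcmap.mask, mean, 0.0)
        frames.append(mean if noiseless else rng.poisson(mean).astype(np.float64))
    return RockingSeries(sample_angles_deg=angles, frames=frames, q_band=q_band)


def render_transmission(
    scene: Scene,
    geometry: DetectorGeometry,
    beam: BeamSpec,
    seed: int | None = None,
    noiseless: bool = False,
) -> np.ndarray:
    """Transmission-WAXS frame: beam normal to the cell-wall plane.

    Out-of-plane texture is invisible in this projection; every phase
    contributes its full radial profile isotropically (rings), at the
    isotropic orientation density 1/(2π).
    """
    _check_seed(seed)
    qcmap = build_transmission_map(geometry, beam)
    mean = scene.isotropic_radiance(qcmap.q)
    for phase in scene.phases:
        if phase.scale == 0:
            continue
        mean = mean + phase.scale * phase_radial_profile(phase.peaks, qcmap.q) / (
            2.0 * math.pi
        )
    mean = scene.exposure * np.where(qcmap.mask, mean, 0.0)
    if noiseless:
        return mean
    rng = np.random.default_rng(seed)
    return rng.poisson(mean).astype(np.float64)


# -------------------------------------------------------------------- presets
def default_detector() -> DetectorGeometry:
    """Desk-scale default: 512×512, 0.172 mm pixels, 120 mm distance.

    The short distance keeps the in-plane wax reflections (q ≈ 1.52 and
    1.68 1/Å) on the detector at 10 keV while the vertical reach extends to
    q ≈ 3.1 1/Å for rocking-scan background bands.
    """
    return DetectorGeometry(
        distance_mm=120.0,
        pixel_mm=0.172,
        beam_center=(502.0, 256.0),
        shape=(512, 512),
    )


def default_transmission_detector() -> DetectorGeometry:
    """Centered beam for transmission rings."""
    return DetectorGeometry(
        distance_mm=120.0,
        pixel_mm=0.172,
        beam_center=(256.0, 256.0),
        shape=(512, 512),
    )


#: Stand-in amorphous halo (center, FWHM, area): the experimental halo of
#: digested/amorphous wall material is not parameterized anywhere in the
#: literature values used here; this is a labeled synthetic choice.
DEFAULT_HALO = (1.4, 0.7, 800.0)

PRESET_NAMES = ("unextracted", "driselase", "chloroform", "ground", "stem_segment4")


def scene_presets(
    name: str,
    sigma_chi_deg: float = 20.0,
    cellulose_scale: float = 3000.0,
    wax_scale: float = 1200.0,
    halo: tuple[float, float, float] | None = DEFAULT_HALO,
    background: float = 2.0,
    exposure: float = 1.0,
) -> Scene:
    """Named scenes emulating the specimen preparations.

    ``unextracted`` — out-of-plane-textured cellulose + in-plane wax + halo;
    ``driselase``   — wax + halo only (all polysaccharides digested);
    ``chloroform``  — textured cellulose + halo (wax dissolved away);
    ``ground``      — isotropic cellulose + halo (milled powder);
    ``stem_segment4`` — isotropic cellulose + halo (cylindrical-tissue
    averaging at the base of the inflorescence stem).
    """
    gaussian = TextureModel("gaussian_out_of_plane", sigma_chi_deg=sigma_chi_deg)
    isotropic = TextureModel("isotropic")
    in_plane = TextureModel("delta_in_plane")
    cellulose = ScenePhase(cellulose_phase(), gaussian, cellulose_scale)
    cellulose_iso = ScenePhase(cellulose_phase(), isotropic, cellulose_scale)
    wax = ScenePhase(wax_phase(), in_plane, wax_scale)

    scenes = {
        "unextracted": [cellulose, wax],
        "driselase": [wax],
        "chloroform": [cellulose],
        "ground": [cellulose_iso],
        "stem_segment4": [cellulose_iso],
    }
    if name not in scenes:
        raise UnknownPresetError(
            f"unknown scene preset {name!r}; available: {', '.join(sorted(scenes))}"
        )
    return Scene(
        phases=scenes[name],
        amorphous_halo=halo,
        flat_background=background,
        exposure=exposure,
    )
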