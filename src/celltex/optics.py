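"""Grazing-incidence X-ray optics and reciprocal-space mapping.

Closed-form optics for a thin organic film on a substrate — wavelength,
electron density, critical angle for total external reflection, and
penetration depth — together with the exact detector→(q, χ) mapping for
grazing-incidence wide-angle scattering (GIWAXS), including the Ewald-sphere
curvature and the missing wedge around the substrate normal.

Conventions
-----------
* Energies in keV, wavelengths in Angstrom, q in 1/Angstrom.
* All interface angles in degrees; radians are internal only.
* χ is the polar angle on the pole sphere measured from the substrate
  normal: χ = 0 out-of-plane (vertical on the detector above the beam
  center), χ = ±90° in-plane, signed left/right of the vertical axis.
* No small-angle approximations anywhere: the laboratory frame is rotated
  exactly by the incidence angle α_i.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InvalidInput

__all__ = [
    "HC_KEV_A",
    "R_E_A",
    "BeamSpec",
    "Material",
    "DetectorGeometry",
    "QChiMap",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "q_from_scattering_angle",
    "scattering_angle_from_q",
    "d_from_q",
    "electron_density",
    "critical_angle",
    "attenuation_coefficient",
    "penetration_depth",
    "build_qchi_map",
    "build_transmission_map",
    "missing_wedge_halfangle",
    "beam_from_config",
    "geometry_from_config",
    "export_qchi_tiff",
]

#: hc in keV·Angstrom (λ[Å] = HC_KEV_A / E[keV]).
HC_KEV_A = 12.3984
#: Classical electron radius in Angstrom.
R_E_A = 2.8179403e-5
#: Avogadro constant.
N_AVOGADRO = 6.02214076e23

#: Z and standard atomic weight for the elements of carbohydrate matter.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
}

# Mass attenuation coefficients (total, cm²/g) on a small static energy grid,
# NIST-style values; interpolated log-log.  Covers the 8-15 keV window used
# at organic-film GIWAXS beamlines.
_MU_RHO_GRID_KEV = np.array([8.0, 10.0, 15.0])
MASS_ATTENUATION: dict[str, np.ndarray] = {
    "H": np.array([0.3912, 0.3854, 0.3764]),
    "C": np.array([4.576, 2.373, 0.8074]),
    "N": np.array([7.562, 3.879, 1.236]),
    "O": np.array([11.63, 5.952, 1.836]),
}

_ORIENTATIONS = ("up_row0", "up_rowN", "up_col0", "up_colN")


# --------------------------------------------------------------------- scalars
def energy_to_wavelength(energy_kev: float) -> float:
    """Photon wavelength in Angstrom, λ = hc/E with hc = 12.3984 keV·Å."""
    if not energy_kev > 0:
        raise InvalidInput(f"energy must be positive, got {energy_kev}")
    return HC_KEV_A / energy_kev


def wavelength_to_energy(wavelength_a: float) -> float:
    if not wavelength_a > 0:
        raise InvalidInput(f"wavelength must be positive, got {wavelength_a}")
    return HC_KEV_A / wavelength_a


def q_from_scattering_angle(theta_deg, wavelength_a: float):
    """Momentum transfer q = 4π sin(θ/2)/λ for full scattering angle θ."""
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 180):
        raise InvalidInput("scattering angle must lie in [0, 180) degrees")
    if not wavelength_a > 0:
        raise InvalidInput("wavelength must be positive")
    q = 4.0 * np.pi * np.sin(np.radians(theta) / 2.0) / wavelength_a
    return float(q) if np.isscalar(theta_deg) else q


def scattering_angle_from_q(q, wavelength_a: float):
    """Inverse of :func:`q_from_scattering_angle` (degrees)."""
    qa = np.asarray(q, dtype=float)
    if not wavelength_a > 0:
        raise InvalidInput("wavelength must be positive")
    s = qa * wavelength_a / (4.0 * np.pi)
    if np.any(s < 0) or np.any(s > 1):
        raise InvalidInput("q outside the accessible range [0, 4π/λ]")
    theta = 2.0 * np.degrees(np.arcsin(s))
    return float(theta) if np.isscalar(q) else theta


def d_from_q(q):
    """Lattice spacing d = 2π/q (an involution: d_from_q(d_from_q(x)) = x)."""
    qa = np.asarray(q, dtype=float)
    if np.any(qa <= 0):
        raise InvalidInput("q must be positive")
    d = 2.0 * np.pi / qa
    return float(d) if np.isscalar(q) else d


# ---------------------------------------------------------------- domain types
@dataclass(frozen=True)
class BeamSpec:
    """Incident beam: photon energy and grazing incidence angle.

    The wavelength is derived (λ = hc/E) and exposed as a property.
    """

    energy_kev: float
    incidence_deg: float = 0.15

    def __post_init__(self) -> None:
        if not self.energy_kev > 0:
            raise InvalidInput(f"energy must be positive, got {self.energy_kev}")
        if not (0 <= self.incidence_deg < 5):
            raise InvalidInput(
                f"incidence angle must lie in [0, 5) degrees, got {self.incidence_deg}"
            )

    @property
    def wavelength_a(self) -> float:
        return energy_to_wavelength(self.energy_kev)

    @property
    def k_a(self) -> float:
        """Wavevector magnitude 2π/λ in 1/Angstrom."""
        return 2.0 * np.pi / self.wavelength_a


@dataclass(frozen=True)
class Material:
    """Amorphous average material: elemental mass fractions and density."""

    mass_fractions: Mapping[str, float]
    density_g_cm3: float

    def __post_init__(self) -> None:
        fractions = dict(self.mass_fractions)
        if not fractions:
            raise InvalidInput("material needs at least one element")
        for symbol, w in fractions.items():
            if symbol not in ELEMENTS:
                raise InvalidInput(f"unknown element symbol: {symbol!r}")
            if w < 0:
                raise InvalidInput(f"negative mass fraction for {symbol}")
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidInput(f"mass fractions must sum to 1, got {total}")
        if not self.density_g_cm3 > 0:
            raise InvalidInput("density must be positive")
        object.__setattr__(self, "mass_fractions", fractions)

    @classmethod
    def from_formula(cls, formula: str, density_g_cm3: float) -> "Material":
        """Build from a Hill-style formula such as ``"C6H10O5"``."""
        tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
        counts: dict[str, float] = {}
        for symbol, num in tokens:
            if not symbol:
                continue
            if symbol not in ELEMENTS:
                raise InvalidInput(f"unknown element symbol: {symbol!r}")
            counts[symbol] = counts.get(symbol, 0.0) + (int(num) if num else 1)
        if not counts:
            raise InvalidInput(f"could not parse formula {formula!r}")
        mass = sum(n * ELEMENTS[s][1] for s, n in counts.items())
        fractions = {s: n * ELEMENTS[s][1] / mass for s, n in counts.items()}
        return cls(mass_fractions=fractions, density_g_cm3=density_g_cm3)

    @classmethod
    def cell_wall(cls, density_g_cm3: float = 1.5) -> "Material":
        """Model primary-cell-wall material: anhydroglucose (C6H10O5).

        Cellulose, pectin and hemicellulose are all polysaccharides of
        near-identical stoichiometry and density (~1.5 g/cm³), so a single
        anhydroglucose composition is an adequate average for the optics.
        """
        return cls.from_formula("C6H10O5", density_g_cm3)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat area detector perpendicular to the incident beam.

    ``beam_center`` is the (row, col) pixel hit by the direct beam —
    fractional values allowed, and it may lie outside the frame.  Pixel
    centers sit at integer indices, row 0 at the image top.  ``orientation``
    declares which image direction points *up* (away from the substrate):
    one of ``up_row0`` (default: top of image is up), ``up_rowN``,
    ``up_col0``, ``up_colN``.
    """

    distance_mm: float
    pixel_mm: float
    beam_center: tuple[float, float]
    shape: tuple[int, int]
    orientation: str = "up_row0"

    def __post_init__(self) -> None:
        if not self.distance_mm > 0:
            raise InvalidInput("sample-detector distance must be positive")
        if not self.pixel_mm > 0:
            raise InvalidInput("pixel size must be positive")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise InvalidInput("shape must be (rows, cols) with positive entries")
        if self.orientation not in _ORIENTATIONS:
            raise InvalidInput(
                f"orientation must be one of {_ORIENTATIONS}, got {self.orientation!r}"
            )

    def pixel_offsets_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (vertical_up, horizontal) offsets from the beam center in mm."""
        rows, cols = self.shape
        r = np.arange(rows, dtype=float)[:, None]
        c = np.arange(cols, dtype=float)[None, :]
        r0, c0 = self.beam_center
        p = self.pixel_mm
        if self.orientation == "up_row0":
            v = (r0 - r) * p + 0.0 * c
            h = (c - c0) * p + 0.0 * r
        elif self.orientation == "up_rowN":
            v = (r - r0) * p + 0.0 * c
            h = (c0 - c) * p + 0.0 * r
        elif self.orientation == "up_col0":
            v = (c0 - c) * p + 0.0 * r
            h = (r - r0) * p + 0.0 * c
        else:  # up_colN
            v = (c - c0) * p + 0.0 * r
            h = (r0 - r) * p + 0.0 * c
        return np.broadcast_to(v, self.shape).copy(), np.broadcast_to(h, self.shape).copy()


@dataclass
class QChiMap:
    """Per-pixel reciprocal-space coordinates for one geometry/beam pair.

    ``q`` — |q| in 1/Angstrom; ``chi`` — signed polar angle from the
    substrate normal in degrees, clipped to [-90, 90]; ``q_xy`` — signed
    in-plane component; ``q_z`` — out-of-plane component (along the sample
    normal); ``weight`` — relative solid angle subtended by the pixel;
    ``mask`` — True where the pixel carries a valid (q, χ) sample (False at
    the direct beam, below the sample horizon, or clipped χ).
    """

    q: np.ndarray
    chi: np.ndarray
    q_xy: np.ndarray
    q_z: np.ndarray
    weight: np.ndarray
    mask: np.ndarray
    beam: BeamSpec = field(default=None)  # type: ignore[assignment]
    geometry: DetectorGeometry = field(default=None)  # type: ignore[assignment]


# ------------------------------------------------------------- optics formulas
def electron_density(material: Material) -> float:
    """Electron density in electrons per cubic Angstrom.

    ρ_e = ρ · N_A · Σ_i (w_i Z_i / A_i), converted from cm⁻³ to Å⁻³.
    """
    z_over_a = sum(
        w * ELEMENTS[s][0] / ELEMENTS[s][1] for s, w in material.mass_fractions.items()
    )
    return material.density_g_cm3 * N_AVOGADRO * z_over_a * 1e-24


def critical_angle(material: Material, energy_kev: float) -> float:
    """Critical angle for total external reflection, in degrees.

    δ = r_e λ² ρ_e / (2π) and θ_c = sqrt(2δ); absorption is neglected in
    θ_c, the standard approximation far from absorption edges.
    """
    lam = energy_to_wavelength(energy_kev)
    rho_e = electron_density(material)
    delta = R_E_A * lam * lam * rho_e / (2.0 * np.pi)
    return math.degrees(math.sqrt(2.0 * delta))


def attenuation_coefficient(
    material: Material,
    energy_kev: float,
    mass_attenuation: Mapping[str, float] | None = None,
) -> float:
    """Linear attenuation coefficient µ in cm⁻¹.

    ``mass_attenuation`` may supply per-element µ/ρ values (cm²/g) directly;
    otherwise the embedded table is interpolated log-log in energy.
    """
    mu_rho_total = 0.0
    for symbol, w in material.mass_fractions.items():
        if mass_attenuation is not None:
            if symbol not in mass_attenuation:
                raise InvalidInput(f"no mass-attenuation entry for element {symbol!r}")
            mu_rho = float(mass_attenuation[symbol])
        else:
            if symbol not in MASS_ATTENUATION:
                raise InvalidInput(f"no mass-attenuation entry for element {symbol!r}")
            table = MASS_ATTENUATION[symbol]
            if not (_MU_RHO_GRID_KEV[0] <= energy_kev <= _MU_RHO_GRID_KEV[-1]):
                raise InvalidInput(
                    f"energy {energy_kev} keV outside embedded attenuation grid "
                    f"[{_MU_RHO_GRID_KEV[0]}, {_MU_RHO_GRID_KEV[-1]}] keV"
                )
            mu_rho = float(
                np.exp(
                    np.interp(
                        np.log(energy_kev),
                        np.log(_MU_RHO_GRID_KEV),
                        np.log(table),
                    )
                )
            )
        mu_rho_total += w * mu_rho
    return material.density_g_cm3 * mu_rho_total


def penetration_depth(
    material: Material,
    energy_kev: float,
    alpha_deg: float,
    convention: str = "intensity",
    mass_attenuation: Mapping[str, float] | None = None,
) -> float:
    """1/e penetration depth of the evanescent/refracted wave, in µm.

    Λ = λ / (4π Im[sqrt(α² − θ_c² + 2iβ)]) with β = µλ/(4π): this is the
    depth at which the *intensity* falls to 1/e (default).  With
    ``convention="amplitude"`` the amplitude-1/e depth (×2) is returned.
    In the absorption-dominated limit α ≫ θ_c the intensity depth tends to
    sin(α)/µ; below θ_c with β → 0 it tends to the evanescent depth
    λ/(4π sqrt(θ_c² − α²)).
    """
    if not alpha_deg > 0:
        raise InvalidInput("incidence angle must be positive")
    if convention not in ("intensity", "amplitude"):
        raise InvalidInput("convention must be 'intensity' or 'amplitude'")
    lam = energy_to_wavelength(energy_kev)
    alpha = math.radians(alpha_deg)
    theta_c = math.radians(critical_angle(material, energy_kev))
    mu_cm = attenuation_coefficient(material, energy_kev, mass_attenuation)
    beta = mu_cm * (lam * 1e-8) / (4.0 * np.pi)
    im_root = complex(alpha * alpha - theta_c * theta_c, 2.0 * beta) ** 0.5
    im = im_root.imag
    if im <= 0:
        return math.inf
    depth_a = lam / (4.0 * np.pi * im)
    if convention == "amplitude":
        depth_a *= 2.0
    return depth_a * 1e-4  # Angstrom -> µm


# -------------------------------------------------------------------- mapping
def missing_wedge_halfangle(q, beam: BeamSpec):
    """Smallest |χ| accessible at momentum transfer q in grazing incidence.

    A flat detector probes, at momentum transfer q, plane normals tilted by
    at least χ_min = arcsin(q/2k) − α_i from the substrate normal (floored
    at zero).  Crystallites oriented more nearly parallel to the substrate
    than this are invisible to GIWAXS and must come from a rocking scan.
    """
    qa = np.asarray(q, dtype=float)
    k = beam.k_a
    if np.any(qa <= 0) or np.any(qa >= 2 * k):
        raise InvalidInput("q must lie strictly inside (0, 2k)")
    chi_min = np.degrees(np.arcsin(qa / (2.0 * k))) - beam.incidence_deg
    chi_min = np.maximum(chi_min, 0.0)
    return float(chi_min) if np.isscalar(q) else chi_min


def build_qchi_map(
    geometry: DetectorGeometry, beam: BeamSpec, incidence_deg: float | None = None
) -> QChiMap:
    """Exact per-pixel (q, χ) map for grazing incidence.

    The beam travels along +y in the laboratory frame; the detector plane is
    perpendicular to it at ``distance_mm``.  The sample surface is tilted by
    α_i against the beam, i.e. its normal is n = (0, −sin α_i, cos α_i), so
    that the specular exit direction (2α_i above the horizon) has χ = 0 at
    q = 2k sin α_i.  For each pixel the
    scattered unit vector is formed exactly, q = k(k̂_f − k̂_i) is decomposed
    into the out-of-plane component q·n and the in-plane remainder, and
    χ = atan2(|q_ip|, q·n) carries the sign of the horizontal offset.

    ``incidence_deg`` overrides the beam's grazing angle — used for
    rocking-scan frames where the sample is tilted well beyond the grazing
    regime (up to 20°).
    """
    v_mm, h_mm = geometry.pixel_offsets_mm()
    d_mm = geometry.distance_mm
    k = beam.k_a
    tilt = beam.incidence_deg if incidence_deg is None else float(incidence_deg)
    if not 0 <= tilt < 20:
        raise InvalidInput("sample tilt must lie in [0, 20) degrees")
    alpha = math.radians(tilt)

    length = np.sqrt(d_mm * d_mm + h_mm * h_mm + v_mm * v_mm)
    ux = h_mm / length
    uy = d_mm / length
    uz = v_mm / length

    # q components (lab frame), units of k
    qx = ux
    qy = uy - 1.0
    qz = uz
    q = k * np.sqrt(np.maximum(qx * qx + qy * qy + qz * qz, 0.0))

    # out-of-plane component along the sample normal n = (0, -sin a, cos a)
    qn = k * (-qy * math.sin(alpha) + qz * math.cos(alpha))
    qip_sq = np.maximum((q / k) ** 2 - (qn / k) ** 2, 0.0)
    qip = k * np.sqrt(qip_sq)

    sign = np.where(h_mm < 0, -1.0, 1.0)
    with np.errstate(invalid="ignore"):
        chi = np.degrees(np.arctan2(qip, qn)) * sign
    chi = np.where(q > 0, chi, 0.0)

    valid = (q > 1e-12) & (qn > 0) & (np.abs(chi) <= 90.0 + 1e-12)
    chi = np.clip(chi, -90.0, 90.0)

    weight = (d_mm / length) ** 3  # relative solid angle of a flat-detector pixel

    return QChiMap(
        q=q,
        chi=chi,
        q_xy=sign * qip,
        q_z=qn,
        weight=weight,
        mask=valid,
        beam=beam,
        geometry=geometry,
    )


def build_transmission_map(geometry: DetectorGeometry, beam: BeamSpec) -> QChiMap:
    """Per-pixel map for transmission geometry (beam normal to the sample).

    χ here is simply the detector azimuth from the "up" axis in degrees,
    spanning (−180, 180]; there is no missing wedge.
    """
    v_mm, h_mm = geometry.pixel_offsets_mm()
    d_mm = geometry.distance_mm
    length = np.sqrt(d_mm * d_mm + h_mm * h_mm + v_mm * v_mm)
    costheta = d_mm / length
    theta = np.degrees(np.arccos(np.clip(costheta, -1.0, 1.0)))
    q = q_from_scattering_angle(theta, beam.wavelength_a)
    chi = np.degrees(np.arctan2(h_mm, v_mm))
    radial = np.sqrt(h_mm * h_mm + v_mm * v_mm)
    mask = q > 1e-12
    # the grazing in-plane/out-of-plane split is meaningless here; store the
    # detector-plane components instead (useful for small-angle line cuts)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_h = np.where(radial > 0, q * h_mm / np.maximum(radial, 1e-300), 0.0)
        q_v = np.where(radial > 0, q * v_mm / np.maximum(radial, 1e-300), 0.0)
    weight = costheta**3
    return QChiMap(
        q=q,
        chi=chi,
        q_xy=q_h,
        q_z=q_v,
        weight=weight,
        mask=mask,
        beam=beam,
        geometry=geometry,
    )


# ---------------------------------------------------------------- config / IO
def beam_from_config(cfg: Mapping) -> BeamSpec:
    """Beam from a flat config block with keys energy_keV, incidence_deg."""
    try:
        return BeamSpec(
            energy_kev=float(cfg["energy_keV"]),
            incidence_deg=float(cfg.get("incidence_deg", 0.15)),
        )
    except KeyError as exc:
        raise InvalidInput(f"missing beam config key: {exc}") from exc


def geometry_from_config(cfg: Mapping) -> DetectorGeometry:
    """Geometry from keys distance_mm, pixel_mm, center_row/col, rows, cols."""
    try:
        return DetectorGeometry(
            distance_mm=float(cfg["distance_mm"]),
            pixel_mm=float(cfg["pixel_mm"]),
            beam_center=(float(cfg["center_row"]), float(cfg["center_col"])),
            shape=(int(cfg["rows"]), int(cfg["cols"])),
            orientation=str(cfg.get("orientation", "up_row0")),
        )
    except KeyError as exc:
        raise InvalidInput(f"missing geometry config key: {exc}") from exc


def export_qchi_tiff(qcmap: QChiMap, prefix) -> list[str]:
    """Write q, χ and mask as TIFFs (``<prefix>_q.tiff`` etc.) for inspection."""
    import tifffile

    paths = []
    for name, array, dtype in (
        ("q", qcmap.q, np.float32),
        ("chi", qcmap.chi, np.float32),
        ("mask", qcmap.mask, np.uint8),
    ):
        path = f"{prefix}_{name}.tiff"
        tifffile.imwrite(path, array.astype(dtype))
        paths.append(path)
    return paths
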