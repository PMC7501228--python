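"""Unit-cell crystallography for cellulose Iβ and epicuticular wax.

d-spacings from the general triclinic metric tensor, geometric peak lists,
Scherrer size broadening in q-space, and simulated 1D powder patterns used
to index grazing-incidence data from plant cell walls.

The monoclinic cellulose Iβ cell (a = 7.784 Å, b = 8.201 Å, c = 10.38 Å,
γ = 96.5°, chain axis along c) places the three equatorial reflections
(1̄10), (110) and (200) at q ≈ 1.055, 1.182 and 1.625 1/Å.  Which member of
the 110 pair carries the bar varies across the literature with the sign
convention of γ; this module therefore reports the *pair* with explicit
q_low/q_high roles and never asserts which label is which.

No structure factors are computed: relative peak weights are user-supplied
(Rietveld machinery is deliberately out of scope).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInput
from .profiles import Profile1D

__all__ = [
    "UnitCell",
    "Reflection",
    "PhasePeakSet",
    "UNIT_CELLS",
    "d_hkl",
    "peak_list",
    "scherrer_fwhm",
    "powder_pattern",
    "cellulose_phase",
    "wax_phase",
    "peaks_to_csv",
]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidInput("cell lengths must be positive")
        for angle in (self.alpha, self.beta, self.gamma):
            if not 0 < angle < 180:
                raise InvalidInput("cell angles must lie in (0, 180) degrees")
        g = self.metric_tensor()
        if np.linalg.det(g) <= 0:
            raise InvalidInput("cell metric tensor is not positive definite")

    def lattice_vectors(self) -> np.ndarray:
        """Rows are a, b, c in a Cartesian frame (a along x, b in xy plane)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        av = np.array([self.a, 0.0, 0.0])
        bv = np.array([self.b * math.cos(ga), self.b * math.sin(ga), 0.0])
        cx = self.c * math.cos(be)
        cy = self.c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz_sq = self.c * self.c - cx * cx - cy * cy
        if cz_sq <= 0:
            raise InvalidInput("cell angles are geometrically inconsistent")
        cv = np.array([cx, cy, math.sqrt(cz_sq)])
        return np.vstack([av, bv, cv])

    def metric_tensor(self) -> np.ndarray:
        vectors = self.lattice_vectors()
        return vectors @ vectors.T

    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())


#: Named cell presets, overridable from the pipeline config.
UNIT_CELLS: dict[str, UnitCell] = {
    # Monoclinic cellulose Iβ solved on tunicate cellulose.
    "cellulose_Ibeta_nishiyama2002": UnitCell(a=7.784, b=8.201, c=10.38, gamma=96.5),
}


@dataclass(frozen=True)
class Reflection:
    """One Bragg reflection: Miller indices, spacing and position."""

    hkl: tuple[int, int, int]
    d_a: float
    q_inv_a: float
    family_label: str = ""

    def __post_init__(self) -> None:
        if not self.q_inv_a > 0:
            raise InvalidInput("q must be positive")
        if abs(self.q_inv_a * self.d_a - 2.0 * np.pi) > 1e-9:
            raise InvalidInput("reflection violates q·d = 2π")


@dataclass
class PhasePeakSet:
    """A crystalline phase: its reflections, coherence size and weight."""

    name: str
    reflections: list[Reflection]
    crystal_size_a: float
    relative_weight: float = 1.0
    peak_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.crystal_size_a > 0:
            raise InvalidInput("crystal size must be positive")
        if self.relative_weight < 0:
            raise InvalidInput("relative weight must be non-negative")
        if self.peak_weights is None:
            self.peak_weights = np.ones(len(self.reflections))
        else:
            self.peak_weights = np.asarray(self.peak_weights, dtype=float)
            if self.peak_weights.size != len(self.reflections):
                raise InvalidInput("one peak weight per reflection required")


# ------------------------------------------------------------------ formulas
def d_hkl(cell: UnitCell, h: int, k: int, l: int) -> tuple[float, float]:
    """Lattice spacing and q of (hkl): returns ``(d_A, q_invA)``.

    Uses the reciprocal metric tensor, valid for any triclinic cell:
    1/d² = hᵀ G* h.
    """
    if (h, k, l) == (0, 0, 0):
        raise InvalidInput("(0,0,0) is not a reflection")
    hv = np.array([h, k, l], dtype=float)
    inv_d_sq = float(hv @ cell.reciprocal_metric() @ hv)
    d = 1.0 / math.sqrt(inv_d_sq)
    return d, 2.0 * np.pi / d


def _canonical(hkl: tuple[int, int, int]) -> bool:
    """True for the representative member of a Friedel pair ±(hkl)."""
    for index in hkl:
        if index > 0:
            return True
        if index < 0:
            return False
    return False


def peak_list(cell: UnitCell, q_max: float, hkl_range: int = 3) -> list[Reflection]:
    """Symmetry-reduced reflections with q ≤ q_max, ascending in q.

    Friedel pairs are collapsed (d(hkl) = d(-h-k-l) exactly) and distinct
    index triples whose spacings coincide within 1e-6 Å are merged into one
    entry with a combined family label such as ``"110/-110"``.
    """
    if not q_max > 0:
        raise InvalidInput("q_max must be positive")
    found: list[tuple[float, float, tuple[int, int, int]]] = []
    rng = range(-hkl_range, hkl_range + 1)
    for hkl in itertools.product(rng, rng, rng):
        if hkl == (0, 0, 0) or not _canonical(hkl):
            continue
        d, q = d_hkl(cell, *hkl)
        if q <= q_max:
            found.append((q, d, hkl))
    found.sort(key=lambda item: (item[0], item[2]))

    out: list[Reflection] = []
    for q, d, hkl in found:
        label = "".join(str(i) for i in hkl)
        if out and abs(out[-1].d_a - d) < 1e-6:
            prev = out[-1]
            out[-1] = Reflection(
                hkl=prev.hkl,
                d_a=prev.d_a,
                q_inv_a=prev.q_inv_a,
                family_label=prev.family_label + "/" + label,
            )
        else:
            out.append(Reflection(hkl=hkl, d_a=d, q_inv_a=q, family_label=label))
    return out


def scherrer_fwhm(crystal_size_a: float, shape_factor: float = 0.9) -> float:
    """Scherrer broadening in q-space: Δq(FWHM) = 2πK/L, 1/Angstrom."""
    if not crystal_size_a > 0:
        raise InvalidInput("crystal size must be positive")
    if not 0.5 <= shape_factor <= 1.5:
        raise InvalidInput("shape factor must lie in [0.5, 1.5]")
    return 2.0 * np.pi * shape_factor / crystal_size_a


_SQRT_8LN2 = math.sqrt(8.0 * math.log(2.0))


def _gaussian_area(q: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-area Gaussian parameterized by FWHM."""
    sigma = fwhm / _SQRT_8LN2
    return np.exp(-0.5 * ((q - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def _lorentzian_area(q: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return (gamma / math.pi) / ((q - center) ** 2 + gamma * gamma)


def phase_radial_profile(
    phase: PhasePeakSet,
    q: np.ndarray,
    shape_factor: float = 0.9,
    profile: str = "gaussian",
    eta: float = 0.5,
) -> np.ndarray:
    """Sum of unit-area peaks of one phase (each scaled by its peak weight)."""
    fwhm = scherrer_fwhm(phase.crystal_size_a, shape_factor)
    out = np.zeros_like(np.asarray(q, dtype=float))
    for refl, w in zip(phase.reflections, phase.peak_weights):
        if profile == "gaussian":
            peak = _gaussian_area(q, refl.q_inv_a, fwhm)
        elif profile == "pseudo_voigt":
            peak = eta * _lorentzian_area(q, refl.q_inv_a, fwhm) + (1 - eta) * _gaussian_area(
                q, refl.q_inv_a, fwhm
            )
        else:
            raise InvalidInput(f"unknown profile shape {profile!r}")
        out += w * peak
    return out


def powder_pattern(
    phases,
    amorphous: tuple[float, float, float] | None,
    q_grid: np.ndarray,
    shape_factor: float = 0.9,
    profile: str = "gaussian",
    eta: float = 0.5,
) -> Profile1D:
    """Simulated isotropic 1D pattern: Scherrer-broadened peaks plus a halo.

    ``amorphous`` is ``(center_q, fwhm_q, area)`` for a broad Gaussian halo,
    or None.  Peak areas are ``relative_weight × peak_weight`` per
    reflection, so the integrated pattern area equals the sum of component
    areas (linearity in phase addition).
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.ndim != 1 or q_grid.size < 2 or not np.all(np.diff(q_grid) > 0):
        raise InvalidInput("q_grid must be strictly increasing")
    intensity = np.zeros_like(q_grid)
    for phase in phases:
        intensity += phase.relative_weight * phase_radial_profile(
            phase, q_grid, shape_factor, profile, eta
        )
    if amorphous is not None:
        center, fwhm, area = amorphous
        intensity += area * _gaussian_area(q_grid, center, fwhm)
    return Profile1D(
        axis="q",
        grid=q_grid,
        intensity=intensity,
        sigma=np.zeros_like(q_grid),
        n_pixels=np.ones_like(q_grid, dtype=int),
        meta={"kind": "simulated_powder_pattern", "profile": profile},
    )


# ------------------------------------------------------------------- presets
def cellulose_phase(
    crystal_size_a: float = 30.0,
    relative_weight: float = 1.0,
    cell_name: str = "cellulose_Ibeta_nishiyama2002",
) -> PhasePeakSet:
    """Equatorial cellulose Iβ phase: the 110 pair plus (200).

    The default 30 Å coherence length matches the ~3 nm microfibril
    diameter of primary-cell-wall cellulose, which merges the 110 pair
    into the familiar single broad peak near q = 1.15 1/Å.
    """
    cell = UNIT_CELLS[cell_name]
    pair = sorted(
        (d_hkl(cell, 1, 1, 0), d_hkl(cell, 1, -1, 0)), key=lambda item: item[1]
    )
    (d_low, q_low), (d_high, q_high) = pair
    d200, q200 = d_hkl(cell, 2, 0, 0)
    reflections = [
        Reflection(hkl=(1, -1, 0), d_a=d_low, q_inv_a=q_low, family_label="110/1-10 pair (q_low)"),
        Reflection(hkl=(1, 1, 0), d_a=d_high, q_inv_a=q_high, family_label="110/1-10 pair (q_high)"),
        Reflection(hkl=(2, 0, 0), d_a=d200, q_inv_a=q200, family_label="200"),
    ]
    return PhasePeakSet(
        name="cellulose_Ibeta",
        reflections=reflections,
        crystal_size_a=crystal_size_a,
        relative_weight=relative_weight,
        peak_weights=np.array([1.0, 1.0, 0.9]),
    )


def wax_phase(crystal_size_a: float = 150.0, relative_weight: float = 1.0) -> PhasePeakSet:
    """Lamellar epicuticular-wax phase: d = 4.13 and 3.73 Å.

    The default coherence length (150 Å) makes the wax rings much sharper
    than the cellulose peaks, as observed for platelet waxes.
    """
    # orthorhombic wax subcell indexing: (110) at 4.13 A, (200) at 3.73 A
    reflections = [
        Reflection(hkl=hkl, d_a=d, q_inv_a=2.0 * np.pi / d,
                   family_label=f"wax subcell d={d}A")
        for hkl, d in (((1, 1, 0), 4.13), ((2, 0, 0), 3.73))
    ]
    return PhasePeakSet(
        name="epicuticular_wax",
        reflections=reflections,
        crystal_size_a=crystal_size_a,
        relative_weight=relative_weight,
    )


def peaks_to_csv(reflections, path) -> None:
    """Export a peak list as CSV (h, k, l, d_A, q_invA, family_label)."""
    with open(path, "w") as fh:
        fh.write("h,k,l,d_A,q_invA,family_label\n")
        for refl in reflections:
            h, k, l = refl.hkl
            fh.write(f"{h},{k},{l},{refl.d_a:.6f},{refl.q_inv_a:.6f},{refl.family_label}\n")
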