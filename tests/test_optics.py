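"""X-ray optics: conversions, critical angles, penetration, q/chi mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celltex import (
    BeamSpec,
    DetectorGeometry,
    InvalidInput,
    Material,
    build_qchi_map,
    critical_angle,
    d_from_q,
    electron_density,
    energy_to_wavelength,
    missing_wedge_halfangle,
    penetration_depth,
    q_from_scattering_angle,
    scattering_angle_from_q,
)
from celltex.optics import (
    attenuation_coefficient,
    beam_from_config,
    export_qchi_tiff,
    geometry_from_config,
)

CELL_WALL = Material.cell_wall()


class TestScalars:
    @pytest.mark.parametrize(
        "energy, expected",
        [(12.3984, 1.0), (10.0, 1.23984), (12.7, 0.97625)],
    )
    def test_energy_to_wavelength(self, energy, expected):
        assert energy_to_wavelength(energy) == pytest.approx(expected, rel=1e-5)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(InvalidInput):
            energy_to_wavelength(0.0)

    @pytest.mark.parametrize(
        "theta, lam, expected",
        [(0.0, 1.0, 0.0), (17.59, 1.23984, 1.550), (10.40, 0.97625, 1.167)],
    )
    def test_q_from_scattering_angle(self, theta, lam, expected):
        assert q_from_scattering_angle(theta, lam) == pytest.approx(expected, abs=5e-4)

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(InvalidInput):
            q_from_scattering_angle(180.0, 1.0)

    @given(theta=st.floats(0.001, 179.0), lam=st.floats(0.5, 2.5))
    @settings(max_examples=200, deadline=None)
    def test_q_theta_roundtrip(self, theta, lam):
        q = q_from_scattering_angle(theta, lam)
        assert scattering_angle_from_q(q, lam) == pytest.approx(theta, rel=1e-9)

    @pytest.mark.parametrize(
        "q, expected", [(1.52, 4.13), (1.70, 3.70), (2 * math.pi, 1.00)]
    )
    def test_d_from_q_paper_spacings(self, q, expected):
        assert d_from_q(q) == pytest.approx(expected, abs=5e-3)

    @given(x=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_d_from_q_involution(self, x):
        assert d_from_q(d_from_q(x)) == pytest.approx(x, rel=1e-12)

    def test_d_from_q_rejects_nonpositive(self):
        with pytest.raises(InvalidInput):
            d_from_q(0.0)


class TestMaterialOptics:
    def test_electron_density_anhydroglucose(self):
        # Z = 86 electrons per C6H10O5, M = 162.14 g/mol at 1.5 g/cm^3
        assert electron_density(CELL_WALL) == pytest.approx(0.4794, rel=1e-3)

    def test_electron_density_hydrogen(self):
        hydrogen = Material({"H": 1.0}, 1.0)
        assert electron_density(hydrogen) == pytest.approx(0.5975, rel=1e-3)

    def test_electron_density_linear_in_density(self):
        doubled = Material.cell_wall(density_g_cm3=3.0)
        assert electron_density(doubled) == pytest.approx(
            2.0 * electron_density(CELL_WALL), rel=1e-12
        )

    def test_unknown_element_named_in_error(self):
        with pytest.raises(InvalidInput, match="Xx"):
            Material({"Xx": 1.0}, 1.0)

    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidInput):
            Material({"C": 0.5, "O": 0.4}, 1.5)

    def test_critical_angle_10_kev(self):
        assert critical_angle(CELL_WALL, 10.0) == pytest.approx(0.148, rel=0.01)

    def test_critical_angle_12p7_kev(self):
        assert critical_angle(CELL_WALL, 12.7) == pytest.approx(0.116, rel=0.01)

    def test_critical_angle_times_energy_constant(self):
        # theta_c scales as lambda, i.e. as 1/E
        products = [critical_angle(CELL_WALL, e) * e for e in (8.0, 10.0, 12.7, 14.9)]
        assert np.ptp(products) / products[0] < 1e-6

    def test_penetration_absorption_limit(self):
        # far above theta_c the intensity 1/e depth tends to sin(alpha)/mu
        mu_cm = attenuation_coefficient(CELL_WALL, 10.0)
        expected_um = math.sin(math.radians(4.0)) / mu_cm * 1e4
        depth = penetration_depth(CELL_WALL, 10.0, 4.0)
        assert depth == pytest.approx(expected_um, rel=0.01)
        amplitude = penetration_depth(CELL_WALL, 10.0, 4.0, convention="amplitude")
        assert amplitude == pytest.approx(2.0 * depth, rel=1e-12)

    def test_penetration_evanescent_limit(self):
        # absorption off: below theta_c the evanescent depth is closed-form
        zero_mu = {"H": 0.0, "C": 0.0, "O": 0.0}
        theta_c = math.radians(critical_angle(CELL_WALL, 10.0))
        alpha = 0.5 * math.degrees(theta_c)
        lam = energy_to_wavelength(10.0)
        expected_a = lam / (
            4 * math.pi * math.sqrt(theta_c**2 - math.radians(alpha) ** 2)
        )
        depth = penetration_depth(CELL_WALL, 10.0, alpha, mass_attenuation=zero_mu)
        assert depth * 1e4 == pytest.approx(expected_a, rel=0.01)
        assert depth * 1e4 < 100.0  # evanescent: tens of Angstroms

    def test_penetration_missing_element_entry(self):
        with pytest.raises(InvalidInput, match="O"):
            penetration_depth(CELL_WALL, 10.0, 0.15, mass_attenuation={"H": 0.4, "C": 2.4})


def _scalar_map_oracle(geometry, beam):
    """Brute-force per-pixel (q, chi) with scalar trigonometry only."""
    rows, cols = geometry.shape
    r0, c0 = geometry.beam_center
    p, dist = geometry.pixel_mm, geometry.distance_mm
    lam = beam.wavelength_a
    k = 2 * math.pi / lam
    alpha = math.radians(beam.incidence_deg)
    q_out = np.zeros(geometry.shape)
    chi_out = np.zeros(geometry.shape)
    for r in range(rows):
        for c in range(cols):
            v = (r0 - r) * p
            h = (c - c0) * p
            length = math.sqrt(dist * dist + h * h + v * v)
            qx = h / length
            qy = dist / length - 1.0
            qz = v / length
            q = k * math.sqrt(qx * qx + qy * qy + qz * qz)
            qn = k * (-qy * math.sin(alpha) + qz * math.cos(alpha))
            qip = math.sqrt(max(q * q - qn * qn, 0.0))
            chi = math.degrees(math.atan2(qip, qn))
            if h < 0:
                chi = -chi
            q_out[r, c] = q
            chi_out[r, c] = max(-90.0, min(90.0, chi)) if q > 0 else 0.0
    return q_out, chi_out


class TestQChiMap:
    def test_matches_scalar_oracle_32x32(self, beam10):
        geometry = DetectorGeometry(
            distance_mm=120.0, pixel_mm=2.75, beam_center=(30.0, 16.0), shape=(32, 32)
        )
        qcmap = build_qchi_map(geometry, beam10)
        q_ref, chi_ref = _scalar_map_oracle(geometry, beam10)
        assert np.max(np.abs(qcmap.q - q_ref)) < 1e-10
        assert np.max(np.abs(qcmap.chi - chi_ref)) < 1e-10

    def test_q_consistent_with_scattering_angle(self, qcmap_small, geometry_small, beam10):
        # |q| from the vector map equals the scalar formula at the pixel's
        # full scattering angle
        v, h = geometry_small.pixel_offsets_mm()
        length = np.sqrt(geometry_small.distance_mm**2 + h**2 + v**2)
        theta = np.degrees(np.arccos(geometry_small.distance_mm / length))
        expected = q_from_scattering_angle(theta, beam10.wavelength_a)
        assert np.allclose(qcmap_small.q, expected, rtol=1e-9, atol=1e-12)

    def test_beam_center_pixel_masked(self, beam10):
        geometry = DetectorGeometry(
            distance_mm=120.0, pixel_mm=1.0, beam_center=(8.0, 8.0), shape=(17, 17)
        )
        qcmap = build_qchi_map(geometry, beam10)
        assert qcmap.q[8, 8] == 0.0
        assert not qcmap.mask[8, 8]

    def test_chi_antisymmetric_left_right(self, beam10):
        geometry = DetectorGeometry(
            distance_mm=120.0, pixel_mm=1.0, beam_center=(40.0, 20.0), shape=(41, 41)
        )
        qcmap = build_qchi_map(geometry, beam10)
        # reflect about the beam-center column (col 20)
        left = qcmap.chi[:, :20]
        right = qcmap.chi[:, 21:][:, ::-1]
        assert np.allclose(left, -right, atol=1e-12)

    def test_mask_consistent_with_missing_wedge(self, qcmap_small, beam10):
        sel = qcmap_small.mask & (qcmap_small.q > 0.2)
        chi_min = missing_wedge_halfangle(qcmap_small.q[sel], beam10)
        assert np.all(np.abs(qcmap_small.chi[sel]) >= chi_min - 1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(InvalidInput):
            DetectorGeometry(distance_mm=0.0, pixel_mm=1.0, beam_center=(0, 0), shape=(4, 4))


class TestMissingWedge:
    def test_example_value(self, beam10):
        # arcsin(q/2k) = 6.51 deg at q=1.15; minus the 0.15 deg incidence
        assert missing_wedge_halfangle(1.15, beam10) == pytest.approx(6.36, abs=0.05)

    def test_vanishes_at_small_q(self, beam10):
        assert missing_wedge_halfangle(1e-6, beam10) == 0.0

    def test_monotone_in_q(self, beam10):
        q = np.linspace(0.2, 3.0, 50)
        wedge = missing_wedge_halfangle(q, beam10)
        assert np.all(np.diff(wedge) >= 0)

    def test_q_beyond_ewald_sphere_rejected(self, beam10):
        with pytest.raises(InvalidInput):
            missing_wedge_halfangle(2.1 * beam10.k_a, beam10)


class TestConfigAndExport:
    def test_roundtrip_from_config_block(self):
        cfg = {
            "energy_keV": 12.7,
            "incidence_deg": 0.12,
            "distance_mm": 275.0,
            "pixel_mm": 0.172,
            "center_row": 500.0,
            "center_col": 256.0,
            "rows": 512,
            "cols": 512,
        }
        beam = beam_from_config(cfg)
        geometry = geometry_from_config(cfg)
        assert beam.energy_kev == 12.7
        assert beam.wavelength_a == pytest.approx(0.97625, rel=1e-5)
        assert geometry.distance_mm == 275.0
        assert geometry.shape == (512, 512)

    def test_missing_key_reported(self):
        with pytest.raises(InvalidInput, match="energy_keV"):
            beam_from_config({"incidence_deg": 0.1})

    def test_tiff_export(self, qcmap_small, tmp_path):
        import tifffile

        paths = export_qchi_tiff(qcmap_small, tmp_path / "map")
        assert len(paths) == 3
        q = tifffile.imread(paths[0])
        assert q.shape == qcmap_small.q.shape
        assert np.allclose(q, qcmap_small.q.astype(np.float32))
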