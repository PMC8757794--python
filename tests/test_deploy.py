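"""Deployment march: nominal limits, foreshortening, curvature modulation."""

import math

import numpy as np
import pytest

from fdmesh import (
    AneurysmRegion,
    DeployedDevice,
    deploy,
    deployed_length,
    field_frame,
    nominal_porosity,
    nominal_row_count,
    region_summary,
)
from fdmesh.errors import DeploymentError
from conftest import arc_tube, straight_tube


class TestNominalDeployment:
    def test_nominal_tube_reproduces_nominal_state(self, spec50):
        dev = deploy(spec50, straight_tube(2.0), distal_s=2.0)
        M = nominal_row_count(spec50)
        assert dev.n_rows == M
        assert np.allclose(dev.expansion, 100.0)
        assert np.allclose(dev.mesh_angle, 2 * spec50.alpha_nom, atol=1e-10)
        assert np.allclose(dev.porosity, nominal_porosity(spec50), atol=1e-12)
        expect_L = M * 2 * spec50.S * math.cos(math.radians(spec50.alpha_nom))
        assert deployed_length(dev) == pytest.approx(expect_L, abs=1e-9)
        assert abs(deployed_length(dev) - spec50.L_nom) <= 2 * spec50.S

    def test_oversized_vessel_is_clamped_to_nominal(self, spec50):
        dev = deploy(spec50, straight_tube(3.0), distal_s=2.0)
        assert np.allclose(dev.expansion, 100.0)
        assert np.all(dev.local_diameter <= spec50.phi_nom)


class TestForeshortening:
    def test_under_expansion_length_ratio(self, spec50):
        nominal = deploy(spec50, straight_tube(2.0), distal_s=2.0)
        under = deploy(spec50, straight_tube(1.5), distal_s=2.0)  # alpha 35.06 deg
        ratio = deployed_length(under) / deployed_length(nominal)
        expected = math.cos(math.radians(35.0670)) / math.cos(math.radians(50.0))
        assert ratio == pytest.approx(expected, rel=1e-6)
        assert ratio == pytest.approx(1.2737, abs=5e-3)

    def test_length_monotone_in_uniform_diameter(self, spec50):
        lengths = [
            deployed_length(deploy(spec50, straight_tube(r), distal_s=2.0))
            for r in (1.2, 1.5, 1.8, 2.0)
        ]
        assert all(a > b for a, b in zip(lengths, lengths[1:]))

    def test_row_count_conserved_across_vessels(self, spec50):
        devs = [
            deploy(spec50, straight_tube(1.4), distal_s=2.0),
            deploy(spec50, straight_tube(2.0), distal_s=2.0),
            deploy(spec50, arc_tube(1.8, 0.03), distal_s=2.0),
        ]
        counts = {d.n_rows for d in devs}
        assert counts == {nominal_row_count(spec50)}


class TestCurvatureModulation:
    def test_straight_vessel_fields_are_circumferentially_constant(self, spec50):
        dev = deploy(spec50, straight_tube(1.7), distal_s=2.0)
        assert float(np.ptp(dev.porosity, axis=1).max()) <= 1e-12
        assert float(np.ptp(dev.mesh_angle, axis=1).max()) <= 1e-12

    def test_inner_wall_less_porous_when_row_angle_above_45(self, spec62):
        # d = 3.4 mm -> alpha_row ~ 48.6 deg > 45
        dev = deploy(spec62, arc_tube(1.7, 0.05), distal_s=2.0)
        assert np.all(dev.alpha_row > 45.0)
        dtheta = (dev.theta[None, :] - dev.theta_normal[:, None] + 180.0) % 360.0 - 180.0
        inner = np.argmin(np.abs(dtheta), axis=1)
        outer = np.argmax(np.abs(dtheta), axis=1)
        rows = np.arange(dev.n_rows)
        assert np.all(dev.porosity[rows, inner] <= dev.porosity[rows, outer] + 1e-12)

    def test_ordering_reverses_below_45(self, spec50):
        # d = 2.0 mm -> alpha_row ~ 22.5 deg < 45
        dev = deploy(spec50, arc_tube(1.0, 0.05), distal_s=2.0)
        assert np.all(dev.alpha_row < 45.0)
        dtheta = (dev.theta[None, :] - dev.theta_normal[:, None] + 180.0) % 360.0 - 180.0
        inner = np.argmin(np.abs(dtheta), axis=1)
        outer = np.argmax(np.abs(dtheta), axis=1)
        rows = np.arange(dev.n_rows)
        assert np.all(dev.porosity[rows, inner] >= dev.porosity[rows, outer] - 1e-12)

    def test_fields_stay_bounded(self, spec62):
        dev = deploy(spec62, arc_tube(1.6, 0.05, length=80.0), distal_s=2.0)
        assert np.all((dev.porosity >= 0) & (dev.porosity <= 1))
        assert np.all((dev.mesh_angle > 0) & (dev.mesh_angle < 180))


class TestRegionSummary:
    def test_uniform_deployment_has_zero_spread(self, spec50):
        dev = deploy(spec50, straight_tube(2.0), distal_s=2.0)
        summ = region_summary(dev, AneurysmRegion(5.0, 15.0))
        assert summ.porosity_sd == 0.0
        assert summ.porosity_mean == pytest.approx(nominal_porosity(spec50), abs=1e-12)
        assert summ.angle_mean == pytest.approx(2 * spec50.alpha_nom, abs=1e-9)
        assert summ.expansion_mean == pytest.approx(100.0)

    def test_single_row_selection(self, spec50):
        dev = deploy(spec50, straight_tube(1.8), distal_s=2.0)
        s0 = dev.s_center[3]
        summ = region_summary(dev, AneurysmRegion(s0 - 1e-6, s0 + 1e-6))
        assert summ.n_points == dev.theta.shape[0]
        assert summ.porosity_mean == pytest.approx(float(dev.porosity[3].mean()))

    def test_hand_built_two_row_arithmetic(self, spec50):
        dev = DeployedDevice(
            spec=spec50,
            s_center=np.array([1.0, 2.0]),
            local_diameter=np.array([3.0, 3.0]),
            alpha_row=np.array([40.0, 40.0]),
            row_length=np.array([0.7, 0.7]),
            kappa=np.zeros(2), theta_normal=np.zeros(2),
            theta=np.array([0.0]),
            porosity=np.array([[0.70], [0.80]]),
            mesh_angle=np.array([[80.0], [80.0]]),
            expansion=np.array([[75.0], [75.0]]),
        )
        summ = region_summary(dev, AneurysmRegion(0.0, 3.0))
        assert summ.porosity_mean == pytest.approx(0.75)
        assert summ.porosity_sd == pytest.approx(0.05)

    def test_empty_region_raises_naming_interval(self, spec50):
        dev = deploy(spec50, straight_tube(2.0), distal_s=2.0)
        with pytest.raises(DeploymentError, match="40.00"):
            region_summary(dev, AneurysmRegion(40.0, 41.0))


class TestErrorsAndExport:
    def test_overrun_reports_rows_placed(self, spec50):
        with pytest.raises(DeploymentError, match="rows"):
            deploy(spec50, straight_tube(1.5, length=12.0), distal_s=2.0)

    def test_field_frame_is_row_major_theta_ascending(self, spec50):
        dev = deploy(spec50, straight_tube(2.0), distal_s=2.0, n_theta=8)
        df = field_frame(dev)
        assert list(df.columns) == ["s_mm", "theta_deg", "porosity", "coverage",
                                    "mesh_angle_deg", "expansion_pct"]
        assert len(df) == dev.n_rows * 8
        assert np.all(np.diff(df["s_mm"].to_numpy()) >= 0)
        np.testing.assert_allclose(df["theta_deg"].to_numpy()[:8],
                                   np.arange(8) * 45.0)
        np.testing.assert_allclose(df["porosity"] + df["coverage"], 1.0)
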