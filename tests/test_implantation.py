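import math

import numpy as np
import pytest

from icrsim.fem import RigidObstacle
from icrsim.implantation import (ProtocolConfig, build_insertion_mold,
                                 build_rigid_tool, place_cross_section)
from icrsim.rings import polygon_area, polygon_centroid, polygon_perimeter


class TestRigidTool:
    def test_zero_offset_identity(self, sections):
        cs = sections[("square-rect", 1)]
        np.testing.assert_allclose(build_rigid_tool(cs, 0.0), cs.polygon)

    def test_negative_offset_rejected(self, sections):
        with pytest.raises(ValueError):
            build_rigid_tool(sections[("square-rect", 1)], -0.01)

    def test_perimeter_grows_by_2_pi_d(self, sections):
        """Minkowski dilation of a convex polygon by a disc of radius d adds
        exactly 2 pi d of perimeter."""
        cs = sections[("square-ellipse", 1)]
        d = 0.05
        tool = build_rigid_tool(cs, d)
        grown = polygon_perimeter(tool) - polygon_perimeter(cs.polygon)
        assert grown == pytest.approx(2 * math.pi * d, rel=0.01)

    def test_dilation_area_formula(self, sections):
        """area(tool) - area(ring) = perimeter * d + pi d^2 for convex
        cross-sections."""
        cs = sections[("square-ellipse", 1)]
        d = 0.04
        tool = build_rigid_tool(cs, d)
        gained = polygon_area(tool) - cs.area
        expected = polygon_perimeter(cs.polygon) * d + math.pi * d ** 2
        assert gained == pytest.approx(expected, rel=0.01)


class TestMold:
    def test_contains_ring_and_spans_slit(self, sections):
        from shapely.geometry import Polygon

        cs = sections[("horizontal-trapezoid", 1)]
        mold = build_insertion_mold(cs, 0.015, 1.2, 0.1)
        assert Polygon(mold).contains(Polygon(cs.polygon))
        assert np.ptp(mold[:, 0]) == pytest.approx(1.2, abs=1e-9)
        assert polygon_area(mold) > 0


class TestPlacement:
    def test_centroid_lands_on_insertion_point(self, sections, geom):
        cs = sections[("rotated-rect", 2)]
        placed = place_cross_section(cs.polygon, geom, 5.5, 0.75)
        phi = geom.phi_at_depth_radius(2.75, 0.75)
        np.testing.assert_allclose(polygon_centroid(placed),
                                   geom.point(phi, 0.75), atol=1e-9)

    def test_rigid_rotation_preserves_area(self, sections, geom):
        cs = sections[("rotated-rect", 2)]
        placed = place_cross_section(cs.polygon, geom, 5.0, 0.75)
        assert polygon_area(placed) == pytest.approx(cs.area, rel=1e-12)

    def test_diameter_outside_cornea_rejected(self, sections, geom):
        with pytest.raises(ValueError, match="outside"):
            place_cross_section(sections[("square-rect", 1)].polygon,
                                geom, 14.0, 0.75)


class TestProtocolConfig:
    def test_defaults(self):
        p = ProtocolConfig()
        assert p.iop_kpa == pytest.approx(1.99983, abs=1e-5)
        assert p.inflation_pressure == 60.0

    def test_inconsistent_override_warns(self):
        with pytest.warns(UserWarning, match="30x IOP"):
            ProtocolConfig(inflation_pressure=5.0)


class TestProtocolRun:
    """End-to-end checks on the reference Keraring-like implantation."""

    def test_all_stages_converged(self, keraring_run):
        assert keraring_run.converged
        for name in ("carved_iop", "inflate_tunnel", "release", "final"):
            assert name in keraring_run.stages

    def test_ring_contact_closed(self, keraring_run):
        d = keraring_run.final_state.contact["ring"]
        forces = np.hypot(d["force"][:, 0], d["force"][:, 1])
        assert (forces > 0).sum() >= 1

    def test_final_penetration_below_tolerance(self, keraring_run):
        d = keraring_run.final_state.contact["ring"]
        assert d["penetration"].max() <= 5 * keraring_run.protocol.penetration_tol

    def test_contact_forces_normal_to_ring(self, keraring_run):
        """Frictionless contact: each nodal force is colinear with the ring
        surface normal at the node's closest point."""
        from icrsim.implantation import place_cross_section

        run = keraring_run
        ring_poly = place_cross_section(run.implant.cross_section.polygon,
                                        run.mesh.geom, run.implant.diameter,
                                        0.75) + [0.0, run.ring_shift]
        obstacle = RigidObstacle(ring_poly, forbidden="inside")
        d = run.final_state.contact["ring"]
        x = run.x_post
        _, nrm = obstacle.penetrations(x[d["nodes"]])
        for f, n in zip(d["force"], nrm):
            mag = np.hypot(*f)
            if mag < 1e-9:
                continue
            tangential = abs(f[0] * n[1] - f[1] * n[0])
            assert tangential / mag < 1e-9

    def test_corneal_flattening(self, keraring_run):
        """The implanted ring reduces the mean keratometry (the surgical
        intent) and thins the central cornea."""
        m = keraring_run.metrics
        assert m.delta_k_mean < -0.5
        assert m.delta_cct < 0.0
        assert m.max_contact_pressure > 0.0
        assert m.contact_area > 0.0

    def test_pre_op_keratometry_is_anterior_radius(self, keraring_run):
        assert keraring_run.metrics.k_pre == pytest.approx(43.27, abs=0.05)

    def test_contact_force_bookkeeping(self, keraring_run):
        """The resultant of the nodal contact forces on the implant equals
        the integrated contact-pressure field (pressure x tributary area x
        surface normal) within 0.5%."""
        from icrsim.implantation import place_cross_section

        run = keraring_run
        ring_poly = place_cross_section(run.implant.cross_section.polygon,
                                        run.mesh.geom, run.implant.diameter,
                                        0.75) + [0.0, run.ring_shift]
        obstacle = RigidObstacle(ring_poly, forbidden="inside")
        d = run.final_state.contact["ring"]
        x = run.x_post
        mesh = run.mesh
        edges = np.concatenate([mesh.edge_nodes(mesh.edge_sets[k])
                                for k in ("tunnel_upper", "tunnel_lower",
                                          "tunnel_tips")])
        trib = {}
        for (n1, n2) in edges:
            L = float(np.linalg.norm(x[n1] - x[n2]))
            trib[n1] = trib.get(n1, 0.0) + 0.5 * L
            trib[n2] = trib.get(n2, 0.0) + 0.5 * L
        _, nrm = obstacle.penetrations(x[d["nodes"]])
        resultant = d["force"].sum(axis=0)
        integrated = np.zeros(2)
        for nd, f, n in zip(d["nodes"], d["force"], nrm):
            mag = float(np.hypot(*f))
            if mag < 1e-12:
                continue
            area = 2 * np.pi * x[nd, 0] * trib[int(nd)]
            pressure = mag / area
            integrated += pressure * area * n
        err = np.linalg.norm(integrated - resultant)
        assert err <= 5e-3 * np.linalg.norm(resultant)

    def test_float_reduces_spurious_anchoring(self, keraring_run):
        """The axial float leaves at most the per-node contact force
        quantum of net axial load on the implant (a grounded obstacle can
        carry arbitrarily more)."""
        d = keraring_run.final_state.contact["ring"]
        active = np.hypot(d["force"][:, 0], d["force"][:, 1])
        quantum = active.max()
        net = abs(d["force"][:, 1].sum())
        assert net <= 1.5 * quantum + 1e-2
        assert keraring_run.float_residual == pytest.approx(
            net / np.abs(d["force"]).sum(), abs=1e-9)

    def test_final_equilibrium_quality(self, keraring_run):
        assert keraring_run.residual_quality <= 0.01
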