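import numpy as np
import pytest

from icrsim.geometry import CorneaGeometry
from icrsim.mesh import (TunnelSpec, build_cornea_mesh, carve_tunnel,
                         read_vtk_points, write_vtk)


class TestGeometry:
    def test_central_thickness(self, geom):
        assert geom.normal_thickness(0.0) == pytest.approx(0.52)

    def test_rim_thickness(self, geom):
        assert float(geom.normal_thickness(geom.rim_angle)) == pytest.approx(0.68)

    def test_thickness_monotone(self, geom):
        phi = np.linspace(0, geom.rim_angle, 100)
        assert np.all(np.diff(geom.normal_thickness(phi)) > 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CorneaGeometry(anterior_radius=6.0, posterior_radius=6.78)
        with pytest.raises(ValueError):
            CorneaGeometry(central_thickness=0.7, peripheral_thickness=0.68)

    def test_depth_radius_inverse(self, geom):
        phi = geom.phi_at_depth_radius(2.75, 0.75)
        assert float(geom.point(phi, 0.75)[0]) == pytest.approx(2.75, abs=1e-10)


class TestBuildMesh:
    def test_element_count_near_target(self, geom):
        mesh = build_cornea_mesh(geom, target_elements=2900,
                                 refinement_zone=(2.75, 0.9))
        assert 2465 <= mesh.n_elements <= 3335

    def test_coarse_uniform_count(self, coarse_mesh):
        assert 425 <= coarse_mesh.n_elements <= 575

    def test_positive_jacobians(self, refined_mesh):
        assert refined_mesh.jacobians_positive()

    def test_axis_nodes_on_axis(self, refined_mesh):
        assert np.all(refined_mesh.nodes[refined_mesh.node_sets["axis"], 0] == 0.0)

    def test_surface_nodes_on_spheres(self, refined_mesh, geom):
        ant = refined_mesh.nodes[refined_mesh.node_sets["anterior"]]
        ra = np.hypot(ant[:, 0], ant[:, 1] + geom.anterior_radius)
        np.testing.assert_allclose(ra, geom.anterior_radius, atol=1e-9)
        post = refined_mesh.nodes[refined_mesh.node_sets["posterior"]]
        zc = -geom.central_thickness - geom.posterior_radius
        rp = np.hypot(post[:, 0], post[:, 1] - zc)
        np.testing.assert_allclose(rp, geom.posterior_radius, atol=1e-9)

    def test_volume_matches_quadrature(self, refined_mesh, geom):
        """Sum of element areas x 2 pi r-bar equals the two-sphere solid of
        revolution volume computed by fine quadrature (within 0.5%)."""
        areas = refined_mesh.element_areas()
        rbar = refined_mesh.element_centroids()[:, 0]
        vol = float(np.sum(2 * np.pi * rbar * areas))
        assert vol == pytest.approx(geom.volume(), rel=5e-3)

    def test_deterministic(self, geom):
        a = build_cornea_mesh(geom, 700, refinement_zone=(2.75, 0.9))
        b = build_cornea_mesh(geom, 700, refinement_zone=(2.75, 0.9))
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.quads, b.quads)

    def test_tunnel_sets_empty_before_carving(self, refined_mesh):
        for name in ("tunnel_upper", "tunnel_lower", "tunnel_tips"):
            assert len(refined_mesh.edge_sets[name]) == 0


class TestCarveTunnel:
    @pytest.fixture(scope="class")
    def carved(self, refined_mesh):
        return carve_tunnel(refined_mesh, TunnelSpec(center_diameter=5.5))

    def test_zero_width_is_noop(self, refined_mesh):
        out = carve_tunnel(refined_mesh, TunnelSpec(center_diameter=5.5,
                                                    slit_width=0.0))
        assert out.n_elements == refined_mesh.n_elements

    def test_unrefined_mesh_rejected(self, coarse_mesh):
        with pytest.raises(ValueError, match="refine"):
            carve_tunnel(coarse_mesh, TunnelSpec(center_diameter=5.5))

    def test_removed_bounding_box(self, refined_mesh, carved, geom):
        """The removed region spans ~1.2 mm along the slit and ~15 um across
        it, within one element size."""
        removed = sorted(set(map(tuple, refined_mesh.quads.tolist()))
                         - set(map(tuple, carved.quads.tolist())))
        ids = np.unique(np.array(removed).ravel())
        pts = refined_mesh.nodes[ids]
        phi = geom.phi_at_depth_radius(2.75, 0.75)
        center = geom.point(phi, 0.75)
        tang = np.array([np.cos(phi), -np.sin(phi)])
        nrm = np.array([np.sin(phi), np.cos(phi)])
        s = (pts - center) @ tang
        h_elem = 1.2 / 30  # typical refined column width
        assert np.ptp(s) == pytest.approx(1.2, abs=2 * h_elem)
        # across the slit: every removed node hugs the (curved) 75%-depth
        # surface to within the slit half-height plus one thin row
        curve = geom.point(np.linspace(0.2, geom.rim_angle * 0.9, 2000), 0.75)
        dmin = np.min(np.linalg.norm(pts[:, None, :] - curve[None], axis=2),
                      axis=1)
        assert dmin.max() < 0.012

    def test_removed_area_bookkeeping(self, refined_mesh, carved):
        removed_area = (np.abs(refined_mesh.element_areas()).sum()
                        - np.abs(carved.element_areas()).sum())
        assert removed_area == pytest.approx(0.015 * 1.2, rel=0.2)

    def test_still_connected_and_sets_exposed(self, carved):
        assert carved.is_connected()
        assert len(carved.edge_sets["tunnel_upper"]) > 10
        assert len(carved.edge_sets["tunnel_lower"]) > 10
        assert len(carved.edge_sets["tunnel_tips"]) == 4
        assert len(carved.node_sets["tunnel"]) > 20

    def test_node_table_unchanged(self, refined_mesh, carved):
        assert np.array_equal(refined_mesh.nodes, carved.nodes)

    def test_orphans_only_inside_slit(self, carved):
        orphans = carved.orphan_nodes()
        assert len(orphans) > 0
        r = carved.nodes[orphans, 0]
        assert np.all((r > 1.8) & (r < 3.6))


class TestVtk:
    def test_roundtrip_points(self, coarse_mesh, tmp_path):
        path = tmp_path / "mesh.vtk"
        write_vtk(path, coarse_mesh,
                  point_data={"displacement": np.zeros_like(coarse_mesh.nodes)})
        pts = read_vtk_points(path)
        assert len(pts) == coarse_mesh.n_nodes
        np.testing.assert_allclose(pts, coarse_mesh.nodes, atol=1e-9)
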