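"""Geometry construction and mesh generation."""

import numpy as np
import pytest

from salinerf.geometry import (GeometryError, GeometryParams, build_geometry,
                               MM)
from salinerf.mesh import generate_mesh, graded_points, rectangle_mesh


@pytest.fixture(scope="module")
def geom():
    return build_geometry(GeometryParams())


@pytest.fixture(scope="module")
def mesh(geom):
    return generate_mesh(geom)


class TestGeometryParams:
    @pytest.mark.parametrize("bad", [
        dict(tissue_radius=-1.0),
        dict(saline_thickness=0.0),
        dict(insertion_depth=2.0),            # deeper than the tip radius
        dict(insertion_depth=1.4, saline_height_on_electrode=1.2),  # D >= L
        dict(saline_thickness=2.0),           # S > L
        dict(scenario_topology="sideways"),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises((GeometryError, ValueError)):
            build_geometry(GeometryParams(**bad))

    def test_zone1_profile_endpoints(self, geom):
        # film height L at the electrode wall, S at distance r0 from it
        assert geom.film_height(geom.a + 1e-12) == pytest.approx(geom.L, rel=1e-6)
        assert geom.film_height(geom.a + geom.r0) == pytest.approx(geom.S)
        assert geom.film_height(geom.a + 2 * geom.r0) == pytest.approx(geom.S)

    def test_degenerate_uniform_film(self):
        # S = L: Zone 1 degenerates into a uniform film of thickness S
        g = build_geometry(GeometryParams(saline_thickness=1.0,
                                          saline_height_on_electrode=1.0))
        r = np.linspace(g.a * 1.001, g.Rs, 20)
        assert np.allclose(g.film_height(r), 1.0 * MM)

    def test_contact_radius_from_insertion_depth(self, geom):
        # the tip pierces the surface on a circle of radius sqrt(a^2 - (a-D)^2)
        assert geom.rcap == pytest.approx(
            np.sqrt(geom.a ** 2 - (geom.a - geom.D) ** 2))
        assert geom.z_electrode_bottom(0.0) == pytest.approx(geom.D)
        assert geom.z_electrode_bottom(geom.rcap) == pytest.approx(0.0, abs=1e-12)


class TestMesh:
    def test_element_count_in_expected_range(self, mesh):
        assert 2500 <= mesh.n_elements <= 22000

    def test_refinement_increases_element_count(self, geom):
        coarse = generate_mesh(geom, h_interface=0.24)
        fine = generate_mesh(geom, h_interface=0.12)
        assert fine.n_elements > coarse.n_elements

    def test_axis_nodes_exact(self, mesh):
        axis = np.unique(mesh.edge_labels["axis"])
        assert np.all(mesh.points[axis, 0] == 0.0)
        assert np.all(mesh.points[:, 0] >= 0.0)

    @pytest.mark.parametrize("topology,with_saline", [
        ("surface_contact", True),
        ("surface_contact", False),
        ("fully_inserted", False),
        ("submerged_in_saline", False),
    ])
    def test_subdomain_areas_match_analytic(self, topology, with_saline):
        g = build_geometry(GeometryParams(scenario_topology=topology,
                                          with_saline=with_saline))
        m = generate_mesh(g)
        exact = g.planar_areas()
        areas = m.subdomain_areas()
        assert set(areas) == set(exact)
        for name, val in exact.items():
            assert areas[name] == pytest.approx(val, rel=5e-3), name

    def test_tissue_volume_of_revolution(self, geom, mesh):
        assert mesh.subdomain_volume("tissue") == pytest.approx(
            geom.tissue_volume(), rel=5e-3)

    def test_mesh_is_valid_and_conforming(self, mesh):
        mesh.check_valid()  # positive areas, manifold edges, r >= 0
        # every expected physical surface is labelled
        for label in ("axis", "dispersive", "tissue_lateral",
                      "saline_free_surface", "saline_tissue_interface",
                      "saline_inflow"):
            assert len(mesh.edge_labels[label]) > 0

    def test_boundary_edges_have_single_owner(self, mesh):
        edges, owners = mesh.boundary_edges
        assert len(edges) == len(np.unique(np.sort(edges, axis=1), axis=0))

    def test_labels_stable_under_refinement(self, geom):
        fine = generate_mesh(geom, h_interface=0.09)
        assert set(fine.edge_labels) == set(generate_mesh(geom).edge_labels)


class TestHelpers:
    def test_rectangle_mesh_two_triangles_per_cell(self):
        pts, tris = rectangle_mesh(0.0, 1.0, 0.0, 1.0, 3, 4)
        assert len(tris) == 2 * 3 * 4
        assert len(pts) == 4 * 5
        # total area preserved
        p = pts[tris]
        area = 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
        assert area.sum() == pytest.approx(1.0)

    def test_graded_points_monotone_and_bounded(self):
        pts = graded_points(0.0, 1.0, 0.01, 0.2, 1.3)
        assert pts[0] == 0.0 and pts[-1] == 1.0
        d = np.diff(pts)
        assert (d > 0).all()
        assert d.max() <= 0.2 * 1.05
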