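"""Chamber geometry construction, meshing, and sweep fixtures."""

import math

import numpy as np
import pytest

from mcelsim.geometry import (GeometryError, GeometryKind, GeometrySpec,
                              build_geometry, confined, make_sweep,
                              unconfined)
from mcelsim.meshing import (MeshingError, generate_construct_mesh,
                             generate_mesh)


class TestSpecs:
    def test_confined_contact_chord_from_height_ratio(self):
        spec = confined()
        # centre 0.8 above the wall and contact points at +/-0.6: the
        # circle-chord geometry of the 90%-of-diameter height
        assert spec.centre_y == pytest.approx(0.8)
        assert spec.contact_half_width == pytest.approx(0.6)
        assert spec.apex_y == pytest.approx(1.8)

    def test_unconfined_clearance(self):
        spec = unconfined(channel_height=3.0)
        assert spec.gap == pytest.approx(0.5)

    def test_construct_does_not_fit_rejected(self):
        with pytest.raises(GeometryError, match="gap"):
            build_geometry(GeometrySpec(GeometryKind.confined,
                                        channel_height=1.5))

    def test_bad_height_ratio_rejected(self):
        with pytest.raises(GeometryError):
            build_geometry(GeometrySpec(GeometryKind.confined,
                                        confined_height_ratio=0.3))

    def test_confined_segment_area_closed_form(self):
        # pi - (acos(0.8) - 0.8*0.6) for the truncated disc
        spec = confined()
        expected = math.pi - (math.acos(0.8) - 0.48)
        assert spec.construct_area == pytest.approx(expected, rel=1e-12)


class TestMeshes:
    def test_unconfined_construct_area(self, construct_mesh_unconfined,
                                       spec_unconfined):
        area = construct_mesh_unconfined.region_area(2)
        assert area == pytest.approx(spec_unconfined.construct_area,
                                     rel=1e-3)

    def test_confined_construct_area(self, construct_mesh_confined,
                                     spec_confined):
        area = construct_mesh_confined.region_area(2)
        assert area == pytest.approx(spec_confined.construct_area, rel=1e-3)

    def test_refinement_reduces_area_error(self, spec_unconfined):
        errs = []
        for res in ["coarse", "fine"]:
            m = generate_construct_mesh(spec_unconfined, res)
            errs.append(abs(m.region_area(2) - spec_unconfined.construct_area))
        assert errs[1] < 0.6 * errs[0]

    @pytest.mark.parametrize("which", ["unconfined", "confined"])
    def test_full_mesh_region_partition(self, which, request):
        mesh = request.getfixturevalue(f"full_mesh_{which}")
        spec = request.getfixturevalue(f"spec_{which}")
        a1 = mesh.region_area(1)
        a2 = mesh.region_area(2)
        total = 2 * spec.L * spec.domain_height
        assert a1 + a2 == pytest.approx(total, rel=1e-10)
        assert a2 == pytest.approx(spec.construct_area, rel=2e-3)

    @pytest.mark.parametrize("which", ["unconfined", "confined"])
    def test_boundary_tag_lengths(self, which, request):
        mesh = request.getfixturevalue(f"full_mesh_{which}")
        spec = request.getfixturevalue(f"spec_{which}")
        L, H = spec.L, spec.domain_height
        rect = 2 * (2 * L + H)
        tags = [t for t in mesh.edges if t != "interface"]
        total = sum(mesh.boundary_length(t) for t in tags)
        assert total == pytest.approx(rect, rel=1e-3)
        # interface polyline vs analytic arc length
        if which == "unconfined":
            arc = math.pi
        else:
            # the arc extends below the circle centre down to the contact
            # points: half-angle pi/2 + atan(centre_y / half_chord)
            th = math.atan2(0.8, 0.6)
            arc = math.pi + 2 * th
        assert mesh.boundary_length("interface") == pytest.approx(arc,
                                                                  rel=1e-3)

    @pytest.mark.parametrize("which", ["unconfined", "confined"])
    def test_element_quality(self, which, request):
        mesh = request.getfixturevalue(f"full_mesh_{which}")
        assert mesh.min_angle() > 20.0

    def test_interface_edges_conform(self, full_mesh_confined):
        """Every consecutive interface node pair is an actual mesh edge and
        separates a channel triangle from a construct triangle."""
        mesh = full_mesh_confined
        e = np.concatenate([mesh.tris[:, [0, 1]], mesh.tris[:, [1, 2]],
                            mesh.tris[:, [2, 0]]])
        e.sort(axis=1)
        edge_set = {tuple(r) for r in e}
        chain = mesh.interface_nodes
        for a, b in zip(chain[:-1], chain[1:]):
            assert (min(a, b), max(a, b)) in edge_set
        # region change across the interface
        cc = np.array([0.0, mesh.spec.centre_y])
        r = np.linalg.norm(mesh.nodes[mesh.tris].mean(axis=1) - cc, axis=1)
        assert (mesh.tri_region[r < 1.0] == 2).all()
        assert (mesh.tri_region[r > 1.0] == 1).all()

    def test_corner_refinement_bands(self, full_mesh_confined):
        """Element size next to the contact point is at least 2^4 smaller
        than the interface size, in geometric bands."""
        mesh = full_mesh_confined
        xc = mesh.spec.contact_half_width
        sizes = mesh.element_sizes()
        cent = mesh.nodes[mesh.tris].mean(axis=1)
        d = np.linalg.norm(cent - [xc, 0.0], axis=1)
        near = sizes[d < 0.02]
        assert len(near) > 0
        assert near.min() <= mesh.sizes["interface"] * 0.5 ** 4 * 1.5

    def test_determinism(self, spec_unconfined):
        m1 = generate_mesh(spec_unconfined, "coarse", seed=3)
        m2 = generate_mesh(spec_unconfined, "coarse", seed=3)
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.tris, m2.tris)

    def test_unknown_resolution_rejected(self, spec_unconfined):
        with pytest.raises(MeshingError):
            generate_mesh(spec_unconfined, "ultra")


class TestSweeps:
    def test_cartesian_sweep_size_and_ids(self):
        runs = make_sweep("fig7", {"Da": [1, 2, 3],
                                   "Rd": list(np.geomspace(0.1, 100, 4))})
        assert len(runs) == 12
        ids = [r["id"] for r in runs]
        assert len(set(ids)) == 12

    def test_id_stable_under_key_reordering(self):
        import json
        r1 = make_sweep("s", {"Da": [2], "Rd": [1]})[0]
        r2 = make_sweep("s", {"Rd": [1], "Da": [2]})[0]
        assert r1["id"] == r2["id"]

    def test_paired_sweep(self):
        runs = make_sweep("pe", {"Pe1": [1, 10, 100], "Da": [5, 5, 5]},
                          paired=True)
        assert len(runs) == 3

    def test_mismatched_pairing_rejected(self):
        with pytest.raises(ValueError, match="equal grid lengths"):
            make_sweep("bad", {"Pe1": [1, 10], "Da": [5]}, paired=True)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_sweep("empty", {"Da": []})
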