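import numpy as np
import pytest

from morphrep.geometry import point_mesh_distance
from morphrep.synth import (
    ALL_RULE_SPECS,
    PLANE_NORMALS,
    PackingCapacityError,
    PackingRuleSpec,
    PolymorphicShapeSpec,
    make_multipiece_volume,
    make_synthetic_nucleus,
    pack_spheres,
    render_punctate_volume,
)
from morphrep.types import InvalidInputError, PlacementError

from conftest import random_rotation


class TestNucleus:
    def test_ellipsoid_volume_closed_form(self):
        # bumpiness 0 gives an exact triaxial ellipsoid; the icosphere
        # discretization underestimates the volume by < 1.5%
        nuc = make_synthetic_nucleus(seed=0, bumpiness=0.0)
        a, b, c = 16.0 * np.array([1.0, 1.25, 0.85])
        want = 4.0 / 3.0 * np.pi * a * b * c
        assert abs(nuc.mesh.volume - want) / want < 0.015

    def test_mask_volume_matches_mesh(self, nucleus):
        ratio = nucleus.mask.data.sum() / nucleus.mesh.volume
        assert 0.97 < ratio < 1.03

    def test_mesh_watertight_and_centered(self, nucleus):
        assert nucleus.mesh.is_watertight
        assert np.abs(nucleus.mesh.vertices.mean(axis=0)).max() < 0.5

    def test_radius_of_matches_mesh_vertices(self, nucleus):
        v = np.asarray(nucleus.mesh.vertices)
        r = np.linalg.norm(v, axis=1)
        assert np.allclose(nucleus.radius_of(v / r[:, None]), r, atol=1e-10)

    def test_deterministic(self):
        a = make_synthetic_nucleus(seed=5)
        b = make_synthetic_nucleus(seed=5)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mask.data, b.mask.data)

    def test_parameter_validation(self):
        with pytest.raises(InvalidInputError):
            make_synthetic_nucleus(seed=0, mean_radius=-1)
        with pytest.raises(InvalidInputError):
            make_synthetic_nucleus(seed=0, bumpiness=1.0)

    def test_rotated_container_consistent(self, nucleus):
        R = random_rotation(9)
        rot = nucleus.rotated(R)
        v = np.asarray(rot.mesh.vertices)
        r = np.linalg.norm(v, axis=1)
        assert np.allclose(rot.radius_of(v / r[:, None]), r, atol=1e-10)
        assert abs(int(rot.mask.data.sum()) - int(nucleus.mask.data.sum())) < (
            0.01 * nucleus.mask.data.sum()
        )


class TestPlaneNormals:
    def test_paper_angles(self):
        assert np.allclose(PLANE_NORMALS[0], [0, 0, 1])
        s = 1 / np.sqrt(2)
        assert np.allclose(PLANE_NORMALS[45], [0, s, s])
        assert np.allclose(PLANE_NORMALS[90], [0, 1, 0])


class TestPacking:
    def test_all_rules_fill_and_clear(self, nucleus):
        for rule, angle in ALL_RULE_SPECS:
            spec = PackingRuleSpec(rule=rule, plane_angle=angle, n_spheres=64, seed=2)
            pc = pack_spheres(nucleus, spec)
            assert len(pc) == 64
            # exact clearance: center at least one radius from the wall
            assert point_mesh_distance(nucleus.mesh, pc.points).min() >= 1.0
            # non-overlap: centers at least two radii apart
            d = np.linalg.norm(pc.points[:, None] - pc.points[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 2.0

    def test_deterministic(self, nucleus):
        spec = PackingRuleSpec(rule="surface", n_spheres=32, seed=3)
        a = pack_spheres(nucleus, spec)
        b = pack_spheres(nucleus, spec)
        assert np.array_equal(a.points, b.points)

    def test_rule_separation_radial_vs_surface(self, nucleus):
        radial = pack_spheres(
            nucleus, PackingRuleSpec(rule="radial", n_spheres=128, seed=4)
        )
        surface = pack_spheres(
            nucleus, PackingRuleSpec(rule="surface", n_spheres=128, seed=4)
        )
        r_rad = np.linalg.norm(radial.points, axis=1).mean()
        r_surf = np.linalg.norm(surface.points, axis=1).mean()
        assert r_rad < r_surf

    def test_planar_depletion(self, nucleus):
        planar = pack_spheres(
            nucleus, PackingRuleSpec(rule="planar", plane_angle=0, n_spheres=128, seed=5)
        )
        random = pack_spheres(
            nucleus, PackingRuleSpec(rule="random", n_spheres=128, seed=5)
        )
        near = lambda pc: np.mean(np.abs(pc.points[:, 2]) < 4.0)  # noqa: E731
        assert near(planar) < near(random)

    def test_zero_spheres_ok(self, nucleus):
        pc = pack_spheres(nucleus, PackingRuleSpec(rule="random", n_spheres=0, seed=0))
        assert len(pc) == 0

    def test_capacity_error_reports_placed(self):
        tiny = make_synthetic_nucleus(seed=0, mean_radius=4.0)
        with pytest.raises(PackingCapacityError) as e:
            pack_spheres(tiny, PackingRuleSpec(rule="random", n_spheres=500, seed=0))
        assert 0 <= e.value.placed < 500

    def test_spec_validation(self):
        with pytest.raises(InvalidInputError):
            PackingRuleSpec(rule="radial", plane_angle=45)  # angle only for planar
        with pytest.raises(InvalidInputError):
            PackingRuleSpec(rule="planar")  # angle required
        with pytest.raises(InvalidInputError):
            PackingRuleSpec(rule="random", n_spheres=-1)

    def test_meta_records_rule_and_seed(self, nucleus):
        pc = pack_spheres(
            nucleus, PackingRuleSpec(rule="planar", plane_angle=45, n_spheres=8, seed=6)
        )
        assert pc.meta["rule"] == "planar45"
        assert pc.meta["seed"] == 6
        assert np.allclose(pc.meta["plane_normal"], PLANE_NORMALS[45])


class TestRendering:
    def test_intensity_inside_mask_only(self, nucleus, small_pack):
        vol = render_punctate_volume(small_pack, nucleus, seed=1)
        assert vol.role == "intensity"
        outside = vol.data[nucleus.mask.data == 0]
        assert np.all(outside == 0)
        assert vol.data.max() > 0

    def test_deterministic(self, nucleus, small_pack):
        a = render_punctate_volume(small_pack, nucleus, seed=2)
        b = render_punctate_volume(small_pack, nucleus, seed=2)
        assert np.array_equal(a.data, b.data)


class TestMultipiece:
    @pytest.mark.parametrize("n", [1, 3, 5])
    def test_exact_component_count(self, n):
        from scipy.ndimage import label

        vol = make_multipiece_volume(PolymorphicShapeSpec(n_pieces=n, seed=11))
        _, count = label(vol.data, structure=np.ones((3, 3, 3)))
        assert count == n

    def test_deterministic(self):
        spec = PolymorphicShapeSpec(n_pieces=2, seed=3)
        assert np.array_equal(
            make_multipiece_volume(spec).data, make_multipiece_volume(spec).data
        )

    def test_impossible_placement_errors(self):
        # each piece fits alone, but ten of them cannot coexist
        spec = PolymorphicShapeSpec(
            n_pieces=10, piece_scale_range=(9.0, 10.0), elongation=1.0, seed=0
        )
        with pytest.raises(PlacementError):
            make_multipiece_volume(spec, grid=(48, 48, 48))
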