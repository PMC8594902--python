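import numpy as np
import pytest

from mesobrush import fixtures as fx
from mesobrush.physics import PinTo, WorldConfig, collidable, resolve_pair
from mesobrush.scene import Scene, SceneError
from mesobrush.strokes import StrokePath


class TestPaint:
    def test_empty_canvas_exact_position(self, scene_with_palette):
        bid = scene_with_palette.paint("blob", (10.0, -5.0))
        assert np.allclose(scene_with_palette.world.bodies[bid].position,
                           [10.0, -5.0])

    def test_occupied_spot_pushes_new_body_only(self, scene_with_palette):
        s = scene_with_palette
        first = s.paint("blob", (0.0, 0.0))
        p0 = s.world.bodies[first].position.copy()
        second = s.paint("blob", (0.5, 0.0))
        assert np.allclose(s.world.bodies[first].position, p0,
                           atol=s.world.config.position_tolerance)
        sep = np.linalg.norm(s.world.bodies[second].position - p0)
        r = s.palette["blob"].main_collider.bbox_radius()
        assert sep > 1.2 * r

    def test_unknown_ingredient(self, scene_with_palette):
        with pytest.raises(SceneError, match="unknown ingredient"):
            scene_with_palette.paint("nope", (0, 0))

    def test_outside_canvas(self, scene_with_palette):
        with pytest.raises(SceneError, match="outside canvas"):
            scene_with_palette.paint("blob", (1e4, 0))

    def test_membrane_bound_without_membrane_warns(self, scene_with_palette):
        with pytest.warns(UserWarning, match="no membrane"):
            bid = scene_with_palette.paint("receptor", (0.0, 0.0))
        assert bid in scene_with_palette.instances


class TestEraseAndCopyNumber:
    def test_copy_number_bookkeeping(self, scene_with_palette):
        s = scene_with_palette
        assert s.copy_number("blob") == 0
        ids = [s.paint("blob", (i * 20.0, 0.0)) for i in range(7)]
        assert s.copy_number("blob") == 7
        assert s.erase(ids[0]) == 1
        assert s.erase(ids[1]) == 1
        assert s.copy_number("blob") == 5

    def test_erase_by_name(self, scene_with_palette):
        s = scene_with_palette
        for i in range(5):
            s.paint("blob", (i * 20.0, 0.0))
        assert s.erase("blob") == 5
        assert s.copy_number("blob") == 0

    def test_erase_unknown_selector(self, scene_with_palette):
        with pytest.raises(SceneError):
            scene_with_palette.erase(12345)
        with pytest.raises(SceneError):
            scene_with_palette.erase("ghost")

    def test_fiber_subunits_counted(self, scene_with_palette):
        s = scene_with_palette
        s.draw_fiber("dna", StrokePath(np.array([[0.0, 0.0], [100.0, 0.0]]),
                                       layer=0))
        assert s.copy_number("dna") == 11

    def test_erase_middle_fiber_subunit_splits_chain(self, scene_with_palette):
        s = scene_with_palette
        chain = s.draw_fiber("dna", StrokePath(np.array([[0.0, 0.0],
                                                         [100.0, 0.0]]),
                                               layer=0))
        mid = chain.subunit_ids[5]
        s.erase(mid)
        assert s.copy_number("dna") == 10
        assert len(s.fiber_chains) == 2
        sizes = sorted(len(c.subunit_ids) for c in s.fiber_chains)
        assert sizes == [5, 5]
        # constraint-graph connectivity oracle: no constraint bridges the parts
        left, right = (set(c.subunit_ids) for c in s.fiber_chains)
        for c in s.world.constraints:
            if hasattr(c, "body_a"):
                assert not ({c.body_a, c.body_b} & left
                            and {c.body_a, c.body_b} & right)


class TestPinning:
    def test_pinned_body_immobile_under_diffusion(self, scene_with_palette):
        s = scene_with_palette
        bid = s.paint("blob", (5.0, 5.0))
        s.pin(bid)
        start = s.world.bodies[bid].position.copy()
        s.world.config.diffusion_enabled = True
        s.step(1000)
        assert (s.world.bodies[bid].position == start).all()

    def test_unpin_restores_mobility(self, scene_with_palette):
        s = scene_with_palette
        bid = s.paint("blob", (5.0, 5.0))
        s.pin(bid)
        s.unpin(bid)
        s.world.config.diffusion_enabled = True
        s.step(50)
        assert not np.allclose(s.world.bodies[bid].position, [5.0, 5.0])

    def test_pin_group_pins_all_members(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        b = s.paint("blob", (30.0, 0.0))
        g = s.group([a, b])
        ids = s.stamp(g, (100.0, 100.0))
        s.pin(ids[0])
        assert all(s.world.bodies[i].pinned for i in ids)


class TestPinTo:
    def test_drag_apart_then_settle_restores_distance(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        b = s.paint("blob", (30.0, 0.0))
        d0 = np.linalg.norm(s.world.bodies[a].position
                            - s.world.bodies[b].position)
        s.pin_to(a, (0, 0), b, (0, 0))
        s.world.bodies[b].position[:] = (90.0, 0.0)
        s.settle(max_steps=300)
        d1 = np.linalg.norm(s.world.bodies[a].position
                            - s.world.bodies[b].position)
        assert d1 == pytest.approx(d0, rel=0.01)

    def test_self_constraint_rejected(self, scene_with_palette):
        bid = scene_with_palette.paint("blob", (0, 0))
        with pytest.raises(SceneError, match="itself"):
            scene_with_palette.pin_to(bid, (0, 0), bid, (1, 1))

    def test_chain_of_three_constraints_all_satisfied(self, scene_with_palette):
        s = scene_with_palette
        s.world.matrix.protein_protein = False
        ids = [s.paint("blob", (i * 25.0, 0.0)) for i in range(4)]
        cons = [s.pin_to(ids[i], (0, 0), ids[i + 1], (0, 0)) for i in range(3)]
        rng = np.random.default_rng(0)
        for bid in ids[1:]:
            s.world.bodies[bid].position += rng.uniform(-15, 15, 2)
        s.world.touch()
        s.settle(max_steps=500)
        for c in cons:
            d = np.linalg.norm(s.world.bodies[c.body_a].position
                               - s.world.bodies[c.body_b].position)
            assert d == pytest.approx(c.distance, rel=0.02)


class TestGroups:
    def test_stamp_preserves_relative_geometry(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        b = s.paint("blob", (10.0, 0.0))
        g = s.group([a, b])
        new = s.stamp(g, (200.0 - 105.0, 100.0))
        pa = s.world.bodies[new[0]].position
        pb = s.world.bodies[new[1]].position
        assert np.linalg.norm(pa - pb) == pytest.approx(10.0, abs=0.2)

    def test_stamp_rotated(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        b = s.paint("blob", (10.0, 0.0))
        g = s.group([a, b])
        new = s.stamp(g, (100.0, -100.0), angle=np.pi / 2)
        delta = s.world.bodies[new[1]].position - s.world.bodies[new[0]].position
        assert np.allclose(delta, [0.0, 10.0], atol=0.2)

    def test_stamped_members_still_diffuse(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        g = s.group([a])
        new = s.stamp(g, (100.0, 100.0))
        start = s.world.bodies[new[0]].position.copy()
        s.world.config.diffusion_enabled = True
        s.step(100)
        assert not np.allclose(s.world.bodies[new[0]].position, start)

    def test_empty_group_rejected(self, scene_with_palette):
        with pytest.raises(SceneError, match="empty"):
            scene_with_palette.group([])


class TestLock:
    def _triads(self, scene, centers):
        ids = []
        offsets = np.array([[0.0, 0.5], [0.0, -0.5], [0.5, 0.0]])
        for c in centers:
            for off in offsets:
                ids.append(scene.paint("blob", np.asarray(c) + off,
                                       settle=False))
        return ids

    def test_close_bodies_one_hull(self, scene_with_palette):
        ids = self._triads(scene_with_palette, [(0.0, 0.0)])
        region = scene_with_palette.lock(ids)
        assert len(region.hulls) == 1

    def test_two_clumps_two_hulls(self, scene_with_palette):
        ids = self._triads(scene_with_palette, [(0.0, 0.0), (40.0, 0.0)])
        region = scene_with_palette.lock(ids)
        assert len(region.hulls) == 2

    def test_painted_body_settles_outside_hull(self, scene_with_palette):
        from shapely.geometry import Point, Polygon as ShapelyPolygon

        s = scene_with_palette
        ids = self._triads(s, [(0.0, 0.0)])
        region = s.lock(ids)
        bid = s.paint("blob", (1.0, 0.0))
        s.settle(max_steps=200)
        hull = ShapelyPolygon(region.hulls[0].vertices)
        tol = 3 * s.world.config.position_tolerance
        assert not hull.contains(Point(*s.world.bodies[bid].position).buffer(-tol))

    def test_lock_idempotent_noop(self, scene_with_palette):
        s = scene_with_palette
        ids = self._triads(s, [(0.0, 0.0)])
        region = s.lock(ids)
        with pytest.warns(UserWarning, match="already locked"):
            region2 = s.lock(ids)
        assert region2.id == region.id

    def test_unlock_then_settle_clean(self, scene_with_palette):
        s = scene_with_palette
        ids = self._triads(s, [(0.0, 0.0)])
        region = s.lock(ids)
        s.unlock(region)
        s.settle(max_steps=300)
        bodies = [s.world.bodies[i] for i in ids]
        for i in range(len(bodies)):
            for j in range(i + 1, len(bodies)):
                if not collidable(bodies[i], bodies[j], s.world.matrix):
                    continue
                corr = resolve_pair(bodies[i], bodies[j])
                depth = sum(np.linalg.norm(v) for v in corr.values())
                assert depth < 2 * s.world.config.position_tolerance

    def test_erase_locked_member_recomputes_hulls(self, scene_with_palette):
        s = scene_with_palette
        ids = self._triads(s, [(0.0, 0.0), (40.0, 0.0)])
        region = s.lock(ids)
        for bid in ids[3:]:
            s.erase(bid)
        assert len(s.lock_regions[region.id].hulls) == 1


class TestMeasure:
    def test_pythagorean_distance(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        b = s.paint("blob", (30.0, 40.0))
        assert s.measure(a, b) == pytest.approx(50.0, abs=0.2)

    def test_self_distance_zero(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (5.0, 5.0))
        assert s.measure(a, a) == 0.0

    def test_live_update_after_steps(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        b = s.paint("blob", (3.0, 0.0))
        s.measure(a, b)
        s.settle(max_steps=100)
        m = list(s.measurements.values())[0]
        assert m.value == pytest.approx(
            np.linalg.norm(s.world.bodies[a].position
                           - s.world.bodies[b].position))

    def test_translation_invariance(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        b = s.paint("blob", (50.0, 0.0))
        d0 = s.measure(a, b)
        for body in s.world.bodies.values():
            body.position += np.array([17.0, -23.0])
        s.update_measurements()
        assert list(s.measurements.values())[0].value == pytest.approx(d0)


class TestBackgroundsAndNudge:
    def test_background_registration(self, scene_with_palette):
        bid = scene_with_palette.set_background("tomo.png", 0.36, opacity=0.5)
        bg = scene_with_palette.backgrounds[bid]
        assert bg.nm_per_pixel == 0.36

    def test_bad_scale_rejected(self, scene_with_palette):
        with pytest.raises(SceneError):
            scene_with_palette.set_background("x.png", 0.0)

    def test_nudge_lock_region_moves_members_and_hull(self, scene_with_palette):
        s = scene_with_palette
        ids = [s.paint("blob", (i * 3.0, 0.0), settle=False) for i in range(3)]
        region = s.lock(ids)
        before = np.array([s.world.bodies[i].position for i in ids])
        hull_before = s.world.bodies[region.hull_body_id].position.copy()
        s.nudge(region.id, (5.0, 0.0))
        after = np.array([s.world.bodies[i].position for i in ids])
        assert np.allclose(after - before, [5.0, 0.0])
        assert np.allclose(s.world.bodies[region.hull_body_id].position
                           - hull_before, [5.0, 0.0])

    def test_nudge_into_body_pushes_it_out(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        b = s.paint("blob", (40.0, 0.0))
        pb = s.world.bodies[b].position.copy()
        s.nudge(a, (40.0, 0.0))
        assert np.allclose(s.world.bodies[a].position, [40.0, 0.0], atol=0.01)
        assert np.linalg.norm(s.world.bodies[b].position - pb) > 1.0

    def test_nudge_pinned_body_reanchors(self, scene_with_palette):
        s = scene_with_palette
        a = s.paint("blob", (0.0, 0.0))
        s.pin(a)
        s.nudge(a, (7.0, 0.0))
        assert np.allclose(s.world.bodies[a].position, [7.0, 0.0])
        s.step(20)
        assert np.allclose(s.world.bodies[a].position, [7.0, 0.0])


class TestInvariants:
    def test_copy_number_matches_instances_after_ops(self, scene_with_palette):
        s = scene_with_palette
        ids = [s.paint("blob", (i * 20.0, 0.0)) for i in range(4)]
        s.erase(ids[1])
        s.draw_fiber("dna", StrokePath(np.array([[0.0, 100.0], [80.0, 100.0]]),
                                       layer=0))
        for name in s.palette:
            assert s.copy_number(name) == \
                sum(1 for n in s.instances.values() if n == name)

    def test_rejected_stroke_leaves_scene_unchanged(self, scene_with_palette):
        import json

        s = scene_with_palette
        s.paint("blob", (150.0, 150.0))
        s.draw_membrane("lipid", StrokePath(fx.circle_stroke(50.0,
                                                             clockwise=True),
                                            layer=0))
        snapshot = {bid: (tuple(b.position), b.angle)
                    for bid, b in s.world.bodies.items()}
        n_constraints = len(s.world.constraints)
        with pytest.raises(Exception):
            s.draw_fiber("dna", StrokePath(np.array([[-100.0, 0.0],
                                                     [100.0, 0.0]]), layer=0))
        assert len(s.world.constraints) == n_constraints
        assert {bid: (tuple(b.position), b.angle)
                for bid, b in s.world.bodies.items()} == snapshot
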