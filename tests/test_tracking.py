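import math

import numpy as np
import pytest

from fibertrack.flow_tensor import OrientationField
from fibertrack.phantom import build_phantom, disk_mask, make_straight_scene, make_texture_scene
from fibertrack.seeding import SeedSet, seeds_from_mask
from fibertrack.stack_io import StackMeta
from fibertrack.tracking import (
    ANGLE_EXCEEDED,
    INVALID_FLOW,
    LEFT_FASCICLE_MASK,
    MaskStack,
    OpticFlowTracker,
    Streamline,
    TensorTracker,
    Tractogram,
    constrain_to_mask,
    edit_create,
    edit_delete,
    propagate,
    read_tractogram_jsonl,
    write_tractogram_jsonl,
    write_tractogram_trk,
)


def analytic_field(depth, size, u_of_z, px=3.0, th=3.0, valid=None):
    """Synthetic orientation field with a prescribed per-slice direction."""
    u = np.zeros((depth, size, size, 3))
    for z in range(depth):
        u[z] = np.asarray(u_of_z(z)) / np.linalg.norm(u_of_z(z))
    v = np.ones((depth, size, size), dtype=bool) if valid is None else valid
    return OrientationField(
        u=u, valid=v, noise_scale=1.0, neighborhood_scale=5.0,
        pixel_size_xy=px, slice_thickness=th,
    )


class _FieldProvider(TensorTracker):
    """TensorTracker over a prescribed orientation field."""

    def __init__(self, field, meta, shape):
        self.orientation = field
        self._meta = meta
        self._shape = shape
        self.noise_scale = field.noise_scale
        self.neighborhood_scale = field.neighborhood_scale
        self.step_size = 64

    @property
    def meta(self):
        return self._meta

    @property
    def shape(self):
        return self._shape

    @property
    def depth(self):
        return self.orientation.u.shape[0]


def _grid_seeds(rows_cols, z0=0):
    pts = np.asarray(rows_cols)
    return SeedSet(
        points=pts, roi_labels=np.ones(len(pts), dtype=int),
        seed_slice_index=z0, density=1.0, rng_seed=0,
    )


def make_provider(depth=20, size=40, u_of_z=lambda z: (0, 0, 1), valid=None):
    meta = StackMeta(3.0, 3.0, ".png", depth, 64)
    field = analytic_field(depth, size, u_of_z, valid=valid)
    return _FieldProvider(field, meta, (size, size))


class TestPropagateTensor:
    def test_straight_phantom_streamlines_vertical(self, straight_phantom):
        seeds = seeds_from_mask(
            straight_phantom.seed_mask, density=0.2, rng_seed=1, mask_is_labelled=True
        )
        tract = propagate(seeds, TensorTracker(straight_phantom.stack), "forward", 75.0)
        iso_px = 3 * straight_phantom.spec.pixel_size_xy
        for s in tract.streamlines:
            assert len(s.points) == straight_phantom.spec.depth
            drift = np.linalg.norm(s.points[-1, :2] - s.points[0, :2])
            assert drift < iso_px  # within one isotropized voxel

    def test_angle_termination_at_prescribed_bend(self):
        a = math.radians(80.0)
        prov = make_provider(
            depth=20, u_of_z=lambda z: (0, 0, 1) if z < 10 else (math.sin(a), 0, math.cos(a))
        )
        tract = propagate(_grid_seeds([(20, 20), (10, 25)]), prov, "forward", 75.0)
        for s in tract.streamlines:
            assert s.termination_reason == ANGLE_EXCEEDED
            assert s.points[-1, 2] == pytest.approx(10 * 3.0)  # stops at the bend

    def test_no_emitted_step_exceeds_max_angle(self):
        a = math.radians(80.0)
        prov = make_provider(
            depth=20, u_of_z=lambda z: (0, 0, 1) if z < 10 else (math.sin(a), 0, math.cos(a))
        )
        tract = propagate(_grid_seeds([(20, 20)]), prov, "forward", 75.0)
        for s in tract.streamlines:
            d = np.diff(s.points, axis=0)
            ang = np.degrees(np.arctan2(np.hypot(d[:, 0], d[:, 1]), np.abs(d[:, 2])))
            assert (ang <= 75.0 + 1e-9).all()

    def test_invalid_voxels_bridged_then_terminated(self):
        valid = np.ones((20, 40, 40), dtype=bool)
        valid[5:7] = False  # two invalid slices: bridged
        prov = make_provider(depth=20, valid=valid)
        t = propagate(_grid_seeds([(20, 20)]), prov, "forward", 75.0)
        assert len(t.streamlines[0].points) == 20

        valid2 = np.ones((20, 40, 40), dtype=bool)
        valid2[5:9] = False  # > MAX_INVALID_BRIDGE consecutive: terminate
        prov2 = make_provider(depth=20, valid=valid2)
        t2 = propagate(_grid_seeds([(20, 20)]), prov2, "forward", 75.0)
        s = t2.streamlines[0]
        assert s.termination_reason == INVALID_FLOW
        assert len(s.points) == 8  # seed + slices 1..7 (two bridged)

    def test_seed_on_invalid_voxel_terminates_at_seed(self):
        valid = np.zeros((20, 40, 40), dtype=bool)
        prov = make_provider(depth=20, valid=valid)
        s = propagate(_grid_seeds([(20, 20)]), prov, "forward", 75.0).streamlines[0]
        assert s.termination_reason == INVALID_FLOW
        assert len(s.points) == 1

    def test_backward_tracking_mirrors_forward_on_straight_phantom(self, straight_phantom):
        depth = straight_phantom.spec.depth
        fwd_seeds = seeds_from_mask(
            straight_phantom.seed_mask, density=0.2, rng_seed=1, mask_is_labelled=True
        )
        prov = TensorTracker(straight_phantom.stack)
        fwd = propagate(fwd_seeds, prov, "forward", 75.0)
        bwd_seeds = SeedSet(
            points=fwd_seeds.points, roi_labels=fwd_seeds.roi_labels,
            seed_slice_index=depth - 1, density=0.2, rng_seed=1,
        )
        bwd = propagate(bwd_seeds, prov, "backward", 75.0)
        iso_px = 3 * straight_phantom.spec.pixel_size_xy
        for sf, sb in zip(fwd.streamlines, bwd.streamlines):
            assert len(sb.points) == depth
            # per-slice distance between forward and backward tracks
            d = np.linalg.norm(sf.points[:, :2] - sb.points[::-1, :2], axis=1)
            assert d.max() < iso_px

    def test_direction_validation(self):
        prov = make_provider()
        with pytest.raises(ValueError):
            propagate(_grid_seeds([(5, 5)]), prov, "sideways", 75.0)
        with pytest.raises(ValueError):
            propagate(_grid_seeds([(5, 5)]), prov, "forward", 95.0)

    def test_determinism(self, straight_phantom):
        seeds = seeds_from_mask(
            straight_phantom.seed_mask, density=0.2, rng_seed=1, mask_is_labelled=True
        )
        t1 = propagate(seeds, TensorTracker(straight_phantom.stack), "forward", 75.0)
        t2 = propagate(seeds, TensorTracker(straight_phantom.stack), "forward", 75.0)
        for a, b in zip(t1.streamlines, t2.streamlines):
            assert np.array_equal(a.points, b.points)


class TestPropagateOpticFlow:
    @pytest.fixture(scope="class")
    def drift_phantom(self):
        return build_phantom(
            make_texture_scene(depth=20, size=160, n_fibers=60,
                               drift_per_slice=(0.5, 0.0), rng_seed=3)
        )

    def test_uniform_drift_recovered(self, drift_phantom):
        seeds = seeds_from_mask(
            drift_phantom.seed_mask, density=0.1, rng_seed=1, mask_is_labelled=True
        )
        prov = OpticFlowTracker(drift_phantom.stack, window=15, levels=2)
        tract = propagate(seeds, prov, "forward", 75.0)
        px = drift_phantom.spec.pixel_size_xy
        full = [s for s in tract.streamlines if len(s.points) == 20]
        assert len(full) >= 0.9 * len(tract)
        slopes = [(s.points[-1, 0] - s.points[0, 0]) / px / 19 for s in full]
        assert abs(np.mean(slopes) - 0.5) <= 0.1

    def test_streamlines_inherit_roi_and_color(self, drift_phantom):
        seeds = seeds_from_mask(
            drift_phantom.seed_mask, density=0.05, rng_seed=1, mask_is_labelled=True
        )
        prov = OpticFlowTracker(drift_phantom.stack, window=15, levels=1)
        tract = propagate(seeds, prov, "forward", 75.0)
        assert {s.roi_label for s in tract.streamlines} == {1}
        assert set(tract.colors) == {1}


class TestConstrainToMask:
    def _tract(self, points_list, meta):
        sls = [
            Streamline(points=np.asarray(p, dtype=float), roi_label=1,
                       termination_reason="reached_end")
            for p in points_list
        ]
        return Tractogram(streamlines=sls, meta=meta,
                          provenance={"stack_shape": [10, 20, 20]})

    def _meta(self):
        return StackMeta(1.0, 1.0, ".png", 10, 64)

    def test_all_foreground_is_identity(self):
        meta = self._meta()
        masks = MaskStack(np.ones((10, 20, 20), dtype=np.uint8), meta)
        pts = [[(5, 5, z) for z in range(10)]]
        tract = self._tract(pts, meta)
        for mode in ("truncate", "remove"):
            out = constrain_to_mask(tract, masks, mode)
            assert len(out) == 1 and len(out.streamlines[0].points) == 10

    def test_truncate_and_remove_semantics(self):
        meta = self._meta()
        labels = np.ones((10, 20, 20), dtype=np.uint8)
        labels[5:, :, 10:] = 0  # right half leaves the mask from slice 5 on
        masks = MaskStack(labels, meta)
        inside = [(5, 5, z) for z in range(10)]
        exits = [(12 if z >= 5 else 5, 5, z) for z in range(10)]
        tract = self._tract([inside, exits], meta)

        trunc = constrain_to_mask(tract, masks, "truncate")
        assert len(trunc) == 2
        cut = trunc.streamlines[1]
        assert len(cut.points) == 5
        assert cut.termination_reason == LEFT_FASCICLE_MASK

        rem = constrain_to_mask(tract, masks, "remove")
        assert len(rem) == 1
        assert np.array_equal(rem.streamlines[0].points, np.asarray(inside, float))

    def test_surviving_points_always_inside(self):
        meta = self._meta()
        rng = np.random.default_rng(0)
        labels = (rng.random((10, 20, 20)) > 0.3).astype(np.uint8)
        masks = MaskStack(labels, meta)
        pts = [[(float(rng.integers(0, 20)), float(rng.integers(0, 20)), z) for z in range(10)]
               for _ in range(20)]
        tract = self._tract(pts, meta)
        for mode in ("truncate", "remove"):
            out = constrain_to_mask(tract, masks, mode)
            for s in out.streamlines:
                zi = np.rint(s.points[:, 2]).astype(int)
                rows = np.rint(s.points[:, 1]).astype(int)
                cols = np.rint(s.points[:, 0]).astype(int)
                assert (labels[zi, rows, cols] > 0).all()

    def test_depth_mismatch_rejected(self):
        meta = self._meta()
        masks = MaskStack(np.ones((3, 20, 20), dtype=np.uint8), meta)
        tract = self._tract([[(5, 5, z) for z in range(10)]], meta)
        with pytest.raises(ValueError):
            constrain_to_mask(tract, masks, "truncate")


class TestEditing:
    def _tract_two_bundles(self):
        meta = StackMeta(1.0, 1.0, ".png", 10, 64)
        mk = lambda x0, roi: Streamline(
            points=np.asarray([(x0, 5.0, float(z)) for z in range(10)]),
            roi_label=roi, termination_reason="reached_end",
        )
        sls = [mk(3.0, 1), mk(3.5, 1), mk(15.0, 2)]
        return Tractogram(streamlines=sls, meta=meta,
                          provenance={"stack_shape": [10, 20, 20]})

    def test_delete_whole_slice_polygon_empties(self):
        t = self._tract_two_bundles()
        out = edit_delete(t, [(-1, -1), (21, -1), (21, 21), (-1, 21)], z=0)
        assert len(out) == 0

    def test_degenerate_polygon_is_identity(self):
        t = self._tract_two_bundles()
        assert len(edit_delete(t, [(5, 5), (5, 5)], z=0)) == 3

    def test_delete_only_covered_bundle(self):
        t = self._tract_two_bundles()
        out = edit_delete(t, [(1, 1), (6, 1), (6, 9), (1, 9)], z=0)
        assert [s.roi_label for s in out.streamlines] == [2]

    def test_delete_z_out_of_stack_rejected(self):
        with pytest.raises(ValueError):
            edit_delete(self._tract_two_bundles(), [(0, 0), (5, 0), (5, 5)], z=50)

    def test_create_duplicates_original_run_modulo_label(self, straight_phantom):
        ph = straight_phantom
        prov = TensorTracker(ph.stack)
        # rectangle around the first fascicle's fibers on slice 0
        rows, cols = np.where(ph.seed_mask == 1)
        pad = 2
        poly = [
            (cols.min() - pad, rows.min() - pad), (cols.max() + pad, rows.min() - pad),
            (cols.max() + pad, rows.max() + pad), (cols.min() - pad, rows.max() + pad),
        ]
        base = Tractogram(streamlines=[], meta=ph.stack.meta,
                          provenance={"stack_shape": [ph.spec.depth, *ph.stack.shape]})
        out = edit_create(base, poly, z=0, density=0.2, rng_seed=9,
                          flow_provider=prov, direction="forward")
        assert len(out) > 0
        out2 = edit_create(base, poly, z=0, density=0.2, rng_seed=9,
                           flow_provider=prov, direction="forward")
        for a, b in zip(out.streamlines, out2.streamlines):
            assert np.array_equal(a.points, b.points)

    def test_create_in_background_terminates_at_seed(self, straight_phantom):
        ph = straight_phantom
        prov = TensorTracker(ph.stack)
        base = Tractogram(streamlines=[], meta=ph.stack.meta,
                          provenance={"stack_shape": [ph.spec.depth, *ph.stack.shape]})
        out = edit_create(base, [(2, 2), (14, 2), (14, 14), (2, 14)], z=0,
                          density=0.2, rng_seed=9, flow_provider=prov,
                          direction="forward")
        assert len(out) > 0
        for s in out.streamlines:
            assert s.termination_reason == INVALID_FLOW
            assert len(s.points) <= 3  # at most the two bridged steps

    def test_create_empty_polygon_is_identity(self):
        t = self._tract_two_bundles()
        out = edit_create(t, [], z=0, density=0.1, rng_seed=0,
                          flow_provider=None, direction="forward")
        assert len(out) == 3


class TestTractogramIO:
    def test_jsonl_round_trip_bit_exact(self, tmp_path, straight_phantom):
        seeds = seeds_from_mask(
            straight_phantom.seed_mask, density=0.2, rng_seed=1, mask_is_labelled=True
        )
        tract = propagate(seeds, TensorTracker(straight_phantom.stack), "forward", 75.0)
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_tractogram_jsonl(tract, p1)
        write_tractogram_jsonl(read_tractogram_jsonl(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_trk_export_viewable(self, tmp_path, straight_phantom):
        import nibabel as nib

        seeds = seeds_from_mask(
            straight_phantom.seed_mask, density=0.2, rng_seed=1, mask_is_labelled=True
        )
        tract = propagate(seeds, TensorTracker(straight_phantom.stack), "forward", 75.0)
        out = tmp_path / "t.trk"
        write_tractogram_trk(tract, out)
        trk = nib.streamlines.load(str(out))
        assert len(trk.streamlines) == len(tract)
        assert tuple(trk.header["voxel_sizes"]) == (0.9, 0.9, 3.0)
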