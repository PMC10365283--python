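"""Porosity formula, pore filling (vs scipy closing oracle), meshes, plate split."""

import dataclasses

import numpy as np
import pytest
import trimesh
from scipy import ndimage

import cochleamorph as cm
from cochleamorph.errors import DomainError, ParameterError, TopologyError
from cochleamorph.io_formats import LabelMask
from cochleamorph.morphometry import mask_to_mesh
from cochleamorph.phantom import _ball_offsets


def as_mask(arr, vs=10.0):
    return LabelMask(np.asarray(arr, dtype=np.uint8), vs)


class TestPorosityFormula:
    def test_printed_values_exact(self):
        assert cm.porosity(47, 100) == 53.0
        assert cm.porosity(43, 100) == 57.0

    def test_limits(self):
        assert cm.porosity(100, 100) == 0.0
        assert cm.porosity(0, 100) == 100.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            cm.porosity(101, 100)
        with pytest.raises(DomainError):
            cm.porosity(1, 0)
        with pytest.raises(DomainError):
            cm.porosity(-1, 100)


class TestFillPoresVoxel:
    def test_solid_slab_unchanged(self):
        slab = np.zeros((12, 20, 20), dtype=np.uint8)
        slab[2:10, 2:18, 2:18] = 1
        out = cm.fill_pores_voxel(as_mask(slab), 4)
        assert np.array_equal(out.data, slab)

    def test_small_pore_filled_exactly_to_pristine(self):
        slab = np.zeros((16, 30, 30), dtype=bool)
        slab[2:14, 2:28, 2:28] = True
        pristine = int(slab.sum())
        ball = _ball_offsets(3) + np.array([8, 15, 15])
        slab[ball[:, 0], ball[:, 1], ball[:, 2]] = False
        out = cm.fill_pores_voxel(as_mask(slab), 5)
        assert int(out.data.sum()) == pristine

    def test_large_pore_survives_small_closing(self):
        slab = np.zeros((24, 34, 34), dtype=bool)
        slab[2:22, 2:32, 2:32] = True
        pristine = int(slab.sum())
        ball = _ball_offsets(5) + np.array([12, 17, 17])
        slab[ball[:, 0], ball[:, 1], ball[:, 2]] = False
        out = cm.fill_pores_voxel(as_mask(slab), 3)
        assert int(out.data.sum()) < pristine

    def test_extensive_increasing_idempotent(self):
        rng = np.random.default_rng(0)
        mask, _ = cm.generate_porous_slab((12, 40, 40), 0.3, 2, seed=5)
        m = mask.astype_bool()
        f2 = cm.fill_pores_voxel(mask, 2).astype_bool()
        f4 = cm.fill_pores_voxel(mask, 4).astype_bool()
        assert (f2 | m).sum() == f2.sum()  # extensive
        assert (f4 | f2).sum() == f4.sum()  # increasing in radius
        again = cm.fill_pores_voxel(cm.fill_pores_voxel(mask, 3), 3)
        assert np.array_equal(again.data, cm.fill_pores_voxel(mask, 3).data)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_scipy_binary_closing(self, seed):
        # EDT-based closing must equal scipy closing with the same discrete ball
        rng = np.random.default_rng(seed)
        arr = rng.random((14, 14, 14)) > 0.45
        radius = 2
        ours = cm.fill_pores_voxel(as_mask(arr), radius).astype_bool()
        ball = np.zeros((2 * radius + 1,) * 3, dtype=bool)
        off = _ball_offsets(radius) + radius
        ball[off[:, 0], off[:, 1], off[:, 2]] = True
        pad = radius + 1
        padded = np.pad(arr, pad)
        ref = ndimage.binary_erosion(ndimage.binary_dilation(padded, ball), ball)
        ref = ref[pad:-pad, pad:-pad, pad:-pad] | arr
        assert np.array_equal(ours, ref)

    def test_radius_validation(self):
        with pytest.raises(ParameterError):
            cm.fill_pores_voxel(as_mask(np.ones((3, 3, 3))), 0)


class TestMeshVolume:
    def test_unit_cube(self):
        assert cm.mesh_volume(trimesh.creation.box((1, 1, 1))) == pytest.approx(1.0)

    def test_icosphere_analytic(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=2.0)
        analytic = 4 / 3 * np.pi * 8
        assert cm.mesh_volume(mesh) == pytest.approx(analytic, rel=0.01)
        assert analytic == pytest.approx(33.51, abs=0.01)

    def test_inverted_orientation_same_magnitude(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        flipped = trimesh.Trimesh(mesh.vertices, mesh.faces[:, ::-1], process=False)
        assert cm.mesh_volume(flipped) == pytest.approx(cm.mesh_volume(mesh))

    def test_non_watertight_rejected(self):
        mesh = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        holey = trimesh.Trimesh(mesh.vertices, mesh.faces[:-1], process=False)
        with pytest.raises(TopologyError):
            cm.mesh_volume(holey)

    def test_mask_mesh_volume_matches_voxel_count(self):
        ball = _ball_offsets(8) + 10
        arr = np.zeros((21, 21, 21), dtype=np.uint8)
        arr[ball[:, 0], ball[:, 1], ball[:, 2]] = 1
        mask = as_mask(arr, 100.0)  # 0.1 mm voxels
        vol_vox = arr.sum() * 0.1**3
        assert cm.mesh_volume(mask_to_mesh(mask)) == pytest.approx(vol_vox, rel=0.02)


class TestFillPoresWrap:
    def test_icosphere_wrap_volume_within_two_percent(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        wrap = cm.fill_pores_wrap(mesh, decimation_target_faces=2000)
        assert len(wrap.faces) <= 2000
        assert cm.mesh_volume(wrap) == pytest.approx(cm.mesh_volume(mesh), rel=0.02)

    def test_porous_slab_wrap_encloses_input(self):
        mask, _ = cm.generate_porous_slab((14, 40, 40), 0.4, (2, 3), seed=0, voxel_size_um=100.0)
        mesh = mask_to_mesh(mask)
        wrap = cm.fill_pores_wrap(mesh, decimation_target_faces=1500)
        assert cm.mesh_volume(wrap) >= cm.mesh_volume(mesh)

    def test_face_budget_validation(self):
        mesh = trimesh.creation.icosphere(subdivisions=1)
        with pytest.raises(ParameterError):
            cm.fill_pores_wrap(mesh, decimation_target_faces=4)

    def test_backends_agree_on_porous_slab(self):
        mask, truth = cm.generate_porous_slab((14, 48, 48), 0.5, (2, 3), seed=1, voxel_size_um=100.0)
        filled = cm.fill_pores_voxel(mask, 5)
        vox3 = (mask.voxel_size_um / 1000.0) ** 3
        p_voxel = cm.porosity(float(mask.data.sum()) * vox3, float(filled.data.sum()) * vox3)
        mesh = mask_to_mesh(mask)
        wrap = cm.fill_pores_wrap(mesh, decimation_target_faces=2000)
        p_mesh = cm.porosity(
            cm.mesh_volume(mesh), max(cm.mesh_volume(wrap), cm.mesh_volume(mesh))
        )
        assert abs(p_voxel - p_mesh) <= 5.0


class TestSplitPlates:
    def test_phantom_plate_assignment(self, phantom_full):
        _, _, masks, truth = phantom_full
        frame = cm.build_reference_frame(**truth.landmarks_mm)
        tymp, vest = cm.split_plates(masks["bone"], frame)
        true_t = truth.plate_masks["tympanic"] & ~truth.pore_masks["tympanic"]
        true_v = truth.plate_masks["vestibular"] & ~truth.pore_masks["vestibular"]
        bone = masks["bone"].astype_bool()
        agree = ((tymp.astype_bool() == true_t) & (vest.astype_bool() == true_v))[bone].mean()
        assert agree >= 0.99
        # exact bipartition of the input
        assert not (tymp.astype_bool() & vest.astype_bool()).any()
        assert np.array_equal(tymp.astype_bool() | vest.astype_bool(), bone)

    def test_single_sheet_topology_error(self, phantom_full):
        _, _, masks, truth = phantom_full
        frame = cm.build_reference_frame(**truth.landmarks_mm)
        single = LabelMask(
            (truth.plate_masks["tympanic"]).astype(np.uint8),
            masks["bone"].voxel_size_um,
            masks["bone"].origin_mm,
        )
        with pytest.raises(TopologyError):
            cm.split_plates(single, frame)

    def test_axis_flip_swaps_plates(self, small_spec):
        _, masks, truth = cm.generate_phantom(small_spec)
        lm = truth.landmarks_mm
        frame = cm.build_reference_frame(lm["center_mm"], lm["helicotrema_mm"], lm["basal_mm"])
        flipped = cm.build_reference_frame(
            lm["center_mm"], lm["center_mm"] - (lm["helicotrema_mm"] - lm["center_mm"]), lm["basal_mm"]
        )
        t1, v1 = cm.split_plates(masks["bone"], frame)
        t2, v2 = cm.split_plates(masks["bone"], flipped)
        assert np.array_equal(t1.data, v2.data)
        assert np.array_equal(v1.data, t2.data)


class TestSegmentPorosity:
    def test_whole_plate_recovery_30pct(self, small_spec):
        spec = dataclasses.replace(small_spec, pore_target_fraction=0.30)
        _, masks, truth = cm.generate_phantom(spec)
        frame = cm.build_reference_frame(**truth.landmarks_mm)
        results = cm.segment_porosity(
            masks["bone"], frame,
            turn_bounds_deg=[("whole", -1.0, 360.0 * spec.turns + 1.0)],
            closing_radius_vox=2,  # 1.5x the 1-voxel max pore radius, rounded up
        )
        assert len(results) == 2
        for r in results:
            assert abs(r.p_pct - truth.true_porosity_pct[r.plate]) <= 3.0
            assert 27.0 <= r.p_pct <= 33.0

    def test_zero_pore_phantom_below_one_percent(self, small_spec):
        spec = dataclasses.replace(small_spec, pore_target_fraction=0.0)
        _, masks, truth = cm.generate_phantom(spec)
        frame = cm.build_reference_frame(**truth.landmarks_mm)
        results = cm.segment_porosity(
            masks["bone"], frame,
            turn_bounds_deg=[("whole", -1.0, 360.0 * spec.turns + 1.0)],
            closing_radius_vox=2,
        )
        for r in results:
            assert r.p_pct <= 1.0

    def test_three_segments_two_plates(self, phantom_full):
        _, _, masks, truth = phantom_full
        frame = cm.build_reference_frame(**truth.landmarks_mm)
        results = cm.segment_porosity(masks["bone"], frame, closing_radius_vox=5)
        assert {(r.segment_label, r.plate) for r in results} == {
            (s, p)
            for s in ("basal", "midturn", "apex")
            for p in ("tympanic", "vestibular")
        }
        for r in results:
            assert 0.0 <= r.p_pct <= 100.0
            assert r.Vo_mm3 <= r.Vf_mm3

    def test_mesh_backend_on_arc_segment(self, small_spec):
        _, masks, truth = cm.generate_phantom(small_spec)
        frame = cm.build_reference_frame(**truth.landmarks_mm)
        results = cm.segment_porosity(
            masks["bone"], frame,
            turn_bounds_deg=[("arc", 100.0, 160.0)],
            backend="mesh_wrap",
            decimation_target_faces=1500,
        )
        assert len(results) == 2
        for r in results:
            assert r.backend == "mesh_wrap"
            assert 0.0 <= r.p_pct <= 100.0
            assert 0.0 < r.Vo_mm3 <= r.Vf_mm3

    def test_unknown_backend(self, small_spec):
        _, masks, truth = cm.generate_phantom(small_spec)
        frame = cm.build_reference_frame(**truth.landmarks_mm)
        with pytest.raises(ParameterError):
            cm.segment_porosity(masks["bone"], frame, backend="surface_nets")
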