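"""Shared fixtures: phantoms at two resolutions and the measured chain."""

import numpy as np
import pytest

import cochleamorph as cm
from cochleamorph.io_formats import LabelMask


@pytest.fixture(scope="session")
def phantom_full():
    """Default-geometry phantom with a cochleolith at the 2 kHz locus."""
    spec = cm.PhantomSpec(inclusion_freq_hz=2000.0, seed=123)
    volume, masks, truth = cm.generate_phantom(spec)
    return spec, volume, masks, truth


@pytest.fixture(scope="session")
def small_spec():
    """Coarse, fast phantom spec for determinism and orchestration tests."""
    return cm.PhantomSpec(
        voxel_size_um=60.0,
        turns=1.75,
        spiral_r0_mm=1.4,
        spiral_growth=0.05,
        pitch_mm_per_turn=1.7,
        width_base_mm=1.2,
        width_apex_mm=0.5,
        plate_thickness_mm=0.42,
        plate_gap_mm=0.24,
        pore_target_fraction=0.3,
        pore_radius_vox_range=(1, 1),
        seed=7,
    )


@pytest.fixture(scope="session")
def measured_chain(phantom_full):
    """Segmentation + geometry chain run once on the full phantom."""
    spec, volume, masks, truth = phantom_full
    frame = cm.build_reference_frame(**truth.landmarks_mm)
    osl = cm.remove_small_components(
        cm.threshold_segment(volume, cm.ThresholdRule(130)), 27
    )
    incl = cm.remove_small_components(
        cm.threshold_segment(volume, cm.ThresholdRule(220)), 27
    )
    from cochleamorph.morphometry import _ball_dilate

    grown = LabelMask(
        _ball_dilate(incl.astype_bool(), 2.0).astype(np.uint8),
        incl.voxel_size_um,
        incl.origin_mm,
    )
    osl = cm.subtract_labels(osl, grown)
    contours = cm.extract_wall_contours(osl, frame)
    smoothed = cm.spiral_geometry.smooth_contours(contours, volume.voxel_size_mm)
    profile = cm.width_profile(smoothed)
    cm.assign_positions(profile)
    return {
        "spec": spec,
        "volume": volume,
        "masks": masks,
        "truth": truth,
        "frame": frame,
        "osl": osl,
        "inclusion": incl,
        "profile": profile,
    }


def make_annulus_mask(
    inner_mm=2.0, outer_mm=3.0, height_mm=0.3, voxel_um=50.0, axis="z"
):
    """Planar annulus voxel mask (centre-in-solid convention), for width oracles.

    The lattice is offset from the ring centre by an irrational sub-voxel
    shift, as for a generically positioned specimen; exact lattice tangency is
    a measure-zero special case that starves whole angular sectors of
    boundary samples.
    """
    vs = voxel_um / 1000.0
    half = outer_mm + 0.2
    n = int(np.ceil(2 * half / vs)) + 1
    nz = int(np.ceil((height_mm + 0.2) / vs)) + 1
    c = (np.arange(n) - (n - 1) / 2.0) * vs + 0.2847 * vs
    cz = (np.arange(nz) - (nz - 1) / 2.0) * vs + 0.1318 * vs
    if axis == "z":
        X, Y = np.meshgrid(c, c, indexing="xy")
        rho = np.hypot(X, Y)
        ring = (rho >= inner_mm) & (rho <= outer_mm)
        mask = ring[None, :, :] & (np.abs(cz)[:, None, None] <= height_mm / 2)
        origin = np.array([c[0], c[0], cz[0]])
        shape_mask = np.broadcast_to(mask, (nz, n, n)).copy()
        return LabelMask(shape_mask.astype(np.uint8), voxel_um, origin)
    if axis == "y":
        # annulus in the x-z plane, ring axis along +y
        Xg, Zg = np.meshgrid(c, c, indexing="xy")  # [iz_like, ix]
        rho = np.hypot(Xg, Zg)
        ring = (rho >= inner_mm) & (rho <= outer_mm)  # [i_c2, i_c1]
        ny = nz
        mask = np.zeros((n, ny, n), dtype=bool)  # (z, y, x)
        for iy in range(ny):
            if abs(cz[iy]) <= height_mm / 2:
                mask[:, iy, :] = ring
        origin = np.array([c[0], cz[0], c[0]])
        return LabelMask(mask.astype(np.uint8), voxel_um, origin)
    raise ValueError(axis)
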