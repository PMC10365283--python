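"""Synthetic cochlea phantom with exact ground truth.

The phantom stands in for a micro-CT scan of the cochlea.  Its osseous spiral
lamina (OSL) is modelled as a ribbon following a logarithmic spiral with axial
pitch,

    r(theta) = r0 * exp(g * theta),   z(theta) = pitch * theta / (2*pi),

built from two parallel bony plates (tympanic below the mid-surface,
vestibular above) separated by a soft-tissue gap.  The ribbon's radial width
falls linearly in unwrapped angle from ``width_base_mm`` to ``width_apex_mm``,
mirroring the descending base-to-apex width of the real lamina.  Spherical
pores are carved into each plate, strictly interior so the void stays
disconnected from the outside and the true porosity is an exact voxel count.
An optional dense inclusion ("cochleolith") is placed at the tonotopic
position of a chosen frequency.  Gaussian noise is added last.

Every random draw goes through one seeded generator, so an identical spec
yields bitwise-identical volumes, masks and truths.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np
from scipy import integrate, ndimage

from .errors import GenerationError, ParameterError
from .io_formats import LabelMask, VoxelVolume
from .tonotopy import FrequencyMapParams, frequency_to_position

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_centerline",
    "generate_phantom",
    "generate_porous_slab",
]

PLATES = ("tympanic", "vestibular")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cochlea.

    Geometry defaults are conventional human-scale values (2.5 turns, ~4 mm
    wide spiral, 1.3 mm axial rise per turn); they are configuration, not
    measured facts.  The width endpoints default to the 1.34 -> 0.28 mm
    base-to-apex range of the human OSL, and the pore target to 53%,
    mid-range of reported OSL plate porosities.
    """

    voxel_size_um: float = 30.0
    turns: float = 2.5
    spiral_r0_mm: float = 1.6
    spiral_growth: float = 0.045
    pitch_mm_per_turn: float = 1.3
    width_base_mm: float = 1.34
    width_apex_mm: float = 0.28
    plate_thickness_mm: float = 0.30
    plate_gap_mm: float = 0.15
    pore_target_fraction: float = 0.53
    pore_radius_vox_range: tuple[int, int] = (2, 3)
    inclusion_freq_hz: float | None = None
    inclusion_radius_mm: float | None = None
    noise_sigma: float = 10.0
    bone_intensity: float = 180.0
    soft_intensity: float = 80.0
    allow_overlapping_pores: bool = True
    margin_mm: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_size_um", "turns", "spiral_r0_mm", "width_base_mm",
                     "width_apex_mm", "plate_thickness_mm"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("pitch_mm_per_turn", "plate_gap_mm", "noise_sigma", "margin_mm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.width_apex_mm > self.width_base_mm:
            raise ParameterError(
                f"width must not increase toward the apex: "
                f"apex {self.width_apex_mm} > base {self.width_base_mm}"
            )
        if not 0 <= self.pore_target_fraction < 1:
            raise ParameterError("pore_target_fraction must lie in [0, 1)")
        lo, hi = self.pore_radius_vox_range
        if lo < 1 or hi < lo:
            raise ParameterError(f"bad pore_radius_vox_range {self.pore_radius_vox_range}")
        if self.inclusion_freq_hz is not None and self.inclusion_freq_hz <= 0:
            raise ParameterError("inclusion_freq_hz must be positive")
        if self.inclusion_radius_mm is not None and self.inclusion_radius_mm <= 0:
            raise ParameterError("inclusion_radius_mm must be positive")

    @property
    def theta_max(self) -> float:
        return 2.0 * math.pi * self.turns

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        return self.spiral_r0_mm * np.exp(self.spiral_growth * np.asarray(theta, dtype=float))

    def z_at(self, theta: np.ndarray) -> np.ndarray:
        return self.pitch_mm_per_turn * np.asarray(theta, dtype=float) / (2.0 * math.pi)

    def width_at(self, theta: np.ndarray) -> np.ndarray:
        t = np.asarray(theta, dtype=float) / self.theta_max
        return self.width_base_mm + (self.width_apex_mm - self.width_base_mm) * t


@dataclasses.dataclass
class PhantomTruth:
    """Exact ground truth carried alongside a generated phantom."""

    true_porosity_pct: dict[str, float]
    width_fn: Callable[[np.ndarray], np.ndarray]  # unwrapped angle in degrees -> mm
    total_arclength_mm: float
    centerline_mm: np.ndarray
    landmarks_mm: dict[str, np.ndarray]
    plate_masks: dict[str, np.ndarray]  # pristine (pre-carving) boolean masks
    pore_masks: dict[str, np.ndarray]
    bone_mask: np.ndarray
    soft_mask: np.ndarray
    inclusion_center_xyz: np.ndarray | None = None
    inclusion_x_norm: float | None = None
    _theta_grid: np.ndarray | None = None
    _arclen_grid: np.ndarray | None = None

    def arclength_at_angle_deg(self, theta_deg) -> np.ndarray:
        """Arc length (mm) from the base to unwrapped angle theta."""
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        return np.interp(th, self._theta_grid, self._arclen_grid)

    def x_norm_at_angle_deg(self, theta_deg, convention: str = "from_apex"):
        """Normalized tonotopic position of unwrapped angle theta."""
        s = self.arclength_at_angle_deg(theta_deg)
        frac = s / self.total_arclength_mm
        return frac if convention == "from_base" else 1.0 - frac


def _arclength_integrand(spec: PhantomSpec) -> Callable[[float], float]:
    g = spec.spiral_growth
    c = spec.pitch_mm_per_turn / (2.0 * math.pi)

    def ds(theta: float) -> float:
        r = spec.spiral_r0_mm * math.exp(g * theta)
        return math.sqrt(r * r * (1.0 + g * g) + c * c)

    return ds


def generate_centerline(spec: PhantomSpec, samples_per_turn: int = 256) -> np.ndarray:
    """Sample the spiral centerline base -> apex as an (n, 3) polyline in mm."""
    if samples_per_turn < 32:
        raise ParameterError("need at least 32 samples per turn")
    n = max(2, int(math.ceil(samples_per_turn * spec.turns)) + 1)
    theta = np.linspace(0.0, spec.theta_max, n)
    r = spec.radius_at(theta)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), spec.z_at(theta)])


def _ball_offsets(radius: int) -> np.ndarray:
    """Voxel offsets of the discrete ball {d <= radius}."""
    rng = np.arange(-radius, radius + 1)
    dz, dy, dx = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = dz * dz + dy * dy + dx * dx <= radius * radius
    return np.column_stack([dz[keep], dy[keep], dx[keep]])


def carve_pores(
    plate: np.ndarray,
    target_fraction: float,
    radius_range: tuple[int, int],
    rng: np.random.Generator,
    allow_overlap: bool = True,
    max_attempts: int = 100_000,
) -> np.ndarray:
    """Carve spherical pores into a boolean plate mask, strictly interior.

    Pores are unions of discrete balls whose every voxel keeps at least a
    one-voxel bony shell toward the plate surface, so the void never connects
    to the outside.  Carving stops once the carved voxel count reaches
    ``target_fraction`` of the pristine plate volume; the achieved fraction is
    exact by construction (it is a voxel count).  Returns the pore mask.
    """
    plate = plate.astype(bool)
    pristine = int(plate.sum())
    void = np.zeros_like(plate)
    if target_fraction <= 0 or pristine == 0:
        return void
    target = target_fraction * pristine
    lo, hi = radius_range
    offsets = {r: _ball_offsets(r) for r in range(lo, hi + 1)}
    # distance to outside-of-plate, with the array border counting as outside;
    # chessboard distance lower-bounds Euclidean distance, so the eligibility
    # test stays conservative (pores strictly interior) at a fraction of the
    # cost of an exact Euclidean transform
    padded = np.pad(plate, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")[1:-1, 1:-1, 1:-1]
    eligible = {r: np.argwhere(dist > r + 1) for r in range(lo, hi + 1)}
    radii = [r for r in range(lo, hi + 1) if len(eligible[r]) > 0]
    if not radii:
        raise GenerationError(
            f"no interior room for pores of radius >= {lo} "
            f"(achieved porosity 0.0% of target {100 * target_fraction:.1f}%)"
        )
    carved = 0
    attempts = 0
    while carved < target:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"pore target fraction {target_fraction:.3f} unreachable in "
                f"{max_attempts} attempts; achieved {carved / pristine:.3f}"
            )
        r = int(rng.integers(radii[0], radii[-1] + 1))
        if r not in offsets or len(eligible[r]) == 0:
            continue
        center = eligible[r][int(rng.integers(len(eligible[r])))]
        coords = center + offsets[r]
        zz, yy, xx = coords[:, 0], coords[:, 1], coords[:, 2]
        hit = void[zz, yy, xx]
        if not allow_overlap and hit.any():
            continue
        new = int((~hit).sum())
        if new == 0:
            continue
        void[zz, yy, xx] = True
        carved += new
    return void


def generate_porous_slab(
    dims_vox: tuple[int, int, int],
    pore_fraction: float,
    pore_radius_vox: int | tuple[int, int],
    seed: int,
    voxel_size_um: float = 10.0,
    allow_overlap: bool = True,
) -> tuple[LabelMask, float]:
    """A rectangular porous plate with exact porosity truth.

    Unit-test fixture for the porosity stage: a full slab of ``dims_vox``
    (z, y, x) voxels with interior spherical pores carved to ``pore_fraction``
    of its volume.  Returns the mask and the true porosity percentage
    (an exact discrete voxel count).
    """
    if isinstance(pore_radius_vox, (int, np.integer)):
        radius_range = (int(pore_radius_vox), int(pore_radius_vox))
    else:
        radius_range = (int(pore_radius_vox[0]), int(pore_radius_vox[1]))
    if radius_range[0] < 1:
        raise ParameterError("pore radius must be >= 1 voxel")
    if not 0 <= pore_fraction < 1:
        raise ParameterError("pore_fraction must lie in [0, 1)")
    if any(d < 4 * radius_range[1] for d in dims_vox):
        raise ParameterError(
            f"slab dims {dims_vox} too small for pore radius {radius_range[1]} "
            f"(each dim must be >= 4x the radius)"
        )
    rng = np.random.default_rng(seed)
    slab = np.ones(tuple(int(d) for d in dims_vox), dtype=bool)
    void = carve_pores(slab, pore_fraction, radius_range, rng, allow_overlap)
    truth_pct = 100.0 * float(void.sum()) / float(slab.sum())
    mask = LabelMask((slab & ~void).astype(np.uint8), voxel_size_um)
    return mask, truth_pct


def _grid_for(spec: PhantomSpec, inclusion_r_mm: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre world coordinates (xs, ys, zs) and the origin, in mm."""
    vs = spec.voxel_size_um / 1000.0
    theta = np.linspace(0.0, spec.theta_max, 2048)
    r_outer = float(np.max(spec.radius_at(theta) + spec.width_at(theta) / 2.0))
    half_extent = r_outer + spec.margin_mm + inclusion_r_mm
    half_h = spec.plate_gap_mm / 2.0 + spec.plate_thickness_mm
    z_lo = -half_h - spec.margin_mm - inclusion_r_mm
    z_hi = spec.z_at(spec.theta_max) + half_h + spec.margin_mm + 2.0 * inclusion_r_mm
    nx = int(math.ceil(2 * half_extent / vs)) + 1
    nz = int(math.ceil((z_hi - z_lo) / vs)) + 1
    xs = (np.arange(nx) - (nx - 1) / 2.0) * vs
    zs = z_lo + np.arange(nz) * vs
    origin = np.array([xs[0], xs[0], zs[0]])
    return xs, xs.copy(), zs, origin


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, dict[str, LabelMask], PhantomTruth]:
    """Generate the phantom volume, per-structure label masks, and its truth.

    Returns ``(volume, masks, truth)`` where ``masks`` has keys ``bone``,
    ``tympanic``, ``vestibular``, ``soft`` and, when an inclusion frequency is
    set, ``inclusion``.
    """
    rng = np.random.default_rng(spec.seed)
    incl_r = spec.inclusion_radius_mm or (0.15 if spec.inclusion_freq_hz else 0.0)
    xs, ys, zs, origin = _grid_for(spec, incl_r)
    vs = spec.voxel_size_um / 1000.0

    X, Y = np.meshgrid(xs, ys, indexing="xy")  # [iy, ix]
    rho = np.hypot(X, Y)
    phi = np.mod(np.arctan2(Y, X), 2.0 * math.pi)

    shape = (len(zs), len(ys), len(xs))
    tymp = np.zeros(shape, dtype=bool)
    vest = np.zeros(shape, dtype=bool)
    soft = np.zeros(shape, dtype=bool)
    half_gap = spec.plate_gap_mm / 2.0
    t = spec.plate_thickness_mm

    for k in range(int(math.ceil(spec.turns)) + 1):
        theta = phi + 2.0 * math.pi * k
        on_turn = theta <= spec.theta_max
        if not on_turn.any():
            break
        r_c = spec.radius_at(theta)
        w = spec.width_at(theta)
        radial = on_turn & (np.abs(rho - r_c) <= w / 2.0)
        if not radial.any():
            continue
        z_c = spec.z_at(theta)
        # only z slices within reach of this turn's plates need evaluating
        zc_sel = z_c[radial]
        z_lo = zc_sel.min() - (half_gap + t)
        z_hi = zc_sel.max() + (half_gap + t)
        iz = np.flatnonzero((zs >= z_lo - vs) & (zs <= z_hi + vs))
        if iz.size == 0:
            continue
        sl = slice(iz[0], iz[-1] + 1)
        dz = zs[sl, None, None] - z_c[None, :, :]
        in_plane = radial[None, :, :]
        tymp[sl] |= in_plane & (-dz > half_gap) & (-dz <= half_gap + t)
        vest[sl] |= in_plane & (dz > half_gap) & (dz <= half_gap + t)
        soft[sl] |= in_plane & (np.abs(dz) <= half_gap)

    plate_masks = {"tympanic": tymp.copy(), "vestibular": vest.copy()}
    pore_masks = {}
    porosity_pct = {}
    for name in PLATES:
        pores = carve_pores(
            plate_masks[name],
            spec.pore_target_fraction,
            spec.pore_radius_vox_range,
            rng,
            spec.allow_overlapping_pores,
        )
        pore_masks[name] = pores
        n_plate = int(plate_masks[name].sum())
        porosity_pct[name] = 100.0 * float(pores.sum()) / n_plate if n_plate else 0.0

    bone = (tymp & ~pore_masks["tympanic"]) | (vest & ~pore_masks["vestibular"])
    soft_all = soft | pore_masks["tympanic"] | pore_masks["vestibular"]

    vol = np.zeros(shape, dtype=np.float32)
    vol[soft_all] = spec.soft_intensity
    vol[bone] = spec.bone_intensity

    # dense arc-length table for the tonotopic position of any angle
    theta_grid = np.linspace(0.0, spec.theta_max, 4096)
    ds = _arclength_integrand(spec)
    ds_vals = np.array([ds(th) for th in theta_grid])
    arclen_grid = integrate.cumulative_trapezoid(ds_vals, theta_grid, initial=0.0)
    total_len = float(integrate.quad(ds, 0.0, spec.theta_max, limit=200)[0])

    inclusion_mask = None
    inclusion_center = None
    inclusion_x = None
    if spec.inclusion_freq_hz is not None:
        inclusion_x = frequency_to_position(spec.inclusion_freq_hz, FrequencyMapParams())
        s_target = (1.0 - inclusion_x) * total_len  # from_apex -> arc length from base
        theta_star = float(np.interp(s_target, arclen_grid, theta_grid))
        r_star = float(spec.radius_at(theta_star))
        z_star = float(spec.z_at(theta_star)) + half_gap + t + 0.4 * incl_r
        inclusion_center = np.array(
            [r_star * math.cos(theta_star), r_star * math.sin(theta_star), z_star]
        )
        d2 = (
            (X[None, :, :] - inclusion_center[0]) ** 2
            + (Y[None, :, :] - inclusion_center[1]) ** 2
            + (zs[:, None, None] - inclusion_center[2]) ** 2
        )
        inclusion_mask = d2 <= incl_r * incl_r
        vol[inclusion_mask] = spec.bone_intensity + 70.0

    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)

    centerline = generate_centerline(spec)
    apex_z = float(spec.z_at(spec.theta_max))
    landmarks = {
        "center_mm": np.array([0.0, 0.0, 0.0]),
        "helicotrema_mm": np.array([0.0, 0.0, apex_z if apex_z > 0 else 1.0]),
        "basal_mm": centerline[0].copy(),
    }

    truth = PhantomTruth(
        true_porosity_pct=porosity_pct,
        width_fn=lambda deg: spec.width_at(np.deg2rad(deg)),
        total_arclength_mm=total_len,
        centerline_mm=centerline,
        landmarks_mm=landmarks,
        plate_masks=plate_masks,
        pore_masks=pore_masks,
        bone_mask=bone,
        soft_mask=soft_all,
        inclusion_center_xyz=inclusion_center,
        inclusion_x_norm=inclusion_x,
        _theta_grid=theta_grid,
        _arclen_grid=arclen_grid,
    )

    volume = VoxelVolume(vol, spec.voxel_size_um, origin)
    masks = {
        "bone": LabelMask(bone.astype(np.uint8), spec.voxel_size_um, origin),
        "tympanic": LabelMask((tymp & ~pore_masks["tympanic"]).astype(np.uint8), spec.voxel_size_um, origin),
        "vestibular": LabelMask((vest & ~pore_masks["vestibular"]).astype(np.uint8), spec.voxel_size_um, origin),
        "soft": LabelMask(soft_all.astype(np.uint8), spec.voxel_size_um, origin),
    }
    if inclusion_mask is not None:
        masks["inclusion"] = LabelMask(inclusion_mask.astype(np.uint8), spec.voxel_size_um, origin)
    return volume, masks, truth
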