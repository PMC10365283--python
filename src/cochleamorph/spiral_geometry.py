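"""Spiral reference frame, angular unwrapping and OSL width profiling.

The cochlear spiral is measured in a cylindrical frame whose axis runs from
the cochlear centre point toward the helicotrema (the mid-modiolar axis) with
the angular origin at the basal end.  Within each angular half-plane through
the axis (a radial section), the lamina's inner (modiolar) and outer (lateral)
wall points are located as centroids of the extreme one-voxel-thick edge sets
of the mask, shifted half a voxel outward/inward to compensate for the
centre-of-voxel sampling bias, and the OSL width is the Euclidean distance
between the paired wall points of that section.

Multiple turns intersect the same half-plane; they are separated by gap
clustering along the axial (and, secondarily, radial) coordinate and indexed
from the basal turn upward, which unwraps the angle beyond 360 degrees.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import savgol_filter

from .errors import CoverageError, GeometryError, ParameterError
from .io_formats import LabelMask

__all__ = [
    "ReferenceFrame",
    "WallContours",
    "WidthProfile",
    "build_reference_frame",
    "unwrap_angle",
    "extract_wall_contours",
    "smooth_contours",
    "width_profile",
    "arc_length",
]

_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class ReferenceFrame:
    """Cylindrical coordinate frame of the spiral.

    ``axis_dir`` points from the cochlear centre toward the helicotrema;
    ``zero_dir`` (perpendicular to the axis) marks the angular origin at the
    basal, round-window end.
    """

    center_mm: np.ndarray
    axis_dir: np.ndarray
    zero_dir: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_mm", np.asarray(self.center_mm, dtype=float))
        a = np.asarray(self.axis_dir, dtype=float)
        z = np.asarray(self.zero_dir, dtype=float)
        if abs(np.linalg.norm(a) - 1) > 1e-6 or abs(np.linalg.norm(z) - 1) > 1e-6:
            raise GeometryError("axis_dir and zero_dir must be unit vectors")
        if abs(float(a @ z)) > 1e-6:
            raise GeometryError("zero_dir must be perpendicular to axis_dir")
        object.__setattr__(self, "axis_dir", a)
        object.__setattr__(self, "zero_dir", z)

    @property
    def ortho_dir(self) -> np.ndarray:
        """Third basis vector completing the right-handed frame."""
        return np.cross(self.axis_dir, self.zero_dir)

    def cylindrical(self, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rho, phi, h): radius, azimuth in [0, 2pi) and axial coordinate."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float)) - self.center_mm
        u = p @ self.zero_dir
        v = p @ self.ortho_dir
        h = p @ self.axis_dir
        rho = np.hypot(u, v)
        phi = np.mod(np.arctan2(v, u), 2.0 * np.pi)
        return rho, phi, h


@dataclasses.dataclass
class WallContours:
    """Inner and outer wall points sampled per unwrapped angle (degrees)."""

    angles_deg: np.ndarray
    inner_pts_mm: np.ndarray
    outer_pts_mm: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.inner_pts_mm = np.asarray(self.inner_pts_mm, dtype=float)
        self.outer_pts_mm = np.asarray(self.outer_pts_mm, dtype=float)
        n = len(self.angles_deg)
        if self.inner_pts_mm.shape != (n, 3) or self.outer_pts_mm.shape != (n, 3):
            raise GeometryError("contour point arrays must be (n, 3) matching angles")
        if n > 1 and not np.all(np.diff(self.angles_deg) > 0):
            raise GeometryError("contour angles must be strictly increasing")


@dataclasses.dataclass
class WidthProfile:
    """Per-angle OSL width samples with midline points and tonotopic positions.

    ``x_norm`` is filled by the tonotopy stage; until then it is None.
    """

    angles_deg: np.ndarray
    width_mm: np.ndarray
    points_mm: np.ndarray  # midline (inner+outer)/2, used for arc length
    x_norm: np.ndarray | None = None

    @property
    def degenerate(self) -> np.ndarray:
        """Samples whose inner and outer wall coincide (zero width)."""
        return self.width_mm <= 0


def build_reference_frame(center_mm, helicotrema_mm, basal_mm) -> ReferenceFrame:
    """Frame from three landmarks: cochlear centre, helicotrema, basal point."""
    c = np.asarray(center_mm, dtype=float)
    h = np.asarray(helicotrema_mm, dtype=float)
    b = np.asarray(basal_mm, dtype=float)
    axis = h - c
    n_axis = np.linalg.norm(axis)
    if n_axis < _EPS:
        raise GeometryError("helicotrema coincides with the centre point")
    axis = axis / n_axis
    v = b - c
    zero = v - (v @ axis) * axis
    n_zero = np.linalg.norm(zero)
    if n_zero < _EPS:
        raise GeometryError("basal landmark lies on the reference axis")
    return ReferenceFrame(c, axis, zero / n_zero)


def unwrap_angle(points_mm: np.ndarray, frame: ReferenceFrame) -> np.ndarray:
    """Continuous unwrapped azimuth (degrees) of an ordered point sequence.

    Successive differences are taken in (-180, 180), so a spiral sweep
    unwraps monotonically past 360 degrees.
    """
    rho, phi, _ = frame.cylindrical(points_mm)
    if np.any(rho < _EPS):
        raise GeometryError("point lies on the reference axis; azimuth undefined")
    return np.degrees(np.unwrap(phi))


def arc_length(points_mm: np.ndarray) -> np.ndarray:
    """Cumulative arc length (mm) along a polyline; starts at 0."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if pts.shape[0] < 2:
        raise ParameterError("need at least 2 points for an arc length")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _gap_split(order_vals: np.ndarray, gap: float) -> list[np.ndarray]:
    """Split sorted-order indices of a 1D coordinate at jumps larger than gap."""
    order = np.argsort(order_vals, kind="stable")
    sorted_vals = order_vals[order]
    cuts = np.flatnonzero(np.diff(sorted_vals) > gap) + 1
    return [seg for seg in np.split(order, cuts) if seg.size]


def extract_wall_contours(
    osl_mask: LabelMask,
    frame: ReferenceFrame,
    n_steps_per_turn: int = 90,
    turn_gap_mm: float = 0.5,
    min_cluster_voxels: int = 4,
) -> WallContours:
    """Contour the inner and outer wall of the lamina per angular step.

    For each of ``n_steps_per_turn`` half-planes through the axis, mask voxels
    are clustered into turns (axial, then radial gap clustering with threshold
    ``turn_gap_mm``), ordered from the basal turn up to unwrap the angle.  The
    wall points are bias-corrected edge-set centroids.  Raises a coverage
    error when fewer than 10% of the half-planes intersect the mask.
    """
    if n_steps_per_turn < 4:
        raise ParameterError("n_steps_per_turn must be >= 4")
    vox = np.argwhere(osl_mask.astype_bool())
    if vox.shape[0] == 0:
        raise CoverageError("mask is empty; nothing to contour")
    pts = osl_mask.world_coords(vox)
    rho, phi, h = frame.cylindrical(pts)
    vs = osl_mask.voxel_size_um / 1000.0

    step = 2.0 * np.pi / n_steps_per_turn
    bins = np.minimum((phi / step).astype(int), n_steps_per_turn - 1)
    covered = np.unique(bins)
    if covered.size < 0.1 * n_steps_per_turn:
        raise CoverageError(
            f"mask intersects only {covered.size}/{n_steps_per_turn} angular half-planes"
        )

    samples: list[tuple[float, np.ndarray, np.ndarray, float]] = []
    for b in covered:
        sel = np.flatnonzero(bins == b)
        clusters: list[np.ndarray] = []
        for h_cl in _gap_split(h[sel], turn_gap_mm):
            for r_cl in _gap_split(rho[sel[h_cl]], turn_gap_mm):
                clusters.append(sel[h_cl[r_cl]])
        clusters = [cl for cl in clusters if cl.size >= min_cluster_voxels]
        # order basal turn first: ascending axial, then radial, position
        clusters.sort(key=lambda cl: (float(np.mean(h[cl])), float(np.mean(rho[cl]))))
        for k, cl in enumerate(clusters):
            angle = np.degrees((b + 0.5) * step) + 360.0 * k
            rho_in, idx_in = _edge_radius(rho[cl], vox[cl], pts[cl], frame, vs, inner=True)
            rho_out, idx_out = _edge_radius(rho[cl], vox[cl], pts[cl], frame, vs, inner=False)
            inner = _wall_point(pts[cl[idx_in]], frame, rho_in)
            outer = _wall_point(pts[cl[idx_out]], frame, rho_out)
            span = float(np.ptp(phi[cl])) / step
            samples.append((angle, inner, outer, span))

    samples.sort(key=lambda t: t[0])
    # the spiral's free ends occupy their angular bin only partially; such a
    # section is not a full radial cross-section, so drop it
    while len(samples) > 2 and samples[0][3] < 0.7:
        samples.pop(0)
    while len(samples) > 2 and samples[-1][3] < 0.7:
        samples.pop()
    angles = np.array([s[0] for s in samples])
    # duplicate angles can only come from mis-split clusters; keep the first
    keep = np.concatenate([[True], np.diff(angles) > 0])
    return WallContours(
        angles_deg=angles[keep],
        inner_pts_mm=np.array([s[1] for s in samples])[keep],
        outer_pts_mm=np.array([s[2] for s in samples])[keep],
    )


def _edge_radius(
    r: np.ndarray,
    ivox: np.ndarray,
    pts: np.ndarray,
    frame: ReferenceFrame,
    vs: float,
    inner: bool,
) -> tuple[float, np.ndarray]:
    """Sub-voxel radial edge position of one angular cluster.

    The one-voxel-thick extreme shell is reduced to one voxel per lattice
    sampling column (the two lattice axes transverse to the local radial
    direction index the columns).  Each such extreme centre sits inside the
    solid at a depth uniform in [0, vs*c) along the radial direction, where c
    is the cosine between the radial direction and the dominant lattice axis,
    so the column-mean shifted outward by vs*c/2 estimates the physical edge
    with sub-voxel accuracy.  Returns the radius estimate and the indices of
    the edge-set voxels.
    """
    # local radial direction in world coordinates (lattice axes = world axes)
    centroid = pts.mean(axis=0)
    v = centroid - frame.center_mm
    radial = v - (v @ frame.axis_dir) * frame.axis_dir
    d = radial / max(np.linalg.norm(radial), _EPS)
    d_zyx = d[::-1]  # ivox columns are (z, y, x)
    axis = int(np.argmax(np.abs(d_zyx)))
    c = float(np.abs(d_zyx[axis]))
    trans = [a for a in range(3) if a != axis]

    shell = r <= r.min() + vs if inner else r >= r.max() - vs
    idx_shell = np.flatnonzero(shell)
    key = ivox[idx_shell, trans[0]].astype(np.int64) * 1_000_003 + ivox[idx_shell, trans[1]]
    order = np.argsort(key, kind="stable")
    _, start = np.unique(key[order], return_index=True)
    bounds = np.append(start, len(order))
    edge = []
    r_shell = r[idx_shell]
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        grp = order[s0:s1]
        edge.append(grp[np.argmin(r_shell[grp])] if inner else grp[np.argmax(r_shell[grp])])
    edge = idx_shell[np.asarray(edge)]
    shift = -0.5 * vs * c if inner else 0.5 * vs * c
    return float(np.mean(r[edge]) + shift), edge


def _wall_point(edge_pts: np.ndarray, frame: ReferenceFrame, rho_target: float) -> np.ndarray:
    """Edge-set centroid repositioned radially to the bias-corrected radius."""
    centroid = edge_pts.mean(axis=0)
    v = centroid - frame.center_mm
    radial = v - (v @ frame.axis_dir) * frame.axis_dir
    n = np.linalg.norm(radial)
    if n < _EPS:
        return centroid
    return centroid + (rho_target / n - 1.0) * radial


def smooth_contours(contours: WallContours, max_dev_mm: float) -> WallContours:
    """Local polynomial (Savitzky-Golay) regularization of both wall contours.

    Averages out the per-section half-voxel sampling noise of the raw wall
    points while deviating from them by at most ``max_dev_mm`` (typically one
    voxel); the window shrinks until that bound holds, so genuinely sharp
    contour variation is preserved.
    """
    n = len(contours.angles_deg)
    if n < 8:
        return contours

    def smooth(pts: np.ndarray) -> np.ndarray:
        window = min(15, (n // 2) * 2 - 1)
        while window >= 5:
            out = savgol_filter(pts, window, polyorder=2, axis=0, mode="interp")
            if np.max(np.linalg.norm(out - pts, axis=1)) <= max_dev_mm:
                return out
            window -= 4
        return pts

    return WallContours(
        contours.angles_deg.copy(),
        smooth(contours.inner_pts_mm),
        smooth(contours.outer_pts_mm),
    )


def width_profile(contours: WallContours) -> WidthProfile:
    """OSL width per unwrapped angle: distance between paired wall points.

    Zero-width (degenerate) samples are kept and exposed through
    :attr:`WidthProfile.degenerate`.
    """
    width = np.linalg.norm(contours.outer_pts_mm - contours.inner_pts_mm, axis=1)
    midline = 0.5 * (contours.inner_pts_mm + contours.outer_pts_mm)
    return WidthProfile(
        angles_deg=contours.angles_deg.copy(),
        width_mm=width,
        points_mm=midline,
    )
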