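"""Volume, mesh and tabular I/O.

Volumes are held as ``(z, y, x)``-indexed arrays with an isotropic physical
voxel size in micrometres and a world origin in millimetres.  On disk they are
multi-page TIFF stacks (pages ordered along z ascending, geometry stored in
the TIFF image description as JSON) or NIfTI-1 (spatial units forced to mm
internally).  Meshes are STL, binary preferred.  Tabular reports are CSV with
'.' decimal, UTF-8 and an always-present header row.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import trimesh

from .errors import FormatError, GeometryError

__all__ = [
    "VoxelVolume",
    "LabelMask",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "write_report",
]


@dataclasses.dataclass
class VoxelVolume:
    """A 3D grayscale scalar grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres (must be positive).
    origin_mm : ndarray, shape (3,)
        World position (x, y, z) in mm of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_um: float
    origin_mm: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be rank 3, got rank {self.data.ndim}")
        if not self.voxel_size_um > 0:
            raise FormatError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.origin_mm.shape != (3,):
            raise FormatError("origin_mm must be a 3-vector")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "VoxelVolume | LabelMask") -> bool:
        return (
            self.data.shape == other.data.shape
            and abs(self.voxel_size_um - other.voxel_size_um) < 1e-9
            and bool(np.allclose(self.origin_mm, other.origin_mm))
        )

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """Map (z, y, x) voxel indices -> (x, y, z) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        xyz = idx[:, ::-1] * self.voxel_size_mm + self.origin_mm
        return xyz


@dataclasses.dataclass
class LabelMask(VoxelVolume):
    """A 3D integer label grid aligned to a source :class:`VoxelVolume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer) and self.data.dtype != bool:
            raise FormatError(f"label mask must have integer dtype, got {self.data.dtype}")

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)


_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in _TIFF_SUFFIXES


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF stack or NIfTI-1 file.

    The format is chosen from the extension (.tif/.tiff or .nii/.nii.gz).
    Round trips preserve the data bitwise and the voxel size to 1e-9 µm.
    """
    path = Path(path)
    if _is_tiff(path):
        meta = {
            "voxel_size_um": volume.voxel_size_um,
            "origin_mm": list(map(float, volume.origin_mm)),
        }
        tifffile.imwrite(
            path, volume.data, photometric="minisblack", description=json.dumps(meta)
        )
    elif _is_nifti(path):
        vs_mm = volume.voxel_size_mm
        affine = np.diag([vs_mm, vs_mm, vs_mm, 1.0])
        affine[:3, 3] = volume.origin_mm
        img = nib.Nifti1Image(np.transpose(volume.data, (2, 1, 0)), affine)
        img.header.set_xyzt_units(xyz="mm")
        # NIfTI-1 affine fields are float32; stash the exact voxel size in the
        # free-text header field so round trips keep full precision.
        img.header["descrip"] = f"voxel_size_um={volume.voxel_size_um!r}".encode()
        nib.save(img, path)
    else:
        raise FormatError(f"unknown volume extension: {path.name} (use .tif/.tiff/.nii/.nii.gz)")


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a TIFF stack or NIfTI-1 file into a :class:`VoxelVolume`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_tiff(path):
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise FormatError(f"TIFF stack has rank {data.ndim}, expected 3")
        voxel_size_um = 1.0
        origin = np.zeros(3)
        try:
            meta = json.loads(desc)
            voxel_size_um = float(meta["voxel_size_um"])
            origin = np.asarray(meta.get("origin_mm", origin), dtype=float)
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            pass
        return VoxelVolume(data, voxel_size_um, origin)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        voxel_size_um = float(zooms[0]) * 1000.0
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
        m = re.match(r"voxel_size_um=([0-9eE+.\-]+)", descrip)
        if m:
            voxel_size_um = float(m.group(1))
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return VoxelVolume(data, voxel_size_um, origin)
    raise FormatError(f"unknown volume extension: {path.name}")


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as an 8-bit TIFF (or NIfTI)."""
    data = mask.data
    if data.dtype != np.uint8 and np.max(data, initial=0) <= 255:
        data = data.astype(np.uint8)
    write_volume(VoxelVolume(data, mask.voxel_size_um, mask.origin_mm), path)


def read_mask(path: str | Path) -> LabelMask:
    v = read_volume(path)
    data = v.data
    if not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data).astype(np.int32)
    return LabelMask(data, v.voxel_size_um, v.origin_mm)


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Read a binary or ASCII STL file as a triangle mesh."""
    path = Path(path)
    try:
        mesh = trimesh.load(path, file_type="stl", force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise FormatError(f"cannot read STL mesh from {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path} contains no triangles")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a triangle mesh as binary STL."""
    if mesh is None or len(mesh.faces) == 0:
        raise FormatError("refusing to write an empty mesh")
    if mesh.faces.shape[1] != 3:
        raise FormatError("mesh is not triangulated")
    Path(path).write_bytes(trimesh.exchange.stl.export_stl(mesh))


def write_report(records: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Write a list of records (dataclasses or dicts) as a CSV report.

    The header row is always present; with an empty record list the column
    schema must be supplied via ``columns``.  Returns the DataFrame written.
    """
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, dict):
            rows.append(dict(rec))
        else:
            raise FormatError(f"unsupported record type: {type(rec)!r}")
    if rows:
        df = pd.DataFrame(rows, columns=columns or list(rows[0].keys()))
    else:
        df = pd.DataFrame(columns=list(columns or ()))
    df.to_csv(path, index=False, encoding="utf-8")
    return df


def check_same_geometry(a: VoxelVolume, b: VoxelVolume) -> None:
    if not a.same_geometry(b):
        raise GeometryError(
            f"geometry mismatch: shapes {a.data.shape} vs {b.data.shape}, "
            f"voxel sizes {a.voxel_size_um} vs {b.voxel_size_um} µm"
        )
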