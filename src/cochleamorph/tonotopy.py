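"""Frequency-position mapping and octave-band partitioning of the cochlear spiral.

The characteristic frequency at normalized position ``x`` along the cochlea
follows the Greenwood-form map

    f(x) = A * (10**(a*x) - k)

with ``x`` measured from the apex (x=0 apex, x=1 base) under the default
convention.  The default constants are the human organ-of-Corti values
A = 165.4 Hz, a = 2.1, k = 0.88, giving f(0) ≈ 19.85 Hz and f(1) ≈ 20.68 kHz.
Spiral-ganglion variants of the map are supported by overriding the constants
and, where the map is stated base-first, the ``from_base`` convention (which
substitutes x -> 1 - x).

The spiral is partitioned into octave bands (boundary frequencies doubling),
each band carrying the mean and sample SD of the OSL width over the samples
that fall inside it, and dense inclusions are localized by the band that
contains most of their voxels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError, ParameterError

__all__ = [
    "FrequencyMapParams",
    "Partition",
    "BandStats",
    "position_to_frequency",
    "frequency_to_position",
    "octave_partitions",
    "assign_band",
    "assign_positions",
    "band_stats",
    "localize_inclusion",
]

_CONVENTIONS = ("from_apex", "from_base")


@dataclasses.dataclass(frozen=True)
class FrequencyMapParams:
    """Constants of the Greenwood-form frequency-position function."""

    A_hz: float = 165.4
    a_exp: float = 2.1
    k_off: float = 0.88
    x_convention: str = "from_apex"
    total_length_mm: float = 35.0

    def __post_init__(self) -> None:
        if self.A_hz <= 0 or self.a_exp <= 0:
            raise ParameterError("A_hz and a_exp must be positive")
        if not 0 <= self.k_off < 1:
            raise ParameterError(f"k_off must be in [0, 1), got {self.k_off}")
        if self.x_convention not in _CONVENTIONS:
            raise ParameterError(f"x_convention must be one of {_CONVENTIONS}")
        if self.total_length_mm <= 0:
            raise ParameterError("total_length_mm must be positive")

    @property
    def f_min_hz(self) -> float:
        """Frequency at the apical end of the map."""
        return self.A_hz * (1.0 - self.k_off)

    @property
    def f_max_hz(self) -> float:
        """Frequency at the basal end of the map."""
        return self.A_hz * (10.0 ** self.a_exp - self.k_off)


@dataclasses.dataclass(frozen=True)
class Partition:
    """One tonotopic octave band: frequency bounds and the half-open
    normalized-position interval [x_lo, x_hi) it occupies."""

    band_label: str
    f_lo_hz: float
    f_hi_hz: float
    x_lo: float
    x_hi: float


@dataclasses.dataclass(frozen=True)
class BandStats:
    """Mean and sample SD of the width samples inside one band."""

    band_label: str
    mean_width_mm: float | None
    sd_width_mm: float | None
    n_samples: int


def _x_apex(x, params: FrequencyMapParams):
    """Re-orient x so it counts from the apex, as Greenwood's map expects."""
    x = np.asarray(x, dtype=float)
    return 1.0 - x if params.x_convention == "from_base" else x


def position_to_frequency(x, params: FrequencyMapParams = FrequencyMapParams()):
    """Characteristic frequency (Hz) at normalized position ``x`` in [0, 1]."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > 1):
        raise DomainError(f"position x must lie in [0, 1], got {x}")
    f = params.A_hz * (10.0 ** (params.a_exp * _x_apex(xa, params)) - params.k_off)
    return float(f) if np.isscalar(x) or np.ndim(x) == 0 else f


def frequency_to_position(f_hz, params: FrequencyMapParams = FrequencyMapParams()):
    """Normalized position of frequency ``f_hz``; analytic inverse of
    :func:`position_to_frequency` (round trip below 1e-9)."""
    f = np.asarray(f_hz, dtype=float)
    lo, hi = params.f_min_hz, params.f_max_hz
    if np.any(f < lo * (1 - 1e-12)) or np.any(f > hi * (1 + 1e-12)):
        raise DomainError(f"frequency {f_hz} Hz outside map range [{lo:.3f}, {hi:.3f}] Hz")
    xa = np.log10(f / params.A_hz + params.k_off) / params.a_exp
    xa = np.clip(xa, 0.0, 1.0)
    x = 1.0 - xa if params.x_convention == "from_base" else xa
    return float(x) if np.isscalar(f_hz) or np.ndim(f_hz) == 0 else x


def _format_freq(f_hz: float) -> str:
    if f_hz >= 1000:
        return f"{f_hz / 1000:g} kHz"
    return f"{f_hz:g} Hz"


def octave_partitions(
    params: FrequencyMapParams, f_min_hz: float, f_max_hz: float
) -> list[Partition]:
    """Partition the map range [f_min, f_max] into octave bands.

    Boundaries sit at f_min * 2**j; the last band is clipped at f_max.
    Adjacent bands share their boundary position exactly.
    """
    if not f_min_hz < f_max_hz:
        raise ParameterError(f"need f_min < f_max, got {f_min_hz} >= {f_max_hz}")
    edges = [float(f_min_hz)]
    while edges[-1] * 2.0 < f_max_hz:
        edges.append(edges[-1] * 2.0)
    edges.append(float(f_max_hz))
    bands = []
    for f_lo, f_hi in zip(edges[:-1], edges[1:]):
        x_a, x_b = frequency_to_position(f_lo, params), frequency_to_position(f_hi, params)
        bands.append(
            Partition(
                band_label=f"{_format_freq(f_lo)}-{_format_freq(f_hi)}",
                f_lo_hz=f_lo,
                f_hi_hz=f_hi,
                x_lo=min(x_a, x_b),
                x_hi=max(x_a, x_b),
            )
        )
    bands.sort(key=lambda b: b.x_lo)
    return bands


def assign_band(x: float, partitions: Sequence[Partition]) -> str:
    """Label of the half-open band [x_lo, x_hi) containing ``x``.

    A position exactly on a shared boundary belongs to the band that starts
    there; the top end of the last band is closed so the extreme position is
    assignable.
    """
    parts = sorted(partitions, key=lambda b: b.x_lo)
    los = np.array([b.x_lo for b in parts])
    idx = int(np.searchsorted(los, x, side="right")) - 1
    if idx < 0 or x > parts[-1].x_hi or (idx < len(parts) - 1 and x >= parts[idx].x_hi and x < los[idx + 1]):
        raise DomainError(f"position {x} outside partition coverage")
    if x >= parts[idx].x_hi and idx < len(parts) - 1:
        idx += 1
    return parts[idx].band_label


def assign_positions(profile, convention: str = "from_apex"):
    """Fill a width profile's normalized positions from its midline arc length.

    The profile's samples are ordered base -> apex; ``from_apex`` maps the
    apical end to x = 0, ``from_base`` the basal end.
    Returns the profile (mutated in place).
    """
    if convention not in _CONVENTIONS:
        raise ParameterError(f"convention must be one of {_CONVENTIONS}")
    pts = np.asarray(profile.points_mm, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ParameterError("profile midline has zero length")
    x = s / total if convention == "from_base" else (total - s) / total
    profile.x_norm = x
    return profile


def band_stats(profile, partitions: Sequence[Partition]) -> list[BandStats]:
    """Mean and sample SD of the width samples inside each band.

    Samples whose position falls outside the partition coverage are ignored;
    bands with no samples are reported with n=0 and null statistics.
    """
    parts = sorted(partitions, key=lambda b: b.x_lo)
    x = np.asarray(profile.x_norm, dtype=float)
    w = np.asarray(profile.width_mm, dtype=float)
    los = np.array([b.x_lo for b in parts])
    idx = np.searchsorted(los, x, side="right") - 1
    # boundary values roll up to the band that starts there
    for j in range(len(parts) - 1):
        idx[(idx == j) & (x >= parts[j].x_hi)] = j + 1
    valid = (idx >= 0) & (x <= parts[-1].x_hi + 1e-12)
    out = []
    for j, band in enumerate(parts):
        wj = w[valid & (idx == j)]
        if wj.size == 0:
            out.append(BandStats(band.band_label, None, None, 0))
        else:
            sd = float(np.std(wj, ddof=1)) if wj.size > 1 else 0.0
            out.append(BandStats(band.band_label, float(np.mean(wj)), sd, int(wj.size)))
    return out


def localize_inclusion(
    inclusion_mask,
    frame,
    centerline_mm: np.ndarray,
    partitions: Sequence[Partition],
    convention: str = "from_apex",
) -> list[tuple[str, float]]:
    """Assign an inclusion ("cochleolith") to tonotopic bands by voxel overlap.

    Each inclusion voxel is mapped to its nearest point on the spiral
    centerline (ordered base -> apex), converted to a normalized position and
    binned into the octave partitions.  Returns (band_label, fraction) pairs
    sorted by decreasing fraction; fractions sum to 1.
    """
    if convention not in _CONVENTIONS:
        raise ParameterError(f"convention must be one of {_CONVENTIONS}")
    vox = np.argwhere(inclusion_mask.astype_bool())
    if vox.shape[0] == 0:
        raise ParameterError("inclusion mask is empty")
    pts = inclusion_mask.world_coords(vox)
    centerline_mm = np.asarray(centerline_mm, dtype=float)
    seg = np.linalg.norm(np.diff(centerline_mm, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    _, nearest = cKDTree(centerline_mm).query(pts)
    x = s[nearest] / total if convention == "from_base" else (total - s[nearest]) / total
    parts = sorted(partitions, key=lambda b: b.x_lo)
    x = np.clip(x, parts[0].x_lo, parts[-1].x_hi)
    counts: dict[str, int] = {}
    for xi in x:
        label = assign_band(float(xi), parts)
        counts[label] = counts.get(label, 0) + 1
    n = float(len(x))
    return sorted(((lab, c / n) for lab, c in counts.items()), key=lambda t: -t[1])
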