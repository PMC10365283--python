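"""End-to-end orchestration: volume -> segmentation -> width -> bands -> porosity.

One configuration drives the whole chain and produces a CSV/STL/JSON report
bundle.  All randomness (phantom generation only) is funneled through the
single configured seed, so a config run twice yields a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Any

import numpy as np

from . import io_formats, morphometry, phantom, segmentation, spiral_geometry, tonotopy
from .errors import ParameterError

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("cochleamorph")

BANDS_COLUMNS = [
    "band_label", "f_lo_hz", "f_hi_hz", "x_lo", "x_hi",
    "mean_width_mm", "sd_width_mm", "n_samples",
]
POROSITY_COLUMNS = ["segment_label", "plate", "backend", "Vo_mm3", "Vf_mm3", "p_pct"]
WIDTH_COLUMNS = ["angle_deg", "x_norm", "width_mm"]


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``phantom_spec`` and ``input_volume`` must be set; with a
    real volume the landmark file (centre / helicotrema / basal points in mm)
    is required too.
    """

    phantom_spec: phantom.PhantomSpec | None = None
    input_volume: str | None = None
    landmarks: str | dict | None = None
    threshold_lo: float = 130.0
    threshold_hi: float = float("inf")
    inclusion_threshold_lo: float | None = 220.0
    min_component_voxels: int = 27
    connectivity: int = 26
    n_steps_per_turn: int = 90
    turn_gap_mm: float = 0.5
    freq_params: tonotopy.FrequencyMapParams = dataclasses.field(
        default_factory=tonotopy.FrequencyMapParams
    )
    band_range_hz: tuple[float, float] = (250.0, 16000.0)
    porosity_backend: str = "voxel_closing"
    closing_radius_vox: float = 5.0
    export_stl: bool = False
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if (self.phantom_spec is None) == (self.input_volume is None):
            raise ParameterError(
                "exactly one of phantom_spec and input_volume must be configured"
            )
        if self.input_volume is not None and self.landmarks is None:
            raise ParameterError("an input volume requires a landmarks file")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        spec = d.pop("phantom", None)
        if spec is not None:
            spec = phantom.PhantomSpec(**spec)
        inp = d.pop("input", None)
        volume = landmarks = None
        if inp is not None:
            volume, landmarks = inp.get("volume"), inp.get("landmarks")
        fm = d.pop("frequency_map", None)
        kwargs: dict[str, Any] = {
            "phantom_spec": spec,
            "input_volume": volume,
            "landmarks": landmarks,
        }
        if fm is not None:
            kwargs["freq_params"] = tonotopy.FrequencyMapParams(**fm)
        thr = d.pop("threshold", None)
        if thr is not None:
            kwargs["threshold_lo"] = thr.get("lo", 130.0)
            hi = thr.get("hi")
            kwargs["threshold_hi"] = float("inf") if hi is None else hi
        por = d.pop("porosity", None)
        if por is not None:
            kwargs["porosity_backend"] = por.get("backend", "voxel_closing")
            kwargs["closing_radius_vox"] = por.get("closing_radius_vox", 5.0)
        band = d.pop("band_range_hz", None)
        if band is not None:
            kwargs["band_range_hz"] = tuple(band)
        for key in ("min_component_voxels", "connectivity", "n_steps_per_turn",
                    "turn_gap_mm", "inclusion_threshold_lo", "export_stl",
                    "seed", "verbose"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ParameterError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _load_landmarks(landmarks) -> dict[str, np.ndarray]:
    if isinstance(landmarks, (str, Path)):
        with open(landmarks, encoding="utf-8") as fh:
            landmarks = json.load(fh)
    return {k: np.asarray(v, dtype=float) for k, v in landmarks.items()}


def _round(x, nd=9):
    if x is None:
        return None
    return round(float(x), nd)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run the full analysis chain and write the report bundle to ``out_dir``.

    Outputs: width.csv, bands.csv, porosity.csv, summary.json, osl_mask.tif
    and (optionally) STL meshes of the original and pore-filled plates.
    Returns the summary dict.
    """
    if cfg.verbose and not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(name)s %(levelname)s %(message)s")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        truth = None
        if cfg.phantom_spec is not None:
            spec = dataclasses.replace(cfg.phantom_spec, seed=cfg.seed)
            log.info("generating phantom (seed=%d)", cfg.seed)
            volume, _, truth = phantom.generate_phantom(spec)
            landmarks = truth.landmarks_mm
        else:
            volume = io_formats.read_volume(cfg.input_volume)
            landmarks = _load_landmarks(cfg.landmarks)

        stage = "segmentation"
        rule = segmentation.ThresholdRule(cfg.threshold_lo, cfg.threshold_hi)
        osl = segmentation.threshold_segment(volume, rule)
        osl = segmentation.remove_small_components(
            osl, cfg.min_component_voxels, cfg.connectivity
        )
        io_formats.write_mask(osl, out / "osl_mask.tif")
        log.info("segmented %d bone voxels", int(osl.data.sum(dtype=np.int64)))

        inclusion_mask = None
        if cfg.inclusion_threshold_lo is not None:
            incl = segmentation.threshold_segment(
                volume, segmentation.ThresholdRule(cfg.inclusion_threshold_lo)
            )
            incl = segmentation.remove_small_components(
                incl, cfg.min_component_voxels, cfg.connectivity
            )
            if incl.data.any():
                inclusion_mask = incl
                # subtract with a 2-voxel safety margin so the inclusion's
                # partial-intensity skin does not stay attached to the lamina
                grown = morphometry._ball_dilate(incl.astype_bool(), 2.0)
                osl = segmentation.subtract_labels(
                    osl,
                    io_formats.LabelMask(
                        grown.astype(np.uint8), incl.voxel_size_um, incl.origin_mm
                    ),
                )

        stage = "geometry"
        frame = spiral_geometry.build_reference_frame(
            landmarks["center_mm"], landmarks["helicotrema_mm"], landmarks["basal_mm"]
        )
        contours = spiral_geometry.extract_wall_contours(
            osl, frame, cfg.n_steps_per_turn, cfg.turn_gap_mm
        )
        contours = spiral_geometry.smooth_contours(contours, volume.voxel_size_mm)
        profile = spiral_geometry.width_profile(contours)

        stage = "tonotopy"
        tonotopy.assign_positions(profile, cfg.freq_params.x_convention)
        io_formats.write_report(
            [
                {"angle_deg": a, "x_norm": x, "width_mm": w}
                for a, x, w in zip(profile.angles_deg, profile.x_norm, profile.width_mm)
            ],
            out / "width.csv",
            columns=WIDTH_COLUMNS,
        )
        partitions = tonotopy.octave_partitions(
            cfg.freq_params, cfg.band_range_hz[0], cfg.band_range_hz[1]
        )
        stats = tonotopy.band_stats(profile, partitions)
        band_rows = [
            {
                "band_label": p.band_label, "f_lo_hz": p.f_lo_hz, "f_hi_hz": p.f_hi_hz,
                "x_lo": p.x_lo, "x_hi": p.x_hi, "mean_width_mm": s.mean_width_mm,
                "sd_width_mm": s.sd_width_mm, "n_samples": s.n_samples,
            }
            for p, s in zip(sorted(partitions, key=lambda b: b.x_lo), stats)
        ]
        io_formats.write_report(band_rows, out / "bands.csv", columns=BANDS_COLUMNS)

        inclusion_bands = None
        if inclusion_mask is not None:
            inclusion_bands = tonotopy.localize_inclusion(
                inclusion_mask, frame, profile.points_mm, partitions,
                cfg.freq_params.x_convention,
            )

        stage = "porosity"
        porosity_results = morphometry.segment_porosity(
            osl, frame,
            backend=cfg.porosity_backend,
            closing_radius_vox=cfg.closing_radius_vox,
            n_steps_per_turn=cfg.n_steps_per_turn,
            turn_gap_mm=cfg.turn_gap_mm,
        )
        io_formats.write_report(
            [
                {
                    "segment_label": r.segment_label, "plate": r.plate,
                    "backend": r.backend, "Vo_mm3": r.Vo_mm3, "Vf_mm3": r.Vf_mm3,
                    "p_pct": r.p_pct,
                }
                for r in porosity_results
            ],
            out / "porosity.csv",
            columns=POROSITY_COLUMNS,
        )
        if cfg.export_stl:
            tymp, vest = morphometry.split_plates(
                osl, frame, cfg.n_steps_per_turn, cfg.turn_gap_mm
            )
            for name, mask in (("tympanic", tymp), ("vestibular", vest)):
                mesh = morphometry.mask_to_mesh(mask)
                io_formats.write_mesh(mesh, out / f"{name}_plate.stl")
                filled = morphometry.fill_pores_voxel(mask, cfg.closing_radius_vox)
                io_formats.write_mesh(
                    morphometry.mask_to_mesh(filled), out / f"{name}_plate_filled.stl"
                )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    summary = {
        "seed": cfg.seed,
        "n_width_samples": int(len(profile.width_mm)),
        "width_mm": {
            "min": _round(np.min(profile.width_mm)),
            "max": _round(np.max(profile.width_mm)),
            "mean": _round(np.mean(profile.width_mm)),
        },
        "bands": [
            {k: (_round(v) if isinstance(v, float) else v) for k, v in row.items()}
            for row in band_rows
        ],
        "porosity": [
            {
                "segment": r.segment_label, "plate": r.plate, "backend": r.backend,
                "Vo_mm3": _round(r.Vo_mm3), "Vf_mm3": _round(r.Vf_mm3),
                "p_pct": _round(r.p_pct),
            }
            for r in porosity_results
        ],
        "inclusion_bands": (
            None if inclusion_bands is None
            else [{"band_label": b, "fraction": _round(f)} for b, f in inclusion_bands]
        ),
    }
    if truth is not None:
        summary["phantom_truth"] = {
            "true_porosity_pct": {k: _round(v) for k, v in truth.true_porosity_pct.items()},
            "total_arclength_mm": _round(truth.total_arclength_mm),
            "inclusion_x_norm": _round(truth.inclusion_x_norm),
        }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
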