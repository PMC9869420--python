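"""End-to-end analysis: sweep bundle in, phase geometries and mechanics out.

Stage order: segmentation -> cardiac timing -> 3D geometry (centerline,
polar grid, envelopes, phase refit) -> mechanics, with an optional
CT-comparison stage when a reference geometry is supplied.  The geometry
and mechanics stages are also callable directly on per-frame contours
(``analyze_contours``), which is how phantom ground truth can be pushed
through the pipeline with the imaging stages bypassed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cardiac, geometry, io, mechanics, registration, segmentation

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "analyze_contours", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved knobs of one pipeline run; YAML round-trips losslessly."""

    vessel_class: str = "healthy"               # or "aaa"
    init_ellipse: tuple = (0.0, 0.0, 10.0, 10.0, 0.0)  # (cx, cy, a, b, phi)
    physio_range_hz: tuple = cardiac.PHYSIO_RANGE_HZ
    n_rays: int = 64
    n_angles: int = 72
    esf_iterations: int = 10
    esf_dt: float = 0.2
    area_pixel_spacing: float = 0.1             # mm, mask rasterization
    slice_spacing: float = 0.2                  # mm, CT comparison
    mask_pixel: float = 0.2                     # mm, CT comparison masks
    icp_iterations: int = 30
    pressure_correction: str = "multiplicative"
    seed: int = 0

    def __post_init__(self):
        if self.vessel_class not in segmentation.BAND_THICKNESS_MM:
            raise ValueError(f"vessel_class must be healthy or aaa")
        if not (0 < self.esf_dt <= 0.25):
            raise ValueError("esf_dt must lie in (0, 0.25]")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["init_ellipse"] = list(self.init_ellipse)
        d["physio_range_hz"] = list(self.physio_range_hz)
        return d

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["init_ellipse"] = tuple(raw["init_ellipse"])
        raw["physio_range_hz"] = tuple(raw["physio_range_hz"])
        return PipelineConfig(**raw)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    contours: list
    area_signal: cardiac.AreaTimeSignal
    heart_frequency: cardiac.HeartFrequencyRange
    ed_frame_indices: np.ndarray
    centerline: geometry.Centerline3D
    grid: geometry.PolarGrid
    envelopes: geometry.EnvelopeSet
    phases: dict            # {"ED"|"ES"|"MAP": PhaseGeometry}
    global_mechanics: mechanics.GlobalMechanics | None = None
    slice_mechanics: list = field(default_factory=list)
    comparison: registration.ComparisonReport | None = None


def analyze_contours(
    contours_inplane: list[np.ndarray],
    poses: list[geometry.ProbePose],
    times: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    pulse_pressure: float | None = None,
) -> PipelineResult:
    """Cardiac timing + 3D geometry (+ mechanics) from per-frame contours.

    ``contours_inplane`` are closed polygons in each frame's image plane
    (mm).  An ellipse is fitted per contour for the area-time signal and
    the ED centre points; the polar grid uses the raw contour polygons.
    """
    times = np.asarray(times, dtype=float)
    ellipses = [segmentation.fit_ellipse(c) for c in contours_inplane]
    signal = cardiac.lumen_area_series(
        ellipses, times, pixel_spacing=config.area_pixel_spacing
    )
    hf = cardiac.detect_heart_frequency(signal, physio_range=tuple(config.physio_range_hz))
    ed_idx = cardiac.detect_ed_frames(signal, hf)
    log.info("heart frequency %.3f Hz, %d ED frames", hf.f_peak, len(ed_idx))

    ed_centers = np.array(
        [poses[i].to_world(ellipses[i].center)[0] for i in ed_idx]
    )
    centerline = geometry.build_centerline(ed_centers)
    origins_w, origins_p, fallback = geometry.frame_origins(
        centerline, poses, first_guess_world=poses[ed_idx[0]].to_world(
            ellipses[ed_idx[0]].center
        )[0],
    )
    if fallback.any():
        log.warning("%d frames used projected centerline origins", int(fallback.sum()))
    grid = geometry.build_polar_grid(
        contours_inplane, origins_p, origins_w, times, poses, n_angles=config.n_angles
    )
    envelopes = geometry.envelope_radii(grid, hf)
    phases = geometry.refit_phase_contours(grid, envelopes)

    result = PipelineResult(
        contours=ellipses,
        area_signal=signal,
        heart_frequency=hf,
        ed_frame_indices=ed_idx,
        centerline=centerline,
        grid=grid,
        envelopes=envelopes,
        phases=phases,
    )
    if pulse_pressure is not None:
        result.global_mechanics = mechanics.global_mechanics(
            phases["ED"], phases["ES"], pulse_pressure
        )
        ed_ell = phases["ED"].ellipses
        es_ell = phases["ES"].ellipses
        result.slice_mechanics = [
            mechanics.local_mechanics(
                e_ed, e_es, pulse_pressure, pixel_spacing=config.area_pixel_spacing
            )
            for e_ed, e_es in zip(ed_ell, es_ell)
        ]
    return result


def run_pipeline(
    bundle_dir,
    config: PipelineConfig = PipelineConfig(),
    pressures: tuple[float, float] | None = None,
    out_dir=None,
    reference: geometry.PhaseGeometry | None = None,
) -> PipelineResult:
    """Full pipeline on a sweep bundle.

    ``pressures`` is the brachial (diastolic, systolic) pair in mmHg; when
    given, the corrected pulse pressure drives the mechanics stage.  When a
    reference geometry is supplied the MAP geometry is registered to it and
    compared slice-wise.
    """
    frames, poses, _meta = io.load_sweep(bundle_dir)
    times = np.array([f.timestamp for f in frames])
    init = segmentation.Ellipse(*config.init_ellipse)
    ellipses = segmentation.segment_sweep(
        frames,
        init,
        vessel_class=config.vessel_class,
        n_rays=config.n_rays,
        esf_iterations=config.esf_iterations,
        esf_dt=config.esf_dt,
    )
    contours = [e.sample(128) for e in ellipses]

    pulse_pressure = None
    pressure = None
    if pressures is not None:
        pressure = mechanics.correct_brachial_pressure(
            *pressures, variant=config.pressure_correction
        )
        pulse_pressure = pressure.pulse_pressure

    result = analyze_contours(
        contours, poses, times, config=config, pulse_pressure=pulse_pressure
    )
    result.contours = ellipses  # keep the tracked (not refitted) ellipses

    if reference is not None:
        result.comparison = registration.compare_geometries(
            result.phases["MAP"],
            reference,
            spacing=config.slice_spacing,
            pixel=config.mask_pixel,
            n_iter=config.icp_iterations,
        )
    if out_dir is not None:
        _write_results(Path(out_dir), result, config, pressure)
    return result


def _write_results(out_dir: Path, result: PipelineResult, config: PipelineConfig, pressure):
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    io.save_contours(out_dir / "contours.csv", result.contours, result.area_signal.times)
    for phase, geom in result.phases.items():
        rows = []
        for f_idx in range(geom.n_contours):
            for a_idx in range(len(geom.angles)):
                x, y, z = geom.contours_world[f_idx, a_idx]
                rows.append((f_idx, a_idx, x, y, z))
        np.savetxt(
            out_dir / f"phase_{phase.lower()}_contours.csv",
            np.asarray(rows),
            delimiter=",",
            header="frame,angle_index,x_mm,y_mm,z_mm",
            comments="",
        )
        geom.to_mesh().export(out_dir / f"phase_{phase.lower()}.ply")
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "heart_frequency_hz": result.heart_frequency.f_peak,
        "n_ed_frames": int(len(result.ed_frame_indices)),
    }
    if pressure is not None:
        report["pulse_pressure_kpa"] = pressure.pulse_pressure
    if result.global_mechanics is not None:
        gm = result.global_mechanics
        report["global"] = {
            "v_ed_ml": gm.v_ed, "v_es_ml": gm.v_es,
            "c_global_ml_kpa": gm.c_global, "d_global_per_kpa": gm.d_global,
        }
    if result.slice_mechanics:
        import pandas as pd

        pd.DataFrame([dataclasses.asdict(s) for s in result.slice_mechanics]).to_csv(
            out_dir / "slice_mechanics.csv", index=False
        )
    if result.comparison is not None:
        report["comparison"] = {
            "median_si": result.comparison.median_si,
            "iqr_si": list(result.comparison.iqr_si),
            "median_hd_mm": result.comparison.median_hd,
            "iqr_hd_mm": list(result.comparison.iqr_hd),
        }
    (out_dir / "mechanics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    config.to_yaml(out_dir / "config.yaml")
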