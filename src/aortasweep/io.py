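"""Sweep-bundle and results I/O.

A sweep bundle is a directory holding one acquisition:

    frames/NNNN.png   16-bit grayscale frames
    poses.csv         frame_index, t_s, x_mm, y_mm, z_mm, qw, qx, qy, qz
    meta.yaml         pixel spacing, image size, sample rate, spec echo
    truth.json        optional phantom ground truth (light form)

Result directories carry contour CSVs, phase meshes (PLY), a mechanics
report (CSV + JSON) and a run log that records the resolved configuration
and seed, so a rerun with the same inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import ProbePose
from .phantom import GroundTruth, PhantomSpec, TrackedFrame
from .segmentation import BModeFrame, Ellipse

__all__ = ["save_sweep", "load_sweep", "save_contours", "load_contours"]

_PNG_SCALE = 65535.0
_PNG_MAX_INTENSITY = 2.0  # float intensities are clipped to [0, 2] on write


def save_sweep(
    directory,
    frames: list[TrackedFrame],
    truth: GroundTruth | None = None,
    spec: PhantomSpec | None = None,
) -> Path:
    """Write a sweep bundle; returns the bundle directory."""
    directory = Path(directory)
    (directory / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    for f in frames:
        scaled = np.clip(f.image / _PNG_MAX_INTENSITY, 0.0, 1.0)
        iio.imwrite(
            directory / "frames" / f"{f.frame_index:04d}.png",
            (scaled * _PNG_SCALE).astype(np.uint16),
        )
        qw, qx, qy, qz = f.pose.quaternion
        x, y, z = f.pose.translation
        rows.append(
            dict(frame_index=f.frame_index, t_s=f.timestamp, x_mm=x, y_mm=y, z_mm=z,
                 qw=qw, qx=qx, qy=qy, qz=qz)
        )
    pd.DataFrame(rows).to_csv(directory / "poses.csv", index=False)
    meta = {
        "pixel_spacing_mm": float(frames[0].pixel_spacing),
        "image_size": [int(s) for s in frames[0].image.shape],
        "intensity_max": _PNG_MAX_INTENSITY,
    }
    if spec is not None:
        echo = dataclasses.asdict(spec)
        echo["centerline_control_points"] = np.asarray(
            spec.centerline_control_points, dtype=float
        ).tolist()
        for key in ("base_radius", "distension"):
            if callable(echo[key]):
                echo[key] = "<callable>"
        meta["spec"] = echo
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    if truth is not None:
        payload = {
            "times_s": truth.times.tolist(),
            "arclengths_mm": truth.arclengths.tolist(),
            "radii_mm": truth.radii.tolist(),
            "radii_ed_mm": truth.radii_ed.tolist(),
            "radii_es_mm": truth.radii_es.tolist(),
            "heart_frequency_hz": truth.heart_frequency,
            "ed_frame_indices": truth.ed_frame_indices.tolist(),
            "d_true_per_kpa": truth.d_true.tolist(),
            "v_ed_ml": truth.v_ed,
            "v_es_ml": truth.v_es,
            "pulse_pressure_kpa": truth.pulse_pressure,
        }
        (directory / "truth.json").write_text(json.dumps(payload))
    return directory


def load_sweep(directory) -> tuple[list[BModeFrame], list[ProbePose], dict]:
    """Read a sweep bundle into B-mode frames, poses and metadata."""
    directory = Path(directory)
    with open(directory / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    spacing = float(meta["pixel_spacing_mm"])
    intensity_max = float(meta.get("intensity_max", 1.0))
    poses_df = pd.read_csv(directory / "poses.csv").sort_values("frame_index")
    frames, poses = [], []
    for _, row in poses_df.iterrows():
        idx = int(row.frame_index)
        img = iio.imread(directory / "frames" / f"{idx:04d}.png").astype(float)
        img = img / _PNG_SCALE * intensity_max
        frames.append(
            BModeFrame(img, pixel_spacing=spacing, frame_index=idx, timestamp=float(row.t_s))
        )
        poses.append(
            ProbePose(
                translation=[row.x_mm, row.y_mm, row.z_mm],
                quaternion=np.array([row.qw, row.qx, row.qy, row.qz])
                / np.linalg.norm([row.qw, row.qx, row.qy, row.qz]),
                timestamp=float(row.t_s),
            )
        )
    if (directory / "truth.json").exists():
        meta["truth"] = json.loads((directory / "truth.json").read_text())
    return frames, poses, meta


def save_contours(path, contours: list[Ellipse], times) -> Path:
    """Write per-frame ellipse parameters to CSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame_index": np.arange(len(contours)),
            "t_s": np.asarray(times, dtype=float),
            "cx_mm": [e.cx for e in contours],
            "cy_mm": [e.cy for e in contours],
            "a_mm": [e.a for e in contours],
            "b_mm": [e.b for e in contours],
            "phi_rad": [e.phi for e in contours],
        }
    )
    df.to_csv(path, index=False)
    return path


def load_contours(path) -> tuple[list[Ellipse], np.ndarray]:
    df = pd.read_csv(path)
    contours = [
        Ellipse(r.cx_mm, r.cy_mm, r.a_mm, r.b_mm, r.phi_rad) for _, r in df.iterrows()
    ]
    return contours, df.t_s.to_numpy()
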