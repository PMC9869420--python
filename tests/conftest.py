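"""Shared fixtures: synthetic sweeps generated at test time (no stored data)."""

import numpy as np
import pytest

from aortasweep.phantom import PhantomSpec, gaussian_bulge_profile, generate_sweep
from aortasweep.pipeline import PipelineConfig, analyze_contours
from aortasweep.segmentation import BModeFrame, Ellipse, segment_sweep


def clean_bulge_spec(**overrides) -> PhantomSpec:
    """Noise-free aneurysm-like sweep: slow probe, several beats per cm."""
    defaults = dict(
        base_radius=gaussian_bulge_profile(8.0, 12.0, 15.0, 8.0),
        distension=0.10,
        heart_rate=72.0,
        probe_speed=2.5,
        sweep_duration=12.0,
        speckle_sigma=0.0,
        tracker_jitter_mm=0.0,
        tracker_jitter_deg=0.0,
        seed=1,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def clean_sweep():
    """(spec, frames, truth) for the clean bulge phantom."""
    spec = clean_bulge_spec()
    frames, truth = generate_sweep(spec)
    return spec, frames, truth


@pytest.fixture(scope="session")
def segmented_sweep(clean_sweep):
    """Star-Kalman contours tracked through the clean sweep images."""
    spec, frames, truth = clean_sweep
    bmode = [
        BModeFrame(f.image, f.pixel_spacing, f.frame_index, f.timestamp) for f in frames
    ]
    init = Ellipse(0.0, 0.0, truth.radii[0], truth.radii[0], 0.0)
    return segment_sweep(bmode, init, vessel_class="aaa")


@pytest.fixture(scope="session")
def pipeline_result(clean_sweep, segmented_sweep):
    """Full analysis of the segmented clean sweep, with mechanics."""
    spec, frames, truth = clean_sweep
    polygons = [e.sample(128) for e in segmented_sweep]
    return analyze_contours(
        polygons,
        [f.pose for f in frames],
        truth.times,
        config=PipelineConfig(vessel_class="aaa"),
        pulse_pressure=truth.pulse_pressure,
    )


@pytest.fixture(scope="session")
def truth_roundtrip_result(clean_sweep):
    """Analysis of the exact ground-truth contours (imaging stages bypassed)."""
    spec, frames, truth = clean_sweep
    return analyze_contours(
        list(truth.contours_inplane),
        [f.pose for f in frames],
        truth.times,
        pulse_pressure=truth.pulse_pressure,
    )
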