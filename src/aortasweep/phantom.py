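"""Synthetic tracked sweeps of a pulsating vessel with analytic ground truth.

The phantom emulates a freehand acquisition: a virtual probe travels along a
3D vessel centerline at constant speed while the vessel wall pulsates with
the cardiac cycle.  Each frame is a 2D cross-sectional image taken in the
plane orthogonal to the local vessel axis, together with the probe pose
(position + orientation quaternion) and a timestamp at a fixed sampling
rate.  The generating radii, cardiac phase and distensibility are stored as
exact ground truth so every downstream stage can be validated without real
data.

The local radius is r(s, t) = r0(s) * (1 + eps(s) * w(t)) with w in [0, 1],
w = 0 at end diastole and w = 1 at end systole.  The true local
distensibility then follows in closed form:
D(s) = ((1 + eps(s))**2 - 1) / dP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import ProbePose

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "TrackedFrame",
    "PhantomValidationError",
    "gaussian_bulge_profile",
    "generate_sweep",
    "render_frame",
]


class PhantomValidationError(ValueError):
    """A PhantomSpec field violates its documented range."""


def _as_profile(value) -> Callable[[np.ndarray], np.ndarray]:
    """Lift a scalar, (s, v) table, or callable to a profile function of s."""
    if callable(value):
        return lambda s: np.asarray(value(np.asarray(s, dtype=float)), dtype=float)
    if np.isscalar(value):
        v = float(value)
        return lambda s: np.full_like(np.asarray(s, dtype=float), v)
    knots, vals = (np.asarray(a, dtype=float) for a in value)
    return lambda s: np.interp(np.asarray(s, dtype=float), knots, vals)


def gaussian_bulge_profile(
    r_base: float, r_max: float, s0: float, sigma: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Aneurysm-like radius profile: a Gaussian bulge on a constant baseline."""
    return lambda s: r_base + (r_max - r_base) * np.exp(
        -((np.asarray(s, dtype=float) - s0) ** 2) / (2 * sigma**2)
    )


@dataclass(frozen=True)
class TrackedFrame:
    """One acquired image with its probe pose -- the acquisition atom."""

    image: np.ndarray
    pose: ProbePose
    pixel_spacing: float
    frame_index: int
    timestamp: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a simulated acquisition.

    Lengths in mm, times in s, pressures in kPa, angles in degrees where
    noted.  ``base_radius`` and ``distension`` accept a scalar, a
    ``(s_knots, values)`` table, or a callable of arclength s.
    """

    centerline_control_points: Sequence = ((0.0, 0.0, 0.0), (0.0, 100.0, 0.0))
    base_radius: object = 10.0          # r0(s), mm
    distension: object = 0.10           # eps(s), fractional ED->ES amplitude
    heart_rate: float = 72.0            # beats/min
    waveform_shape: str = "raised-cosine"  # or "skewed-systolic"
    probe_speed: float = 2.5            # mm/s along the centerline
    sweep_duration: float = 12.0        # s
    sample_rate: float = 25.0           # Hz
    pixel_spacing: float = 0.35         # mm/pixel
    image_size: int = 128               # pixels (square)
    wall_thickness: float = 2.0         # bright wall band, mm
    lumen_intensity: float = 0.12
    wall_intensity: float = 0.85
    background_intensity: float = 0.45
    lateral_attenuation: float = 0.0    # 0..1 wall-contrast loss in lateral sectors
    speckle_sigma: float = 0.2          # multiplicative noise SD
    tracker_jitter_mm: float = 0.5      # positional jitter SD
    tracker_jitter_deg: float = 0.5     # angular jitter SD
    ed_pressure: float = 9.0            # kPa
    es_pressure: float = 17.0           # kPa
    seed: int = 0
    n_contour_points: int = 120

    def __post_init__(self):
        if not (40.0 <= self.heart_rate <= 120.0):
            raise PhantomValidationError("heart_rate must lie in 40-120 beats/min")
        if self.sample_rate * self.sweep_duration < 2:
            raise PhantomValidationError(
                "sample_rate * sweep_duration must cover at least 2 frames"
            )
        if self.es_pressure <= self.ed_pressure:
            raise PhantomValidationError("es_pressure must exceed ed_pressure")
        if self.probe_speed < 0:
            raise PhantomValidationError("probe_speed must be non-negative")
        if self.waveform_shape not in ("raised-cosine", "skewed-systolic"):
            raise PhantomValidationError(
                f"waveform_shape unknown: {self.waveform_shape!r}"
            )
        s_check = np.linspace(0.0, self.probe_speed * self.sweep_duration + 1e-9, 64)
        if np.any(self.radius_profile(s_check) <= 0):
            raise PhantomValidationError("base_radius must be positive everywhere")
        if np.any(self.distension_profile(s_check) < 0):
            raise PhantomValidationError("distension must be non-negative everywhere")

    @property
    def radius_profile(self) -> Callable[[np.ndarray], np.ndarray]:
        return _as_profile(self.base_radius)

    @property
    def distension_profile(self) -> Callable[[np.ndarray], np.ndarray]:
        return _as_profile(self.distension)

    @property
    def pulse_pressure(self) -> float:
        return self.es_pressure - self.ed_pressure

    @property
    def heart_frequency(self) -> float:
        return self.heart_rate / 60.0

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Cardiac modulation w(t) in [0, 1]; 0 at ED instants, 1 at ES."""
        phase = np.mod(np.asarray(t, dtype=float) * self.heart_frequency, 1.0)
        if self.waveform_shape == "raised-cosine":
            return 0.5 - 0.5 * np.cos(2 * np.pi * phase)
        # skewed systole: faster upstroke, slower relaxation
        return 0.5 - 0.5 * np.cos(2 * np.pi * phase**0.65)

    def true_distensibility(self, s) -> np.ndarray:
        eps = self.distension_profile(s)
        return ((1.0 + eps) ** 2 - 1.0) / self.pulse_pressure


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating quantities of a simulated sweep."""

    times: np.ndarray                  # (F,)
    arclengths: np.ndarray             # probe arclength s per frame, mm
    radii: np.ndarray                  # instantaneous true radius per frame, mm
    radii_ed: np.ndarray               # r0(s) per frame
    radii_es: np.ndarray               # r0(s)*(1+eps) per frame
    contours_inplane: np.ndarray       # (F, P, 2) true interface, mm
    contours_world: np.ndarray         # (F, P, 3) via the noise-free poses
    heart_frequency: float             # Hz
    ed_frame_indices: np.ndarray
    d_true: np.ndarray                 # local distensibility per frame, 1/kPa
    v_ed: float                        # ml, over the swept extent
    v_es: float
    pulse_pressure: float              # kPa

    @property
    def d_global_true(self) -> float:
        return (self.v_es - self.v_ed) / (self.v_ed * self.pulse_pressure)


def _centerline_interpolator(control_points: np.ndarray):
    """Arclength-parameterized position and tangent along the control polyline."""
    cp = np.asarray(control_points, dtype=float)
    if cp.ndim != 2 or cp.shape[1] != 3 or cp.shape[0] < 2:
        raise PhantomValidationError(
            "centerline_control_points must be >= 2 points in 3D"
        )
    # densify so arclength parameterization is accurate even for curved paths
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
    if t[-1] <= 0:
        raise PhantomValidationError("centerline_control_points are degenerate")
    dense_t = np.linspace(0.0, t[-1], max(4 * len(cp), 400))
    dense = np.column_stack([np.interp(dense_t, t, cp[:, k]) for k in range(3)])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]

    def position(si: float) -> np.ndarray:
        si = min(max(si, 0.0), total)
        return np.array([np.interp(si, s, dense[:, k]) for k in range(3)])

    def tangent(si: float) -> np.ndarray:
        h = max(total * 1e-4, 1e-6)
        d = position(min(si + h, total)) - position(max(si - h, 0.0))
        return d / np.linalg.norm(d)

    return position, tangent, total


def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane axes (e1, e2) with e1 x e2 = tangent."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tangent)) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    e1 = ref - np.dot(ref, tangent) * tangent
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)
    return e1, e2


def generate_sweep(spec: PhantomSpec) -> tuple[list[TrackedFrame], GroundTruth]:
    """Simulate a tracked sweep; identical seeds give identical output."""
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.sample_rate * spec.sweep_duration))
    times = np.arange(n_frames) / spec.sample_rate
    position, tangent, total_len = _centerline_interpolator(
        np.asarray(spec.centerline_control_points, dtype=float)
    )
    s_f = np.minimum(spec.probe_speed * times, total_len)
    r0 = spec.radius_profile(s_f)
    eps = spec.distension_profile(s_f)
    w = spec.waveform(times)
    radii = r0 * (1.0 + eps * w)

    theta = np.linspace(0.0, 2 * np.pi, spec.n_contour_points, endpoint=False)
    unit = np.column_stack([np.cos(theta), np.sin(theta)])

    frames: list[TrackedFrame] = []
    contours = np.empty((n_frames, spec.n_contour_points, 2))
    contours_world = np.empty((n_frames, spec.n_contour_points, 3))
    for i, (t_i, s_i, r_i) in enumerate(zip(times, s_f, radii)):
        contour = r_i * unit
        contours[i] = contour
        origin = position(s_i)
        tau = tangent(s_i)
        e1, e2 = _plane_basis(tau)
        R_clean = np.column_stack([e1, e2, tau])
        contours_world[i] = origin + contour @ np.column_stack([e1, e2]).T
        rot = Rotation.from_matrix(R_clean)
        trans = origin.copy()
        if spec.tracker_jitter_deg > 0:
            wobble = Rotation.from_rotvec(
                np.deg2rad(spec.tracker_jitter_deg) * rng.standard_normal(3)
            )
            rot = wobble * rot
        if spec.tracker_jitter_mm > 0:
            trans = trans + spec.tracker_jitter_mm * rng.standard_normal(3)
        pose = ProbePose.from_rotation(rot, trans, timestamp=float(t_i))
        image = render_frame(contour, spec, rng=rng)
        frames.append(
            TrackedFrame(
                image=image,
                pose=pose,
                pixel_spacing=spec.pixel_spacing,
                frame_index=i,
                timestamp=float(t_i),
            )
        )

    f = spec.heart_frequency
    n_beats = int(np.floor(times[-1] * f)) + 1
    ed_times = np.arange(n_beats) / f
    ed_idx = np.unique(np.round(ed_times * spec.sample_rate).astype(int))
    ed_idx = ed_idx[ed_idx < n_frames]

    # volumes over the swept extent by quadrature of the generating profiles
    s_grid = np.linspace(s_f[0], s_f[-1], 4001)
    r_ed_grid = spec.radius_profile(s_grid)
    r_es_grid = r_ed_grid * (1.0 + spec.distension_profile(s_grid))
    v_ed = float(np.trapezoid(np.pi * r_ed_grid**2, s_grid)) / 1000.0
    v_es = float(np.trapezoid(np.pi * r_es_grid**2, s_grid)) / 1000.0

    truth = GroundTruth(
        times=times,
        arclengths=s_f,
        radii=radii,
        radii_ed=r0,
        radii_es=r0 * (1.0 + eps),
        contours_inplane=contours,
        contours_world=contours_world,
        heart_frequency=f,
        ed_frame_indices=ed_idx,
        d_true=spec.true_distensibility(s_f),
        v_ed=v_ed,
        v_es=v_es,
        pulse_pressure=spec.pulse_pressure,
    )
    return frames, truth


def render_frame(
    true_contour: np.ndarray, spec: PhantomSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one cross-sectional image: dark lumen, bright wall band, speckle.

    ``true_contour`` is the interface polygon in in-plane mm (origin at the
    image centre).  Lateral sectors (rays nearly parallel to the image x
    axis) can have their wall contrast attenuated to mimic the reduced
    echogenicity of side-wall regions.
    """
    contour = np.asarray(true_contour, dtype=float)
    half = (spec.image_size - 1) / 2.0 * spec.pixel_spacing
    margin = spec.wall_thickness
    if np.any(np.abs(contour) > half - margin):
        raise PhantomValidationError("contour (plus wall band) exceeds the field of view")

    n = spec.image_size
    coords = (np.arange(n) - (n - 1) / 2.0) * spec.pixel_spacing
    X, Y = np.meshgrid(coords, coords)
    rho = np.hypot(X, Y)
    ang = np.arctan2(Y, X)

    # interface radius per pixel angle from the (star-shaped) contour polygon
    c_ang = np.mod(np.arctan2(contour[:, 1], contour[:, 0]), 2 * np.pi)
    c_rad = np.hypot(contour[:, 0], contour[:, 1])
    order = np.argsort(c_ang)
    c_ang, c_rad = c_ang[order], c_rad[order]
    c_ang_ext = np.concatenate([c_ang - 2 * np.pi, c_ang, c_ang + 2 * np.pi])
    c_rad_ext = np.concatenate([c_rad, c_rad, c_rad])
    r_if = np.interp(np.mod(ang, 2 * np.pi), c_ang_ext, c_rad_ext)

    wall_gain = spec.wall_intensity - spec.background_intensity
    if spec.lateral_attenuation > 0:
        wall_gain = wall_gain * (1.0 - spec.lateral_attenuation * np.cos(ang) ** 2)

    image = np.full((n, n), spec.background_intensity)
    in_wall = (rho >= r_if) & (rho < r_if + spec.wall_thickness)
    image[in_wall] = spec.background_intensity + (
        wall_gain[in_wall] if np.ndim(wall_gain) else wall_gain
    )
    image[rho < r_if] = spec.lumen_intensity

    if spec.speckle_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        image = image * (1.0 + spec.speckle_sigma * rng.standard_normal(image.shape))
        np.clip(image, 0.0, None, out=image)
    return image
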