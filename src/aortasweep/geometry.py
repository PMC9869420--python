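"""From per-frame contours to 3D phase geometries.

Segmented contours live in their frame's image plane.  The probe tracker
pose maps each plane rigidly into world coordinates.  A 3D centerline is
interpolated through the end-diastolic contour centres, smoothed, and
intersected with every frame plane to give a per-frame origin.  Contours
are then expressed on a polar (r, theta, t) grid about those origins, and
per-angle envelope detection over time separates the end-systolic upper
envelope from the end-diastolic lower envelope.  The mean-arterial-pressure
radius is the midpoint r_map = r_ed + 0.5 * (r_es - r_ed).  Finally an
ellipse is refitted per frame and phase to regularize angle-wise
irregularities, and the refit contours are mapped back to 3D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation
from shapely.geometry import Point, Polygon

from .cardiac import HeartFrequencyRange
from .segmentation import Ellipse, SegmentationError, fit_ellipse

__all__ = [
    "GeometryError",
    "ProbePose",
    "Centerline3D",
    "PolarGrid",
    "EnvelopeSet",
    "PhaseGeometry",
    "contour_to_world",
    "build_centerline",
    "frame_origins",
    "polar_resample",
    "build_polar_grid",
    "envelope_radii",
    "map_radius",
    "refit_phase_contours",
]


class GeometryError(ValueError):
    """Invalid input to a geometry operation."""


@dataclass(frozen=True)
class ProbePose:
    """Rigid pose of one image plane: p_world = R @ (x, y, 0) + t.

    ``quaternion`` is scalar-first (qw, qx, qy, qz) and must be unit norm.
    The image plane normal is R @ ez.
    """

    translation: np.ndarray
    quaternion: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.translation, dtype=float).reshape(3)
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise GeometryError("quaternion must have unit norm")
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "quaternion", q)

    @staticmethod
    def from_rotation(rot: Rotation, translation, timestamp: float = 0.0) -> "ProbePose":
        q = rot.as_quat(canonical=True)  # (x, y, z, w)
        return ProbePose(
            np.asarray(translation, dtype=float),
            np.array([q[3], q[0], q[1], q[2]]),
            timestamp,
        )

    @property
    def rotation(self) -> Rotation:
        qw, qx, qy, qz = self.quaternion
        return Rotation.from_quat([qx, qy, qz, qw])

    @property
    def normal(self) -> np.ndarray:
        return self.rotation.apply([0.0, 0.0, 1.0])

    def to_world(self, points_inplane: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_inplane, dtype=float))
        p3 = np.column_stack([pts, np.zeros(len(pts))])
        return self.rotation.apply(p3) + self.translation

    def to_plane(self, points_world: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_world, dtype=float))
        local = self.rotation.inv().apply(pts - self.translation)
        return local[:, :2]


def contour_to_world(contour: np.ndarray, pose: ProbePose) -> np.ndarray:
    """Rigidly embed in-plane (mm) contour points into world coordinates."""
    return pose.to_world(contour)


@dataclass(frozen=True)
class Centerline3D:
    """Densely sampled, smoothed vessel centerline."""

    points: np.ndarray      # (N, 3) mm
    arclength: np.ndarray   # (N,) cumulative, strictly increasing

    def __post_init__(self):
        if np.any(np.diff(self.arclength) <= 0):
            raise GeometryError("centerline arclength must be strictly increasing")


def _moving_average(x: np.ndarray, kernel: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    half = kernel // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean(axis=0)
    return out


def build_centerline(
    ed_centers_world: np.ndarray,
    resample_step: float = 0.5,
    smoothing_kernel: int = 15,
) -> Centerline3D:
    """Cubic spline through the ED contour centres, then a moving average.

    The spline is parameterized by cumulative chord length and densely
    resampled (default 0.5 mm) before the 15-sample moving-average smoother,
    so the effective smoothing length is ``smoothing_kernel * resample_step``
    millimetres.
    """
    centers = np.asarray(ed_centers_world, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise GeometryError("ed_centers_world must be (N, 3)")
    if len(centers) < 4:
        raise GeometryError("too few cardiac cycles captured: need >= 4 ED centers")
    chord = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    if np.any(chord <= 0):
        keep = np.concatenate([[True], chord > 0])
        centers = centers[keep]
        chord = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        if len(centers) < 4:
            raise GeometryError("too few distinct ED centers")
    u = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(u, centers, bc_type="natural")
    n = max(int(np.ceil(u[-1] / resample_step)) + 1, 2)
    dense = spline(np.linspace(0.0, u[-1], n))
    smooth = _moving_average(dense, smoothing_kernel)
    seg = np.linalg.norm(np.diff(smooth, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    smooth = smooth[keep]
    s = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(smooth, axis=0), axis=1))]
    )
    return Centerline3D(points=smooth, arclength=s)


def frame_origins(
    centerline: Centerline3D,
    poses: list[ProbePose],
    first_guess_world: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersect the centerline polyline with every frame plane.

    Returns (origins_world (F, 3), origins_inplane (F, 2), fallback_flags
    (F,) bool).  When a plane has several crossings the one nearest the
    previous frame's origin is kept (first frame: nearest to
    ``first_guess_world``, default the frame's translation).  A plane with
    no crossing falls back to the orthogonal projection of the nearest
    centerline point, flagged True.
    """
    P = centerline.points
    origins_w = np.empty((len(poses), 3))
    origins_p = np.empty((len(poses), 2))
    flags = np.zeros(len(poses), dtype=bool)
    prev: np.ndarray | None = (
        np.asarray(first_guess_world, dtype=float) if first_guess_world is not None else None
    )
    for i, pose in enumerate(poses):
        n = pose.normal
        d = (P - pose.translation) @ n
        sign_change = np.where(d[:-1] * d[1:] <= 0)[0]
        candidates = []
        for k in sign_change:
            denom = d[k + 1] - d[k]
            t = 0.0 if abs(denom) < 1e-15 else -d[k] / denom
            candidates.append(P[k] + np.clip(t, 0.0, 1.0) * (P[k + 1] - P[k]))
        if candidates:
            candidates = np.array(candidates)
            anchor = prev if prev is not None else pose.translation
            origin = candidates[np.argmin(np.linalg.norm(candidates - anchor, axis=1))]
        else:
            k = int(np.argmin(np.abs(d)))
            origin = P[k] - d[k] * n
            flags[i] = True
        origins_w[i] = origin
        origins_p[i] = pose.to_plane(origin)[0]
        prev = origin
    return origins_w, origins_p, flags


def polar_resample(
    contour: np.ndarray, origin: np.ndarray, n_angles: int = 72
) -> np.ndarray:
    """Radii of a closed contour polygon along equidistant rays from origin.

    Each ray is intersected with the polygon edges (linear interpolation
    between contour vertices); the nearest positive intersection wins.  The
    origin must lie strictly inside the contour.
    """
    pts = np.asarray(contour, dtype=float)
    origin = np.asarray(origin, dtype=float).reshape(2)
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if not poly.contains(Point(origin)):
        raise GeometryError("origin outside lumen")
    rel = pts - origin
    nxt = np.roll(rel, -1, axis=0)
    edge = nxt - rel
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    radii = np.empty(n_angles)
    for j, th in enumerate(angles):
        u = np.array([np.cos(th), np.sin(th)])
        denom = u[0] * edge[:, 1] - u[1] * edge[:, 0]
        ok = np.abs(denom) > 1e-15
        s = np.where(ok, (rel[:, 0] * u[1] - rel[:, 1] * u[0]) / np.where(ok, denom, 1.0), np.nan)
        t = np.where(ok, (rel[:, 0] * edge[:, 1] - rel[:, 1] * edge[:, 0]) / denom, np.nan)
        hit = ok & (s >= -1e-12) & (s <= 1.0 + 1e-12) & (t > 1e-12)
        if not np.any(hit):
            raise GeometryError("origin outside lumen or open contour")
        radii[j] = np.min(t[hit])
    return radii


@dataclass(frozen=True)
class PolarGrid:
    """Radii indexed by (angle, time): one column per frame."""

    radii: np.ndarray            # (A, F) mm
    angles: np.ndarray           # (A,) equidistant in [0, 2pi)
    times: np.ndarray            # (F,) s
    origins_world: np.ndarray    # (F, 3)
    origins_inplane: np.ndarray  # (F, 2)
    poses: list[ProbePose] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.radii <= 0):
            raise GeometryError("polar grid radii must be positive")
        step = np.diff(self.angles)
        if step.size and not np.allclose(step, step[0]):
            raise GeometryError("angle spacing must be constant")


def build_polar_grid(
    contours_inplane: list[np.ndarray],
    origins_inplane: np.ndarray,
    origins_world: np.ndarray,
    times: np.ndarray,
    poses: list[ProbePose],
    n_angles: int = 72,
) -> PolarGrid:
    """Assemble the (r, theta, t) grid from per-frame in-plane contours."""
    angles = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    radii = np.empty((n_angles, len(contours_inplane)))
    for j, contour in enumerate(contours_inplane):
        radii[:, j] = polar_resample(contour, origins_inplane[j], n_angles)
    return PolarGrid(
        radii=radii,
        angles=angles,
        times=np.asarray(times, dtype=float),
        origins_world=np.asarray(origins_world, dtype=float),
        origins_inplane=np.asarray(origins_inplane, dtype=float),
        poses=list(poses),
    )


@dataclass(frozen=True)
class EnvelopeSet:
    """Per-angle ED (lower) and ES (upper) envelopes over frame time.

    ``anchored_span`` is the time interval covered by detected anchors at
    every non-degenerate angle; outside it the envelopes are held at their
    nearest anchor value, so per-frame phase radii there are extrapolations
    (the boundary cardiac cycles of the sweep).
    """

    r_ed: np.ndarray   # (A, F)
    r_es: np.ndarray   # (A, F)
    degenerate_angles: np.ndarray  # bool (A,), fell back to global min/max
    anchored_span: tuple[float, float] = (-np.inf, np.inf)


def _envelope_1d(r: np.ndarray, t: np.ndarray, min_sep_samples: int):
    """Upper envelope through local maxima; None if < 2 anchors."""
    peaks, _ = find_peaks(r, distance=max(1, min_sep_samples))
    if len(peaks) < 2:
        return None, None
    interp = PchipInterpolator(t[peaks], r[peaks], extrapolate=False)
    env = interp(t)
    env[t <= t[peaks[0]]] = r[peaks[0]]
    env[t >= t[peaks[-1]]] = r[peaks[-1]]
    return env, (t[peaks[0]], t[peaks[-1]])


def envelope_radii(grid: PolarGrid, hf: HeartFrequencyRange) -> EnvelopeSet:
    """Detect ES (upper) and ED (lower) envelopes of each angle's r-t signal.

    Peaks must be separated by at least the minimal cardiac period
    (1 / f_high).  The ED envelope is found by running the same detection on
    the negated signal.  Between anchors a shape-preserving monotone cubic
    (PCHIP) interpolates; before the first / after the last anchor the
    nearest anchor value is held.  Angles with fewer than two anchors fall
    back to the global min/max of their signal, flagged degenerate.
    """
    t = grid.times
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    min_sep = int(np.ceil((1.0 / hf.f_high) / dt))
    A, F = grid.radii.shape
    r_es = np.empty((A, F))
    r_ed = np.empty((A, F))
    degenerate = np.zeros(A, dtype=bool)
    span_lo, span_hi = -np.inf, np.inf
    for i in range(A):
        r = grid.radii[i]
        upper, span_up = _envelope_1d(r, t, min_sep)
        lower, span_lo_i = _envelope_1d(-r, t, min_sep)
        if upper is None or lower is None:
            warnings.warn(
                f"angle index {i}: < 2 envelope anchors; using global min/max",
                stacklevel=2,
            )
            degenerate[i] = True
            r_es[i] = r.max()
            r_ed[i] = r.min()
        else:
            r_es[i] = upper
            r_ed[i] = -lower
            span_lo = max(span_lo, span_up[0], span_lo_i[0])
            span_hi = min(span_hi, span_up[1], span_lo_i[1])
    r_ed = np.minimum(r_ed, r_es)
    return EnvelopeSet(
        r_ed=r_ed, r_es=r_es, degenerate_angles=degenerate,
        anchored_span=(float(span_lo), float(span_hi)),
    )


def map_radius(r_ed, r_es):
    """Mean-arterial-pressure radius: the ED/ES midpoint r_ed + 0.5 (r_es - r_ed)."""
    r_ed = np.asarray(r_ed, dtype=float)
    r_es = np.asarray(r_es, dtype=float)
    if np.any(r_es < r_ed) or np.any(r_ed <= 0):
        raise GeometryError("requires r_es >= r_ed > 0 (envelope inversion upstream)")
    out = r_ed + 0.5 * (r_es - r_ed)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PhaseGeometry:
    """3D contour stack for one cardiac phase (ED, ES or MAP)."""

    phase: str
    contours_world: np.ndarray    # (F, A, 3)
    contours_inplane: np.ndarray  # (F, A, 2)
    origins_world: np.ndarray     # (F, 3)
    angles: np.ndarray            # (A,)
    times: np.ndarray             # (F,)
    ellipses: list[Ellipse] = field(default_factory=list)

    @property
    def n_contours(self) -> int:
        return len(self.contours_world)

    def point_cloud(self) -> np.ndarray:
        return self.contours_world.reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PhaseGeometry":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        cw = self.contours_world @ R.T + t
        ow = self.origins_world @ R.T + t
        return PhaseGeometry(
            phase=self.phase,
            contours_world=cw,
            contours_inplane=self.contours_inplane,
            origins_world=ow,
            angles=self.angles,
            times=self.times,
            ellipses=self.ellipses,
        )

    def to_mesh(self):
        """Closed surface: ruled triangulation between matched-angle rings
        plus centroid fan caps at both ends."""
        import trimesh

        F, A, _ = self.contours_world.shape
        if F < 2:
            raise GeometryError("need >= 2 contours to build a closed mesh")
        verts = self.contours_world.reshape(-1, 3)
        faces = []
        for i in range(F - 1):
            base0, base1 = i * A, (i + 1) * A
            for j in range(A):
                jn = (j + 1) % A
                faces.append([base0 + j, base1 + j, base1 + jn])
                faces.append([base0 + j, base1 + jn, base0 + jn])
        c0 = self.contours_world[0].mean(axis=0)
        c1 = self.contours_world[-1].mean(axis=0)
        i0, i1 = len(verts), len(verts) + 1
        verts = np.vstack([verts, c0, c1])
        for j in range(A):
            jn = (j + 1) % A
            faces.append([i0, jn, j])
            faces.append([i1, (F - 1) * A + j, (F - 1) * A + jn])
        return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def _ray_ellipse_radius(ellipse: Ellipse, origin: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from ``origin`` to the ellipse boundary along each ray angle."""
    c, s = np.cos(ellipse.phi), np.sin(ellipse.phi)
    Rm = np.array([[c, s], [-s, c]])  # world -> ellipse axes
    p0 = Rm @ (np.asarray(origin, dtype=float) - ellipse.center)
    radii = np.empty(len(angles))
    inv_a2, inv_b2 = 1.0 / ellipse.a**2, 1.0 / ellipse.b**2
    for j, th in enumerate(angles):
        u = Rm @ np.array([np.cos(th), np.sin(th)])
        A = u[0] ** 2 * inv_a2 + u[1] ** 2 * inv_b2
        B = 2 * (p0[0] * u[0] * inv_a2 + p0[1] * u[1] * inv_b2)
        C = p0[0] ** 2 * inv_a2 + p0[1] ** 2 * inv_b2 - 1.0
        disc = B**2 - 4 * A * C
        if disc < 0:
            raise GeometryError("origin outside refit ellipse")
        radii[j] = (-B + np.sqrt(disc)) / (2 * A)
    return radii


def refit_phase_contours(
    grid: PolarGrid, envelopes: EnvelopeSet
) -> dict[str, PhaseGeometry]:
    """Refit an ellipse per frame and phase, and map contours to 3D.

    For each frame the phase radii (ED lower envelope, ES upper envelope,
    MAP midpoint, evaluated at the frame time) are converted to in-plane
    Cartesian points about the frame origin, an ellipse is fitted to
    regularize angle-wise irregularities, the ellipse is sampled along the
    grid-angle rays from the origin, and the samples are mapped to world
    coordinates with the frame pose.
    """
    phases = {
        "ED": envelopes.r_ed,
        "ES": envelopes.r_es,
        "MAP": map_radius(envelopes.r_ed, envelopes.r_es),
    }
    A, F = grid.radii.shape
    cos_t, sin_t = np.cos(grid.angles), np.sin(grid.angles)
    out: dict[str, PhaseGeometry] = {}
    for phase, r_phase in phases.items():
        contours_w = np.empty((F, A, 3))
        contours_p = np.empty((F, A, 2))
        ellipses: list[Ellipse] = []
        keep = np.ones(F, dtype=bool)
        for j in range(F):
            origin = grid.origins_inplane[j]
            pts = origin + np.column_stack(
                [r_phase[:, j] * cos_t, r_phase[:, j] * sin_t]
            )
            try:
                ell = fit_ellipse(pts)
                radii = _ray_ellipse_radius(ell, origin, grid.angles)
            except (GeometryError, SegmentationError) as exc:
                warnings.warn(f"frame {j} ({phase}): {exc}; skipped", stacklevel=2)
                keep[j] = False
                continue
            contours_p[j] = origin + np.column_stack([radii * cos_t, radii * sin_t])
            contours_w[j] = grid.poses[j].to_world(contours_p[j])
            ellipses.append(ell)
        out[phase] = PhaseGeometry(
            phase=phase,
            contours_world=contours_w[keep],
            contours_inplane=contours_p[keep],
            origins_world=grid.origins_world[keep],
            angles=grid.angles,
            times=grid.times[keep],
            ellipses=ellipses,
        )
    return out
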