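"""Star-Kalman lumen segmentation of transverse B-mode frames.

The lumen-wall (or thrombus-wall) interface of the aorta is modelled as an
ellipse per frame.  Tracking proceeds frame to frame: the previous frame's
ellipse defines a radial search band, a star-shaped set of rays detects
dark-to-bright step edges inside that band, an ellipse is fitted through the
accepted edge points, and a Kalman filter on the five ellipse parameters
stabilizes the estimate over time.  Before edge detection each frame is
despeckled with Euclidean shortening flow (curvature motion, an
edge-preserving speckle filter) and smoothed with a 3x3 Gaussian.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel

log = logging.getLogger(__name__)

__all__ = [
    "BModeFrame",
    "Ellipse",
    "SearchBand",
    "TrackerState",
    "EdgeCandidate",
    "SegmentationError",
    "EllipseFitError",
    "TrackLostError",
    "esf_despeckle",
    "gaussian_smooth",
    "star_edge_candidates",
    "fit_ellipse",
    "kalman_step",
    "segment_sweep",
]

#: Total radial search-band thickness (mm) per vessel class.
BAND_THICKNESS_MM = {"healthy": 2.5, "aaa": 7.0}


class SegmentationError(ValueError):
    """Invalid input to a segmentation operation."""


class EllipseFitError(SegmentationError):
    """Raised when edge support is insufficient for an ellipse fit."""


class TrackLostError(RuntimeError):
    """Raised when too many consecutive frames fail to produce a fit."""


@dataclass(frozen=True)
class BModeFrame:
    """One grayscale cross-sectional image with its acquisition metadata.

    In-plane physical coordinates are in mm with the origin at the image
    centre, x along columns and y along rows (isotropic pixels).
    """

    intensity: np.ndarray
    pixel_spacing: float
    frame_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self):
        img = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(img)):
            raise SegmentationError("frame intensities must be finite")
        if not self.pixel_spacing > 0:
            raise SegmentationError("pixel_spacing must be positive")
        object.__setattr__(self, "intensity", img)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def mm_to_pixel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (x, y) mm coordinates to fractional (row, col) indices."""
        pts = np.atleast_2d(points_mm)
        h, w = self.intensity.shape
        col = pts[:, 0] / self.pixel_spacing + (w - 1) / 2.0
        row = pts[:, 1] / self.pixel_spacing + (h - 1) / 2.0
        return np.column_stack([row, col])

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Half-extents (x, y) of the field of view in mm."""
        h, w = self.intensity.shape
        return ((w - 1) / 2.0 * self.pixel_spacing, (h - 1) / 2.0 * self.pixel_spacing)


@dataclass(frozen=True)
class Ellipse:
    """Five-parameter ellipse: centre (mm), semi-axes a >= b (mm), tilt phi.

    ``phi`` is normalized to [0, pi); parameters are normalized on
    construction (axes swapped if needed).
    """

    cx: float
    cy: float
    a: float
    b: float
    phi: float

    def __post_init__(self):
        a, b, phi = float(self.a), float(self.b), float(self.phi)
        if a < b:
            a, b = b, a
            phi += np.pi / 2
        if not b > 0:
            raise SegmentationError("ellipse semi-axes must be positive")
        phi = float(np.mod(phi, np.pi))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "phi", phi)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy], dtype=float)

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)

    def perimeter(self) -> float:
        """Analytic circumference (Ramanujan's second approximation)."""
        a, b = self.a, self.b
        h = ((a - b) / (a + b)) ** 2
        return float(np.pi * (a + b) * (1.0 + 3 * h / (10.0 + np.sqrt(4.0 - 3 * h))))

    def radius_at(self, theta) -> np.ndarray:
        """Polar radius from the centre along absolute image angle theta."""
        t = np.asarray(theta, dtype=float) - self.phi
        a, b = self.a, self.b
        return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)

    def sample(self, n: int = 64, angles: np.ndarray | None = None) -> np.ndarray:
        """Boundary points at polar angles about the centre (default equiangular)."""
        if angles is None:
            angles = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        r = self.radius_at(angles)
        return self.center + np.column_stack([r * np.cos(angles), r * np.sin(angles)])

    def as_vector(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.a, self.b, self.phi], dtype=float)

    @staticmethod
    def from_vector(v: np.ndarray) -> "Ellipse":
        return Ellipse(*(float(x) for x in v))


@dataclass(frozen=True)
class SearchBand:
    """Radial annulus around a reference ellipse in which edges are sought."""

    reference: Ellipse
    inward: float
    outward: float

    def __post_init__(self):
        if self.inward < 0 or self.outward < 0:
            raise SegmentationError("band extrusions must be non-negative")
        if self.inward >= self.reference.b:
            raise SegmentationError(
                "inward extrusion must be smaller than the reference semi-minor axis"
            )

    @property
    def thickness(self) -> float:
        return self.inward + self.outward

    @staticmethod
    def for_class(reference: Ellipse, vessel_class: str) -> "SearchBand":
        """Band with the configured total thickness, split half in / half out."""
        try:
            thickness = BAND_THICKNESS_MM[vessel_class]
        except KeyError:
            raise SegmentationError(
                f"vessel_class must be one of {sorted(BAND_THICKNESS_MM)}, got {vessel_class!r}"
            ) from None
        half = thickness / 2.0
        inward = min(half, 0.9 * reference.b)
        return SearchBand(reference, inward, thickness - inward)


@dataclass(frozen=True)
class EdgeCandidate:
    theta: float
    point: np.ndarray  # (x, y) mm
    score: float


def _check_psd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-9):
        raise SegmentationError(f"{name} covariance must be symmetric")
    if np.linalg.eigvalsh(m).min() < -1e-9:
        raise SegmentationError(f"{name} covariance must be positive semi-definite")
    return m


@dataclass(frozen=True)
class TrackerState:
    """Kalman state over the five ellipse parameters (random-walk dynamics)."""

    x: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        for name in ("P", "Q", "R"):
            object.__setattr__(self, name, _check_psd(getattr(self, name), name))

    @property
    def ellipse(self) -> Ellipse:
        return Ellipse.from_vector(self.x)

    @staticmethod
    def initial(
        ellipse: Ellipse,
        process_sd: tuple[float, float] = (0.3, 0.02),
        measurement_sd: tuple[float, float] = (0.3, 0.02),
    ) -> "TrackerState":
        """State centred on ``ellipse``; SDs are (mm for centre/axes, rad for phi)."""
        q_lin, q_ang = process_sd
        r_lin, r_ang = measurement_sd
        Q = np.diag([q_lin**2] * 4 + [q_ang**2])
        R = np.diag([r_lin**2] * 4 + [r_ang**2])
        return TrackerState(ellipse.as_vector(), Q.copy(), Q, R)


def esf_despeckle(frame: BModeFrame, n_iter: int = 10, dt: float = 0.2) -> BModeFrame:
    """Euclidean shortening flow: iterate I <- I + dt * kappa * |grad I|.

    Curvature motion shrinks level-set curves proportionally to their
    curvature, removing speckle while preserving straight edges.  The
    maximum principle is enforced (output range never exceeds the input
    range).
    """
    if n_iter < 0:
        raise SegmentationError("n_iter must be >= 0")
    if not (0.0 < dt <= 0.25):
        raise SegmentationError("dt must lie in (0, 0.25] for stability")
    img = frame.intensity.copy()
    lo, hi = img.min(), img.max()
    eps = 1e-12
    for _ in range(n_iter):
        Iy, Ix = np.gradient(img)
        Iyy, Iyx = np.gradient(Iy)
        Ixy, Ixx = np.gradient(Ix)
        num = Ixx * Iy**2 - (Iyx + Ixy) * Ix * Iy + Iyy * Ix**2
        img = img + dt * num / (Ix**2 + Iy**2 + eps)
        np.clip(img, lo, hi, out=img)
    return replace(frame, intensity=img)


_GAUSS3 = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0


def gaussian_smooth(frame: BModeFrame) -> BModeFrame:
    """Convolve with a normalized 3x3 Gaussian kernel (reflective border)."""
    img = ndimage.correlate(frame.intensity, _GAUSS3, mode="reflect")
    return replace(frame, intensity=img)


def star_edge_candidates(
    frame: BModeFrame,
    band: SearchBand,
    n_rays: int = 64,
    step_mm: float = 0.1,
    kernel_half_width: int = 5,
    accept_fraction: float = 0.3,
) -> list[EdgeCandidate]:
    """Detect one dark-to-bright step edge per ray inside the search band.

    Rays are cast equiangularly from the reference ellipse centre; along each
    ray intensity is sampled only within [r_ref - inward, r_ref + outward].
    The edge score is the response of a symmetric step kernel (-1 inside,
    +1 outside); the maximal-score position wins, refined to sub-sample
    precision by parabolic interpolation.  Rays whose best score falls below
    ``accept_fraction`` times the frame's best score yield no candidate.
    """
    ref = band.reference
    ex, ey = frame.extent_mm
    thetas = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    r_ref = ref.radius_at(thetas)
    r_out = r_ref + band.outward
    reach = ref.center + np.column_stack([r_out * np.cos(thetas), r_out * np.sin(thetas)])
    if np.any(np.abs(reach[:, 0]) > ex) or np.any(np.abs(reach[:, 1]) > ey):
        raise SegmentationError("search band extends outside the image")

    w = kernel_half_width
    kernel = np.concatenate([-np.ones(w), np.ones(w)]) / (2.0 * w)
    raw: list[tuple[float, np.ndarray, float]] = []
    for theta, r0 in zip(thetas, r_ref):
        radii = np.arange(r0 - band.inward, r0 + band.outward + step_mm / 2, step_mm)
        pts = ref.center + np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
        samples = ndimage.map_coordinates(
            frame.intensity, frame.mm_to_pixel(pts).T, order=1, mode="nearest"
        )
        if samples.size < 2 * w + 1:
            continue
        resp = np.correlate(samples, kernel, mode="valid")
        k = int(np.argmax(resp))
        score = float(resp[k])
        # parabolic sub-sample refinement of the peak position
        shift = 0.0
        if 0 < k < resp.size - 1:
            denom = resp[k - 1] - 2 * resp[k] + resp[k + 1]
            if abs(denom) > 1e-12:
                shift = float(np.clip(0.5 * (resp[k - 1] - resp[k + 1]) / denom, -0.5, 0.5))
        # response index k corresponds to the kernel centred between sample
        # k+w-1 and k+w, i.e. radius offset (k + w - 0.5) steps from the start
        r_edge = radii[0] + (k + w - 0.5 + shift) * step_mm
        point = ref.center + r_edge * np.array([np.cos(theta), np.sin(theta)])
        raw.append((float(theta), point, score))

    if not raw:
        return []
    best = max(score for _, _, score in raw)
    if best <= 1e-12:
        return []
    return [
        EdgeCandidate(theta, point, score)
        for theta, point, score in raw
        if score >= accept_fraction * best
    ]


def fit_ellipse(points: np.ndarray) -> Ellipse:
    """Least-squares ellipse through >= 5 points (direct conic fit).

    Uses the Halir-Flusser ellipse-constrained conic fit followed by
    conversion to geometric parameters; exact input ellipses are recovered
    to machine precision.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise EllipseFitError("insufficient edge support: need >= 5 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise EllipseFitError("insufficient edge support: collinear points")
    with np.errstate(divide="ignore", invalid="ignore"):  # circles: a == c branch
        model = EllipseModel.from_estimate(pts)
    if not model:
        raise EllipseFitError("insufficient edge support: degenerate configuration")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise EllipseFitError("insufficient edge support: degenerate configuration")
    return Ellipse(float(xc), float(yc), float(a), float(b), float(theta))


def _wrap_phi_towards(phi: float, target: float) -> float:
    """Shift phi by multiples of pi to the representative nearest ``target``."""
    k = np.round((target - phi) / np.pi)
    return float(phi + k * np.pi)


def kalman_step(
    state: TrackerState, measurement: Ellipse, R: np.ndarray | None = None
) -> TrackerState:
    """One predict-update cycle with random-walk dynamics and identity H.

    The tilt measurement is wrapped (mod pi) to the branch nearest the
    prediction before the update so the filter never averages across the
    axis-swap ambiguity of near-circular ellipses.
    """
    Rm = state.R if R is None else _check_psd(R, "R")
    x_pred = state.x
    P_pred = state.P + state.Q
    z = measurement.as_vector()
    z[4] = _wrap_phi_towards(z[4], x_pred[4])
    S = P_pred + Rm
    K = P_pred @ np.linalg.inv(S)
    x_new = x_pred + K @ (z - x_pred)
    P_new = (np.eye(5) - K) @ P_pred
    P_new = 0.5 * (P_new + P_new.T)
    return TrackerState(x_new, P_new, state.Q, Rm)


def _radial_residual_sd(ellipse: Ellipse, points: np.ndarray) -> float:
    d = points - ellipse.center
    r = np.hypot(d[:, 0], d[:, 1])
    theta = np.arctan2(d[:, 1], d[:, 0])
    return float(np.std(r - ellipse.radius_at(theta)))


def segment_sweep(
    frames,
    init: Ellipse,
    vessel_class: str = "healthy",
    n_rays: int = 64,
    esf_iterations: int = 10,
    esf_dt: float = 0.2,
    max_consecutive_failures: int = 10,
    process_sd: tuple[float, float] = (0.3, 0.02),
    min_measurement_sd: tuple[float, float] = (0.05, 0.01),
) -> list[Ellipse]:
    """Track the lumen interface through a sweep, one ellipse per frame.

    Frame k's search band is built on frame k-1's (Kalman-filtered) output
    ellipse.  A frame whose fit fails inherits the previous ellipse with a
    warning; more than ``max_consecutive_failures`` consecutive failures
    abort with :class:`TrackLostError` ("track lost").
    """
    frames = list(frames)
    if not frames:
        raise SegmentationError("empty sweep")
    state = TrackerState.initial(init, process_sd=process_sd)
    results: list[Ellipse] = []
    previous = init
    failures = 0
    for frame in frames:
        pre = gaussian_smooth(esf_despeckle(frame, n_iter=esf_iterations, dt=esf_dt))
        try:
            band = SearchBand.for_class(previous, vessel_class)
            candidates = star_edge_candidates(pre, band, n_rays=n_rays)
            if len(candidates) < 5:
                raise EllipseFitError("insufficient edge support")
            pts = np.array([c.point for c in candidates])
            measurement = fit_ellipse(pts)
            sd = max(_radial_residual_sd(measurement, pts), min_measurement_sd[0])
            R = np.diag([sd**2] * 4 + [max(0.1 * sd, min_measurement_sd[1]) ** 2])
            state = kalman_step(state, measurement, R=R)
            previous = state.ellipse
            failures = 0
        except SegmentationError as exc:
            failures += 1
            log.warning(
                "frame %d: %s; propagating previous ellipse (%d consecutive failures)",
                frame.frame_index, exc, failures,
            )
            warnings.warn(f"frame {frame.frame_index}: {exc}", stacklevel=2)
            if failures > max_consecutive_failures:
                raise TrackLostError(
                    f"track lost after {failures} consecutive fit failures"
                ) from exc
        results.append(previous)
    return results
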