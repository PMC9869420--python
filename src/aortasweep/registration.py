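"""Rigid registration and surface-agreement metrics.

A sweep-derived geometry is aligned to a reference geometry (e.g. a CT
segmentation) with iterative closest point: alternate nearest-neighbour
correspondence and least-squares rigid alignment (Kabsch/SVD), capped at a
fixed iteration count.  Agreement is then quantified slice by slice along
the vessel length: the Dice similarity index of rasterized cross-sections
and the Hausdorff distance of the contour point sets, summarized as medians
with interquartile ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff
from skimage.draw import polygon2mask

from .geometry import PhaseGeometry

__all__ = [
    "RegistrationError",
    "RigidTransform",
    "SliceStack",
    "ComparisonReport",
    "icp_register",
    "resample_slices",
    "similarity_index",
    "hausdorff_distance",
    "rasterize_contour",
    "compare_geometries",
]


class RegistrationError(ValueError):
    """Degenerate input to registration or comparison."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map p -> R p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-9 or not np.allclose(
            R @ R.T, np.eye(3), atol=1e-9
        ):
            raise RegistrationError("rotation must be proper orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, dtype=float)) @ self.rotation.T + self.translation


def _kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping source onto target (paired)."""
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    return R, t


def icp_register(
    source: np.ndarray,
    target: np.ndarray,
    n_iter: int = 30,
    tolerance: float = 1e-6,
    return_history: bool = False,
):
    """Iterative closest point with single-nearest-neighbour correspondence.

    Runs ``n_iter`` iterations or stops early once the RMS correspondence
    distance changes by less than ``tolerance`` mm; the RMS is
    non-increasing across iterations by construction of the Kabsch step.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    for name, pts in (("source", src), ("target", tgt)):
        if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
            raise RegistrationError(f"{name} cloud is degenerate (need >= 3 non-collinear points)")
    tree = cKDTree(tgt)
    transform = RigidTransform.identity()
    history: list[float] = []
    for _ in range(n_iter):
        moved = transform.apply(src)
        dist, idx = tree.query(moved)
        rms = float(np.sqrt(np.mean(dist**2)))
        if history and abs(history[-1] - rms) < tolerance:
            break
        history.append(rms)
        R, t = _kabsch(src, tgt[idx])
        transform = RigidTransform(R, t)
    if return_history:
        return transform, history
    return transform


@dataclass(frozen=True)
class SliceStack:
    """Paired planar contours at equidistant stations along the vessel axis."""

    y: np.ndarray                       # slice coordinates, strictly increasing
    contours_a: list[np.ndarray] = field(default_factory=list)  # (P, 2) each, in-slice (x, z)
    contours_b: list[np.ndarray] = field(default_factory=list)
    axis: int = 1

    def __post_init__(self):
        if len(self.y) and np.any(np.diff(self.y) <= 0):
            raise RegistrationError("slice coordinates must be strictly increasing")


def _interp_contours(geometry: PhaseGeometry, ys: np.ndarray, axis: int) -> list[np.ndarray]:
    """Linear matched-angle interpolation of contours at the requested stations."""
    stack = geometry.contours_world
    yc = stack[..., axis].mean(axis=1)
    order = np.argsort(yc)
    yc, stack = yc[order], stack[order]
    inplane_axes = [k for k in range(3) if k != axis]
    out = []
    for y in ys:
        j = int(np.searchsorted(yc, y))
        j = min(max(j, 1), len(yc) - 1)
        y0, y1 = yc[j - 1], yc[j]
        w = 0.0 if y1 == y0 else np.clip((y - y0) / (y1 - y0), 0.0, 1.0)
        contour = (1.0 - w) * stack[j - 1] + w * stack[j]
        out.append(contour[:, inplane_axes])
    return out


def resample_slices(
    geom_a: PhaseGeometry,
    geom_b: PhaseGeometry,
    spacing: float = 0.2,
    axis: int = 1,
) -> SliceStack:
    """Equidistant paired slices over the overlapping extent of two geometries.

    Both geometries must already be in a common frame.  Stations outside
    either geometry's extent are excluded; an empty overlap raises
    "registration failed or disjoint extents".
    """
    ya = geom_a.contours_world[..., axis].mean(axis=1)
    yb = geom_b.contours_world[..., axis].mean(axis=1)
    lo = max(ya.min(), yb.min())
    hi = min(ya.max(), yb.max())
    if hi <= lo:
        raise RegistrationError("registration failed or disjoint extents")
    ys = np.arange(lo, hi + spacing / 2, spacing)
    ys = ys[ys <= hi + 1e-12]
    return SliceStack(
        y=ys,
        contours_a=_interp_contours(geom_a, ys, axis),
        contours_b=_interp_contours(geom_b, ys, axis),
        axis=axis,
    )


def similarity_index(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A&B| / (|A| + |B|) of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise RegistrationError("masks must share the same grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise RegistrationError("empty slice")
    return 2.0 * int((a & b).sum()) / (na + nb)


def hausdorff_distance(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets (any dimension)."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise RegistrationError("point sets must be nonempty")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def rasterize_contour(
    contour: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int],
    pixel: float,
) -> np.ndarray:
    """Binary mask of a closed polygon on a grid anchored at ``origin``."""
    pts = (np.asarray(contour, dtype=float) - np.asarray(origin)) / pixel
    return polygon2mask(shape, pts[:, ::-1])


@dataclass(frozen=True)
class ComparisonReport:
    """Per-slice and summary agreement between two geometries."""

    slice_y: np.ndarray
    slice_si: np.ndarray
    slice_hd: np.ndarray
    median_si: float
    iqr_si: tuple[float, float]
    median_hd: float
    iqr_hd: tuple[float, float]
    transform: RigidTransform


def compare_geometries(
    geom_us: PhaseGeometry,
    geom_ref: PhaseGeometry,
    spacing: float = 0.2,
    pixel: float = 0.2,
    n_iter: int = 30,
    register: bool = True,
    axis: int = 1,
) -> ComparisonReport:
    """Register (ICP), slice, and score two geometries with Dice + Hausdorff.

    Quartiles use linear interpolation (numpy default).
    """
    transform = (
        icp_register(geom_us.point_cloud(), geom_ref.point_cloud(), n_iter=n_iter)
        if register
        else RigidTransform.identity()
    )
    moved = geom_us.transformed(transform.rotation, transform.translation)
    stack = resample_slices(moved, geom_ref, spacing=spacing, axis=axis)
    sis, hds = [], []
    for ca, cb in zip(stack.contours_a, stack.contours_b):
        allpts = np.vstack([ca, cb])
        origin = allpts.min(axis=0) - 2 * pixel
        extent = allpts.max(axis=0) - origin + 2 * pixel
        shape = (int(np.ceil(extent[1] / pixel)) + 1, int(np.ceil(extent[0] / pixel)) + 1)
        ma = rasterize_contour(ca, origin, shape, pixel)
        mb = rasterize_contour(cb, origin, shape, pixel)
        sis.append(similarity_index(ma, mb))
        hds.append(hausdorff_distance(ca, cb))
    sis = np.asarray(sis)
    hds = np.asarray(hds)
    return ComparisonReport(
        slice_y=stack.y,
        slice_si=sis,
        slice_hd=hds,
        median_si=float(np.median(sis)),
        iqr_si=(float(np.percentile(sis, 25)), float(np.percentile(sis, 75))),
        median_hd=float(np.median(hds)),
        iqr_hd=(float(np.percentile(hds, 25)), float(np.percentile(hds, 75))),
        transform=transform,
    )
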