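"""Compliance, distensibility and circumferential strain of the aortic wall.

Brachial cuff pressures systematically deviate from intra-aortic pressures
(diastolic overestimated by 12%, systolic underestimated by 5%); the cuff
values are corrected accordingly and converted to kPa before use.  With the
corrected pulse pressure dP,

    C_local  = dA / dP          (mm^2/kPa, per cross-section)
    D_local  = C_local / A_ED   (1/kPa)
    C_global = dV / dP          (ml/kPa, from closed-mesh volumes)
    D_global = C_global / V_ED  (1/kPa)
    strain   = (l_ES - l_ED) / l_ED   (circumferential, dimensionless)

where dA and dV are the area and volume change between end systole and end
diastole.  Areas come from rasterized binary masks of the phase contours;
circumferences default to the analytic perimeter of the fitted ellipse
(Ramanujan's second approximation), which avoids the pixelation bias of
mask-traced perimeters (a mask-based variant is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .cardiac import ellipse_mask_area
from .geometry import PhaseGeometry
from .segmentation import Ellipse

__all__ = [
    "MMHG_TO_KPA",
    "MechanicsError",
    "PressureMeasurement",
    "SliceMechanics",
    "GlobalMechanics",
    "RankSumResult",
    "correct_brachial_pressure",
    "ellipse_circumference",
    "local_mechanics",
    "closed_mesh_volume",
    "global_mechanics",
    "rank_sum_test",
    "cohort_summary",
]

MMHG_TO_KPA = 0.1333224

#: Enumerate the exact rank-sum permutation distribution up to this many subsets.
_EXACT_ENUMERATION_CAP = 200_000


class MechanicsError(ValueError):
    """Non-physiological or degenerate input."""


@dataclass(frozen=True)
class PressureMeasurement:
    """Brachial cuff pair and its aorta-corrected counterpart."""

    brachial_dia: float   # mmHg
    brachial_sys: float   # mmHg
    corrected_dia: float  # kPa
    corrected_sys: float  # kPa

    @property
    def pulse_pressure(self) -> float:
        """Corrected pulse pressure dP in kPa."""
        return self.corrected_sys - self.corrected_dia


def correct_brachial_pressure(
    dia_mmhg: float, sys_mmhg: float, variant: str = "multiplicative"
) -> PressureMeasurement:
    """Remove the cuff biases (+12% diastolic, -5% systolic) and convert to kPa.

    The default removes the biases multiplicatively (x0.88 and x1.05); the
    ``"division"`` variant divides by (1.12, 0.95) instead.
    """
    if not (0 < dia_mmhg < sys_mmhg):
        raise MechanicsError("need 0 < diastolic < systolic pressure")
    if variant == "multiplicative":
        dia_c, sys_c = 0.88 * dia_mmhg, 1.05 * sys_mmhg
    elif variant == "division":
        dia_c, sys_c = dia_mmhg / 1.12, sys_mmhg / 0.95
    else:
        raise MechanicsError(f"unknown correction variant: {variant!r}")
    return PressureMeasurement(
        brachial_dia=float(dia_mmhg),
        brachial_sys=float(sys_mmhg),
        corrected_dia=dia_c * MMHG_TO_KPA,
        corrected_sys=sys_c * MMHG_TO_KPA,
    )


def ellipse_circumference(ellipse: Ellipse, method: str = "analytic") -> float:
    """Ellipse perimeter: Ramanujan II (default), dense polygonal arc length,
    or the Crofton perimeter of a rasterized mask."""
    if method == "analytic":
        return ellipse.perimeter()
    if method == "polygonal":
        pts = ellipse.center + np.column_stack(
            [
                ellipse.a * np.cos(np.linspace(0, 2 * np.pi, 4097)),
                ellipse.b * np.sin(np.linspace(0, 2 * np.pi, 4097)),
            ]
        )
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if method == "mask":
        from skimage.measure import perimeter_crofton

        spacing = 0.05
        n = int(np.ceil(2 * (ellipse.a + 2 * spacing) / spacing)) | 1
        x = (np.arange(n) - (n - 1) / 2.0) * spacing
        X, Y = np.meshgrid(x, x)
        c, s = np.cos(ellipse.phi), np.sin(ellipse.phi)
        u, v = X * c + Y * s, -X * s + Y * c
        mask = (u / ellipse.a) ** 2 + (v / ellipse.b) ** 2 <= 1.0
        return float(perimeter_crofton(mask, directions=4) * spacing)
    raise MechanicsError(f"unknown circumference method: {method!r}")


@dataclass(frozen=True)
class SliceMechanics:
    """Per-cross-section mechanics between the ED and ES phases."""

    a_ed: float       # mm^2
    a_es: float       # mm^2
    c_local: float    # mm^2/kPa
    d_local: float    # 1/kPa
    l_ed: float       # mm
    l_es: float       # mm
    strain: float     # circumferential, dimensionless
    negative_distension: bool = False

    @property
    def da(self) -> float:
        return self.a_es - self.a_ed


def local_mechanics(
    contour_ed: Ellipse,
    contour_es: Ellipse,
    pulse_pressure: float,
    pixel_spacing: float = 0.1,
    circumference_method: str = "analytic",
    area_method: str = "mask",
) -> SliceMechanics:
    """Local compliance, distensibility and strain for one cross-section.

    Areas follow the binary-mask convention of the area-time signal by
    default (``area_method="analytic"`` uses pi*a*b instead).  An ES area
    below the ED area (possible under segmentation error) is retained and
    flagged rather than rejected.
    """
    if not pulse_pressure > 0:
        raise MechanicsError("pulse pressure must be positive")
    if area_method == "mask":
        a_ed = ellipse_mask_area(contour_ed, pixel_spacing)
        a_es = ellipse_mask_area(contour_es, pixel_spacing)
    elif area_method == "analytic":
        a_ed, a_es = contour_ed.area, contour_es.area
    else:
        raise MechanicsError(f"unknown area method: {area_method!r}")
    l_ed = ellipse_circumference(contour_ed, circumference_method)
    l_es = ellipse_circumference(contour_es, circumference_method)
    c_local = (a_es - a_ed) / pulse_pressure
    return SliceMechanics(
        a_ed=a_ed,
        a_es=a_es,
        c_local=c_local,
        d_local=c_local / a_ed,
        l_ed=l_ed,
        l_es=l_es,
        strain=(l_es - l_ed) / l_ed,
        negative_distension=a_es < a_ed,
    )


def closed_mesh_volume(geometry: PhaseGeometry) -> float:
    """Volume (ml) of the closed solid built from the contour stack.

    The surface is a ruled triangulation between consecutive matched-angle
    contours with centroid fan caps; the signed divergence-theorem volume is
    taken in absolute value, so the result is orientation independent.
    """
    mesh = geometry.to_mesh()
    if not mesh.is_watertight:
        warnings.warn("phase mesh is not watertight (self-intersecting contours?)",
                      stacklevel=2)
    return abs(float(mesh.volume)) / 1000.0


@dataclass(frozen=True)
class GlobalMechanics:
    """Volume-based mechanics of the whole captured segment."""

    v_ed: float       # ml
    v_es: float       # ml
    c_global: float   # ml/kPa
    d_global: float   # 1/kPa

    @property
    def dv(self) -> float:
        return self.v_es - self.v_ed


def global_mechanics(
    geom_ed: PhaseGeometry, geom_es: PhaseGeometry, pulse_pressure: float
) -> GlobalMechanics:
    if not pulse_pressure > 0:
        raise MechanicsError("pulse pressure must be positive")
    v_ed = closed_mesh_volume(geom_ed)
    v_es = closed_mesh_volume(geom_es)
    c_global = (v_es - v_ed) / pulse_pressure
    return GlobalMechanics(v_ed=v_ed, v_es=v_es, c_global=c_global, d_global=c_global / v_ed)


@dataclass(frozen=True)
class RankSumResult:
    p_value: float
    u_statistic: float
    ties_present: bool
    method: str  # "exact-enumeration" or "normal-approximation"


def rank_sum_test(group1, group2) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum test between independent groups.

    For small samples the exact permutation distribution of the U statistic
    is enumerated in full over all C(n1+n2, n1) group assignments of the
    pooled mid-ranks (valid in the presence of ties).  Larger samples fall
    back to the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise MechanicsError("both groups need at least 2 values")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks
    ties = len(np.unique(pooled)) < len(pooled)
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if comb(n1 + n2, n1) <= _EXACT_ENUMERATION_CAP:
        idx = np.fromiter(
            (i for c in combinations(range(n1 + n2), n1) for i in c), dtype=np.intp
        ).reshape(-1, n1)
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-9))
        return RankSumResult(p, float(u_obs), ties, "exact-enumeration")

    # tie-corrected normal approximation with continuity correction
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return RankSumResult(1.0, float(u_obs), ties, "normal-approximation")
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    return RankSumResult(p, float(u_obs), ties, "normal-approximation")


def cohort_summary(values) -> tuple[float, float]:
    """Arithmetic mean and n-1 sample standard deviation."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise MechanicsError("need at least 2 values for a cohort summary")
    return float(v.mean()), float(v.std(ddof=1))
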