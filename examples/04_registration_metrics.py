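"""Rigid registration and overlap scoring of two 3D geometries.

A sweep-derived geometry is ICP-registered to a reference (the stand-in
for a CT segmentation), resampled into paired ~0.2 mm slices along the
vessel axis, and scored per slice with the Dice similarity index and the
Hausdorff distance.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from aortasweep.geometry import PhaseGeometry
from aortasweep.registration import compare_geometries


def bulged_tube(n_c=120, n_a=72, length=60.0):
    ys = np.linspace(0, length, n_c)
    ang = np.linspace(0, 2 * np.pi, n_a, endpoint=False)
    cw = np.empty((n_c, n_a, 3))
    for i, y in enumerate(ys):
        r = 9.0 + 6.0 * np.exp(-((y - 30.0) ** 2) / (2 * 81.0))
        cw[i] = np.column_stack(
            [r * np.cos(ang), np.full(n_a, y), r * np.sin(ang)]
        )
    return PhaseGeometry("MAP", cw, np.zeros((n_c, n_a, 2)), cw.mean(axis=1), ang, ys)


reference = bulged_tube()
# the "ultrasound" geometry: same vessel, displaced and slightly dilated
moved = reference.transformed(
    Rotation.from_euler("zy", [4.0, -3.0], degrees=True).as_matrix(),
    np.array([6.0, -2.0, 3.0]),
)
dilated = PhaseGeometry(
    "MAP",
    moved.origins_world[:, None, :]
    + 1.02 * (moved.contours_world - moved.origins_world[:, None, :]),
    moved.contours_inplane, moved.origins_world, moved.angles, moved.times,
)

report = compare_geometries(dilated, reference)
print(f"slices compared : {len(report.slice_y)} at 0.2 mm spacing")
print(f"median SI       : {report.median_si:.3f} "
      f"[{report.iqr_si[0]:.3f}-{report.iqr_si[1]:.3f}]")
print(f"median HD       : {report.median_hd:.2f} mm "
      f"[{report.iqr_hd[0]:.2f}-{report.iqr_hd[1]:.2f}]")
# After ICP removes the rigid displacement, the residual disagreement is the
# 2% dilation: SI near 0.98 and HD a fraction of a millimetre.
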