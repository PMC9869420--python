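"""Track the lumen-wall interface through a sweep with the star-Kalman loop.

Each frame is despeckled (curvature flow) and smoothed, edges are found on
radial rays inside a band around the previous frame's ellipse, an ellipse
is fitted, and a Kalman filter stabilizes the parameters frame to frame.
"""

import numpy as np

from aortasweep.phantom import PhantomSpec, generate_sweep
from aortasweep.segmentation import BModeFrame, Ellipse, segment_sweep

spec = PhantomSpec(base_radius=10.0, distension=0.08, speckle_sigma=0.25,
                   sweep_duration=6.0, tracker_jitter_mm=0.0, tracker_jitter_deg=0.0,
                   seed=3)
frames, truth = generate_sweep(spec)
bmode = [BModeFrame(f.image, f.pixel_spacing, f.frame_index, f.timestamp)
         for f in frames]

# manual initialization: an ellipse roughly at the vessel in frame 0
init = Ellipse(cx=0.0, cy=0.0, a=10.5, b=9.5, phi=0.0)
contours = segment_sweep(bmode, init, vessel_class="healthy")

r_est = np.array([np.sqrt(e.a * e.b) for e in contours])
err = np.abs(r_est - truth.radii)
print(f"tracked {len(contours)} frames under speckle (SD {spec.speckle_sigma})")
print(f"equivalent-radius error: mean {err.mean():.3f} mm, max {err.max():.3f} mm")
# Sub-tenth-millimetre mean error is what makes the pulsation (~0.8 mm
# radius swing here) recoverable downstream.
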