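# Methods

This note documents the models, numerical choices and limitations behind
`aortasweep`, in the order the pipeline runs.

## Acquisition model and the phantom

A sweep is an ordered series of 2D grayscale cross-sections, each with a
rigid probe pose (translation + unit quaternion, image plane = the pose's
x–y plane) and a timestamp at a fixed 25 Hz sampling rate. Because the
probe moves freehand, spatial frame spacing varies with probe speed while
temporal spacing is constant; all timing logic therefore lives in the time
domain.

The phantom emulates this acquisition for a pulsating vessel. The local
interface radius is

    r(s, t) = r0(s) · (1 + ε(s) · w(t)),     w(t) ∈ [0, 1],

with arclength s along the centerline, baseline radius r0(s), fractional
distension ε(s), and a cardiac waveform w that is 0 at end diastole and 1
at end systole. The default waveform is a raised cosine,
w = 0.5 − 0.5·cos(2πft), chosen so that ED and ES are unambiguous smooth
extrema; a skewed-systolic variant (faster upstroke, w = 0.5 −
0.5·cos(2π·φ^0.65) over the cycle phase φ) is available for realism. The
default aneurysm profile is a Gaussian bulge r0(s) = r_base + (r_max −
r_base)·exp(−(s−s0)²/2σ²) — smooth, differentiable, and capturing the
large axial change in caliber that makes envelope detection hard in real
AAAs. The true distensibility follows in closed form, D(s) = ((1+ε(s))² −
1)/ΔP, which is the oracle for every recovery test; ED/ES segment volumes
come from quadrature of π·r².

Frames are rendered as dark lumen, bright wall band (2 mm default) on a
mid-gray background, with optional multiplicative Gaussian speckle
(SD 0.2 by default) and optional lateral wall-contrast attenuation to
mimic the poor echogenicity of side-wall regions. Tracker noise is
additive Gaussian on position and small-angle rotation, 0.5 mm / 0.5° by
default, consistent with the ~1.5 mm point accuracy reported for
electromagnetic probe trackers of this class. The phantom deliberately
omits point-spread-function convolution, refraction, scan conversion and
breathing motion: passing tests demonstrate correctness of the *signal
processing chain*, not robustness to every artifact of clinical B-mode
imaging.

Default study conditions used by the recovery tests: bulge 8 → 12 mm
(s0 = 15 mm, σ = 8 mm), ε = 0.10, 72 beats/min, probe 2.5 mm/s for 12 s
(300 frames, ~4.8 cardiac cycles per cm of vessel), pressures 9/17 kPa
(ΔP = 8 kPa), with noise and jitter set to zero for the "clean sweep"
checks. These sizes keep a full end-to-end run near ten seconds on one
core.

## Segmentation

Preprocessing is Euclidean shortening flow — iterated curvature motion
I ← I + dt·κ|∇I| with κ|∇I| = (I_xx I_y² − 2 I_xy I_x I_y + I_yy I_x²) /
(I_x² + I_y²) — followed by a normalized 3×3 Gaussian. Defaults are 10
iterations at dt = 0.2 (dt ≤ 0.25 for stability; the output is clipped to
the input range, enforcing the maximum principle exactly). The iteration
count is an engineering default: enough to suppress speckle at the 0.1 mm
edge-sampling scale without rounding the wall edge away.

The star detector casts 64 equiangular rays (even coverage at ~0.5 mm arc
spacing on a 10 mm vessel) from the previous ellipse's centre and samples
intensity at 0.1 mm steps, restricted to the radial band
[r_ref − inward, r_ref + outward]. The band totals 2.5 mm for healthy
aortas and 7 mm for AAAs, split half inward / half outward since nothing
favours either side. The edge score is the response of a symmetric step
kernel (−1 × 5, +1 × 5 samples, dark-to-bright going outward); the peak is
refined by three-point parabolic interpolation, and rays scoring below 0.3
of the frame's best score are dropped so attenuated side-wall sectors
cannot inject spurious points — the ellipse fit then bridges the gap.

The ellipse fit is the direct least-squares conic fit with ellipse
constraint (via `skimage.measure.EllipseModel`), normalized to a ≥ b > 0
and tilt φ ∈ [0, π). Points that are collinear to numerical rank are
rejected before fitting. The Kalman filter uses random-walk dynamics on
(cx, cy, a, b, φ) with process SD 0.3 mm / 0.02 rad; the measurement noise
is set per frame from the radial residual SD of the fit (floored at
0.05 mm), so clean frames are trusted nearly verbatim and ragged fits are
smoothed. The tilt measurement is wrapped mod π onto the branch nearest
the prediction, which keeps near-circular frames (where φ is nearly
unidentifiable) from dragging the state. A frame whose fit fails inherits
the previous ellipse with a warning; more than 10 consecutive failures
abort as a lost track. Manual initialization is a config entry (centre,
axes, tilt), not an interactive step.

## Cardiac timing

Lumen area per frame is measured from a rasterized binary mask of the
fitted ellipse (default 0.1 mm pixels; boundary pixels contribute a 4×4
sub-sampled coverage fraction, giving ~0.02 mm² accuracy on a 10 mm
circle; ellipses under 2 pixels fall back to π·a·b with a warning). The
signal is resampled to equidistant steps at the median sampling interval
by linear interpolation — the simplest defensible choice — mean-removed,
and analysed with a Hann-windowed periodogram. The heart frequency is the
highest peak inside the physiological band, 0.67–2.0 Hz (40–120
beats/min); a ±0.2 Hz band (±12 beats/min) around it absorbs the rate
drift common during breath-hold. A peak is only accepted if it exceeds
5× the median in-band power; otherwise the signal carries no cardiac
information and the stage fails loudly.

ED frames are the minima of the resampled signal with minimum separation
1/f_high and prominence ≥ 10% of the signal's peak-to-peak (the period
separation is the physiological constraint; the prominence floor is an
added guard against noise wiggles). Each minimum maps back to the nearest
original frame.

## 3D geometry and envelopes

Contours map to world coordinates by p = R·(x, y, 0) + T. The centerline
is a natural cubic spline through the ED contour centres, parameterized by
cumulative chord length, densely resampled at 0.5 mm, then smoothed
component-wise by a 15-sample moving average with shrinking edge windows.
Since the smoothing kernel is specified in samples, the effective
smoothing length is kernel × step = 7.5 mm; the resampling step is
recorded in run metadata for that reason. Per-frame origins are the
crossings of the centerline polyline with each image plane; among multiple
crossings the one nearest the previous frame's origin wins (continuity),
and a plane with no crossing falls back, flagged, to the orthogonal
projection of the nearest centerline point.

Each contour is resampled to 72 equidistant angles (5° — fine enough that
polygonal area falls short of the true ellipse area by ~0.13%) by exact
ray–polygon intersection about the frame origin; θ = 0 is the in-plane +x
axis, counterclockwise, purely by convention. Per angle, ES anchors are
the local maxima of r(t) separated by at least the minimal cardiac period,
and ED anchors are found identically on −r(t). Between anchors the
envelopes interpolate with a shape-preserving monotone cubic (PCHIP),
which cannot overshoot the anchor values; beyond the first/last anchor the
nearest anchor value is held. An angle with fewer than two anchors falls
back to its global min/max and is flagged degenerate. The anchored time
span common to all angles is reported (`EnvelopeSet.anchored_span`):
outside it phase radii are extrapolations of the boundary cardiac cycles,
and local mechanics there should not be trusted quantitatively —
recovery tests therefore evaluate local distensibility inside that span.
MAP radii are the ED/ES midpoint. Finally an ellipse is refitted per frame
and phase to the (θ, r_phase) points — regularizing angle-wise
irregularities exactly as the per-frame segmentation does — sampled along
the original grid-angle rays from the origin, and mapped back to 3D.

## Registration and comparison

ICP alternates single-nearest-neighbour correspondence with the SVD
(Kabsch) rigid solution, capped at 30 iterations with a 1e-6 mm RMS-change
tolerance and no outlier trimming. The MAP geometry is the natural one to
register against a CT-derived surface, since CT integrates over the
cardiac cycle. Registered geometries are resampled into paired planar
contours every 0.2 mm along the vessel axis (linear matched-angle
interpolation between bracketing contours, overlap region only), each pair
is rasterized at 0.2 mm pixels for the Dice similarity index
2|A∩B|/(|A|+|B|), and the Hausdorff distance is computed on the contour
point samples (not filled regions). Summaries are medians with 25th/75th
percentiles by linear interpolation.

## Mechanics

Brachial cuff pressures are corrected multiplicatively — diastolic × 0.88,
systolic × 1.05, removing the documented +12%/−5% cuff biases — then
converted at 0.1333224 kPa/mmHg. The multiplicative form (rather than
dividing by 1.12/0.95) is the default because it reproduces every
volunteer row of the shipped global-mechanics table exactly at printed
precision; the division variant is available behind a flag.

Local compliance and distensibility use the same rasterized-mask areas as
the area-time signal. Circumference defaults to the analytic perimeter of
the fitted ellipse (Ramanujan's second approximation, within 0.1% of the
dense polygonal arc length over all aspect ratios used here) because
pixel-counted mask perimeters are systematically biased; polygonal and
Crofton mask-based variants are implemented for comparison. A
cross-section whose ES area falls below its ED area is retained and
flagged (negative distension occurs under segmentation error and is
reported, not hidden).

Volumes come from a deterministic closed mesh: ruled triangulation between
consecutive matched-angle contours plus centroid fan caps, signed volume
by the divergence theorem, taken in absolute value so orientation is
irrelevant. This replaces any interactive solid-modelling step; volumes
agree with cylinder/frustum closed forms to ≲0.15% at 72 angles.

The group comparison is a two-sided Mann–Whitney rank-sum test. For the
sample sizes involved the permutation distribution of U is enumerated in
full over all C(n1+n2, n1) group assignments of the pooled mid-ranks,
which remains valid under ties; beyond an enumeration cap of 2×10⁵
subsets, the tie-corrected normal approximation with continuity correction
takes over (flagged in the result). Cohort summaries are mean ± n−1 SD.

## Shipped cohort tables and known inconsistencies

The package ships three per-subject fixture tables: demographics with
brachial pressures, per-subject mean local distensibility and strain, and
ED/ES volumes with global compliance/distensibility. Two quirks are stored
verbatim rather than "corrected": (1) the patient blood-pressure columns
in the source demographics table are printed systolic-first despite their
header; the fixture stores them in the physiologically consistent
(diastolic, systolic) order, which is also the only reading under which
the volume table rederives. (2) Patient rows B2 and B7 are internally
inconsistent — their printed global compliance cannot be obtained from
their printed volumes and pressures under either correction variant —
and are flagged as anomalies, excluded from reproduction pass criteria.
Cohort summaries are computed over the printed distensibility columns
(including the anomalous cells), exactly as the published summary rows
are.

## Limitations

The interface model is a single ellipse per frame: adequate for aortas,
imperfect for strongly non-elliptical AAA sections, and there is no
active-contour refinement or thrombus–lumen segmentation. Local estimates
degrade where fewer cardiac cycles cover a given vessel length (fast probe
motion) and at the sweep boundaries outside the envelope anchor span, in
both cases by construction of the envelope interpolation. Registration is
rigid only, so a deforming aneurysm between acquisitions contributes
irreducible disagreement. The phantom's idealizations mean imaging-physics
failure modes (shadowing, reverberation, refraction) are untested here.
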