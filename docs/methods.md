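# Methods

This note records the models, conventions and numerical choices behind
`mvfruit`, and what the synthetic experiments do and do not demonstrate.

## Geometry

World coordinates are a local metric ENU frame; converting geodetic
trajectories into it is an I/O concern outside the package. The camera is
a pinhole with optional Brown radial–tangential distortion (default zero;
undistortion is a 12-step fixed-point iteration, exact to < 1e-6 px for
mild lenses). Pixels are 0-based, continuous, origin top-left, u right,
v down; the camera frame is z-forward/x-right/y-down. Poses are stored as
positions plus unit quaternions (scalar-last internally; trajectory CSV
uses the conventional scalar-first `qw,qx,qy,qz`, or `roll,pitch,yaw` in
degrees, auto-detected).

Navigation typically runs an order of magnitude faster than the camera
(50 Hz vs 5 Hz here), so pose lookup interpolates linearly in position and
spherically (slerp) in orientation between the bracketing samples. Image
timestamps are corrected by an additive clock offset before lookup.

Finite epipolar segments clip the viewing ray to camera-to-fruit ranges
of 2.5–8 m (configurable) — a conservative envelope for an orchard row
viewed from the adjacent corridor. If exactly one clip point falls behind
the second camera the 3D chord is clipped to that camera's forward
half-space before projection; if both do, no segment exists. Segments may
leave the image: the extent test in the association cost handles that.

## Tracking and counting

The association cost is the perpendicular distance to the segment's
*supporting line*, with a separate validity test that the centroid's
orthogonal foot lies within the segment; beyond-end candidates and
distances above the threshold get a large constant cost (6000 px,
exceeding the 4120 px image diagonal). Assignment is
`scipy.optimize.linear_sum_assignment`; matches at the large constant are
discarded afterwards. Tracking is strictly sequential: every track whose
latest observation is in the previous processed frame participates in the
next assignment; unmatched tracks terminate permanently and unmatched
detections seed new tracks, so track frames are strictly consecutive. A
fruit occluded for one frame and re-exposed is counted twice — the
documented fragmentation failure mode, exercised in the tests. Frames
without trajectory coverage are skipped with a warning and break all live
tracks; segments are never synthesised across a pose gap (frames merely
missing from the input are paired normally, giving geometrically longer,
more ambiguous segments — also exercised in the tests).

Counting requires ≥ 2 observations, which suppresses one-off false
positives. Per-tree totals sum the two independent side passes of a row
without cross-side deduplication; fruit visible from both sides is
double-counted, which the occlusion model keeps to a few percent.

## Localisation

Triangulation is the unweighted midpoint method over all unordered ray
pairs; ray pairs within 0.1° of parallel are excluded (their midpoint is
numerically unstable), and a track whose pairs are all near-parallel keeps
its count but is flagged. Rays here are unconstrained, unlike the clipped
tracking segments. The ground elevation raster uses 0.5 m cells with the
5th-percentile height per cell (robust to grass and canopy returns) and
nearest-cell fill; fruit height is position z minus the containing (or
nearest) cell's elevation.

## Tree masks

The thinned cloud (20 cm voxel representatives, 5% random keep, seeded)
builds the per-frame tree inventory: a tree is "in" a frame when one
thinned point projects inside it with positive depth. Masks are rendered
from the full row cloud: points below 20 cm above the local ground are
deleted first (so fallen fruit are not attributed to canopies), LiDAR-vs-
camera perspective occlusion is resolved point-wise (a point is suppressed
when a different tree's point lies nearer within a 20 px lateral radius),
then each tree's pixels are dilated by a 20 px disk and painted
farthest-to-nearest by mean point depth. Because masks are label lookups
rather than imagery, they are rasterised at 1/4 of the sensor resolution
with the radius scaled to match (`MaskParams.render_scale`); dilating a
sparse point raster is implemented as disk-stamping, which is equivalent
and much faster. Track-to-tree assignment is the modal non-zero mask label
over a track's centroids, ties broken to the lowest tree id. Processing is
strictly one row at a time, which suppresses background-row trees by
construction.

Row passes are detected from the navigation data alone: yaw rate
differenced over a 0.5 s window (so chassis vibration does not read as a
turn) against a 10°/s threshold, keeping straight runs of at least 20 m of
path (headland connector legs are shorter). Side labels follow the travel
direction relative to the first pass.

## Calibration

The zero-intercept fit uses m = Σxy/Σx² and the conventional
mean-centred R² (which can be negative for a bad through-origin fit). The
clock-offset scan covers −0.1 to +0.2 s in 5 ms steps and minimises the
mean matched perpendicular distance, averaging matched pairs only. Offset
errors are observable only through platform rotation rates: on a
constant-velocity, constant-attitude path a time shift displaces both
cameras of a frame pair identically and cancels out of the epipolar
geometry. This is why the synthetic platform carries attitude wobble by
default (below), and why the residual tracking noise floor scales with
rotation rate × sync error.

Detection evaluation matches predicted and truth boxes one-to-one,
greedily by descending IoU with a 0.2 floor — for equal squares that floor
corresponds to √(1/3) ≈ 58% overlap along each axis — so double
detections cost precision and merged detections cost recall.

## The synthetic orchard

Defaults describe the scan regime the pipeline targets and are chosen
once:

| parameter | default | why |
| --- | --- | --- |
| platform speed / frame rate | 1.4 m/s, 5 Hz | ~25 viewpoints per tree side |
| navigation rate | 50 Hz | typical GPS/INS output |
| rows × trees | 1 × 16 | the ground-truthed study size |
| tree / row spacing | 4 m / 9 m | mature mango block geometry; camera-to-fruit range stays inside 2.5–8 m |
| canopy | ellipsoid 1.5×1.5×1.6 m, centre 2 m | fruit in the outer shell (inner radius 0.5) |
| fruit per tree | negative binomial, mean 130, k=10 | average-yield scale with realistic tree-to-tree spread |
| camera | 3296×2472, fx=fy=2060 (~77° HFOV) | survey sensor geometry, so pixel-denominated parameters (30 px gate, 20 px dilation, 2 px noise) carry their intended meaning |
| occlusion window | 110° azimuth per fruit | a single central view sees ~31% of fruit and two opposing views ~60% — the observed single/dual-view regime — while nearly every fruit is exposed somewhere along a pass |
| persistent miss rate | 5% per fruit and pass | detector failures correlate strongly across near-identical consecutive views; an i.i.d. 5% per-frame miss would fragment every ~20-frame track (≈1.9 detection runs per fruit) and force a ~1.4 slope, which no near-unity-slope system could exhibit |
| transient miss rate | 0.5% per frame | the uncorrelated component that fragments tracks |
| false positives | Poisson, 2% of true detections per frame | rejected by the ≥2-observation rule unless they chain |
| centroid noise | σ = 2 px | benign detector localisation error |
| attitude wobble | 1° yaw + 0.5° pitch at 2.5 Hz | chassis vibration; makes the clock offset observable |

The simulator emulates the *statistical* structure of a scan, not its
photometry: occlusion is a per-fruit azimuth window rather than ray-cast
foliage, misses are draws rather than detector physics, and the LiDAR
cloud samples canopy surfaces (4000 points/tree, enough that the dilated
silhouette is hole-free at the mask render scale) rather than real beam
returns. Consequently the synthetic experiments demonstrate the
*machinery* — exact recovery in the noiseless limit, plateau stability,
offset recovery, the multi-view-beats-single-view ordering — but the
specific slopes and errors of any real orchard depend on its detector,
canopy and navigation quality and are not claimed here.

## Problem sizes

The standard study tracks ~2,000 fruit across ~500 frames (two side
passes of 16 trees) and labels every detection against rendered masks;
it completes in a couple of minutes on one core. The offset scan uses a
60-frame subsequence at 5 ms steps; noiseless-recovery checks use a
5-tree, 60-fruit scene. The acceptance script runs all of these from one
seed.

## Known limitations

- No re-association across occlusion gaps (fragmentation over-counts) and
  no appearance cues; purely geometric association can swap ids of
  bunched fruit, which affects triangulation but not counts.
- No cross-side 3D deduplication; two-sided totals double-count fruit
  visible from both corridors (a few percent under the default occlusion
  model).
- Triangulation is unweighted and not robust to association outliers.
- Tree segmentation of the LiDAR cloud is consumed, not produced.
- The fallen-fruit ground layer is not tallied; grass returns above the
  20 cm cutoff can still leak into masks (the generator can produce such
  scenes for testing).
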