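# Methods

`helixafm` quantifies conformational changes of actin filaments in
high-speed AFM (HS-AFM) time-lapse height maps: the half-helical pitch
and crossover-peak height of the two-start actin helix, the ~2 nm height
increase and ~27% pitch shortening induced by cofilin decoration, the
asymmetric supertwist propagation into the bare zone on the pointed-end
side of a cofilin cluster, the pointed-end-biased growth of clusters,
and the classification of severing sites relative to cluster boundaries.
Because raw HS-AFM movies of this kind are not publicly deposited, the
package includes a calibrated synthetic movie generator, and every
analysis stage is validated against generated ground truth.

## The measurement model

A filament appears in a topograph as a ridge whose height is maximal at
the crossover points, where the two strands of the double helix align
vertically. The axial distance between consecutive crossover peaks is
the **half-helical pitch** (bare: 36.8 ± 4.3 nm observed; fully
cofilin-decorated: 26.9 ± 3.8 nm), and the peak height is the apparent
filament thickness (8.6 ± 0.8 nm bare, 10.6 ± 1.0 nm decorated).

The observed pitch SD mixes true structural variation with measurement
error. Actin paracrystals (laterally bundled filaments with suppressed
structural twist variation) calibrate the error: their apparent pitch SD
(3.0 nm) is an upper bound on the measurement error, and assuming
independent normals,

    sd_true = sqrt(sd_obs^2 - sd_err^2),

giving structural SDs of 3.1 nm (bare, from 4.3) and 2.3 nm (decorated,
from 3.8). `subtract_measurement_variance` implements exactly this and
refuses `sd_obs < sd_err`. The supertwist is summarized as
`ratio = pitch_bare / pitch_decorated` (36.8/26.9 = 1.37) and
`percent = 100*(1 - 1/ratio)` (27%).

## Peak measurement

Frames are first cleaned by the two preprocessing filters: spike removal
(pixels deviating more than 2 nm from their 3×3 median are replaced by
that median, shrinking the window at frame borders) and first-order
plane flattening fitted to background (non-foreground-masked) pixels.

Backbones are traced by skeletonizing the connected region above a
height floor, taking the longest skeleton path, snapping it to the ridge
(perpendicular height-weighted centroid, re-smoothed each pass so the
snap does not zig-zag the polyline and inflate arc length), resampling
at 1-pixel arc steps, and extending past the skeleton's retracted tips
along the end tangents while the height stays above the floor — without
the extension, skeletonization loses the terminal crossover peaks.

Peaks are picked semi-automatically. Candidate maxima come from the
height profile sampled along the trace, Gaussian-smoothed (σ = 2 px) to
suppress pixel noise and the subunit-scale corrugation, with a minimum
separation of 15 nm (about half of the shortest decorated pitch) and a
0.4 nm prominence cut; an approximate point can also be supplied
manually (`refine_peak` is the manual mode). Each candidate is refined
by the two-step rule: the maximum pixel of the 5×5 window (7.5 × 7.5 nm²
at the default 1.5 nm pixel), then the height-weighted center of mass of
the 5×5 window around that maximum, weights being heights minus the
window minimum (translation-invariant in height). The reported height is
bilinearly interpolated at the refined position (the max-pixel height is
available as an option). A second pass re-searches implausibly long
inter-peak gaps (>1.7× the trace's median pitch) at minimal prominence,
recovering rare low-drawn peaks. Pitch is the arc distance between
consecutive refined peaks along the traced backbone (not the 2D chord):
filaments are quasi-straight at half-helix scale and arc length
generalizes to curved filaments.

On sub-pixel-shifted Gaussian bumps the center-of-mass refinement is
accurate to <0.2 px over a grid of offsets. On rendered filaments the
residual axial localization error is ~0.5–0.8 nm per peak; it partially
*anticorrelates* with the localization jitter (the center of mass is
pulled toward the envelope structure), so the realized pitch-level error
of the full loop matches the 3.0 nm calibration with the default jitter
(see below) rather than adding to it in quadrature.

## Decoration, clusters, growth, severing

A half helix is called decorated when the mean of its two bounding peak
heights is at least 9.6 nm — the midpoint of the printed bare and
decorated modes; with the printed mode SDs the expected per-half-helix
error rate is the Gaussian tail overlap at 9.6 nm (~10–16%), so cluster
boundaries are intrinsically fuzzy at single-frame level, matching the
half-helix resolution limit of the imaging itself.

For multi-frame movies the per-frame states are consolidated: for every
half helix the (height, pitch) series over frames is converted to a
Gaussian log-likelihood ratio (decorated vs bare, printed parameters)
and fitted with a piecewise-constant model with at most one changepoint
— decoration is effectively a one-way transition and the underlying
structure persists between frames — making per-helix states monotone in
time and immune to frame-level flicker. Residual 1–2-helix holes and
isolated single-helix islands (caused by single extreme height draws
corrupting two neighboring half helices) are closed morphologically.
The supertwisted first pointed-side neighbor is usually absorbed into
the apparent span, a constant half-helix boundary offset that cancels in
span-change counting.

Clusters are maximal decorated runs; growth events are counted from
span changes between consecutive frames (clusters matched by maximal
overlap; one event per half helix gained, pointed or barbed side by the
polarity annotation; losses ignored; births without overlap are
nucleation). Filament polarity cannot be read from topography — it
enters as an annotation (experimentally, from the tilted binding angle
of transiently bound myosin S1). The pointed-end preference is reported
with an exact Clopper–Pearson 95% CI.

Severing is detected as a new interior gap (≥10 nm below the floor along
a previously continuous trace) persisting for ≥2 frames; the site is the
half helix containing the gap midpoint in the pre-break frame (post-break
retraction corrupts states, so classification uses the frame before the
gap), classified into four categories: `far_bare`, `neighbor_bare`
(bare, adjacent to a cluster), `end_cluster` (decorated, at a run end or
the physical filament end — the latter flagged separately), and
`inner_cluster`. `neighbor_bare + end_cluster` is the boundary-proximal
pool (within one half helix of a boundary). The tally reports both
pooled and per-category counts, so either reading of "immediately
neighboring the boundary" is checkable.

Peak-rise time series (tracked by greedy nearest-neighbor linking with a
10 nm displacement cap) are fitted with piecewise-constant models of 0,
1 or 2 steps compared by BIC (`n·log(SSE/n) + k·log(n)`, k = levels +
changepoints), with a 0.5 nm minimum step — level changes below the
measurement noise are not substeps. Two substeps correspond to
out-of-register cofilin arrival on the two strands.

Where polarity is unknown, the asymmetry around a site is the
longer/shorter ratio of the two flanking pitch measurements (≥1 by
construction; ~1.0 for symmetric sites measured with ~1 nm EM-grade
span error).

## The synthetic generator

The generator emulates the study conditions, not arbitrary data. Each
half helix draws a true pitch from its state's (mean, structural SD)
normal, truncated at >10 nm (>8σ from every mean; a non-physicality
guard only), and a true peak height from the state's height normal:

| state       | pitch (nm)   | height (nm) |
|-------------|--------------|-------------|
| bare        | 36.8 ± 3.1   | 8.6 ± 0.8   |
| decorated   | 26.9 ± 2.3   | 10.6 ± 1.0  |
| p_neighbor  | 28.8 ± 3.4   | 9.2 ± 1.0   |
| b_neighbor  | 37.3 ± 3.5   | 9.0 ± 0.9   |
| paracrystal | 36.5 ± 0     | 8.6 ± 0.8   |

Pitch SDs are structural (the observed SDs follow by quadrature with the
3.0 nm measurement error; the neighbor structural SDs are the quadrature
residuals of the observed 4.5/4.6 nm). Neighbor states are assigned
automatically beside decorated runs, the supertwisted one on the
pointed-end side (pointed end at index 0 by convention); a half helix
between two runs takes the pointed-side label, since that is the side
the supertwist propagates to.

Rendering: peaks sit at the true crossover arcs plus an optional
deterministic orientation-dependent offset (uniform over
±`offset_range_nm`, default 0 — see below) plus per-frame Gaussian
jitter σ_p = 3.0/√2 nm, so that pitch-level error (difference of two
independent jitters) matches the paracrystal calibration. The axial
envelope between consecutive peaks is a raised cosine dipping to 0.75 of
the local peak height, with smoothstep height blending (zero slope at
the nodes keeps each rendered apex exactly at its arc and height even
when neighboring peaks differ), plus a 0.4 nm corrugation at the 5.5 nm
actin-subunit period, phase-anchored at each crossover — the corrugation
is what makes the apparent peak sharp enough for pixel-level
localization, exactly as the discrete subunits do in real topographs.
Peak height attribution: each half helix owns its pointed-side peak;
peaks adjacent to a decorated half helix take the decorated draw (the
boundary crossover belongs to the cluster). The cross-section is a
hemi-ellipse of half-width height/2; the surface is dilated by a
spherical tip (grayscale dilation, default radius 2 nm — which preserves
apex heights and broadens widths), and i.i.d. N(0, 0.15 nm) pixel noise
is added. Cosine tapers roll the envelope off over 10 nm beyond the
terminal crossovers. Filaments render straight along a raster row by
default; arbitrary (e.g., circular-arc) backbone polylines are supported
via nearest-point projection.

The ±2.5 nm orientation-dependent offset between apparent peak and true
crossover is exposed (`offset_range_nm`, `orientation_phase_deg`) but
disabled by default: its SD (~1.44 nm for a uniform ±2.5 nm offset) is
not separable from the localization jitter in any downstream statistic,
so by default the full localization error budget lives in σ_p, keeping
the paracrystal calibration exact.

Dynamics: per frame each cluster gains one half helix with probability
`growth_rate_per_s·Δt` (default 0.05 /s, read off published time
courses of ~1 half helix per 15–60 s; imaging at 2 frames/s), toward the
pointed end with probability β (default 0.8), else barbed; a step whose
target is off the filament or already decorated is dropped, not
redirected, so logged fractions stay at β. Newly decorated half helices
redraw pitch and height from the decorated distributions and neighbor
states are refreshed. Severing draws per half helix per frame with
category-dependent rates (defaults 0; presets enable them), removes
~15 nm of filament around a point inside the half helix, and is logged
with its true category. Every event is recorded in a ground-truth
sidecar (JSON) together with per-frame states, true and observed
crossover arcs, and polarity.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis consumes: state
distributions, quadrature error composition, boundary asymmetry, growth
kinetics and directionality, severing categories, tip broadening, pixel
noise. It does not render atomic structure, bound S1 or cofilin
molecules as objects (polarity and decoration enter as ground truth),
scan-line artifacts, drift, or cantilever dynamics; the paracrystal
preset renders parallel filaments one band apart rather than
touching-packed bundles (it emulates the zero-structural-variance
property, not lateral packing). Passing tests therefore demonstrate that
the measurement chain is correct and unbiased under calibrated
conditions, not that it is robust to every artifact of real instrument
data.

## Numerical and design choices

- Pixel size 1.5 nm (a 5×5 window spans 7.5 nm), 32-bit float heights in
  nm, 0-based pixel indices, x = column·pixel size.
- Tie-breaks: flat refinement windows return the smallest row, then
  column (flagged degenerate); a gap midpoint exactly on a peak belongs
  to the pointed-side half helix; equal-overlap cluster matches go to
  the lower span start (flagged).
- Greedy nearest-neighbor peak linking; assignments beyond 10 nm start
  new tracks rather than teleporting.
- Filament identity across frames by trace centroid, with the axial
  offset down-weighted 10× (decoration contracts the filament, sliding
  the centroid along the axis while the lateral position is fixed).
- Tracing uses a 3 nm floor (peaks use 4 nm) so envelope dips of
  low-drawn peaks cannot split a trace; growth statistics ignore
  filaments present in fewer than half the frames (transient fragments).
- Gaussian summaries report the maximum-likelihood fit (sample mean/SD)
  with a ±3σ (99.73%) display range; reported pitches/heights round to
  0.1 nm and ratios to 0.01.
- Reproduction problem sizes: ~2000 half helices for each free-filament
  distribution (100 × 20 bare, 75 × 27 decorated, one frame each), 1000
  paracrystal pitches (50 × 20), ≥400 pooled neighbor half helices
  (250 clusters × 2 frames), and ≥188 growth events from ~8–9 movies of
  1000 frames. Long observations of few filaments are preferred for
  growth counting: the apparent boundary carries a bounded per-filament
  uncertainty of about half a helix, so relative count error shrinks
  with events per filament.
- The neighbor-asymmetry reproduction takes decoration states from
  the ground-truth sidecar while pitches are fully measured; the 0.5 nm
  recovery bound leaves no budget for boundary-classification noise, and
  the original analysis likewise knew cluster positions by eye across
  frames. Height-threshold classification accuracy is validated
  separately against its Gaussian-overlap expectation.

## Known limitations

- Half-helix-granular cluster boundaries: the apparent span is offset by
  the absorbed pointed-side neighbor and cannot distinguish
  `neighbor_bare` from `end_cluster` for breaks exactly at a boundary
  (both are boundary-proximal).
- The severing-site classifier trusts the pre-break decoration states;
  for filaments severed more than twice in the same region,
  fragment-local half-helix indices no longer match whole-filament
  ordinals.
- Growth counting assumes immobilized filaments (anisotropic centroid
  matching); freely gliding filaments would need real tracking.
- Sparse single-molecule binding (too small to image directly) is out of
  scope; the longer/shorter ratio statistic is provided for externally
  measured flanking spans.
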