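# Methods

This note documents the models, estimators and numerical choices behind
`endopatch`, in the order data flows through the pipeline.

## Synthetic movies

The generator emulates single budding-yeast cells imaged by wide-field
two-channel fluorescence at 65 nm/pixel. A movie is a `[frame, channel,
row, col]` stack in arbitrary photon-scaled units (no camera calibration is
modeled): a uniform background (default 20 photons/px), a soft-edged
cytoplasmic fill (default +12 photons/px inside the cell, logistic edge of
~2 px width), rendered point sources, then Poisson noise on the total and
additive Gaussian read noise (default SD 2), clipped at zero.

**Events.** Each cortical event has a lifetime drawn from a normal
distribution truncated below at 4 s (and above so the whole event fits in
the movie); per-event amplitudes are normal around
`peak_amplitude_photons` (default 2000) with CV 0.1. The green trace is
piecewise linear: a rise over `rise_fraction` of the lifetime (default
0.6), a plateau, and — for internalizing events — a linear decline over the
final quarter. The red (actin) trace is zero until onset, rises over
`red_rise_s` (default 6 s) to `red_amplitude_photons` (default 1500), and
dims with the green decline. Three onset modes exist:

- `threshold` (default): the red onset is the first frame where the
  noiseless green trace reaches `f × max(green)`; `f` is either fixed
  (`threshold_fraction_f`, default 0.75) or drawn per event uniformly in
  `threshold_fraction_range`. Because the crossing is "first frame at or
  above", the realized intensity ratio at the onset frame overshoots `f`
  by on average half a rise step (~2–4 points); ground truth records the
  frame, so estimator checks compare against the realized ratio.
- `delay`: the red onset fires a normally distributed time after green
  onset (truncated to the event support) — emulates conditions in which
  actin onset is decoupled from the NPF level (e.g. a type I myosin fusion
  recruited early whose actin response waits ~12.6 ± 4.9 s).

**Geometry.** Sites are uniform on the cell boundary conditioned on a
minimum angular separation (default 0.5 rad ≈ 13.5 px at the default
27 px cell radius), sampled exactly by spreading the angular slack with
sorted uniforms. Events are static, internalizing (centroid moves
radially inward by `internalization_depth_px`, default 3 px ≈ 195 nm,
over the final quarter of the lifetime), or — in the comet condition —
drifting tangentially along the cortex at `drift_speed_px_per_frame`
(default 0.15). The comet condition adds independent red objects moving
in straight lines through the cytoplasm (reflected at 0.9 R) with an
exponentially decaying trail along their recent trajectory.

**Determinism.** One root seed; per-event sub-streams are keyed by
`(seed, event index)` via `numpy` seed sequences, so event k is
reproducible regardless of cohort composition. Identical parameters give
bit-identical movies.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photobleaching, camera gain/offset calibration,
focal drift and out-of-focus light, cell-to-cell expression variability
beyond the amplitude CV, patch substructure, and true stochastic protein
recruitment kinetics (the piecewise-linear profiles are a deliberate
simplification that keeps analytic oracles possible). Conclusions about
estimator bias transfer to real movies only insofar as real traces are
smooth on the 3-frame scale and sites are diffraction-limited.

## Cell outline

The outline is fitted on the time-averaged green channel. A grey-scale
opening with a disk of radius 5 px removes diffraction-limited blobs (and
their halos) while leaving the convex cell body intact; a 3×3 median
filter tames residual noise; the isodata threshold then cuts the smooth
cell edge at its half-level (a median + k·MAD rule was tried first and
rejected: on time-averaged frames the MAD is so small that the threshold
sits just above background and swallows the soft edge, biasing the radius
by >2 px). The largest connected component is kept, holes are filled, and
a subpixel contour is resampled at ~1 px arc spacing. Finally a circular
grey opening on the radius-versus-arc profile (window ~1/8 of the
perimeter) removes outward bulges that bright cortical patches still
imprint on the contour — important in conditions where patches persist
for most of the movie. Accuracy on synthetic cells: center and mean
radius within 0.5 px.

Coordinates are 0-based `(row, col)` with pixel centers on integers;
angles are measured from the +col axis toward +row and boundary points are
ordered by increasing angle.

## Detection, linking, classification, exclusion

Spots are detected per frame by a difference of Gaussians (σ = 1.5 px and
2σ; 1.5 px is a diffraction-limited blob at 65 nm/px), local maxima above
`k_det = 4` robust SDs (1.4826·MAD) of the band-passed image, localized by
intensity-weighted centroid in a 5×5 window. Linking assigns open track
ends to detections per frame by optimal bipartite assignment on Euclidean
distance (links > 3 px forbidden), closes gaps up to 2 frames under a
constant-position prediction, and drops tracks with fewer than 4
detections. Ties are resolved deterministically (assignment on a fixed
ordering; output sorted by birth frame and id).

Motility classes: a track *internalizes* if it starts within the 3 px
cortical band and its final quartile moves inward by ≥ 2 px (slope of a
straight-line fit to the radial coordinate times the window length —
endpoint positions are too noisy); otherwise it is *static* if its net
displacement (endpoint positions averaged over ≤ 5 frames) is < 2 px and
it stays within the cortical band; everything else is
*cytoplasmic-motile*. Internalization is tested first because a 3 px
inward excursion can leave a net displacement under the 2 px static
threshold — an inward-moving patch is not "nonmotile".

The crowded-patch rule flags **both** members of any same-channel pair of
tracks simultaneously alive and ever closer than 5 px (≈ 325 nm, about
two PSF widths); flagged tracks are excluded from intensity
quantification and from the motility percentages. A side effect worth
knowing: a drifting patch that runs into a static one is censored by this
rule, so motile percentages are computed over the resolvable population —
the same population a manual analysis would count.

## Traces and event statistics

**Photometry.** Per frame, intensity is summed in a 3 px aperture around
the track position (interpolated inside the track span, endpoint-extended
outside it, so the trace covers the whole movie and provides a local
noise baseline), minus the median of a 5–8 px annulus times the aperture
area. At the curved, soft cell edge this leaves a small positive pedestal
(~1–3 photons/px equivalent); all threshold rules therefore add the
trace's own quiet-segment median as a baseline term. Smoothing for
intensity readouts is a centered 3-frame moving average.

**Lifetime.** The measured lifetime is `(last − first + 1) × Δt` over the
maximal above-threshold run (threshold = quiet baseline + 3 noise SDs),
allowing single-frame dips, where the run must overlap the track's own
lifespan. The run is delimited on a 3-frame *median*-filtered copy of the
trace rather than the moving average: the moving average leaks one third
of the last bright frame past the event and stretched every lifetime by
about +1 frame; the median filter suppresses noise comparably but is
edge-preserving. Residual bias is < 0.2 s for ~24 s events and about
−2.3 s for ~79 s events (threshold-crossing lag on slow rises — any fixed
3 SD rule clips the dim head of a slow ramp), well inside the 2 SEM bands
used for validation. Increasing the threshold multiplier can only shorten
the measured lifetime (tested as a monotonicity property).

**Onset (T2).** Actin onset is the first frame starting a run of
3 consecutive frames above baseline + 3 SD on the **raw** red trace (a
smoothed trace crosses one frame early on a fast rise). When the trace
carries track metadata, baseline and SD come from the whole pre-birth
quiet segment; an incremental pre-window estimate is used for bare
arrays. The short pre-window variant is noticeably worse — a robust SD
from ≤ 15 samples is underestimated often enough to produce ~2 % false
onsets — which is why the track-aware path exists.

**Onset fraction, L and T1.** The onset fraction is the smoothed,
baseline-subtracted green value at T2 over the smoothed green maximum.
The reference level L is the cohort mean green-intensity-at-onset; T1 is
the first time the smoothed green trace sustainedly (2 consecutive
frames) reaches L. The T2-on-T1 ordinary least squares regression is run
on times measured from each event's measured green birth, so it reflects
per-event durations, not when in the movie events started. Note a
statistical property, not an implementation artifact: with per-event
amplitude scatter, a fixed *fraction-of-own-max* coupling is not a common
absolute level, and the regression slope is attenuated (errors in
variables). The switch-coupling validation therefore uses equal
amplitudes — where fraction-of-max coupling *is* level coupling — and a
wide lifetime spread, recovering slope 0.93–0.95 with R² ≈ 0.98.

**Delays and colocalization.** The arrival delay is T2 minus the measured
green birth (the lifetime run start); its recovery bias is about −1 s
(the green threshold crossing trails the true onset by more than the red
one, because the green ramp is slower). A static green track counts as
transiently colocalized with a motile red track if they are within 3 px
for ≥ 2 frames; percentages are reported to one decimal.

**Group comparisons.** `mann_whitney_u` wraps the SciPy implementation:
exact p by full enumeration of the U distribution when the pooled size is
≤ 12 without ties, otherwise the normal approximation with continuity
correction and midrank ties; two-sided throughout. No multiple-testing
correction is applied (single pairwise contrasts).

## Validation problem sizes

The end-to-end checks use 112 events over 14 cells per lifetime cohort
(recovery within 2 SEM of the generating mean), 55+ paired events over
7 cells for the onset-fraction and T1/T2 experiments, 216 events over
20 cells for the double-mutant motility condition, and 80 paired events
over 10 cells for the delay condition; movies are 96×96 px at 100–260
frames. These sizes put sampling error comfortably above estimator bias
while the whole acceptance run stays around a minute on one CPU.

## Known limitations

- The lifetime estimator underestimates slow-rise events (see above);
  cohorts with lifetime SD ≫ frame interval inherit a small negative bias.
- Onset fractions inherit the +2–4 point discretization overshoot of a
  first-frame-at-threshold coupling; at 1 frame/s and ~15 s rises this is
  sub-frame physics, not removable by the estimator.
- Segmentation assumes one roughly convex cell per movie with interior
  brighter than exterior; multi-cell fields must be cropped upstream.
- The tracker has no motion model and no merge/split handling; it is
  built for sub-pixel-per-frame cortical patches, not fast cytoplasmic
  traffic (comet leading tips at the default 0.5 px/frame are fine).
- Whether the cortical band should be aggregated by mean or maximum when
  unrolling the cortex is not derivable from published descriptions;
  circumferential kymographs use a max projection over the band (robust
  to a patch sitting slightly off the fitted boundary), radial ones a
  mean over a narrow width. Both are fixed and documented here.
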