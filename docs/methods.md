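# Methods

This note documents the models and procedures implemented in
`retinawaves`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the package's known limitations.

## ΔF/F and grid ROIs

The baseline image `F0` is the per-pixel temporal median of the stack —
robust to transients as long as a pixel is active in fewer than half of
the frames.  `ΔF/F = (F − F0)/F0`; pixels with `F0 ≤ ε` (default
`ε = 1e-6`, configurable) are flagged invalid and excluded from every
downstream mean rather than emitting NaN/inf, because dark sensor
regions and areas outside the tissue are routine in whole-mount
recordings.

Grid ROIs are squares of `roi_size_um` (default 10 µm) at pitch
`roi_size_um + gap_um`.  The default gap is 7 µm; an alternative reading
of "1.5 pixels apart" at the binned 5.9-µm pixel pitch (gap ≈ 8.9 µm) is
supported by setting `gap_um` accordingly — the two conventions differ
only in ROI count, not in any per-ROI quantity.  Geometry is
pixel-centred (origin top-left, x rightward, y downward, half-open pixel
footprints); a pixel belongs to an ROI when its centre does.  All ROI
geometry is carried in µm so that analyses are invariant to binning.

Spatial binning (`bin_movie`) is block averaging; trailing rows/columns
that do not fill a block are dropped with a warning, so the global mean
is conserved exactly up to those edges.

## Transient detection

Per ROI, the baseline noise SD is estimated as `1.4826 × MAD` over the
whole trace — the median absolute deviation is insensitive to the sparse
transients riding on the baseline, so no explicit baseline segmentation
is needed.  The detection threshold is `max(k_sigma · SD, floor_dff)`
with `k_sigma = 10` and `floor_dff = 0.10` ΔF/F; the absolute floor
guards the degenerate zero-variance case and encodes the convention that
a transient means at least a 10 % fluorescence change.

Peaks are located with `scipy.signal.find_peaks` using three
constraints: height ≥ threshold, separation ≥ `min_separation_s`
(default 1 s, preventing double counts from frame-scale jitter), and
**prominence ≥ threshold**.  The prominence constraint is a deliberate
design choice: with indicator decay times of ~1.5 s, noise ripples on
the decaying shoulder of a genuine transient sit above the absolute
threshold for ~2–3 s and would otherwise be counted as separate events,
grossly inflating the sub-20-s part of the ITI distribution.  Requiring
a peak to rise by at least the threshold relative to its surroundings
removes these shoulder artifacts while leaving isolated transients
untouched.  No smoothing is applied before detection.

ITIs are successive peak-frame differences divided by the frame rate
(seconds).  Histograms default to 20-s bins over 0–200 s with intervals
beyond the last edge reported in a separate overflow row.

## Wave segmentation

The population-activity trace is the percentage of ROIs with a transient
*peak* in each frame, z-scored against the whole recording.  Waves are
local maxima with z ≥ 1 separated by ≥ 12 s; peaks within 6 s of either
recording end are discarded as edge cases.  Tying the minimum peak
separation (12 s) to the participation window (± 6 s) prevents one wave
from being counted under two peaks.

A ROI participates in a wave when it has ≥ 1 transient within ± 6 s of
the peak; where windows overlap, a transient counts only toward its
nearest peak (ties to the earlier).  Area = participating ROIs as a
percentage of all ROIs.  Events whose participating-centroid bounding
box is within 160 µm on **both** axes are *non-propagating (local)*:
they are excluded from area and frequency summaries but their transients
remain in the ITI statistics.  An additional reporting split of
propagating waves into small (≤ 25 % area) and large (≤ 90 %) is
available as a threshold on `area_pct`; it is not a separate algorithm.

**Initiation site** = component-wise spatial median of the centroids of
all ROIs whose first in-window transient falls in the earliest
activation frame.  If two such ROIs lie > 200 µm apart the event is
flagged `ambiguous_initiation` (e.g. two simultaneous seeds); the site
is still reported.

**Speed** is this package's own definition (validated against ground
truth, see below): each participating ROI contributes the point
(activation latency, distance from initiation site), and the speed is
the median of per-ROI distance/latency ratios — a through-origin
Theil–Sen slope, robust to stragglers and re-activations.  The constant
kinetic delay between membrane depolarization and the fluorescence peak
cancels in the latencies, so indicator kinetics do not bias the
estimate.  Speed is reported as absent when the event has < 10 ROIs,
< 3 distinct activation frames, a latency span < 0.3 s (synchronous
events have no measurable front), or degenerate geometry.

`summarize_speeds` reports the arithmetic mean and the n−1 sample SD, as
used for the packaged reference table of per-wave speeds.

## Participation bootstrap

The test statistic is the **mean** ΔF/F over a window (not the maximum):
it is symmetric between null and test windows and robust to single-frame
noise.  For each cell, 1000 windows of wave-window length are drawn
uniformly with replacement from start frames whose full window contains
no wave frame; the cell's 95th percentile of these window means is its
participation threshold for every wave (one null per cell, not per
wave — the windows are exchangeable under the null, and reusing the null
keeps the per-cell test size at 5 %).  Wave windows truncated by the
recording edge are excluded from the denominator.  Response amplitude is
the window **maximum**, averaged per cell over participated waves and
then over cells for field-of-view summaries; the group-comparison layer
is a plain two-sample t test on per-cell metrics.

## Mosaic statistics

Quadrat density: 200-µm squares tiled from the field origin; squares not
fully inside the boundary, or touching an exclusion mask, are ineligible;
a seeded random subset (default 50) is drawn without replacement and the
density is the mean count divided by the quadrat area.  Densities are
reported per mm² (a soma mosaic at hundreds of cells per µm² would be
physically impossible).

NND uses a k-d tree with no edge correction, matching common practice
for these analyses; the regularity index RI = mean(NND)/SD(NND) with the
n−1 SD convention (consistent with the speed summaries).  For an
unbounded Poisson process the NND is Rayleigh and RI = √(π/(4−π)) ≈
1.913 independent of density; in a bounded window without edge
correction the empirical mean RI at n = 1000 sits ≈ 0.04 below this
value because boundary points have inflated NNDs (this is visible in the
validation studies and is a property of the uncorrected estimator, not a
bug).  The median NND is reported alongside the mean; the RI uses the
mean.  The Monte-Carlo reference (`random_mosaic_reference`) simulates
hard-core mosaics with minimum separation equal to the soma diameter
(7–10 µm for the cells this emulates) at the observed density and
reports the RI mean, SD and central 95 % band; RI is computed on all
points without subtype resolution.

## Synthetic generators

`simulate_movie` renders a constant-baseline field on which each event
adds `baseline · A · k(t − t_act)` per covered pixel, with
`k` a difference of exponentials normalized to unit peak
(`tau_rise = 0.2 s`, `tau_decay = 1.5 s`, GCaMP6s-like) and `A = 0.5`
ΔF/F.  Propagating waves are circular fronts of constant speed from a
uniformly placed initiation site, grown until their footprint covers the
target fraction of field pixels (clipping at the field boundary is
recorded); local events are identical but capped at a ≤ 160-µm extent.
Activation times are quantized to the frame grid.  Additive Gaussian
noise (default SD = 1 % of baseline) is applied to intensities.
Identical config + seed gives a bit-identical movie, and every event is
returned with its true time, site, speed and realized footprint.

Wave timing defaults to an exponential (memoryless) interval model with
mean 80 s; `fixed` and `gamma` schedules are available.  The ITI
validation study uses the gamma schedule (shape 8, mean 80 s): a peaked
ITI distribution — as observed in these recordings — implies
refractory-like regularity between waves, which a memoryless schedule
cannot produce (its ITIs have mode zero).  Transient amplitude is
constant across cells; amplitude heterogeneity is left as a free
parameter because no empirical distribution is available.

What the movie generator does **not** emulate: wavefront anisotropy or
curvature changes, photobleaching, motion (input is assumed registered;
motion correction is an upstream external step), raster-scan timing
skew, and indicator saturation.  Passing the validation studies
therefore demonstrates correctness of the measurement chain under these
idealized conditions, not robustness to every artifact of real
recordings.

`simulate_mosaic` draws a Poisson point count at the target intensity
and places points by sequential-inhibition dart throwing under the
hard-core constraint (plain uniform sampling when the constraint is
zero), failing explicitly — naming the achieved density — if the attempt
budget is exhausted (random sequential packing jams near 55 % disc
occupancy, well below the static feasibility bound).  `thin_mosaic`
keeps each point independently, emulating developmental cell death;
thinning preserves hard-core constraints and maps Poisson patterns to
Poisson patterns.

## Validation-study design (problem sizes and their rationale)

- **Speed recovery**: one wave per movie on a 1.5 × 1.5 mm grid at
  10 Hz, footprint 17 %, initiation pinned at field centre.  The
  footprint is kept moderate so the slowest fronts (80 µm/s) finish
  crossing within the ± 6-s participation window; a footprint whose
  crossing outlasts the window truncates the early latencies and biases
  a through-origin fit.
- **Area recovery**: one wave per movie on a 1 × 1 mm grid, footprints
  10–90 %, sites in the central half of the field and speeds
  200–250 µm/s so even 90 % footprints finish within the window.
- **ITI structure**: an hour at 10 Hz on a 400-µm field with 95 %
  footprints, so nearly every ROI sees nearly every wave; gamma
  schedule as above.
- **Classification**: waves (25 % footprint) and local events (40–60 µm
  radius) alternating 25 s apart on a 400-µm field.  Events are
  explicitly scheduled rather than random so each is resolvable by the
  12-s peak-separation rule; local events below ~1.5 % field coverage
  can drop below the z ≥ 1 population-activity threshold altogether
  (a sensitivity limit of the wave detector, distinct from
  classification).
- **Bootstrap calibration**: trace-level synthesis (100 cells, 20 waves,
  1000 bootstrap windows); the null call rate checks the 5 % test size,
  the programmed-response rate checks power.
- **Mosaics**: 100 Poisson mosaics of ~1000 points for the RI constant;
  a 3 × 3 mm hard-core mosaic at 600/mm² for the quadrat estimator.

These sizes keep each study to seconds-to-a-minute of compute while
leaving estimator errors (a few percent) far smaller than the tolerances
being checked.

## Known limitations

- The wave detector counts *peak frames*, so the percent-active trace of
  a slow wide wave is a plateau rather than a spike; very small events
  on very large fields can fail to reach z ≥ 1 (see above).
- Speed estimation assumes a single initiation site and a roughly
  isotropic front; colliding or merging waves are not split.
- NND/RI carry uncorrected edge effects (≈ 2 % at n = 1000); comparisons
  should use matched field geometries, as the validation studies do.
- The participation test controls the per-cell error rate at 5 %; no
  multiplicity correction across cells is applied.
- Movies are processed in memory as float32 (a full-scale
  800 × 800 × hour-long stack is large; analyses at that scale should
  tile or crop upstream).
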