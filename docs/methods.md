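# Methods

## The measurement problem

Fluorescence time-lapse of *Chlamydomonas*-like cells is dominated by
chloroplast autofluorescence: photosynthetic pigments excite and emit so
broadly that they register in GFP/YFP detection channels, while GFP/YFP do
not register under RFP detection.  The pipeline therefore treats the red
channel as a pure autofluorescence reference and models every reporter
pixel as reporter plus a fixed multiple of the reference.  Everything
downstream — totals, concentrations, kinetics, event scoring — operates on
the unmixed residual.

## Unmixing model and estimator

Per pixel, `G = F·R + k·CYC`, with `F` the green-per-red bleed ratio and
`k` an arbitrary scale fixed at 1 (all reporter quantities are in
arbitrary units).  `F` is re-estimated for every frame so that slow lamp or
exposure drift cancels; the estimate is the mean of per-pixel `G/R` over
the top `top_fraction` (default 0.01) of reference pixels, which in these
cells sit in the posterior chloroplast cup and carry no reporter.

Two numerical choices matter:

* **Ranking key.**  Pixels are ranked on a Gaussian-smoothed (σ = 2 px)
  copy of the reference image, not raw values.  Selecting the brightest
  *raw* pixels preferentially picks upward shot-noise excursions; since
  those same excursions sit in the denominator of `G/R`, the estimate of
  `F` is biased low by roughly `σ_noise/μ_top`, leaving a spurious positive
  unmixing residual (in our noise regime, a ~40-standard-error bias in the
  mean residual of reporter-free frames).  Smoothing only the ranking key
  decorrelates selection from per-pixel noise and removes the bias; the
  ratio itself remains per-pixel.  `rank_sigma=0` restores raw ranking.
* **Signed residuals.**  Unmixed images are kept signed and written as
  32-bit float TIFF; clipping negatives at zero would bias every total
  upward.  Clipping is for display only.

A `sum_ratio` estimator (ratio of summed green to summed red over the top
set) is available; it is slightly less noisy but the mean-of-ratios form
is the default.  The z-blur used before maximum projection of z-stacks is
the symmetric (0.5, 1, 0.5) kernel along z, truncated at stack boundaries.

## Thresholds and masks

Both histogram thresholds are implemented from scratch because their exact
behaviour is part of the contract, and both are verified against
exhaustive brute-force oracles in the test suite:

* **Intermeans (IsoData variant)** — iterate `t ← (mean below t + mean
  above t)/2` from the global mean until the change is below one bin.
  Used (after a 1.5-px Gaussian blur) for the "peak" mask holding polar
  dots, spindle and furrow.
* **Triangle** — the bin of maximum perpendicular distance from the line
  joining the histogram peak to the far end of its longer tail, ties
  toward the peak.  Used (after a 2-px blur) for the cell-body mask from
  autofluorescence; the strong blur deliberately expands the mask over the
  cortex.

Blur radii are interpreted as Gaussian σ.  Float images are histogrammed
into 256 bins spanning min–max, reproducing 8-bit behaviour
deterministically.  Cytoplasm = cell AND NOT peak, so the cytoplasm and
peak regions never overlap.  Background is the mean intensity over
non-cell pixels and is subtracted uniformly.

For *region traces* of transient structures the mask set is built **once**
from a reference frame and applied to the whole movie
(`build_static_mask_set`; the reference is the frame with the brightest
extended structure, i.e. the spindle frame).  Built per frame, the
threshold would put the moving comets themselves into the peak mask and
the cytoplasm trace could never show comet suppression.  Event scoring, by
contrast, uses per-frame masks, since the structures it classifies change
from frame to frame.

## Half-signal hull

Pixels in the cell region are ranked by intensity (ties in raster order)
and the smallest prefix holding ≥ 50% of the total is selected; the
greedy prefix is provably the minimal-area choice for radially decreasing
blobs, and the exact minimum over all half-mass subsets is combinatorially
infeasible.  The hull area is reported as the number of pixel centres
covered by the hull polygon (discrete area, px²) rather than the shoelace
area of the centre polygon: by Pick's theorem the centre polygon loses
about half a pixel per boundary pixel, which for a σ = 5 px Gaussian blob
is a 15% underestimate of the analytic half-mass disk, while the discrete
area matches it to ~0.1% and keeps `concentration = signal / pixels of
support` a true per-pixel density.  Degenerate selections (single pixel,
collinear set) use the pixel count as area.

## Kinetics

Landmarks: the baseline segment grows from the first frames while values
stay inside `median + 3·MAD` of the segment so far; onset is the first
frame above the band, the peak the maximum before the trace first returns
to the band, and the trough that first return.  The detector is
deterministic and needs no tuning on noiseless data because the band
collapses to a relative tolerance.

The half-life fit is ordinary least squares of `ln(y − baseline)` against
time over the frames from peak to trough that lie strictly above baseline:
`t½ = ln 2/|slope|`, with r² reported.  It is exact on noiseless
exponential decays.  Two caveats are inherent to sampling: the
frame-quantized "peak" of a piecewise trace may sit on the linear rise
rather than the decay curve (fitting from `peak + 1` avoids this at the
cost of one point), and at 3-minute frames a ~3-minute half-life leaves
only 3–5 usable points, so single-trace estimates scatter by tens of
percent while cohort means converge.

Trough-to-division intervals are plain frame differences times the frame
interval and may be negative; at 3-minute sampling a ~1-minute lag
quantizes to 0 or 1 frames.

## Event scoring

Connected components of the peak mask are classified per frame:

* **PS** — ≥ 2 compact foci near the anterior reference whose pairwise
  distance lies in `[d_min, d_max_factor × radius]` (defaults 3 px and
  0.6).  The lower bound resolves genuinely split poles; the upper bound
  rejects the anterior dots of separate sibling cells after a division.
  The anterior reference is the recurring compact-focus position over the
  first frames — the polar dot stays put while comets appear at fresh
  positions every frame.
* **SP** — a component with major axis ≥ the cell radius (continuous
  across the midline).  Its orientation is recorded as the spindle axis.
* **SPB** — the first later frame with no component within ±20° of that
  axis.  The furrow, perpendicular to the axis, therefore cannot mask the
  breakdown.
* **CF** — a dark brightfield line, or an elongated component
  perpendicular (±20°) to the recorded axis.  After CF, scoring waits for
  the furrow signal to fade before rescanning, and the cycle index
  increments.

Censoring follows the published bookkeeping: a spindle never seen scores a
zero-frame duration only when the preceding PS was clearly visible; cells
with neither PS nor SP are excluded from interval statistics, which report
mean ± sample s.d. with the number of qualifying cells, or ND when none
qualify.  Frame-quantized duration scoring is unbiased under uniform
phase: the expected tick count in a length-L window on a Δ grid is L/Δ.

## Synthetic movies

The generator is the ground-truth source for every stage.  Geometry: a
circular cell (radius 40 px at 0.2 µm/px ≈ 8 µm) centred in a 128×128
frame; a cup-shaped posterior chloroplast whose red intensity rises toward
the posterior rim (base 800 counts across the body, up to ~3200 in the
cup), so the brightest ~1% of red pixels are guaranteed pure; a soft-edged
anterior nucleus whose rendered sum equals the kinetic trace exactly.
Divisions are synchronous among siblings and the rendered outline remains
the mother footprint, matching how real movies are quantified.

Kinetics defaults are the observed values: 20 min linear accumulation,
3 min degradation half-life, 1.2 min trough-to-division lag, 30 min
between divisions, 0–3 divisions.  The exponential cannot literally reach
baseline, so decay runs until the amplitude falls to `decay_end_fraction`
(default 0.15) of the peak and then snaps to baseline at the trough;
0.15 is the largest floor for which one full cycle (20 + 8.2 + 1.2 ≈
29.4 min) still fits inside the 30-min inter-division interval, keeping
the defaults mutually consistent.

EB1 structures follow the observed choreography: an anterior polar dot
(σ = 2 px, 12 000 counts) splits into two foci (initial separation 10 px —
enough to resolve as two components at the spindle-frame threshold —
separating at 2 px/min); 4 min later a spindle bar (length 1.2 × radius,
15 000 counts) crosses the midline; it lives 4 min; the furrow line
appears perpendicular to it 1.5 min after breakdown, coincident with
division, and also darkens the optional brightfield channel.  Cortical
comets (Poisson, 6/frame, 5 000 counts — deliberately dimmer than
spindle/dots, as in real movies) plus a diffuse cytosolic pool
(30 counts/px) populate the lateral cortex and are suppressed to 30% while
a spindle exists, mirroring EB1 redistribution onto the spindle; comets
avoid the anterior cap (keeping the polar dot unambiguous) and the
posterior rim (keeping the bleed-ratio pixels pure).  Camera noise is
Poisson on expected counts plus Gaussian read noise (σ = 5).  One master
seed feeds named child streams (structures, camera), so identical seeds
give byte-identical movies.

Presets encode the mutant phenomenologies: `apc_mutant` (APC inactivated)
accumulates reporter without degradation, reaches PS and SP, and keeps a
stable spindle indefinitely with permanent comet suppression;
`cycb1_mutant` shows only the persistent anterior dot and no accumulation;
`cdkb1_mutant` accumulates without precipitous degradation and, like the
cyclin null, fails spindle morphogenesis.

**What the simulator does not emulate** — and hence what passing tests do
not certify on real data: true cell geometry and chloroplast optics,
photobleaching, cell motility and hatching, focus drift, spatially varying
bleed ratios, and comet motion within a frame.  The generator exists to
validate the algorithms (does the pipeline recover known inputs?), not to
mimic any particular microscope.

## Problem sizes

Default test and acceptance workloads: 20-frame noiseless movies for
exactness checks; 100 reporter-free frames for unbiasedness; 200 random
histograms per threshold oracle; 1000 random images for hull containment;
15 noisy traces per half-life; 10 000 phases for duration scoring; 25–50
seeded wild-type movies (120 frames at 20-s intervals, 128×128) for event
recovery.  These sizes give comfortable statistical margins for every
bound the suite asserts.

## Known limitations

* Multi-cycle event scoring aggregates sibling spindles per cycle
  (earliest per cycle); per-daughter lineage tracking is out of scope.
* `F` estimation assumes some pure-reference pixels exist; movies whose
  reporter covers the brightest reference regions will bias `F` upward
  (the overlap sweep in the test suite quantifies this monotone error).
* The half-signal hull is greedy; for strongly non-convex or multi-focal
  signal distributions (e.g. separated daughter nuclei) the hull spans the
  foci and the concentration reads low — the same behaviour the manual
  analysis exhibits.
* Landmark detection presumes the trace starts at baseline; movies that
  begin mid-degradation yield no onset and an empty landmark set.
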