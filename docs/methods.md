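# Methods

## The measurement model

`pmscan` quantifies membrane recruitment of a fluorescent reporter as a
*local* PM/cytoplasm intensity ratio.  The design premise is that in a
field of hundreds of cells, absolute intensities vary over an order of
magnitude (expression level, focus, illumination), but the ratio of
membrane-local to adjacent-cytoplasm intensity within one cell is
invariant to any multiplicative intensity change.  The pipeline
therefore guarantees, and the test suite enforces, exact gain invariance
of every ray ratio and approximate invariance to additive offsets after
background subtraction.

### Segmentation

1. **Background subtraction** — per-channel morphological grey opening
   with a square structuring element spanning 4× the expected cell
   radius (default radius 16 px → 129 px element).  The opening removes
   constant offsets and smooth gradients exactly, so thresholds operate
   on signal above local background.  A separable square element is
   used instead of a ball for speed on full-scale fields; offsets are
   removed identically.
2. **Centroids** — one of three strategies, selectable per run:
   the *nuclear hole* left by a reporter excluded from the nucleus, the
   dark *void* enclosed by a membrane-only reporter's ring, or a bright
   *nuclear marker*.  Each thresholds the smoothed channel (Otsu),
   labels blobs, drops blobs under 30 px² or touching the image border,
   and takes intensity-weighted centers (inverted weights for
   holes/voids).  Otsu on a background-only field would split pure
   noise, so a detection is only accepted when the threshold clears 6×
   the robust (MAD-based) noise scale.
3. **PM mask** — Otsu-thresholded membrane band, skeletonized to a
   ≤2 px ridge.
4. **Territories** — watershed flooding from centroid markers over an
   elevation map of distance-to-nearest-centroid plus a high barrier on
   the PM ridge.  Territories meet at the equidistance line in open
   background but cannot cross a closed membrane ring (geodesic
   preference), which keeps all per-cell statistics on the right side
   of shared boundaries.
5. **Border cells** — a cell is flagged when its PM ring is interrupted
   by the image edge, detected as: hole-filling the PM ridge does not
   cover the centroid.  (Territory-touches-border would over-drop,
   since territories tile the whole image.)

### Radial scan

From each centroid, `n_rays = 360` rays at 1° spacing, sampled
bilinearly at 0.5 px steps.  A ray terminates at its first crossing of
the PM mask inside the cell's territory.  The crossing is then refined
to sub-pixel precision on the *membrane-intensity ridge*: the skeleton
of an even-width band can sit ~0.5 px off the true centerline, and for
rays over a depleted band a misplaced window biases the max-estimator
upward, so the crossing is moved to the parabolic peak of the smoothed
membrane profile along the ray (falling back to a parabolic fit of the
mask response when no membrane channel exists).

* `I_PM` = maximum reporter sample within ±`w_pm` = 1.5 px of the
  crossing (robust to residual mask placement error);
* `I_cyto` = mean over a `w_cyto` = 5 px window starting `gap` = 3 px
  interior to the crossing.  The gap is the sum of half the band width
  (1.5 px), the discretized band edge (0.5 px) and 2σ of the soft
  optical edge (1 px), so the window clears the band's blurred tail.
  Samples inside the 1 px-dilated nuclear mask are excluded — in small
  cells the window can reach the nucleus, and a nucleus-excluded
  reporter would otherwise deflate the denominator; rays with fewer
  than 3 remaining samples are invalid.
* Rays that exit the territory or image before crossing, whose window
  does not fit, or whose denominator hits the zero floor are recorded
  with a reason code (`no-crossing`, `out-of-bounds`,
  `zero-denominator`); the ratio is only defined for valid rays.

These window parameters are not dictated by the assay itself; they are
measurement-design choices, fixed so that the identity case (uniform
reporter → ratio 1.000) and noiseless enrichment recovery hold, and all
are exposed in `RayScanParams`.  An independent dense-polar oracle (in
the test suite) recomputes the same ratio from the analytic cell
geometry without any segmentation; implementation and oracle agree
within 0.02 across random noiseless cells.

Per-cell ratio = mean of valid ray ratios (median available as a
policy).  QC drops cells by border contact, <50% valid rays, territory
area outside bounds, or ratio outside a sanity window (0.1–20), each
with a deterministic reason code.  Field summaries report mean, SEM
(sample SD with the n−1 denominator over √n) and counts.

### Nuclear readouts

`nuc_cyto_ratio` computes, per cell, mean reporter intensity over the
1 px-eroded nucleus divided by the mean over the cytoplasm zone (inside
the cell's closed PM ring, minus the dilated PM band and nucleus,
restricted to the territory), and averages ratios per field
*cell-first*.  `bulk_nuc_cyto_intensity` pools all nuclear and all
cytoplasmic pixels of the image with no per-cell step — the two
conventions differ whenever cell areas are unequal, and the test suite
distinguishes them on a constructed unequal-area field.

## Statistical layer

* **Dose–response**: four-parameter logistic on log10 dose, least
  squares with multi-start over Hill-slope sign and midpoint grid;
  `R² = 1 − SS_res/SS_tot`; flat curves are flagged rather than fitted;
  EC50s outside the dosed range are marked extrapolated.  The
  parameterization is symmetric under `h → −h` with top/bottom swapped;
  fits report the direction via `sign(hill)·sign(top − bottom)`.
* **Kinetics**: `y(t) = y0 + A(1 − e^{−k(t−t_lag)})` for `t ≥ t_lag`.
  Joint least squares is non-smooth in the lag, so the lag is profiled
  over the observed frame times and then refined continuously between
  the bracketing frames; `(y0, A, k)` are fit conditionally with
  `k > 0` bounded.
* **Z-factor**: sample-moment plug-in `1 − 3(σ₊+σ₋)/|μ₊−μ₋|`;
  undefined (None, not a number) when the means coincide.  Invariant
  under common affine transforms of both groups.
* **Group comparison**: Welch (unequal-variance) two-sided t-test; the
  degenerate all-identical case returns an explicit undefined marker.
* **SEM** uses the sample SD (n−1).  Note `sem([0, 2]) = 1.0` under
  this convention.

## Synthetic data: what it emulates and what it does not

Cells are rendered as mild ellipses (eccentricity ≤ 0.3, default drawn
from U(0, 0.2)) with a raised-intensity PM annulus of width 3 px, a
concentric circular nucleus at 42% of the cell radius, and a 0.5 px
Gaussian soft edge standing in for optics.  Default cytoplasmic
amplitude is 1000 AU, membrane 1500 AU, nuclear marker 800 AU, over a
100 AU background.  Camera noise has a signal-dependent shot component
(variance = 0.1 × intensity, i.e. ~1% at cytoplasmic amplitude — a
bright-confocal regime) plus additive read noise of SD 20 AU (2% of
cytoplasmic amplitude).  Radii are N(16, 1.5²) px clipped to [12, 20];
there is no stated physical pixel pitch in the emulated assay, so all
geometry is in pixels.

Dose series drive the per-dose *target* enrichment through the
four-parameter logistic exactly; time-lapse series drive per-frame
targets through the delayed exponential (with an optional second event
that redirects the trajectory toward a new plateau after a gap);
per-cell enrichments scatter normally (SD 0.05) around the target, and
each frame/field is rendered independently (population-level kinetics,
no cell tracking — matching the analysis, which also does not track).

Benchmark presets fix the study conditions: endpoint fields of 400
cells at 1448², dose-series fields of 200 cells at 1024² (10 doses,
2.52× dilution from 100 µM), and time-lapse frames of 70 cells at 600²
(3 pre-addition baseline frames; 3 min frames for the slow-onset
scenarios, 1.5 min for the fast ones).  The kinetic frame spacing
follows the 3-minute acquisition described for the slow-onset
experiments.  The time-lapse frame count × field size was chosen so a
full trajectory renders in about a minute; the field SEM (~0.006) is
far below the 0.4-unit response amplitudes, so onset estimates are not
resolution-limited.

Passing tests on these synthetics demonstrate that the *measurement
machinery* is unbiased and sensitive under the stated geometry and
noise; they cannot demonstrate robustness to everything real microscopy
adds — out-of-focus light and PSF anisotropy, membrane ruffling,
touching/overlapping cells, motility during acquisition,
photobleaching, debris.  Ring-shaped geometry is the strongest
assumption: cells whose equatorial section deviates grossly from a
closed convex ring will fail the closed-ring QC rather than be measured.

## Numerical choices and degenerate inputs

* Bilinear interpolation everywhere along rays; nearest-neighbor for
  label images.  Crossing detection samples the 1 px skeleton
  bilinearly with a 0.2 threshold so rays passing between diagonal
  8-connected pixels still register.
* Ties in nearest-centroid territory assignment resolve by flood order
  at equal elevation (watershed FIFO), which is deterministic.
* Zero-valued denominators are guarded by an explicit floor (1e-6 AU);
  empty fields, flat membrane channels, non-monotone dose vectors,
  shuffled frame orders and impossible placements all raise typed
  errors rather than propagating garbage.
* All randomness flows from a single integer seed per run
  (`numpy.random.default_rng`); identical seeds render bit-identical
  fields and byte-identical output tables.

## Known limitations

* No 3D, no PSF convolution, no photobleaching, no cell tracking.
* The radial scan presumes a star-convex cell around its centroid;
  strongly non-convex cells produce invalid rays and fail QC.
* The max-estimator for `I_PM` carries a small positive noise bias
  (max of correlated noisy samples); at default noise it is below
  0.01 ratio units and is the price of robustness to mask placement.
* Sub-pixel accuracy of the crossing relies on the membrane channel
  when present; with only a mask available, accuracy degrades to the
  skeleton's ±0.5 px.
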