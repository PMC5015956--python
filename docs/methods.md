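# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `colonyscan`, and what the synthetic-plate tests do and do
not establish about real scanner data.

## Plate geometry and the reference grid

Pinning formats follow the SBS doubling series: 96 = 8×12, 384 = 16×24,
1536 = 32×48.  Indexing is 0-based and row-major with row 0 at the image
top and col 0 at the left.  When a 384 array is replicated four-fold onto
a 1536 plate, each source position becomes a 2×2 tetrad; the control rule
reserves the lower-right position of every tetrad, i.e. all (odd, odd)
positions — exactly a quarter of the plate, evenly spaced, and absent
from the row-0 and col-0 edges.  Spatial-bias correction is therefore
expected to be weakest along those two edges, where the surface must be
extrapolated.  Adjacency, wherever the notion is needed, is the
8-neighbor Moore scheme.

## Calibration

Two polynomial maps, both fitted by ordinary least squares from supplied
pair tables (strip localization on images is out of scope):

* **Pixel opacity** — raw intensity → standardized opacity, default
  degree 3, fitted from the per-segment mean intensities of a gray-scale
  strip against the manufacturer's opacity values.  The fit must be
  strictly monotone over the data range (checked on a dense grid;
  violations are rejected) so pixel ordering is preserved.  Out-of-range
  pixels at evaluation are clamped and counted rather than rejected,
  because plates can contain specular artifacts.
* **Cells per pixel** — background-subtracted opacity → cell count,
  default degree 5 with the intercept constrained to zero (no colony, no
  cells); negative predictions are clipped at evaluation.

Degrees are defaults of this package, configurable; the map shapes (a
low-order polynomial each) are the method's substance, the exact degrees
are not.

## Image analysis

Analysis is reverse-chronological: the virtual grid is fitted on the
last image of the series, where colonies are largest, and reused with
fixed centers for all earlier images, where faint colonies could not be
localized independently.

* **Gridding** — Otsu threshold, connected components, per-axis robust
  lattice fit of the component centroids: cluster the sorted coordinates
  by gap splitting, estimate the spacing from inter-cluster gaps (integer
  multiples absorb missing lattice lines), refine offset and spacing by
  least squares on (integer index, cluster center), and generate the full
  rows×cols lattice — including positions with no visible colony.  Blank
  or aperiodic images raise a gridding failure.
* **Segmentation** — per window: Otsu threshold with two guards.  A
  minimum-contrast guard (window range < 5 opacity units) declares "no
  colony"; and the threshold is floored at window median + 5×scaled MAD,
  because Otsu alone misplaces the threshold inside the background noise
  when the colony covers only a few pixels (observed failure mode on
  early-timepoint windows).  The above-threshold component nearest the
  window center seeds the colony and is grown down to just above the
  background level (hysteresis), so dim colony rims are not counted as
  background.  A 2 px dilation ring (safety margin) plus all other blobs
  are "trash" — assigned to neither colony nor background.  The three
  masks partition the window by construction.
* **Measurement** — background level = median opacity over background
  pixels (robust to residual blob pixels); population = Σ over colony
  pixels of the cell calibration applied to (opacity − background), each
  pixel clipped at zero.  Empty-background windows yield an invalid
  (NaN) measurement rather than an abort.

## Growth features

* **Smoothing** — median filter (window 5) then Gaussian filter
  (σ = 1.5 samples), applied to log2(population): growth and its
  measurement noise are multiplicative.  Edges are handled by padding the
  log2 series with a linear extrapolation of the local trend before
  filtering; this leaves exactly exponential stretches — including the
  endpoints that feed the initial-population and total-doublings
  features — invariant, where reflected-edge convolution would bend
  them.  Curves with non-positive values fall back to linear-space
  filtering; curves shorter than the median window pass through and are
  flagged.
* **Minimum doubling time** — OLS slope of log2(population) against time
  over every run of 5 consecutive timepoints with positive values;
  dt_min = 1 / (maximum slope), in hours per doubling.  Ties are broken
  by the earliest window center.  The standard error of the winning
  slope is retained as a quality index.  At the default 20-min sampling
  a 5-point window spans 80 min, so the secant slope understates a
  smooth sigmoid's instantaneous maximum by under 2% — while noise makes
  the max-over-windows selection overstate it, by more for slowly
  growing colonies (the same absolute slope noise is a larger relative
  error on a shallow slope).  The net effect at default noise is a small
  (≲ 0.1 log2) compression of strong negative phenotypes; it is visible
  in the handicap-recovery tests and is inherent to the extraction
  definition.
* **Chapman–Richards quality fit** — y(t) = y0 + (K − y0)(1 − b e^{−rt})^ν
  on log2(population), bounded least squares (0 < b ≤ 1, r > 0, ν > 0)
  with analytic Jacobian and 8 deterministic multi-starts.  The RMSE in
  log2 units is a quality index only; non-convergence yields an infinite
  sentinel plus a flag, never an exception, and the fit never feeds the
  phenotype itself.
* **Flags** — raised when the regression SE exceeds 0.02 log2/hr, the
  sigmoid-fit RMSE exceeds 0.10 log2, or the winning window sits at
  either end of the series.  The thresholds sit several-fold above the
  index distributions of clean simulated curves at ~2% measurement noise
  (SE ≤ 0.005, RMSE ≤ 0.015), so ordinary curves pass while signal-free
  curves are reliably caught (chiefly by the RMSE index).  Flagging is
  per-index; no combined quality-ranking score is computed.

## Normalization

* **Control outliers** — controls outside median ± 3×scaled-MAD of
  log2(dt) are removed; more than 50% removed aborts the surface.
* **Surface** — Gaussian-kernel local-polynomial regression of the
  retained controls' log2(dt) on (row, col), evaluated at every
  position, exponentiated back to hours.  Interpolation happens in log2
  space, where multiplicative rate bias is additive.  Defaults: local
  quadratic, bandwidth 6 index units (three tetrad spacings).  The
  choice is driven by an error budget: the surface's estimation noise is
  shared by adjacent colonies and therefore inflates the adjacency
  false-positive diagnostic, and with only a quarter of positions
  carrying controls that noise — not lack-of-fit to a softly undulating,
  plate-scale bias field — is the binding term.  A local quadratic is
  unbiased through third-order field structure and free of boundary bias
  on the control-free edges, so the bandwidth can be generous; with it
  the post-normalization false-positive rate on simulated 384-format
  plates averages ~8% at α = 5% versus ~9.5% for a local-linear smoother
  at one tetrad spacing.  A floor remains: n/4 controls of noise σ can
  never yield a surface with error below σ·√(p/n_controls), and that
  error is indistinguishable from true local bias to the diagnostic.
  Both order and bandwidth are configurable.
* **Relative phenotype** — rel = log2(surface/observed), so slower
  growth than the local expectation is negative (a growth defect).  The
  order of subtraction is fixed by that sign convention.
* **Between plates** — each plate's doubling times are shifted
  multiplicatively so its raw-control log2 mean matches the pooled
  control mean over all plates; shifts are logged and expected small.
* **Condition difference** — per-position stress phenotype minus basal
  phenotype, matched on (row, col) with strain identity verified,
  removing general growth defects from condition-specific effects.

## Diagnostics

For each focal experimental colony with ≥ 2 valid experimental Moore
neighbors: one-sample Student's t-test of the neighbor values against
the mean of all nonadjacent experimental values.  The nonadjacent mean
averages > 1000 colonies on a 1536 plate, so treating it as a fixed
reference rather than pairing each neighbor with a matched nonadjacent
colony is accurate to first order.  Controls are excluded
from focal, adjacent and nonadjacent sets; zero-variance neighborhoods
are skipped and counted; no multiplicity correction, by design — the
chance-expectation logic requires raw per-colony tests.  The
implementation is vectorized via neighborhood convolutions and verified
against literal per-focal scipy t-tests in the tests.  Plate CV is
100·sd/mean with the n−1 denominator; neighbor CV is the same statistic
within each focal neighborhood.

## Synthetic plates

The generator defines the study conditions for every test:

| parameter | default | meaning |
|---|---|---|
| mean_dt | 2.0 hr | plate-mean minimum doubling time (wild type, basal medium) |
| doublings | 5.0 | log2 growth span per colony |
| shape ν | 4.0 | sigmoid shape; gives a few hours of lag |
| bias_amplitude | 0.05 | log2 sd of the smooth rate-multiplying field |
| pinning_cv | 0.25 | lognormal CV of deposited initial cells (2·10⁴ mean) |
| noise_cv | 0.02 | multiplicative per-timepoint measurement noise |
| t_end, interval | 72 hr, 20 min | 217 timepoints; 7-min hardware floor enforced |

Each colony follows l(t) = l0 + D(1 − e^{−rt})^ν in log2 cells, with r
solved analytically so the steepest log2 slope equals 1/dt for that
colony's true doubling time; dt combines the plate mean, a per-strain
log2 handicap, and the bias field (which multiplies rate).  The bias
field is plate-scale by construction — random tilt, one half-period
cosine mode per axis, and their interaction, standardized to the target
log2 sd — reflecting the assumption of a softly undulating rather than
rugged bias landscape.  Rendering draws each colony as a paraboloid
opacity dome whose summed opacity equals its population exactly
(identity cell calibration) and whose radius grows as population^(1/3),
so footprint area grows far more slowly than cell count, as on real
transmissive scans; a flat background plus Gaussian pixel noise
(sd 2 opacity units on background 20) completes the image.

Deliberately not simulated: neighbor nutrient competition (extraction at
the time of maximal growth minimizes its influence, and modeling it
would need a reaction–diffusion substrate), scanner optics, light-stress
growth inhibition, agar drying, and pH fields.  Passing tests therefore
show that the algorithms recover known truth under realistic noise and
plate-scale bias; they do not certify behavior under strong colony–colony
interaction, rugged short-wavelength bias, or real scanner artifacts.

## Problem sizes and numerical choices

The full-pipeline recovery tests run three rendered 384-format plates at
the full 217-timepoint schedule with 16 px colony pitch — the package's
standard scaled-down configuration, chosen so a complete
render→analyze→extract→normalize cycle of each plate stays within a few
minutes on one core.  The null calibration of the adjacency diagnostic
uses 200 simulated 1536-format plates (the vectorized test makes this
seconds).  All randomness flows through seeded `numpy` generators;
reruns with the same seed are bitwise identical.  Degenerate inputs
resolve conservatively: empty colony masks give zero population, empty
backgrounds give invalid measurements, non-growing curves give NaN
doubling times plus flags, and surfaces refuse to build from fewer than
8 controls or fewer than 4 distinct control rows/columns.
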