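# Methods

This note documents the models behind `sourmon`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducing its outputs.

## Perfusion mass balance and sOUR

The culture sits in a chamber of working volume ~25 µL perfused at
Q = 300 µL h⁻¹, so the hydraulic residence time is about 5 minutes — far
below the hours-scale dynamics of growth and respiration. The oxygen
balance is therefore treated as quasi-steady: the outlet concentration is

    O₂,out(t) = O₂,in − sOUR(t) · X(t) / Q     (clipped at 0 µM),

and the analysis inverts this to OUR = Q·(O₂,in − O₂,out) (mol s⁻¹, with Q
converted to L s⁻¹ and concentrations to mol L⁻¹) and sOUR = OUR/X
(reported in amol cell⁻¹ s⁻¹). No spatial transport model is used; the
outlet sensor's dynamics are represented phenomenologically by a
first-order sensor lag (default time constant 3 min) plus a pure transport
delay (default 5 min, one residence time; configurable, since tubing dead
volume can make the real delay far longer).

Unit conventions are fixed package-wide: concentrations in µM
(1 mg L⁻¹ O₂ = 31.25 µM), flow in µL h⁻¹ at interfaces, sOUR in
amol cell⁻¹ s⁻¹. The sensor range is 0–45 mg L⁻¹ (1406.25 µM).

Negative sOUR values arise whenever sensor noise exceeds the true
inlet–outlet differential — typical of early cultures with few cells. They
are physically meaningless, so they are kept in the data with
`negative_flag=True` (auditable) but excluded from plots and plateau
estimation.

Raw OUR is smoothed by a centered rolling median over 5 samples (75 min at
the 15-minute sensing cadence) before division by X; the window is
config-exposed. The median was chosen over a mean for robustness to the
occasional unflagged excursion.

## Optical oxygen sensing

Phase-fluorimetric sensors report a luminescence phase shift that falls
with oxygen (dynamic quenching). The package uses the standard tan-phase
Stern–Volmer form for this sensor class,

    tan φ₀ / tan φ = 1 + K_sv · C,

anchored by a two-point calibration: a zero-oxygen (sulfite) stream and an
air-saturated stream, each accepted only when the trailing 3-minute phase
window stays within ±0.05° (max−min ≤ 0.1°). Any strictly monotone
two-point-anchored transfer function would satisfy the same contract; the
anchors are reproduced exactly by construction. Air-saturation
concentration defaults to 200 µM at 37 °C (configurable); the inlet
setpoint defaults to 215 µM.

Inlet/outlet spikes of instrumental origin occur at identical timestamps
on both channels, so they cancel in the differential. The despiker flags a
timestamp only when BOTH channels deviate from their rolling median
(window 7) by more than k = 5 channel MADs; flagged samples are excluded
from OUR smoothing while the raw differential is retained.

## Image analysis

Stage tiles are placed on a common canvas by translating calibrated stage
coordinates (µm per pixel scalar, optional y-flip; origin top-left,
row-major, 0-based). Overlaps are feather-averaged. Optional refinement
corrects stage jitter by an exhaustive integer-offset search (±5 px
default) minimizing the mean squared difference against the
already-placed canvas; on synthetic tiles with ±3 px jitter the residual
placement error is ≤1 px.

The stitched image is partitioned into a rows×cols grid (default 47×15 =
705 regions, matching the chamber geometry); remainder pixels are absorbed
by edge regions. Deselection of uninformative regions (in-situ sensor
footprint, uneven chamber edges) is data-driven — explicit indices, a
border ring, or rectangular blocks in a config — rather than GUI-manual. A
packaged synthetic layout (border ring + 13×6 central sensor block,
discarding 198 regions, retaining 507) stands in for a real chamber's
manual selection.

Pixel classification is a regularized logistic model over 7 handcrafted
features per pixel: raw intensity, local mean and SD at 3 px and 9 px
scales, Sobel gradient magnitude, and a Laplacian-of-Gaussian response at
σ = 2 px (sensitive to the bright halo rim of phase-contrast cells).
Features are standardized with training-set statistics; training subsamples
up to 40k pixels per class and reports held-out accuracy on a 25% split.
Ties at the decision boundary (score exactly 0) go to background — the
conservative choice for confluency. Post-processing removes connected
components below 30 px and fills holes below 100 px (both config-exposed;
the thresholds are conventional for ~600 µm² cells at 1 µm/px).

## Confluency, packing correction and density

Per-region confluency is the cell-pixel fraction; culture-wide confluency
is the unweighted mean over retained regions (edge regions differ slightly
in size; the unweighted mean mirrors the per-region bookkeeping and the
difference is negligible at 705 regions).

Raw confluency understates cell number once cells touch and overlap. The
packing-corrected confluency multiplies the raw value by a monotone
packing factor ≥ 1 (identity for isolated cells):

    density = confluency · pf(confluency) / footprint.

`pf` is a piecewise-linear monotone curve with ≤5 knots, and the footprint
is the pooled (count-weighted) covered-area-per-cell over low-confluency
fixtures (confluency ≤ 0.30, where cells are isolated and pf = 1).
Calibration requires ≥3 fixtures spanning ≥20% confluency and enforces
monotonicity by pool-adjacent-violators; it is unbiased on its fixture set
to within ±3% mean relative error. The pipeline calibrates on a dedicated
rendered sweep (9 frames, 5–80% confluency, deterministic in the run
seed) so that short runs spanning little of the culture arc still get a
full-range curve; real-data runs must supply a calibrated `PackingModel`.
A QC flag is raised when raw confluency exceeds 0.85, where the monolayer
assumption — and hence area-based density — degrades.

## Growth kinetics

µ = ln(X/X₀)/t and g = ln 2/µ, so g·µ = ln 2 exactly. Replicate spread uses
the population standard deviation (divisor n).

µ_max is extracted from the density series by log-linear least squares in
windows of 10 h (default). A diagnostic series `mu_t` uses a sliding
window at every sample, but µ_max itself is the maximum over
*non-overlapping* windows whose fit R² ≥ 0.95. The distinction matters:
dozens of overlapping windows share noise, and the maximum of many
correlated noisy slopes is badly biased upward (we measured +20–90% at 5%
multiplicative density noise, depending on the gating); with the handful
of independent windows the selection bias stays within ±10% even at 5%
noise, and vanishes for clean data. When no window reaches the R² gate,
the better-fitting half of the non-overlapping windows is used.

Lag is estimated by a flat-then-exponential breakpoint fit: every
candidate breakpoint on the sampling grid is scored by the residual sum of
squares of a constant-then-linear model of log density, and the best
breakpoint is the lag. On noise-free lag fixtures this recovers the true
lag to within one imaging interval (30 min).

## sOUR-vs-density and the plateau

sOUR points (negative- and spike-flagged excluded) are binned over
log-spaced density bins. The plateau estimate is the **median** sOUR over
densities above 5×10⁴ cells cm⁻² (default; config-exposed). The median is
robust to the transient sOUR spike often seen early in a culture, which
would drag a mean upward.

## Respiratory event detection

The in-situ (chamber-floor) sensor is biased by cells overgrowing it, so
it is treated as qualitative only — never converted to sOUR — and feeds
event detection: a rise in in-situ oxygen means an uptake decrease
(e.g. ATP-synthase inhibition by oligomycin), a fall means an uptake
increase (e.g. FCCP uncoupling). Detection is a causal threshold rule: a
candidate timestamp must show a local slope above 15 µM h⁻¹ AND every
sample of the following 1 h window must have moved past 20 µM from the
preceding 1 h median, in the slope's direction. Requiring the whole
following window to shift rejects isolated noise excursions (zero false
events in 50 noise-only simulations at the default 1.5 µM noise) while
pinning the event to the first shifted sample, giving sub-sample latency
on simulated assays. Events within 1 h of a previous detection are
suppressed.

## The synthetic-data generator

The generator defines the study conditions the package is validated under:

- **Growth**: seeding density held through an optional lag, then
  exponential at µ_max, smoothly capped (soft-min with 5% transition
  width) so confluency never exceeds `saturation_confluency`. Defaults:
  CHO-like — 3×10⁴ cells cm⁻², no lag, µ_max 0.041 h⁻¹, footprint
  600 ± 90 µm², isolated cells; mESC-like — 5×10⁴ cells cm⁻², 72 h lag,
  µ_max 0.035 h⁻¹, footprint 180 ± 40 µm², clustered colonies. Chamber:
  0.8 cm², 25 µL, 300 µL h⁻¹. The chamber area is not a measured value;
  it is consistent with ~25 µL at a typical chamber depth and is always
  explicit in the config.
- **Images**: cells are textured dark ellipses with a bright halo rim on
  a noisy background, placed until the painted union reaches the target
  confluency (realized within 2% absolute). Isolated mode prefers
  non-overlapping placement and falls back to minimal overlap as the
  canvas jams; colony mode places cells adjacent to existing ones with a
  target contact overlap. The packing factor is therefore *emergent*
  (summed single-cell area / union area), and pipeline ground truth uses
  the realized counts so images and sensor traces describe the same
  culture. Default canvas: 2×2 tiles of 192×192 px with 10% overlap at
  1 µm/px — a deliberately scaled-down chamber that keeps a full 40 h
  run's rendering and segmentation in seconds while preserving hundreds
  of cells per frame.
- **Sensors**: quasi-steady outlet with transport delay and first-order
  lag, Gaussian noise per channel (default SD 1.5 µM), Poisson spike
  artifacts injected on inlet AND outlet at identical timestamps (common
  mode by construction), and an in-situ overgrowth bias — a linear ramp
  in confluency reaching a configurable ceiling at a configurable
  confluency (defaults: full inlet setpoint at confluency 0.8). The ramp
  shape is a free modeling choice: overgrowth depletion is real but no
  quantitative model of it exists, so the bias is monotone, configurable
  and documented rather than inferred.
- **Assay preset**: dense static-seeded culture (5×10⁵ cells cm⁻², no
  growth, base sOUR 25 amol cell⁻¹ s⁻¹), oligomycin ×0.2 at 2.5 h, FCCP
  ×3.0 at 6 h over 9 h, with a 60 µM bias ceiling so the in-situ trace
  sits mid-range and swings visibly in both directions.

What the generator does **not** emulate: phase-contrast optics (the
rendering is stylized, sufficient because segmentation is judged against
the generator's own per-pixel truth, not against real microscopy);
3-D/overgrown colonies (the monolayer failure mode appears only as the
packing factor and QC flag); illumination drift; sensor drift between
calibrations; temperature/salinity effects on oxygen solubility.
Passing tests therefore demonstrate the *pipeline's* correctness and noise
behavior under these stated conditions, not classifier transfer to real
phase-contrast images.

## Determinism and numerics

All randomness flows from a single integer seed: the run seed spawns
independent substreams for frame rendering and for sensors, and the
packing-calibration sweep derives its stream from the same seed.
Identical config + seed reproduces bit-identical outputs. Degenerate
inputs are handled explicitly: constant images yield exactly-zero contrast
features (variance residue clamped); zero-oxygen/air anchors reproduce to
machine precision; empty masks, single-class labels, non-positive
densities in fit windows, all-flagged sOUR tables and empty retained-region
sets raise informative errors rather than propagating NaN.

## Problem sizes used in validation

The shipped tests and the acceptance script run the full pipeline on the
scaled-down chamber described above: 81 imaging frames over 40 h per
culture scenario, 161 DO samples, 50 + 50 seeded assay/null simulations
for event-detection rates, and a 6-point confluency sweep for
segmentation fidelity. These sizes were chosen to keep a complete
validation run in a few minutes on one CPU while leaving hundreds of cells
per frame and >100 sOUR samples per run.

## Known limitations

- Density from area is a monolayer-regime estimator; past ~85% raw
  confluency it undercounts (flagged, not corrected).
- The in-situ channel is qualitative by design; its bias model is a
  placeholder shape, so only event timing and direction are meaningful.
- The classifier is a linear model over handcrafted features: adequate
  for the stylized renderer, but real phase-contrast data would need
  retraining and possibly richer features.
- µ_max from non-overlapping windows quantizes the search over window
  placement; with a 10 h window on short runs (<20 h) only one or two
  windows exist and the R² gate can leave µ_max undefined (NaN).
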