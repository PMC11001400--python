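# Methods

## The data-reduction problem

A serial crystallography run produces a stream of 2-D detector frames at
kHz–MHz rates, of which typically only a few percent are hits (a crystal in
the beam, Bragg peaks on the detector). The pipeline's job is an online
veto: estimate and remove the background and static detector artefacts,
detect Bragg-peak apices, summarize each frame as a small feature vector,
and classify it hit or miss so that misses can be discarded before storage.

## Background and artefact reduction

The background model is purely empirical: the pixel-wise median over a
FIFO buffer of the `B` most recent non-hit frames (default `B = 100`).
The median, unlike the mean, is insensitive to the occasional bright
outlier inside a buffered frame, and it removes simultaneously the diffuse
scattering background, the smooth fixed-pattern offset and static hot
pixels, since all of them are (near-)constant across buffered frames. For
an even number of frames the median is the arithmetic mean of the two
central order statistics, matching a per-pixel full sort exactly.

Subtracted frames are clamped at zero: the detector thresholds on positive
photon counts and negative residuals carry no information downstream.

The estimate is refreshed every `U` buffer insertions (default `U = 10`);
a count-based period keeps the online pipeline deterministic. Buffered
frames are stored raw (not background-subtracted), so the median always
estimates the full artefact-plus-background signal.

**Warm-up.** Online operation needs miss labels to fill the buffer, but
labelling needs a background estimate. Until the buffer holds
`warmup_min_frames` frames (default 10), detection runs on raw frames and
a key-point-count heuristic routes frames with at most
`miss_count_threshold` key points (default 5) into the buffer; that
heuristic also supplies the warm-up verdict, which keeps the invariant that
only miss-labelled frames feed the buffer. The heuristic assumes raw miss
frames are nearly key-point-free; on detectors with many hot pixels this
fails (every raw frame shows apparent peaks), in which case an initial
background estimate — e.g. from a dark or calibration run, via
`run_stream(..., initial_background=...)` or `classify --background` —
skips warm-up entirely.

## MP-FAST key-point detection

For every interior pixel `p` of a (subtracted) frame:

1. *Threshold test*: pixels with `I(p) <= tr` are ignored (`tr = 20`
   counts by default). Bragg peaks carry hundreds of counts; the residual
   background after subtraction stays well below 20.
2. *Cardinal test*: `I(p)` must strictly exceed at least 3 of the 4
   compass-point pixels of the radius-3 FAST circle, at offsets (−3,0),
   (0,+3), (+3,0), (0,−3). Checking 4 pixels instead of the full 16-pixel
   segment is what makes the detector cheap enough for per-pulse rates.
3. *Apex refinement*: real peaks can span several pixels, so the candidate
   is replaced by the maximum over its 3×3 neighbourhood. Ties resolve to
   the candidate, then smallest row, then smallest column — a total order
   that makes output deterministic.
4. *Dedup*: distinct candidates refining to one apex merge (set
   semantics); output is sorted by (row, col).

The canonical semantics evaluate every pixel independently
(`order_independent` mode), so the result cannot depend on scan order or
on how the frame is split across parallel workers; `chunked_detect`
(horizontal bands, merged and deduplicated) is provably identical to
whole-frame detection. A `sequential_flags` mode reproduces the classic
raster scan with a per-pixel checked-flag grid (a 3×3 flag block around
each processed candidate); it can differ from the canonical output when
candidates are adjacent, and is provided as a documented fast path, not the
reference semantics. A deliberately naive loop-based re-statement
(`brute_force_oracle`) exists solely as a test reference.

Pixels within 3 of any edge are never candidates, and refined apices that
land inside that border are discarded, so no key point ever sits within
3 px of an edge.

**Satellite apices.** Refinement moves a candidate at most one pixel. A
blob wide enough that pixels 3 px from the apex pass both tests (Gaussian
width σ ≳ 1.2 px at high amplitude) therefore yields extra recorded apices
about 2 px from the true one. This is intrinsic to the single-step
refinement, not a bug; it is one reason the detector is tuned for the
compact peaks (one to a few pixels) that photon-counting pixel detectors
actually record.

## Region-count descriptor

The frame is tiled by a `grid_rows × grid_cols` rectangular grid (default
2×4, n = 8 regions, a roughly symmetric coverage of the detector face).
Tile boundaries are integer splits, half-open on the right, so the tiling
is an exact partition; the descriptor is the per-region key-point count.
Counts are raw (no normalization) and the vector length is constant, with
miss frames mapping to the all-zero vector — classifiers need fixed
dimensionality. A radial-wedge tiling would be an equally defensible
8-way split; the grid is the simplest choice and the geometry is
configurable.

## Classifiers

Four classical models over the 8-vectors, via scikit-learn:

| kind | defaults |
|------|----------|
| mlp  | hidden layers (50, 30, 20, 20), logistic activation, SGD, alpha 1e-5, constant learning rate |
| svm  | RBF kernel, C = 10 |
| rf   | Gini impurity, max depth 30, 100 estimators |
| nb   | Gaussian, var_smoothing 1e-9 |

Where the standard toolkits leave MLP optimization knobs open, this
package sets `learning_rate_init = 0.1`, `max_iter = 1000` and disables
every early-stopping path (`tol = 0`, `n_iter_no_change = max_iter`).
The four-layer logistic stack starts on a flat region of the loss where
per-epoch improvement is tiny; with patience-based stopping enabled the
optimizer quits there and the fit degenerates to the majority class for
some seeds. Running the full epoch budget with a larger constant step
makes training reproducible and seed-robust at both small (tens of
samples) and moderate (thousands) training sizes, at a cost of a few
seconds per fit.

No feature scaling is applied by default — region counts are small,
nonnegative and commensurate — but `ClassifierSpec(scale=True)` inserts a
standardization step.

Metrics are computed from the binary confusion tally with `hit` positive:
precision TP/(TP+FP), recall TP/(TP+FN), F1 the harmonic mean, accuracy
(TP+TN)/N, reported as percentages; degenerate denominators return 0 by
convention so folds without predicted positives stay defined. Multi-class
labels (the optional five-class mode) use macro-averaged one-vs-rest
metrics; macro is a declared choice, not the only defensible one. The
cross-data-set protocol trains on one named corpus in full and tests on
another in full; diagonal cells use a stratified 80/20 held-out split
(seeded) so they measure generalization rather than memorization.

Grid-search tuning (`tune_hyperparameters`) is an explicit list of
candidate specs scored by stratified K-fold mean accuracy, ties broken by
grid order.

## Synthetic frames

The generator emulates the statistical structure the pipeline relies on,
not the physics of diffraction:

* **Diffuse background**: i.i.d. Poisson counts per pixel
  (`background_rate`, default 1 count — sparse photon background typical
  of a subtracted-gain detector at moderate intensity).
* **Fixed pattern**: a smooth low-frequency offset field (coarse uniform
  grid, cubic upsampling, scaled to `fixed_pattern_amplitude`, default 5
  counts) plus `round(hot_pixel_fraction · H · W)` hot pixels stuck at
  `hot_pixel_value` (defaults 10⁻³ and 500 counts). The field is static
  across a run, as detector artefacts are.
* **Peaks**: per hit frame, K ~ Uniform{5..20} apices, pairwise ≥ 8 px
  apart and ≥ 4 px from borders (rejection sampling, 1000 attempts per
  peak, then a deterministic error). Each peak is an isotropic Gaussian
  truncated at 3σ whose apex pixel carries the drawn amplitude
  (100–300 counts); the footprint radius is ⌊3σ⌋, so σ < 1/3 px renders a
  single-pixel peak. The default σ range (0–1 px, FWHM ≤ 2.4 px) matches
  the one-to-a-few-pixel peaks of photon-counting detectors and keeps each
  apex unambiguous at the pixel level.
* **Determinism**: every frame's random stream is keyed by
  (run seed, frame index), so stacks are bit-reproducible and any single
  frame can be regenerated in isolation.
* Peak profiles are not Poisson-resampled by default, so planted apex
  positions are exact ground truth; `poisson_peaks=True` adds counting
  noise to the profiles when realism matters more than exact oracles.

What it deliberately does **not** model: Ewald-sphere geometry, unit cells
or space groups, detector panel gaps and multi-module geometry, per-pixel
gain variation, jet-scattering anisotropy, beam-position drift. Passing
tests on these frames shows the pipeline's logic is correct under its
stated assumptions; it does not certify performance on facility data,
where background is structured and peak shapes vary.

The optional five-class mode (blank / no-crystal / weak / good / strong)
maps classes to planted-peak count bands (0 with no background, 0, 1–5,
6–20, 21–60) to exercise multi-class evaluation; it does not claim
fidelity to any external graded data set.

## Study problem sizes

The test suite and `scripts/acceptance.py` use: 500 random 128×128 frames
for the detector-vs-reference check; 200 random buffers (1–100 frames) for
the median check; 200 hit frames at 256×256 for planted-peak recovery
(recall within a 1-pixel Chebyshev radius, false positives = detections
with no planted apex within 1 px, measured with diffuse background only so
the detector is isolated from the subtraction stage); a 500-hit + 500-miss
corpus at 256×256 for classification (stratified 80/20 split); a shifted
condition (background rate 4, 3–10 peaks, different fixed pattern) for
cross-condition robustness; and a 500-frame stream with a ~3% hit fraction
for the data-reduction experiment, its background primed from 100 miss
frames of the same run. These sizes give stable statistics while keeping a
full run in the tens of seconds.

## Known limitations

* The sequential flagged scan is not guaranteed to equal the canonical
  output for touching candidates; the package treats order-independent
  output as normative.
* Hot pixels are removed only via the median background; a frame acquired
  before any background exists sees them as key points (the warm-up
  caveat above).
* The detector reports integer apex positions only — no sub-pixel
  centroiding, peak integration or SNR estimation.
* Region counts discard peak intensity and radial position; classifiers
  that need those features require a different descriptor.
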