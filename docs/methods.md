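# Methods

## Trace model and preprocessing

A recording is a matrix of mean-ROI fluorescence values, one column per cell,
sampled uniformly (default 0.5 Hz, i.e. 2 s frames). Preprocessing follows
the standard Ca²⁺-imaging recipe in two steps, smoothing first:

* **Retrospective smoothing.** Each sample is replaced by the mean of the
  trailing window of 10 frames *including* the current sample; the first
  nine samples average whatever history exists, so no look-ahead occurs and
  the trace keeps its length. The phrase "previous N values" is ambiguous
  about the current sample; we adopt the inclusive reading as default and
  provide `include_current=False` for the strict-exclusion variant (first
  sample left unchanged). The window is exposed as `smooth_window`.
* **F/F0 normalisation.** F0 is the mean of each cell's first `f0_frames`
  samples (default 30, matching the default pre-stimulus baseline of the
  simulator: 30 frames = 60 s). Baselines with |F0| < 1e-12 are an error.
  Normalisation is affine per cell and therefore does not change Pearson
  correlations; it matters for display and for comparing amplitudes.

Zero-variance traces (variance ≤ 1e-12) make Pearson R undefined and are
removed by `drop_degenerate_cells` before correlation, with each removal
logged.

## Pairwise correlation and significance

`pearson_matrix` is the standard product-moment coefficient for all
unordered pairs (diagonal reported as NaN, never 1 — self-pairs are outside
the analysis). Significance per pair comes from resampling frames:

* **pairs_bootstrap (default).** Frame indices are drawn with replacement
  and applied identically to both members of the pair; R is recomputed per
  replicate. The one-sided p = (1 + #{replicate R ≤ 0}) / (n_boot + 1) is
  the bootstrap-percentile test of "the confidence interval for R excludes
  zero", one-sided because functional connectivity here means *positive*
  coupling (the edge rule is R > 0.25). This scheme assumes exchangeable
  (approximately independent) frames.
* **block_bootstrap.** Identical, but contiguous blocks of `block_len`
  frames (default: the smoothing window, 10) are resampled, preserving
  short-range autocorrelation. This is the appropriate variant when traces
  have been smoothed, since smoothing correlates neighbouring frames and
  makes the plain bootstrap anti-conservative.
* **permutation.** One trace's frames are permuted per replicate and
  p = (1 + #{replicate R ≥ observed}) / (n_boot + 1) — a null-based rather
  than CI-based test. Whether the original analysis was CI- or null-based
  is not recoverable; both are provided and the default is documented, not
  asserted.

`n_boot` defaults to 10,000 so that p < 0.001 is resolvable; the minimum
attainable p is 1/(n_boot + 1), and p is never exactly 0. Each pair draws
from its own RNG substream (`SeedSequence(seed, spawn_key=(i, j))`), so
results are independent of evaluation order and fully reproducible.
Replicates in which a resampled series is constant are redrawn and counted;
a pair exceeding 10% discards errors out. No multiple-testing correction is
applied across pairs by default (none is applied in the original recipe);
`bh_adjust` can be applied to the pair table if desired.

Statistical validation (the heavier tests) runs the chain on F0-normalised
but **unsmoothed** traces: the type-I calibration claim belongs to the
exchangeable-frames regime, and smoothing would have to be paired with the
block bootstrap, whose calibration is only approximate. The
smooth-then-correlate order remains the default of `preprocess` for
display-faithful analysis.

## Edge rule, bins, summaries

An edge requires r > r_min (default 0.25) AND p < alpha (default 0.001),
both strict, so r = 0.25 exactly is not an edge. Strength bins partition
(0.25, 1.0]: green (0.25, 0.5), yellow [0.5, 0.75), red [0.75, 1.0] — the
published ranges overlap at 0.5 and 0.75, and we assign boundaries to the
upper bin. Coefficients within 1e-9 above 1 (floating-point noise) are
clipped to 1.0 before binning. Graph products: edge list TSV, summary JSON
(percent connected pairs = 100·edges/C(n,2), degrees, mean significant R),
heatmap matrix TSV clipped to [−1, 1] with NA diagonal, and SVG/PNG
renderings (line map, heatmap with fixed [−1, 1] scale) that contain no
logic of their own.

## The synthetic islet

The simulator emulates what the analysis consumes — per-ROI traces and
coordinates — not microscope images or channel biophysics. Cell *i*'s trace
is f0ᵢ·(1 + aᵢ·s(t − τᵢ)·1[t ≥ t_stim]) + drift·t + noise with:

* **s**: a shared zero-mean unit-variance waveform, by default a square
  burst train of period 60 s (Ca²⁺ oscillations are pulse-like rather than
  sinusoidal; a sine option exists). The sampled waveform is standardised
  over the post-stimulus window, so its unit variance is exact.
* **aᵢ**: `coupling_amplitude` for coupled cells, 0 otherwise. The coupled
  set is one Bernoulli(coupled_fraction) draw per simulation (default 0.4),
  or an explicit mask for exact planted counts.
* **τᵢ**: a per-cell constant phase shift ~ N(0, phase_jitter_s), applied
  per cell rather than per cycle so the closed form below stays valid at
  zero jitter and interpretable otherwise. Default 0.
* **noise**: iid N(0, noise_sd²) per frame, default σ = 10 AU on baselines
  f0 ~ N(100, 5) AU (clipped positive), i.e. ~10% noise — a realistic
  regime for single-islet fluo dyes. Default drift is 0; a linear `drift_slope`
  is available to stress F0 normalisation.
* **geometry**: ROI centres rejection-sampled uniformly in a disc of radius
  100 with minimum spacing 8 (cells do not overlap); infeasible packings
  raise an error naming the densest count reached.

Defaults: 50 cells, 300 frames at 2 s (10 min recording), 30 baseline
frames before stimulus. Seeding uses one top-level `SeedSequence` split
into substreams (coordinates, mask, baselines, one per cell), so identical
specs give byte-identical outputs.

Under zero jitter/drift, the post-stimulus correlation of two coupled cells
is ρ = a²v/(a²v + σ²) with v = f0², exposed as `expected_pairwise_r` and
inverted by `amplitude_for_expected_r`. The closed form assumes a common
baseline (f0_sd = 0); with baseline spread it holds to first order at
f0_mean. Empirical calibration at 10,000 frames agrees within ±0.02 (the
~30 baseline frames dilute ρ by a factor (n−b)/n ≈ 0.997, far below that
tolerance).

What the simulator does **not** emulate — bleaching curves, movement
artefacts, heterogeneous per-cell amplitudes, wave propagation delays,
non-Gaussian photon noise — bounds what passing tests show: they validate
the statistical machinery (calibration, recovery, determinism), not
robustness to every artefact of real recordings.

### Validation problem sizes

Pure-noise calibration pools 17 simulated islets (20,825 pairs) at
n_boot = 2000 and checks the fraction of p < 0.001 pairs against the 95%
binomial band; planted-network recovery uses 5 islets of 50 cells with 20
coupled at planted R = 0.6 (precision and recall ≥ 0.9 per seed, observed
1.0); simulator calibration uses 6 coupled cells × 10,000 frames. These
sizes keep the full validation suite to a few minutes while leaving the
binomial bands tight enough to detect miscalibration of a factor ~1.5.

## Pre-ranked enrichment

The ES is the signed maximum deviation of the running sum over the ranked
list: hit *i* adds |statᵢ|^w / Σ_set|stat|^w, each miss subtracts
1/(N − N_hit), so the sum ends at exactly 0 and |ES| ≤ 1. Weight w = 1
(weighted, the common pre-ranked default) with w = 0 for the classic
unweighted statistic. Ties in stats are broken lexicographically by gene id
so the ranking (and hence ES) is deterministic. Set members absent from the
ranked list are dropped with a logged count, not treated as misses. The
leading edge is the members at or before the extremum (after it for
negative ES); with ties in |running sum| the earliest extremum is used.

Significance is by gene-label permutation — the only null available for
pre-ranked input — drawing same-size member sets without replacement, or
enumerating all C(N, n_hit) placements when that count is ≤ 20,000. The
p-value is sign-stratified, as is standard for the signed ES: only null
scores with the observed sign enter, p = (1 + #{same-sign null at least as
extreme}) / (n_same_sign + 1) (exact mode: the same fraction without
smoothing; the observed placement is among the enumerated ones, so p > 0).
Sign-stratification is what makes p approximately uniform under the null —
the unconditional variant concentrates on (0, ~0.5) and roughly doubles the
nominal rate. NES = ES / mean(|same-sign null ES|). Across a family of gene
sets, permutation p-values are BH-adjusted (`bh_adjust`, standard step-up
with monotonicity); the GSEA-style NES-based FDR is deliberately not
implemented, anchoring instead on the plain BH procedure.

## Numerical choices

* Variance/zero tolerances: 1e-12 (traces, F0, degenerate replicates with a
  scale-aware factor n).
* Bootstrap replicate correlations use one-pass sufficient-statistic sums;
  for the value ranges here (F/F0 ~ 1, raw ~ 100 AU) cancellation error is
  ≤ 1e-10 of the centred sums, far below any decision boundary, and the
  implementation is checked to equality of p against a two-pass per-replicate
  reference on identical indices.
* Frame-time uniformity is enforced at 1e-9 relative tolerance.
* Trace CSVs are written at full shortest-repr precision and parsed with
  correctly-rounded conversion, so write→read is the identity.

## Known limitations

* The pairs bootstrap is anti-conservative on strongly autocorrelated
  (e.g. smoothed) traces; use `method="block_bootstrap"` there, whose
  calibration is approximate rather than exact.
* Connectivity is undirected, zero-lag and marginal: no lagged
  cross-correlation, directionality, or partial correlation.
* The enrichment module consumes rankings; it does not produce Wald
  statistics (no differential-expression fitting) and ships only an
  illustrative gene-set fixture — any GMT can be supplied.
* `expected_pairwise_r` is a population quantity for the homogeneous case;
  with per-cell baseline spread or phase jitter it is only a first-order
  guide (and the function refuses jitter/drift rather than mislead).
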