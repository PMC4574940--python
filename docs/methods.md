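# Methods

This note documents the models, estimators, defaults, and design choices
behind `meegconnet`, and what the synthetic-data tests do and do not show
about real recordings.

## Data model and preprocessing

A `Recording` holds a `Nc × Ns × Nt` array (channels × samples × trials)
with a sampling rate in Hz, unique channel labels, and optional stimulus
onset and baseline annotations. All sample indices are 0-based, on disk
and in memory. Trial-averaged data is an ordinary recording with one
trial.

**FIR band-pass.** Windowed-sinc (Hamming) design. The default tap count
follows the `3.3 / (normalized transition width)` rule of thumb with a
transition width of 25% of the narrower band edge, rounded to an odd
length. Application is forward–backward (`filtfilt`), i.e. zero-phase
with squared magnitude response: phase-based connectivity must not
inherit a filter group delay. A `causal=True` option applies the filter
once and compensates the group delay by shifting, for users who need
causality. Signals must be at least 3× the filter length.

**Resampling** uses polyphase anti-aliased resampling with the rational
ratio `new_sfreq / sfreq` (denominator limited to 1000). Onset and
baseline annotations are rescaled.

**Baselining** records the `[start, end)` span and subtracts the
per-channel baseline mean from every trial. The span later feeds the
noise-covariance estimator. Subtracting at set time (rather than only
recording the span) keeps all downstream estimators working on zero-mean
baselines.

**Morlet time–frequency.** Complex Morlet wavelets with
`σ_t = n_cycles / (2πf)`, truncated at ±5σ, L2-normalized and zero-mean.
The default of 7 cycles at every frequency is a common balance of time
and frequency resolution; it is configurable per frequency. Power is the
squared coefficient magnitude.

## Inverse solutions

Given a fixed-orientation lead field `G` (`Nc × Ndip`) and a noise
covariance `C`, the data are whitened by the inverse Cholesky factor of
`C`, and sources estimated with

    ŝ = W G_wᵀ (G_w W G_wᵀ + λ μ I)⁻¹ y_w ,   μ = trace(G_w W G_wᵀ)/Nc .

The trace normalization `μ` makes λ dimensionless, so the default
λ = 1/SNR² with SNR = 3 (λ ≈ 0.111) behaves consistently across lead
fields of different scale. The operator is computed once and applied to
every sample and trial (the estimate is linear in the data).

* **MNE**: `W = I`.
* **wMNE**: `W = diag(‖gᵢ‖₂^(−2γ))` with depth exponent γ = 0.5 by
  default (γ ∈ [0, 1]). Depth weighting counteracts the superficial bias
  of plain minimum-norm: deeper sources have smaller gain columns and
  would otherwise be assigned systematically less amplitude.
* **LORETA**: `W = (BᵀB)⁻¹` with `B = I − D⁻¹A`, where `A` is the
  symmetrized 6-nearest-neighbour adjacency of the source positions and
  `D` its degree matrix. `B` annihilates locally constant source fields,
  so `BᵀB` carries a small ridge (`1e-8 · trace/N`) to stay invertible.
  k = 6 approximates the face-neighbour count of a volumetric grid.

**Noise covariance** is the empirical covariance of the baseline samples
pooled across trials, with diagonal loading `1e-6 · mean(diag)`. A
baseline shorter than the channel count triggers a warning (the estimate
is then rank-deficient and the loading dominates conditioning).

**ROI aggregation.** A scout atlas maps ROI labels to member source
indices. The ROI trace is the mean of its members after sign alignment:
the first left-singular vector of the member × time matrix defines the
ROI's principal direction, members with negative loading are flipped, and
the sign convention follows the member majority. Plain averaging was
rejected because fixed-orientation dipoles on opposite sulcal walls
cancel; first-PC extraction alone was rejected because it discards
amplitude information and flips arbitrarily between runs. The aggregation
convention is recorded in this note and applies uniformly.

**Toy forward model.** For tests and simulations only: sensors projected
onto the unit sphere, sources uniform on an inner sphere (radius 0.7),
gain = inverse squared sensor–source distance. It is deterministic given
a seed and labelled synthetic; realistic lead fields (BEM/FEM) are inputs
to the package, not products of it.

## Connectivity estimators

Phase-based estimators extract instantaneous phase from the analytic
signal (Hilbert transform) and assume band-limited input — filter first.
The first and last 5% of samples are excluded from phase averages to
suppress transform edge artifacts.

* **xcorr**: per-trial maximum over lags of |normalized cross-correlation|
  of mean-removed signals, averaged across trials (per-trial maxima are
  averaged rather than pooling, preserving per-trial lag structure);
  values in [0, 1]. Zero-variance channels produce 0 with a warning.
* **PLV (within-trial)** and **MPC**: `|mean_t exp(i Δφ(t))|` per trial,
  averaged over trials. With analytic-signal phases these two definitions
  coincide numerically; both names are kept because both are established.
* **PLV (inter-trial)**: `|mean_trials exp(i Δφ(t))|` per sample,
  requiring `Nt ≥ 2`. This is the variant that resolves coupling at each
  instant. Its time average (edges trimmed) is available as a static
  matrix for thresholding and masking.
* **MI**: 2-D histogram estimate in bits pooled over time and trials,
  default bin count `ceil(√(N/5))` capped at 64, Miller–Madow bias
  correction `(Kx + Ky − Kxy − 1)/(2N ln 2)`, negatives clipped to 0. A
  warning fires below `5·n_bins²` samples.

**Dynamics.** Sliding windows of `window` samples every `step` samples
give `Nw = ⌊(Ns − window)/step⌋ + 1` connectivity slices. k-means
(k-means++ init, 50 restarts, seeded) on the vectorized upper triangles
segments the slices into recurring states; centroids are reassembled as
symmetric zero-diagonal matrices.

## Surrogate significance testing

The rank test sorts `[C_org; C_surr]` ascending; the two-tailed p-value
is `2·min(rank, n_surr+2−rank)/(n_surr+1)`, capped at 1, with floor
`2/(n_surr+1)` (≈ 0.0198 at 100 surrogates — α below the floor can never
reject, and a warning fires below 19 surrogates). Ties with surrogate
values are resolved conservatively: `C_org` takes the most central
admissible rank, so a tie at the extreme doubles the p-value relative to
a clear exceedance and never reaches the floor.

Fourier-transform surrogates randomize spectral phases per trial
(Hermitian-symmetric; DC and Nyquist untouched), exactly preserving each
channel's amplitude spectrum. Two modes:

* **multivariate** (default for `ft_surrogate`): one phase vector shared
  by all channels. Cross-spectra — hence auto- AND cross-correlation —
  are conserved exactly; the surrogate realizes a linear stationary
  process with the original's full second-order structure. This is the
  null for "structure beyond linear correlation".
* **univariate** (default for `significance_mask`): independent phase
  vectors per channel, conserving auto-correlations but destroying
  cross-channel coupling.

The masking default is a deliberate design choice: a surrogate that
conserves the cross-spectrum also conserves phase-coupling statistics, so
testing an edge against the multivariate ensemble has essentially no
power against the very dependence being tested (measured here: 9/20
detections of a strongly coupled pair, versus 20/20 with univariate
surrogates at the same, calibrated false-positive rate). Edge
significance therefore tests the no-interdependence null. Both modes are
exposed; `surrogate_mode="multivariate"` restores the
cross-spectrum-conserving ensemble.

No correction for testing many edges is applied by default (the test is
per-edge); `fdr=True` switches on Benjamini–Hochberg across edges.

## Graph metrics

Path-based quantities (characteristic path length, efficiency, radius,
diameter, betweenness, shortcuts) use binary hop distances even on
weighted graphs, matching the topological definitions of these measures;
`weighted_paths=True` switches to `1/weight` edge lengths. Conventions
for disconnected graphs: unreachable pairs are excluded from the CPL
mean and contribute zero inverse distance to efficiency (keeping it
finite), while radius and diameter are infinite. A graph with no
connected pair at all has infinite CPL.

Betweenness (node and edge) is reported unnormalized — raw counts of
shortest paths with fractional credit for multiplicities — with a
normalized variant behind a flag, since "fraction of shortest paths"
admits several normalization constants. A node is never credited for
paths it terminates; an edge is credited for its endpoint pair.

"Shortcut" edges are operationalized as `ΔCPL = CPL(g − e) − CPL(g) > 0`,
with the ΔCPL magnitude reported so users can apply stricter cutoffs; no
significance procedure is attached to the flag. Coreness is the integer
k-core index by iterative peeling. The participation coefficient is
`1 − Σ_m (k_im/k_i)²` over modules, 0 for isolated nodes.

Thresholding keeps weights above an absolute value, or the top fraction
of off-diagonal entries (ties at the cut broken by stable index order and
logged). Module detection is weighted Louvain with 20 seeded restarts,
keeping the best modularity. Lobe-level aggregation averages member-ROI
values per (lobe, hemisphere), the hemisphere taken from the sign of the
ROI centroid's x-coordinate (atlases carry no explicit hemisphere field;
the x < 0 → left convention matches RAS-style coordinates).

## Synthetic data

The generator produces what the estimators are designed to detect:
narrowband oscillators whose phase relation is reproducible across
trials. Each source is a sinusoid (default 10 Hz at 128 Hz sampling,
2 s, 20 trials) whose initial phase is redrawn every trial. A coupled
group shares a per-trial phase with von Mises jitter whose concentration
κ solves `(I₁/I₀)(κ)² = c`, so the circular variance of any within-group
phase difference equals `1 − c` (verified to ±0.05 at 1000 trials).
Heterogeneous coupling strengths inside one group are realized at their
mean (one concentration per group is all a shared-phase construction can
express) with a warning. Additive Gaussian sample noise is optional;
scalp projection through a lead field adds white sensor noise at a target
SNR in dB.

This emulates inter-trial phase coupling with known ground truth, and
deliberately not: 1/f background spectra, volume-conduction artifacts
beyond the linear lead-field mixing, amplitude dynamics, nonstationary
coupling, or artifacts (blinks, muscle). Passing tests therefore
demonstrate correctness of the estimators and the statistical machinery
under the stated model — not robustness to every property of real EEG.

## Problem sizes and numerical choices

The test suite runs its statistical checks at sizes chosen to make the
assertions sharp yet quick: surrogate calibration uses 200 null
replicates of 2 × 512-sample band-passed noise with 100 surrogates each;
end-to-end recovery uses 32 sensors, 40 candidate sources, 4 active
sources (one coupled pair) over 30 trials of 2 s at 128 Hz, SNR 10 dB,
repeated over 20 seeds; graph-metric equivalence sweeps 200 random
graphs with up to 7 nodes against brute-force enumeration. Degenerate
inputs are handled explicitly: zero-variance channels yield zero
cross-correlation (with a warning), isolated nodes have zero clustering
and participation, empty graphs get singleton modules with Q = 0, and
`λ = 0` with a rank-deficient lead field raises an error advising
regularization.

All randomness flows through `numpy.random.default_rng` seeds; pipeline
stages and replicate loops derive child seeds from a single root via
`SeedSequence.spawn`, so every result in the package is reproducible from
one integer.

## Known limitations

* Undirected measures only; directed/effective connectivity (e.g.
  transfer-function methods) is out of scope, and imported adjacency
  matrices must be symmetric to 1e-8.
* No artifact rejection, bad-channel handling, or ICA; inputs are assumed
  preprocessed to that level.
* Fixed-orientation sources only (one gain column per source); no
  BEM/FEM forward modelling — lead fields are inputs.
* The within-trial PLV of two same-frequency deterministic sinusoids is
  1 by construction regardless of any causal relation; detecting coupling
  among narrowband oscillators requires either broadband/noisy signals or
  the inter-trial estimator.
* Group-level statistics are not provided; analyses are single-recording.
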