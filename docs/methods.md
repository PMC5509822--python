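# Methods

## The model

A single-channel time-lapse stack `Y[i,j,t]` (height × width × T frames) is
modeled as a sum of M functionally independent units (FIUs):

```
Y[i,j,t] = β₀[i,j] + Σₘ βₘ[i,j] · Xₘ[t − τᵢⱼ] + ε[i,j,t]
```

* `Xₘ` — the unit's characteristic curve, constrained to zero mean and unit
  L2 norm (removes the scale ambiguity between `Xₘ` and `βₘ`);
* `βₘ ≥ 0` — per-pixel loading; each pixel loads on at most one unit and the
  support of each `βₘ` is 8-connected;
* `τᵢⱼ` — integer per-pixel frame lag from slow intracellular Ca²⁺ wave
  propagation; lags are reported source-relative (earliest pixel at 0);
* `ε` — Gaussian noise, independent over time, pixel-specific variance
  `σ₀²[i,j]`. Real fluorescence noise is Poisson–Gaussian; a generalized
  square-root (Anscombe-type) variance stabilization is available and turns
  it approximately into this form. Synthetic data is already Gaussian, so
  stabilization is off by default.

The model assumes no cell migration or deformation over the recording (or
that registration has been applied first). M is never specified in advance:
it emerges from a significance threshold.

## Stage 1 — active regions

`z_px = √(N−3)·atanh(r)` where `r` is the Pearson correlation between a
pixel's curve and the mean curve of its 8 in-bounds neighbors (N = number of
frames). Under the null (pixel in no unit) `z_px ~ N(0,1)`; in a unit it is
positive because neighbors share the unit's signal. An alternative variant
takes the maximum correlation with the mean of the two opposite 8-neighbors
along each of the four line orientations through the pixel — pixels on the
wavefront line stay synchronized even under slow propagation — with the
max-of-k null correction `Φ⁻¹(Φ(F(r))ᵏ)`. The 8-neighbor average is the
default: at the low SNR typical of astrocyte recordings, noise suppression
from eight neighbors beats propagation robustness from two (the package's
own simulations reproduce the crossover; see `test_scores.py`).

The z-map is segmented by seeded region growing. A candidate region C is
scored by its mean z; because the procedure *selects* (seed = maximal
unsearched pixel; growth attaches the best-scoring frontier prefix), the
null distribution of that mean is the one of rank-selected **normal order
statistics** within the pool of unsearched pixels:

```
E[S(C)]   = (1/n_C) Σₖ Φ⁻¹(v_k)
Var(S(C)) = (1/(n_C² n)) Σ_{k₁,k₂} v_(k₁)(1−v_(k₂)) / (φ(Φ⁻¹(v_(k₁))) φ(Φ⁻¹(v_(k₂))))
```

(`v_(k₁) ≤ v_(k₂)`; n = pool size; v_k from the rank of C's k-th pixel).

Numerical choices, each validated in the test suite:

* **Plotting position.** `v_k = (J_k + 0.625)/(n + 0.25)` (Blom). The
  midpoint position `(J_k + 0.5)/n` overestimates extreme-rank expectations
  (E[max of 4096] ≈ 3.67 vs ≈ 3.45 exact), which makes the test noticeably
  conservative for weak regions; Blom's position matches a brute-force
  Monte-Carlo oracle to ~0.3% in the mean. The midpoint form remains
  available (`position="hazen"`). Both variance formulas are asymptotic
  (5–10% relative error at very small pools), so calibration is always also
  verified empirically.
* **Termination.** Growth attaches, at each step, the frontier prefix (by
  descending rank) maximizing `z_region = (s(C) − E)/√Var`, and stops at the
  significance maximum. Two robustness devices: growth continues for up to
  `patience` (default 8) steps across significance dips before giving up,
  and the returned state is chosen among the visited states. For
  active-region detection the argmax state is returned (noise pixels at the
  rim cost significance, so the argmax has clean edges); for unit extraction
  (stage 2) the *largest* state within 5% (`rel_tol=0.02` at extraction) of
  the maximum is returned, because there the failure mode to avoid is
  under-coverage of a genuine member plateau.
* **Honest p-values.** The returned state is the best of ~tens of dependent
  states along one growth path; the reported p-value is Bonferroni-corrected
  by the number of visited states. Real regions sit orders of magnitude
  below α, so this costs essentially no power while restoring family-wise
  false-positive control on pure-noise maps (measured 1–2 maps in 100 at
  α = 0.05, vs 13–16 uncorrected).
* Seeds must exceed `seed_threshold` (default 2.0); emitted regions need
  `p ≤ α` (default 0.05, one-sided) and at least `min_size = 4` pixels. Ties
  everywhere break by row-major index, so results do not depend on memory
  layout. A central-limit variant of the moments (E = 0, Var = 1/n_C) is
  kept behind a flag purely as a contrast: it floods pure-noise maps with
  "significant" regions.

The union of emitted regions forms the active-region map; stage 2 operates
on its connected components.

## Stage 2 — sequential unit learning

Within a component, one unit at a time:

1. **Initialization.** `X̂` = the curve of the pixel with the largest `z_px`,
   centered and normalized; its lag is 0 and stays pinned (it defines the
   time origin, which stops the lag field from drifting between iterations).
2. **Pixel pass.** Pixels are visited in breadth-first order from the init
   pixel. Each pixel's lag is the best `Δt ∈ [−U_τ, U_τ]` (default `U_τ=5`)
   around its BFS predecessor's lag, maximizing the correlation of the
   aligned curve with `X̂` *minus a lag penalty* of 0.01 (correlation units)
   per frame of deviation. The penalty matters: at 5 dB the correlation
   differences between nearby lags are far below the sampling noise of r,
   and the unpenalized argmax produces lag estimates so jittery that
   ignoring propagation entirely gives better curves. Then
   `β̂ = X̂ᵀ(aligned, centered curve)` and `σ̂₀² = mean squared residual`
   (divided by T, no degrees-of-freedom correction).
3. **Curve update.** `X̂ ← Σₖ (β̂ₖ/σ̂₀²ₖ)·(aligned curve)`, centered,
   renormalized. Two robustness devices: the first update uses β-only
   weights (on the first pass `X̂` *is* the init pixel's curve, so that
   pixel's residual is exactly zero and 1/σ² weighting would freeze the
   estimate on a single noisy curve), and afterwards σ̂₀² is floored at a
   quarter of its within-region median (within one unit the true noise level
   varies little; a far-below-median estimate reflects fit bias).
4. **Convergence** when `sd(X̂ₙₑw − X̂)/sd(X̂ₙₑw) < tol` (default 0.01),
   or at `max_iter = 50` with a logged flag. Typically under a dozen
   iterations. After convergence the lag field is median-filtered (3×3,
   in-region) with a ±1 re-scan — propagation is spatially smooth, the same
   continuity assumption that justifies the predecessor-anchored search —
   which removes the remaining independent per-pixel lag jitter that would
   otherwise smear the curve like a smoothing kernel. Noiseless recovery
   stays exact.
5. **Membership score.** `z = √2·(½Φ⁻¹(Φᴷ(F(r_fit))) − ½F(r_res))` with
   `K = 2U_τ + 1` (the number of candidate lags actually maximized over).
   `r_fit` is computed **leave-one-out**: the pixel's own weighted
   contribution is removed from the unit curve before correlating, otherwise
   every pixel of even a pure-noise region correlates positively with a
   curve containing its own noise. `r_res` is the correlation of the pixel's
   residual with its neighbors' mean residual: residuals of pixels belonging
   to a *different*, still-unmodeled unit share that unit's curve and
   correlate, so the term pushes confounded pixels out without knowing the
   other unit's curve. The two ½-weighted ~N(0,1) terms give null variance
   ½, hence the √2 rescale for the downstream unit-variance test.
6. **Extraction and acceptance.** The same order-statistics growing, seeded
   at the maximal membership score and restricted to the remaining region,
   yields the unit's mask and p-value. A unit is accepted if `p ≤ α`, its
   size ≥ `min_size`, and — a secondary veto — its pixels' mean activity
   score `z_px` is incompatible with pure noise (`mean·√n` against N(0,1)).
   The veto exists because the iterated lag search gives pixels more
   selection freedom than the max-of-K correction models, so the membership
   test alone is optimistic on the rare noise region that slips past
   stage 1; a genuine unit passes it trivially. Accepted units are
   re-referenced to their source frame (reference lag = minimum of the
   7×7-median-filtered lag field, robust to single-pixel jitter), their
   pixels are removed, and the search continues on the remaining connected
   pieces until nothing significant is left.
7. **Refined curve.** `Cₘ = Σ_{k∈Kₘ} (βₖ/σ₀²ₖ)·(lag-aligned raw curve)` over
   mask pixels only, unnormalized — a fluorescence curve with its baseline,
   ready for ΔF/F₀ analysis. As a final safety net, adjacent accepted units
   whose refined curves correlate above 0.9 at the best relative lag are
   rejoined (by the FIU definition they are one unit); distinct neighboring
   units correlate far below that, and under the default simulation
   conditions the step is a measured no-op.

## Stage 3 — features and screening

From `Cₘ`: F₀ = 10th percentile (linear-interpolation percentile, so the
baseline is bit-reproducible); ΔF/F₀ = (Cₘ−F₀)/F₀; events = peaks of the
5-frame moving-average-smoothed ΔF/F₀ with prominence ≥ max(0.2·max ΔF/F₀,
3× the first-difference noise SD); per-event amplitude = max ΔF/F₀ in the
event's span; frequency = 1/mean inter-peak interval (more stable than
count/duration at the 1–few events typical of 200 s recordings; the two
agree asymptotically); T₀.₅ = linearly interpolated time from peak to half
amplitude. Area in px and µm²; propagation speed = 1/mean|∇τ| over mask
pixels with nonzero gradient (the lag field is box-smoothed first — integer
lags form a staircase whose raw gradient is biased upward), converted to
µm/s; a constant lag field reports the `inf` sentinel ("synchronous").
Screening applies configurable predicates (min/max area, min event count,
max roughness); the roughness statistic — SD of first differences over SD of
the curve — is a stand-in for curve smoothness, for which no canonical
definition exists.

## Synthetic data

The generator emulates the conditions of the simulation benchmarks: 100
frames (200 s at 2 s/frame), unit centroids uniform in the field, one silent
unit for every three beyond the active ones (active fraction 1/4), curves
`Σᵢ (t−tᵢ)e^{−(t−tᵢ)/η}` affinely rescaled so max ΔF/F₀ ∈ [0.5, 4],
constant-velocity radial lag maps (integer frames; speed uniform on [1, 30]
px/frame; `inf` = synchronous), loadings fading linearly over the outer 2 px
of each unit, and noise set by SNR in dB via the 20-log rule.

Choices where a value had to be fixed:

* **Shapes** are procedural star-shaped blobs with a random smooth radial
  profile (templates from real recordings are not shipped); they are
  irregular and heterogeneous but less filamentous than real astrocyte
  processes. Default areas: log-uniform on [30, 200] px (40-unit fields) and
  [10, 40] px (high-density fields).
* **Events per curve**: uniform 2–6 per 200 s, with η uniform on [2, 8]
  frames — event rates of ~1–2 per minute and half-decay times of ~13–50 s,
  in the range of spontaneous and agonist-evoked astrocyte transients. Very
  sparse curves (a single sharp transient) carry so little temporal energy
  that no correlation-based score can detect them at 5 dB; the default is
  chosen to represent the operating point of the benchmarks.
* **Noise semantics**: the per-pixel noise SD tracks the local signal
  magnitude, `σ = β·(max X − min X)/10^{SNR/20}`, so every pixel of a unit
  sits at the configured SNR and the faded boundary is dimmer but not
  relatively noisier — the shot-noise-like behavior of fluorescence, and the
  only reading consistent with size-insensitive detection. Background σ =
  median of the in-unit values. Units carry their own baseline (the curve
  minimum is strictly positive; no background pedestal underneath), so the
  observed per-pixel ΔF/F₀ equals the configured curve amplitude.
* Rendering holds the first/last curve value at the movie edges (no
  wrap-around), and the same seed reproduces scene and movie bit-for-bit.

What passing tests on this data do **not** show: robustness to motion,
bleaching and baseline drift (none are simulated), to non-Gaussian noise
(apply variance stabilization first), to overlapping sources (the model
forbids them by construction), or to real astrocyte morphology (procedural
blobs only approximate it).

## Benchmark problem sizes

The acceptance script runs the low-SNR study at 25 movies × 40 units
(128×128×100, 5 dB), the density study at 5 replicates × 210 units, and the
binarization study at 20 movies with unit counts 15–45, areas from
[10–40, 60–240] px, speeds U[1, 30] and SNR uniform on [0, 10] dB; the test
suite uses 4/2/12 replicates of the same designs. Detection metrics pool
units across movies (units are generated independently).

## Known limitations

* The order-statistics moments are asymptotic; the region test's empirical
  family-wise false-positive rate, not the printed formulas, is the
  authoritative calibration (measured ≲ α).
* Precision under the strict matching rules (a report must cover >50% of
  one unit and ≤10% of every other) degrades for small units in crowded
  fields, where a 2–3 px boundary error already violates the 10% rule; most
  residual errors are under-covered fragments of weak, boundary-faded units.
* Lag estimation is per-pixel maximum-correlation and remains noisy at low
  SNR even after spatial regularization; propagation speeds recovered from
  fast units (delays of 0–1 frame) are not meaningful, and the velocity
  feature reports `inf` for synchronous lag fields.
* Amplitude estimates on small units at low SNR are biased upward because
  residual noise in the refined curve biases the percentile baseline low.
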