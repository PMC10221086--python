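# Methods

## Signal model

A multicomponent nonstationary signal is modelled as the analytic
associate z(t) = Σᵢ aᵢ(t) e^{jφᵢ(t)} of a real signal.  Each FM
component carries an instantaneous-frequency law f₀ᵢ(t) = φᵢ′(t)/2π
(the ridge across time slices); its dual, the group delay τ_dᵢ(f),
is the ridge across frequency slices.  EEG seizure segments are
emulated as a sum of slow piecewise-FM components (rhythmic activity)
and unit impulses at shifted times (spikes); spikes have no meaningful
IF — their signature is a full column in the TF plane, which is why a
GD reading is required for them.

## Discrete TFD conventions

* **WVD.** Computed in the lag domain, K[n, m] = z[n+m] z*[n−m] with
  zero padding outside the signal support, FFT over lag per time
  instant.  Rows are time samples, columns are the N_f = N_t frequency
  bins k/(2N_f) covering [0, 0.5).  The grid is scaled so its total sum
  equals the analytic-signal energy.
* **EMBD.** The separable ambiguity kernel is discretized so that the
  *same* cosh^{−2α} smoothing profile acts along both grid axes: the
  Doppler factor is the transform of cosh^{−2β_E} on the time grid, the
  lag factor the transform of cosh^{−2α_E} on the frequency-bin grid,
  both normalized to unit gain at the origin.  Evaluating the lag
  factor on integer lags instead (the other natural choice) gives an
  ~18-bin frequency blur versus an ~4-sample time blur at
  α_E = β_E = 0.25, which destroys the transpose symmetry that the
  boundary-sweep calibration below presupposes.
* **Directional filter.** The double-derivative directional Gaussian is
  sampled on a centred WL × WL lattice spanning [−1/2, 1/2]², with the
  Mexican-hat orientation (positive central lobe across the ridge,
  Gaussian low-pass along it).  Each patch is de-meaned, so the
  zero-integral property of a second derivative holds exactly on the
  truncated lattice, and normalized by its positive mass so that
  responses are on one scale across (a, b, WL) — without this the
  pointwise-minimum combination degenerates to the lowest-gain kernel
  (raw gains differ by ~50×).
* **Window-length selection.** For each (a, b) family the window length
  minimizing the concentration measure M = (ΣΣ|ρ|^{1/2})²/(N_tN_f) over
  its grid is selected (smaller M = more concentrated).  The nominal
  search grids [N_t/8 : 4 : N_t/4] and [N_t/4 : 4 : 3N_t/8] contain
  even values; they are rounded up to odd so the filter lattice stays
  centred.
* **Angle grid.** 24 uniformly spaced orientations in (−π/2, π/2],
  configurable.  Convolutions are zero-padded; all window lengths of a
  family share one padded FFT of the input, so one LO-ADTFD at
  N_t = 256 costs a few seconds on one CPU.

## Local Rényi-entropy counts

Counts use α_R = 3 and sliding windows Θ_t = Θ_f = 11 slices for smooth
synthetic signals, 5 for spike-rich (EEG-like) ones.  Negative TFD
values are clipped to zero before entropy evaluation; a slice whose
localized window is entirely zero has count exactly 0.  For odd α_R the
windowed entropy reduces to sliding sums of the per-slice totals of ρ
and ρ^α, so a whole profile costs one pass over the grid.

References: the STRE reference is a unit cosine at normalized frequency
0.1, the NBRE reference a unit impulse at sample 15, both transformed
with the same TFD pipeline as the analysed signal and cached per signal
length.  A **binary ridge map** is a different representation from a
continuous TFD, so its counts are compared against the
representation-matched *ideal* reference (a one-bin line, resp. a
one-sample column): comparing a one-pixel-wide binary map against the
finite-resolution reference would bias every count low by the
reference's effective ridge width (~3–5×), making even perfect
estimates score large errors.

**Calibration.** The marginal component for both orientations is the
noise-free LFM sweeping 0 → 0.5 over N_t = 256: with the conventions
above its time-averaged STRE count and frequency-averaged NBRE count
are 1.458 and 1.466 (suspicion threshold ΔNC = 1.50 sits just above).

## Alignment map

The map construction follows the decision procedure: global
initialization by comparing the 8-connected region counts N_r of the
time- and frequency-shrunk ridge maps (ties favour time); scan of the
primary-axis count profile for suspicious maxima; re-localization of
each suspicious segment on the opposite axis; per-block assignment by
the local N_r comparison; component-free slices assigned by the lower
restricted N_r; written blocks widened by ⌈Θ/2⌉ slices (the sliding
window detects supports slightly wider than the true ones).

Two points the verbal procedure leaves open are resolved as follows:

* **ΔNC is a prominence** — the *smaller* of the drops from a maximum
  to its two flanking minima.  Using the larger drop marks every
  component-band edge (a one-sided rise from an empty region) as
  suspicious and floods the map with spurious blocks.
* **Flip intervals are N_r-validated.**  Component intervals of the
  opposite-axis profile that are not themselves suspicious are
  candidate flips to the opposite orientation, but they are assigned by
  the same local N_r comparison as suspicious blocks (ties keep the
  initial orientation).  An unconditional flip turns every noise-floor
  interval into an opposite-orientation stripe.

One nesting level only: segments are re-localized on the opposite axis
exactly once, as in the written procedure.

## Estimators

* **Shrinkage.**  Per slice: local maxima (plateaus report their
  leftmost sample) are ranked by the inclusive sum of samples between
  the separating minima (slice borders act as minima; ties break by
  peak value, then index); the round-half-up of the local count caps
  how many survive, with δ = 1 sample kept around each.  Slices are
  clipped at zero first — the negative skirts the directional filter
  leaves around sharp autoterms would otherwise cancel their areas and
  let broad low-level background outrank them.
* **Image-based.**  Frequency-direction peaks (derivative sign change
  from non-negative to negative), linked with the 10-neighborhood
  {(x±1, y+d), |d| ≤ 2}, thresholded by the least component support:
  the rounded count profile is decomposed into level sets and the
  shortest maximal run over all levels is the minimum duration.
* **BSS.**  Iterative: seed at the largest remaining peak among slices
  with remaining counts, zero the band up to the flanking minima
  (capped at N_f/4), decrement the count, extend in both directions
  following the in-band peak until the first difference of the rounded
  count profile is nonzero.  Each pass removes at least one count unit,
  bounding the iteration by Σ round(NC).
* **Combined driver.**  The chosen estimator runs on κ_t{ρ} with STRE
  counts computed on the extracted grid, and on the transpose of
  κ_f{ρ} with NBRE counts; outputs are OR-ed.  For the shrinkage
  estimator the combined output is exactly κ_t{ρ_t} + κ_f{ρ_f}.

## Evaluation

The LRE error compares count profiles of the TFD and of the binary
estimate, normalized per slice by the larger count; squared (MSE) or
absolute (MAE), averaged per axis and across axes.  Counts are
real-valued estimates of integer component numbers, so a slice where
both profiles round to zero components contributes zero error.  F1
matches estimated pixels against the ideal ridge set within ±1
frequency bin (IF-type truth pixels, one per time sample) or ±1 time
sample (GD-type truth: spike columns, plus the per-bin sampling of
steep FM ridges); each truth sample is matched at most once, and zero
denominators yield 0.

## Synthetic fixtures

* `zlfm_like` — four parallel LFM ramps, amplitudes 1.0/0.8/0.6/0.4,
  each sweeping 0.05 → 0.45 over 90 samples with overlapping supports:
  every slice is occupied and the slope (~2.3 bins/sample) is steep
  enough that per-time-slice peak linking breaks down, which is the
  phenomenon the steep-LFM experiment studies.  Noise-free, the
  image-based estimator's error drops by ~71 % when the GD branch is
  enabled.
* `zmix_like` — two constant tones (0.08 and 0.42) across most of the
  record plus four steep/curved components (two LFM ramps, two
  sinusoidal-FM arcs) with staggered supports; the alignment map should
  assign the tone bands to time localization and the midband to
  frequency localization.
* `eeg_like` — a slow FM component and a short tone plus five unit
  spikes; analysed with Θ = 5 and, following the whitening practice for
  EEG, after a first-difference differentiator that enhances the spike
  signature.  Without the differentiator the spike columns are too weak
  relative to the rhythmic components and the map degenerates to
  all-ones — mirroring the known difficulty of the unfiltered case.
* Noise is real white Gaussian added to the real signal before
  analytic-signal construction, with the realized power ratio scaled to
  the requested SNR exactly; spikes are unit impulses.

What the fixtures do *not* emulate: physiological 1/f background,
artifacts, or amplitude modulation within components; conclusions about
real EEG transfer only qualitatively.

## Known limitations

* The Rényi counts are amplitude-blind within a window: at low SNR
  (≲ 3 dB) the positive noise floor of the TFD contributes O(1)
  spurious counts per slice whose level overlaps the weakest
  component's ridge, so no threshold separates them.  Binary estimates
  place pixels by energy ranking and cannot reproduce those noise
  counts when read along the opposite axis; consequently the
  LRE-MSE advantage of combined estimation, which is decisive on
  noiseless/filtered inputs and at SNR ≥ 10 dB, inverts at SNR ≈ 3 dB
  even with an ideal alignment map.  F1 (which does see pixel
  placement) still prefers the combined estimates at every SNR.
* The finite-resolution skirts of the EMBD kernel around loud constant
  tones inflate the NBRE counts over ~15 shoulder bins; a one-pixel
  estimate cannot match them, which bounds the noiseless
  mixed-orientation error from below at roughly 0.1.
* The alignment map is a union of axis-aligned rectangles; components
  that change orientation within their support (sinusoidal-FM arcs)
  cannot be perfectly partitioned.
* Experiment sizes default to N_t = 256 with 20-seed averages for noisy
  protocols and a 4-point SNR grid with 3 seeds for the noise-sweep
  (repetition counts are configurable in `ExperimentConfig`).
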