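# tfridge

Automatic estimation of instantaneous frequency (IF) **and** group delay
(GD) ridges in time–frequency distributions of multicomponent
nonstationary signals — the setting of EEG seizure analysis, where
oscillatory activity (best described by the IF, a ridge across time
slices) coexists with spikes and sharp transients (best described by
the GD, a ridge across frequency slices).

Classical IF estimators read the TF plane one time slice at a time and
therefore shatter any component that leans toward the frequency axis.
`tfridge` decides, automatically and without prior knowledge of the
number of components, *which regions of the TF plane should be read in
which direction*, and runs the estimation in both orientations at once.

## Method

For a real signal s(t) with analytic associate
z(t) = Σᵢ aᵢ(t) e^{jφᵢ(t)}, the package computes:

1. **A high-resolution TFD.** The Wigner–Ville distribution
   W(t, f) = ∫ z(t+τ/2) z*(t−τ/2) e^{−j2πfτ} dτ is filtered in the
   ambiguity (Doppler–lag) domain with the Extended Modified B
   Distribution kernel (cosh^{−2α_E} windows, α_E = β_E = 0.25), then
   sharpened with an adaptive directional Gaussian filter γ_θ(t, f)
   whose orientation θ(t, f) = argmax_θ ||ρ| ∗∗ γ_θ| is selected per TF
   point.  The locally optimized variant (LO-ADTFD) takes the pointwise
   minimum over a candidate set (a, b) ∈ {(3,6), (3,8), (2,20), (2,30)}
   with the window length of each candidate chosen by a concentration
   measure M = (ΣΣ |ρ|^{1/2})²/(N_t N_f).

2. **Local component counts.** The order-3 Rényi entropy of a sliding
   window of time slices (STRE) or frequency slices (NBRE), compared
   against a single-component reference (a cosine at normalized
   frequency 0.1, resp. an impulse at sample 15, both run through the
   same TFD pipeline), yields the local number of components
   NC(s) = 2^{R(Γ_s{ρ}) − R(Γ_s{ρ_ref})} per slice.

3. **The binary alignment map BM(t, f).**  STRE and NBRE systematically
   over-count components that deviate from their reference orientation;
   that sensitivity is used as a detector.  Ridge maps ρ_t and ρ_f are
   obtained by a per-slice shrinkage operator (keep the NC largest-area
   local maxima), their fragmentation is scored by the number of
   8-connected regions N_r, and pronounced count maxima (ΔNC ≥ 1.50,
   the count excess of the boundary sweep 0 → 0.5 whose mean count is
   ≈ 1.48) trigger a block-by-block re-examination in the opposite
   orientation.  The result is a binary map: 1 = read this region in
   time slices (IF), 0 = read it in frequency slices (GD).

4. **Ridge estimation.**  Three estimators share the map: an
   image-processing method (TFD peaks linked by a 10-neighborhood
   connectivity criterion, thresholded by the least component support),
   a blind-source-separation method (iterative extraction of the
   strongest component within an adaptive frequency band, steered by
   the local counts), and the shrinkage operator itself
   (B^(shrink) = κ_t{ρ_t} + κ_f{ρ_f}).  Each runs on the
   time-oriented part κ_t{ρ} directly and on the transposed
   frequency-oriented part κ_f{ρ}, and the two binary maps are OR-ed.

5. **Evaluation.**  LRE-based MSE/MAE (normalized per-slice count
   differences between the TFD and the estimate), precision/recall/F1
   against the ideal ridges of the synthetic truth, the scaled squared
   Frobenius norm between maps, and N_r.

All experiments run on internally generated synthetic signals
(steep-LFM mixtures, mixed-orientation tone/FM mixtures, and an
EEG-like model of slow FM components plus spike impulses, optionally
whitened with a first-difference filter and embedded in white Gaussian
noise at a prescribed SNR).

## Worked example

```python
import tfridge as tr
from tfridge.pipeline import Pipeline
from tfridge.synthetic import differentiate

pipe = Pipeline(window_time=5, window_freq=5)     # spike-rich setting
sig = tr.fixture("eeg_like", seed=1)              # slow FM + 5 spikes
rho = pipe.transform(differentiate(sig.samples))  # whiten, LO-ADTFD
params = pipe.localization_params(256)
bm = tr.build_alignment_map(rho, params)
print(f"alignment map: {bm.values.mean():.1%} of the TF plane time-localized")
for combined in (False, True):
    est = pipe.estimate(rho, algorithm="bss", combined=combined, bm=bm)
    report = pipe.evaluate(rho, est, signal=sig)
    mode = "IF+GD (combined)" if combined else "IF only        "
    print(f"{mode}: MSE_tf = {report.mse_tf:.4f}  F1 = {report.f1:.3f}  Nr = {report.nr}")
```

prints

```
alignment map: 13.0% of the TF plane time-localized
IF only        : MSE_tf = 0.2409  F1 = 0.332  Nr = 222
IF+GD (combined): MSE_tf = 0.1216  F1 = 0.593  Nr = 70
```

Reading the whole plane in time slices (IF only) shatters the spike
columns: 222 disconnected ridge fragments, F1 = 0.33.  Splitting the
plane with the alignment map and estimating the spikes as group delay
halves the count-profile error, nearly doubles F1 and drops the
fragment count to 70.

A `tfridge` command-line tool exposes each stage
(`simulate`, `tfd`, `counts`, `shrink`, `map`, `estimate`, `evaluate`,
`experiment`); run `tfridge --help`.

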