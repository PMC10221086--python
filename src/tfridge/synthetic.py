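"""Synthetic test signals emulating EEG seizure structure.

Signals are sums of amplitude-scaled FM components (the rhythmic,
oscillatory part of a seizure) plus unit-amplitude impulses at shifted
times (the spike part), optionally embedded in additive white Gaussian
noise at a prescribed SNR.  Each component carries its ideal IF law
(frequency ridge over its time support) or, for spikes, its ideal GD
column, so every generated signal knows its ground-truth ridge pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import InvalidParameterError

__all__ = ["ComponentSpec", "SyntheticSignal", "synthesize", "fixture", "differentiate"]

KINDS = ("constant_tone", "lfm", "sinusoidal_fm", "spike")


@dataclass(frozen=True)
class ComponentSpec:
    """Declarative description of one signal component.

    ``phase_params`` by kind:
      constant_tone: (frequency,)
      lfm:           (start_frequency, stop_frequency)
      sinusoidal_fm: (center_frequency, modulation_depth, modulation_rate)
                     with the rate in cycles/sample
      spike:         (spike_time,)
    ``support`` is the inclusive (start_sample, stop_sample) range.
    """

    kind: str
    amplitude: float
    phase_params: tuple
    support: tuple[int, int]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidParameterError(f"unknown component kind {self.kind!r}")
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be positive")
        if self.support[0] > self.support[1] or self.support[0] < 0:
            raise InvalidParameterError("invalid support")

    def if_law(self) -> np.ndarray | None:
        """Ideal instantaneous frequency over the support (None for spikes)."""
        start, stop = self.support
        t = np.arange(stop - start + 1, dtype=float)
        if self.kind == "constant_tone":
            (f0,) = self.phase_params
            freq = np.full_like(t, float(f0))
        elif self.kind == "lfm":
            f_start, f_stop = self.phase_params
            duration = max(stop - start, 1)
            freq = f_start + (f_stop - f_start) * t / duration
        elif self.kind == "sinusoidal_fm":
            f_c, f_dev, f_mod = self.phase_params
            freq = f_c + f_dev * np.sin(2 * np.pi * f_mod * t)
        else:
            return None
        if np.any(freq < 0) or np.any(freq >= 0.5):
            raise InvalidParameterError("normalized frequency outside [0, 0.5)")
        return freq


@dataclass
class SyntheticSignal:
    """Generated realization with its component specs and ridge truth."""

    samples: np.ndarray
    components: list[ComponentSpec]
    n_samples: int
    snr_db: float | None = None
    seed: int | None = None
    clean: np.ndarray = field(default=None, repr=False)
    noise: np.ndarray = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def truth_if_pixels(self, n_freq: int) -> np.ndarray:
        """(time, frequency-bin) ridge pixels of all FM components."""
        pixels = []
        for comp in self.components:
            law = comp.if_law()
            if law is None:
                continue
            start, stop = comp.support
            bins = np.clip(np.round(law * 2 * n_freq).astype(int), 0, n_freq - 1)
            for t, b in zip(range(start, stop + 1), bins):
                pixels.append((t, b))
        return np.array(sorted(set(pixels)), dtype=int).reshape(-1, 2)

    def truth_gd_pixels(self, n_freq: int) -> np.ndarray:
        """Group-delay ridge pixels: the ideal time per frequency bin.

        Spikes contribute their full frequency column.  FM components
        contribute their ridge sampled per frequency bin (the inverse of
        the IF law, rasterized by densely interpolating the ridge
        polyline), so steep ridges have one truth pixel per crossed bin
        rather than one per time sample.  Pixels already present in the
        IF sampling are excluded.
        """
        if_pixels = {tuple(p) for p in self.truth_if_pixels(n_freq)}
        pixels = set()
        for comp in self.components:
            if comp.kind == "spike":
                (ti,) = comp.phase_params
                pixels.update((int(ti), b) for b in range(n_freq))
                continue
            law = comp.if_law()
            start, _ = comp.support
            t_dense = np.linspace(0, law.size - 1, 8 * law.size)
            bins = np.interp(t_dense, np.arange(law.size), law) * 2 * n_freq
            for t, b in zip(np.round(t_dense + start).astype(int),
                            np.clip(np.round(bins).astype(int), 0, n_freq - 1)):
                if (t, b) not in if_pixels:
                    pixels.add((int(t), int(b)))
        return np.array(sorted(pixels), dtype=int).reshape(-1, 2)

    def measured_snr_db(self) -> float:
        if self.noise is None or not np.any(self.noise):
            raise InvalidParameterError("signal carries no noise realization")
        return float(
            10 * np.log10(np.mean(self.clean**2) / np.mean(self.noise**2))
        )


def synthesize(
    components: Sequence[ComponentSpec],
    n_samples: int,
    snr_db: float | None = None,
    seed: int | None = None,
) -> SyntheticSignal:
    """Sum amplitude-scaled FM cosines and impulses; optionally add AWGN.

    FM phases are 2*pi times the cumulative sum of the IF law over the
    support.  The noise vector is scaled so the realized power ratio
    equals the requested SNR exactly.
    """
    clean = np.zeros(int(n_samples))
    for comp in components:
        start, stop = comp.support
        if stop >= n_samples:
            raise InvalidParameterError("component support exceeds the signal length")
        if comp.kind == "spike":
            (ti,) = comp.phase_params
            clean[int(ti)] += comp.amplitude
        else:
            law = comp.if_law()
            phase = 2 * np.pi * np.cumsum(law)
            clean[start : stop + 1] += comp.amplitude * np.cos(phase)
    noise = None
    samples = clean
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(clean.size)
        p_signal = np.mean(clean**2)
        p_target = p_signal / 10 ** (snr_db / 10)
        noise *= np.sqrt(p_target / np.mean(noise**2))
        samples = clean + noise
    return SyntheticSignal(
        samples=samples,
        components=list(components),
        n_samples=int(n_samples),
        snr_db=snr_db,
        seed=seed,
        clean=clean,
        noise=noise,
    )


def fixture(
    name: str,
    seed: int = 0,
    snr_db: float | None = None,
    n_samples: int = 256,
) -> SyntheticSignal:
    """Named study fixtures.

    ``zlfm_like``: four steep parallel LFM ramps with distinct
    amplitudes, each sweeping a wide band over a short time support so
    the components lean toward the frequency axis.

    ``zmix_like``: two constant tones spanning most of the record plus
    four steep/curved components with staggered supports (mixed
    orientations).

    ``eeg_like``: one slow FM component and one short tone (rhythmic
    seizure activity) plus five unit spikes.
    """
    scale = n_samples / 256  # supports scale with the record length

    def s(x: float) -> int:
        return int(round(x * scale))

    if name == "zlfm_like":
        # four parallel steep ramps with overlapping supports: every
        # slice is occupied and the common slope (~2.3 bins/sample, well
        # beyond the boundary 0 -> 0.5 sweep) leans the components
        # toward the frequency axis strongly enough that per-time-slice
        # peak linking breaks down
        amplitudes = (1.0, 0.8, 0.6, 0.4)
        starts = (0, 55, 110, 166)
        length = 90
        components = [
            ComponentSpec(
                kind="lfm",
                amplitude=a,
                phase_params=(0.05, 0.45),
                support=(s(t0), s(t0 + length) - 1),
            )
            for a, t0 in zip(amplitudes, starts)
        ]
    elif name == "zmix_like":
        components = [
            ComponentSpec("constant_tone", 1.0, (0.08,), (s(8), s(248) - 1)),
            ComponentSpec("constant_tone", 1.0, (0.42,), (s(8), s(248) - 1)),
            ComponentSpec("lfm", 0.9, (0.15, 0.35), (s(20), s(76) - 1)),
            ComponentSpec("sinusoidal_fm", 0.8, (0.25, 0.08, 0.0125), (s(90), s(151) - 1)),
            ComponentSpec("lfm", 0.85, (0.35, 0.15), (s(160), s(216) - 1)),
            ComponentSpec("sinusoidal_fm", 0.8, (0.25, 0.07, 0.011), (s(190), s(246) - 1)),
        ]
    elif name == "eeg_like":
        components = [
            ComponentSpec("lfm", 1.0, (0.05, 0.09), (s(10), s(246) - 1)),
            ComponentSpec("constant_tone", 0.7, (0.14,), (s(60), s(201) - 1)),
        ] + [
            ComponentSpec("spike", 1.0, (s(ti),), (s(ti), s(ti)))
            for ti in (40, 90, 140, 190, 230)
        ]
    else:
        raise InvalidParameterError(f"unknown fixture {name!r}")
    return synthesize(components, n_samples=n_samples, snr_db=snr_db, seed=seed)


def differentiate(signal: Sequence[float]) -> np.ndarray:
    """First-order difference whitening filter, y[0] = x[0]."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("signal must have at least 2 samples")
    out = np.empty_like(x)
    out[0] = x[0]
    out[1:] = np.diff(x)
    return out
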