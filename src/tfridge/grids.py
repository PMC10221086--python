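"""Core data containers for time-frequency analysis.

All grids follow one orientation convention: rows are time samples
(0-based sample indices), columns are frequency bins.  Frequency bins are
``Nf`` uniformly spaced normalized frequencies covering ``[0, 0.5)``,
i.e. bin ``k`` sits at ``k / (2 * Nf)`` cycles/sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

GRID_KINDS = ("wvd", "qtfd", "adtfd", "lo_adtfd", "ridge_binary", "alignment")


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid data."""


class InvalidParameterError(ValueError):
    """Raised when an operation receives an out-of-range parameter."""


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{what} contains non-finite entries")


@dataclass(frozen=True)
class AnalyticSignal:
    """Analytic associate z(t) of a real signal: one-sided spectrum."""

    samples: np.ndarray

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=complex)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 8:
            raise InvalidInputError("analytic signal needs >= 8 samples")
        _check_finite(samples, "analytic signal")

    @property
    def sample_count(self) -> int:
        return int(self.samples.size)


@dataclass
class TFDGrid:
    """Real-valued time x frequency energy matrix with axis metadata."""

    values: np.ndarray
    kind: str = "qtfd"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("TFD grid must be a 2-D matrix")
        _check_finite(self.values, "TFD grid")
        if self.kind not in GRID_KINDS:
            raise InvalidParameterError(f"unknown grid kind {self.kind!r}")
        if self.kind in ("ridge_binary", "alignment"):
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise InvalidInputError(f"{self.kind} grid must be binary")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_freq(self) -> int:
        return self.values.shape[1]

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_time)

    @property
    def freq_axis(self) -> np.ndarray:
        # Nf bins uniformly spanning [0, 0.5)
        return np.arange(self.n_freq) / (2.0 * self.n_freq)

    def copy(self, values: np.ndarray | None = None, kind: str | None = None) -> "TFDGrid":
        return TFDGrid(
            values=self.values.copy() if values is None else np.asarray(values, float),
            kind=self.kind if kind is None else kind,
        )

    def save(self, path: str | Path) -> None:
        """Persist as a headerless CSV matrix plus a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",")
        meta = {"kind": self.kind, "n_time": self.n_time, "n_freq": self.n_freq}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "TFDGrid":
        path = Path(path)
        values = np.loadtxt(path, delimiter=",", ndmin=2)
        kind = "qtfd"
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            kind = json.loads(meta_path.read_text()).get("kind", "qtfd")
        return cls(values=values, kind=kind)


@dataclass
class AmbiguityGrid:
    """Doppler x lag matrix: 2-D Fourier dual of a TFD grid.

    Rows index Doppler (nu, FFT over time), columns index lag (tau, in
    FFT wrap order over the centred lag grid).
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise InvalidInputError("ambiguity grid must be a 2-D matrix")
        _check_finite(self.values, "ambiguity grid")


@dataclass(frozen=True)
class KernelSpec:
    """Smoothing-kernel parameters for the EMBD/ADTFD stage.

    ``alpha_e``/``beta_e`` shape the separable cosh ambiguity kernel;
    ``a``/``b`` are the directional-Gaussian extents along the rotated
    time/frequency axes; ``window_length`` is the (odd) directional
    filter size in samples; ``theta_count`` the number of discrete
    orientations in (-pi/2, pi/2].
    """

    alpha_e: float = 0.25
    beta_e: float = 0.25
    a: float = 2.0
    b: float = 20.0
    window_length: int = 33
    theta_count: int = 24

    def __post_init__(self):
        if self.alpha_e <= 0 or self.beta_e <= 0:
            raise InvalidParameterError("alpha_e and beta_e must be positive")
        if self.a <= 0 or self.b <= 0:
            raise InvalidParameterError("a and b must be positive")
        wl = int(self.window_length)
        if wl < 3 or wl % 2 == 0:
            raise InvalidParameterError("window_length must be odd and >= 3")
        if self.theta_count < 2:
            raise InvalidParameterError("theta_count must be >= 2")

    @property
    def thetas(self) -> np.ndarray:
        """Discrete angle grid, ``theta_count`` values in (-pi/2, pi/2]."""
        n = self.theta_count
        return -np.pi / 2 + np.pi * np.arange(1, n + 1) / n


@dataclass
class LocalCountProfile:
    """Per-slice local number of signal components NC(t) or NC(f)."""

    counts: np.ndarray
    axis: str  # "time" or "frequency"
    alpha_r: int = 3
    window: int = 11
    reference_id: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.axis not in ("time", "frequency"):
            raise InvalidParameterError("axis must be 'time' or 'frequency'")
        _check_finite(self.counts, "count profile")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")

    def rounded(self) -> np.ndarray:
        """Round-half-up to integer counts, floored at zero."""
        return np.maximum(np.floor(self.counts + 0.5), 0.0).astype(int)

    def __len__(self) -> int:
        return int(self.counts.size)


@dataclass
class RidgeMap:
    """Binary ridge-sample map produced by an IF/GD estimator."""

    values: np.ndarray
    axis_of_estimation: str = "time"  # time | frequency | combined
    source: str = "shrink"  # shrink | image | bss

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InvalidInputError("ridge map must be a 2-D matrix")
        if not np.all(np.isin(np.unique(self.values), (0, 1))):
            raise InvalidInputError("ridge map must be binary")
        self.values = self.values.astype(np.uint8)
        if self.axis_of_estimation not in ("time", "frequency", "combined"):
            raise InvalidParameterError("bad axis_of_estimation")

    def as_grid(self) -> TFDGrid:
        return TFDGrid(values=self.values.astype(float), kind="ridge_binary")


@dataclass
class Segment:
    """Suspicious interval of a local-count profile (inclusive bounds)."""

    axis: str
    start: int
    stop: int
    delta_nc: float

    def __post_init__(self):
        if self.start > self.stop:
            raise InvalidInputError("segment start must be <= stop")
        if self.delta_nc < 0:
            raise InvalidInputError("delta_nc must be >= 0")

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop + 1)


@dataclass
class AlignmentMap:
    """Binary component-alignment map.

    1 marks regions analysed with time slices (IF estimation), 0 marks
    regions analysed with frequency slices (GD estimation).  The
    ``provenance`` record documents every decision taken while the map
    was built (initial orientation, segments, per-block region counts).
    """

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InvalidInputError("alignment map must be a 2-D matrix")
        if not np.all(np.isin(np.unique(self.values), (0, 1))):
            raise InvalidInputError("alignment map must be binary")
        self.values = self.values.astype(np.uint8)


@dataclass
class ComponentTrack:
    """Single extracted component ridge (one position per slice)."""

    slice_indices: np.ndarray
    ridge_positions: np.ndarray
    band_left: np.ndarray
    band_right: np.ndarray

    def __post_init__(self):
        self.slice_indices = np.asarray(self.slice_indices, dtype=int)
        self.ridge_positions = np.asarray(self.ridge_positions, dtype=int)
        self.band_left = np.asarray(self.band_left, dtype=int)
        self.band_right = np.asarray(self.band_right, dtype=int)
        n = self.slice_indices.size
        if not (self.ridge_positions.size == self.band_left.size == self.band_right.size == n):
            raise InvalidInputError("component track vectors must share one length")


def load_signal(path: str | Path) -> np.ndarray:
    """Read a single-column headerless CSV / plain-text signal."""
    data = np.loadtxt(path, dtype=float)
    data = np.atleast_1d(np.squeeze(data))
    if data.ndim != 1:
        raise InvalidInputError("expected a single-column signal file")
    return data


def save_signal(path: str | Path, samples: Sequence[float]) -> None:
    np.savetxt(path, np.asarray(samples, float))
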