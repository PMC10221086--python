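"""Quadratic and adaptive-directional time-frequency distributions.

The processing chain implemented here is

    real signal -> analytic signal -> WVD -> ambiguity-domain EMBD
    filtering -> adaptive directional smoothing (ADTFD) -> locally
    optimized ADTFD (pointwise minimum over a candidate kernel set).

Discrete conventions
--------------------
The discrete WVD is computed in the lag domain from the analytic signal:
``K[n, m] = z[n+m] conj(z[n-m])`` with zero padding outside the signal
support, followed by an FFT over lag per time instant.  With unit lag
step the effective lag is ``2m``, so the ``Nf = Nt`` frequency bins
uniformly cover normalized frequencies ``[0, 0.5)``.  The grid is scaled
so its total sum equals the analytic-signal energy.
"""

from __future__ import annotations

import functools
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.fft import fft, ifft, next_fast_len, rfft2, irfft2

from .grids import (
    AmbiguityGrid,
    AnalyticSignal,
    InvalidInputError,
    InvalidParameterError,
    KernelSpec,
    TFDGrid,
)

__all__ = [
    "make_analytic",
    "wvd",
    "ambiguity",
    "qtfd_from_ambiguity",
    "embd_filter",
    "directional_filter_patch",
    "adtfd",
    "concentration_measure",
    "lo_adtfd",
    "default_candidates",
]


def make_analytic(samples: Sequence[float]) -> AnalyticSignal:
    """Analytic associate of a real signal (one-sided spectrum)."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise InvalidInputError("signal must be 1-D with >= 8 samples")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite values")
    return AnalyticSignal(samples=sps.hilbert(x))


def _instantaneous_autocorrelation(z: np.ndarray) -> np.ndarray:
    """Time-lag kernel K[n, m] = z[n+m] conj(z[n-m]), lag in FFT wrap order."""
    n_t = z.size
    K = np.zeros((n_t, n_t), dtype=complex)
    half = n_t // 2
    for n in range(n_t):
        m_max = min(n, n_t - 1 - n, half - 1)
        m = np.arange(-m_max, m_max + 1)
        K[n, m % n_t] = z[n + m] * np.conj(z[n - m])
    return K


def wvd(z: AnalyticSignal) -> TFDGrid:
    """Discrete Wigner-Ville distribution on an Nt x Nt grid over [0, 0.5)."""
    K = _instantaneous_autocorrelation(z.samples)
    n_t = z.sample_count
    # K is Hermitian in lag, so the FFT over lag is real up to rounding.
    W = np.real(fft(K, axis=1)) / n_t
    return TFDGrid(values=W, kind="wvd")


def ambiguity(W: TFDGrid) -> AmbiguityGrid:
    """Ambiguity function A(nu, tau): 2-D Fourier dual of a WVD grid."""
    n_t = W.n_time
    K = ifft(W.values * n_t, axis=1)
    return AmbiguityGrid(values=fft(K, axis=0))


def qtfd_from_ambiguity(A: AmbiguityGrid, kind: str = "qtfd") -> TFDGrid:
    """Inverse transform of an ambiguity grid back to the TF plane."""
    K = ifft(A.values, axis=0)
    n_t = A.values.shape[0]
    return TFDGrid(values=np.real(fft(K, axis=1)) / n_t, kind=kind)


#: grid-cell scale of the cosh smoothing windows: the discrete EMBD
#: kernel evaluates cosh^{-2 alpha} at (cell index) * EMBD_CELL_SCALE, so
#: larger values mean less smoothing and sharper (but noisier) ridges.
EMBD_CELL_SCALE = 1.0

#: half-extent of the directional-filter lattice; the WL x WL patch
#: samples the continuous kernel over [-DGF_SPAN, DGF_SPAN]^2.
DGF_SPAN = 0.5


def _cosh_transform_window(n: int, exponent: float) -> np.ndarray:
    """FT of cosh^{-2 exponent}(.) on a centred scaled grid, unit DC gain."""
    u = (np.arange(n) - n // 2) * EMBD_CELL_SCALE
    win = np.cosh(u.astype(float)) ** (-2.0 * exponent)
    G = np.real(fft(np.fft.ifftshift(win)))
    return G / G[0]


def embd_filter(W: TFDGrid, k: KernelSpec) -> TFDGrid:
    """Extended Modified B Distribution: cosh-kernel filtering in the AF domain.

    The separable kernel applies the same cosh^{-2 alpha} smoothing
    profile along both grid axes: the Doppler factor is the transform of
    cosh^{-2 beta_E}(t) on the time grid (time smoothing), the lag
    factor the transform of cosh^{-2 alpha_E}(f) on the frequency-bin
    grid (frequency smoothing), each normalized to unit gain at the
    origin so g(0, 0) = 1.  Discretizing both factors through the same
    construction keeps the time and frequency resolutions matched in
    grid cells, so transposed signals are treated symmetrically.
    """
    A = ambiguity(W)
    n_t = W.n_time
    G_nu = _cosh_transform_window(n_t, k.beta_e)
    G_tau = _cosh_transform_window(W.n_freq, k.alpha_e)
    filtered = A.values * np.outer(G_nu, G_tau)
    return qtfd_from_ambiguity(AmbiguityGrid(values=filtered), kind="qtfd")


def embd_kernel_value(nu_index: int, tau_index: int, n_t: int, k: KernelSpec) -> float:
    """Evaluate the discrete EMBD kernel g at one (Doppler, lag) grid point."""
    G_nu = _cosh_transform_window(n_t, k.beta_e)
    G_tau = _cosh_transform_window(n_t, k.alpha_e)
    return float(G_nu[nu_index % n_t] * G_tau[tau_index % n_t])


@functools.lru_cache(maxsize=512)
def _dgf_patch_cached(a: float, b: float, wl: int, theta: float) -> np.ndarray:
    u = np.linspace(-DGF_SPAN, DGF_SPAN, wl)
    t, f = np.meshgrid(u, u, indexing="ij")  # rows: time offset, cols: frequency
    t_r = t * np.cos(theta) + f * np.sin(theta)
    f_r = -t * np.sin(theta) + f * np.cos(theta)
    # Mexican-hat orientation: positive central lobe along the rotated
    # frequency axis, low-pass Gaussian along the rotated time axis.
    patch = (a * b / (2.0 * np.pi)) * (2.0 * b**2 - 4.0 * b**4 * f_r**2) * np.exp(
        -(a**2) * t_r**2 - b**2 * f_r**2
    )
    # A second derivative of a Gaussian integrates to zero; enforce the
    # zero-sum property exactly on the truncated discrete lattice.
    patch = patch - patch.mean()
    # Normalize by the positive mass so filter responses are comparable
    # across (a, b, WL): without this the concentration-measure window
    # selection and the pointwise-minimum combination compare outputs on
    # incompatible scales (raw gains differ by ~50x across candidates).
    patch = patch / np.clip(patch, 0.0, None).sum()
    patch.setflags(write=False)
    return patch


def directional_filter_patch(k: KernelSpec, theta: float) -> np.ndarray:
    """Double-derivative directional Gaussian filter on a WL x WL lattice.

    The lattice spans [-DGF_SPAN, DGF_SPAN]^2 in rotated coordinates
    ``t_theta = t cos(theta) + f sin(theta)``,
    ``f_theta = -t sin(theta) + f cos(theta)``; ``a`` and ``b`` act as
    inverse widths relative to the window extent.
    """
    if not (-np.pi / 2 < theta <= np.pi / 2 + 1e-12):
        raise InvalidParameterError("theta must lie in (-pi/2, pi/2]")
    wl = int(k.window_length)
    if wl % 2 == 0:
        raise InvalidParameterError("window length must be odd")
    return np.array(_dgf_patch_cached(float(k.a), float(k.b), wl, float(theta)))


def _dgf_stack(a: float, b: float, wl: int, thetas: np.ndarray) -> np.ndarray:
    return np.stack([_dgf_patch_cached(a, b, wl, float(th)) for th in thetas])


def _adtfd_values(
    rho: np.ndarray,
    a: float,
    b: float,
    window_lengths: Sequence[int],
    thetas: np.ndarray,
    return_angles: bool = False,
):
    """ADTFD grids for one (a, b) pair over several window lengths.

    Yields ``(wl, adtfd_values[, selected_angles])``.  All window lengths
    share one padded FFT of the input so the per-window cost is two
    batched inverse transforms (correlation with |rho| for the angle
    selection of Eq.-style argmax, and the smoothing of rho itself).
    """
    n_t, n_f = rho.shape
    wl_max = max(window_lengths)
    shape = (next_fast_len(n_t + wl_max - 1), next_fast_len(n_f + wl_max - 1))
    rho_f = rfft2(rho, shape)
    abs_f = rfft2(np.abs(rho), shape)
    for wl in window_lengths:
        kernels = _dgf_stack(a, b, int(wl), thetas)
        ker_f = rfft2(kernels, shape, axes=(1, 2))
        corr = irfft2(abs_f[None, :, :] * ker_f, shape, axes=(1, 2))
        out = irfft2(rho_f[None, :, :] * ker_f, shape, axes=(1, 2))
        # crop the 'same' region of the linear convolution
        r0, c0 = (wl - 1) // 2, (wl - 1) // 2
        corr = corr[:, r0 : r0 + n_t, c0 : c0 + n_f]
        out = out[:, r0 : r0 + n_t, c0 : c0 + n_f]
        idx = np.argmax(np.abs(corr), axis=0)
        values = np.take_along_axis(out, idx[None, :, :], axis=0)[0]
        if return_angles:
            yield int(wl), values, thetas[idx]
        else:
            yield int(wl), values


def adtfd(rho: TFDGrid, k: KernelSpec, return_angles: bool = False):
    """Adaptive directional TFD: per-point best-angle directional smoothing.

    At every TF point the angle maximizing the magnitude of the
    correlation between |rho| and the directional filter is selected,
    and the output is rho convolved with the filter at that angle
    (zero-padded boundaries).
    """
    if k.theta_count < 2:
        raise InvalidParameterError("theta_count must be >= 2")
    result = next(
        iter(
            _adtfd_values(
                rho.values, k.a, k.b, [k.window_length], k.thetas, return_angles
            )
        )
    )
    if return_angles:
        _, values, angles = result
        return TFDGrid(values=values, kind="adtfd"), angles
    _, values = result
    return TFDGrid(values=values, kind="adtfd")


def concentration_measure(rho: TFDGrid | np.ndarray) -> float:
    """Normalized square of the summed square-root magnitudes.

    ``M = (1 / (Nt Nf)) * (sum sum |rho|^(1/2))**2``; for a fixed total
    energy, M is smaller for more concentrated distributions.
    """
    values = rho.values if isinstance(rho, TFDGrid) else np.asarray(rho, float)
    n_t, n_f = values.shape
    return float(np.sum(np.sqrt(np.abs(values))) ** 2 / (n_t * n_f))


def _odd(n: int) -> int:
    n = int(n)
    return n if n % 2 == 1 else n + 1


def default_candidates(n_t: int) -> list[tuple[float, float, tuple[int, ...]]]:
    """Default (a, b, window-length grid) candidate families.

    Shape pairs {(3,6), (2,20)} search window lengths in [Nt/8, Nt/4]
    with step 4; pairs {(3,8), (2,30)} search [Nt/4, 3Nt/8].  Window
    lengths are rounded up to odd so the filter lattice stays centred.
    """
    lo = tuple(sorted({_odd(w) for w in range(n_t // 8, n_t // 4 + 1, 4)}))
    hi = tuple(sorted({_odd(w) for w in range(n_t // 4, 3 * n_t // 8 + 1, 4)}))
    return [(3.0, 6.0, lo), (3.0, 8.0, hi), (2.0, 20.0, lo), (2.0, 30.0, hi)]


def lo_adtfd(
    z: AnalyticSignal,
    candidates: Iterable[tuple[float, float, Sequence[int]]] | None = None,
    theta_count: int = 24,
    alpha_e: float = 0.25,
    beta_e: float = 0.25,
) -> TFDGrid:
    """Locally optimized ADTFD.

    For each candidate (a, b) family the window length minimizing the
    concentration measure over its grid is selected; the final grid is
    the pointwise minimum over the per-family ADTFDs, which preserves
    short-duration components while keeping close components resolved.
    """
    if candidates is None:
        candidates = default_candidates(z.sample_count)
    candidates = list(candidates)
    if not candidates:
        raise InvalidParameterError("candidate set must not be empty")
    base = KernelSpec(alpha_e=alpha_e, beta_e=beta_e, theta_count=theta_count)
    rho = embd_filter(wvd(z), base)
    thetas = base.thetas
    best_grids = []
    for a, b, wl_grid in candidates:
        wl_grid = [int(w) for w in wl_grid]
        if not wl_grid:
            raise InvalidParameterError("window-length grid must not be empty")
        best = None
        for _, values in _adtfd_values(rho.values, float(a), float(b), wl_grid, thetas):
            m = concentration_measure(values)
            if best is None or m < best[0]:
                best = (m, values)
        best_grids.append(best[1])
    return TFDGrid(values=np.minimum.reduce(best_grids), kind="lo_adtfd")
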