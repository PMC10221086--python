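"""Slice-wise shrinkage of a TFD to its ridge samples, and the region count.

The shrinkage operator works one slice at a time: it detects local
maxima, ranks them by the area enclosed between the flanking local
minima (borders act as minima; the flanking minima samples are included
in the area sum), retains the ``n_keep`` largest-area maxima with
``delta`` samples kept around each, and zeroes everything else.  With
``delta = 1`` only the maximum sample itself survives, which turns the
TFD into a ridge (IF or GD) estimate.

The quality of a binary ridge map is measured by ``Nr``, the number of
8-connected regions of its ones: discontinuous ridges fragment into
many regions, so lower is better.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .grids import (
    InvalidInputError,
    InvalidParameterError,
    LocalCountProfile,
    RidgeMap,
    TFDGrid,
)

__all__ = ["shrink_slice", "shrink_tfd", "count_regions", "local_maxima"]


def local_maxima(v: np.ndarray, include_borders: bool = True) -> list[int]:
    """Indices of local maxima; a plateau reports its leftmost sample."""
    v = np.asarray(v, dtype=float)
    n = v.size
    out: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left = v[i - 1] if i > 0 else -np.inf
        right = v[j + 1] if j + 1 < n else -np.inf
        if v[i] > left and v[i] > right:
            if include_borders or (i > 0 and j + 1 < n):
                out.append(i)
        i = j + 1
    return out


def peak_areas(v: np.ndarray) -> list[tuple[int, float, int, int]]:
    """Per-maximum (index, area, left-minimum, right-minimum) of a slice.

    Adjacent maxima are separated at the smallest sample between them
    (leftmost on ties); slice borders act as minima.  The area is the
    inclusive sum of samples between the two flanking minima.
    """
    v = np.asarray(v, dtype=float)
    maxima = local_maxima(v)
    if not maxima:
        return []
    bounds = [0]
    for left, right in zip(maxima[:-1], maxima[1:]):
        bounds.append(left + int(np.argmin(v[left : right + 1])))
    bounds.append(v.size - 1)
    return [
        (m, float(v[lo : hi + 1].sum()), lo, hi)
        for m, lo, hi in zip(maxima, bounds[:-1], bounds[1:])
    ]


def shrink_slice(slice_values: np.ndarray, n_keep: int, delta: int = 1) -> np.ndarray:
    """Retain the ``n_keep`` largest-area local maxima of one slice.

    ``delta`` samples are kept around each retained maximum (``delta=1``
    keeps only the maximum itself); everything else is zeroed.  Ties in
    area break by larger peak value, then lower index.
    """
    if int(delta) < 1:
        raise InvalidParameterError("delta must be >= 1")
    v = np.asarray(slice_values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("slice contains non-finite values")
    # negative bilinear residues carry no component energy; without this
    # the negative skirts around sharp autoterms cancel their areas and
    # broad low-level background outranks them
    v = np.clip(v, 0.0, None)
    out = np.zeros_like(v)
    n_keep = int(n_keep)
    if n_keep <= 0 or not np.any(v):
        return out
    peaks = peak_areas(v)
    peaks.sort(key=lambda p: (-p[1], -v[p[0]], p[0]))
    for m, _, _, _ in peaks[:n_keep]:
        lo, hi = max(0, m - (delta - 1)), min(v.size, m + delta)
        out[lo:hi] = v[lo:hi]
    return out


def shrink_tfd(rho: TFDGrid, counts: LocalCountProfile, delta: int = 1) -> RidgeMap:
    """Apply the shrinkage operator along every slice of the counts' axis.

    ``n_keep`` per slice is the rounded (half-up) local component count.
    The output is binarized: retained samples become ones.
    """
    axis_len = rho.n_time if counts.axis == "time" else rho.n_freq
    if len(counts) != axis_len:
        raise InvalidInputError("counts length does not match the grid axis")
    n_keep = counts.rounded()
    values = rho.values if counts.axis == "time" else rho.values.T
    out = np.zeros_like(values)
    for s in range(values.shape[0]):
        out[s] = shrink_slice(values[s], int(n_keep[s]), delta=delta)
    binary = (out != 0).astype(np.uint8)
    if counts.axis == "frequency":
        binary = binary.T
    return RidgeMap(values=binary, axis_of_estimation=counts.axis, source="shrink")


def count_regions(binary_map: RidgeMap | TFDGrid | np.ndarray) -> int:
    """Number of 8-connected regions of ones in a binary matrix."""
    if isinstance(binary_map, RidgeMap):
        values = binary_map.values
    elif isinstance(binary_map, TFDGrid):
        values = binary_map.values
    else:
        values = np.asarray(binary_map)
    if values.size and not np.all(np.isin(np.unique(values), (0, 1))):
        raise InvalidInputError("region counting requires a binary matrix")
    if values.size == 0 or not np.any(values):
        return 0
    _, num = measure.label(values.astype(np.uint8), connectivity=2, return_num=True)
    return int(num)
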