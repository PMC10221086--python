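"""Ridge estimators: image-based peak linking, blind source separation,
and the combined IF+GD driver.

All three estimators consume a TFD plus a per-slice local component
count profile and emit a binary ridge map, so they share one output
type and one evaluation suite.  The combined driver splits the TFD with
the alignment-map kappa operators, runs the chosen estimator on the
time-oriented part directly (IF branch) and on the transposed
frequency-oriented part (GD branch), and ORs the two maps.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np

from .alignment import extract_components
from .grids import (
    AlignmentMap,
    ComponentTrack,
    InvalidParameterError,
    LocalCountProfile,
    RidgeMap,
    TFDGrid,
)
from .renyi import LocalizationParams
from .shrinkage import peak_areas, shrink_tfd

__all__ = [
    "image_peaks",
    "link_components",
    "image_estimate",
    "bss_extract",
    "tracks_to_map",
    "combined_estimate",
    "if_only_estimate",
]

#: m = 10 neighborhood: adjacent time instants, frequency within +/- 2 bins.
M_CONNECTIVITY_OFFSETS = tuple(
    (dt, df) for dt in (-1, 1) for df in (-2, -1, 0, 1, 2)
)


def image_peaks(rho: TFDGrid) -> np.ndarray:
    """Ones where the frequency derivative changes sign from non-negative
    to negative (strict local maximum along frequency; plateaus report
    their leftmost sample)."""
    v = np.clip(rho.values, 0.0, None)  # peaks of energy, not of residues
    n_t, n_f = v.shape
    peaks = np.zeros((n_t, n_f), dtype=np.uint8)
    for t in range(n_t):
        row = v[t]
        f = 0
        while f < n_f:
            j = f
            while j + 1 < n_f and row[j + 1] == row[f]:
                j += 1
            left = row[f - 1] if f > 0 else -np.inf
            falls_right = j + 1 < n_f and row[j + 1] < row[f]
            if row[f] > left and falls_right:
                peaks[t, f] = 1
            f = j + 1
    return peaks


def link_components(peaks: np.ndarray, m: int = 10) -> list[np.ndarray]:
    """Group peak pixels into components via the 10-neighborhood
    {(x +/- 1, y), (x +/- 1, y +/- 1), (x +/- 1, y +/- 2)}.

    Same-column links are excluded by construction, so a component
    chains across time instants.  Returns one (n, 2) pixel array per
    component, raster-ordered.
    """
    if int(m) != 10:
        raise InvalidParameterError("only the 10-neighborhood criterion is supported")
    peaks = np.asarray(peaks)
    pixel_set = {(int(t), int(f)) for t, f in zip(*np.nonzero(peaks))}
    seen: set[tuple[int, int]] = set()
    components: list[np.ndarray] = []
    for start in sorted(pixel_set):
        if start in seen:
            continue
        queue = deque([start])
        seen.add(start)
        comp = []
        while queue:
            t, f = queue.popleft()
            comp.append((t, f))
            for dt, df in M_CONNECTIVITY_OFFSETS:
                nb = (t + dt, f + df)
                if nb in pixel_set and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        components.append(np.array(sorted(comp), dtype=int))
    return components


def _min_support(counts: LocalCountProfile) -> int:
    """Least component support implied by a count profile.

    The rounded profile is decomposed into level sets: for every level
    L >= 1 each maximal run of slices with count >= L is one component
    support interval.  The threshold is the shortest such run, so a
    short-lived count increase (a brief extra component) produces a
    correspondingly short duration threshold.
    """
    rounded = counts.rounded()
    if not np.any(rounded >= 1):
        return 0
    shortest = None
    for level in range(1, int(rounded.max()) + 1):
        length = 0
        for flag in rounded >= level:
            if flag:
                length += 1
            elif length:
                shortest = length if shortest is None else min(shortest, length)
                length = 0
        if length:
            shortest = length if shortest is None else min(shortest, length)
    return int(shortest or 0)


def image_estimate(rho: TFDGrid, counts: LocalCountProfile) -> RidgeMap:
    """Image-based estimator: peak detection, m-connectivity linking and
    a duration threshold taken from the least component support in the
    count profile."""
    peaks = image_peaks(rho)
    components = link_components(peaks)
    threshold = _min_support(counts)
    out = np.zeros_like(peaks)
    kept = 0
    for comp in components:
        duration = np.unique(comp[:, 0]).size
        if threshold > 0 and duration >= threshold:
            out[comp[:, 0], comp[:, 1]] = 1
            kept += 1
    if kept == 0:
        warnings.warn("no component satisfied the duration threshold")
    return RidgeMap(values=out, axis_of_estimation=counts.axis, source="image")


def _flanking_band(row: np.ndarray, ridge: int, cap: int) -> tuple[int, int]:
    """Distances to the nearest flanking local minima around ``ridge``."""
    n = row.size
    left = ridge
    while left > 0 and row[left - 1] < row[left]:
        left -= 1
    right = ridge
    while right + 1 < n and row[right + 1] < row[right]:
        right += 1
    bl = min(ridge - left, cap)
    br = min(right - ridge, cap)
    return bl, br


def bss_extract(rho: TFDGrid, counts: LocalCountProfile) -> list[ComponentTrack]:
    """Blind-source-separation extraction of component ridges.

    Repeatedly seeds at the largest remaining TFD peak, zeroes the
    adaptive frequency band around it, and extends the track in both
    time directions - following the local peak within the propagated
    band - until the first difference of the rounded count profile
    signals a component edge.  Each pass removes at least one count
    unit, so the loop terminates after at most sum(rounded counts)
    passes.
    """
    work = np.clip(rho.values, 0.0, None)
    n_t, n_f = work.shape
    cap = max(1, n_f // 4)
    rounded = counts.rounded()
    remaining = rounded.copy()
    tracks: list[ComponentTrack] = []

    def _extract_at(t: int, ridge: int) -> tuple[int, int, int]:
        bl, br = _flanking_band(work[t], ridge, cap)
        work[t, max(0, ridge - bl) : min(n_f, ridge + br + 1)] = 0.0
        remaining[t] = max(remaining[t] - 1, 0)
        return ridge, bl, br

    while np.any(remaining > 0):
        allowed = remaining > 0
        masked = np.where(allowed[:, None], work, -np.inf)
        t0, f0 = np.unravel_index(int(np.argmax(masked)), work.shape)
        if masked[t0, f0] <= 0.0:
            break
        entries = {}
        ridge, bl, br = _extract_at(t0, f0)
        entries[t0] = (ridge, bl, br)
        for step in (-1, 1):
            prev_ridge, prev_bl, prev_br = ridge, bl, br
            t = t0 + step
            while 0 <= t < n_t:
                if rounded[t] != rounded[t - step]:
                    break  # |NC'(t)| != 0: component edge
                lo = max(0, prev_ridge - prev_bl)
                hi = min(n_f, prev_ridge + prev_br + 1)
                band = work[t, lo:hi]
                if band.size == 0 or band.max() <= 0.0:
                    break
                new_ridge = lo + int(np.argmax(band))
                prev_ridge, prev_bl, prev_br = _extract_at(t, new_ridge)
                entries[t] = (prev_ridge, prev_bl, prev_br)
                t += step
        order = sorted(entries)
        tracks.append(
            ComponentTrack(
                slice_indices=np.array(order),
                ridge_positions=np.array([entries[t][0] for t in order]),
                band_left=np.array([entries[t][1] for t in order]),
                band_right=np.array([entries[t][2] for t in order]),
            )
        )
    return tracks


def tracks_to_map(
    tracks: list[ComponentTrack], shape: tuple[int, int], axis: str = "time"
) -> RidgeMap:
    """Rasterize BSS tracks into a binary ridge map (one pixel per slice)."""
    out = np.zeros(shape, dtype=np.uint8)
    for track in tracks:
        out[track.slice_indices, track.ridge_positions] = 1
    return RidgeMap(values=out, axis_of_estimation=axis, source="bss")


def _run_estimator(rho: TFDGrid, counts: LocalCountProfile, algorithm: str) -> RidgeMap:
    if algorithm == "image":
        return image_estimate(rho, counts)
    if algorithm == "bss":
        return tracks_to_map(bss_extract(rho, counts), rho.values.shape, counts.axis)
    raise InvalidParameterError(f"unknown algorithm {algorithm!r}")


def if_only_estimate(
    rho: TFDGrid, params: LocalizationParams, algorithm: str
) -> RidgeMap:
    """IF estimation alone: the chosen estimator driven by STRE counts
    on the full TFD (no alignment map)."""
    nct = params.counts_time(rho)
    if algorithm == "shrink":
        ridge = shrink_tfd(rho, nct, delta=params.delta)
        return RidgeMap(values=ridge.values, axis_of_estimation="time", source="shrink")
    return _run_estimator(rho, nct, algorithm)


def combined_estimate(
    rho: TFDGrid,
    bm: AlignmentMap,
    algorithm: str,
    params: LocalizationParams,
) -> RidgeMap:
    """Combined IF + GD estimation steered by the alignment map.

    The IF branch runs the estimator on kappa_t{rho} with STRE counts
    computed on the extracted grid; the GD branch transposes
    kappa_f{rho}, runs the same estimator with NBRE counts, and
    transposes back.  The output is the elementwise OR.  For
    ``algorithm='shrink'`` the output is the union of the kappa-masked
    whole-grid shrink maps instead.
    """
    if algorithm not in ("image", "bss", "shrink"):
        raise InvalidParameterError(f"unknown algorithm {algorithm!r}")
    kappa_t = extract_components(rho, bm, "time")
    kappa_f = extract_components(rho, bm, "frequency")

    if algorithm == "shrink":
        rho_t = shrink_tfd(rho, params.counts_time(rho), delta=params.delta)
        rho_f = shrink_tfd(rho, params.counts_freq(rho), delta=params.delta)
        values = np.where(bm.values == 1, rho_t.values, rho_f.values)
        return RidgeMap(values=values, axis_of_estimation="combined", source="shrink")

    n_t, n_f = rho.values.shape
    if np.any(kappa_t.values):
        b_time = _run_estimator(kappa_t, params.counts_time(kappa_t), algorithm).values
    else:
        b_time = np.zeros((n_t, n_f), dtype=np.uint8)
    if np.any(kappa_f.values):
        ncf = params.counts_freq(kappa_f)
        transposed = TFDGrid(values=kappa_f.values.T, kind=rho.kind)
        counts_as_time = LocalCountProfile(
            counts=ncf.counts, axis="time", alpha_r=ncf.alpha_r,
            window=ncf.window, reference_id=ncf.reference_id,
        )
        b_freq = _run_estimator(transposed, counts_as_time, algorithm).values.T
    else:
        b_freq = np.zeros((n_t, n_f), dtype=np.uint8)
    combined = np.logical_or(b_time, b_freq).astype(np.uint8)
    return RidgeMap(values=combined, axis_of_estimation="combined", source=algorithm)
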