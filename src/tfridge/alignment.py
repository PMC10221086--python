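"""Binary component-alignment map and the kappa extraction operators.

A multicomponent signal can mix components that hug the time axis
(tones, slow FM - best analysed slice-by-slice in time, i.e. IF
estimation) with components that hug the frequency axis (spikes, steep
chirps - best analysed slice-by-slice in frequency, i.e. GD
estimation).  The STRE and NBRE counters systematically over-count
components that deviate from their respective reference orientation;
that sensitivity is turned into a detector here: a pronounced local
maximum of a count profile (a drop of at least 1.50 components to the
flanking minima) flags a region whose components likely need the
opposite localization strategy.

``build_alignment_map`` implements the decision procedure: initialize
the whole map from a global comparison of ridge fragmentation (the Nr
region count of the time-shrunk versus frequency-shrunk ridge maps),
then re-examine every suspicious segment with the opposite-axis counter
and assign each resulting TF block by its local Nr comparison.
"""

from __future__ import annotations

import warnings

import numpy as np

from .grids import (
    AlignmentMap,
    InvalidInputError,
    LocalCountProfile,
    Segment,
    TFDGrid,
)
from .renyi import LocalizationParams
from .shrinkage import count_regions, local_maxima, shrink_tfd

__all__ = ["suspicious_segments", "build_alignment_map", "extract_components"]

SUSPICION_THRESHOLD = 1.50


def suspicious_segments(
    profile: LocalCountProfile, threshold: float = SUSPICION_THRESHOLD
) -> list[Segment]:
    """Intervals of a count profile whose maxima rise >= threshold above
    the flanking minima.

    For every local maximum, ``delta_nc`` is the smaller of the drops to
    the separating minima on each side (slice borders act as minima), so
    a maximum is suspicious only when it rises above *both* flanks - a
    mere band edge (one-sided rise) does not qualify.  Maxima with
    ``delta_nc >= threshold`` define segments spanning their flanking
    minima; overlapping or adjacent segments are merged.
    """
    v = np.asarray(profile.counts, dtype=float)
    maxima = local_maxima(v)
    if not maxima:
        return []
    bounds = [0]
    for left, right in zip(maxima[:-1], maxima[1:]):
        bounds.append(left + int(np.argmin(v[left : right + 1])))
    bounds.append(v.size - 1)
    raw: list[tuple[int, int, float]] = []
    for m, lo, hi in zip(maxima, bounds[:-1], bounds[1:]):
        delta_nc = min(v[m] - v[lo], v[m] - v[hi])
        if delta_nc >= threshold:
            raw.append((lo, hi, float(delta_nc)))
    merged: list[list[float]] = []
    for lo, hi, d in sorted(raw):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = max(merged[-1][2], d)
        else:
            merged.append([lo, hi, d])
    return [
        Segment(axis=profile.axis, start=int(lo), stop=int(hi), delta_nc=d)
        for lo, hi, d in merged
    ]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[splits + 1]))
    stops = np.concatenate((idx[splits], [idx[-1]]))
    return [(int(a), int(b)) for a, b in zip(starts, stops)]


def _widen(start: int, stop: int, grow: int, limit: int) -> tuple[int, int]:
    return max(0, start - grow), min(limit - 1, stop + grow)


def _block(
    time_range: tuple[int, int] | None, freq_range: tuple[int, int] | None
) -> tuple[slice, slice]:
    rows = slice(None) if time_range is None else slice(time_range[0], time_range[1] + 1)
    cols = slice(None) if freq_range is None else slice(freq_range[0], freq_range[1] + 1)
    return rows, cols


def build_alignment_map(rho: TFDGrid, params: LocalizationParams) -> AlignmentMap:
    """Binary map BM(t, f): 1 = time-localization region, 0 = frequency.

    Steps: (i) shrink the TFD along both axes; (ii) initialize the map
    from the global Nr comparison; (iii) scan the primary-axis count
    profile for suspicious segments; (iv) re-localize each segment on
    the opposite axis, evaluate each suspicious sub-block by its local
    Nr comparison, and flip non-suspicious component intervals to the
    opposite orientation; (v) assign component-free slices by the lower
    restricted Nr; (vi) widen written blocks by half the localization
    window on each side.
    """
    n_t, n_f = rho.values.shape
    if not np.any(rho.values):
        warnings.warn("degenerate all-zero grid: returning an all-ones map")
        return AlignmentMap(values=np.ones((n_t, n_f), dtype=np.uint8),
                            provenance={"degenerate": True})

    nct = params.counts_time(rho)
    ncf = params.counts_freq(rho)
    rho_t = shrink_tfd(rho, nct, delta=params.delta)
    rho_f = shrink_tfd(rho, ncf, delta=params.delta)
    nr_t, nr_f = count_regions(rho_t), count_regions(rho_f)

    init = 1 if nr_t <= nr_f else 0
    primary = nct if init == 1 else ncf
    primary_axis = primary.axis
    grow_primary = int(np.ceil((params.window_time if primary_axis == "time"
                                else params.window_freq) / 2))
    grow_opp = int(np.ceil((params.window_freq if primary_axis == "time"
                            else params.window_time) / 2))
    axis_len = n_t if primary_axis == "time" else n_f
    opp_len = n_f if primary_axis == "time" else n_t

    bm = np.full((n_t, n_f), init, dtype=np.uint8)
    prov: dict = {
        "nr_time": nr_t,
        "nr_frequency": nr_f,
        "initial_orientation": init,
        "primary_axis": primary_axis,
        "segments": [],
        "blocks": [],
        "empty_slices": None,
    }

    segments = suspicious_segments(primary, params.threshold)
    prov["segments"] = [(s.start, s.stop, s.delta_nc) for s in segments]

    # (v) component-free slices on the primary axis, assigned by the
    # lower Nr restricted to those slices (tie keeps the initial value).
    seg_mask = np.zeros(axis_len, dtype=bool)
    for seg in segments:
        seg_mask[seg.start : seg.stop + 1] = True
    empty = (primary.rounded() == 0) & ~seg_mask
    if np.any(empty):
        if primary_axis == "time":
            nr_te = count_regions(rho_t.values[empty, :])
            nr_fe = count_regions(rho_f.values[empty, :])
        else:
            nr_te = count_regions(rho_t.values[:, empty])
            nr_fe = count_regions(rho_f.values[:, empty])
        if nr_te != nr_fe:
            val = 1 if nr_te < nr_fe else 0
            if primary_axis == "time":
                bm[empty, :] = val
            else:
                bm[:, empty] = val
            prov["empty_slices"] = {"nr_time": nr_te, "nr_frequency": nr_fe,
                                    "value": val}

    for seg in segments:
        sub = np.zeros_like(rho.values)
        rows, cols = _block(
            (seg.start, seg.stop) if primary_axis == "time" else None,
            (seg.start, seg.stop) if primary_axis == "frequency" else None,
        )
        sub[rows, cols] = rho.values[rows, cols]
        sub_grid = rho.copy(values=sub)
        opp_axis = "frequency" if primary_axis == "time" else "time"
        try:
            opp_profile = params.counts(sub_grid, opp_axis)
        except ValueError:
            continue
        sub_segs = suspicious_segments(opp_profile, params.threshold)
        sub_mask = np.zeros(opp_len, dtype=bool)
        for ss in sub_segs:
            sub_mask[ss.start : ss.stop + 1] = True

        # Candidate blocks along the opposite axis: the suspicious
        # sub-segments, plus the remaining intervals with detected
        # components (the step-5 "flip" candidates).  Every block is
        # validated by the local Nr comparison of the two shrink maps;
        # ties keep the initial orientation, so component-free noise
        # intervals never overturn the global decision.
        component = (opp_profile.rounded() >= 1) & ~sub_mask
        blocks = [("suspicious", ss.start, ss.stop) for ss in sub_segs]
        blocks += [("flip", lo, hi) for lo, hi in _runs(component)]
        for kind, lo, hi in blocks:
            rows, cols = _block(
                (lo, hi) if opp_axis == "time" else (seg.start, seg.stop),
                (lo, hi) if opp_axis == "frequency" else (seg.start, seg.stop),
            )
            nrt_b = count_regions(rho_t.values[rows, cols])
            nrf_b = count_regions(rho_f.values[rows, cols])
            if nrt_b < nrf_b:
                val = 1
            elif nrt_b > nrf_b:
                val = 0
            else:
                val = init
            lo_w, hi_w = _widen(lo, hi, grow_opp, opp_len)
            seg_lo, seg_hi = _widen(seg.start, seg.stop, grow_primary, axis_len)
            rows, cols = _block(
                (lo_w, hi_w) if opp_axis == "time" else (seg_lo, seg_hi),
                (lo_w, hi_w) if opp_axis == "frequency" else (seg_lo, seg_hi),
            )
            if val != init:
                bm[rows, cols] = val
            prov["blocks"].append(
                {"kind": kind, "primary_range": (seg.start, seg.stop),
                 "opposite_range": (lo, hi),
                 "nr_time": nrt_b, "nr_frequency": nrf_b, "value": val}
            )

    return AlignmentMap(values=bm, provenance=prov)


def extract_components(rho: TFDGrid, bm: AlignmentMap, which: str) -> TFDGrid:
    """Kappa operators: keep the BM = 1 regions (time) or BM = 0 (frequency).

    For any grid, ``kappa_t{rho} + kappa_f{rho} = rho`` elementwise.
    """
    if bm.values.shape != rho.values.shape:
        raise InvalidInputError("alignment map shape does not match the grid")
    if which == "time":
        mask = bm.values == 1
    elif which == "frequency":
        mask = bm.values == 0
    else:
        raise InvalidInputError("which must be 'time' or 'frequency'")
    return rho.copy(values=np.where(mask, rho.values, 0.0))
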