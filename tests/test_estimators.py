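"""Image-based, BSS and combined IF/GD ridge estimators."""

import numpy as np
import pytest

from tfridge.estimators import (
    M_CONNECTIVITY_OFFSETS,
    bss_extract,
    combined_estimate,
    if_only_estimate,
    image_estimate,
    image_peaks,
    link_components,
    tracks_to_map,
)
from tfridge.grids import AlignmentMap, InvalidParameterError, LocalCountProfile, TFDGrid

from conftest import grid_of, tone


def peaks_oracle(row):
    """Brute-force strict local maxima along one slice (plateau leftmost)."""
    row = np.clip(np.asarray(row, float), 0, None)
    out = np.zeros(len(row), dtype=int)
    i = 0
    while i < len(row):
        j = i
        while j + 1 < len(row) and row[j + 1] == row[i]:
            j += 1
        left = row[i - 1] if i > 0 else -np.inf
        if j + 1 < len(row) and row[j + 1] < row[i] and row[i] > left:
            out[i] = 1
        i = j + 1
    return out


def bfs_components(peaks):
    """Oracle: breadth-first search over the 10-neighbor offset set."""
    pixels = {(int(t), int(f)) for t, f in zip(*np.nonzero(peaks))}
    seen, comps = set(), []
    for p in sorted(pixels):
        if p in seen:
            continue
        comp, queue = [], [p]
        seen.add(p)
        while queue:
            t, f = queue.pop()
            comp.append((t, f))
            for dt, df in M_CONNECTIVITY_OFFSETS:
                q = (t + dt, f + df)
                if q in pixels and q not in seen:
                    seen.add(q)
                    queue.append(q)
        comps.append(sorted(comp))
    return sorted(comps)


def counts_of(values, axis="time"):
    return LocalCountProfile(counts=np.asarray(values, float), axis=axis)


class TestImagePeaks:
    def test_monotone_slice_has_no_peaks(self):
        rho = grid_of(np.tile(np.arange(16.0), (4, 1)))
        assert image_peaks(rho).sum() == 0

    def test_tone_has_one_peak_per_slice(self, cheap_pipeline):
        rho = cheap_pipeline.transform(tone(128, 0.2))
        peaks = image_peaks(rho)
        assert np.all(peaks[15:-15].sum(axis=1) >= 1)
        assert np.all(peaks[15:-15, round(0.2 * 256)] == 1)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            row = np.round(rng.random(32), 2)
            got = image_peaks(grid_of(row[None, :]))[0]
            assert np.array_equal(got, peaks_oracle(row))


class TestLinkComponents:
    def _map_from(self, pixels, shape=(16, 16)):
        out = np.zeros(shape, dtype=np.uint8)
        for t, f in pixels:
            out[t, f] = 1
        return out

    def test_small_jumps_stay_one_component(self):
        ridge = [(t, 2 * t) for t in range(6)]  # jumps of 2 bins
        comps = link_components(self._map_from(ridge))
        assert len(comps) == 1

    def test_separated_ridges_are_two_components(self):
        pixels = [(t, 2) for t in range(6)] + [(t, 9) for t in range(6)]
        comps = link_components(self._map_from(pixels))
        assert len(comps) == 2

    def test_three_bin_jump_splits_component(self):
        pixels = [(0, 2), (1, 2), (2, 5), (3, 5)]  # 3-bin jump at t=2
        comps = link_components(self._map_from(pixels))
        assert len(comps) == 2

    def test_matches_bfs_oracle_on_random_maps(self, rng):
        for _ in range(50):
            peaks = (rng.random((12, 12)) < 0.15).astype(np.uint8)
            got = sorted(sorted(map(tuple, c)) for c in link_components(peaks))
            assert got == bfs_components(peaks)

    def test_only_ten_neighborhood_supported(self):
        with pytest.raises(InvalidParameterError):
            link_components(np.zeros((4, 4)), m=8)


class TestImageEstimate:
    def test_tone_ridge_recovered(self, cheap_pipeline, cheap_params):
        rho = cheap_pipeline.transform(tone(128, 0.2))
        est = image_estimate(rho, cheap_params.counts_time(rho))
        bin_ = round(0.2 * 256)
        assert np.all(est.values[15:-15, bin_] == 1)

    def test_no_survivor_warns_and_returns_empty(self):
        rho = grid_of(np.zeros((16, 16)))
        with pytest.warns(UserWarning):
            est = image_estimate(rho, counts_of(np.zeros(16)))
        assert est.values.sum() == 0


class TestBssExtract:
    def test_single_tone_single_track(self, cheap_pipeline, cheap_params):
        x = np.zeros(128)
        x[16:113] = np.cos(2 * np.pi * 0.2 * np.arange(97))
        rho = cheap_pipeline.transform(x)
        tracks = bss_extract(rho, cheap_params.counts_time(rho))
        assert len(tracks) >= 1
        main = max(tracks, key=lambda tr: tr.slice_indices.size)
        assert main.slice_indices.size >= 80
        assert np.all(np.abs(main.ridge_positions - round(0.2 * 256)) <= 2)

    def test_louder_tone_extracted_first(self, cheap_pipeline, cheap_params):
        x = tone(128, 0.15) + 0.6 * tone(128, 0.35)
        rho = cheap_pipeline.transform(x)
        tracks = bss_extract(rho, cheap_params.counts_time(rho))
        assert len(tracks) >= 2
        assert np.median(np.abs(tracks[0].ridge_positions - round(0.15 * 256))) <= 2

    def test_zero_counts_give_no_tracks(self, rng):
        rho = grid_of(rng.random((16, 16)))
        assert bss_extract(rho, counts_of(np.zeros(16))) == []

    def test_termination_bound(self, rng):
        rho = grid_of(rng.random((24, 24)))
        counts = counts_of(rng.integers(0, 4, 24).astype(float))
        tracks = bss_extract(rho, counts)
        assert len(tracks) <= counts.rounded().sum()


class TestCombinedEstimate:
    def test_all_ones_map_equals_time_only_estimation(self, cheap_pipeline, cheap_params):
        rho = cheap_pipeline.transform(tone(128, 0.2))
        bm = AlignmentMap(values=np.ones((128, 128), dtype=np.uint8))
        for alg in ("image", "bss", "shrink"):
            combined = combined_estimate(rho, bm, alg, cheap_params)
            if_only = if_only_estimate(rho, cheap_params, alg)
            assert np.array_equal(combined.values, if_only.values)

    def test_branches_have_disjoint_support(self, cheap_pipeline, cheap_params, rng):
        x = tone(128, 0.1)
        x[64] += 5.0  # tone + spike
        rho = cheap_pipeline.transform(x)
        bm = AlignmentMap(values=(rng.random((128, 128)) < 0.5).astype(np.uint8))
        from tfridge.alignment import extract_components
        from tfridge.estimators import _run_estimator

        kt = extract_components(rho, bm, "time")
        kf = extract_components(rho, bm, "frequency")
        bt = _run_estimator(kt, cheap_params.counts_time(kt), "bss").values
        tr = TFDGrid(values=kf.values.T, kind=rho.kind)
        ncf = cheap_params.counts_freq(kf)
        bf = _run_estimator(
            tr, counts_of(ncf.counts, "time"), "bss"
        ).values.T
        assert not np.any(np.logical_and(bt, bf))

    def test_tone_plus_spike_yields_both_ridges(self, cheap_pipeline, cheap_params):
        x = tone(128, 0.1)
        x[64] += 5.0
        rho = cheap_pipeline.transform(x)
        from tfridge.alignment import build_alignment_map

        bm = build_alignment_map(rho, cheap_params)
        est = combined_estimate(rho, bm, "shrink", cheap_params)
        tone_bin = round(0.1 * 256)
        # horizontal ridge: tone bin occupied across many slices
        assert est.values[20:-20, tone_bin - 1 : tone_bin + 2].sum() >= 60
        # vertical ridge: spike column occupied across many bins
        assert est.values[62:67, :].sum() >= 40

    def test_unknown_algorithm_rejected(self, cheap_pipeline, cheap_params):
        rho = cheap_pipeline.transform(tone(128, 0.2))
        bm = AlignmentMap(values=np.ones((128, 128), dtype=np.uint8))
        with pytest.raises(InvalidParameterError):
            combined_estimate(rho, bm, "ridge", cheap_params)

    def test_shrink_combined_is_kappa_masked_union(self, cheap_pipeline, cheap_params):
        x = tone(128, 0.1)
        x[64] += 5.0
        rho = cheap_pipeline.transform(x)
        from tfridge.alignment import build_alignment_map, extract_components
        from tfridge.shrinkage import shrink_tfd

        bm = build_alignment_map(rho, cheap_params)
        est = combined_estimate(rho, bm, "shrink", cheap_params)
        rho_t = shrink_tfd(rho, cheap_params.counts_time(rho))
        rho_f = shrink_tfd(rho, cheap_params.counts_freq(rho))
        kt = extract_components(rho_t.as_grid(), bm, "time").values
        kf = extract_components(rho_f.as_grid(), bm, "frequency").values
        assert np.array_equal(est.values, (kt + kf).astype(np.uint8))
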