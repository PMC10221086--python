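"""TFD stage: analytic signal, WVD, EMBD, directional filters, LO combination."""

import numpy as np
import pytest

from tfridge.grids import (
    AnalyticSignal,
    InvalidInputError,
    InvalidParameterError,
    KernelSpec,
)
from tfridge.tfd import (
    adtfd,
    ambiguity,
    concentration_measure,
    default_candidates,
    directional_filter_patch,
    embd_filter,
    embd_kernel_value,
    lo_adtfd,
    make_analytic,
    qtfd_from_ambiguity,
    wvd,
)

from conftest import chirp, tone


class TestAnalyticSignal:
    def test_cosine_becomes_complex_exponential(self):
        t = np.arange(256)
        z = make_analytic(np.cos(2 * np.pi * 0.1 * t))
        expected = np.exp(1j * 2 * np.pi * 0.1 * t)
        # spectral leakage (0.1 is not an integer number of cycles over
        # 256 samples) bounds the agreement at the few-percent level
        assert np.abs(z.samples[16:-16] - expected[16:-16]).max() < 0.05
        assert np.allclose(z.samples.real, np.cos(2 * np.pi * 0.1 * t))

    def test_zero_signal_maps_to_zero(self):
        z = make_analytic(np.zeros(32))
        assert np.allclose(z.samples, 0.0)

    def test_one_sided_spectrum(self, rng):
        z = make_analytic(rng.standard_normal(64))
        spectrum = np.fft.fft(z.samples)
        negative = np.sum(np.abs(spectrum[33:]) ** 2)
        assert negative <= 1e-9 * np.sum(np.abs(spectrum) ** 2)

    @pytest.mark.parametrize("bad", [np.full(16, np.nan), np.r_[np.ones(15), np.inf]])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            make_analytic(bad)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            make_analytic(np.ones(4))


class TestWVD:
    def test_tone_concentrated_at_its_bin(self):
        z = make_analytic(tone(128, 0.1))
        W = wvd(z)
        expected_bin = round(0.1 * 2 * 128)
        hits = [np.argmax(W.values[t]) for t in range(16, 112)]
        assert all(h == expected_bin for h in hits)

    def test_impulse_concentrated_in_time(self):
        # a unit complex impulse: all WVD energy in one flat time slice
        x = np.zeros(64, dtype=complex)
        x[32] = 1.0
        W = wvd(AnalyticSignal(samples=x))
        energy_by_slice = np.abs(W.values).sum(axis=1)
        assert np.argmax(energy_by_slice) == 32
        assert energy_by_slice[32] > 0.999 * energy_by_slice.sum()
        assert np.ptp(W.values[32]) < 1e-9 * np.abs(W.values[32]).max()

    def test_energy_matches_analytic_signal(self, rng):
        z = make_analytic(rng.standard_normal(64))
        W = wvd(z)
        assert np.isclose(W.values.sum(), np.sum(np.abs(z.samples) ** 2), rtol=1e-8)

    def test_lfm_ridge_follows_linear_law(self):
        x, law = chirp(256, 0.05, 0.45)
        W = wvd(make_analytic(x))
        bins = np.argmax(W.values, axis=1)
        expected = np.round(law * 2 * 256).astype(int)
        assert np.all(np.abs(bins - expected)[20:-20] <= 1)


class TestAmbiguity:
    def test_round_trip_recovers_wvd(self, rng):
        W = wvd(make_analytic(rng.standard_normal(64)))
        back = qtfd_from_ambiguity(ambiguity(W))
        err = np.linalg.norm(back.values - W.values) / np.linalg.norm(W.values)
        assert err < 1e-8


class TestEMBD:
    def test_kernel_unit_gain_at_origin(self):
        assert np.isclose(embd_kernel_value(0, 0, 128, KernelSpec()), 1.0)

    def test_single_tone_ridge_unchanged(self):
        z = make_analytic(tone(128, 0.1))
        W = wvd(z)
        rho = embd_filter(W, KernelSpec())
        for t in range(16, 112):
            assert np.argmax(rho.values[t]) == np.argmax(W.values[t])

    def test_two_tone_cross_terms_reduced(self):
        x = tone(128, 0.1) + tone(128, 0.3)
        W = wvd(make_analytic(x))
        rho = embd_filter(W, KernelSpec())
        band = slice(round(0.19 * 256), round(0.21 * 256) + 1)
        assert np.abs(rho.values[:, band]).sum() < np.abs(W.values[:, band]).sum()

    def test_invalid_smoothing_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            KernelSpec(alpha_e=-0.1)


class TestDirectionalFilter:
    def test_axis_aligned_profile_is_mexican_hat(self):
        patch = directional_filter_patch(KernelSpec(a=2, b=6, window_length=33), 0.0)
        profile = patch.sum(axis=0)
        center = len(profile) // 2
        assert profile[center] > 0  # positive central lobe
        assert profile[4] < 0 and profile[-5] < 0  # negative side lobes

    @pytest.mark.parametrize("theta", [0.3, 0.9, 1.2])
    def test_mirror_symmetry_in_theta(self, theta):
        k = KernelSpec(a=2, b=20, window_length=21)
        assert np.allclose(
            directional_filter_patch(k, theta),
            directional_filter_patch(k, -theta)[:, ::-1],
            atol=1e-12,
        )

    @pytest.mark.parametrize(
        "a,b,wl,theta", [(2, 20, 33, 0.0), (3, 6, 17, 0.7), (2, 30, 65, -1.2), (3, 8, 49, 1.5)]
    )
    def test_zero_sum(self, a, b, wl, theta):
        patch = directional_filter_patch(KernelSpec(a=a, b=b, window_length=wl), theta)
        assert abs(patch.sum()) <= 1e-6 * np.abs(patch).sum()

    def test_even_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            KernelSpec(window_length=16)


class TestADTFD:
    def test_chirp_angles_follow_ridge_orientation(self):
        x, law = chirp(128, 0.1, 0.4)
        k = KernelSpec(a=2, b=20, window_length=17, theta_count=24)
        rho = embd_filter(wvd(make_analytic(x)), k)
        _, angles = adtfd(rho, k, return_angles=True)
        slope = (0.4 - 0.1) / 128 * 2 * 128  # bins per sample
        expected = np.arctan(slope)
        bins = np.round(law * 2 * 128).astype(int)
        ridge_angles = np.array([angles[t, bins[t]] for t in range(20, 108)])
        step = np.pi / 24
        circ_mean = np.angle(np.mean(np.exp(2j * ridge_angles))) / 2
        assert abs(circ_mean - expected) <= step

    def test_tone_ridge_angle_along_time_axis(self):
        k = KernelSpec(a=2, b=20, window_length=17, theta_count=24)
        rho = embd_filter(wvd(make_analytic(tone(128, 0.2))), k)
        _, angles = adtfd(rho, k, return_angles=True)
        b = round(0.2 * 2 * 128)
        step = np.pi / 24
        on_ridge = angles[20:108, b]
        # angle grid is (-pi/2, pi/2]: "along time" is theta near 0
        assert np.all(np.minimum(np.abs(on_ridge), np.pi - np.abs(on_ridge)) <= step + 1e-12)

    def test_tone_ridge_position_preserved(self):
        k = KernelSpec(a=2, b=20, window_length=17)
        rho = embd_filter(wvd(make_analytic(tone(128, 0.2))), k)
        out = adtfd(rho, k)
        for t in range(20, 108):
            assert abs(int(np.argmax(out.values[t])) - int(np.argmax(rho.values[t]))) <= 1


class TestConcentrationMeasure:
    @pytest.mark.parametrize("values,expected", [([[1.0, 0.0]], 0.5), ([[0.5, 0.5]], 1.0)])
    def test_closed_form_examples(self, values, expected):
        assert np.isclose(concentration_measure(np.array(values)), expected)

    def test_matches_double_loop_oracle(self, rng):
        grid = rng.random((8, 8))
        total = 0.0
        for i in range(8):
            for j in range(8):
                total += abs(grid[i, j]) ** 0.5
        assert np.isclose(concentration_measure(grid), total**2 / 64)


class TestLOADTFD:
    def test_pointwise_minimum_property(self):
        z = make_analytic(tone(64, 0.2) + tone(64, 0.35))
        candidates = default_candidates(64)
        base = KernelSpec(theta_count=8)
        rho = embd_filter(wvd(z), base)
        singles = []
        for a, b, wls in candidates:
            best = None
            for wl in wls:
                k = KernelSpec(a=a, b=b, window_length=wl, theta_count=8)
                vals = adtfd(rho, k).values
                m = concentration_measure(vals)
                if best is None or m < best[0]:
                    best = (m, vals)
            singles.append(best[1])
        lo = lo_adtfd(z, candidates=candidates, theta_count=8)
        assert np.all(lo.values <= np.minimum.reduce(singles) + 1e-9)

    def test_single_candidate_equals_that_adtfd(self):
        z = make_analytic(tone(64, 0.2))
        lo = lo_adtfd(z, candidates=[(2.0, 20.0, [9])], theta_count=8)
        k = KernelSpec(a=2, b=20, window_length=9, theta_count=8)
        single = adtfd(embd_filter(wvd(z), k), k)
        assert np.allclose(lo.values, single.values)

    def test_empty_candidate_set_rejected(self):
        z = make_analytic(tone(64, 0.2))
        with pytest.raises(InvalidParameterError):
            lo_adtfd(z, candidates=[])

    def test_burst_and_tone_both_tracked(self):
        n = 128
        t = np.arange(n)
        burst = np.where((t >= 40) & (t < 72), np.cos(2 * np.pi * 0.35 * t), 0.0)
        x = tone(n, 0.1) + burst
        lo = lo_adtfd(make_analytic(x), theta_count=12)
        tone_bin, burst_bin = round(0.1 * 2 * n), round(0.35 * 2 * n)
        tone_hits = sum(
            abs(int(np.argmax(lo.values[s])) - tone_bin) <= 1 for s in range(10, 118)
        )
        assert tone_hits >= 0.9 * 108
        burst_hits = sum(
            abs(int(np.argmax(lo.values[s, burst_bin - 6 :]) + burst_bin - 6) - burst_bin) <= 1
            for s in range(44, 68)
        )
        assert burst_hits >= 0.9 * 24

    def test_window_grids_are_odd(self):
        for _, _, wls in default_candidates(256):
            assert all(w % 2 == 1 for w in wls)
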