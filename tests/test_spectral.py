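"""Gain-profile construction and FFT-domain application contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freqhar.spectral import (
    DCProtectionError,
    GainProfile,
    SpectrumGrid,
    Window,
    apply_gains,
    apply_profile,
    make_emphasis_profile,
    make_gaussian_profile,
    make_mask_profile,
    make_peak_profile,
    make_random_profile,
    make_triangular_profile,
    make_unit_profile,
)

from conftest import make_tone, tone_amplitude


class TestSpectrumGrid:
    def test_bin_layout(self, grid256):
        assert grid256.n_bins == 129
        assert grid256.bin_hz == pytest.approx(0.390625)
        # walking cadence sits on bin 2 of this grid
        assert grid256.bin_to_hz(2) == pytest.approx(0.78125)
        assert grid256.bin_to_hz(grid256.n_bins - 1) <= grid256.fs / 2

    def test_hz_to_bin_roundtrip(self, grid256):
        for k in (0, 1, 8, 64, 128):
            assert grid256.hz_to_bin(grid256.bin_to_hz(k)) == k

    @pytest.mark.parametrize("w,fs", [(1, 100.0), (64, 0.0), (64, -5.0)])
    def test_invalid_grid_rejected(self, w, fs):
        with pytest.raises(ValueError):
            SpectrumGrid(w, fs)


class TestMaskProfile:
    def test_single_bin_mask(self):
        grid = SpectrumGrid(8, 8.0)
        profile = make_mask_profile(grid, 1)
        assert profile.kind == "mask"
        np.testing.assert_array_equal(profile.gains, [1, 0, 1, 1, 1])

    def test_band_mask(self, grid256):
        profile = make_mask_profile(grid256, (3, 5))
        assert profile.gains[2] == 1 and profile.gains[6] == 1
        np.testing.assert_array_equal(profile.gains[3:6], 0)

    def test_dc_is_protected(self, grid256):
        with pytest.raises(DCProtectionError):
            make_mask_profile(grid256, 0)
        with pytest.raises(DCProtectionError):
            make_mask_profile(grid256, (0, 4))

    def test_out_of_range_band(self, grid256):
        with pytest.raises(ValueError):
            make_mask_profile(grid256, grid256.n_bins)

    def test_masked_tone_loses_its_energy(self):
        grid = SpectrumGrid(8, 8.0)
        x = make_tone(8, 1)
        out = apply_gains(x, make_mask_profile(grid, 1).gains)
        assert np.sum(out**2) < 1e-12 * np.sum(x**2)


class TestEmphasisProfiles:
    def test_peak_shape(self, grid256):
        profile = make_peak_profile(grid256, 8)  # ~3.13 Hz
        assert profile.gains[8] == 1.0
        assert profile.gains[5] == 0.5
        assert profile.gains[0] == 1.0  # DC never attenuated
        assert profile.center_hz == pytest.approx(3.125)

    def test_peak_with_unit_floor_is_identity(self, grid256):
        profile = make_peak_profile(grid256, 40, floor=1.0)
        np.testing.assert_array_equal(profile.gains, 1.0)

    @pytest.mark.parametrize("floor", [0.0, -0.1, 1.5])
    def test_bad_floor_rejected(self, grid256, floor):
        with pytest.raises(ValueError):
            make_peak_profile(grid256, 8, floor=floor)

    def test_gaussian_shape(self, grid256):
        profile = make_gaussian_profile(grid256, 8, sigma_bins=10)
        assert profile.gains[8] == 1.0
        # one sigma from the centre: 0.5 + 0.5 * exp(-1/2)
        assert profile.gains[18] == pytest.approx(0.5 + 0.5 * np.exp(-0.5))
        # far tail approaches the floor
        assert profile.gains[-1] == pytest.approx(0.5, abs=1e-6)
        assert np.all(profile.gains >= 0.5) and np.all(profile.gains <= 1.0)

    def test_gaussian_bad_sigma(self, grid256):
        with pytest.raises(ValueError):
            make_gaussian_profile(grid256, 8, sigma_bins=0)

    def test_triangular_shape(self, grid256):
        profile = make_triangular_profile(grid256, 20, half_width_bins=4)
        assert profile.gains[20] == 1.0
        assert profile.gains[22] == pytest.approx(0.75)  # halfway down the ramp
        assert profile.gains[18] == pytest.approx(0.75)
        assert profile.gains[24] == 0.5
        assert np.all(profile.gains[25:] == 0.5)  # clamped past the ramp

    def test_triangular_default_half_width_spans_spectrum(self, grid256):
        profile = make_triangular_profile(grid256, 8)
        # ramp reaches the far edge just as it hits the floor
        assert profile.gains[-1] == pytest.approx(0.5)
        assert profile.gains[9] > profile.gains[50] > 0.5

    def test_random_gains_bounded_and_reproducible(self, grid256):
        p1 = make_random_profile(grid256, rng_seed=7)
        p2 = make_random_profile(grid256, rng_seed=7)
        np.testing.assert_array_equal(p1.gains, p2.gains)
        randomized = p1.gains[1:20]
        assert np.all(randomized >= 0.5) and np.all(randomized <= 1.0)

    def test_random_respects_cutoff(self, grid256):
        # 7.8 Hz on this grid: bins 1..19 randomized, the rest untouched
        profile = make_random_profile(grid256, cutoff_hz=7.8, rng_seed=0)
        assert profile.gains[0] == 1.0
        assert np.all(profile.gains[20:] == 1.0)
        assert np.any(profile.gains[1:20] < 1.0)

    def test_random_bad_cutoff(self, grid256):
        with pytest.raises(ValueError):
            make_random_profile(grid256, cutoff_hz=0.0)
        with pytest.raises(ValueError):
            make_random_profile(grid256, cutoff_hz=51.0)

    def test_emphasis_dispatch(self, grid256):
        for kind in ("peak", "gaussian", "triangular", "random"):
            profile = make_emphasis_profile(grid256, kind, 8, rng_seed=1)
            assert profile.kind == kind
        with pytest.raises(ValueError):
            make_emphasis_profile(grid256, "hann", 8)

    def test_gains_must_stay_in_unit_interval(self, grid256):
        with pytest.raises(ValueError):
            GainProfile(grid256, np.full(grid256.n_bins, 1.5), kind="unit")


class TestApplyProfile:
    def test_unit_profile_is_identity(self, grid32):
        rng = np.random.default_rng(0)
        window = Window(rng.normal(size=(3, 32)), label="walk", subject="S0")
        out = apply_profile(window, make_unit_profile(grid32))
        np.testing.assert_allclose(out.values, window.values, atol=1e-9)
        assert out.label == "walk" and out.subject == "S0"

    def test_tone_amplitude_follows_gain(self, grid32):
        profile = make_gaussian_profile(grid32, 5)
        for k in range(1, 16):
            x = make_tone(32, k, amplitude=2.0, phase=0.7)
            out = apply_gains(x, profile.gains)
            assert tone_amplitude(out, k) == pytest.approx(
                2.0 * profile.gains[k], abs=1e-9
            )

    def test_phase_is_preserved(self, grid32):
        x = make_tone(32, 5, phase=1.1)
        out = apply_gains(x, make_peak_profile(grid32, 9).gains)
        # halved amplitude, same shape: out == 0.5 * x exactly
        np.testing.assert_allclose(out, 0.5 * x, atol=1e-9)

    def test_shape_mismatch_rejected(self, grid32):
        window = Window(np.zeros((3, 64)), label="a", subject="s")
        with pytest.raises(ValueError):
            apply_profile(window, make_unit_profile(grid32))

    def test_nonfinite_window_rejected(self):
        with pytest.raises(ValueError):
            Window(np.full((3, 8), np.nan), label="a", subject="s")

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_energy_contraction(self, seed):
        """All gains <= 1 can only remove energy (Parseval)."""
        rng = np.random.default_rng(seed)
        grid = SpectrumGrid(64, 64.0)
        x = rng.normal(size=(3, 64))
        gains = rng.uniform(0, 1, size=grid.n_bins)
        out = apply_gains(x, gains)
        assert np.sum(out**2) <= np.sum(x**2) + 1e-9

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        grid = SpectrumGrid(32, 32.0)
        gains = make_gaussian_profile(grid, 4).gains
        x, y = rng.normal(size=(2, 32))
        a, b = rng.uniform(-3, 3, size=2)
        lhs = apply_gains(a * x + b * y, gains)
        rhs = a * apply_gains(x, gains) + b * apply_gains(y, gains)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_masking_is_idempotent(self, grid32):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(3, 32))
        gains = make_mask_profile(grid32, 4).gains
        once = apply_gains(x, gains)
        twice = apply_gains(once, gains)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_output_is_real_and_batched(self, grid32):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 3, 32))
        out = apply_gains(X, make_peak_profile(grid32, 3).gains)
        assert out.shape == X.shape
        assert np.isrealobj(out)


def test_profile_text_export(tmp_path, grid32):
    profile = make_peak_profile(grid32, 3)
    path = tmp_path / "profile.tsv"
    profile.to_text(path)
    rows = path.read_text().strip().splitlines()
    assert rows[0] == "bin_hz\tgain"
    assert len(rows) == grid32.n_bins + 1
    hz, gain = rows[4].split("\t")  # bin 3
    assert float(hz) == pytest.approx(3.0)
    assert float(gain) == 1.0
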