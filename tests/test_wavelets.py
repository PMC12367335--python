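"""Filter-bank correctness: hand examples, brute-force oracles, perfect
reconstruction, energy conservation, and denoising behaviour."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from wtlstm.wavelets import (
    DenoiseConfig,
    OutputMode,
    PaddingMode,
    WaveletSpec,
    analysis_step,
    denoise,
    synthesis_step,
)

SQRT2 = np.sqrt(2.0)


def brute_force_analysis(x, filt, mode):
    """Independent reference: pad, full convolution, take every second sample."""
    x = np.asarray(x, float)
    L = len(filt)
    if mode == "periodic":
        if len(x) % 2:
            x = np.append(x, x[0])
        n = len(x)
        out = np.zeros(n // 2)
        for k in range(n // 2):
            for m in range(L):
                out[k] += filt[m] * x[(2 * k + 1 - m) % n]
        return out
    if mode == "zero":
        padded = np.concatenate([np.zeros(L - 1), x, np.zeros(L - 1)])
    else:
        padded = np.pad(x, L - 1, mode="symmetric")
    full = np.convolve(padded, filt, mode="valid")
    return full[1::2]


class TestWaveletSpec:
    def test_standard_families_validate(self):
        for name in ("haar", "db2", "db4", "db8", "sym4"):
            spec = WaveletSpec.from_name(name)
            assert spec.orthogonal
            assert len(spec.dec_lo) % 2 == 0
            assert abs(spec.dec_lo.sum() - SQRT2) < 1e-10

    def test_broken_qmf_rejected(self):
        good = WaveletSpec.from_name("haar")
        with pytest.raises(ValueError, match="quadrature"):
            WaveletSpec("bad", good.dec_lo, good.dec_lo, good.rec_lo, good.rec_hi)

    def test_wrong_normalization_rejected(self):
        with pytest.raises(ValueError, match="sqrt"):
            WaveletSpec("bad", [0.5, 0.5], [-0.5, 0.5], [0.5, 0.5], [0.5, -0.5])

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError, match="even length"):
            WaveletSpec("bad", [1.0, 1.0, 1.0], [1, 1, 1], [1, 1, 1], [1, 1, 1],
                        orthogonal=False)


class TestAnalysisStep:
    @pytest.mark.parametrize("mode", ["zero", "periodic"])
    def test_haar_on_ones(self, mode):
        spec = WaveletSpec.from_name("haar")
        approx, detail = analysis_step([1.0, 1.0, 1.0, 1.0], spec, mode)
        np.testing.assert_allclose(approx, [SQRT2, SQRT2], atol=1e-12)
        np.testing.assert_allclose(detail, [0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("name", ["haar", "db2", "db4"])
    def test_constant_signal(self, name):
        spec = WaveletSpec.from_name(name)
        c = 3.7
        approx, detail = analysis_step(np.full(64, c), spec, "periodic")
        np.testing.assert_allclose(approx, c * spec.dec_lo.sum(), atol=1e-10)
        np.testing.assert_allclose(detail, 0.0, atol=1e-10)

    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, seed, a, b):
        spec = WaveletSpec.from_name("db2")
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=32), rng.normal(size=32)
        ax, dx = analysis_step(x, spec, "symmetric")
        ay, dy = analysis_step(y, spec, "symmetric")
        axy, dxy = analysis_step(a * x + b * y, spec, "symmetric")
        np.testing.assert_allclose(axy, a * ax + b * ay, atol=1e-9)
        np.testing.assert_allclose(dxy, a * dx + b * dy, atol=1e-9)

    @pytest.mark.parametrize("name", ["haar", "db4"])
    @pytest.mark.parametrize("mode", ["zero", "symmetric", "periodic"])
    def test_matches_brute_force_oracle(self, name, mode):
        spec = WaveletSpec.from_name(name)
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(spec.filter_length, 90))
            x = rng.normal(size=n)
            approx, detail = analysis_step(x, spec, mode)
            ref_a = brute_force_analysis(x, spec.dec_lo, mode)
            ref_d = brute_force_analysis(x, spec.dec_hi, mode)
            worst = max(worst, np.max(np.abs(approx - ref_a)),
                        np.max(np.abs(detail - ref_d)))
        assert worst < 1e-10

    @pytest.mark.parametrize("name", ["haar", "db2", "db4"])
    @pytest.mark.parametrize("mode", ["zero", "symmetric"])
    def test_matches_pywt(self, name, mode):
        # independent library cross-check (zero/symmetric share pywt's
        # convention; our periodic convention differs by a circular phase)
        rng = np.random.default_rng(5)
        x = rng.normal(size=61)
        approx, detail = analysis_step(x, WaveletSpec.from_name(name), mode)
        ca, cd = pywt.dwt(x, name, mode=mode)
        np.testing.assert_allclose(approx, ca, atol=1e-12)
        np.testing.assert_allclose(detail, cd, atol=1e-12)

    def test_too_short_signal_raises(self):
        spec = WaveletSpec.from_name("db4")
        with pytest.raises(ValueError, match="too short"):
            analysis_step([1.0, 2.0], spec, "zero")

    def test_nonfinite_raises(self):
        spec = WaveletSpec.from_name("haar")
        with pytest.raises(ValueError, match="finite"):
            analysis_step([1.0, np.nan, 2.0, 3.0], spec, "zero")


class TestSynthesisStep:
    @pytest.mark.parametrize("name", ["haar", "db2", "db4"])
    @pytest.mark.parametrize("mode", ["zero", "symmetric", "periodic"])
    def test_perfect_reconstruction_one_level(self, name, mode):
        spec = WaveletSpec.from_name(name)
        x = np.random.default_rng(1).normal(size=64)
        a, d = analysis_step(x, spec, mode)
        xr = synthesis_step(a, d, spec, len(x), mode)
        np.testing.assert_allclose(xr, x, atol=1e-8)

    def test_zero_coefficients_give_zero(self):
        spec = WaveletSpec.from_name("db4")
        out = synthesis_step(np.zeros(16), np.zeros(16), spec, 32, "periodic")
        np.testing.assert_array_equal(out, 0.0)

    def test_mismatched_lengths_raise(self):
        spec = WaveletSpec.from_name("haar")
        with pytest.raises(ValueError, match="equal length"):
            synthesis_step(np.zeros(4), np.zeros(5), spec, 8)

    @pytest.mark.parametrize("name", ["haar", "db2", "db4"])
    def test_energy_conservation_periodic(self, name):
        spec = WaveletSpec.from_name(name)
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=64)
            a, d = analysis_step(x, spec, "periodic")
            assert abs(np.sum(a**2) + np.sum(d**2) - np.sum(x**2)) < 1e-8


class TestDenoise:
    def test_level_zero_is_identity(self):
        x = np.random.default_rng(3).normal(size=50)
        out = denoise(x, DenoiseConfig(level=0))
        np.testing.assert_array_equal(out, x)

    def test_level2_haar_constant(self):
        c = 2.5
        out = denoise(np.full(32, c), DenoiseConfig(level=2),
                      WaveletSpec.from_name("haar"))
        assert len(out) == 8
        np.testing.assert_allclose(out, 2 * c, atol=1e-12)

    @pytest.mark.parametrize("name,levels", [("haar", 3), ("db4", 3)])
    def test_multilevel_reconstruction_roundtrip(self, name, levels):
        # low-pass-only reconstruction of a low-pass-only signal (constant)
        # is exact at any level
        spec = WaveletSpec.from_name(name)
        x = np.full(128, 4.2)
        for level in range(1, levels + 1):
            cfg = DenoiseConfig(level=level, output_mode="reconstruction",
                                padding_mode="periodic")
            np.testing.assert_allclose(denoise(x, cfg, spec), x, atol=1e-8)

    def test_reconstruction_distortion_clean_below_noisy(self):
        # a slow sinusoid passes the level-2 low-pass almost unchanged;
        # adding white noise of the same amplitude must raise the distortion
        spec = WaveletSpec.from_name("db4")
        cfg = DenoiseConfig(level=2, output_mode="reconstruction",
                            padding_mode="symmetric")
        t = np.arange(256)
        clean = np.sin(2 * np.pi * t / 64)
        noisy = clean + np.random.default_rng(4).normal(0, 1.0, 256)
        d_clean = np.linalg.norm(denoise(clean, cfg, spec) - clean) / np.linalg.norm(clean)
        d_noisy = np.linalg.norm(denoise(noisy, cfg, spec) - clean) / np.linalg.norm(clean)
        assert d_clean < d_noisy
        assert d_clean < 0.1

    def test_noise_suppression_over_replicates(self):
        # denoise(trend + noise) is closer to the trend than the raw series,
        # for every one of 20 seeded replicates
        spec = WaveletSpec.from_name("db4")
        cfg = DenoiseConfig(level=2, output_mode="reconstruction",
                            padding_mode="symmetric")
        t = np.arange(288)
        trend = 85 + 5 * np.sin(2 * np.pi * t / 288) + 0.01 * t
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            noisy = trend + rng.normal(0, 4.0, len(t))
            mse_den = np.mean((denoise(noisy, cfg, spec) - trend) ** 2)
            mse_raw = np.mean((noisy - trend) ** 2)
            wins += mse_den < mse_raw
        assert wins == 20

    @pytest.mark.parametrize("mode", ["periodic", "symmetric"])
    def test_dc_shift_equivariance(self, mode):
        # the low-pass branch preserves a constant offset exactly
        spec = WaveletSpec.from_name("db4")
        cfg = DenoiseConfig(level=2, output_mode="reconstruction", padding_mode=mode)
        x = np.random.default_rng(6).normal(size=128)
        np.testing.assert_allclose(
            denoise(x + 5.0, cfg, spec), denoise(x, cfg, spec) + 5.0, atol=1e-8
        )

    def test_approximation_matches_pywt_cascade(self):
        # independent cross-check of the whole cascade (symmetric mode)
        x = np.random.default_rng(8).normal(size=200)
        ours = denoise(x, DenoiseConfig(level=2, padding_mode="symmetric"),
                       WaveletSpec.from_name("db4"))
        ref = pywt.wavedec(x, "db4", mode="symmetric", level=2)[0]
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_too_short_for_level_names_minimum(self):
        spec = WaveletSpec.from_name("db4")
        with pytest.raises(ValueError, match="minimum admissible length"):
            denoise(np.ones(10), DenoiseConfig(level=2), spec)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            DenoiseConfig(level=-1)
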