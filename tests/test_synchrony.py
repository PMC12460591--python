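import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dyadkin as dk
from dyadkin.synchrony import FOURIER_FACTOR, BandSpec

from conftest import make_table


def moving_dyad_table(n=40, fps=30.0, seed=0):
    rng = np.random.default_rng(seed)
    data = {
        person: {k: (rng.random(n) * 500 + off, rng.random(n) * 400 + 100)
                 for k in range(3)}
        for off, person in ((100, "left"), (1100, "right"))
    }
    return make_table(data, fps=fps)


class TestMotionEnergy:
    def test_static_pose_zero_energy(self):
        x = np.full(10, 50.0)
        table = make_table({"left": {0: (x, x)}, "right": {0: (x + 900, x)}})
        energy = dk.compute_motion_energy(table)
        for s in energy.values():
            np.testing.assert_array_equal(s.values, 0.0)
            assert len(s) == 9  # frames - 1 after differencing

    def test_single_step_triangle(self):
        x = np.array([0.0, 3.0, 3.0])
        y = np.array([0.0, 4.0, 4.0])
        table = make_table({"left": {0: (x, y)}})
        absolute = dk.compute_motion_energy(table, method="absolute")["left"]
        squared = dk.compute_motion_energy(table, method="squared")["left"]
        assert absolute.values[0] == pytest.approx(5.0)
        assert squared.values[0] == pytest.approx(25.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_scaling_homogeneity(self, seed):
        table = moving_dyad_table(seed=seed)
        k = 3.0
        scaled = table.copy()
        cols = [c for c in table.triplet_columns() if c[0] in "xy"]
        scaled.df[cols] = scaled.df[cols] * k
        e1 = dk.compute_motion_energy(table, "absolute")["left"].values
        e2 = dk.compute_motion_energy(scaled, "absolute")["left"].values
        np.testing.assert_allclose(e2, k * e1, rtol=1e-9)
        s1 = dk.compute_motion_energy(table, "squared")["left"].values
        s2 = dk.compute_motion_energy(scaled, "squared")["left"].values
        np.testing.assert_allclose(s2, k**2 * s1, rtol=1e-9)

    def test_concatenation_matches_segment_energies(self):
        rng = np.random.default_rng(1)
        xa, xb = rng.random(10) * 100, rng.random(10) * 100
        whole = np.r_[xa, xb]
        t_whole = make_table({"left": {0: (whole, whole)}})
        t_a = make_table({"left": {0: (xa, xa)}})
        t_b = make_table({"left": {0: (xb, xb)}})
        e_whole = dk.compute_motion_energy(t_whole)["left"].values
        e_a = dk.compute_motion_energy(t_a)["left"].values
        e_b = dk.compute_motion_energy(t_b)["left"].values
        np.testing.assert_allclose(e_whole[:9], e_a)
        np.testing.assert_allclose(e_whole[10:], e_b)  # junction frame excluded

    def test_missing_keypoints_contribute_zero_with_coverage(self):
        x = np.arange(10.0)
        table = make_table({"left": {0: (x, x), 1: (x, x)}})
        table.df.loc[table.df.frame >= 5, ["x1", "y1"]] = np.nan
        s = dk.compute_motion_energy(table)["left"]
        assert s.coverage[0] == 1.0 and s.coverage[-1] == 0.5
        assert np.isfinite(s.values).all()

    def test_too_few_frames_rejected(self):
        x = np.array([1.0])
        table = make_table({"left": {0: (x, x)}})
        with pytest.raises(ValueError, match="2 frames"):
            dk.compute_motion_energy(table)


class TestMorletCwt:
    @pytest.mark.parametrize("period", [1.0, 2.0, 4.0])
    def test_sinusoid_power_peaks_at_its_period(self, period):
        fps = 30.0
        t = np.arange(1024) / fps
        x = np.sin(2 * np.pi * t / period)
        W, scales, period_s, _ = dk.morlet_cwt(x, fps)
        power = (np.abs(W) ** 2).mean(axis=1)
        best = period_s[np.argmax(power)]
        # dyadic scale grid: nearest scale is within one dj step (2^(1/12))
        assert abs(np.log2(best / period)) <= 1.5 / 12

    def test_fourier_factor_matches_analytic_form(self):
        w0 = 6.0
        assert FOURIER_FACTOR == pytest.approx(4 * np.pi / (w0 + np.sqrt(2 + w0**2)))

    def test_zero_series_zero_transform(self):
        W, *_ = dk.morlet_cwt(np.zeros(64), 30.0)
        np.testing.assert_allclose(np.abs(W), 0.0, atol=1e-12)

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=128)
        W1, *_ = dk.morlet_cwt(x, 30.0)
        W2, *_ = dk.morlet_cwt(2.0 * x, 30.0)
        np.testing.assert_allclose(W2, 2.0 * W1, rtol=1e-9, atol=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            dk.morlet_cwt(np.zeros(8), 30.0)

    def test_coi_monotone_toward_edges(self):
        _, _, _, coi = dk.morlet_cwt(np.random.default_rng(0).normal(size=100), 30.0)
        mid = len(coi) // 2
        assert (np.diff(coi[:mid]) >= 0).all() and (np.diff(coi[mid:]) <= 0).all()


class TestWaveletCoherence:
    def test_identical_series_coherence_near_one(self):
        x = np.random.default_rng(0).normal(size=512)
        res = dk.wavelet_coherence(x, x, 30.0)
        assert res.coherence[res.valid_mask()].mean() > 0.99

    def test_shared_frequency_beats_two_octaves_away(self):
        rng = np.random.default_rng(1)
        fps, n, f0 = 30.0, 1024, 0.5
        t = np.arange(n) / fps
        x = np.sin(2 * np.pi * f0 * t) + 0.5 * rng.normal(size=n)
        y = np.sin(2 * np.pi * f0 * t) + 0.5 * rng.normal(size=n)
        res = dk.wavelet_coherence(x, y, fps)
        m = res.valid_mask()
        at = np.argmin(np.abs(res.freq_hz - f0))
        away = np.argmin(np.abs(res.freq_hz - f0 / 4))
        coh_at = res.coherence[at][m[at]].mean()
        coh_away = res.coherence[away][m[away]].mean()
        assert coh_at > coh_away + 0.2

    def test_in_phase_signals_phase_near_zero(self):
        rng = np.random.default_rng(2)
        fps, n = 30.0, 512
        t = np.arange(n) / fps
        x = np.sin(2 * np.pi * 0.5 * t) + 0.2 * rng.normal(size=n)
        y = np.sin(2 * np.pi * 0.5 * t) + 0.2 * rng.normal(size=n)
        res = dk.wavelet_coherence(x, y, fps)
        at = np.argmin(np.abs(res.freq_hz - 0.5))
        m = res.valid_mask()[at]
        mean_phase = np.angle(np.exp(1j * res.phase[at][m]).mean())
        assert abs(mean_phase) < 0.1

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=256), rng.normal(size=256)
        ab = dk.wavelet_coherence(x, y, 30.0)
        ba = dk.wavelet_coherence(y, x, 30.0)
        np.testing.assert_allclose(ba.coherence, ab.coherence, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(ba.phase, -ab.phase, rtol=1e-9, atol=1e-9)

    @settings(deadline=None, max_examples=10)
    @given(seed=st.integers(0, 10_000))
    def test_coherence_bounded_on_arbitrary_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(32, 300))
        x = rng.normal(size=n) * rng.uniform(0.1, 50)
        y = rng.normal(size=n) * rng.uniform(0.1, 50)
        res = dk.wavelet_coherence(x, y, 30.0)
        assert res.coherence.max() <= 1.0 + 1e-9
        assert res.coherence.min() >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            dk.wavelet_coherence(np.zeros(100), np.zeros(101), 30.0)


class TestBandCoherence:
    def test_default_slow_band_resolvable_at_30fps(self):
        x = np.random.default_rng(0).normal(size=512)
        res = dk.wavelet_coherence(x, x, 30.0)
        out = dk.band_coherence(res, (BandSpec("slow", 0.1, 0.5),))
        assert out.iloc[0].n_cells > 0

    def test_identical_inputs_all_bands_near_one(self):
        x = np.random.default_rng(1).normal(size=512)
        res = dk.wavelet_coherence(x, x, 30.0)
        out = dk.band_coherence(res)
        assert (out.mean_coherence > 0.99).all()

    def test_independent_noise_below_identical_signal(self):
        rng = np.random.default_rng(2)
        n, fps = 1024, 30.0
        a, b = rng.normal(size=n), rng.normal(size=n)
        ident = dk.band_coherence(dk.wavelet_coherence(a, a, fps))
        indep = dk.band_coherence(dk.wavelet_coherence(a, b, fps))
        slow_ident = ident.set_index("band").loc["slow", "mean_coherence"]
        slow_indep = indep.set_index("band").loc["slow", "mean_coherence"]
        assert slow_indep < slow_ident - 0.3

    def test_unresolvable_band_errors_with_name(self):
        x = np.random.default_rng(0).normal(size=64)
        res = dk.wavelet_coherence(x, x, 30.0)
        with pytest.raises(ValueError, match="glacial"):
            dk.band_coherence(res, (BandSpec("glacial", 0.0001, 0.0002),))

    def test_band_above_nyquist_rejected(self):
        x = np.random.default_rng(0).normal(size=64)
        res = dk.wavelet_coherence(x, x, 30.0)
        with pytest.raises(ValueError, match="Nyquist"):
            dk.band_coherence(res, (BandSpec("hyper", 10.0, 20.0),))

    def test_invalid_band_spec_rejected(self):
        with pytest.raises(ValueError, match="f_lo"):
            BandSpec("bad", 0.5, 0.1)


class TestSignificance:
    def test_same_seed_identical_mask(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=256), rng.normal(size=256)
        m1, _ = dk.coherence_significance(x, y, 30.0, n_surrogates=100, seed=5)
        m2, _ = dk.coherence_significance(x, y, 30.0, n_surrogates=100, seed=5)
        np.testing.assert_array_equal(m1, m2)

    def test_shared_sinusoid_detected(self):
        rng = np.random.default_rng(1)
        t = np.arange(512) / 30.0
        s = np.sin(2 * np.pi * 0.5 * t)
        x = s + 0.3 * rng.normal(size=512)
        y = s + 0.3 * rng.normal(size=512)
        mask, res = dk.coherence_significance(x, y, 30.0, n_surrogates=100, seed=2)
        at = np.argmin(np.abs(res.freq_hz - 0.5))
        valid = res.valid_mask()[at]
        assert mask[at][valid].mean() > 0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            dk.coherence_significance(np.zeros(256), np.random.default_rng(0).normal(size=256),
                                      30.0, n_surrogates=100, seed=0)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError, match="100 surrogates"):
            dk.coherence_significance(np.zeros(256), np.zeros(256), 30.0, n_surrogates=50)
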