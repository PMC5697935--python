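"""Multitaper spectra, coherence, VAR fitting, and spectral Granger causality."""

import numpy as np
import pandas as pd
import pytest

from riskephys.core import LFPChannel, TrialTable
from riskephys.spectra import (band_mean, baseline_power, fit_var,
                               gc_permutation_bound, granger_pair,
                               msc_coherence, multitaper_spectrogram,
                               normalize_spectrogram, peri_event_segments,
                               spectral_gc)
from riskephys.synth import ground_truth
from riskephys.pipeline import RunConfig, spectra_stage


def _trials(n, spacing=12.0):
    cue = 6.0 + spacing * np.arange(n)
    return TrialTable(pd.DataFrame({
        "trial_id": np.arange(n), "block": np.ones(n, int),
        "cue_time": cue, "action_time": cue + 1.0, "reward_time": cue + 2.0,
        "shock_flag": np.zeros(n, bool), "rt": np.ones(n),
        "immobile_rt": np.full(n, 0.2), "reward_rt": np.ones(n)}))


def _channel(samples, fs=500.0, region="mPFC"):
    return LFPChannel(region, samples, fs)


class TestSpectrogram:
    def test_pure_tone_power_concentrated_at_its_frequency(self):
        """NW = 5 at 500 ms gives a +-10 Hz half-bandwidth, so a 10 Hz tone
        occupies 0-20 Hz; essentially no power leaks beyond the main lobe."""
        fs = 500.0
        t = np.arange(0, 120, 1 / fs)
        lfp = _channel(np.sin(2 * np.pi * 10 * t), fs)
        spec = multitaper_spectrogram(lfp, _trials(8), "action", (-1.0, 1.0))
        in_lobe = spec.freqs <= 20.0
        for row in spec.power:
            assert spec.freqs[np.argmax(row)] <= 20.0
            assert row[in_lobe].sum() / row.sum() > 0.99

    def test_white_noise_spectrum_flat(self, rng):
        fs = 500.0
        lfp = _channel(rng.standard_normal(int(120 * fs)), fs)
        spec = multitaper_spectrogram(lfp, _trials(8), "action", (-1.0, 1.0))
        mean_psd = spec.power.mean(0)
        sel = (spec.freqs > 15) & (spec.freqs < 110)
        ratio = mean_psd[sel].max() / mean_psd[sel].min()
        assert ratio < 1.6

    def test_parseval_total_power_matches_variance(self, rng):
        """One-sided PSD integrates to the segment variance."""
        fs = 500.0
        lfp = _channel(rng.standard_normal(int(120 * fs)), fs)
        spec = multitaper_spectrogram(lfp, _trials(10), "action",
                                      (-0.25, 0.25), fmax=fs / 2)
        df = spec.freqs[1] - spec.freqs[0]
        total = spec.power.mean(0).sum() * df
        assert total == pytest.approx(1.0, rel=0.1)

    def test_low_fs_rejected(self, rng):
        lfp = _channel(rng.standard_normal(1000), fs=100.0)
        with pytest.raises(ValueError):
            multitaper_spectrogram(lfp, _trials(2), "action", (-0.5, 0.5),
                                   fmax=125.0)


class TestNormalization:
    def test_baseline_equal_spectrogram_gives_zero(self, rng):
        fs = 500.0
        lfp = _channel(rng.standard_normal(int(150 * fs)), fs)
        trials = _trials(10)
        spec = multitaper_spectrogram(lfp, trials, "action", (-1.0, 1.0))
        base = baseline_power(lfp, trials)
        z = normalize_spectrogram(spec, base)
        # same stationary process: z fluctuates around 0
        assert abs(np.nanmean(z.power)) < 0.5

    def test_exact_two_sd_elevation(self):
        from riskephys.spectra import Spectrogram
        base = np.array([[1.0, 2.0], [3.0, 4.0], [2.0, 3.0]])  # trials x freq
        mu, sd = base.mean(0), base.std(0, ddof=1)
        spec = Spectrogram(power=(mu + 2 * sd)[None, :],
                           freqs=np.array([5.0, 10.0]),
                           window_centers=np.array([0.0]))
        z = normalize_spectrogram(spec, base)
        assert np.allclose(z.power, 2.0)

    def test_block_theta_decline_recovered(self, coupled_session):
        """Programmed block-decreasing theta amplitude appears as declining
        pre-action theta z-power."""
        out = spectra_stage(coupled_session, RunConfig())
        for region in ("VTA", "mPFC"):
            z = out["theta_z"][region]
            assert z[1] > z[2] > z[3]
            assert z[1] - z[3] > 0
        coh = out["coherence"]
        assert coh[1] > coh[3]
        gc = out["gc"]
        for b in (1, 2, 3):
            assert gc[b]["vta_to_mpfc"] > gc[b]["mpfc_to_vta"]


class TestCoherence:
    def test_identical_channels_fully_coherent(self, rng):
        fs = 500.0
        x = _channel(rng.standard_normal(int(100 * fs)), fs, "mPFC")
        y = _channel(x.samples.copy(), fs, "VTA")
        coh = msc_coherence(x, y, _trials(6), "action", (-0.5, 0.5))
        assert np.all(coh.power > 0.999)

    def test_independent_noise_low_coherence(self, rng):
        fs = 500.0
        n = int(150 * fs)
        x = _channel(rng.standard_normal(n), fs, "mPFC")
        y = _channel(rng.standard_normal(n), fs, "VTA")
        coh = msc_coherence(x, y, _trials(10), "action", (-0.5, 0.5))
        # bias floor ~ 1/(n_tapers*n_trials) = 1/90
        assert coh.power.mean() < 5.0 / 90.0

    def test_delayed_copy_elevates_band(self, rng):
        fs = 500.0
        n = int(100 * fs)
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, (8, 12), btype="bandpass", fs=fs, output="sos")
        s = sosfiltfilt(sos, rng.standard_normal(n)) * 5
        x = _channel(s + 0.5 * rng.standard_normal(n), fs, "mPFC")
        y_samples = np.zeros(n)
        y_samples[10:] = s[:-10]
        y = _channel(y_samples + 0.5 * rng.standard_normal(n), fs, "VTA")
        coh = msc_coherence(x, y, _trials(8), "action", (-0.5, 0.5))
        in_band = band_mean(coh.power.mean(0), coh.freqs, (8, 12))
        out_band = band_mean(coh.power.mean(0), coh.freqs, (40, 60))
        assert in_band > 5 * out_band

    def test_degenerate_pooling_rejected(self, rng):
        x = _channel(rng.standard_normal(5000), 500.0)
        y = _channel(rng.standard_normal(5000), 500.0)
        empty = TrialTable(_trials(1).df.iloc[:0])
        with pytest.raises(ValueError):
            msc_coherence(x, y, empty, "action", (-0.5, 0.5))


def _var2_sim(rng, n=20000, a=0.5):
    x1 = rng.standard_normal(n)
    x2 = np.empty(n)
    e2 = rng.standard_normal(n)
    x2[0] = e2[0]
    x2[1:] = a * x1[:-1] + e2[1:]
    return x1, x2


class TestVAR:
    def test_known_var2_coefficients_recovered(self, rng):
        n = 10000
        A1 = np.array([[0.5, 0.1], [0.0, 0.3]])
        A2 = np.array([[-0.2, 0.0], [0.15, 0.1]])
        x = np.zeros((2, n))
        eps = rng.standard_normal((2, n))
        for t in range(2, n):
            x[:, t] = A1 @ x[:, t - 1] + A2 @ x[:, t - 2] + eps[:, t]
        var = fit_var(x[0], x[1], order_max=6)
        assert var.order == 2
        se = 3.0 / np.sqrt(n)
        assert np.allclose(var.A[0], A1, atol=3 * se)
        assert np.allclose(var.A[1], A2, atol=3 * se)

    def test_white_noise_small_order_and_couplings(self, rng):
        x = rng.standard_normal(20000)
        y = rng.standard_normal(20000)
        var = fit_var(x, y, order_max=8)
        off = [abs(var.A[j][0, 1]) for j in range(var.order)] + \
              [abs(var.A[j][1, 0]) for j in range(var.order)]
        assert max(off) < 0.05

    def test_duplicated_channel_raises(self, rng):
        x = rng.standard_normal(5000)
        with pytest.raises(np.linalg.LinAlgError):
            fit_var(x, x.copy(), order_max=4)


class TestSpectralGC:
    def test_closed_form_unidirectional(self, rng):
        """X2 = 0.5 X1(t-1) + e: band-integrated GC(1->2) = ln 1.25."""
        x1, x2 = _var2_sim(rng, n=100000)
        var = fit_var(x1, x2, order_max=5)
        freqs = np.linspace(0.002, 0.498, 250)
        gc = spectral_gc(var, freqs)
        assert gc.gc_xy.mean() == pytest.approx(np.log(1.25), rel=0.05)
        assert gc.gc_yx.mean() < 0.005

    def test_swapping_channels_swaps_directions(self, rng):
        x1, x2 = _var2_sim(rng, n=30000)
        f = np.linspace(0.01, 0.49, 50)
        g_a = spectral_gc(fit_var(x1, x2, order=3), f)
        g_b = spectral_gc(fit_var(x2, x1, order=3), f)
        assert np.allclose(g_a.gc_xy, g_b.gc_yx, atol=1e-10)
        assert np.allclose(g_a.gc_yx, g_b.gc_xy, atol=1e-10)

    def test_spectral_integral_matches_time_domain(self, rng):
        """Mean spectral GC over (0, Nyquist) equals ln(reduced/full
        residual variance) from explicit AR fits."""
        x1, x2 = _var2_sim(rng, n=50000, a=0.4)
        order = 3
        var = fit_var(x1, x2, order=order)
        freqs = np.linspace(1e-3, 0.5 - 1e-3, 400)
        spec_int = spectral_gc(var, freqs).gc_xy.mean()
        # reduced model: x2 on its own past only (independent AR fit)
        n = x2.size
        X = np.column_stack([x2[order - j: n - j] for j in range(1, order + 1)])
        Y = x2[order:]
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        red_var = np.var(Y - X @ beta)
        td = np.log(red_var / var.Sigma[1, 1])
        assert spec_int == pytest.approx(td, rel=0.05)

    def test_gc_nonnegative(self, rng):
        x1, x2 = _var2_sim(rng, n=20000)
        gc = spectral_gc(fit_var(x1, x2, order=4),
                         np.linspace(0.01, 0.49, 60))
        assert np.all(gc.gc_xy >= 0) and np.all(gc.gc_yx >= 0)


class TestPermutationBound:
    def _segments(self, rng, n_seg=40, n_samp=500, coupled=False):
        xs, ys = [], []
        for _ in range(n_seg):
            x = rng.standard_normal(n_samp)
            y = rng.standard_normal(n_samp)
            if coupled:
                y[1:] += 0.4 * x[:-1]
            xs.append(x)
            ys.append(y)
        return xs, ys

    def test_null_pair_below_bound(self, rng):
        xs, ys = self._segments(rng)
        res = gc_permutation_bound(xs, ys, order_max=3, n_perm=60,
                                   alpha=0.05, rng=rng,
                                   freqs=np.linspace(0.02, 0.48, 20))
        frac_above = np.mean(res.gc_xy > res.perm_bound)
        assert frac_above <= 0.25  # ~alpha with MC noise across 20 freqs

    def test_coupled_pair_exceeds_bound(self, rng):
        xs, ys = self._segments(rng, coupled=True)
        res = gc_permutation_bound(xs, ys, order_max=3, n_perm=60,
                                   alpha=0.05, rng=rng,
                                   freqs=np.linspace(0.02, 0.48, 20))
        assert np.mean(res.gc_xy > res.perm_bound) > 0.9

    def test_alpha_one_degenerate_minimum(self, rng):
        xs, ys = self._segments(rng, n_seg=10)
        res = gc_permutation_bound(xs, ys, order_max=2, n_perm=25, alpha=1.0,
                                   rng=rng, freqs=np.linspace(0.05, 0.45, 5))
        assert np.all(res.perm_bound >= 0)

    def test_too_few_permutations_rejected(self, rng):
        xs, ys = self._segments(rng, n_seg=5)
        with pytest.raises(ValueError):
            gc_permutation_bound(xs, ys, n_perm=10, rng=rng)


class TestSessionGC:
    def test_programmed_direction_recovered(self, coupled_session,
                                            coupled_trials):
        """GC(VTA->mPFC) exceeds GC(mPFC->VTA) in the theta band."""
        truth = ground_truth(coupled_session)
        assert truth["lfp_coupling"]["direction"] == "VTA->mPFC"
        sub = TrialTable(coupled_trials.df[coupled_trials.df["block"] == 1])
        fs = coupled_session.lfp["VTA"].fs
        segs_v = peri_event_segments(coupled_session.lfp["VTA"], sub)
        segs_m = peri_event_segments(coupled_session.lfp["mPFC"], sub)
        gc = granger_pair(segs_v, segs_m, fs=fs)
        theta_fwd = band_mean(gc.gc_xy, gc.freqs, (5, 15))
        theta_rev = band_mean(gc.gc_yx, gc.freqs, (5, 15))
        assert theta_fwd > 2 * theta_rev
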