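"""Peri-event binning, wPEV, surrogate bands, SRC, and RT correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskephys.core import SpikeTrain, TrialTable, ValidationError
from riskephys.encoding import (baseline_block_modulation, bin_peri_event,
                                boxcar_smooth, classify_encoder, compute_wpev,
                                encode_unit, rate_rt_correlation,
                                src_direction, surrogate_bands, wpev_by_bin,
                                zscore_to_baseline, to_rates)
from riskephys.synth import GeneratorConfig, UnitTemplate, generate_session, \
    ground_truth
import pandas as pd


def _trials_df(n, spacing=10.0):
    cue = 5.0 + spacing * np.arange(n)
    return TrialTable(pd.DataFrame({
        "trial_id": np.arange(n), "block": np.ones(n, int),
        "cue_time": cue, "action_time": cue + 1.0, "reward_time": cue + 2.0,
        "shock_flag": np.zeros(n, bool), "rt": np.ones(n),
        "immobile_rt": np.full(n, 0.2), "reward_rt": np.ones(n)}))


class TestBinning:
    def test_spikes_fall_into_half_open_bins(self):
        trials = _trials_df(1)
        ev = trials.event_times("action")[0]
        spikes = SpikeTrain("u", "mPFC", ev + np.array([0.01, 0.06]), 0.4)
        t = bin_peri_event(spikes, trials, "action", (0.0, 0.2),
                           bin_width=0.05)
        assert t.data[0, 0].tolist() == [1, 1, 0, 0]

    def test_empty_spike_train_gives_zero_tensor(self):
        trials = _trials_df(3)
        spikes = SpikeTrain("u", "mPFC", np.empty(0), 0.4)
        t = bin_peri_event(spikes, trials, "cue", (-1.0, 1.0), 0.05)
        assert not t.data.any()

    def test_missing_event_names_trial(self):
        trials = _trials_df(3)
        trials.df.loc[1, "reward_time"] = np.nan
        spikes = SpikeTrain("u", "mPFC", np.array([5.0]), 0.4)
        with pytest.raises(ValidationError, match="trial 1"):
            bin_peri_event(spikes, trials, "reward", (-1.0, 1.0), 0.05)

    def test_boxcar_center_value(self):
        assert boxcar_smooth(np.array([0, 0, 5, 0, 0]), 5)[2] == 1.0

    def test_boxcar_edge_truncation_renormalizes(self):
        out = boxcar_smooth(np.ones(10), 5)
        assert np.allclose(out, 1.0)

    def test_bin_centers_tile_window(self):
        trials = _trials_df(2)
        spikes = SpikeTrain("u", "mPFC", np.empty(0), 0.4)
        t = bin_peri_event(spikes, trials, "action", (-1.0, 1.0), 0.2, 0.05)
        assert t.bin_starts[0] == -1.0
        assert t.bin_starts[-1] + t.bin_width == pytest.approx(1.0)


class TestZScore:
    def _tensors(self, rate_hz, base_hz, sd_pattern=None):
        # two tensors with programmed rates via direct data injection
        from riskephys.core import PeriEventTensor
        ev = PeriEventTensor(np.full((1, 4, 5), rate_hz * 0.05), "action",
                             (-0.1, 0.15), 0.05, 0.05, np.arange(4), ["u"])
        base_data = np.full((1, 4, 8), base_hz * 0.05)
        if sd_pattern is not None:
            base_data += sd_pattern
        base = PeriEventTensor(base_data, "baseline", (-2.5, -0.5), 0.05,
                               0.05, np.arange(4), ["u"])
        return ev, base

    def test_rate_equal_to_baseline_mean_gives_zero(self):
        pattern = np.tile([-1e-3, 1e-3], 16).reshape(1, 4, 8)  # zero mean
        ev, base = self._tensors(4.0, 4.0, sd_pattern=pattern)
        z, flagged = zscore_to_baseline(ev, base)
        assert not flagged
        assert np.allclose(z, 0.0, atol=1e-9)

    def test_two_sd_above_baseline(self):
        from riskephys.core import PeriEventTensor
        rng = np.random.default_rng(0)
        base_rates = np.array([2.0, 6.0] * 16).reshape(1, 4, 8)  # mean 4 sd 2
        base = PeriEventTensor(base_rates * 0.05, "baseline", (-2.5, -0.5),
                               0.05, 0.05, np.arange(4), ["u"])
        ev = PeriEventTensor(np.full((1, 4, 5), 8.0 * 0.05), "action",
                             (-0.1, 0.15), 0.05, 0.05, np.arange(4), ["u"])
        z, _ = zscore_to_baseline(ev, base)
        sd = np.std(base_rates, ddof=1)
        assert np.allclose(z, (8.0 - 4.0) / sd)

    def test_zero_variance_baseline_flagged(self):
        ev, base = self._tensors(8.0, 4.0)
        z, flagged = zscore_to_baseline(ev, base)
        assert flagged == ["u"]
        assert np.isnan(z).all()

    def test_programmed_bump_peak_location(self, coupled_session,
                                           coupled_trials):
        """Z-scored rate peaks at the programmed response latency +-1 bin."""
        unit = coupled_session.unit("v00")  # reward response at 0.1 s
        ev = bin_peri_event(unit, coupled_trials, "reward", (-1.0, 1.0), 0.05)
        base = bin_peri_event(unit, coupled_trials, "baseline", (-2.5, -0.5),
                              0.05)
        z, _ = zscore_to_baseline(ev, base)
        mean_z = boxcar_smooth(z[0].mean(0), 5)
        peak = ev.bin_centers[np.argmax(mean_z)]
        assert abs(peak - 0.1) <= 0.075  # programmed latency +-1 bin + center


class TestWPEV:
    def test_perfect_separation_gives_one(self):
        assert compute_wpev([[0, 0], [2, 2], [4, 4]]) == pytest.approx(1.0)

    def test_identical_blocks_give_minus_half(self):
        assert compute_wpev([[1, 3], [1, 3], [1, 3]]) == pytest.approx(-0.5)

    def test_all_equal_counts_give_zero_by_convention(self):
        assert compute_wpev([[2, 2], [2, 2], [2, 2]]) == 0.0

    def test_short_block_rejected(self):
        with pytest.raises(ValueError):
            compute_wpev([[1], [2, 3]])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_label_permutation_invariance(self, seed):
        """Relabeling blocks by a permutation leaves wPEV unchanged."""
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, (30, 4)).astype(float)
        labels = np.repeat([1, 2, 3], 10)
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = np.vectorize(perm.get)(labels)
        assert np.allclose(wpev_by_bin(counts, labels),
                           wpev_by_bin(counts, relabeled))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_wpev_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(2.0, (24, 3)).astype(float)
        labels = np.repeat([1, 2, 3], 8)
        assert np.all(wpev_by_bin(counts, labels) <= 1.0 + 1e-12)


class TestSurrogateBands:
    def test_global_band_at_least_pointwise(self, rng):
        counts = rng.poisson(2.0, (90, 20)).astype(float)
        labels = np.repeat([1, 2, 3], 30)
        bands = surrogate_bands(counts, labels, 300, 0.05, rng)
        assert np.all(bands.global_band >= bands.pointwise - 1e-12)

    def test_single_bin_global_equals_pointwise(self, rng):
        counts = rng.poisson(2.0, (90, 1)).astype(float)
        labels = np.repeat([1, 2, 3], 30)
        bands = surrogate_bands(counts, labels, 300, 0.05, rng)
        assert bands.global_band == pytest.approx(bands.pointwise[0])

    def test_all_zero_surrogates_give_zero_bands(self, rng):
        counts = np.zeros((30, 4))
        labels = np.repeat([1, 2, 3], 10)
        bands = surrogate_bands(counts, labels, 200, 0.01, rng)
        assert bands.global_band == 0.0
        assert np.all(bands.pointwise == 0.0)

    def test_bands_monotone_in_alpha(self):
        counts = np.random.default_rng(3).poisson(2.0, (90, 10)).astype(float)
        labels = np.repeat([1, 2, 3], 30)
        strict = surrogate_bands(counts, labels, 400, 0.01,
                                 np.random.default_rng(9))
        loose = surrogate_bands(counts, labels, 400, 0.10,
                                np.random.default_rng(9))
        assert strict.global_band >= loose.global_band
        assert np.all(strict.pointwise >= loose.pointwise - 1e-12)

    def test_too_few_shuffles_rejected(self, rng):
        with pytest.raises(ValueError):
            surrogate_bands(np.zeros((30, 2)), np.repeat([1, 2, 3], 10),
                            50, 0.01, rng)


class TestClassifyEncoder:
    def test_trace_below_band_is_not_encoder(self, rng):
        from riskephys.encoding import SurrogateBands
        bands = SurrogateBands(np.full(5, 0.3), 0.5, 0.0, 0.1, 1000, 0.01)
        res = classify_encoder(np.full(5, 0.1), bands, "u")
        assert not res.encoder and res.crossing_bins.size == 0

    def test_crossing_bins_recorded(self):
        from riskephys.encoding import SurrogateBands
        bands = SurrogateBands(np.full(20, 0.3), 0.5, 0.0, 0.1, 1000, 0.01)
        trace = np.zeros(20)
        trace[12:16] = 0.6
        res = classify_encoder(trace, bands, "u")
        assert res.encoder
        assert res.crossing_bins.tolist() == [12, 13, 14, 15]

    def test_encode_unit_deterministic(self, coupled_session, coupled_trials):
        u = coupled_session.unit("m00")
        a = encode_unit(u, coupled_trials, n_shuffles=200, seed=5)
        b = encode_unit(u, coupled_trials, n_shuffles=200, seed=5)
        assert a.global_band == b.global_band
        assert np.array_equal(a.wpev, b.wpev)


class TestSRC:
    def test_counts_proportional_to_block_give_one(self):
        blocks = np.repeat([1, 2, 3], 4)
        res = src_direction(2.0 * blocks, blocks)
        assert res.summary == pytest.approx(1.0)
        assert res.sign == "excitatory"

    def test_constant_counts_give_zero_with_flag(self):
        blocks = np.repeat([1, 2, 3], 4)
        res = src_direction(np.full(12, 5.0), blocks)
        assert res.summary == 0.0
        assert res.flagged_bins.size > 0

    def test_src_equals_pearson(self, rng):
        """Standardized beta*(Sx/Sy) coincides with Pearson r to 1e-12."""
        from scipy import stats
        blocks = np.repeat([1, 2, 3], 15)
        counts = rng.poisson(4.0, 45).astype(float)
        res = src_direction(counts, blocks)
        # independent oracle: explicit OLS slope times Sx/Sy
        x = blocks.astype(float)
        beta = np.polyfit(x, counts, 1)[0]
        src_manual = beta * x.std(ddof=1) / counts.std(ddof=1)
        assert res.summary == pytest.approx(src_manual, abs=1e-12)
        assert res.summary == pytest.approx(stats.pearsonr(x, counts)[0],
                                            abs=1e-12)


class TestBaselineModulation:
    def test_programmed_baseline_shift_detected(self, coupled_session,
                                                coupled_trials):
        truth = ground_truth(coupled_session)
        unit = coupled_session.unit("m20")  # baseline offsets (1, 1.15, 1.5)
        assert truth["units"]["m20"]["baseline_modulated"]
        out = baseline_block_modulation(unit, coupled_trials)
        assert out["modulated"] and out["direction"] == "excitatory"

    def test_null_calibration(self):
        """Identical baseline distributions: rejection at ~alpha."""
        rng = np.random.default_rng(2)
        n_units, rejected = 150, 0
        blocks = np.repeat([1, 2, 3], 45)
        from scipy import stats as sps
        for _ in range(n_units):
            counts = rng.poisson(8.0, 135)
            groups = [counts[blocks == b] for b in (1, 2, 3)]
            rejected += sps.kruskal(*groups).pvalue < 0.05
        rate = rejected / n_units
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_units)

    def test_constant_rate_non_rejection(self):
        trials = _trials_df(30)
        trials.df["block"] = np.repeat([1, 2, 3], 10)
        spikes = SpikeTrain("u", "mPFC", np.arange(0.0, 300.0, 0.5), 0.4)
        out = baseline_block_modulation(spikes, trials)
        assert not out["modulated"]


class TestRateRTCorrelation:
    def test_exact_linear_relation_gives_unit_r(self):
        rts = np.linspace(0.5, 3.0, 20)
        rates = 2.0 + 3.0 * np.log(rts)
        out = rate_rt_correlation(rates, rts)
        assert out["r"] == pytest.approx(1.0)

    def test_constant_rates_flagged(self):
        out = rate_rt_correlation(np.full(20, 2.0), np.linspace(1, 2, 20))
        assert out["flagged"] and np.isnan(out["r"])

    def test_latent_coupled_unit_sign(self, coupled_session, coupled_trials):
        """Positive latent coupling: peri-action rate correlates positively
        with RT across trials."""
        u = coupled_session.unit("m10")  # non-encoder, latent_gain > 0
        t = bin_peri_event(u, coupled_trials, "action", (-0.5, 0.5), 1.0)
        out = rate_rt_correlation(t.data[0, :, 0],
                                  coupled_trials.df["rt"].to_numpy())
        assert out["r"] > 0


class TestRecovery:
    def test_encoder_recovery_sensitivity_specificity(self, coupled_session,
                                                      coupled_trials):
        """Detected encoder set matches the programmed one (>= 0.9/0.9)."""
        truth = ground_truth(coupled_session)["units"]
        tp = fp = fn = tn = 0
        for u in coupled_session.units:
            res = encode_unit(u, coupled_trials, n_shuffles=500, seed=0)
            is_true = truth[u.unit_id]["encoder"]
            tp += res.encoder and is_true
            fp += res.encoder and not is_true
            fn += (not res.encoder) and is_true
            tn += (not res.encoder) and not is_true
        assert tp / (tp + fn) >= 0.9
        assert tn / (tn + fp) >= 0.9
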