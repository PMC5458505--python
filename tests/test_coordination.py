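import numpy as np
import pytest
from scipy.stats import binom

import sleepcoord as sc
from sleepcoord.coordination import (
    binomial_order_test,
    bonferroni_level,
    conditional_ds_probability,
    corticothalamic_ds_delay,
    ds_onset_latency,
    enrichment_factor,
    event_histogram,
    gamma_trough_delay,
    histogram_peak_latency,
    overlap_fraction,
    proportion_spindles_with_ds,
)
from sleepcoord.recording import CORTEX, THALAMUS
from sleepcoord.signal_core import Signal


class TestEventHistogram:
    def test_identical_lists_pile_into_zero_lag_bin(self):
        refs = [1.0, 5.0, 9.0]
        h = event_histogram(refs, refs, window_s=0.5)
        i = np.searchsorted(h.edges_s, 0.0)
        assert h.counts[i] == 3 and h.counts.sum() == 3

    def test_fixed_offset_counts_in_expected_bin(self):
        refs = np.arange(10, 110, 10.0)
        targets = refs + 0.120
        h = event_histogram(refs, targets, window_s=2.0)
        centers = h.centers_s
        i = np.argmin(np.abs(centers - 0.125))
        assert h.counts[i] == 10
        assert h.counts.sum() == 10

    def test_empty_target_list_gives_zeros(self):
        h = event_histogram([1.0, 2.0], [], window_s=0.5)
        assert h.counts.sum() == 0

    def test_empty_reference_warns(self):
        with pytest.warns(UserWarning):
            h = event_histogram([], [1.0], window_s=0.5)
        assert h.counts.sum() == 0

    def test_invariant_under_global_time_shift(self):
        rng = np.random.default_rng(0)
        refs = np.sort(rng.uniform(0, 100, 50))
        tgts = np.sort(rng.uniform(0, 100, 60))
        h1 = event_histogram(refs, tgts)
        h2 = event_histogram(refs + 1234.5, tgts + 1234.5)
        np.testing.assert_array_equal(h1.counts, h2.counts)


class TestBinomialOrderTest:
    def test_ten_versus_zero(self):
        refs = [100.0 * i for i in range(10)]
        targets = [r - 0.2 for r in refs]  # all targets precede
        r = binomial_order_test(refs, targets)
        assert r.n_before == 10 and r.n_after == 0
        assert r.p_two_sided == pytest.approx(2 * 0.5 ** 10, rel=1e-9)

    def test_balanced_counts_give_p_one(self):
        refs = [100.0 * i for i in range(10)]
        targets = [r - 0.2 for r in refs[:5]] + [r + 0.2 for r in refs[5:]]
        r = binomial_order_test(refs, targets)
        assert r.p_two_sided == pytest.approx(1.0)
        assert r.direction == "none"

    def test_seven_three_split(self):
        refs = [100.0 * i for i in range(10)]
        targets = [r - 0.2 for r in refs[:7]] + [r + 0.2 for r in refs[7:]]
        r = binomial_order_test(refs, targets)
        assert r.p_two_sided == pytest.approx(0.34375, rel=1e-9)

    def test_zero_lag_pairs_excluded_and_empty_errors(self):
        with pytest.raises(ValueError):
            binomial_order_test([1.0], [1.0])

class TestBonferroni:
    def test_printed_level_for_sixty_four_pairs(self):
        level = bonferroni_level(0.05, 64)
        assert level == pytest.approx(0.00078125)
        assert float(f"{level:.2g}") == 0.00078

    def test_single_test_is_alpha(self):
        assert bonferroni_level(0.05, 1) == 0.05

    def test_twenty_tests(self):
        assert bonferroni_level(0.05, 20) == pytest.approx(0.0025)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_level(0.05, 0)


class TestConditionalDsProbability:
    def test_single_channel_is_one_by_one(self):
        res = conditional_ds_probability({"C1": [1.0, 2.0]}, [1.1, 2.5])
        assert res.probability.shape == (1, 1)
        assert np.isnan(res.p_chi2).all()

    def test_coupled_schedule_raises_joint_probability(self):
        # sparse clusters (low per-cluster participation) so the number of
        # co-occurring cortical DSs genuinely varies from cluster to cluster
        cfg = sc.SimConfig(duration_s=7200.0, seed=6, cluster_rate_per_min=60.0)
        gt = sc.build_event_schedule(cfg)
        ctx = {ch: gt.ds_peaks(ch) for ch in ["C1", "C2", "C3", "C4"]}
        res = conditional_ds_probability(ctx, gt.ds_peaks("T1"))
        diag = np.diag(res.probability)
        off = res.probability[~np.eye(4, dtype=bool)]
        assert np.nanmean(off) > np.nanmean(diag)
        assert res.significant.any()

    def test_independent_trains_show_no_bias(self):
        rng = np.random.default_rng(7)
        dur, rate = 3000.0, 0.3
        ctx = {f"C{i}": np.sort(rng.uniform(0, dur, int(dur * rate))) for i in range(2)}
        thal = np.sort(rng.uniform(0, dur, int(dur * rate)))
        res = conditional_ds_probability(ctx, thal)
        diag = np.diag(res.probability)
        off = res.probability[~np.eye(2, dtype=bool)]
        assert np.nanmean(off) == pytest.approx(np.nanmean(diag), abs=0.1)

class TestCorticothalamicDelay:
    def _sim(self, delay_sd, seed=10):
        cfg = sc.SimConfig(duration_s=900.0, seed=seed, ct_ds_delay_s=(0.2, delay_sd))
        return sc.simulate(cfg)

    def test_recovers_zero_sd_delay_exactly(self):
        rec, gt = self._sim(0.0)
        ds = {ch: gt.ds_peaks(ch) for ch in rec.channel_names}
        est = corticothalamic_ds_delay([("C1", "T1")], rec.signals, ds)
        assert est.value_s == pytest.approx(-0.2, abs=1.5 / 256)

    def test_overall_is_mean_of_pairs(self):
        rec, gt = self._sim(0.05)
        ds = {ch: gt.ds_peaks(ch) for ch in rec.channel_names}
        pairs = [("C1", "T1"), ("C2", "T1"), ("C1", "T2")]
        est = corticothalamic_ds_delay(pairs, rec.signals, ds)
        assert est.value_s == pytest.approx(np.mean(list(est.per_pair_s.values())))

    def test_all_pairs_skipped_errors(self):
        rec, gt = self._sim(0.0)
        ds = {ch: np.array([]) for ch in rec.channel_names}
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                corticothalamic_ds_delay([("C1", "T1")], rec.signals, ds)


class TestDsOnsetLatency:
    def test_cubic_with_known_inflection(self):
        t = np.linspace(-1, 1, 513)
        y = (t + 0.3) ** 3  # inflection exactly at -0.3
        sig = Signal(y, rate_hz=256.0, t0_s=-1.0)
        assert ds_onset_latency(sig, guess_s=-0.25) == pytest.approx(-0.3, abs=0.001)

    def test_symmetric_waveform_tie_goes_to_nearer(self):
        t = np.linspace(-1, 1, 513)
        y = t ** 4 - t ** 2  # inflections symmetric around 0
        sig = Signal(y, rate_hz=256.0, t0_s=-1.0)
        lat = ds_onset_latency(sig, guess_s=0.2)
        assert lat > 0

    def test_sigmoid_onset_recovered_precisely(self):
        # smooth sigmoid drop: analytic inflection exactly at -0.25
        rate = 256.0
        t = np.arange(-1.0, 1.0, 1 / rate)
        y = -50.0 * (1.0 + np.tanh((t + 0.25) / 0.05))
        sig = Signal(y, rate_hz=rate, t0_s=-1.0)
        lat = ds_onset_latency(sig, guess_s=-0.25)
        assert lat == pytest.approx(-0.25, abs=0.01)

    def test_ds_template_onset_recovered_coarsely(self):
        # the half-sine template's onset is a curvature kink rather than a
        # sign-change inflection, so the polynomial method localizes it only
        # to within about a tenth of a second
        rate = 256.0
        t = np.arange(-1.0, 1.0, 1 / rate)
        y = np.zeros_like(t)
        sel = (t >= -0.25) & (t <= 0.25)
        y[sel] = -100 * np.sin(np.pi * (t[sel] + 0.25) / 0.5)
        sig = Signal(y, rate_hz=rate, t0_s=-1.0)
        lat = ds_onset_latency(sig, guess_s=-0.25)
        assert lat == pytest.approx(-0.25, abs=0.12)

    def test_pure_line_has_no_inflection(self):
        t = np.linspace(-1, 1, 257)
        sig = Signal(1e-6 * t, rate_hz=128.0, t0_s=-1.0)
        try:
            lat = ds_onset_latency(sig, guess_s=0.0)
        except ValueError:
            return  # acceptable: no real inflection
        assert -1.0 <= lat <= 1.0  # numerically degenerate fits stay in range


class TestHistogramPeak:
    def _hist(self, counts, bin_s=0.05, window_s=0.5):
        n = int(window_s / bin_s)
        edges = bin_s * np.arange(-n, n + 1)
        return sc.EventHistogram("", "", "", "", bin_s, edges, np.asarray(counts))

    def test_bin_midpoint_returned(self):
        counts = np.zeros(20, dtype=int)
        counts[12] = 7  # bin [100,150) ms... edges at -500..500
        h = self._hist(counts)
        assert histogram_peak_latency(h) == pytest.approx(0.125)

    def test_tie_prefers_nearest_zero_then_earlier(self):
        counts = np.zeros(20, dtype=int)
        counts[10] = 5   # [0, 50) -> center 25 ms
        counts[16] = 5   # [300, 350)
        h = self._hist(counts)
        assert histogram_peak_latency(h) == pytest.approx(0.025)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            histogram_peak_latency(self._hist(np.zeros(20, dtype=int)))


class TestGammaTroughDelay:
    def test_recovers_configured_lag(self, sim30):
        rec, gt = sim30
        troughs = gt.projected_troughs("T1", "C1")
        est = gamma_trough_delay(rec.signals["T1"], rec.signals["C1"], troughs,
                                 subset_size=150)
        assert est.value_s * 1000 == pytest.approx(15.0, abs=5.0)
        assert est.p_value is not None and est.p_value < 0.05

    def test_empty_troughs_error(self, sim30):
        rec, _ = sim30
        with pytest.raises(ValueError):
            gamma_trough_delay(rec.signals["T1"], rec.signals["C1"], [])


class TestEnrichment:
    def test_printed_formula_worked_example(self):
        # tallest bin 5, 100 DSs, 300 spindles in 60 min:
        # peak = (20*60*5)/100 = 60/min, overall = 5/min, factor 12
        ds = 100.0 * np.arange(100)
        background = 5.55 + 10.0 * np.arange(295)   # never within 0.5 s of a DS
        spindles = list(background) + [ds[i] + 0.01 for i in range(5)]
        res = enrichment_factor(spindles, ds, total_minutes=60.0)
        assert res.n_ds == 100 and res.n_spindles == 300
        assert res.peak_density_per_min == pytest.approx(60.0)
        assert res.overall_density_per_min == pytest.approx(5.0)
        assert res.factor == pytest.approx(12.0)

    def test_no_spindles_gives_zero_factor(self):
        res = enrichment_factor([], [1.0, 2.0], total_minutes=10.0)
        assert res.factor == 0.0

    def test_zero_ds_errors(self):
        with pytest.raises(ValueError):
            enrichment_factor([1.0], [], total_minutes=10.0)

    def test_independent_trains_enrichment_near_one(self):
        rng = np.random.default_rng(11)
        dur = 36000.0
        ds = np.sort(rng.uniform(0, dur, int(dur / 60 * 15)))
        sp = np.sort(rng.uniform(0, dur, int(dur / 60 * 6)))
        res = enrichment_factor(sp, ds, total_minutes=dur / 60)
        assert 0.8 < res.factor < 1.6  # max-bin bias keeps it slightly above 1


class TestProportionWithDs:
    def test_printed_normalization_worked_example(self):
        # 40 of 100 spindles coupled; 200 DSs; subject max 400 -> 0.8
        ds = np.arange(0, 2000, 10.0)[:200]
        spindles = [ds[i] + 0.5 for i in range(40)]          # inside [0,0.75]
        spindles += [ds[i] + 5.0 for i in range(40, 100)]    # far from any DS
        p = proportion_spindles_with_ds(spindles, ds, CORTEX, [200, 400])
        assert p == pytest.approx((40 / 100) / (200 / 400))

    def test_max_channel_equals_raw_proportion(self):
        ds = np.arange(0, 1000, 10.0)
        spindles = [ds[0] + 0.2, ds[1] + 5.0]
        p = proportion_spindles_with_ds(spindles, ds, CORTEX, [len(ds)])
        assert p == pytest.approx(0.5)

    def test_thalamic_window_is_asymmetric(self):
        ds = [100.0]
        assert proportion_spindles_with_ds([99.7], ds, THALAMUS, [1]) == 1.0
        assert proportion_spindles_with_ds([99.7], ds, CORTEX, [1]) == 0.0

    def test_no_coupled_spindles_is_zero(self):
        assert proportion_spindles_with_ds([50.0], [10.0], CORTEX, [1]) == 0.0


class TestOverlapFraction:
    def test_identical_and_disjoint(self):
        a = [(0.0, 1.0), (2.0, 3.0)]
        assert overlap_fraction(a, a)[0] == 1.0
        assert overlap_fraction(a, [(5.0, 6.0)])[0] == 0.0

    def test_asymmetric_example(self):
        a = [(0.0, 1.0)]
        b = [(0.9, 1.5), (3.0, 4.0)]
        assert overlap_fraction(a, b)[0] == 1.0
        frac_b, matched = overlap_fraction(b, a)
        assert frac_b == 0.5

    def test_boundary_touching_counts(self):
        assert overlap_fraction([(0.0, 1.0)], [(1.0, 2.0)])[0] == 1.0
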