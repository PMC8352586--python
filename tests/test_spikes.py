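import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdvmotive import behavior, spikes, synth
from tdvmotive.spikes import ResponseWindow

from conftest import poisson_spike_data


def manual_window(start, end, event="cue"):
    return ResponseWindow(
        event=event, start_ms=float(start), end_ms=float(end), is_responsive=True,
        p_values=np.array([]), window_starts=np.array([]), significant=np.array([]),
    )


class TestSpikeData:
    def test_unsorted_raises(self):
        trials = pd.DataFrame(
            {"session_id": "s", "trial_index": [0], "reward_size": [1],
             "delay_class": [0], "delay_mean_s": [0.3], "outcome": ["correct"],
             "rcum": [0.5], "go_ms": [1000.0], "release_ms": [1350.0], "reward_ms": [1650.0]}
        )
        with pytest.raises(ValueError, match="not sorted"):
            spikes.SpikeData("n", trials, [np.array([5.0, 1.0])])


class TestDetectResponse:
    def test_zero_spikes_not_responsive(self):
        rng = np.random.default_rng(0)
        sd = poisson_spike_data(rng, n_trials=10, rate_fn=lambda i: [(-1000, 2100, 0.0)])
        win = spikes.detect_response(sd, "cue")
        assert not win.is_responsive
        assert win.start_ms is None and win.end_ms is None

    def test_injected_step_detected(self):
        rng = np.random.default_rng(1)
        sd = poisson_spike_data(
            rng, n_trials=30,
            rate_fn=lambda i: [(-1000, 100, 10.0), (100, 500, 30.0), (500, 2100, 10.0)],
        )
        win = spikes.detect_response(sd, "cue")
        assert win.is_responsive
        assert 50 <= win.start_ms <= 200
        assert win.end_ms <= 700
        assert win.duration_ms == win.end_ms - win.start_ms

    def test_pearson_variant_runs(self):
        rng = np.random.default_rng(2)
        sd = poisson_spike_data(
            rng, n_trials=30,
            rate_fn=lambda i: [(-1000, 100, 10.0), (100, 500, 30.0), (500, 2100, 10.0)],
        )
        win = spikes.detect_response(sd, "cue", test="pearson")
        assert win.is_responsive

    def test_release_alignment(self):
        # response locked to bar release, not cue
        rng = np.random.default_rng(3)

        def rate_fn(i):
            rel = 1350.0
            return [(-1000, rel - 100, 5.0), (rel - 100, rel + 100, 40.0), (rel + 100, 2100, 5.0)]

        sd = poisson_spike_data(rng, n_trials=30, rate_fn=rate_fn)
        win = spikes.detect_response(sd, "release")
        assert win.is_responsive
        assert -150 <= win.start_ms <= -50

    def test_false_positive_rate_oracle_equivalence(self):
        # implementation-vs-oracle: the detector's significance trace matches a
        # direct recomputation of the pooled 2x2 exact test
        rng = np.random.default_rng(4)
        sd = poisson_spike_data(rng, n_trials=20, rate_fn=lambda i: [(-1000, 2100, 3.0)])
        win = spikes.detect_response(sd, "cue")
        n_bg = 500 * sd.n_trials
        filled_bg = sum(
            np.unique(np.floor(s[(s >= -500) & (s < 0)]).astype(int)).size for s in sd.spikes
        )
        for j, t0 in enumerate(win.window_starts[:30]):
            fw = sum(
                np.unique(np.floor(s[(s >= t0) & (s < t0 + 100)]).astype(int)).size
                for s in sd.spikes
            )
            n_w = 100 * sd.n_trials
            p = min(2 * stats.hypergeom.sf(fw - 1, n_w + n_bg, fw + filled_bg, n_w), 1.0)
            assert win.p_values[j] == pytest.approx(p, rel=1e-9)
            assert win.significant[j] == (p < 0.05 and fw / n_w > filled_bg / n_bg)


class TestResponseRate:
    def test_arithmetic(self):
        trials = pd.DataFrame(
            {"session_id": "s", "trial_index": [0, 1], "reward_size": [1, 1],
             "delay_class": [0, 0], "delay_mean_s": [0.3, 0.3],
             "outcome": ["correct", "correct"], "rcum": [0.2, 0.4],
             "go_ms": [1000.0] * 2, "release_ms": [1350.0] * 2, "reward_ms": [1650.0] * 2}
        )
        sd = spikes.SpikeData("n", trials, [np.array([110.0, 150.0, 299.0]), np.empty(0)])
        rates = spikes.response_rate(sd, manual_window(100, 300))
        np.testing.assert_allclose(rates, [15.0, 0.0])

    def test_zero_duration_raises(self):
        rng = np.random.default_rng(0)
        sd = poisson_spike_data(rng, n_trials=3)
        with pytest.raises(ValueError):
            spikes.response_rate(sd, manual_window(100, 100))

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sd = poisson_spike_data(rng, n_trials=8, rate_fn=lambda i: [(-1000, 2100, 20.0)])
            a, b = sorted(rng.uniform(-500, 1500, 2))
            if b - a < 1:
                continue
            win = manual_window(a, b)
            got = spikes.response_rate(sd, win)
            want = [sum(1 for t in s if a <= t < b) / ((b - a) / 1000) for s in sd.spikes]
            np.testing.assert_allclose(got, want)


class TestDvRegression:
    def test_perfect_fit(self):
        dv = np.tile([0.5, 1.0, 2.0, 4.0], 10)
        y = 2.0 + 3.0 * dv
        fit = spikes.fit_dv_regression(y, dv)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coef_of("dv") == pytest.approx(3.0)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(6)
        dv = np.tile([0.5, 1.0, 2.0, 4.0], 25)
        y = 1.0 + 0.5 * dv + rng.normal(0, 1, dv.size)
        fit = spikes.fit_dv_regression(y, dv)
        r = np.corrcoef(y, dv)[0, 1]
        assert fit.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_constant_dv_raises(self):
        with pytest.raises(ValueError):
            spikes.fit_dv_regression(np.ones(10), np.full(10, 2.0))

    def test_permutation_calibration(self):
        rng = np.random.default_rng(7)
        dv = np.tile([0.5, 1.0, 2.0, 4.0], 15)
        y = rng.normal(5, 1, dv.size)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            fit = spikes.fit_dv_regression(y, rng.permutation(dv))
            hits += fit.p_of("dv") < 0.05
        assert 0.03 <= hits / n_perm <= 0.07

    def test_sprc_sign_matches_coef(self):
        rng = np.random.default_rng(8)
        dv = np.tile([0.5, 1.0, 2.0, 4.0], 10)
        y = 10 - 2.0 * dv + rng.normal(0, 0.5, dv.size)
        fit = spikes.fit_dv_regression(y, dv)
        assert fit.coef_of("dv") < 0
        assert fit.sprc_of("dv") < 0


class TestClassifyNeuron:
    @staticmethod
    def design(n_rep=20, k=0.5):
        R = np.tile([1.0, 1, 1, 4, 4, 4], n_rep)
        D = np.tile([0.3, 3.3, 6.9] * 2, n_rep)
        dv = R / (1 + k * D)
        return R, D, dv

    def test_dv_neuron(self):
        rng = np.random.default_rng(9)
        R, D, dv = self.design()
        y = 5 + 4 * dv + rng.normal(0, 1, dv.size)
        cat, fit = spikes.classify_neuron(y, D, R, dv)
        assert cat == "DV"
        assert fit.sprc_of("dv") > 0

    def test_size_neuron(self):
        rng = np.random.default_rng(10)
        R, D, dv = self.design()
        y = 5 + 3 * R + rng.normal(0, 1, dv.size)
        cat, _ = spikes.classify_neuron(y, D, R, dv)
        assert cat == "Size"

    def test_null_neuron_na(self):
        rng = np.random.default_rng(11)
        R, D, dv = self.design()
        y = rng.normal(5, 1, dv.size)
        cat, _ = spikes.classify_neuron(y, D, R, dv)
        assert cat == "NA"

    def test_affine_invariance(self):
        rng = np.random.default_rng(12)
        R, D, dv = self.design()
        for y in (
            5 + 4 * dv + rng.normal(0, 1, dv.size),
            5 + 3 * R + rng.normal(0, 1, dv.size),
            rng.normal(5, 1, dv.size),
        ):
            cat1, fit1 = spikes.classify_neuron(y, D, R, dv)
            cat2, fit2 = spikes.classify_neuron(3.0 * y + 7.0, D, R, dv)
            assert cat1 == cat2
            np.testing.assert_allclose(fit1.sprc, fit2.sprc, atol=1e-10)

    def test_collinear_design_refused(self):
        rng = np.random.default_rng(13)
        R, D, _ = self.design()
        fake_dv = 2.0 * R - D  # exact linear combination
        y = rng.normal(5, 1, R.size)
        with pytest.raises(ValueError, match="condition number|collinear"):
            spikes.classify_neuron(y, D, R, fake_dv)


class TestSatiationRegression:
    def test_rcum_effect_recovered(self):
        rng = np.random.default_rng(14)
        R, D, dv = TestClassifyNeuron.design()
        rcum = np.linspace(0, 1, dv.size)
        y = 5 + 2 * dv + 6 * rcum + rng.normal(0, 1, dv.size)
        fit = spikes.satiation_regression(y, dv, rcum)
        assert fit.p_of("rcum") < 0.05
        assert fit.coef_of("rcum") > 0

    def test_rcum_null_not_significant(self):
        sig = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            R, D, dv = TestClassifyNeuron.design()
            rcum = rng.permutation(np.linspace(0, 1, dv.size))
            y = 5 + 2 * dv + rng.normal(0, 1, dv.size)
            fit = spikes.satiation_regression(y, dv, rcum)
            sig += fit.p_of("rcum") < 0.05
        assert sig <= 1

    def test_orthogonal_rcum_leaves_dv_slope(self):
        # identical rcum values within every dv level -> exactly orthogonal
        rng = np.random.default_rng(15)
        R, D, dv = TestClassifyNeuron.design(n_rep=10)
        order = np.argsort(dv, kind="stable")
        rcum = np.empty(dv.size)
        rcum[order] = np.tile(np.linspace(0.05, 0.95, 10), 6)
        y = 5 + 2 * dv + rng.normal(0, 1, dv.size)
        eq7 = spikes.fit_dv_regression(y, dv)
        eq9 = spikes.satiation_regression(y, dv, rcum)
        assert eq9.coef_of("dv") == pytest.approx(eq7.coef_of("dv"), abs=1e-6)

    def test_constant_rcum_raises(self):
        with pytest.raises(ValueError):
            spikes.satiation_regression(np.ones(10), np.arange(10.0), np.full(10, 0.5))


class TestEffectTimecourse:
    @staticmethod
    def dv_neuron(rng, n_per_cond=25, betaV=8.0, on=100, off=900):
        conds = [(1, 0.3), (1, 3.3), (1, 6.9), (4, 0.3), (4, 3.3), (4, 6.9)]
        rows, sp = [], []
        idx = 0
        for R, D in conds:
            dv = R / (1 + 0.5 * D)
            for _ in range(n_per_cond):
                rate = 3 + betaV * dv
                t = np.concatenate(
                    [
                        rng.uniform(-1000, 2100, rng.poisson(2.0 * 3.1)),
                        rng.uniform(on, off, rng.poisson(rate * (off - on) / 1000)),
                    ]
                )
                sp.append(np.sort(t))
                rows.append(
                    {"session_id": "s", "trial_index": idx, "reward_size": R,
                     "delay_class": 0, "delay_mean_s": D, "outcome": "correct",
                     "rcum": 0.5, "go_ms": 1000.0, "release_ms": 1350.0,
                     "reward_ms": 1650.0}
                )
                idx += 1
        return spikes.SpikeData("n", pd.DataFrame(rows), sp)

    def test_bounds_and_peak_in_kernel(self):
        rng = np.random.default_rng(16)
        sd = self.dv_neuron(rng)
        dv = sd.trials["reward_size"] / (1 + 0.5 * sd.trials["delay_mean_s"])
        tc = spikes.dv_effect_timecourse(sd, np.asarray(dv), "cue")
        assert np.all((tc.r2 >= 0) & (tc.r2 <= 1))
        peak_t = tc.times_ms[np.argmax(tc.r2)]
        assert 100 <= peak_t <= 900
        pre = tc.r2[tc.times_ms < 0]
        assert tc.r2.max() > 5 * pre.mean()

    def test_non_dv_neuron_within_permuted_band(self):
        rng = np.random.default_rng(17)
        sd = self.dv_neuron(rng, betaV=0.0)
        dv = np.asarray(sd.trials["reward_size"] / (1 + 0.5 * sd.trials["delay_mean_s"]))
        tc = spikes.dv_effect_timecourse(sd, dv, "cue")
        perm_means = [
            spikes.dv_effect_timecourse(sd, rng.permutation(dv), "cue").r2.mean()
            for _ in range(30)
        ]
        assert tc.r2.mean() <= np.quantile(perm_means, 0.97)

    def test_time_reversed_negative_control(self):
        rng = np.random.default_rng(18)
        sd = self.dv_neuron(rng)
        # reverse time about a dummy event at +1800 ms: the pre-event window
        # then maps onto post-response baseline of the original train
        reversed_spikes = [np.sort(1800.0 - s) for s in sd.spikes]
        sd_rev = spikes.SpikeData("n", sd.trials.copy(), reversed_spikes)
        dv = np.asarray(sd.trials["reward_size"] / (1 + 0.5 * sd.trials["delay_mean_s"]))
        tc = spikes.dv_effect_timecourse(sd_rev, dv, "cue", t_range=(-500.0, 0.0))
        # chance level of R^2 is ~1/(n-1)
        assert tc.r2.mean() < 3.0 / (sd.n_trials - 1)

    def test_all_zero_window_r2_zero(self):
        rng = np.random.default_rng(19)
        sd = poisson_spike_data(rng, n_trials=10, rate_fn=lambda i: [(0, 500, 10.0)])
        dv = np.linspace(1, 2, 10)
        tc = spikes.dv_effect_timecourse(sd, dv, "cue", t_range=(-500.0, 1500.0))
        assert np.all(tc.r2[tc.times_ms < -100] == 0.0)


class TestHalfSplit:
    @staticmethod
    def deterministic_sd(first_count=8, second_count=8):
        conds = [(1, 0.3, 0), (1, 3.3, 1), (1, 6.9, 2), (4, 0.3, 0), (4, 3.3, 1), (4, 6.9, 2)]
        rows, sp = [], []
        idx = 0
        for half, cnt in (("first", first_count), ("second", second_count)):
            for rep in range(4):
                for R, D, dc in conds:
                    sp.append(np.linspace(150, 650, cnt))
                    rows.append(
                        {"session_id": "s", "trial_index": idx, "reward_size": R,
                         "delay_class": dc, "delay_mean_s": D, "outcome": "correct",
                         "rcum": 0.5, "go_ms": 1000.0, "release_ms": 1350.0,
                         "reward_ms": 1650.0}
                    )
                    idx += 1
        return spikes.SpikeData("n", pd.DataFrame(rows), sp)

    def test_normalizer_is_one(self):
        sd = self.deterministic_sd()
        out = spikes.half_split_comparison(sd, manual_window(100, 700))
        assert out.loc[(4, 0), "first"] == pytest.approx(1.0)

    def test_stationary_ratios_near_one(self):
        sd = self.deterministic_sd()
        out = spikes.half_split_comparison(sd, manual_window(100, 700))
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_injected_halving(self):
        sd = self.deterministic_sd(first_count=8, second_count=4)
        out = spikes.half_split_comparison(sd, manual_window(100, 700))
        np.testing.assert_allclose(out["second"].to_numpy(), 0.5 * out["first"].to_numpy())
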