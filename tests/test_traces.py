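"""Trace analysis: baseline, mean curves, delay calling, fits, cross-correlation."""

import numpy as np
import pytest

from adaswitch.traces import (ActivationCall, Trace, TraceError,
                              baseline_subtract, delay_fit,
                              detect_activation_delay, population_mean_curve,
                              steady_state_crosscorr)


def make_trace(values, cell_id=0, onset=30.0, dt=3.0, channel="ada", **extra):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * dt
    channels = {channel: values}
    channels.update({k: np.asarray(v, float) for k, v in extra.items()})
    return Trace(cell_id=cell_id, times=t, channels=channels, onset=onset)


class TestBaseline:
    def test_constant_trace_becomes_zero(self):
        tr = make_trace(np.full(40, 100.0))
        out = baseline_subtract(tr, "ada")
        np.testing.assert_allclose(out.channels["ada"], 0.0)
        assert out.baseline["ada"] == pytest.approx(100.0)

    def test_step_trace_offset(self):
        v = np.where(np.arange(40) * 3.0 < 30.0, 100.0, 600.0)
        out = baseline_subtract(make_trace(v), "ada")
        assert out.channels["ada"][-1] == pytest.approx(500.0)

    def test_noise_moments_recovered(self):
        rng = np.random.default_rng(0)
        sigma = 4.0
        v = sigma * rng.standard_normal(2000)
        out = baseline_subtract(make_trace(v, onset=3000.0), "ada")
        # onset at the end: the whole series is baseline window
        assert abs(np.mean(out.channels["ada"])) < 0.3
        assert out.baseline_sd["ada"] == pytest.approx(sigma, rel=0.1)

    def test_too_few_preonset_frames_names_cell(self):
        with pytest.raises(TraceError, match="cell 7"):
            baseline_subtract(make_trace(np.zeros(40), cell_id=7, onset=3.0),
                              "ada")


class TestPopulationMeanCurve:
    def test_identical_traces_mean_is_trace(self):
        tr = baseline_subtract(make_trace(np.arange(40.0)), "ada")
        t, curve = population_mean_curve([tr, tr], "ada")
        np.testing.assert_allclose(curve, tr.channels["ada"])

    def test_hand_computed_mean_and_normalisation(self):
        t1 = make_trace(np.arange(11.0), onset=0.0)
        t3 = make_trace(3 * np.arange(11.0), onset=0.0)
        _, curve = population_mean_curve([t1, t3], "ada")
        np.testing.assert_allclose(curve, 2 * np.arange(11.0))
        _, norm = population_mean_curve([t1, t3], "ada", normalize=True)
        np.testing.assert_allclose(norm, 2 * np.arange(11.0) / 20.0)
        assert norm.max() == pytest.approx(1.0)

    def test_all_zero_normalisation_rejected(self):
        tr = make_trace(np.zeros(11), onset=0.0)
        with pytest.raises(TraceError, match="normalise"):
            population_mean_curve([tr], "ada", normalize=True)


def _called(values, onset=30.0, noise_sd=1.0, **kwargs):
    tr = make_trace(values, onset=onset)
    # inject a tiny baseline jitter so baseline SD is defined and small
    rng = np.random.default_rng(1)
    tr.channels["ada"] = tr.channels["ada"] + noise_sd * rng.standard_normal(
        tr.times.size) * 0.0
    tr.baseline["ada"] = float(np.mean(values[: int(onset / 3)]))
    tr.baseline_sd["ada"] = noise_sd
    return detect_activation_delay(tr, "ada", **kwargs)


class TestDelayDetection:
    def test_clean_step_called_at_step_time(self):
        t = np.arange(80) * 3.0
        v = np.where(t >= 30.0 + 63.0, 10.0, 0.0)
        call = _called(v)
        assert call.delay == pytest.approx(63.0)
        assert call.label == "Activated"

    def test_flat_trace_is_delayed(self):
        call = _called(np.zeros(80))
        assert call.delay is None and call.label == "Delayed"

    def test_truncated_dead_trace_is_nocall(self):
        v = np.zeros(80)
        v[30:] = np.nan     # death at 90 min, well before the 120-min cutoff
        call = _called(v)
        assert call.label == "NoCall"

    def test_late_crossing_is_delayed(self):
        t = np.arange(100) * 3.0
        v = np.where(t >= 30.0 + 150.0, 10.0, 0.0)
        call = _called(v)
        assert call.label == "Delayed"
        assert call.delay == pytest.approx(150.0)

    def test_translation_invariance(self):
        """Shifting trace and onset together leaves the delay unchanged."""
        t = np.arange(100) * 3.0
        delays = []
        for shift in (0.0, 30.0):
            v = np.where(t >= 60.0 + shift, 10.0, 0.0)
            tr = make_trace(v, onset=30.0 + shift)
            tr.baseline["ada"] = 0.0
            tr.baseline_sd["ada"] = 1.0
            delays.append(detect_activation_delay(tr, "ada").delay)
        assert delays[0] == delays[1]

    def test_min_frames_requires_sustained_crossing(self):
        v = np.zeros(80)
        v[20] = 10.0        # single-frame blip must not trigger
        assert _called(v).delay is None
        v[20:23] = 10.0     # three consecutive frames do
        assert _called(v).delay == pytest.approx(20 * 3.0 - 30.0)

    def test_increasing_k_sigma_never_shortens_delay(self, wt_pop):
        from adaswitch.traces import traces_from_population
        trs = traces_from_population(wt_pop)[:40]
        for tr in trs:
            tb = baseline_subtract(tr, "ada")
            prev = None
            for k in (3.0, 5.0, 8.0):
                c = detect_activation_delay(tb, "ada", k_sigma=k)
                d = np.inf if c.delay is None else c.delay
                if prev is not None:
                    assert d >= prev
                prev = d

    def test_missing_baseline_rejected(self):
        tr = make_trace(np.zeros(40))
        with pytest.raises(TraceError, match="baseline"):
            detect_activation_delay(tr, "ada")


def calls_from(delays, channel="ada"):
    return [ActivationCall(i, channel, d, "Activated", 1.0)
            for i, d in enumerate(delays)]


class TestDelayFit:
    def test_exact_affine_relation(self):
        a = np.array([30.0, 45.0, 60.0, 90.0, 120.0])
        fit = delay_fit(calls_from(a), calls_from(a + 8.0, "alka"))
        assert fit.r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(8.0)
        assert fit.mean_diff == pytest.approx(8.0)

    def test_self_fit_identity(self):
        a = np.array([30.0, 45.0, 60.0, 90.0])
        fit = delay_fit(calls_from(a), calls_from(a))
        assert (fit.r, fit.slope, fit.intercept) == pytest.approx((1.0, 1.0, 0.0))

    def test_permuted_delays_uncorrelated(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(20, 120, 400)
        b = rng.permutation(a)
        fit = delay_fit(calls_from(a), calls_from(b, "alka"))
        assert abs(fit.r) < 0.15

    def test_pairing_by_cell_id_and_exclusions(self):
        ca = calls_from([10.0, 20.0, 30.0])
        cb = calls_from([12.0, 22.0], "alka") + [
            ActivationCall(99, "alka", None, "Delayed", 1.0)]
        fit = delay_fit(ca, cb)
        assert fit.n == 2 and fit.n_excluded == 2

    def test_too_few_pairs_rejected(self):
        with pytest.raises(TraceError):
            delay_fit(calls_from([10.0]), calls_from([12.0], "alka"))


class TestCrossCorrelation:
    @staticmethod
    def ou_trace(seed, n=200, tau=5.0, lag_frames=0):
        rng = np.random.default_rng(seed)
        x = np.empty(n + lag_frames)
        x[0] = rng.standard_normal()
        a = np.exp(-1.0 / tau)
        for i in range(1, n + lag_frames):
            x[i] = a * x[i - 1] + np.sqrt(1 - a * a) * rng.standard_normal()
        return x

    def test_autocorrelation_is_one_at_zero_lag(self):
        x = self.ou_trace(0)
        tr = Trace(0, np.arange(200) * 3.0,
                   {"a": x[:200], "b": x[:200], "constitutive": x[:200]}, 0.0)
        cc = steady_state_crosscorr([tr], "a", "b", (0, 597), max_lag=30)
        assert cc.correlation[cc.lags == 0][0] == pytest.approx(1.0)
        assert np.all(np.abs(cc.correlation) <= 1.0 + 1e-12)

    def test_shift_moves_peak_to_positive_lag(self):
        """If B lags A by 9 min the peak sits at +9 min."""
        x = self.ou_trace(1, lag_frames=3)
        a, b = x[3:], x[:-3]
        tr = Trace(0, np.arange(a.size) * 3.0,
                   {"a": a, "b": b, "constitutive": a}, 0.0)
        cc = steady_state_crosscorr([tr], "a", "b", (0, 3 * (a.size - 1)),
                                    max_lag=30)
        assert cc.lags[np.argmax(cc.correlation)] == pytest.approx(9.0)

    def test_shuffled_control_kills_correlation(self):
        traces = []
        for i in range(40):
            x = self.ou_trace(100 + i)
            traces.append(Trace(i, np.arange(200) * 3.0,
                                {"a": x, "b": x, "constitutive": x}, 0.0))
        paired = steady_state_crosscorr(traces, "a", "b", (0, 597), 30)
        shuffled = steady_state_crosscorr(traces, "a", "b", (0, 597), 30,
                                          mode="shuffled", seed=2)
        assert paired.correlation[paired.lags == 0][0] == pytest.approx(1.0)
        se = 1.0 / np.sqrt(len(traces) * 200)
        assert np.all(np.abs(shuffled.correlation) < 3 * 5 * se + 0.15)
        assert np.max(np.abs(shuffled.correlation)) < 0.5 * np.max(
            np.abs(paired.correlation))

    def test_window_shorter_than_twice_lag_rejected(self):
        x = self.ou_trace(3)
        tr = Trace(0, np.arange(200) * 3.0,
                   {"a": x, "b": x, "constitutive": x}, 0.0)
        with pytest.raises(TraceError):
            steady_state_crosscorr([tr], "a", "b", (0, 50), max_lag=30)

    def test_simulated_dual_reporter_correlated_with_offset(self, steady_pop):
        """Paired steady-state curve beats both null controls over +-1 h."""
        from adaswitch.traces import traces_from_population
        trs = traces_from_population(steady_pop)
        window = (180.0, 600.0)
        paired = steady_state_crosscorr(trs, "ada", "alka", window, max_lag=60.0)
        shuffled = steady_state_crosscorr(trs, "ada", "alka", window,
                                          max_lag=60.0, mode="shuffled", seed=5)
        const = steady_state_crosscorr(trs, "ada", "alka", window,
                                       max_lag=60.0, mode="constitutive")
        sel = np.abs(paired.lags) <= 60.0
        assert np.all(paired.correlation[sel]
                      > np.abs(shuffled.correlation[sel]))
        assert np.all(paired.correlation[sel] > np.abs(const.correlation[sel]))
        # the alkA channel reads the shared fluctuation with a positive lag
        assert paired.lags[np.argmax(paired.correlation)] > 0.0
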