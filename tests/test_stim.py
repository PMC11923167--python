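import numpy as np
import pytest

import stridefiber as sf
from stridefiber.bouts import WindowError


def make_norm(dff, rate=100.0):
    t = np.arange(dff.size) / rate
    z = (dff - dff.mean()) / dff.std() if dff.std() > 0 else np.zeros_like(dff)
    return sf.NormalizedTrace(
        t=t, dff=dff, zscore=z, f0=np.ones_like(dff), method="stim_mode",
        sample_rate=rate,
    )


def protocol(onsets=(30.0, 90.0), dur=10.0, kind="trial_10s"):
    return sf.StimProtocol(
        trial_onsets=np.array(onsets, float), trial_durations=dur, schedule_kind=kind
    )


class TestExtractTrials:
    def test_constant_dff_gives_zero_trials(self, params):
        norm = make_norm(0.4 * np.ones(15000) + 1e-6 * np.sin(np.arange(15000)))
        trials = sf.extract_stim_trials(norm, protocol(), params)
        assert len(trials) == 2
        for tr in trials:
            np.testing.assert_allclose(tr.dff, 0.0, atol=1e-5)

    def test_baseline_window_mean_is_zero(self, params):
        rng = np.random.default_rng(0)
        norm = make_norm(rng.standard_normal(15000))
        for tr in sf.extract_stim_trials(norm, protocol(), params):
            base = tr.dff[(tr.lags >= -5.0 - 1e-9) & (tr.lags < -1e-9)]
            assert abs(base.mean()) < 1e-9

    def test_trial_without_margin_dropped(self, params):
        rng = np.random.default_rng(1)
        norm = make_norm(rng.standard_normal(15000))
        trials = sf.extract_stim_trials(norm, protocol(onsets=(2.0, 90.0)), params)
        assert [tr.trial_index for tr in trials] == [1]

    def test_lag_span(self, params):
        norm = make_norm(np.random.default_rng(2).standard_normal(15000))
        tr = sf.extract_stim_trials(norm, protocol(), params)[0]
        assert tr.lags[0] == pytest.approx(-5.0)
        assert tr.lags[-1] == pytest.approx(19.0)


class TestTrialMetrics:
    def _trial(self, dff, dur=10.0, rate=100.0):
        n = dff.size
        lags = np.arange(n) / rate - 5.0
        return sf.StimTrialWindow(0, lags, dff, dur)

    def test_boxcar_elevation(self, params):
        rate = 100.0
        lags = np.arange(2400) / rate - 5.0
        dff = np.where((lags >= 0.3) & (lags < 1.2), 0.5, 0.0)
        assert sf.initial_elevation(self._trial(dff), params) == pytest.approx(0.5)

    def test_flat_trial_zero_everywhere(self, params):
        dff = np.zeros(2400)
        tr = self._trial(dff)
        assert sf.initial_elevation(tr, params) == 0.0
        assert sf.max_reduction(tr, params) == 0.0
        assert sf.post_stim_change(tr, params) == 0.0

    def test_linear_decline_minimum_at_last_sample(self, params):
        rate = 100.0
        lags = np.arange(2400) / rate - 5.0
        dff = np.where((lags >= 0) & (lags < 10.0), -2.0 * (lags / 10.0), 0.0)
        got = sf.max_reduction(self._trial(dff), params)
        assert got == pytest.approx(-2.0 * 9.99 / 10.0, abs=1e-9)

    def test_noise_biases_per_trial_minimum_down(self, params):
        """E[min] over the 1-s window of pure noise is negative and matches
        a brute-force order-statistic simulation."""
        rate, sigma, n_rep = 100.0, 0.3, 300
        rng = np.random.default_rng(3)
        mins = []
        for _ in range(n_rep):
            dff = np.zeros(2400)
            dff[:] = sigma * rng.standard_normal(2400)
            mins.append(sf.max_reduction(self._trial(dff), params))
        brute = [
            sigma * rng.standard_normal(int(rate)).min() for _ in range(n_rep)
        ]
        assert np.mean(mins) < 0
        assert np.mean(mins) == pytest.approx(np.mean(brute), abs=0.02)

    def test_exponential_rebound_matches_geometric_closed_form(self, params):
        rate, tau, amp, dur = 1000.0, 5.0, 1.0, 10.0
        lags = np.arange(int(24 * rate)) / rate - 5.0
        dff = np.where(lags >= dur, amp * np.exp(-(lags - dur) / tau), 0.0)
        got = sf.post_stim_change(self._trial(dff, dur=dur, rate=rate), params)
        dt = 1.0 / rate
        n = int(round(5.0 * rate))
        q = np.exp(-dt / tau)
        expected = amp * np.exp(-4.0 / tau) * (1 - q**n) / (n * (1 - q))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_residual_suppression_reported(self, params):
        rate = 100.0
        lags = np.arange(2400) / rate - 5.0
        dff = np.where(lags >= 10.0, -0.5, 0.0)
        assert sf.post_stim_change(self._trial(dff), params) == pytest.approx(-0.5)

    def test_metrics_invariant_to_constant_offset(self, params):
        """Adding a constant to the session dF/F changes nothing: the
        baseline subtraction removes it."""
        rng = np.random.default_rng(4)
        dff = 0.01 * rng.standard_normal(15000)
        prot = protocol()
        t0 = sf.extract_stim_trials(make_norm(dff), prot, params)
        t1 = sf.extract_stim_trials(make_norm(dff + 0.7), prot, params)
        for a, b in zip(t0, t1):
            assert sf.initial_elevation(a, params) == pytest.approx(
                sf.initial_elevation(b, params), abs=1e-12
            )
            assert sf.max_reduction(a, params) == pytest.approx(
                sf.max_reduction(b, params), abs=1e-12
            )
            assert sf.post_stim_change(a, params) == pytest.approx(
                sf.post_stim_change(b, params), abs=1e-12
            )

    def test_window_outside_trace_raises(self, params):
        lags = np.arange(600) / 100.0 - 5.0  # ends 1 s after onset
        tr = sf.StimTrialWindow(0, lags, np.zeros(600), 10.0)
        with pytest.raises(WindowError):
            sf.max_reduction(tr, params)

    def test_qualitative_subtype_ordering(self, params):
        """A preset with deep suppression and rebound vs one with elevation
        and shallow suppression reproduce the expected ordering."""
        results = {}
        for name, preset in (("K", sf.KREMEN1_LIKE), ("C", sf.CALB1_LIKE)):
            cfg = sf.SynthConfig(
                duration=300.0, rate=100.0, seed=6, noise_sd=0.0,
                stim_noise_dff=0.0, **preset,
            )
            prot = protocol(onsets=(60.0, 160.0))
            bundle, _ = sf.simulate_stim_session(cfg, prot)
            norm = sf.reference_correct_stim(bundle.photometry, params)
            trials = sf.extract_stim_trials(norm, prot, params)
            results[name] = (
                np.mean([sf.max_reduction(t, params) for t in trials]),
                np.mean([sf.post_stim_change(t, params) for t in trials]),
                np.mean([sf.initial_elevation(t, params) for t in trials]),
            )
        red_k, post_k, _ = results["K"]
        red_c, post_c, elev_c = results["C"]
        assert red_k < red_c < 0
        assert post_k > 0
        assert abs(post_c) < 0.2 * post_k
        assert elev_c > 0


class TestSummaries:
    def test_mean_trace_mode_reduces_minimum_bias(self, params):
        rng = np.random.default_rng(7)
        trials = []
        rate = 100.0
        lags = np.arange(2400) / rate - 5.0
        for i in range(10):
            trials.append(
                sf.StimTrialWindow(i, lags, 0.05 * rng.standard_normal(2400), 10.0)
            )
        df = sf.summarize_stim_trials(trials, params)
        df_mean = sf.summarize_stim_trials(trials, params, on_mean_trace=True)
        per_trial = df[df["level"] == "session"]["max_reduction"].iloc[0]
        mean_trace = df_mean[df_mean["level"] == "session"]["max_reduction"].iloc[0]
        assert per_trial < mean_trace <= 0


class TestEpochSummary:
    def _epoch_setup(self, scale_on=1.0, scale_off=1.0, base=5.0):
        rate = 50.0
        prot = protocol(onsets=(200.0, 560.0), dur=180.0, kind="epoch_3min")
        n = int(950 * rate)
        t = np.arange(n) / rate
        v = base * np.ones(n)
        for on, dur in zip(prot.trial_onsets, prot.trial_durations):
            v[(t >= on) & (t < on + dur)] *= scale_on
            v[(t >= on + dur) & (t < on + dur + 180.0)] *= scale_off
        return sf.BehaviorTrack(t=t, velocity=v), prot

    def test_constant_velocity_all_ratios_one(self, params):
        track, prot = self._epoch_setup()
        df = sf.epoch_velocity_summary(track, prot, params)
        np.testing.assert_allclose(df["velocity_ratio"], 1.0, atol=1e-12)
        np.testing.assert_allclose(df["mean_velocity"], 5.0, atol=1e-12)

    def test_halved_on_epoch_ratio(self, params):
        track, prot = self._epoch_setup(scale_on=0.5)
        df = sf.epoch_velocity_summary(track, prot, params).set_index("epoch")
        assert df.loc["on_1", "velocity_ratio"] == pytest.approx(0.5)
        assert df.loc["prior", "velocity_ratio"] == 1.0

    def test_generated_epoch_factors_recovered(self, params):
        cfg = sf.SynthConfig(
            duration=950.0, rate=50.0, seed=9, bout_rate=6.0,
            stim_on_vel_factor=0.6, stim_off_vel_factor=1.3,
        )
        prot = protocol(onsets=(200.0, 560.0), dur=180.0, kind="epoch_3min")
        bundle, truth = sf.simulate_stim_session(cfg, prot)
        df = sf.epoch_velocity_summary(
            bundle.behavior, prot, params
        ).set_index("epoch")
        expected = truth.epoch_factors["expected_velocity_ratio"]
        for name, want in expected.items():
            assert df.loc[name, "velocity_ratio"] == pytest.approx(
                want, rel=0.05
            ), name

    def test_zero_prior_velocity_rejected(self, params):
        track, prot = self._epoch_setup(base=0.0)
        with pytest.raises(ValueError, match="prior"):
            sf.epoch_velocity_summary(track, prot, params)

    def test_bout_clipping_at_epoch_edges(self, params):
        track, prot = self._epoch_setup()
        rows = [
            # straddles the prior/on_1 boundary at 200 s: counted in prior,
            # clipped there
            {"onset": 190.0, "offset": 210.0, "duration": 20.0,
             "mean_velocity": 5.0, "kind": "ambulation"},
            {"onset": 220.0, "offset": 230.0, "duration": 10.0,
             "mean_velocity": 5.0, "kind": "ambulation"},
        ]
        bouts = sf.BoutTable.from_rows(rows, span=950.0)
        df = sf.epoch_velocity_summary(
            track, prot, params, ambulation=bouts
        ).set_index("epoch")
        assert df.loc["prior", "ambulation_freq_per_min"] == pytest.approx(1 / 3)
        assert df.loc["prior", "ambulation_mean_dur"] == pytest.approx(10.0)
        assert df.loc["on_1", "ambulation_freq_per_min"] == pytest.approx(1 / 3)
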