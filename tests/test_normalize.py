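import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import stridefiber as sf
from oracles import brute_sliding_percentile


class TestSlidingPercentileBaseline:
    def test_constant_trace(self):
        x = np.full(2000, 3.7)
        f0 = sf.sliding_percentile_baseline(x, rate=100.0)
        np.testing.assert_array_equal(f0, x)

    @pytest.mark.parametrize("align", ["centered", "trailing"])
    def test_matches_brute_force_on_ramp(self, align):
        rate = 100.0
        x = np.linspace(0.0, 5.0, 1000)  # 10-s strictly increasing ramp
        f0 = sf.sliding_percentile_baseline(x, rate, align=align)
        if align == "centered":
            oracle = brute_sliding_percentile(x, rate)
            np.testing.assert_allclose(f0, oracle, atol=1e-12)
        # a 10th percentile of a window around i lies below the trace
        interior = slice(300, 700)
        assert np.all(f0[interior] < x[interior])

    def test_matches_brute_force_on_noise(self):
        rate = 100.0
        rng = np.random.default_rng(0)
        x = rng.standard_normal(3000)
        f0 = sf.sliding_percentile_baseline(x, rate)
        np.testing.assert_allclose(f0, brute_sliding_percentile(x, rate), atol=1e-12)

    def test_narrow_spike_does_not_move_baseline(self):
        rate = 100.0
        x = np.ones(2000)
        x[1000:1030] = 10.0  # 0.3-s spike, < 10% of the 5-s window
        f0 = sf.sliding_percentile_baseline(x, rate)
        assert f0[1015] == pytest.approx(1.0)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            sf.sliding_percentile_baseline(np.ones(100), 100.0, window=-1.0)
        with pytest.raises(ValueError):
            sf.sliding_percentile_baseline(np.ones(100), 100.0, window=5.0)


class TestPrenormalize:
    def test_identity_and_scaling(self):
        f0 = np.linspace(1.0, 2.0, 100)
        np.testing.assert_allclose(sf.prenormalize_dff(f0, f0), 0.0, atol=1e-15)
        np.testing.assert_allclose(
            sf.prenormalize_dff(1.1 * f0, f0), 0.1, atol=1e-12
        )

    def test_nonpositive_f0_names_index(self):
        f0 = np.ones(10)
        f0[3] = -0.5
        with pytest.raises(ValueError, match="sample 3"):
            sf.prenormalize_dff(np.ones(10), f0)

    def test_slow_bleach_leaves_small_dff(self):
        """With bleach tau >> window the baseline tracks the decay and
        |dF/F| stays below 1% away from the edges."""
        rate, dur = 100.0, 60.0
        t = np.arange(int(dur * rate)) / rate
        trace = 1.0 + 0.15 * np.exp(-t / 500.0)  # tau = 100x the 5-s window
        f0 = sf.sliding_percentile_baseline(trace, rate)
        dff = sf.prenormalize_dff(trace, f0)
        interior = slice(int(5 * rate), int((dur - 5) * rate))
        assert np.max(np.abs(dff[interior])) < 0.01


class TestReferenceCorrection:
    def test_identical_channels_cancel(self, params):
        # identical, in-band (well below the 3 Hz corner) channels cancel
        t = np.arange(5000) / 100.0
        x = 0.02 * np.sin(2 * np.pi * 0.03 * t)
        corrected, transformed = sf.reference_correct_behavior(x, x, 100.0, params)
        # zero-phase filtering leaves small edge transients; judge the interior
        assert np.max(np.abs(corrected[500:-500])) < 1e-6

    def test_artifact_removed_signal_kept(self, params):
        """signal = true + 0.7*artifact; referencing strips the artifact."""
        rate, n = 100.0, 20000
        rng = np.random.default_rng(2)
        from scipy import signal as sps

        sos = sps.butter(2, 1.0, fs=rate, output="sos")
        artifact = sps.sosfiltfilt(sos, rng.standard_normal(n))
        artifact /= artifact.std()
        true = np.zeros(n)
        for i in range(500, n - 500, 2000):
            true[i : i + 100] += 1.0
        signal = true + 0.7 * artifact
        ref = artifact + 0.05 * rng.standard_normal(n)
        corrected, _ = sf.reference_correct_behavior(signal, ref, rate, params)
        assert abs(stats.pearsonr(signal, artifact).statistic) > 0.8
        assert abs(stats.pearsonr(corrected, artifact).statistic) < 0.1

    def test_uncorrelated_reference_leaves_signal(self, params):
        """White-noise reference: fitted slope ~0, corrected ~ signal - b."""
        rate, n = 100.0, 5000
        slopes = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            signal = 0.01 * np.sin(np.arange(n) / 200.0)  # dF/F-scale activity
            ref = rng.standard_normal(n)
            corrected, transformed = sf.reference_correct_behavior(
                signal, ref, rate, params, random_state=seed
            )
            # recover the fitted line from the transformed reference
            from scipy import signal as sps

            sos = sps.butter(2, 3.0, fs=rate, output="sos")
            rf = sps.sosfiltfilt(sos, ref)
            slope = np.polyfit(rf, transformed, 1)[0]
            slopes.append(slope)
            intercept = transformed.mean() - slope * rf.mean()
            np.testing.assert_allclose(
                corrected[200:-200],
                (signal - intercept)[200:-200],
                atol=5 * abs(slope) * rf.std() + 1e-9,
            )
        assert np.all(np.abs(slopes) < 0.05)


class TestStimMode:
    def _session(self, signal, reference, rate=100.0):
        t = np.arange(signal.size) / rate
        return sf.PhotometrySession(
            t=t, signal=signal, reference=reference, sample_rate=rate,
            signal_wavelength=560,
        )

    def test_proportional_channels_give_zero_dff(self, params):
        rng = np.random.default_rng(3)
        ref = 1.0 + 0.1 * np.abs(rng.standard_normal(2000))
        norm = sf.reference_correct_stim(self._session(2.0 * ref, ref), params)
        np.testing.assert_allclose(norm.dff, 0.0, atol=1e-9)
        np.testing.assert_allclose(norm.f0, 2.0 * ref, atol=1e-9)

    def test_multiplicative_modulation_recovered(self, params):
        rate, n = 100.0, 20000
        t = np.arange(n) / rate
        rng = np.random.default_rng(4)
        f_true = 1.0 + 0.2 * np.exp(-t / 300.0)
        r = np.zeros(n)  # sparse transient-like modulation, mostly baseline
        for i in range(1000, n - 1000, 2500):
            r[i : i + 200] = 0.01
        ref = f_true + 1e-4 * rng.standard_normal(n)
        norm = sf.reference_correct_stim(
            self._session(f_true * (1.0 + r), ref), params
        )
        np.testing.assert_allclose(norm.dff, r, atol=1e-3)

    def test_nonpositive_f_rejected(self, params):
        ref = np.linspace(1.0, -0.5, 1000)
        ref = np.abs(ref) + 0.1
        signal = -1.0 * np.ones(1000)
        with pytest.raises(ValueError, match="non-positive"):
            sf.reference_correct_stim(self._session(signal, ref), params)


class TestQC:
    @pytest.mark.parametrize(
        "max_dff_pct,corr_level,included,reason",
        [
            (3.0, 0.2, True, ""),
            (1.0, 0.2, False, "low signal"),
            (3.0, 0.8, False, "motion-contaminated"),
            (1.0, 0.8, False, "low signal"),
        ],
    )
    def test_truth_table(self, params, max_dff_pct, corr_level, included, reason):
        rng = np.random.default_rng(0)
        n = 5000
        shared = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        w = corr_level
        dff = w * shared + np.sqrt(1 - w * w) * noise
        dff *= (max_dff_pct / 100.0) / dff.max()
        ref = shared.copy()
        qc = sf.qc_session(dff, ref, params)
        assert qc.included == included
        assert qc.reason == reason
        assert qc.max_dff == pytest.approx(max_dff_pct)
        assert abs(qc.signal_ref_corr - corr_level) < 0.1

    def test_zero_variance_excluded(self, params):
        qc = sf.qc_session(np.zeros(100), np.ones(100), params)
        assert not qc.included
        assert qc.reason == "zero-variance input"


class TestZScore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        z = sf.zscore_session(rng.standard_normal(10_000) * 3.0 + 7.0)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0, allow_nan=False),
        shift=st.floats(-50.0, 50.0, allow_nan=False),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(2000)
        np.testing.assert_allclose(
            sf.zscore_session(scale * x + shift), sf.zscore_session(x), atol=1e-9
        )

    def test_matches_two_pass_oracle_on_long_trace(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(1_000_000) * 1e-3 + 5.0
        z = sf.zscore_session(x)
        mu = np.longdouble(0.0)
        for chunk in np.array_split(x, 100):
            mu += chunk.sum(dtype=np.longdouble)
        mu /= x.size
        var = np.longdouble(0.0)
        for chunk in np.array_split(x, 100):
            var += ((chunk - float(mu)) ** 2).sum(dtype=np.longdouble)
        sd = np.sqrt(var / x.size)
        np.testing.assert_allclose(z, (x - float(mu)) / float(sd), atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sf.zscore_session(np.full(100, 2.0))


class TestBehaviorPipeline:
    def test_full_pipeline_z_invariants_and_qc(self, params, small_config):
        track, bouts = sf.simulate_locomotion(small_config, params)
        cfg = small_config.model_copy(update={"motion_amp": 0.05})
        session, _ = sf.simulate_photometry(cfg, track, bouts)
        norm = sf.normalize_behavior(session, params, random_state=1)
        assert norm.method == "behavior_mode"
        assert abs(norm.zscore.mean()) < 1e-9
        assert abs(norm.zscore.std() - 1.0) < 1e-9
        assert norm.qc is not None and norm.qc.included
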