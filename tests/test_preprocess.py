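"""Preprocessing chain: filter design, resampling, epoching, baseline, EOG
regression, amplitude rejection, re-referencing, and pipeline order."""

import numpy as np
import pandas as pd
import pytest
import scipy.signal

from conftest import SRATE, WINDOW
from ctpcit import preprocess, synth_eeg
from ctpcit.containers import EpochSet, Recording
from ctpcit.preprocess import (
    FilterSpec, bandpass_fir, baseline_correct, design_fir, extract_epochs,
    regress_eog, reject_amplitude, rereference_linked_mastoids, resample,
    run_pipeline,
)


def _epochs(data, ch=("Pz", "TP9", "TP10", "VEOG1"), srate=SRATE, tmin=-100.0):
    return EpochSet(data, srate, list(ch), tmin)


class TestFilter:
    def test_minus6db_at_cutoffs(self):
        taps = design_fir(FilterSpec(0.3, 30.0), SRATE)
        w, h = scipy.signal.freqz(taps, worN=2 ** 16, fs=SRATE)
        gain = np.abs(h)
        for f0 in (0.3, 30.0):
            g = np.interp(f0, w, gain)
            assert g == pytest.approx(0.5, abs=0.05)

    def test_dc_removed(self):
        sig = np.full((1, 20000), 7.0)
        out = bandpass_fir(sig, FilterSpec(0.3, 30.0), srate=SRATE)
        # steady-state (interior) response to a constant is ~0
        assert np.abs(out[0, 8000:12000]).max() < 0.05

    def test_passband_10hz_unity(self):
        t = np.arange(20000) / SRATE
        sig = np.sin(2 * np.pi * 10 * t)[None, :]
        out = bandpass_fir(sig, FilterSpec(0.3, 30.0), srate=SRATE)
        amp = np.abs(out[0, 8000:12000]).max()
        assert amp == pytest.approx(1.0, abs=0.02)

    def test_stopband_50hz_attenuated(self):
        t = np.arange(20000) / SRATE
        sig = np.sin(2 * np.pi * 50 * t)[None, :]
        out = bandpass_fir(sig, FilterSpec(0.3, 30.0), srate=SRATE)
        amp = np.abs(out[0, 8000:12000]).max()
        assert amp < 10 ** (-20 / 20)  # >= 20 dB down

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_fir(FilterSpec(0.3, 125.0), SRATE)

    def test_kernel_p300pp_preserved_within_5pct(self):
        """Band-passing a noiseless P300 kernel barely changes its score."""
        from ctpcit import erp_score
        wave = synth_eeg.p300_kernel(550, 400, 10.0, SRATE, WINDOW)
        # embed in a long continuous trace so the 0.3 Hz high-pass is usable
        trace = np.zeros((1, 25000))
        start = 12000
        trace[0, start:start + len(wave)] = wave
        filt = bandpass_fir(trace, FilterSpec(0.3, 30.0), srate=SRATE)
        seg = filt[0, start:start + len(wave)]
        before = erp_score.p300_pp(wave, srate=SRATE, tmin_ms=WINDOW[0]).p300pp_uv
        after = erp_score.p300_pp(seg, srate=SRATE, tmin_ms=WINDOW[0]).p300pp_uv
        assert abs(after - before) / before < 0.05


class TestResample:
    def test_downsample_factor_four(self):
        rec = Recording(np.zeros((2, 4000)), 1000.0, ["Pz", "Cz"],
                        pd.DataFrame({"onset_sample": [1000]}))
        out = resample(rec, 250.0)
        assert abs(out.n_samples - 1000) <= 1
        assert out.events.onset_sample.iloc[0] == 250

    def test_identity(self):
        rec = Recording(np.ones((1, 100)), 250.0, ["Pz"])
        assert resample(rec, 250.0) is rec

    def test_sine_amplitude_preserved(self):
        t = np.arange(40000) / 1000.0
        rec = Recording(np.sin(2 * np.pi * 10 * t)[None, :], 1000.0, ["Pz"])
        out = resample(rec, 250.0)
        assert np.abs(out.data[0, 1000:-1000]).max() == pytest.approx(1.0, abs=0.01)

    def test_upsampling_rejected(self):
        rec = Recording(np.zeros((1, 100)), 250.0, ["Pz"])
        with pytest.raises(ValueError, match="upsampling"):
            resample(rec, 500.0)


class TestExtractEpochs:
    def test_sample_count_and_onset_index(self):
        data = np.zeros((1, 2000))
        data[0, 500] = 42.0  # spike at the event onset
        rec = Recording(data, SRATE, ["Pz"],
                        pd.DataFrame({"onset_sample": [500]}))
        epochs, skipped = extract_epochs(rec, window_ms=WINDOW)
        assert epochs.n_samples == 375  # 1.5 s x 250 Hz, half-open window
        assert skipped == []
        assert epochs.data[0, 0, 25] == 42.0  # onset at index 100 ms * srate

    def test_event_without_margin_skipped(self):
        rec = Recording(np.zeros((1, 2000)), SRATE,
                        ["Pz"], pd.DataFrame({"onset_sample": [10, 500]}))
        epochs, skipped = extract_epochs(rec, window_ms=WINDOW)
        assert skipped == [0]
        assert epochs.n_epochs == 1


class TestBaseline:
    def test_baseline_mean_zero(self):
        rng = np.random.default_rng(0)
        ep = _epochs(rng.normal(0, 5, (4, 4, 375)))
        out = baseline_correct(ep)
        t = out.times_ms
        bl = (t >= -100) & (t < 0)
        assert np.allclose(out.data[:, :, bl].mean(axis=2), 0.0, atol=1e-12)

    def test_constant_epoch_becomes_zero(self):
        ep = _epochs(np.full((1, 4, 375), 7.0))
        assert np.allclose(baseline_correct(ep).data, 0.0)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        ep = _epochs(rng.normal(0, 3, (2, 4, 375)))
        out = baseline_correct(ep)
        t = ep.times_ms
        bl = (t >= -100) & (t < 0)
        expected = ep.data - ep.data[:, :, bl].mean(axis=2, keepdims=True)
        np.testing.assert_allclose(out.data, expected)

    def test_empty_baseline_rejected(self):
        ep = _epochs(np.zeros((1, 4, 375)))
        with pytest.raises(ValueError):
            baseline_correct(ep, baseline_ms=(-500.0, -400.0))


class TestEOGRegression:
    def test_pure_leakage_removed(self):
        rng = np.random.default_rng(2)
        eog = rng.normal(0, 50, (3, 1, 375))
        data = np.concatenate([0.4 * np.repeat(eog, 3, axis=1), eog], axis=1)
        ep = _epochs(data)
        out, beta = regress_eog(ep, eog_channels=["VEOG1"])
        assert np.allclose(out.data[:, :3, :], 0.0, atol=1e-9)
        assert beta[:, 0] == pytest.approx(0.4, abs=1e-9)

    def test_zero_eog_is_noop(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 5, (2, 4, 375))
        data[:, 3, :] = 0.0
        ep = _epochs(data)
        out, beta = regress_eog(ep, eog_channels=["VEOG1"])
        np.testing.assert_array_equal(out.data, ep.data)
        assert not beta.any()

    def test_two_coefficients_recovered_under_noise(self):
        rng = np.random.default_rng(4)
        n, ns = 40, 375
        e1 = rng.normal(0, 30, (n, ns))
        e2 = rng.normal(0, 30, (n, ns))
        scalp = 0.4 * e1 + 0.1 * e2 + rng.normal(0, 1, (n, ns))
        data = np.stack([scalp, e1, e2], axis=1)
        ep = _epochs(data, ch=("Pz", "VEOG1", "VEOG2"))
        _, beta = regress_eog(ep, eog_channels=["VEOG1", "VEOG2"])
        assert beta[0, 0] == pytest.approx(0.4, abs=0.01)
        assert beta[0, 1] == pytest.approx(0.1, abs=0.01)


class TestRejection:
    def test_threshold_edge_cases(self):
        data = np.zeros((3, 4, 375))
        data[1, 0, 100] = 80.0   # Pz over threshold -> dropped
        data[2, 3, 100] = 500.0  # EOG channel is not monitored
        ep = _epochs(data)
        kept, log = reject_amplitude(ep, 75.0)
        assert kept.n_epochs == 2
        assert log.table.kept.tolist() == [True, False, True]
        assert log.table.loc[1, "channel"] == "Pz"

    def test_planted_exceedances_exact_indices(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 5, (50, 4, 375))
        bad = [3, 17, 41]
        for i in bad:
            data[i, rng.integers(0, 3), 200] = 120.0
        kept, log = reject_amplitude(_epochs(data), 75.0)
        assert kept.n_epochs == 47
        assert sorted(np.flatnonzero(~log.table.kept.to_numpy())) == bad


class TestRereference:
    def test_arithmetic(self):
        data = np.zeros((1, 4, 375))
        data[0, 0, 10] = 5.0
        data[0, 1, 10] = 2.0
        data[0, 2, 10] = 4.0
        out = rereference_linked_mastoids(_epochs(data))
        assert out.data[0, 0, 10] == pytest.approx(2.0)  # 5 - (2+4)/2

    def test_zero_mastoids_noop(self):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 3, (2, 4, 375))
        data[:, 1:3, :] = 0.0
        out = rereference_linked_mastoids(_epochs(data))
        np.testing.assert_array_equal(out.data[:, 0], data[:, 0])

    def test_cancellation(self):
        rng = np.random.default_rng(7)
        m = rng.normal(0, 3, (2, 375))
        data = np.zeros((1, 4, 375))
        data[0, 1], data[0, 2] = m
        data[0, 0] = m.mean(axis=0)
        out = rereference_linked_mastoids(_epochs(data))
        assert np.allclose(out.data[0, 0], 0.0, atol=1e-12)

    def test_missing_channel_rejected(self):
        ep = _epochs(np.zeros((1, 2, 375)), ch=("Pz", "Cz"))
        with pytest.raises(KeyError):
            rereference_linked_mastoids(ep)


class TestPipeline:
    def test_canonical_step_order_continuous(self):
        """The runner applies the chain in the documented narrative order."""
        rng = np.random.default_rng(8)
        ch = ["Pz", "Cz", "Fz", "TP9", "TP10", "VEOGu", "VEOGl", "HEOGl", "HEOGr"]
        onsets = np.arange(2000, 58000, 2000)
        rec = Recording(rng.normal(0, 5, (9, 60000)), 1000.0, ch,
                        pd.DataFrame({"onset_sample": onsets}))
        res = run_pipeline(rec)
        assert res.steps == ["resample", "bandpass_fir", "extract_epochs",
                             "baseline_correct", "regress_eog",
                             "reject_amplitude", "rereference_linked_mastoids"]
        assert res.epochs.srate == 250.0
        assert res.epochs.n_samples == 375
        assert "OLS regression" in res.provenance["eog_method"]

    def test_epoched_input_order_and_bookkeeping(self, session_plan):
        prim, _, _ = synth_eeg.simulate_session(
            session_plan, synth_eeg.SubjectProfile(), seed=9,
            include_secondary=False)
        res = run_pipeline(prim)
        assert res.steps == ["lowpass_fir", "baseline_correct", "regress_eog",
                             "reject_amplitude", "rereference_linked_mastoids"]
        assert res.epochs.n_epochs <= prim.n_epochs
        assert res.rejection.n_kept == res.epochs.n_epochs
        assert res.rejection.n_kept + res.rejection.n_dropped == prim.n_epochs
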