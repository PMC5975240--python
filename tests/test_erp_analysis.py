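"""Scalp pipeline: EOG regression, band-pass response, epoching and
rejection semantics, N1 measurement and the paired condition contrast."""

import numpy as np
import pytest
from scipy import stats

from speechdcm import erp_analysis as ea


def make_recording(data, fs=256.0, events=(), extra_eog=True):
    n_ch = data.shape[0]
    names = [f"E{i:02d}" for i in range(n_ch)]
    if extra_eog:
        data = np.vstack([data, np.zeros((2, data.shape[1]))])
        names += ["VEOG", "HEOG"]
    return ea.Recording(data=data, fs=fs, ch_names=names, events=list(events))


class TestEogRegress:
    def test_removes_known_propagation(self, rng):
        n = 5000
        veog = rng.normal(size=n).cumsum()  # slow, blink-like
        veog -= veog.mean()
        heog = rng.normal(size=n)
        clean = np.sin(2 * np.pi * 7 * np.arange(n) / 256.0)
        eeg = clean + 0.3 * veog
        rec = ea.Recording(
            data=np.vstack([eeg, veog, heog]),
            fs=256.0,
            ch_names=["E00", "VEOG", "HEOG"],
            events=[],
        )
        out = ea.eog_regress(rec)
        resid = out.data[0] - clean
        # residual propagation coefficient < 0.01
        coef = np.abs(np.dot(resid, veog) / np.dot(veog, veog))
        assert coef < 0.01
        assert np.array_equal(out.data[1], veog)  # EOG untouched

    def test_zero_eog_leaves_recording_unchanged(self, rng):
        data = rng.normal(size=(3, 1000))
        rec = make_recording(data)
        out = ea.eog_regress(rec)
        assert np.allclose(out.data[:3], data)

    def test_orthogonal_eog_coefficients_near_zero(self):
        n = 4096
        t = np.arange(n) / 256.0
        eeg = np.sin(2 * np.pi * 5 * t)
        veog = np.sin(2 * np.pi * 11 * t)  # orthogonal-ish tones
        heog = np.cos(2 * np.pi * 17 * t)
        rec = ea.Recording(
            data=np.vstack([eeg, veog, heog]),
            fs=256.0,
            ch_names=["E00", "VEOG", "HEOG"],
            events=[],
        )
        out = ea.eog_regress(rec)
        assert np.allclose(out.data[0], eeg, atol=1e-6)

    def test_missing_eog_channel_raises(self, rng):
        rec = ea.Recording(rng.normal(size=(2, 100)), 256.0, ["E00", "VEOG"], [])
        with pytest.raises(ValueError, match="HEOG"):
            ea.eog_regress(rec)


class TestBandpass:
    fs = 256.0

    def _tone_response(self, freq):
        n = int(self.fs * 30)
        t = np.arange(n) / self.fs
        x = np.sin(2 * np.pi * freq * t)
        rec = make_recording(x[None, :], fs=self.fs)
        y = ea.bandpass(rec).data[0]
        mid = slice(n // 4, 3 * n // 4)  # avoid filter edges
        return y[mid].std() / x[mid].std()

    def test_passband_tone_preserved(self):
        assert self._tone_response(10.0) == pytest.approx(1.0, abs=0.05)

    def test_passband_ripple_under_1db(self):
        for f in (1.0, 5.0, 25.0):
            g = self._tone_response(f)
            assert 20 * np.log10(g) > -1.0
            assert g < 1.05

    def test_stopband_tone_attenuated(self):
        assert self._tone_response(50.0) < 10 ** (-20 / 20)

    def test_dc_offset_removed(self):
        rec = make_recording(np.full((1, 8192), 13.0), fs=self.fs)
        assert abs(ea.bandpass(rec).data[0, 2000:-2000].mean()) < 0.05

    def test_invalid_band_rejected(self):
        rec = make_recording(np.zeros((1, 1000)), fs=50.0)
        with pytest.raises(ValueError):
            ea.bandpass(rec, 0.5, 30.0)  # 30 Hz above Nyquist at fs=50


def rec_with_trials(n_trials=5, amp=20.0, fs=256.0):
    iti = int(1.5 * fs)
    n = iti * (n_trials + 1)
    data = np.zeros((2, n))
    events = []
    for k in range(n_trials):
        s = iti * (k + 1)
        dur = int(0.1 * fs)
        data[:, s + dur : s + 2 * dur] = -amp  # post-onset deflection
        events.append((s, "cued" if k % 2 else "passive"))
    return make_recording(data, fs=fs, events=events)


class TestEpochAndReject:
    fs = 256.0

    def _rec_with_trials(self, n_trials=5, amp=20.0, fs=256.0):
        return rec_with_trials(n_trials, amp, fs)

    def test_clean_trials_all_survive(self):
        eps = ea.epoch_and_reject(self._rec_with_trials(amp=20.0))
        assert len(eps.labels) == 5
        assert eps.rejected.sum() == 0
        assert eps.epochs.shape[2] == round(0.5 * self.fs)

    def test_injected_spike_rejects_exactly_that_trial(self):
        rec = self._rec_with_trials(n_trials=6, amp=20.0)
        bad = rec.events[3][0]
        rec.data[0, bad + 30 : bad + 40] += 80.0
        eps = ea.epoch_and_reject(rec)
        assert list(np.nonzero(eps.rejected)[0]) == [3]
        assert "exceeds" in eps.reject_reasons[3]

    def test_eog_amplitude_does_not_trigger_rejection(self):
        rec = self._rec_with_trials()
        rec.data[-2, :] = 200.0  # VEOG saturated everywhere
        eps = ea.epoch_and_reject(rec)
        assert eps.rejected.sum() == 0

    def test_edge_event_skipped_and_logged(self):
        rec = self._rec_with_trials()
        rec.events.insert(0, (2, "cued"))  # pre-stimulus window unavailable
        log = []
        eps = ea.epoch_and_reject(rec, log=log)
        assert len(eps.labels) == 5
        assert any("skipped" in line for line in log)

    def test_baseline_window_zero_mean(self):
        eps = ea.epoch_and_reject(self._rec_with_trials())
        base = (eps.times_ms >= -100) & (eps.times_ms <= 0)
        assert np.allclose(eps.epochs[:, :, base].mean(axis=2), 0.0, atol=1e-10)


class TestAverageErp:
    def test_identical_trials_average_to_any_trial(self):
        ep = np.tile(np.arange(10.0)[None, None, :], (4, 2, 1))
        eps = ea.EpochSet(
            epochs=ep,
            times_ms=np.linspace(-100, 396, 10),
            fs=20.0,
            ch_names=["a", "b"],
            labels=["cued"] * 4,
            rejected=np.zeros(4, bool),
            reject_reasons=[None] * 4,
        )
        erp = ea.average_erp(eps, "cued")
        assert np.array_equal(erp.data, ep[0])
        assert erp.n_trials == 4

    def test_rejected_trials_excluded(self):
        ep = np.zeros((3, 1, 4))
        ep[2] = 99.0
        eps = ea.EpochSet(
            epochs=ep,
            times_ms=np.array([-100.0, 0.0, 100.0, 200.0]),
            fs=10.0,
            ch_names=["a"],
            labels=["passive"] * 3,
            rejected=np.array([False, False, True]),
            reject_reasons=[None, None, "amplitude"],
        )
        assert np.all(ea.average_erp(eps, "passive").data == 0.0)
        with pytest.raises(ValueError):
            ea.average_erp(eps, "cued")

    def test_noise_shrinks_like_sqrt_n(self, rng):
        n_trials, n_samp = 64, 200
        noise = rng.normal(size=(n_trials, 1, n_samp))
        eps = ea.EpochSet(
            epochs=noise,
            times_ms=np.linspace(-100, 400, n_samp),
            fs=400.0,
            ch_names=["a"],
            labels=["cued"] * n_trials,
            rejected=np.zeros(n_trials, bool),
            reject_reasons=[None] * n_trials,
        )
        ratio = ea.average_erp(eps, "cued").data.std() * np.sqrt(n_trials)
        assert ratio == pytest.approx(1.0, rel=0.2)


class TestN1Peak:
    def _erp(self, wave, fs=1000.0):
        t = np.arange(len(wave)) - 100.0  # 1 ms steps from -100 ms
        return ea.ERPWaveform(
            data=np.asarray(wave)[None, :],
            times_ms=t,
            fs=fs,
            ch_names=["Cz"],
            condition="cued",
            n_trials=10,
        )

    def test_known_trough(self):
        w = np.zeros(500)
        w[200] = -5.0  # t = 100 ms
        m = ea.n1_peak(self._erp(w))
        assert (m.amplitude, m.latency) == (-5.0, 100.0)

    def test_monotone_decreasing_hits_window_boundary(self):
        w = -np.linspace(0, 1, 500)
        assert ea.n1_peak(self._erp(w)).latency == 150.0

    def test_tie_breaks_to_earliest(self):
        w = np.zeros(500)
        w[[180, 220]] = -3.0  # 80 ms and 120 ms
        assert ea.n1_peak(self._erp(w)).latency == 80.0


class TestPairedContrast:
    def test_identical_lists_give_zero_effect(self):
        res = ea.paired_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.cohens_d == 0.0

    def test_closed_form_on_diffs_1_2_3(self):
        passive = np.array([0.0, 0.0, 0.0])
        cued = np.array([1.0, 2.0, 3.0])
        res = ea.paired_contrast(cued, passive)
        assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.df == 2
        # cross-check against the reference implementation
        ref = stats.ttest_rel(cued, passive)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.cohens_d == pytest.approx(2.0 / 1.0)

    def test_swapping_lists_flips_signs(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        r1 = ea.paired_contrast(a, b)
        r2 = ea.paired_contrast(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.cohens_d == pytest.approx(-r2.cohens_d)
        assert r1.p == pytest.approx(r2.p)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            ea.paired_contrast([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])


def test_rereference_subtracts_reference_mean(rng):
    data = rng.normal(size=(3, 100))
    rec = make_recording(data)
    out = ea.rereference(rec, ["E00", "E01"])
    ref = data[:2].mean(axis=0)
    assert np.allclose(out.data[2], data[2] - ref)


def test_preprocess_logs_fixed_stage_order():
    rec = rec_with_trials()
    log = []
    ea.preprocess(rec, log=log)
    joined = " ".join(log)
    assert joined.index("eog_regress") < joined.index("bandpass") < joined.index("epoch")
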