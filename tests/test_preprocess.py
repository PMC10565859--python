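"""Filtering, resampling, re-referencing, epoching and artifact tests."""

import numpy as np
import pandas as pd
import pytest

from earload.containers import Channel, EventStream, Montage, Recording
from earload.preprocess import (
    bandpass,
    epoch_fixed_windows,
    epoch_stimulus_locked,
    reject_artifact_epochs,
    remove_blinks,
    rereference,
    resample,
)
from earload.spectral import periodogram_psd
from earload.synth import EffectProfile, make_arithmetic_schedule, synthesize_recording

from conftest import small_arith_design, small_montage


def toy_recording(data, fs=500.0, names=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = names or [f"c{i}" for i in range(data.shape[0])]
    montage = Montage([Channel(n, "cap", "scalp") for n in names], fs)
    frame = pd.DataFrame(
        [(0.0, 0.0, 1, 1, 0, "block_start"),
         (data.shape[1] / fs - 1e-3, 0.0, 1, 1, 0, "block_end")],
        columns=["onset_s", "duration_s", "session", "block", "level", "kind"],
    )
    return Recording(data=data, sampling_rate=fs, montage=montage, events=EventStream(frame))


class TestBandpass:
    def test_dc_rejection(self):
        rec = toy_recording(np.full((1, 5000), 10.0))
        out = bandpass(rec, 0.5, 100.0)
        assert np.abs(out.data[:, 1000:-1000]).max() < 1.0

    @pytest.mark.parametrize(
        "freq,min_gain,max_gain",
        [(10.0, 0.9, 1.1), (0.1, 0.0, 0.1)],  # passband identity; sub-band stop
    )
    def test_frequency_response(self, freq, min_gain, max_gain):
        fs, dur = 500.0, 60.0
        t = np.arange(int(fs * dur)) / fs
        rec = toy_recording(np.sin(2 * np.pi * freq * t)[None, :])
        out = bandpass(rec, 0.5, 100.0)
        interior = out.data[0, int(10 * fs):-int(10 * fs)]
        amp = np.abs(interior).max()
        assert min_gain <= amp <= max_gain

    def test_passband_flatness_contract(self):
        """Gain within +-1 dB over [2*low, 0.9*high]."""
        fs = 500.0
        t = np.arange(int(fs * 30)) / fs
        for freq in (1.0, 10.0, 45.0, 90.0):
            rec = toy_recording(np.sin(2 * np.pi * freq * t)[None, :])
            amp = np.abs(bandpass(rec, 0.5, 100.0).data[0, 2500:-2500]).max()
            assert 10 ** (-1 / 20) <= amp <= 10 ** (1 / 20)

    def test_invalid_edges(self):
        rec = toy_recording(np.zeros((1, 1000)))
        for low, high in [(0.0, 100.0), (100.0, 0.5), (0.5, 300.0)]:
            with pytest.raises(ValueError):
                bandpass(rec, low, high)


class TestResample:
    def test_length_arithmetic(self):
        rec = toy_recording(np.zeros((2, 5000)))  # 10 s at 500 Hz
        out = resample(rec, 256.0)
        assert out.data.shape == (2, 2560)
        assert out.sampling_rate == 256.0

    def test_amplitude_below_nyquist(self):
        t = np.arange(5000) / 500.0
        rec = toy_recording(np.sin(2 * np.pi * 10 * t)[None, :])
        out = resample(rec, 256.0)
        assert np.abs(out.data[0, 200:-200]).max() == pytest.approx(1.0, rel=0.05)

    def test_alias_suppression(self):
        """A 120 Hz tone resampled to 200 Hz must not fold to 80 Hz."""
        fs = 500.0
        t = np.arange(int(fs * 20)) / fs
        rec = toy_recording(np.sin(2 * np.pi * 120 * t)[None, :])
        out = resample(rec, 200.0)
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 200.0)
        power = np.abs(np.fft.rfft(out.data[0])) ** 2
        alias = power[np.abs(freqs - 80.0) < 0.5].sum()
        original = (np.abs(np.fft.rfft(rec.data[0])) ** 2).max()
        assert alias <= 0.01 * original

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(toy_recording(np.zeros((1, 100))), 600.0)


class TestRereference:
    def test_hand_computation_and_noop(self):
        rec = toy_recording(np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]]), names=["a", "b"])
        out = rereference(rec, {"a": "b"})
        np.testing.assert_allclose(out.data[0], [-9.0, -18.0, -27.0])
        np.testing.assert_allclose(out.data[1], rec.data[1])  # unmapped unchanged
        np.testing.assert_array_equal(rereference(rec, {}).data, rec.data)
        assert np.all(rereference(rec, {"a": "a"}).data[0] == 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        d1, d2 = rng.standard_normal((2, 2, 50))
        scheme = {"a": "b"}
        r1, r2 = toy_recording(d1, names=["a", "b"]), toy_recording(d2, names=["a", "b"])
        rsum = toy_recording(d1 + d2, names=["a", "b"])
        np.testing.assert_allclose(
            rereference(rsum, scheme).data,
            rereference(r1, scheme).data + rereference(r2, scheme).data,
        )

    def test_missing_reference(self):
        rec = toy_recording(np.zeros((1, 10)), names=["a"])
        with pytest.raises(KeyError):
            rereference(rec, {"a": "zz"})


def _stim_recording(n_stim=20, fs=500.0, soa=2.5):
    """Recording with evenly spaced stimuli inside one block."""
    dur = n_stim * soa + 10.0
    rows = [(0.5, 0.0, 1, 1, 2, "block_start")]
    for i in range(n_stim):
        rows.append((1.0 + i * soa, 0.5, 1, 1, 2, "stimulus_nontarget"))
    rows.append((dur - 1.0, 0.0, 1, 1, 2, "block_end"))
    frame = pd.DataFrame(rows, columns=["onset_s", "duration_s", "session", "block", "level", "kind"])
    rng = np.random.default_rng(5)
    data = rng.standard_normal((2, int(dur * fs)))
    montage = Montage([Channel("a", "cap", "scalp"), Channel("b", "cap", "scalp")], fs)
    return Recording(data=data, sampling_rate=fs, montage=montage, events=EventStream(frame))


class TestEpoching:
    def test_stimulus_locked_shape_and_labels(self):
        rec = _stim_recording(n_stim=20)
        ep = epoch_stimulus_locked(rec)
        assert ep.n_trials == 20
        assert ep.n_samples == int(round(2.0 * rec.sampling_rate))
        assert np.all(ep.labels == 2)

    def test_edge_epoch_dropped(self):
        rec = _stim_recording(n_stim=20)
        # truncate so the last epoch cannot fit
        short = rec.copy_with(rec.data[:, : int((1.0 + 19 * 2.5 + 0.5) * rec.sampling_rate)])
        ep = epoch_stimulus_locked(short)
        assert ep.n_trials == 19

    def test_baseline_zero_mean_and_idempotence(self):
        rec = _stim_recording()
        ep = epoch_stimulus_locked(rec, baseline=(-0.2, 0.0))
        t = ep.times
        mask = (t >= -0.2) & (t < 0.0)
        np.testing.assert_allclose(ep.data[:, :, mask].mean(axis=2), 0.0, atol=1e-12)
        again = ep.data - ep.data[:, :, mask].mean(axis=2, keepdims=True)
        np.testing.assert_allclose(again, ep.data, atol=1e-12)

    def test_fixed_windows_count(self):
        """A 60 s block at 2 s windows / 1 s step yields 59 windows."""
        fs = 500.0
        frame = pd.DataFrame(
            [(0.0, 0.0, 1, 1, 4, "block_start"), (60.0, 0.0, 1, 1, 4, "block_end")],
            columns=["onset_s", "duration_s", "session", "block", "level", "kind"],
        )
        montage = Montage([Channel("a", "cap", "scalp")], fs)
        rec = Recording(
            data=np.zeros((1, int(61 * fs))), sampling_rate=fs,
            montage=montage, events=EventStream(frame),
        )
        ep = epoch_fixed_windows(rec, win=2.0, step=1.0)
        assert ep.n_trials == 59
        assert np.all(ep.labels == 4)

    def test_windows_do_not_straddle_blocks(self):
        fs = 100.0
        rows = [
            (0.0, 0.0, 1, 1, 1, "block_start"), (5.0, 0.0, 1, 1, 1, "block_end"),
            (7.0, 0.0, 1, 2, 2, "block_start"), (12.0, 0.0, 1, 2, 2, "block_end"),
        ]
        frame = pd.DataFrame(rows, columns=["onset_s", "duration_s", "session", "block", "level", "kind"])
        montage = Montage([Channel("a", "cap", "scalp")], fs)
        # signal encodes time so we can recover each window's origin
        data = np.arange(int(13 * fs), dtype=float)[None, :] / fs
        rec = Recording(data=data, sampling_rate=fs, montage=montage, events=EventStream(frame))
        ep = epoch_fixed_windows(rec, win=2.0, step=1.0)
        assert ep.n_trials == 8  # 4 per 5 s block
        for trial in range(ep.n_trials):
            start, end = ep.data[trial, 0, 0], ep.data[trial, 0, -1]
            assert (start >= 0.0 and end < 5.0) or (start >= 7.0 and end < 12.0)

    def test_short_block_skipped(self):
        fs = 100.0
        frame = pd.DataFrame(
            [(0.0, 0.0, 1, 1, 1, "block_start"), (1.0, 0.0, 1, 1, 1, "block_end"),
             (2.0, 0.0, 1, 2, 1, "block_start"), (6.0, 0.0, 1, 2, 1, "block_end")],
            columns=["onset_s", "duration_s", "session", "block", "level", "kind"],
        )
        montage = Montage([Channel("a", "cap", "scalp")], fs)
        rec = Recording(np.zeros((1, 700)), fs, montage, EventStream(frame))
        ep = epoch_fixed_windows(rec, win=2.0, step=1.0)
        assert ep.n_trials == 3  # only the 4 s block contributes


class TestRejection:
    def test_vacuous_and_constructed_outlier(self, ):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((10, 2, 100))
        data[4, 1, 50] += 100.0  # injected spike
        from conftest import make_epochs

        ep = make_epochs(data)
        kept, report = reject_artifact_epochs(ep, peak_to_peak_limit=np.inf)
        assert report.n_removed == 0 and kept.n_trials == 10
        kept, report = reject_artifact_epochs(ep, peak_to_peak_limit=50.0)
        assert list(report.removed_indices) == [4]
        assert kept.n_trials == 9

    def test_eog_channels_exempt(self):
        from conftest import make_epochs

        data = np.zeros((5, 2, 100))
        data[2, 0, 10] = 500.0  # huge excursion but on the EOG channel
        ep = make_epochs(data, roles=["eog", "scalp"])
        _, report = reject_artifact_epochs(ep, peak_to_peak_limit=100.0)
        assert report.n_removed == 0

    def test_default_limit_rejects_under_5pct(self, nback_epochs):
        _, rejection, _ = nback_epochs
        assert rejection.fraction < 0.05


@pytest.fixture(scope="module")
def blinky():
    design = small_arith_design(n_blocks_per_session=2, levels=(1, 2))
    ev = make_arithmetic_schedule(design, 21)
    eff = EffectProfile.null(design.levels)
    eff.blink_rate = 15.0
    return synthesize_recording(ev, small_montage(4), eff, seed=22)


class TestBlinkRemoval:
    def test_contract_on_synthetic_blinks(self, blinky):
        cleaned, report = remove_blinks(blinky)
        assert 1 <= report.n_removed <= 3
        truth = blinky.ground_truth["blink_timecourse"]
        frontal = [i for i, r in enumerate(blinky.montage.roles) if r == "eog"]
        for i in frontal:
            c = np.corrcoef(cleaned.data[i], truth)[0, 1]
            assert abs(c) < 0.2
        # alpha band power on non-frontal channels barely changes
        active = truth != 0
        quiet = ~active
        for i in range(blinky.data.shape[0]):
            if i in frontal:
                continue
            f0, p0 = _alpha_power(blinky.data[i][quiet], blinky.sampling_rate)
            f1, p1 = _alpha_power(cleaned.data[i][quiet], blinky.sampling_rate)
            assert p1 == pytest.approx(p0, rel=0.05)

    def test_recovered_pattern_close_to_truth(self, blinky):
        _, report = remove_blinks(blinky)
        truth = blinky.ground_truth["blink_pattern"]
        best = 90.0
        for k in range(report.patterns.shape[1]):
            v = report.patterns[:, k]
            cos = abs(v @ truth) / np.linalg.norm(v)
            best = min(best, np.degrees(np.arccos(np.clip(cos, -1, 1))))
        assert best < 10.0

    def test_no_blinks_noop(self):
        design = small_arith_design(n_blocks_per_session=2, levels=(1, 2))
        ev = make_arithmetic_schedule(design, 23)
        rec = synthesize_recording(ev, small_montage(4), EffectProfile.null(design.levels), seed=24)
        cleaned, report = remove_blinks(rec)
        rms = np.sqrt(np.mean((cleaned.data - rec.data) ** 2)) / np.sqrt(np.mean(rec.data**2))
        assert rms < 0.02


def _alpha_power(x, fs):
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    p = np.abs(np.fft.rfft(x)) ** 2
    m = (freqs >= 8) & (freqs <= 12)
    return freqs, p[m].sum()
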