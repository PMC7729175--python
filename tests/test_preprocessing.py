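"""Filtering, epoching, artifact screening, and decimation."""

import numpy as np
import pytest
from scipy import signal as sps

from orthobci.preprocessing import (ArtifactThresholds, BandSpec, Epoch,
                                    SYSTEM_BANDS, assess_quality,
                                    design_bandpass, downsample, extract_epoch,
                                    filter_bands, filter_recording)
from orthobci.session import Montage, Recording, StimulusEvent

FS = 256.0


def _recording(signals):
    return Recording(signals=np.asarray(signals, dtype=float),
                     montage=Montage())


def _sine_recording(freq_hz, amplitude=1.0, seconds=10.0):
    t = np.arange(int(seconds * FS)) / FS
    row = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return _recording(np.tile(row, (8, 1))), t


def _epoch_from(x_4_14=None, x_20_40=None, x_4_40=None, n_t=204):
    zero = np.zeros((8, n_t))
    ev = StimulusEvent(onset_sample=0, option_id=0, run_id=0, cued_target=0)
    return Epoch(X_4_14=zero if x_4_14 is None else x_4_14,
                 X_20_40=zero if x_20_40 is None else x_20_40,
                 X_4_40=zero if x_4_40 is None else x_4_40,
                 source_event=ev)


class TestFiltering:
    def test_zero_input_gives_zero_output(self):
        rec = _recording(np.zeros((8, 1024)))
        for band in SYSTEM_BANDS.values():
            assert np.allclose(filter_recording(rec, band).signals, 0.0)

    @pytest.mark.parametrize("freq,band,passband", [
        (10.0, BandSpec(4, 14), True),
        (50.0, BandSpec(4, 14), False),
        (30.0, BandSpec(20, 40), True),
    ])
    def test_designed_frequency_response(self, freq, band, passband):
        # Independent oracle: evaluate the designed taps' transfer function.
        taps = design_bandpass(band, FS)
        _, h = sps.freqz(taps, worN=[freq], fs=FS)
        gain = np.abs(h[0])
        if passband:
            assert abs(gain - 1.0) < 0.05
        else:
            assert 20 * np.log10(gain) <= -40.0

    def test_passband_sine_amplitude_preserved_in_steady_state(self):
        rec, t = _sine_recording(10.0)
        out = filter_recording(rec, BandSpec(4, 14)).signals[0]
        mid = out[1024:-1024]
        assert np.abs(np.abs(mid).max() - 1.0) < 0.05

    def test_stopband_sine_attenuated_40db(self):
        rec, _ = _sine_recording(50.0)
        out = filter_recording(rec, BandSpec(4, 14)).signals[0]
        assert np.abs(out[1024:-1024]).max() < 10 ** (-40 / 20)

    def test_group_delay_compensation_keeps_stimulus_locking(self):
        # A pulse at sample k must produce output peaking near sample k.
        sig = np.zeros((8, 2048))
        sig[:, 1000] = 1.0
        out = filter_recording(_recording(sig), BandSpec(4, 40)).signals
        assert abs(int(np.abs(out[0]).argmax()) - 1000) <= 2

    def test_band_violating_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            filter_recording(_recording(np.zeros((8, 512))), BandSpec(4, 130))

    def test_filter_then_epoch_commutes_with_trimming(self, rng):
        sig = rng.normal(0, 5, size=(8, 4096))
        rec = _recording(sig)
        band = BandSpec(4, 40)
        full = filter_recording(rec, band).signals[:, 2000:2204]
        # Epoching a longer interior window first, then filtering and trimming.
        sub = _recording(sig[:, 1000:3000])
        trimmed = filter_recording(sub, band).signals[:, 1000:1204]
        assert np.allclose(full, trimmed, atol=1e-6)


class TestEpochExtraction:
    def _bands(self, n=2048):
        ramp = np.tile(np.arange(n, dtype=float), (8, 1))
        rec = _recording(ramp)
        return {name: rec for name in SYSTEM_BANDS}

    def test_onset_zero_slices_first_204_samples(self):
        bands = self._bands()
        ev = StimulusEvent(onset_sample=0, option_id=0, run_id=0)
        ep = extract_epoch(bands, ev)
        assert ep.n_t == 204
        assert np.array_equal(ep.X_4_40[0], np.arange(204.0))

    def test_identical_onsets_give_identical_epochs(self):
        bands = self._bands()
        e1 = extract_epoch(bands, StimulusEvent(onset_sample=77, option_id=0,
                                                run_id=0))
        e2 = extract_epoch(bands, StimulusEvent(onset_sample=77, option_id=3,
                                                run_id=1))
        assert np.array_equal(e1.X_4_14, e2.X_4_14)

    def test_boundary_window_arithmetic(self):
        bands = self._bands(n=2048)
        ok = StimulusEvent(onset_sample=2048 - 204, option_id=0, run_id=0)
        assert extract_epoch(bands, ok).n_t == 204
        bad = StimulusEvent(onset_sample=2048 - 203, option_id=0, run_id=0)
        with pytest.raises(IndexError):
            extract_epoch(bands, bad)


class TestArtifactScreening:
    def test_all_zero_epoch_is_a_degenerate_artifact(self):
        q = assess_quality(_epoch_from())
        assert np.all(q.v_pp == 0) and np.all(q.sigma == 0)
        assert np.all(np.isnan(q.power_ratio))
        assert q.verdict == "artifact"

    def test_sine_statistics_match_closed_form(self):
        # 60 uV 10 Hz sine spanning the window: pp ~ 120, sigma ~ A/sqrt(2).
        t = np.arange(204) / FS
        sine = 60.0 * np.sin(2 * np.pi * 10 * t)
        ep = _epoch_from(x_4_40=np.tile(sine, (8, 1)),
                         x_20_40=np.zeros((8, 204)))
        q = assess_quality(ep)
        assert q.v_pp == pytest.approx(120.0, rel=0.01)
        assert q.sigma == pytest.approx(60.0 / np.sqrt(2), rel=0.02)
        assert q.power_ratio == pytest.approx(0.0, abs=1e-12)
        assert q.verdict == "valid"
        # Direct evaluation of the definitions as an independent oracle.
        x = ep.X_4_40[0]
        assert q.v_pp[0] == pytest.approx(x.max() - x.min())
        mu = x.sum() / 204
        assert q.sigma[0] == pytest.approx(np.sqrt(((x - mu) ** 2).sum() / 203))

    def test_single_large_sample_trips_peak_to_peak(self):
        x = np.zeros((8, 204))
        x[5, 40] = 250.0
        q = assess_quality(_epoch_from(x_4_40=x))
        assert q.v_pp[5] >= 200.0
        assert q.verdict == "artifact"

    def test_threshold_semantics_are_greater_or_equal(self):
        # Non-zero baseline keeps other channels out of the degenerate rule.
        x = np.ones((8, 204))
        x[0, 0] = 201.0  # exactly 200 uV peak-to-peak on channel 0
        assert assess_quality(_epoch_from(x_4_40=x)).verdict == "artifact"
        x[0, 0] = 200.99
        assert assess_quality(_epoch_from(x_4_40=x)).verdict == "valid"

    def test_power_ratio_threshold(self):
        base = np.random.default_rng(0).normal(0, 5, (8, 204))
        q_low = assess_quality(_epoch_from(x_4_40=base,
                                           x_20_40=0.5 * base))
        assert q_low.verdict == "valid"  # ratio 0.25 everywhere
        q_high = assess_quality(_epoch_from(x_4_40=base,
                                            x_20_40=0.9 * base))
        assert q_high.verdict == "artifact"  # ratio 0.81 >= 0.7

    def test_metrics_permute_with_channels(self, rng):
        x44 = rng.normal(0, 20, (8, 204))
        x24 = rng.normal(0, 5, (8, 204))
        q = assess_quality(_epoch_from(x_4_40=x44, x_20_40=x24))
        perm = rng.permutation(8)
        qp = assess_quality(_epoch_from(x_4_40=x44[perm], x_20_40=x24[perm]))
        assert np.allclose(qp.v_pp, q.v_pp[perm])
        assert np.allclose(qp.sigma, q.sigma[perm])
        assert qp.verdict == q.verdict

    def test_power_ratio_bounded_on_filtered_subband_input(self, rng):
        sig = rng.normal(0, 10, size=(8, 4096))
        bands = filter_bands(_recording(sig))
        ev = StimulusEvent(onset_sample=2000, option_id=0, run_id=0)
        q = assess_quality(extract_epoch(bands, ev))
        assert np.all(q.power_ratio >= 0)
        assert np.all(q.power_ratio <= 1.05)


class TestDecimation:
    def test_constant_and_index_arithmetic(self):
        const = _epoch_from(x_4_14=np.full((8, 204), 3.25))
        assert downsample(const).Y.shape == (8, 51)
        assert np.all(downsample(const).Y == 3.25)
        cols = _epoch_from(x_4_14=np.tile(np.arange(204.0), (8, 1)))
        assert np.array_equal(downsample(cols).Y[0], np.arange(0, 204, 4.0))

    def test_every_fourth_sample_exhaustively(self, rng):
        x = rng.normal(size=(8, 204))
        y = downsample(_epoch_from(x_4_14=x)).Y
        for e in range(8):
            for k in range(51):
                assert y[e, k] == x[e, 4 * k]

    def test_artifact_epoch_refused(self):
        bad = _epoch_from()  # degenerate all-zero epoch
        quality = assess_quality(bad)
        with pytest.raises(ValueError, match="artifact"):
            downsample(bad, quality)
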