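"""Filtering, re-referencing, epoching, and artifact rejection contracts."""

import numpy as np
import pytest
from scipy import signal as sps

from attnloc.synthdata import (
    CHANNELS, TaskDesign, GroundTruth, Recording, generate_schedule,
    synthesize_subject, inject_artifacts,
)
from attnloc.preprocess import (
    RejectionCriteria, bandpass_filter, filter_recording, rereference,
    epoch_and_baseline, reject_artifacts, exclude_subjects,
    _sliding_ptp_exceeds,
)
from conftest import make_epochs

SFREQ = 512.0


def sine(freq, sfreq=SFREQ, seconds=20.0):
    t = np.arange(int(seconds * sfreq)) / sfreq
    return np.sin(2 * np.pi * freq * t), t


class TestBandpassFilter:
    def test_dc_removed(self):
        x = np.full(int(10 * SFREQ), 10.0)
        y = bandpass_filter(x, 0.1, 30.0, SFREQ)
        assert np.abs(y[int(2 * SFREQ):-int(2 * SFREQ)]).max() < 0.5

    def test_passband_unit_gain_zero_phase(self):
        x, _ = sine(5.0)
        y = bandpass_filter(x, 0.1, 30.0, SFREQ)
        core = slice(int(2 * SFREQ), -int(2 * SFREQ))
        gain = y[core].std() / x[core].std()
        assert abs(gain - 1.0) < 0.01
        # zero phase: cross-correlation peaks at lag 0
        lags = sps.correlation_lags(len(x[core]), len(y[core]))
        xc = sps.correlate(x[core], y[core])
        assert lags[np.argmax(xc)] == 0

    def test_stopband_attenuation_matches_design_response(self):
        # forward-backward filtering applies the magnitude response twice;
        # measure the 50 Hz component by quadrature projection (the long
        # 0.1 Hz high-pass transient would pollute a broadband std ratio)
        x, t = sine(50.0)
        y = bandpass_filter(x, 0.1, 30.0, SFREQ)
        sos = sps.butter(4, (0.1, 30.0), btype="bandpass", fs=SFREQ,
                         output="sos")
        _, h = sps.sosfreqz(sos, worN=[50.0], fs=SFREQ)
        expected = np.abs(h[0]) ** 2
        core = slice(int(2 * SFREQ), -int(2 * SFREQ))
        c = np.cos(2 * np.pi * 50.0 * t[core])
        s = np.sin(2 * np.pi * 50.0 * t[core])
        measured = np.hypot(y[core] @ c, y[core] @ s) / (c.size / 2)
        assert expected < 0.05  # it is genuinely a stop band
        assert measured == pytest.approx(expected, rel=0.05)

    def test_double_filtering_nearly_idempotent_in_passband(self):
        x, _ = sine(5.0)
        once = bandpass_filter(x, 0.1, 30.0, SFREQ)
        twice = bandpass_filter(once, 0.1, 30.0, SFREQ)
        core = slice(int(2 * SFREQ), -int(2 * SFREQ))
        assert abs(twice[core].std() / once[core].std() - 1.0) < 0.01

    def test_band_outside_nyquist_rejected(self):
        x, _ = sine(5.0, seconds=2.0)
        with pytest.raises(ValueError):
            bandpass_filter(x, 0.1, 300.0, SFREQ)
        with pytest.raises(ValueError):
            bandpass_filter(x, 0.0, 30.0, SFREQ)


def _recording_from(data, events=None):
    import pandas as pd
    events = events if events is not None else pd.DataFrame(
        {"sample": [], "kind": [], "location": [], "cued_location": []})
    return Recording(data=data, channels=CHANNELS, sfreq=SFREQ, events=events)


class TestRereference:
    def test_zero_mastoids_identity(self):
        data = np.random.default_rng(0).normal(size=(10, 1000))
        data[8:] = 0.0
        rec = _recording_from(data.copy())
        out = rereference(rec)
        assert np.array_equal(out.data, data)

    def test_constant_mastoids_shift(self):
        data = np.zeros((10, 100))
        data[CHANNELS.index("M1")] = 2.0
        data[CHANNELS.index("M2")] = 4.0
        out = rereference(_recording_from(data))
        for name in ("PO7", "PO8", "O1", "O2", "PO3", "PO4"):
            np.testing.assert_allclose(out.channel(name), -3.0)
        np.testing.assert_allclose(out.channel("HEOG"), 0.0)  # EOG untouched

    def test_matches_direct_subtraction(self):
        data = np.random.default_rng(1).normal(size=(10, 500))
        rec = _recording_from(data.copy())
        out = rereference(rec)
        ref = 0.5 * (data[CHANNELS.index("M1")] + data[CHANNELS.index("M2")])
        for name in ("PO7", "PO8", "O1", "O2", "PO3", "PO4"):
            np.testing.assert_allclose(out.channel(name),
                                       data[CHANNELS.index(name)] - ref)
        for name in ("HEOG", "VEOG"):
            np.testing.assert_allclose(out.channel(name),
                                       data[CHANNELS.index(name)])

    def test_missing_mastoid_rejected(self):
        data = np.zeros((8, 100))
        rec = Recording(data=data, channels=CHANNELS[:8], sfreq=SFREQ,
                        events=_recording_from(np.zeros((10, 1))).events)
        with pytest.raises(ValueError, match="mastoid"):
            rereference(rec)


class TestEpochAndBaseline:
    @staticmethod
    def _events(samples):
        import pandas as pd
        return pd.DataFrame({"sample": samples, "kind": "cue",
                             "location": 1, "cued_location": 1})

    def test_constant_channel_becomes_zero(self):
        data = np.full((10, 2000), 5.0)
        ep = epoch_and_baseline(_recording_from(data), self._events([600]))
        assert ep.n_epochs == 1
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)

    def test_epoch_length_and_baseline_mean(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(10, 4000))
        ep = epoch_and_baseline(_recording_from(data),
                                self._events([700, 1500, 2500]))
        assert ep.data.shape == (3, 10, int(round(1.0 * SFREQ)))
        pre = ep.times < 0
        np.testing.assert_allclose(ep.data[:, :, pre].mean(axis=2), 0.0,
                                   atol=1e-12)

    def test_linear_ramp_closed_form(self):
        # ramp a·t has baseline mean a·mean(t_pre); output = a·t − that
        a = 3.0
        n = 4000
        t = np.arange(n) / SFREQ
        data = np.tile(a * t, (10, 1))
        ep = epoch_and_baseline(_recording_from(data), self._events([1000]))
        pre = int(0.2 * SFREQ)
        t_epoch = (np.arange(int(SFREQ)) + 1000 - pre) / SFREQ
        expected = a * t_epoch - a * t_epoch[:pre].mean()
        np.testing.assert_allclose(ep.data[0, 0], expected, atol=1e-9)

    def test_edge_events_dropped(self):
        data = np.zeros((10, 1000))
        ep = epoch_and_baseline(_recording_from(data),
                                self._events([10, 500, 995]))
        assert ep.n_epochs == 1
        assert list(ep.metadata["event_sample"]) == [500]


class TestRejectArtifacts:
    def test_all_zero_epoch_kept(self):
        ep = make_epochs(np.zeros((3, 10, 512)))
        out = reject_artifacts(ep)
        assert out.kept.all()

    def test_absolute_limit(self):
        data = np.zeros((1, 10, 512))
        data[0, CHANNELS.index("O1"), 300] = 120.0
        out = reject_artifacts(make_epochs(data))
        assert not out.kept[0]
        assert out.reject_reason[0] == "absolute limit"

    def test_eog_excluded_from_absolute_rule(self):
        data = np.zeros((1, 10, 512))
        data[0, CHANNELS.index("VEOG"), :] = 45.0  # large but constant
        data[0, CHANNELS.index("VEOG"), 0] = 0.0   # avoid baseline trickery
        out = reject_artifacts(make_epochs(data))
        # constant 45 uV VEOG: below the 50 uV p-p rule, and the +-100 uV
        # rule does not apply to EOG channels
        assert out.kept[0]

    def test_blink_step_within_window(self):
        data = np.zeros((1, 10, 512))
        data[0, CHANNELS.index("VEOG"), 250:] = 60.0  # 60 uV step
        out = reject_artifacts(make_epochs(data))
        assert not out.kept[0]
        assert out.reject_reason[0] == "blink"

    def test_slow_heog_drift_kept(self):
        # 30 uV spread over 600 ms: <= 35 uV inside any 300 ms window
        sfreq = 512.0
        n = 512
        data = np.zeros((1, 10, n))
        ramp_len = int(0.6 * sfreq)
        drift = np.concatenate([
            np.linspace(0, 30, ramp_len),
            np.full(n - ramp_len, 30.0),
        ])
        data[0, CHANNELS.index("HEOG")] = drift
        out = reject_artifacts(make_epochs(data))
        assert out.kept[0]

    def test_fast_heog_step_rejected(self):
        data = np.zeros((1, 10, 512))
        data[0, CHANNELS.index("HEOG"), 250:] = 40.0
        out = reject_artifacts(make_epochs(data))
        assert not out.kept[0]
        assert out.reject_reason[0] == "eye movement"

    def test_sliding_ptp_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        x = rng.normal(scale=10.0, size=(20, 200))
        for window, thr in [(7, 25.0), (16, 30.0), (77, 45.0)]:
            fast = _sliding_ptp_exceeds(x, window, thr)
            brute = np.array([
                any(row[i:i + window].max() - row[i:i + window].min() > thr
                    for i in range(len(row) - window + 1))
                for row in x
            ])
            np.testing.assert_array_equal(fast, brute)

    def test_recall_on_injected_blinks_and_saccades(self, small_design,
                                                    clean_truth):
        """Every epoch containing a supra-threshold injected artifact is
        flagged; with artifacts off and no noise there are zero rejections."""
        sched = generate_schedule(small_design, seed=13)
        rec = synthesize_subject(sched, clean_truth, seed=2)
        out = reject_artifacts(epoch_and_baseline(
            filter_recording(rereference(rec))))
        assert out.kept.all()

        noisy, labels = inject_artifacts(
            rec, {"blink": 0.4, "saccade": 0.4}, seed=5)
        assert len(labels) >= 5
        ep = reject_artifacts(epoch_and_baseline(
            filter_recording(rereference(noisy))))
        pre = int(0.2 * ep.sfreq)
        post = int(0.8 * ep.sfreq)
        for art in labels.itertuples(index=False):
            dur = int(0.25 * ep.sfreq) if art.kind == "blink" \
                else int(0.4 * ep.sfreq)
            for i, s in enumerate(ep.metadata["event_sample"]):
                # artifact core overlaps the epoch window
                if s - pre <= art.sample + dur // 2 <= s + post:
                    assert not ep.kept[i], (art.kind, art.sample, s)

    def test_subthreshold_saccade_not_flagged(self, small_design, clean_truth):
        sched = generate_schedule(small_design, seed=13)
        rec = synthesize_subject(sched, clean_truth, seed=2)
        noisy, labels = inject_artifacts(rec, {"blink": 0.0, "saccade": 0.5},
                                         seed=6, saccade_amp_uv=20.0)
        assert len(labels) >= 3
        ep = reject_artifacts(epoch_and_baseline(
            filter_recording(rereference(noisy))))
        assert ep.kept.all()


class TestExcludeSubjects:
    def test_threshold_rate_excluded(self):
        kept = exclude_subjects({"a": 0.05, "b": 0.10, "c": 0.30})
        assert kept == ["a", "b"]

    def test_all_clean_kept(self):
        rates = {f"s{i}": 0.0 for i in range(5)}
        assert exclude_subjects(rates) == list(rates)

    def test_study_sized_exclusion(self):
        rates = {f"S{i:02d}": 0.05 for i in range(1, 17)}
        rates["S09"] = 0.30
        kept = exclude_subjects(rates)
        assert len(kept) == 15 and "S09" not in kept

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="all subjects"):
            exclude_subjects({"a": 0.9, "b": 1.0})

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            exclude_subjects({"a": 1.5})
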