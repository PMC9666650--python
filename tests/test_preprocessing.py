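"""Filtering, re-referencing, epoching, baseline, rejection, inclusion."""

import numpy as np
import pytest
from scipy import signal

from vectionerp import (
    Condition,
    Direction,
    Event,
    EventKind,
    FilterSpec,
    Recording,
    RejectionCriteria,
    ValidationError,
    apply_filters,
    baseline_correct,
    check_participant_inclusion,
    epoch_recording,
    reject_artifacts,
    rereference_common_average,
)
from vectionerp.preprocessing import design_bandpass, design_notch, zero_phase_filter

from conftest import make_epochs

# short transitions so test fixtures stay small; cutoffs are the defaults
FAST_SPEC = FilterSpec(hp_transition=1.0, lp_transition=7.5)


def _gain(kernel: np.ndarray, freq: float, srate: float) -> float:
    w, h = signal.freqz(kernel, worN=[2 * np.pi * freq / srate])
    return float(np.abs(h[0]))


class TestFilters:
    def test_notch_attenuates_50hz_by_30db(self):
        for spec in (FilterSpec(), FAST_SPEC):
            k = design_notch(50.0, spec, 1000.0)
            assert 20 * np.log10(_gain(k, 50.0, 1000.0) + 1e-12) < -30

    def test_bandpass_preserves_10hz_within_5pct(self):
        k = design_bandpass(FAST_SPEC, 1000.0)
        assert _gain(k, 10.0, 1000.0) == pytest.approx(1.0, abs=0.05)
        k_default = design_bandpass(FilterSpec(), 1000.0)
        assert _gain(k_default, 10.0, 1000.0) == pytest.approx(1.0, abs=0.05)

    def test_applied_filter_attenuates_line_noise_and_keeps_passband(self):
        srate, dur = 1000.0, 20.0
        t = np.arange(int(srate * dur)) / srate
        rec = Recording(
            np.vstack([np.sin(2 * np.pi * 50 * t), np.sin(2 * np.pi * 10 * t)]),
            srate, ["A", "B"],
        )
        out = apply_filters(rec, FAST_SPEC)
        mid = slice(int(5 * srate), int(15 * srate))  # away from edges
        assert np.abs(out.data[0, mid]).max() < 0.05  # 50 Hz removed
        assert np.abs(out.data[1, mid]).max() == pytest.approx(1.0, abs=0.05)

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros((2, 8000)), 1000.0, ["A", "B"])
        out = apply_filters(rec, FAST_SPEC)
        np.testing.assert_allclose(out.data, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = Recording(rng.normal(size=(2, 8000)), 1000.0, ["A", "B"])
        b = Recording(rng.normal(size=(2, 8000)), 1000.0, ["A", "B"])
        ab = Recording(a.data + b.data, 1000.0, ["A", "B"])
        np.testing.assert_allclose(
            apply_filters(ab, FAST_SPEC).data,
            apply_filters(a, FAST_SPEC).data + apply_filters(b, FAST_SPEC).data,
            atol=1e-10,
        )

    def test_zero_phase_no_delay_on_passband_burst(self):
        # a 10 Hz burst keeps its envelope peak sample after filtering
        srate = 1000.0
        t = np.arange(8000) / srate
        env = np.exp(-((t - 4.0) ** 2) / (2 * 0.5**2))
        x = env * np.sin(2 * np.pi * 10 * (t - 4.0))
        k = design_bandpass(FAST_SPEC, srate)
        y = zero_phase_filter(x[None, :], k)[0]
        assert abs(int(np.argmax(np.abs(signal.hilbert(y)))) - 4000) <= 5

    def test_filter_edge_above_nyquist_rejected(self):
        rec = Recording(np.zeros((1, 1000)), 150.0, ["A"])
        with pytest.raises(ValidationError, match="Nyquist"):
            apply_filters(rec, FAST_SPEC)


class TestRereference:
    def test_two_channel_closed_form(self):
        rec = Recording(np.array([[4.0, 2.0], [2.0, 6.0]]), 1000.0, ["A", "B"])
        out = rereference_common_average(rec)
        np.testing.assert_allclose(out.data, [[1.0, -2.0], [-1.0, 2.0]])
        assert out.reference == "common_average"

    def test_mean_across_eeg_channels_is_zero(self):
        rng = np.random.default_rng(1)
        rec = Recording(rng.normal(size=(6, 100)), 1000.0, [f"E{i}" for i in range(6)])
        out = rereference_common_average(rec)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_eog_excluded_and_unchanged(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4, 50))
        rec = Recording(data.copy(), 1000.0, ["C3", "C4", "hEOG", "vEOG"])
        out = rereference_common_average(rec)
        np.testing.assert_allclose(out.data[2:], data[2:])
        np.testing.assert_allclose(out.data[:2].mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rec = Recording(rng.normal(size=(4, 50)), 1000.0, ["a", "b", "c", "d"])
        once = rereference_common_average(rec)
        twice = rereference_common_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)


def _recording_with_onsets(n_events=100, srate=1000.0, spacing=1000, lead=500):
    n_s = lead + spacing * n_events + 1000
    rng = np.random.default_rng(4)
    events = [
        Event(
            lead + i * spacing,
            EventKind.MOTION_ONSET,
            Condition.COHERENT if i % 2 == 0 else Condition.INCOHERENT,
            Direction.CW if i % 4 < 2 else Direction.CCW,
        )
        for i in range(n_events)
    ]
    return Recording(rng.normal(size=(3, n_s)), srate, ["Fp1", "Cz", "Pz"], events=events)


class TestEpoching:
    def test_one_epoch_per_motion_onset(self):
        es = epoch_recording(_recording_with_onsets(100))
        assert es.n_epochs == 100
        assert es.data.shape[2] == 600  # 600 ms at 1000 Hz

    def test_times_axis_spans_epoch_window(self):
        es = epoch_recording(_recording_with_onsets(4))
        assert es.times[0] == -200.0
        assert es.times[-1] == 399.0

    def test_out_of_bounds_event_dropped(self):
        rec = _recording_with_onsets(4)
        rec = Recording(
            rec.data, rec.srate, rec.channel_labels,
            events=rec.events + [Event(10, EventKind.MOTION_ONSET, Condition.COHERENT, Direction.CW)],
        )
        es = epoch_recording(rec)
        assert es.n_epochs == 4

    def test_no_events_errors(self):
        rec = Recording(np.zeros((1, 1000)), 1000.0, ["Cz"])
        with pytest.raises(ValidationError):
            epoch_recording(rec)

    def test_epoch_content_matches_source_samples(self):
        rec = _recording_with_onsets(2)
        es = epoch_recording(rec)
        ev = [e for e in rec.events if e.kind == EventKind.MOTION_ONSET][0]
        np.testing.assert_array_equal(
            es.data[0], rec.data[:, ev.sample_index - 200 : ev.sample_index + 400]
        )


class TestBaseline:
    def test_constant_offset_removed(self):
        es = make_epochs(np.full((2, 3, 600), 7.0), ["a", "b", "c"])
        out = baseline_correct(es)
        np.testing.assert_allclose(out.data, 0.0)

    def test_post_stimulus_shifted_by_baseline_mean(self):
        data = np.zeros((1, 1, 600))
        data[:, :, :200] = 3.0
        data[:, :, 200:] = 10.0
        out = baseline_correct(make_epochs(data, ["a"]))
        np.testing.assert_allclose(out.data[0, 0, 300], 7.0)

    def test_zero_mean_baseline_is_identity(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(3, 2, 600))
        data -= data[:, :, :200].mean(axis=2, keepdims=True)
        out = baseline_correct(make_epochs(data.copy(), ["a", "b"]))
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_double_application_rejected(self):
        es = baseline_correct(make_epochs(np.zeros((1, 1, 600)), ["a"]))
        with pytest.raises(ValidationError):
            baseline_correct(es)


CHANNELS = ["hEOG", "vEOG", "Fp1", "Fp2", "Fz", "Cz"]


class TestRejection:
    def _epochs(self, n=1):
        return np.zeros((n, len(CHANNELS), 600))

    def test_high_sd_window_rejected_with_rule_a(self):
        data = self._epochs()
        data[0, CHANNELS.index("Fp1"), 100:300] = 80.0 * np.sin(np.arange(200))  # SD >> 35
        kept, log = reject_artifacts(make_epochs(data, CHANNELS))
        assert kept.n_epochs == 0
        assert log.loc[0, "rule"] == "sd"
        assert log.loc[0, "channel"] == "Fp1"

    def test_quiet_epoch_kept(self):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 5, size=(10, len(CHANNELS), 600))
        kept, log = reject_artifacts(make_epochs(data, CHANNELS))
        assert kept.n_epochs == 10
        assert log["kept"].all()

    def test_range_rule_on_eeg_channel(self):
        data = self._epochs()
        data[0, CHANNELS.index("Cz"), 250:260] = 120.0  # range 120 > 100 in Cz
        kept, log = reject_artifacts(make_epochs(data, CHANNELS))
        assert kept.n_epochs == 0
        assert log.loc[0, "rule"] == "range"
        assert log.loc[0, "channel"] == "Cz"

    def test_range_rule_ignores_eog(self):
        data = self._epochs()
        data[0, CHANNELS.index("hEOG"), 250:260] = 120.0  # below SD limit, EOG-only range
        crit = RejectionCriteria(sd_threshold=1e9)  # isolate the range rule
        kept, _ = reject_artifacts(make_epochs(data, CHANNELS), crit)
        assert kept.n_epochs == 1

    def test_sd_boundary_is_strict_inequality(self):
        base = np.tile([1.0, -1.0], 100)  # zero-mean alternating block
        sd0 = np.std(base, ddof=1)
        for scale, expect_kept in ((35.0 / sd0 * (1 - 1e-9), True), (35.0 / sd0 * (1 + 1e-6), False)):
            data = self._epochs()
            data[0, CHANNELS.index("Fz"), 0:200] = base * scale
            crit = RejectionCriteria(range_threshold=1e9)  # isolate the SD rule
            kept, _ = reject_artifacts(make_epochs(data, CHANNELS), crit)
            assert (kept.n_epochs == 1) is expect_kept

    def test_windows_are_9_full_200ms_steps(self):
        # an excursion visible only to the final full window must still be seen
        data = self._epochs()
        data[0, CHANNELS.index("Cz"), 560:590] = 150.0
        kept, log = reject_artifacts(make_epochs(data, CHANNELS))
        assert kept.n_epochs == 0
        assert log.loc[0, "window_start_sample"] == 400  # last full window

    def test_rejection_invariant_to_epoch_order(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 20, size=(12, len(CHANNELS), 600))
        es = make_epochs(data, CHANNELS)
        _, log_fwd = reject_artifacts(es)
        perm = rng.permutation(12)
        _, log_perm = reject_artifacts(make_epochs(data[perm], CHANNELS))
        assert (
            log_fwd["kept"].to_numpy()[perm].tolist() == log_perm["kept"].tolist()
        )

    def test_missing_sd_channel_rejected(self):
        es = make_epochs(np.zeros((1, 2, 600)), ["Cz", "Pz"])
        with pytest.raises(ValidationError, match="sd_channels"):
            reject_artifacts(es)

    def test_injected_artifacts_rejected_exactly(self):
        from vectionerp import inject_artifacts

        rng = np.random.default_rng(8)
        data = rng.normal(0, 5, size=(20, len(CHANNELS), 600))
        es = make_epochs(data, CHANNELS)
        noisy, truth = inject_artifacts(es, {"blink": 0.25, "range": 0.15}, seed=9)
        _, log = reject_artifacts(noisy)
        rejected = set(log.loc[~log["kept"], "epoch"])
        assert rejected == set(truth["epoch"])


class TestInclusion:
    def _kept(self, n_coh, n_inc):
        data = np.zeros((n_coh + n_inc, 1, 600))
        conds = ["coherent"] * n_coh + ["incoherent"] * n_inc
        es = make_epochs(data, ["Cz"], conditions=conds)
        es.rejection_applied = True
        return es

    @pytest.mark.parametrize(
        "n_coh,n_inc,expected",
        [(29, 45, False), (50, 50, True), (30, 30, True), (45, 29, False)],
    )
    def test_threshold_semantics(self, n_coh, n_inc, expected):
        included, counts = check_participant_inclusion(self._kept(n_coh, n_inc))
        assert included is expected
        assert counts == {"coherent": n_coh, "incoherent": n_inc}
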