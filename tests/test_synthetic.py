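"""Synthetic cohort generator: templates, noise, artifacts, behavior."""

import numpy as np
import pytest
from scipy import stats

from vectionerp import (
    BehaviorSpec,
    CohortSpec,
    Condition,
    ErpTemplateSpec,
    ValidationError,
    inject_artifacts,
    simulate_behavior,
    simulate_cohort,
    simulate_subject_epochs,
)
from vectionerp.synthetic import planted_electrodes, template_projection

NOISELESS = dict(pink_rms_uv=0.0, white_sd_uv=0.0, subject_scale_sigma=0.0,
                 attenuation_jitter_sd=0.0)


class TestTemplates:
    def test_default_peaks_inside_analysis_windows(self):
        t = ErpTemplateSpec()
        assert 160 <= t.components[0].peak_latency_ms <= 220
        assert 260 <= t.components[1].peak_latency_ms <= 300

    def test_polarity_reversal_between_windows(self, layout):
        t = ErpTemplateSpec()
        times = np.arange(-200.0, 400.0)
        sig = template_projection(t, layout, times)
        cz = layout.index("Cz")
        early = sig[cz, (times >= 160) & (times <= 220)].mean()
        late = sig[cz, (times >= 260) & (times <= 300)].mean()
        assert early < 0 < late

    def test_planted_sets_are_central_and_compact(self, layout):
        t = ErpTemplateSpec()
        for comp in (0, 1):
            members = planted_electrodes(t, layout, comp)
            names = {layout.names[i] for i in members}
            assert "Cz" in names and "CPz" in names
            assert 4 <= len(members) <= 25

    def test_component_latency_outside_epoch_rejected(self):
        from vectionerp.synthetic import ErpComponent

        bad = ErpTemplateSpec(components=(ErpComponent(900.0, 20.0, 1.0),))
        with pytest.raises(ValidationError):
            bad.validate(-200.0, 400.0)


class TestSubjectEpochs:
    def test_zero_noise_epochs_equal_template_projection(self, layout):
        cohort = CohortSpec(trials_per_condition=3, **NOISELESS)
        epochs, params = simulate_subject_epochs(
            ErpTemplateSpec(), cohort, "s01", "right", seed=0, layout=layout
        )
        inc = epochs.select_condition(Condition.INCOHERENT)
        expected = template_projection(ErpTemplateSpec(), layout, epochs.times)
        for e in range(inc.n_epochs):
            np.testing.assert_allclose(inc.data[e, : layout.n], expected, atol=1e-12)

    def test_zero_noise_attenuation_ratio_forced(self, layout):
        template = ErpTemplateSpec()
        cohort = CohortSpec(trials_per_condition=2, condition_attenuation=0.7,
                            group_effect_ratio=1.0, **NOISELESS)
        epochs, _ = simulate_subject_epochs(template, cohort, "s01", "right", 0, layout=layout)
        cz = layout.index("Cz")
        mask = (epochs.times >= 160) & (epochs.times <= 220)
        coh = epochs.select_condition(Condition.COHERENT).data[0, cz, mask].mean()
        inc = epochs.select_condition(Condition.INCOHERENT).data[0, cz, mask].mean()
        assert coh / inc == pytest.approx(0.7, abs=1e-10)

    def test_noisy_average_recovers_template(self, layout):
        # Monte-Carlo consistency of the condition average with the noise model
        cohort = CohortSpec(trials_per_condition=50, subject_scale_sigma=0.0,
                            attenuation_jitter_sd=0.0)
        epochs, _ = simulate_subject_epochs(ErpTemplateSpec(), cohort, "s01", "right", 1,
                                            layout=layout)
        inc = epochs.select_condition(Condition.INCOHERENT)
        expected = template_projection(ErpTemplateSpec(), layout, epochs.times)
        resid = inc.data[:, : layout.n].mean(axis=0) - expected
        per_sample_sd = np.hypot(cohort.pink_rms_uv, cohort.white_sd_uv)
        se = per_sample_sd / np.sqrt(50)
        # pointwise 5-sigma bound (tail-safe over ~40k correlated points) and
        # global RMS agreement with the configured noise level
        assert np.abs(resid).max() < 5 * se
        assert resid.std() == pytest.approx(se, rel=0.5)

    def test_epoch_geometry(self, layout):
        cohort = CohortSpec(trials_per_condition=4, **NOISELESS)
        epochs, _ = simulate_subject_epochs(ErpTemplateSpec(), cohort, "s01", "left", 2,
                                            layout=layout)
        assert epochs.data.shape == (8, layout.n + 2, 600)
        assert epochs.times[0] == -200.0 and epochs.times[-1] == 399.0
        counts = epochs.labels.groupby(["condition", "direction"]).size()
        assert set(counts) == {2}


class TestCohort:
    def test_cohort_sizes_and_labels(self, layout):
        cohort = CohortSpec(n_left=3, n_right=4, trials_per_condition=2, **NOISELESS)
        sc = simulate_cohort(ErpTemplateSpec(), cohort, layout=layout)
        assert len(sc.subjects) == 7
        assert sum(g == "left" for g in sc.groups.values()) == 3
        assert sum(g == "right" for g in sc.groups.values()) == 4

    def test_same_seed_bit_identical(self, layout):
        cohort = CohortSpec(n_left=2, n_right=2, trials_per_condition=3, seed=5)
        a = simulate_cohort(ErpTemplateSpec(), cohort, layout=layout)
        b = simulate_cohort(ErpTemplateSpec(), cohort, layout=layout)
        for s in a.subjects:
            np.testing.assert_array_equal(a.epoch_sets[s].data, b.epoch_sets[s].data)

    def test_group_effect_ratio_one_gives_equal_group_differences(self, layout):
        # left/right subject-level condition differences share a distribution
        cohort = CohortSpec(n_left=20, n_right=20, trials_per_condition=2,
                            group_effect_ratio=1.0, pink_rms_uv=0.0, white_sd_uv=0.0,
                            seed=6)
        sc = simulate_cohort(ErpTemplateSpec(), cohort, layout=layout)
        cz = layout.index("Cz")
        diffs = {"left": [], "right": []}
        for s in sc.subjects:
            es = sc.epoch_sets[s]
            mask = (es.times >= 160) & (es.times <= 220)
            coh = es.select_condition(Condition.COHERENT).data[0, cz, mask].mean()
            inc = es.select_condition(Condition.INCOHERENT).data[0, cz, mask].mean()
            diffs[sc.groups[s]].append(coh - inc)
        _, p = stats.mannwhitneyu(diffs["left"], diffs["right"], alternative="two-sided")
        assert p > 0.01


class TestArtifacts:
    def _clean(self, n=100):
        rng = np.random.default_rng(7)
        from conftest import make_epochs

        channels = ["hEOG", "vEOG", "Fp1", "Fp2", "Fz", "Cz", "Pz"]
        return make_epochs(rng.normal(0, 5, size=(n, len(channels), 600)), channels)

    def test_zero_rates_identity(self):
        es = self._clean(10)
        out, truth = inject_artifacts(es, {"blink": 0.0, "range": 0.0}, seed=0)
        np.testing.assert_array_equal(out.data, es.data)
        assert truth.empty

    def test_blink_windowed_sd_exceeds_35(self):
        es = self._clean(5)
        zero = np.zeros_like(es.data)
        es.data[:] = 0.0
        out, truth = inject_artifacts(es, {"blink": 1.0, "range": 0.0}, seed=1)
        fp1 = es.channel_labels.index("Fp1")
        for e in truth["epoch"]:
            wave = out.data[e, fp1]
            sds = [wave[s : s + 200].std(ddof=1) for s in range(0, 401, 50)]
            assert max(sds) > 35.0
        assert not np.array_equal(out.data, zero)

    def test_range_artifact_exceeds_100uv_peak_to_peak(self):
        es = self._clean(5)
        es.data[:] = 0.0
        out, truth = inject_artifacts(es, {"blink": 0.0, "range": 1.0}, seed=2)
        for e in truth["epoch"]:
            rng_ = out.data[e].max(axis=1) - out.data[e].min(axis=1)
            assert rng_.max() > 100.0

    def test_labeled_count_within_binomial_expectation(self):
        es = self._clean(100)
        _, truth = inject_artifacts(es, {"blink": 0.2, "range": 0.0}, seed=3)
        n = len(truth)
        lo, hi = stats.binom.ppf([0.001, 0.999], 100, 0.2)
        assert lo <= n <= hi

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValidationError):
            inject_artifacts(self._clean(2), {"blink": 1.5}, seed=0)


class TestBehavior:
    def test_zero_presence_prob_gives_no_vection_strength_zero(self):
        import dataclasses

        cb = dataclasses.replace(BehaviorSpec().incoherent, presence_prob=0.0)
        spec = dataclasses.replace(BehaviorSpec(), incoherent=cb)
        trials = simulate_behavior(spec, 50, "incoherent", seed=0)
        assert all(not t.vection_intervals for t in trials)
        assert all(t.strength == 0 for t in trials)

    def test_degenerate_latency_distribution(self):
        import dataclasses

        cb = dataclasses.replace(
            BehaviorSpec().coherent, presence_prob=1.0, latency_median_s=6.0,
            latency_sigma=0.0,
        )
        spec = dataclasses.replace(BehaviorSpec(), coherent=cb)
        trials = simulate_behavior(spec, 20, "coherent", seed=1)
        for t in trials:
            assert t.vection_intervals[0][0] - t.motion_onset_time == pytest.approx(6.0)

    def test_events_stay_inside_trial(self):
        trials = simulate_behavior(BehaviorSpec(), 200, "coherent", seed=2)
        for t in trials:
            for a, b in t.vection_intervals:
                assert a >= t.motion_onset_time
                assert b <= t.motion_onset_time + 30.0 + 1e-9

    def test_coupling_calibration(self):
        # coupling 0.8 between subject score and median strength recovers a
        # Spearman correlation in the configured band at cohort scale
        import dataclasses

        spec = dataclasses.replace(BehaviorSpec(), strength_brain_coupling=0.8)
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(57)
        medians = []
        for i, z in enumerate(scores):
            trials = simulate_behavior(spec, 50, "coherent", subject_score=z, seed=100 + i)
            medians.append(np.median([t.strength for t in trials]))
        rho = stats.spearmanr(scores, medians).statistic
        assert 0.6 <= rho <= 0.95

    def test_determinism(self):
        a = simulate_behavior(BehaviorSpec(), 30, "coherent", 0.5, seed=4)
        b = simulate_behavior(BehaviorSpec(), 30, "coherent", 0.5, seed=4)
        assert a == b
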