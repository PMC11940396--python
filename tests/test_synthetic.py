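"""Generator unit and property tests: IPFM trains, injectors, rendering, cohorts."""

import numpy as np
import pytest
from scipy import signal as sps

import ratafib as rf
from ratafib.synthetic import sample_af_durations


class TestIPFM:
    def test_unmodulated_train_is_exact(self, quiet_params):
        rec = rf.generate_nn_times(quiet_params, 60.0, seed=1)
        assert rec.n_beats == 300
        assert np.allclose(rec.rr_ms(), 200.0, rtol=1e-9)

    def test_zero_duration_gives_empty_series(self, quiet_params):
        rec = rf.generate_nn_times(quiet_params, 0.0, seed=1)
        assert rec.n_beats == 0

    def test_hf_modulation_peaks_at_programmed_frequency(self):
        # oracle: direct Lomb-Scargle periodogram of the generated RR series
        params = rf.AutonomicParams(
            mean_hr=330.0,
            lf_mod_depth=0.0,
            hf_mod_depth=0.1,
            hf_freq=1.5,
            vlf_mod_depth=0.0,
            rr_jitter_cv=0.0,
        )
        rec = rf.generate_nn_times(params, 300.0, seed=2)
        rr, t = rf.rr_series(rec.beat_times)
        freqs = np.arange(0.05, 2.6, 0.005)
        psd = sps.lombscargle(t, rr - rr.mean(), 2 * np.pi * freqs)
        assert abs(freqs[np.argmax(psd)] - 1.5) < 0.05

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_duration_rejected(self, quiet_params, bad):
        with pytest.raises(ValueError):
            rf.generate_nn_times(quiet_params, bad, seed=0)

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            rf.AutonomicParams(mean_hr=float("nan")).validate()

    @pytest.mark.parametrize("seed", range(5))
    def test_beat_times_strictly_increasing(self, study_params, seed):
        rec = rf.generate_nn_times(study_params, 120.0, seed=seed)
        assert np.all(np.diff(rec.beat_times) > 0)

    def test_band_frequencies_validated(self):
        with pytest.raises(ValueError):
            rf.AutonomicParams(lf_freq=0.7).validate()
        with pytest.raises(ValueError):
            rf.AutonomicParams(hf_freq=0.5).validate()


class TestAPBInjection:
    def test_zero_rate_is_identity(self, study_params):
        rec = rf.generate_nn_times(study_params, 60.0, seed=3)
        out = rf.inject_apbs(rec, rf.ArrhythmiaParams(apb_rate=0.0), seed=4)
        assert np.array_equal(out.beat_times, rec.beat_times)
        assert np.array_equal(out.beat_labels, rec.beat_labels)

    def test_coupling_interval_is_prematurity_times_sinus_rr(self, quiet_params):
        rec = rf.generate_nn_times(quiet_params, 60.0, seed=5)
        params = rf.ArrhythmiaParams(apb_rate=60.0, apb_prematurity=0.5)
        out = rf.inject_apbs(rec, params, seed=6)
        apb_idx = np.where(out.beat_labels == rf.APB)[0]
        assert len(apb_idx) > 0
        rr = np.diff(out.beat_times) * 1000.0
        # coupling = 0.5 x 200 ms; compensatory pause restores the next beat
        assert np.allclose(rr[apb_idx - 1], 100.0, atol=1e-6)
        assert np.allclose(rr[apb_idx], 300.0, atol=1e-6)

    def test_poisson_count_calibration(self, quiet_params):
        # 200 injection seeds on one fixed base recording
        rec = rf.generate_nn_times(quiet_params, 3600.0, seed=7)
        params = rf.ArrhythmiaParams(apb_rate=60.0)
        counts = [
            int(np.sum(rf.inject_apbs(rec, params, seed=s).beat_labels == rf.APB))
            for s in range(200)
        ]
        se = np.sqrt(60.0 / 200)
        assert abs(np.mean(counts) - 60.0) < 3 * se

    def test_prematurity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rf.ArrhythmiaParams(apb_prematurity=1.5).validate()


class TestAFInjection:
    def test_zero_rate_is_identity(self, study_params):
        rec = rf.generate_nn_times(study_params, 60.0, seed=8)
        out = rf.inject_af_episodes(rec, rf.ArrhythmiaParams(af_rate=0.0), seed=9)
        assert np.array_equal(out.beat_times, rec.beat_times)

    def test_episode_beats_lack_p_waves(self, af_recording):
        af = af_recording.beat_labels == rf.AF
        assert af.sum() > 0
        assert not af_recording.p_present[af].any()

    def test_every_true_episode_has_three_or_more_beats(self, af_recording):
        eps = [e for e in af_recording.true_episodes if e.type == rf.AF]
        assert len(eps) == 3
        assert all(e.n_beats >= 3 for e in eps)

    def test_duration_sampler_matches_study_statistics(self):
        # stimulation-induced episodes: 123.2 +/- 36.4 s
        params = rf.ArrhythmiaParams(af_rate=1.0)
        rng = np.random.default_rng(10)
        durs = sample_af_durations(params, 50, rng)
        assert abs(np.mean(durs) - 123.2) < 2 * 36.4 / np.sqrt(50)

    def test_invalid_duration_mean_rejected(self, study_params):
        rec = rf.generate_nn_times(study_params, 60.0, seed=11)
        bad = rf.ArrhythmiaParams(af_rate=5.0, af_duration_mean=-1.0)
        with pytest.raises(ValueError):
            rf.inject_af_episodes(rec, bad, seed=12, n_episodes=1)


class TestRendering:
    def test_empty_beat_list_renders_noise_only(self):
        rec = rf.AnnotatedRecording(
            beat_times=np.array([]),
            beat_labels=np.array([], dtype="<U8"),
            p_present=np.array([], dtype=bool),
            p_morph_match=np.array([], dtype=bool),
            duration=2.0,
        )
        wf = rf.render_ecg(rec, fs=1000.0, noise_sd=0.0, seed=1)
        assert np.allclose(wf.samples, 0.0)

    def test_matched_filter_recovers_programmed_beat_times(self, quiet_params):
        rec = rf.generate_nn_times(quiet_params, 2.1, seed=13)
        assert rec.n_beats == 10
        wf = rf.render_ecg(rec, fs=1000.0, noise_sd=0.0, seed=2)
        # oracle: scan with an R-wave template, pick the 10 largest maxima
        tt = np.arange(-0.01, 0.011, 0.001)
        tmpl = np.exp(-0.5 * (tt / 0.004) ** 2)
        score = np.correlate(wf.samples, tmpl, mode="same")
        peaks, _ = sps.find_peaks(score, distance=100)
        best = peaks[np.argsort(score[peaks])[-10:]]
        best = np.sort(best) / wf.fs
        assert np.all(np.abs(best - rec.beat_times) < 0.002)

    def test_af_beats_have_no_p_band_energy(self):
        def p_band_peak(label):
            rec = rf.AnnotatedRecording(
                beat_times=np.array([0.5, 0.62, 0.75, 0.86]),
                beat_labels=np.array([label] * 4, dtype="<U8"),
                p_present=np.full(4, label == "sinus"),
                p_morph_match=np.full(4, label == "sinus"),
                duration=1.5,
            )
            wf = rf.render_ecg(rec, fs=1000.0, noise_sd=0.0, seed=3)
            return np.max(np.abs(wf.samples[500 - 61 : 500 - 19]))

        # no P template is drawn for AF beats: only far QRS tails remain,
        # 3+ orders of magnitude below a rendered sinus P wave
        assert p_band_peak("af") < 1e-3
        assert p_band_peak("sinus") > 0.1

    def test_low_sampling_rate_rejected(self, af_recording):
        with pytest.raises(ValueError):
            rf.render_ecg(af_recording, fs=250.0)


class TestCohort:
    @pytest.fixture(scope="class")
    def small_spec(self):
        return rf.CohortSpec(
            n_control=2,
            n_af=3,
            periods_control=rf.default_period_specs("control", 300.0),
            periods_af=rf.default_period_specs("af", 300.0),
            seed=20,
        )

    def test_control_arm_never_contains_af(self, small_spec):
        cohort = rf.generate_cohort(small_spec)
        for (animal, _), rec in cohort.items():
            if animal.startswith("ctl"):
                assert not np.any(rec.beat_labels == rf.AF)

    def test_af_arm_has_no_af_before_pacing(self, small_spec):
        cohort = rf.generate_cohort(small_spec)
        for (animal, period), rec in cohort.items():
            if animal.startswith("af") and period == "before":
                assert not np.any(rec.beat_labels == rf.AF)

    def test_same_seed_reproduces_bitwise(self, small_spec):
        c1 = rf.generate_cohort(small_spec)
        c2 = rf.generate_cohort(small_spec)
        assert sorted(c1) == sorted(c2)
        for key in c1:
            assert np.array_equal(c1[key].beat_times, c2[key].beat_times)
            assert np.array_equal(c1[key].beat_labels, c2[key].beat_labels)

    def test_af_only_cohort(self):
        spec = rf.CohortSpec(
            n_control=0,
            n_af=2,
            periods_control=rf.default_period_specs("control", 120.0),
            periods_af=rf.default_period_specs("af", 120.0),
            seed=21,
        )
        cohort = rf.generate_cohort(spec)
        assert all(a.startswith("af") for a, _ in cohort)
        assert len(cohort) == 8

    def test_programmed_hr_decline_in_af_arm_defaults(self):
        hrs = [p.autonomic.mean_hr for p in rf.default_period_specs("af")]
        assert hrs[0] > hrs[1] > hrs[2] >= hrs[3]


class TestExpressionAndStimulation:
    def test_expression_gapdh_normalization_recovers_programmed_means(self):
        df = rf.generate_expression_cohort(seed=30)
        hk = df[df.gene == "GAPDH"].set_index("animal")["raw_level"]
        sub = df[(df.gene == "Hcn4") & (df.group == "af")]
        norm = sub["raw_level"].to_numpy() / sub["animal"].map(hk).to_numpy()
        # programmed mean 1.42, between-animal sd 0.02*sqrt(7)
        assert abs(norm.mean() - 1.42) < 3 * 0.02 * np.sqrt(7) / np.sqrt(7)

    def test_stimulation_outcomes_shapes(self):
        proto = rf.StimulationProtocol()
        out = rf.simulate_stimulation(proto, n_animals=3, seed=31)
        assert len(out) == 3
        assert all(len(a["cycle_outcomes"]) == 150 for a in out)
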