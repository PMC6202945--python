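"""Tests for the synthetic cohort generator."""

import dataclasses

import numpy as np
import pytest

from motorbattery import synthgen
from motorbattery.synthgen import CohortConfig, ConfigurationError, GroupParams


def _small_cfg(**kw):
    base = dict(n_per_group=4, sessions_per_subject=2.0, seed=5,
                voice_s=1.0, accel_s=10.0, tap_s=5.0, n_reaction_trials=3)
    base.update(kw)
    return CohortConfig(**base)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        s1, ses1 = synthgen.generate_cohort(_small_cfg())
        s2, ses2 = synthgen.generate_cohort(_small_cfg())
        assert s1.equals(s2)
        assert len(ses1) == len(ses2)
        np.testing.assert_array_equal(ses1[0].voice.samples, ses2[0].voice.samples)
        np.testing.assert_array_equal(ses1[-1].accel["gait"].az,
                                      ses2[-1].accel["gait"].az)
        assert [t.t for t in ses1[0].taps] == [t.t for t in ses2[0].taps]

    def test_subject_table_shape_and_session_mean(self):
        cfg = _small_cfg(n_per_group=10, sessions_per_subject=3.0, seed=7)
        subjects, sessions = synthgen.generate_cohort(cfg)
        assert len(subjects) == 30
        counts = {}
        for s in sessions:
            counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
        assert min(counts.values()) >= 1
        mean_count = np.mean(list(counts.values()))
        assert abs(mean_count - 3.0) <= 1.0  # truncated-Poisson LLN, n=30

    def test_sex_ratio_boundary(self):
        subjects, _ = synthgen.generate_cohort(_small_cfg(sex_ratio=1.0))
        assert (subjects["sex"] == "male").all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_per_group"):
            synthgen.generate_cohort(_small_cfg(n_per_group=1))
        with pytest.raises(ConfigurationError, match="sex_ratio"):
            synthgen.generate_cohort(_small_cfg(sex_ratio=1.5))
        bad = _small_cfg()
        bad.group_params["pd"] = dataclasses.replace(GroupParams(),
                                                     tremor_freq_hz=10.0)
        with pytest.raises(ConfigurationError, match="tremor_freq_hz"):
            synthgen.generate_cohort(bad)

    def test_session_task_times_increasing(self):
        _, sessions = synthgen.generate_cohort(_small_cfg())
        for ses in sessions[:3]:
            times = [ses.task_start_times[t] for t in synthgen.TASK_ORDER]
            assert all(a < b for a, b in zip(times, times[1:]))


class TestSynthVoice:
    def test_noiseless_limit_strictly_periodic(self):
        p = GroupParams(f0_hz=125.0, jitter_frac=0.0, shimmer_frac=0.0,
                        hnr_db=np.inf)
        v = synthgen.synth_voice(p, 2.0, 16000, 0)
        # integer period (128 samples): consecutive cycles identical
        period = 128
        n_cycles = len(v.samples) // period - 1
        cycles = v.samples[: n_cycles * period].reshape(n_cycles, period)
        assert np.abs(cycles[1:] - cycles[:-1]).max() < 1e-9

    def test_nyquist_guard(self):
        p = GroupParams(f0_hz=400.0)
        with pytest.raises(ValueError, match="Nyquist"):
            synthgen.synth_voice(p, 2.0, 3000, 0)

    def test_duration_precondition(self):
        with pytest.raises(ValueError):
            synthgen.synth_voice(GroupParams(), 0.5, 16000, 0)

    def test_hnr_controls_noise(self):
        p_clean = GroupParams(hnr_db=40.0)
        p_noisy = GroupParams(hnr_db=5.0)
        clean = synthgen.synth_voice(p_clean, 2.0, 16000, 1).samples
        noisy = synthgen.synth_voice(p_noisy, 2.0, 16000, 1).samples
        # high-frequency residual energy grows as HNR drops
        assert np.abs(np.diff(noisy)).mean() > np.abs(np.diff(clean)).mean()


class TestSynthAccel:
    def test_unknown_task(self):
        with pytest.raises(ValueError, match="unknown"):
            synthgen.synth_accel("jumping", GroupParams(), 12.0, 100.0, 0)

    def test_duration_precondition(self):
        with pytest.raises(ValueError):
            synthgen.synth_accel("gait", GroupParams(), 5.0, 100.0, 0)

    def test_planted_tremor_peak(self):
        p = GroupParams(tremor_amp_rest_ms2=2.0, tremor_freq_hz=5.0)
        st = synthgen.synth_accel("rest_tremor", p, 20.0, 100.0, 2)
        x = st.ax - st.ax.mean()
        f = np.fft.rfftfreq(len(x), 0.01)
        spec = np.abs(np.fft.rfft(x))
        assert abs(f[np.argmax(spec)] - 5.0) <= 0.2

    def test_zero_tremor_band_at_baseline(self):
        from motorbattery._dsp import band_power, welch_psd
        p0 = GroupParams(tremor_amp_rest_ms2=0.0)
        st = synthgen.synth_accel("rest_tremor", p0, 30.0, 100.0, 3)
        base = synthgen.synth_accel("balance", p0, 30.0, 100.0, 3)
        bands = []
        for s in (st, base):
            f, pxx = welch_psd(s.ax - s.ax.mean(), 100.0)
            bands.append(band_power(f, pxx, 3.0, 8.0))
        assert bands[0] <= bands[1] * 1.5

    def test_gait_cadence_autocorrelation(self):
        from motorbattery._dsp import autocorr_at_lag
        p = GroupParams(cadence_hz=1.8)
        st = synthgen.synth_accel("gait", p, 30.0, 100.0, 4)
        mag = st.magnitude()
        lags = np.arange(int(0.3 * 100), int(0.9 * 100))
        acs = [autocorr_at_lag(mag, int(l)) for l in lags]
        best = lags[int(np.argmax(acs))] / 100.0
        assert abs(best - 1.0 / 1.8) <= 0.05


class TestSynthTaps:
    def test_degenerate_noise_equal_intervals(self):
        p = GroupParams(iti_cv=0.0, iti_drift=0.0, iti_mean_s=0.25)
        taps = synthgen.synth_taps(p, 10.0, 0)
        iti = np.diff([t.t for t in taps])
        np.testing.assert_allclose(iti, 0.25, rtol=1e-12)

    def test_alternating_targets(self):
        taps = synthgen.synth_taps(GroupParams(), 10.0, 1)
        ids = [t.target_id for t in taps]
        assert all(a != b for a, b in zip(ids, ids[1:]))

    def test_negative_drift_detectable(self):
        from scipy import stats
        p = GroupParams(iti_drift=-0.002, iti_cv=0.02, iti_mean_s=0.3)
        taps = synthgen.synth_taps(p, 35.0, 3)
        iti = np.diff([t.t for t in taps])
        assert len(iti) >= 99
        res = stats.linregress(np.arange(len(iti)), iti)
        assert res.slope < 0
        assert res.pvalue < 0.05

    def test_zero_scatter_hits_centers(self):
        p = GroupParams(tap_scatter_px=0.0)
        for tap in synthgen.synth_taps(p, 5.0, 2):
            cx, cy = synthgen.BUTTON_CENTERS[tap.target_id]
            assert (tap.x, tap.y) == (cx, cy)


class TestSynthReactions:
    def test_degenerate_latency(self):
        p = GroupParams(rt_mu_s=0.3, rt_sigma_s=0.0, rt_tau_s=0.0)
        for ev in synthgen.synth_reactions(p, 10, 0):
            assert ev.press_t - ev.stim_on_t == pytest.approx(0.3, abs=1e-12)

    def test_exgaussian_mean(self):
        p = GroupParams(rt_mu_s=0.3, rt_sigma_s=0.02, rt_tau_s=0.1)
        evs = synthgen.synth_reactions(p, 1000, 1)
        lat = np.array([e.press_t - e.stim_on_t for e in evs])
        assert lat.mean() == pytest.approx(0.4, abs=0.02)  # mean = mu + tau

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            synthgen.synth_reactions(GroupParams(), 0, 0)

    def test_event_ordering_invariants(self):
        for ev in synthgen.synth_reactions(GroupParams(), 20, 3):
            assert ev.press_t >= ev.stim_on_t
            assert ev.release_t >= ev.stim_off_t


class TestNullConfiguration:
    def test_groups_identical_params(self):
        cfg = synthgen.make_cohort_config(effect_size=0.0)
        assert cfg.group_params["control"] == cfg.group_params["pd"]
        assert cfg.group_params["control"] == cfg.group_params["irbd"]

    def test_effect_directions(self):
        cfg = synthgen.make_cohort_config(effect_size=1.0)
        c, i, p = (cfg.group_params[g] for g in ("control", "irbd", "pd"))
        for field in ("tremor_amp_rest_ms2", "jitter_frac", "iti_mean_s",
                      "rt_mu_s"):
            assert getattr(c, field) < getattr(i, field) < getattr(p, field)
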