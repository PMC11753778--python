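"""Stimulus generators: construction invariants and design geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcd.stimuli import (
    AMStimSpec,
    ImpulseSeqSpec,
    PeriodicStimSpec,
    StepStimSpec,
    gen_am_pair,
    gen_detection_pair,
    gen_impulse_pair,
    gen_onset_offset_pair,
    gen_periodic_pair,
    gen_step_pair,
    pearson_corr,
)
from mcd.timeseries import TimeSeries

FS = 1000.0


class TestStepPairs:
    def test_off_is_mirror_of_on_about_baseline(self):
        on_v, on_a = gen_step_pair(StepStimSpec(condition="on-on", lag=0.1), FS)
        off_v, off_a = gen_step_pair(StepStimSpec(condition="off-off", lag=0.1), FS)
        np.testing.assert_array_equal(off_v.values, 2 * 1.0 - on_v.values)
        np.testing.assert_array_equal(off_a.values, 2 * 1.0 - on_a.values)

    def test_zero_lag_steps_coincide(self):
        v, a = gen_step_pair(StepStimSpec(condition="on-on", lag=0.0), FS)
        np.testing.assert_array_equal(v.values, a.values)

    def test_lag_moves_audio_step(self):
        v, a = gen_step_pair(StepStimSpec(condition="on-on", lag=0.2), FS)
        i_v = int(np.argmax(np.diff(v.values)))
        i_a = int(np.argmax(np.diff(a.values)))
        assert (i_a - i_v) / FS == pytest.approx(0.2, abs=1 / FS)

    def test_lag_exceeding_duration_errors(self):
        with pytest.raises(ValueError):
            StepStimSpec(lag=2.0)

    def test_unknown_condition_errors(self):
        with pytest.raises(ValueError):
            StepStimSpec(condition="on-maybe")


class TestPeriodicPairs:
    def test_zero_phase_shift_identical_envelopes(self):
        v, a = gen_periodic_pair(PeriodicStimSpec(phase_shift=0.0), FS)
        np.testing.assert_array_equal(v.values, a.values)

    def test_pi_shift_mirrors_about_pedestal(self):
        spec = PeriodicStimSpec(phase_shift=np.pi)
        v, a = gen_periodic_pair(spec, FS)
        # square components anti-phase, shared window: v + a = 2*pedestal
        # (up to the edge samples where the square-wave sign is ambiguous)
        resid = v.values + a.values - 2 * spec.pedestal
        assert np.mean(np.abs(resid) > 1e-12) < 0.01

    def test_three_full_cycles_at_defaults(self):
        spec = PeriodicStimSpec()
        assert spec.total_duration / spec.period == 3
        v, _ = gen_periodic_pair(spec, FS)
        # three cycles = six half-cycle segments = five interior polarity flips
        comp = v.values - spec.pedestal
        mid = comp[np.abs(comp) > 1e-6 * np.max(np.abs(comp))]
        crossings = np.sum(np.diff(np.sign(mid)) != 0)
        assert crossings == 5

    def test_non_integer_cycles_rejected(self):
        with pytest.raises(ValueError):
            PeriodicStimSpec(period=2.0, total_duration=5.0)

    def test_window_starts_and_ends_at_pedestal(self):
        spec = PeriodicStimSpec(phase_shift=1.0)
        v, a = gen_periodic_pair(spec, FS)
        for ts in (v, a):
            assert ts.values[0] == pytest.approx(spec.pedestal)
            assert abs(ts.values[-1] - spec.pedestal) < 1e-4


class TestImpulsePairs:
    def test_event_counts(self):
        v, a = gen_impulse_pair(ImpulseSeqSpec(n_events_v=5, n_events_a=5, duration=1.0, rng_seed=3), FS)
        assert int(v.values.sum()) == 5 and int(a.values.sum()) == 5

    def test_rate_controlled_count(self):
        spec = ImpulseSeqSpec(duration=2.0, rate=14.0, rng_seed=1)
        v, a = gen_impulse_pair(spec, FS)
        assert int(v.values.sum()) == 28 and int(a.values.sum()) == 28

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_seed_reproducibility(self, seed):
        s = ImpulseSeqSpec(rng_seed=seed)
        v1, a1 = gen_impulse_pair(s, FS)
        v2, a2 = gen_impulse_pair(s, FS)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(a1.values, a2.values)

    def test_too_dense_events_error(self):
        with pytest.raises(ValueError):
            gen_impulse_pair(ImpulseSeqSpec(n_events_v=120, duration=1.0), sample_rate=100.0)


class TestOnsetOffsetPairs:
    def test_zero_lag_identical(self):
        v, a = gen_onset_offset_pair(0.0, "onset", sample_rate=FS)
        np.testing.assert_array_equal(v.values, a.values)

    def test_lag_applies_only_to_named_edge(self):
        lag = 0.12
        v, a = gen_onset_offset_pair(lag, "offset", plateau=1.0, sample_rate=FS)
        on_v = int(np.argmax(v.values > 0))
        on_a = int(np.argmax(a.values > 0))
        off_v = len(v) - int(np.argmax(v.values[::-1] > 0))
        off_a = len(a) - int(np.argmax(a.values[::-1] > 0))
        assert on_v == on_a
        assert (off_a - off_v) / FS == pytest.approx(lag, abs=1 / FS)

    def test_plateau_shorter_than_lag_errors(self):
        with pytest.raises(ValueError):
            gen_onset_offset_pair(0.5, "onset", plateau=0.4, sample_rate=FS)


class TestDetectionPairs:
    def test_zero_soa_increments_coincide(self):
        v, a = gen_detection_pair(0.0, sample_rate=FS)
        np.testing.assert_array_equal(v.values > 1.0, a.values > 1.0)

    def test_zero_audio_increment_constant_trace(self):
        _, a = gen_detection_pair(0.1, a_increment=0.0, sample_rate=FS)
        assert np.ptp(a.values) == 0

    def test_negative_increment_errors(self):
        with pytest.raises(ValueError):
            gen_detection_pair(0.0, v_increment=-1.0, sample_rate=FS)


class TestAMPairs:
    def test_matched_frequency_zero_phase_perfectly_correlated(self):
        v, a = gen_am_pair(AMStimSpec(f_v=6.0, f_a=6.0, phase_deg=0.0), FS)
        assert pearson_corr(v, a) == pytest.approx(1.0, abs=1e-12)

    def test_zero_depth_identical_regardless_of_phase(self):
        v, a = gen_am_pair(AMStimSpec(f_a=7.0, phase_deg=135.0, depth_fraction=0.0), FS)
        np.testing.assert_array_equal(v.values, a.values)

    def test_whole_grid_strongly_positively_correlated(self):
        # pedestal and ramps dominate, so even the least correlated
        # frequency/phase cell stays strongly positive
        corrs = []
        for f_a in np.linspace(6.0, 7.0, 5):
            for ph in np.arange(0.0, 360.0, 45.0):
                v, a = gen_am_pair(AMStimSpec(f_a=float(f_a), phase_deg=float(ph)), FS)
                corrs.append(pearson_corr(v, a))
        corrs = np.array(corrs)
        assert corrs.min() > 0.5
        assert corrs.max() == pytest.approx(1.0, abs=1e-9)


class TestPearson:
    def test_identity_and_negation(self):
        x = TimeSeries(np.sin(np.linspace(0, 10, 500)), FS)
        y = x.with_values(2 * x.values.mean() - x.values)
        assert pearson_corr(x, x) == pytest.approx(1.0)
        assert pearson_corr(x, y) == pytest.approx(-1.0)

    def test_orthogonal_sin_cos(self):
        t = np.arange(1000) / 1000.0
        s = TimeSeries(np.sin(2 * np.pi * 3 * t), FS)
        c = TimeSeries(np.cos(2 * np.pi * 3 * t), FS)
        assert abs(pearson_corr(s, c)) < 1e-9

    def test_constant_input_errors(self):
        x = TimeSeries(np.ones(100), FS)
        with pytest.raises(ValueError):
            pearson_corr(x, x)
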