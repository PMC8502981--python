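"""Preprocessing: rescaling, adaptive resampling, onsets, artifacts, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apforecast.dataset import (ResampleConfig, SampledSeries,
                                detect_beat_onsets,
                                reconstruct_stimulus_channel,
                                remove_artifacts_spline, resample,
                                rescale_unit_interval, split_train_test)


def _series(times, voltage, stimulus=None):
    return SampledSeries(np.asarray(times, float), np.asarray(voltage, float),
                         None if stimulus is None
                         else np.asarray(stimulus, float))


@st.composite
def random_series(draw):
    n = draw(st.integers(min_value=2, max_value=200))
    seed = draw(st.integers(min_value=0, max_value=2**16))
    rng = np.random.default_rng(seed)
    times = np.cumsum(rng.uniform(0.05, 5.0, size=n))
    voltage = rng.uniform(0.0, 1.0, size=n)
    return _series(times, voltage)


class TestSampledSeries:
    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            _series([0, 1, 1], [0, 0, 0])  # not strictly increasing
        with pytest.raises(ValueError):
            _series([0, 1], [0, 0, 0])
        with pytest.raises(ValueError):
            _series([0, 1], [0, np.nan])

    def test_csv_roundtrip(self, tmp_path):
        s = _series([0.0, 1.5, 3.0], [0.1, 0.9, 0.2], [0.4, 0.0, 0.0])
        s.meta["model"] = "demo"
        path = tmp_path / "series.csv"
        s.save_csv(path)
        loaded = SampledSeries.load_csv(path)
        np.testing.assert_allclose(loaded.times, s.times)
        np.testing.assert_allclose(loaded.stimulus, s.stimulus)
        assert loaded.meta["model"] == "demo"

    def test_hdf5_roundtrip(self, tmp_path):
        s = _series([0.0, 1.0, 2.0], [0.0, 1.0, 0.5])
        path = tmp_path / "series.h5"
        s.save_hdf5(path)
        loaded = SampledSeries.load_hdf5(path)
        np.testing.assert_array_equal(loaded.voltage, s.voltage)
        assert loaded.stimulus is None


class TestRescale:
    def test_affine_map_from_physical_units(self):
        s = _series([0, 1, 2], [-80.0, 40.0, -20.0])
        out, amap = rescale_unit_interval(s)
        assert out.voltage.min() == 0.0
        assert out.voltage.max() == 1.0
        np.testing.assert_allclose(amap(np.array([-80.0, 40.0])), [0.0, 1.0])

    def test_roundtrip_inverse(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        s = _series(np.arange(50), v)
        out, amap = rescale_unit_interval(s)
        np.testing.assert_allclose(amap.inverse(out.voltage), v, atol=1e-12)

    def test_prescaled_passthrough_and_constant_rejection(self):
        s = _series([0, 1], [0.2, 0.8])
        out, amap = rescale_unit_interval(s, assume_scaled=True)
        np.testing.assert_array_equal(out.voltage, s.voltage)
        assert (amap.scale, amap.offset) == (1.0, 0.0)
        with pytest.raises(ValueError):
            rescale_unit_interval(_series([0, 1], [0.5, 0.5]))


class TestResample:
    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        s = _series(np.arange(100) * 0.7, rng.uniform(size=100))
        out = resample(s, ResampleConfig(0.0, 20.0))
        np.testing.assert_array_equal(out.times, s.times)
        np.testing.assert_array_equal(out.voltage, s.voltage)

    def test_constant_voltage_keeps_time_rule_only(self):
        s = _series(np.arange(0, 500, 1.0), np.zeros(500))
        out = resample(s, ResampleConfig(0.1, 50.0))
        gaps = np.diff(out.times)
        assert np.all(gaps == 51.0)  # first gap strictly exceeding 50 ms

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(random_series(),
           st.floats(min_value=0, max_value=0.5),
           st.floats(min_value=0.5, max_value=50))
    def test_kept_pairs_satisfy_rule_and_are_input_points(self, s, dv, dtm):
        out = resample(s, ResampleConfig(dv, dtm))
        # every kept sample is an input sample (no interpolation)
        assert set(out.times) <= set(s.times)
        for i in range(1, len(out)):
            ok_v = abs(out.voltage[i] - out.voltage[i - 1]) >= dv
            ok_t = out.times[i] - out.times[i - 1] > dtm
            assert ok_v or ok_t

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(random_series(), st.floats(min_value=0, max_value=0.5))
    def test_idempotent(self, s, dv):
        cfg = ResampleConfig(dv, 10.0)
        once = resample(s, cfg)
        twice = resample(once, cfg)
        np.testing.assert_array_equal(once.times, twice.times)

    def test_output_size_monotone_in_dv_threshold(self):
        rng = np.random.default_rng(2)
        s = _series(np.arange(300) * 0.5, rng.uniform(size=300))
        sizes = [len(resample(s, ResampleConfig(dv, 25.0)))
                 for dv in (0.0, 0.05, 0.1, 0.2, 0.4)]
        assert sizes == sorted(sizes, reverse=True)


class TestBeatOnsets:
    def test_fk_onsets_follow_stimuli(self, fk_series_slow):
        series, protocol = fk_series_slow
        onsets = detect_beat_onsets(series)
        assert len(onsets) == len(protocol.pulse_times)
        delays = onsets - protocol.pulse_times
        assert np.all(delays > 0)
        assert np.all(delays < 10.0)

    def test_flat_series_has_no_onsets(self):
        s = _series(np.arange(100.0), np.zeros(100))
        assert len(detect_beat_onsets(s)) == 0

    def test_single_triangular_pulse(self):
        t = np.arange(0, 100.0)
        v = np.interp(t, [0, 50, 99], [0, 1, 0])
        onsets = detect_beat_onsets(_series(t, v))
        assert len(onsets) == 1

    def test_lockout_suppresses_chatter(self):
        t = np.arange(0, 40.0, 0.5)
        v = 0.15 + 0.02 * np.sin(t)  # oscillates around threshold
        onsets = detect_beat_onsets(_series(t, v), 0.15, lockout_ms=50.0)
        assert len(onsets) == 1


class TestStimulusReconstruction:
    def test_uniform_grid_pulse_width(self):
        grid = np.arange(0, 200, 0.1)
        stim = reconstruct_stimulus_channel(np.array([100.0]), grid)
        assert np.sum(stim == 0.2) == 20  # 2 ms at 0.1 ms spacing
        assert stim[(grid < 100) | (grid >= 102)].max() == 0.0

    def test_empty_onsets_zero_channel(self):
        stim = reconstruct_stimulus_channel(np.array([]), np.arange(10.0))
        assert np.all(stim == 0)

    def test_missed_pulse_on_sparse_grid_warns(self):
        grid = np.array([0.0, 50.0, 99.0, 103.0, 150.0])
        with pytest.warns(UserWarning):
            stim = reconstruct_stimulus_channel(np.array([100.0]), grid)
        assert np.all(stim == 0)

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_stimulus_channel(np.array([10.0, 11.0]),
                                         np.arange(20.0))

    def test_onset_redetection_roundtrip(self, fk_series_slow):
        series, protocol = fk_series_slow
        onsets = detect_beat_onsets(series)
        stim = reconstruct_stimulus_channel(onsets, series.times)
        starts = series.times[np.nonzero(np.diff((stim > 0).astype(int)) == 1)[0] + 1]
        dt = series.meta["dt"]
        assert np.all(np.abs(starts - onsets) <= dt + 1e-9)


class TestArtifactRemoval:
    def test_empty_window_list_is_identity(self):
        s = _series(np.arange(10.0), np.arange(10.0) ** 2)
        out = remove_artifacts_spline(s, [])
        np.testing.assert_array_equal(out.voltage, s.voltage)

    def test_spike_removed_to_within_one_percent(self):
        t = np.arange(0, 100, 0.25)
        clean = np.sin(2 * np.pi * t / 40.0)
        dirty = clean.copy()
        spike = (t >= 50) & (t <= 52)
        dirty[spike] += 5.0
        out = remove_artifacts_spline(_series(t, dirty), [(49.5, 52.5)])
        assert np.max(np.abs(out.voltage - clean)) < 0.01

    def test_window_order_irrelevant(self):
        rng = np.random.default_rng(3)
        s = _series(np.arange(100.0), rng.uniform(size=100))
        a = remove_artifacts_spline(s, [(10, 15), (60, 65)])
        b = remove_artifacts_spline(s, [(60, 65), (10, 15)])
        np.testing.assert_array_equal(a.voltage, b.voltage)

    def test_boundary_window_rejected(self):
        s = _series(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            remove_artifacts_spline(s, [(0.0, 2.0)])


class TestSplit:
    def _beaty_series(self, n_beats, per_beat=20):
        t = np.arange(n_beats * per_beat, dtype=float)
        v = np.tile(np.r_[np.linspace(0, 1, 5), np.linspace(1, 0, 15)],
                    n_beats)
        return _series(t, v), np.arange(n_beats) * float(per_beat)

    def test_partition_arithmetic(self):
        s, onsets = self._beaty_series(100)
        split = split_train_test(s, onsets, 10, 70)
        assert split.n_test_beats == 20
        assert len(split.pre_train) + len(split.train) + len(split.test) == len(s)

    def test_concatenation_recovers_series(self):
        s, onsets = self._beaty_series(30)
        split = split_train_test(s, onsets, 5, 20)
        full = split.full
        np.testing.assert_array_equal(full.times, s.times)
        np.testing.assert_array_equal(full.voltage, s.voltage)

    def test_insufficient_beats_error(self):
        s, onsets = self._beaty_series(10)
        with pytest.raises(ValueError):
            split_train_test(s, onsets, 5, 5)
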