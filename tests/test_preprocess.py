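import numpy as np
import pytest
from dataclasses import replace

import insolegait as ig
from insolegait.preprocess import (
    DEFAULT_T,
    FlattenedStep,
    NormalizedStep,
    UnitStep,
    assemble_samples,
    detect_phase_boundaries,
    flatten_step,
    normalize_step,
    reduce_swing_noise,
    segment_unit_steps,
    stack_samples,
    standardize,
    unflatten_step,
)
from insolegait.records import GaitType
from insolegait.simulate import truth_annotation

from conftest import left_pressure_from_sums


class TestPhaseDetection:
    def test_all_zero_pressure_has_one_swing_and_no_stance(self):
        ann = detect_phase_boundaries(np.zeros((20, 16), dtype=int))
        assert ann.swing_starts == [0]
        assert ann.stance_starts == []

    def test_hand_traced_mid_recording_swing(self):
        # left-foot sums 3,2,0,0,0,0,2,3 with >=2 active channels when non-zero
        pressure = left_pressure_from_sums([3, 2, 0, 0, 0, 0, 2, 3])
        ann = detect_phase_boundaries(pressure)
        assert ann.swing_starts == [2]
        assert ann.stance_starts == [6]

    def test_hand_traced_two_cycles_starting_in_swing(self):
        pressure = left_pressure_from_sums([0, 0, 2, 2, 0, 0, 3, 3])
        ann = detect_phase_boundaries(pressure)
        assert ann.swing_starts == [0, 4]
        assert ann.stance_starts == [2, 6]
        assert ann.is_alternating()

    def test_single_active_sensor_does_not_start_stance(self):
        # one channel at 2 is loaded, but heel strike needs >= 2 sensors
        pressure = left_pressure_from_sums([0, 0, 2, 2], n_active=[0, 0, 1, 2])
        ann = detect_phase_boundaries(pressure)
        assert ann.stance_starts == [3]


class TestNoiseReduction:
    def test_sum_one_frame_inside_swing_is_zeroed(self):
        # swing sums [0,0,1,0] then stance: channel 3 reads 1 mid-swing
        pressure = left_pressure_from_sums([2, 2, 0, 0, 0, 0, 2, 2])
        pressure[3, 3] = 1
        ann = detect_phase_boundaries(pressure)
        cleaned, corrections = reduce_swing_noise(pressure, ann)
        assert corrections == 1
        assert cleaned[3, 3] == 0
        untouched = np.delete(np.arange(8), 3)
        assert np.array_equal(cleaned[untouched], pressure[untouched])

    def test_noise_free_input_is_returned_unchanged(self):
        pressure = left_pressure_from_sums([0, 0, 2, 2, 0, 0, 3, 3])
        cleaned, corrections = reduce_swing_noise(pressure, detect_phase_boundaries(pressure))
        assert corrections == 0
        assert np.array_equal(cleaned, pressure)

    def test_sum_two_swing_frame_is_left_alone(self):
        # a lone sensor at level 2 has sum 2: the rule fires only on sum == 1
        pressure = left_pressure_from_sums(
            [2, 2, 0, 2, 0, 0, 2, 2], n_active=[2, 2, 0, 1, 0, 0, 2, 2]
        )
        ann = detect_phase_boundaries(pressure)
        cleaned, corrections = reduce_swing_noise(pressure, ann)
        assert corrections == 0
        assert np.array_equal(cleaned, pressure)

    def test_cleaning_repairs_split_swing(self):
        # noise splits one swing into two zero-runs; after cleaning the
        # re-detected annotation has a single swing start for that cycle
        pressure = left_pressure_from_sums([2, 2, 0, 0, 1, 0, 0, 2, 2, 0, 0])
        noisy_ann = detect_phase_boundaries(pressure)
        assert len(noisy_ann.swing_starts) > 2  # the double-swing error
        cleaned, corrections = reduce_swing_noise(pressure, noisy_ann)
        assert corrections == 1
        ann = detect_phase_boundaries(cleaned)
        assert ann.swing_starts == [2, 9]
        assert ann.stance_starts == [7]


class TestSegmentation:
    def test_recovers_ground_truth_on_clean_recording(self, walking_recording):
        rec, truth = walking_recording
        steps = segment_unit_steps(rec)
        assert [(s.start, s.end) for s in steps] == truth.step_intervals
        assert all(s.label is rec.label for s in steps)

    def test_recovers_ground_truth_with_default_artifacts(self, sim_config):
        for label in ig.GaitType:
            rec, truth = ig.simulate_recording(sim_config, label, 12, seed=17 + label)
            steps = segment_unit_steps(rec)
            assert [(s.start, s.end) for s in steps] == truth.step_intervals

    def test_idempotent_on_cleaned_pressure(self, sim_config):
        rec, _ = ig.simulate_recording(sim_config, ig.GaitType.RUNNING, 8, seed=5)
        cleaned, _ = reduce_swing_noise(rec.pressure, detect_phase_boundaries(rec.pressure))
        rec2 = ig.SensorRecording(cleaned, rec.accel, rec.gyro, rec.label)
        first = [(s.start, s.end) for s in segment_unit_steps(rec)]
        second = [(s.start, s.end) for s in segment_unit_steps(rec2)]
        assert first == second

    def test_frames_are_conserved_and_disjoint(self, walking_recording):
        rec, _ = walking_recording
        steps = segment_unit_steps(rec)
        spans = [(s.start, s.end) for s in steps]
        assert all(b == c for (_, b), (c, _) in zip(spans, spans[1:]))
        total = sum(b - a for a, b in spans)
        assert total == spans[-1][1] - spans[0][0]

    def test_no_complete_step_yields_empty_list(self):
        rec = ig.SensorRecording(
            pressure=np.zeros((30, 16), dtype=int),
            accel=np.zeros((30, 6)),
            gyro=np.zeros((30, 6)),
            label=GaitType.WALKING,
        )
        assert segment_unit_steps(rec) == []

    def test_truncated_final_stance_is_dropped(self, sim_config):
        rec, truth = ig.simulate_recording(
            replace(sim_config, artifact_prob=0.0), ig.GaitType.WALKING, 5, seed=9
        )
        cut = truth.step_intervals[-1][1] - 3  # mid-stance of the last step
        rec2 = ig.SensorRecording(
            rec.pressure[:cut], rec.accel[:cut], rec.gyro[:cut], rec.label
        )
        steps = segment_unit_steps(rec2)
        assert [(s.start, s.end) for s in steps] == truth.step_intervals[:-1]


def _step_from_arrays(pressure, accel=None, gyro=None):
    L = pressure.shape[0]
    accel = np.zeros((L, 6)) if accel is None else accel
    gyro = np.zeros((L, 6)) if gyro is None else gyro
    return UnitStep(pressure, accel, gyro, GaitType.WALKING, 0, L)


class TestNormalization:
    def test_identity_when_length_already_matches(self):
        rng = np.random.default_rng(0)
        step = _step_from_arrays(
            rng.integers(0, 3, (63, 16)), rng.normal(size=(63, 6)), rng.normal(size=(63, 6))
        )
        out = normalize_step(step, t=63)
        assert np.array_equal(out.pressure, step.pressure)
        assert np.allclose(out.accel, step.accel)

    def test_output_shapes_and_value_domain(self):
        rng = np.random.default_rng(1)
        step = _step_from_arrays(
            rng.integers(0, 3, (126, 16)), rng.normal(size=(126, 6)), rng.normal(size=(126, 6))
        )
        out = normalize_step(step, t=63)
        assert out.pressure.shape == (63, 16)
        assert out.accel.shape == (63, 6) and out.gyro.shape == (63, 6)
        assert set(np.unique(out.pressure)) <= {0, 1, 2}

    @pytest.mark.parametrize("L", [2, 17, 63, 200])
    def test_constant_channels_stay_constant(self, L):
        step = _step_from_arrays(
            np.full((L, 16), 2, dtype=int), np.full((L, 6), 3.5), np.full((L, 6), -1.25)
        )
        out = normalize_step(step, t=63)
        assert np.all(out.pressure == 2)
        assert np.allclose(out.accel, 3.5) and np.allclose(out.gyro, -1.25)

    def test_degenerate_single_frame_step_is_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_step(_step_from_arrays(np.zeros((1, 16), dtype=int)), t=63)


class TestFlattening:
    def test_lengths_at_default_t(self):
        rng = np.random.default_rng(2)
        step = NormalizedStep(
            rng.integers(0, 3, (DEFAULT_T, 16)), rng.normal(size=(DEFAULT_T, 6)),
            rng.normal(size=(DEFAULT_T, 6)), GaitType.WALKING, DEFAULT_T,
        )
        flat = flatten_step(step)
        assert len(flat.pressure_vec) == 1008
        assert len(flat.accel_vec) == 378
        assert len(flat.gyro_vec) == 378

    def test_time_major_ordering_and_invertibility(self):
        rng = np.random.default_rng(3)
        step = NormalizedStep(
            rng.integers(0, 3, (5, 16)), rng.normal(size=(5, 6)),
            rng.normal(size=(5, 6)), GaitType.RUNNING, 5,
        )
        flat = flatten_step(step)
        assert np.array_equal(flat.pressure_vec[:16], step.pressure[0])
        back = unflatten_step(flat, t=5)
        assert np.array_equal(back.pressure, step.pressure)
        assert np.allclose(back.accel, step.accel)
        assert np.allclose(back.gyro, step.gyro)


class TestAssembly:
    @pytest.mark.parametrize("n_steps,k,expected", [(10, 2, 5), (10, 3, 3), (10, 1, 10)])
    def test_window_counts_drop_remainders(self, n_steps, k, expected):
        rng = np.random.default_rng(4)
        steps = [
            NormalizedStep(
                rng.integers(0, 3, (7, 16)), rng.normal(size=(7, 6)),
                rng.normal(size=(7, 6)), GaitType.WALKING, 7,
            )
            for _ in range(n_steps)
        ]
        samples = assemble_samples(steps, k)
        assert len(samples) == expected
        assert samples[0].arrays["pressure"].shape == (7 * k, 16)

    def test_k3_t63_pressure_sample_is_189_by_16(self, small_samples):
        steps = [
            NormalizedStep(
                np.zeros((63, 16), dtype=int), np.zeros((63, 6)), np.zeros((63, 6)),
                GaitType.WALKING, 63,
            )
            for _ in range(3)
        ]
        (sample,) = assemble_samples(steps, 3)
        assert sample.arrays["pressure"].shape == (189, 16)
        assert sample.arrays["accel"].shape == (189, 6)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            assemble_samples([], 0)


class TestStandardization:
    def test_train_features_zero_mean_unit_variance(self, small_samples):
        train = small_samples[:100]
        std_train, _, _ = standardize(train, [])
        X, _ = stack_samples(std_train)
        for arr in X.values():
            mean = arr.mean(axis=0)
            var = arr.var(axis=0)
            assert np.all(np.abs(mean) < 1e-9)
            assert np.all((np.abs(var - 1) < 1e-6) | (var == 0))

    def test_test_set_uses_train_statistics(self, small_samples):
        train = small_samples[:50]
        shifted = [
            replace(s, arrays={m: a + 5.0 for m, a in s.arrays.items()}) for s in train
        ]
        _, std_shifted, scaler = standardize(train, shifted)
        X, _ = stack_samples(std_shifted)
        # identical data shifted by a constant must not re-center to zero
        nonzero_var = scaler.var["accel"] > 0
        assert np.abs(X["accel"].mean(axis=0)[nonzero_var]).min() > 0.1

    def test_single_sample_train_maps_to_all_zero(self, small_samples):
        std_train, _, _ = standardize(small_samples[:1], [])
        X, _ = stack_samples(std_train)
        assert all(np.all(a == 0) for a in X.values())

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            standardize([], [])


class TestNoiseInjectionRoundTrip:
    @pytest.mark.parametrize("p", [0.05, 0.3, 1.0])
    def test_reduce_inverts_inject_exactly(self, sim_config, p):
        clean_cfg = replace(sim_config, artifact_prob=0.0)
        rec, truth = ig.simulate_recording(clean_cfg, ig.GaitType.FAST_WALKING, 10, seed=21)
        noisy, injected = ig.inject_swing_noise(rec, truth, p=p, channel=2, seed=8)
        if p > 0:
            assert injected > 0
        cleaned, corrections = reduce_swing_noise(noisy.pressure, truth_annotation(truth))
        assert corrections == injected
        assert np.array_equal(cleaned, rec.pressure)

    def test_p_zero_is_identity(self, sim_config):
        clean_cfg = replace(sim_config, artifact_prob=0.0)
        rec, truth = ig.simulate_recording(clean_cfg, ig.GaitType.WALKING, 6, seed=2)
        noisy, injected = ig.inject_swing_noise(rec, truth, p=0.0, channel=2, seed=8)
        assert injected == 0
        assert noisy.equals(rec)

    def test_p_one_saturates_swing_interiors(self, sim_config):
        clean_cfg = replace(sim_config, artifact_prob=0.0)
        rec, truth = ig.simulate_recording(clean_cfg, ig.GaitType.WALKING, 6, seed=2)
        noisy, injected = ig.inject_swing_noise(rec, truth, p=1.0, channel=2, seed=8)
        sums = noisy.pressure[:, :8].sum(axis=1)
        n_interior = 0
        for ss, st in zip(truth.swing_starts, truth.stance_starts):
            assert np.all(sums[ss + 1 : st] == 1)
            n_interior += st - ss - 1
        assert injected == n_interior
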