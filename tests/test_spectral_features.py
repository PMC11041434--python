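"""Segmentation, detrending, spectra (vs brute-force DFT), and subsetting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gripscreen import recording_io as rio
from gripscreen import spectral_features as sf
from gripscreen.errors import DesignError, InsufficientLengthError, SchemaError


def brute_force_dft_magnitudes(x):
    """O(n^2) DFT magnitude oracle, independent of any FFT routine."""
    n = x.size
    t = np.arange(n)
    out = np.empty(n)
    for k in range(n):
        re = np.sum(x * np.cos(-2 * np.pi * k * t / n))
        im = np.sum(x * np.sin(-2 * np.pi * k * t / n))
        out[k] = np.hypot(re, im)
    return out


class TestPlanSegments:
    def test_minimum_length_gives_fully_overlapping_plan(self):
        plan = sf.plan_segments(64)
        assert plan.offsets == (0,) * 15

    def test_even_stride_at_120_frames(self):
        plan = sf.plan_segments(120)
        assert plan.offsets == tuple(range(0, 57, 4))

    def test_too_short_raises(self):
        with pytest.raises(InsufficientLengthError):
            sf.plan_segments(63)

    @pytest.mark.parametrize("T", [64, 65, 100, 507, 64 * 15, 2000])
    def test_offsets_cover_whole_recording(self, T):
        plan = sf.plan_segments(T)
        offsets = np.asarray(plan.offsets)
        assert offsets[0] == 0
        assert offsets[-1] == T - 64
        assert np.all(np.diff(offsets) >= 0)
        assert np.all(offsets + 64 <= T)


class TestDetrendSegment:
    @given(st.floats(-100, 100), st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_input_annihilated(self, a, b):
        t = np.arange(64, dtype=float)
        residual = sf.detrend_segment(a + b * t)
        np.testing.assert_allclose(residual, 0.0, atol=1e-9)

    def test_residual_orthogonal_to_affine_regressors(self):
        rng = np.random.default_rng(4)
        t = np.arange(64, dtype=float)
        for _ in range(10):
            r = sf.detrend_segment(rng.normal(size=64))
            assert abs(r.sum()) < 1e-9 * 64
            assert abs(r @ t) < 1e-7 * 64

    def test_matches_explicit_normal_equations(self):
        t = np.arange(64, dtype=float)
        x = np.sin(2 * np.pi * t / 64)
        design = np.column_stack([np.ones(64), t])
        beta = np.linalg.solve(design.T @ design, design.T @ x)
        np.testing.assert_allclose(sf.detrend_segment(x), x - design @ beta,
                                   atol=1e-12)


class TestSegmentSpectrum:
    def test_zero_segment_gives_16_zeros(self):
        out = sf.segment_spectrum(np.zeros(64))
        assert out.shape == (16,)
        np.testing.assert_array_equal(out, 0.0)

    def test_output_is_16_nonnegative_values(self):
        rng = np.random.default_rng(5)
        out = sf.segment_spectrum(rng.normal(size=64))
        assert out.shape == (16,)
        assert np.all(out >= 0)

    def test_three_cycle_cosine_peaks_at_bin_three(self):
        t = np.arange(64)
        out = sf.segment_spectrum(np.cos(2 * np.pi * 3 * t / 64))
        assert np.argmax(out) == 3

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            seg = rng.normal(size=64)
            expected = brute_force_dft_magnitudes(seg * sf.WINDOW)[:16]
            got = sf.segment_spectrum(seg)
            np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-9)

    def test_window_is_symmetric_hanning(self):
        t = np.arange(64)
        np.testing.assert_allclose(sf.WINDOW,
                                   0.5 * (1 - np.cos(2 * np.pi * t / 63)),
                                   atol=1e-15)

    def test_parseval_identity_under_unnormalized_dft(self):
        rng = np.random.default_rng(7)
        x = sf.detrend_segment(rng.normal(size=64))
        windowed = x * sf.WINDOW
        full = np.fft.fft(windowed)
        assert np.sum(np.abs(full) ** 2) == pytest.approx(
            64 * np.sum(windowed ** 2), rel=1e-12)
        # the exported bins are the head of that same spectrum
        np.testing.assert_allclose(sf.segment_spectrum(x),
                                   np.abs(full[:16]), rtol=1e-9)

    def test_dialect_without_dc_shifts_bins(self):
        t = np.arange(64)
        x = np.cos(2 * np.pi * 3 * t / 64)
        shifted = sf.segment_spectrum(x, sf.FeatureOptions(include_dc=False))
        assert np.argmax(shifted) == 2  # bin 3 now sits at position 2
        power = sf.segment_spectrum(x, sf.FeatureOptions(power=True))
        np.testing.assert_allclose(power, sf.segment_spectrum(x) ** 2,
                                   rtol=1e-12)


class TestFeaturizeTrial:
    @pytest.mark.parametrize("T", [64, 200, 507])
    def test_dimension_is_54960_independent_of_length(self, control_recording, T):
        frames = control_recording.frames[:T]
        rec = rio.Recording("p", "control", "right", 1, frames)
        fv = sf.featurize_trial(rec)
        assert fv.values.shape == (54960,)
        assert np.all(np.isfinite(fv.values))
        assert np.all(fv.values >= 0)

    def test_affine_drift_on_one_channel_leaves_features_unchanged(
            self, control_recording):
        fv = sf.featurize_trial(control_recording)
        frames = control_recording.frames.copy()
        t = np.arange(frames.shape[0])
        frames[:, 17] += 3.0 - 0.25 * t
        drifted = rio.Recording("p", "control", "right", 1, frames)
        fv2 = sf.featurize_trial(drifted)
        np.testing.assert_allclose(fv2.values, fv.values, atol=1e-9)

    def test_scale_covariance_is_channel_local(self, control_recording):
        fv = sf.featurize_trial(control_recording)
        frames = control_recording.frames.copy()
        frames[:, 40] *= -2.5
        scaled = sf.featurize_trial(
            rio.Recording("p", "control", "right", 1, frames))
        block = slice(40 * 240, 41 * 240)
        np.testing.assert_allclose(scaled.values[block],
                                   2.5 * fv.values[block], rtol=1e-9)
        mask = np.ones(54960, bool)
        mask[block] = False
        np.testing.assert_array_equal(scaled.values[mask], fv.values[mask])

    def test_index_mapping_is_a_bijection(self):
        seen = set()
        for p in (0, 1, 100, 228):
            for s in range(15):
                for b in range(16):
                    pos = sf.feature_position(p, s, b)
                    assert sf.feature_triple(pos) == (p, s, b)
                    seen.add(pos)
        assert len(seen) == 4 * 15 * 16
        with pytest.raises(IndexError):
            sf.feature_position(229, 0, 0)
        with pytest.raises(IndexError):
            sf.feature_triple(54960)

    def test_feature_layout_matches_index_map(self, control_recording):
        fv = sf.featurize_trial(control_recording)
        plan = sf.plan_segments(control_recording.n_frames)
        p, s = 33, 7
        seg = control_recording.frames[plan.offsets[s]:plan.offsets[s] + 64, p]
        expected = sf.segment_spectrum(sf.detrend_segment(seg))
        got = fv.values[[sf.feature_position(p, s, b) for b in range(16)]]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_short_recording_propagates_length_error(self):
        rec = rio.Recording("p", "control", "right", 1, np.zeros((63, 229)))
        with pytest.raises(Exception):
            sf.featurize_trial(rec)


def _fv(pid, side, trial, fill, group="CM"):
    return sf.FeatureVector(values=np.full(54960, float(fill)),
                            participant_id=pid, group=group, side=side,
                            trial=trial)


class TestCombineTrials:
    def test_hand_level_combination_length(self):
        sample = sf.combine_trials([_fv("p", "right", 1, 1),
                                    _fv("p", "right", 2, 2)], "CM_nonCM")
        assert sample.values.shape == (109920,)
        assert sample.values[0] == 1 and sample.values[-1] == 2

    def test_participant_level_combination_length_and_order(self):
        vs = [_fv("p", "left", 2, 4), _fv("p", "right", 1, 1),
              _fv("p", "left", 1, 3), _fv("p", "right", 2, 2)]
        sample = sf.combine_trials(vs, "CM_control")
        assert sample.values.shape == (219840,)
        blocks = sample.values.reshape(4, -1)[:, 0]
        np.testing.assert_array_equal(blocks, [1, 2, 3, 4])
        assert sample.sides == ("right", "right", "left", "left")
        assert sample.trials == (1, 2, 1, 2)

    def test_mixed_participants_rejected(self):
        with pytest.raises(DesignError, match="participants"):
            sf.combine_trials([_fv("p", "right", 1, 0),
                               _fv("q", "right", 2, 0)], "CM_nonCM")

    def test_wrong_trial_structure_rejected(self):
        with pytest.raises(DesignError):
            sf.combine_trials([_fv("p", "right", 1, 0),
                               _fv("p", "left", 2, 0)], "CM_nonCM")
        with pytest.raises(DesignError):
            sf.combine_trials([_fv("p", "right", 1, 0),
                               _fv("p", "right", 2, 0)], "CM_control")


class TestBoneFeatureSubset:
    def test_single_bone_subset_has_2160_features(self):
        fv = _fv("p", "right", 1, 0)
        sub = sf.bone_feature_subset(fv, "index", "proximal_phalanx")
        assert sub.shape == (2160,)

    def test_bone_subsets_partition_bone_typed_features(self):
        all_idx = [sf.bone_feature_indices(f, b) for f, b in sf.all_bones()]
        union = np.concatenate(all_idx)
        assert len(all_idx) == 20
        assert union.size == 20 * 2160
        assert np.unique(union).size == union.size  # pairwise disjoint
        covered_params = {sf.feature_triple(i)[0] for i in union}
        bone_typed = {d.index for d in rio.parameter_schema()
                      if d.category in rio.BONE_CATEGORIES}
        assert covered_params == bone_typed
        assert len(bone_typed) == 180

    def test_thumb_request_resolves_via_display_alias(self):
        idx = sf.bone_feature_indices("thumb", "middle_phalanx")
        params = sorted({sf.feature_triple(i)[0] for i in idx})
        schema = rio.parameter_schema()
        assert all(schema[p].finger == "thumb" and
                   schema[p].bone == "proximal_phalanx" for p in params)

    def test_unknown_bone_rejected(self):
        with pytest.raises(SchemaError):
            sf.bone_feature_indices("index", "carpal")

    def test_sample_vector_subset_is_blockwise(self):
        a = _fv("p", "right", 1, 0)
        b = _fv("p", "right", 2, 0)
        a.values[sf.bone_feature_indices("ring", "metacarpus")] = 5.0
        b.values[sf.bone_feature_indices("ring", "metacarpus")] = 7.0
        sample = sf.combine_trials([a, b], "CM_nonCM")
        sub = sf.bone_feature_subset(sample, "ring", "metacarpus")
        assert sub.shape == (2 * 2160,)
        np.testing.assert_array_equal(sub[:2160], 5.0)
        np.testing.assert_array_equal(sub[2160:], 7.0)
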