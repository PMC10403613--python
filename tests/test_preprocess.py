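"""Frame-zero division, blank subtraction, averaging, artifact masking."""

import numpy as np
import pytest

from vsdpop.core import AcquisitionSpec, StimulusSpec, TrialStack
from vsdpop.preprocess import (average_trials, blank_subtract,
                               frame_zero_divide, mask_bleached_pixels,
                               mask_stimulation_frames, preprocess_session)
from vsdpop.synth import ArtifactModel, ResponseModel, simulate_session

ACQ = AcquisitionSpec(height_px=8, width_px=8, n_frames=10, onset_frame=3)


def stack_from(data):
    return TrialStack(np.asarray(data, dtype=float), ACQ)


def constant_stack(value, n_trials=2):
    return stack_from(np.full((n_trials, 10, 8, 8), value))


class TestFrameZeroDivide:
    def test_constant_trial_gives_zeros(self):
        out = frame_zero_divide(constant_stack(1000.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_hand_division(self):
        data = np.full((1, 10, 8, 8), 1000.0)
        data[0, 5] = 1004.0
        out = frame_zero_divide(stack_from(data))
        assert out[0, 5, 0, 0] == pytest.approx(0.004)
        assert out[0, 4, 0, 0] == pytest.approx(0.0)

    def test_two_frame_baseline_mean(self):
        acq = AcquisitionSpec(height_px=2, width_px=2, n_frames=4, onset_frame=2)
        data = np.empty((1, 4, 2, 2))
        data[0, 0] = 999.0
        data[0, 1] = 1001.0
        data[0, 2] = 1000.0
        data[0, 3] = 1000.0
        out = frame_zero_divide(TrialStack(data, acq))
        assert out[0, 2, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_baseline_names_pixel(self):
        data = np.full((1, 10, 8, 8), 1000.0)
        data[0, :3, 2, 5] = 0.0
        with pytest.raises(ValueError, match=r"\(2, 5\)"):
            frame_zero_divide(stack_from(data))


class TestBlankSubtract:
    def test_identical_blank_mean_gives_zero(self):
        dff = np.random.default_rng(0).normal(size=(3, 10, 8, 8))
        out = blank_subtract(dff, np.broadcast_to(dff.mean(0), (2, 10, 8, 8)))
        np.testing.assert_allclose(out, dff - dff.mean(0), atol=1e-15)

    def test_shared_drift_removed_exactly(self):
        drift = np.broadcast_to(
            np.linspace(0, -0.01, 10)[None, :, None, None], (1, 10, 8, 8))
        resp = np.zeros((1, 10, 8, 8))
        resp[0, 5] = 0.004
        out = blank_subtract(resp + drift, np.repeat(drift, 3, axis=0))
        assert np.abs(out - resp).max() < 1e-12

    def test_zero_blank_is_identity(self):
        dff = np.random.default_rng(1).normal(size=(2, 10, 8, 8))
        np.testing.assert_array_equal(
            blank_subtract(dff, np.zeros((2, 10, 8, 8))), dff)

    def test_shape_mismatch_and_empty_blank(self):
        dff = np.zeros((2, 10, 8, 8))
        with pytest.raises(ValueError):
            blank_subtract(dff, np.zeros((2, 9, 8, 8)))
        with pytest.raises(ValueError):
            blank_subtract(dff, np.zeros((0, 10, 8, 8)))


class TestAverageTrials:
    def test_single_trial_identity(self):
        x = np.random.default_rng(2).normal(size=(1, 10, 8, 8))
        movie = average_trials(x, ACQ)
        np.testing.assert_array_equal(movie.data, x[0])
        assert movie.n_trials == 1

    def test_symmetric_trials_cancel(self):
        a = np.random.default_rng(3).normal(size=(10, 8, 8))
        movie = average_trials(np.stack([a, -a]), ACQ)
        np.testing.assert_allclose(movie.data, 0.0, atol=1e-15)

    def test_arithmetic_mean(self):
        trials = np.stack([np.full((10, 8, 8), v) for v in (1.0, 2.0, 3.0)])
        movie = average_trials(trials, ACQ)
        np.testing.assert_allclose(movie.data, 2.0)


class TestMaskStimulationFrames:
    def movie(self, modality):
        stim = StimulusSpec(modality=modality, pulse_ms=10.0, site_px=(4, 4))
        data = np.zeros((1, 10, 8, 8))
        return average_trials(data, ACQ, stim=stim)

    def test_opto_masks_exactly_t0_and_t10(self):
        out = mask_stimulation_frames(self.movie("opto"))
        t = out.time_ms
        expected_invalid = np.isin(t, (0.0, 10.0))
        np.testing.assert_array_equal(~out.valid_frames, expected_invalid)
        assert np.isnan(out.data[ACQ.frame_at(0.0)]).all()

    def test_icms_unchanged(self):
        out = mask_stimulation_frames(self.movie("icms"))
        assert out.valid_frames.all()

    def test_idempotent(self):
        once = mask_stimulation_frames(self.movie("opto"))
        twice = mask_stimulation_frames(once)
        np.testing.assert_array_equal(once.valid_frames, twice.valid_frames)
        np.testing.assert_array_equal(np.isnan(once.data), np.isnan(twice.data))


class TestMaskBleachedPixels:
    def base_movie(self):
        data = np.zeros((10, 8, 8))
        return average_trials(data[None], ACQ)

    def test_no_dip_no_mask(self):
        out = mask_bleached_pixels(self.base_movie(), (4, 4))
        assert out.valid_pixels.all()

    def test_known_spot_masked_exactly(self):
        movie = self.base_movie()
        spot = [(4, 4), (4, 5), (3, 4)]
        for r, c in spot:
            movie.data[5, r, c] = -0.01  # t = 20 ms, inside 10-40 window
        out = mask_bleached_pixels(movie, (4, 4), search_radius_um=200.0)
        masked = np.argwhere(~out.valid_pixels)
        assert {tuple(m) for m in masked} == set(spot)
        assert np.isnan(out.data[:, 4, 4]).all()

    def test_dip_outside_search_radius_not_masked(self):
        movie = self.base_movie()
        movie.data[5, 0, 7] = -0.01  # ~290 um away from (4,4)? ensure far
        out = mask_bleached_pixels(movie, (4, 4), search_radius_um=100.0)
        assert out.valid_pixels.all()

    def test_threshold_sign_checked(self):
        with pytest.raises(ValueError):
            mask_bleached_pixels(self.base_movie(), (4, 4), neg_threshold=0.01)


class TestEndToEnd:
    def test_noise_free_chain_recovers_generator_field(self):
        acq = AcquisitionSpec()
        stim = StimulusSpec(modality="opto", pulse_ms=10.0, site_px=(50, 50))
        resp = ResponseModel(amplitude=3.6e-3)
        art = ArtifactModel(noise_sd=0.0)  # artifacts on, camera noise off
        stim_stack, blank_stack, truth = simulate_session(acq, stim, resp, art,
                                                          3, 3, seed=7)
        movie = preprocess_session(stim_stack, blank_stack)
        got = movie.masked_data()
        valid = np.isfinite(got)
        assert valid.any()
        assert np.abs(np.where(valid, got - truth.dff, 0.0)).max() < 1e-10

    def test_linear_op_order_invariance(self):
        """Averaging before or after blank subtraction is identical."""
        rng = np.random.default_rng(4)
        dff_stim = rng.normal(size=(4, 10, 8, 8))
        dff_blank = rng.normal(size=(3, 10, 8, 8))
        a = blank_subtract(dff_stim, dff_blank).mean(axis=0)
        b = dff_stim.mean(axis=0) - dff_blank.mean(axis=0)
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_masked_entries_do_not_propagate(self):
        """Poisoned masked entries leave downstream means unchanged."""
        from vsdpop.timecourse import CircleROI, extract_tc

        acq = AcquisitionSpec()
        stim = StimulusSpec(modality="opto", pulse_ms=10.0, site_px=(50, 50))
        resp = ResponseModel(amplitude=3.6e-3)
        art = ArtifactModel(noise_sd=0.0)
        stim_stack, blank_stack, _ = simulate_session(acq, stim, resp, art,
                                                      2, 2, seed=1)
        movie = preprocess_session(stim_stack, blank_stack)
        poisoned = movie.copy()
        poisoned.data[~poisoned.valid_frames, :, :] = 1e6
        poisoned.data[:, ~poisoned.valid_pixels] = 1e6
        roi = CircleROI((50, 50), radius_px=5)
        a = extract_tc(movie, roi)
        b = extract_tc(poisoned, roi)
        np.testing.assert_array_equal(np.nan_to_num(a.values),
                                      np.nan_to_num(b.values))
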