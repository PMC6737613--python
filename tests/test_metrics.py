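"""Edge fitting / FWHM, CNR and FSIM readouts."""

import numpy as np
import pytest
from scipy.special import erf

from nvca import (EdgeProfile, FrameSequence, MovingInsertSpec, NoiseParams,
                  ROISpec, cnr, fit_edge, fsim, fwhm_over_profiles,
                  make_moving_insert_sequence, reference_from_time_average)
from nvca.metrics import FWHM_PER_SIGMA


def erf_edge(x, c, d, offset=0.0, amplitude=1.0):
    return offset + amplitude * 0.5 * (1.0 - erf((x - c) / (np.sqrt(2.0) * d)))


class TestFitEdge:
    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0, 3.5, 5.0])
    @pytest.mark.parametrize("c_off", [-2.0, -1.0, 0.0, 1.0, 2.0])
    def test_recovers_noiseless_parameters(self, d, c_off):
        x = np.arange(60.0)
        c = 29.5 + c_off
        y = erf_edge(x, c, d, offset=0.2, amplitude=0.5)
        fit = fit_edge(EdgeProfile(x, y))
        assert not fit.flagged
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.d == pytest.approx(d, abs=1e-6)
        assert fit.fwhm == pytest.approx(FWHM_PER_SIGMA * d, abs=1e-5)

    def test_fwhm_to_d_ratio_is_fixed(self):
        x = np.arange(40.0)
        fit = fit_edge(EdgeProfile(x, erf_edge(x, 19.5, 2.0)))
        assert fit.fwhm / fit.d == pytest.approx(FWHM_PER_SIGMA)

    def test_mirrored_profile_gives_same_width(self):
        x = np.arange(50.0)
        y = erf_edge(x, 24.5, 1.7, offset=0.1, amplitude=0.4)
        falling = fit_edge(EdgeProfile(x, y))
        rising = fit_edge(EdgeProfile(x, y[::-1].copy()))
        assert rising.d == pytest.approx(falling.d, abs=1e-6)
        assert np.sign(rising.amplitude) == -np.sign(falling.amplitude)

    def test_flat_profile_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="flat"):
            fit_edge(EdgeProfile(x, np.full(20, 0.3)))

    def test_noisy_garbage_is_flagged_not_raised(self, rng):
        x = np.arange(30.0)
        fit = fit_edge(EdgeProfile(x, rng.normal(0, 1, 30)), r2_floor=0.9)
        assert fit.flagged

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            EdgeProfile(np.array([0.0, 1.0, 2.5, 3.0, 4.0]), np.zeros(5))


class TestFwhmOverProfiles:
    def test_identical_profiles_have_zero_std(self):
        x = np.arange(30.0)
        row = erf_edge(x, 14.5, 1.5, offset=0.2, amplitude=0.5)
        frame = np.tile(row, (40, 1))
        s = fwhm_over_profiles(frame, ROISpec(0, 0, 40, 30), n_profiles=40)
        assert s.std_fwhm == pytest.approx(0.0, abs=1e-9)
        assert s.mean_fwhm == pytest.approx(FWHM_PER_SIGMA * 1.5, abs=1e-5)
        assert s.n_profiles == 40

    def test_clean_moving_insert_edge_is_subpixel(self):
        spec = MovingInsertSpec(n_frames=6)
        clean, _, rois = make_moving_insert_sequence(
            spec, NoiseParams(0.0, 0.0), "gaussian_approx", seed=0)
        s = fwhm_over_profiles(clean, rois[5], n_profiles=10, frame_index=5)
        assert s.mean_fwhm < 1.0  # ideal step: fit floor is sub-pixel

    def test_moving_average_blurs_more_than_raw(self, fluoro_noise):
        from nvca import MaskSpec, StepPhantomSpec, make_step_sequence, moving_average
        spec = StepPhantomSpec(frame_height=96, frame_width=96, n_frames=8,
                               step_levels=(0.4,), step_edge_fractions=(0.7,),
                               background_level=0.7)
        _, noisy, _ = make_step_sequence(spec, fluoro_noise, seed=4)
        side = spec.side_px()[0]
        edge_col = 48 - side // 2
        roi = ROISpec(30, edge_col - 9, 36, 18)
        raw = fwhm_over_profiles(noisy, roi, n_profiles=20, frame_index=-1)
        ma = fwhm_over_profiles(moving_average(noisy, MaskSpec(5, 5)), roi,
                                n_profiles=20, frame_index=-1)
        assert ma.mean_fwhm > raw.mean_fwhm

    def test_vertical_direction_transposes(self):
        x = np.arange(30.0)
        col = erf_edge(x, 14.5, 2.0)
        frame = np.tile(col[:, None], (1, 12))  # horizontal edge
        s = fwhm_over_profiles(frame, ROISpec(0, 0, 30, 12), n_profiles=12,
                               direction="vertical")
        assert s.mean_fwhm == pytest.approx(FWHM_PER_SIGMA * 2.0, abs=1e-4)

    def test_too_many_profiles_rejected(self):
        frame = np.tile(erf_edge(np.arange(20.0), 9.5, 1.0), (5, 1))
        with pytest.raises(ValueError, match="profiles"):
            fwhm_over_profiles(frame, ROISpec(0, 0, 5, 20), n_profiles=10)


class TestCNR:
    @staticmethod
    def frame_with(meanA, stdA, meanB, stdB):
        # four-pixel ROIs whose sample stats are exact by construction
        u = np.array([-1.0, -1.0, 1.0, 1.0]) * np.sqrt(3.0) / 2.0  # sample std 1
        frame = np.zeros((2, 4))
        frame[0] = meanA + stdA * u
        frame[1] = meanB + stdB * u
        return frame, ROISpec(0, 0, 1, 4), ROISpec(1, 0, 1, 4)

    def test_hand_computed_examples(self):
        frame, roiA, roiB = self.frame_with(2.0, 1.0, 1.0, 1.0)
        assert cnr(frame, roiA, roiB).cnr == pytest.approx(1.0)
        frame, roiA, roiB = self.frame_with(0.6, 0.05, 0.4, 0.05)
        assert cnr(frame, roiA, roiB).cnr == pytest.approx(4.0)

    def test_identical_content_gives_zero(self):
        frame, roiA, roiB = self.frame_with(0.5, 0.1, 0.5, 0.1)
        assert cnr(frame, roiA, roiB).cnr == pytest.approx(0.0)

    def test_shift_and_scale_invariance(self, rng):
        frame = rng.random((20, 20))
        roiA, roiB = ROISpec(0, 0, 8, 8), ROISpec(10, 10, 8, 8)
        base = cnr(frame, roiA, roiB).cnr
        assert cnr(frame + 5.0, roiA, roiB).cnr == pytest.approx(base)
        assert cnr(3.0 * frame, roiA, roiB).cnr == pytest.approx(base)

    def test_sequence_returns_per_frame_values(self, rng):
        frames = rng.random((5, 16, 16)) + np.linspace(0, 1, 5)[:, None, None] * 0
        frames[:, :8] += 0.5
        res = cnr(FrameSequence(frames), ROISpec(0, 0, 8, 16), ROISpec(8, 0, 8, 16))
        assert res.per_frame.shape == (5,)
        assert res.cnr == pytest.approx(res.per_frame.mean())

    def test_overlapping_rois_rejected(self, rng):
        frame = rng.random((10, 10))
        with pytest.raises(ValueError, match="disjoint"):
            cnr(frame, ROISpec(0, 0, 5, 5), ROISpec(2, 2, 5, 5))

    def test_zero_pooled_variance_rejected(self):
        frame = np.ones((4, 4))
        with pytest.raises(ValueError, match="pooled"):
            cnr(frame, ROISpec(0, 0, 2, 4), ROISpec(2, 0, 2, 4))


class TestFSIM:
    def test_self_similarity_is_one(self, rng):
        img = rng.random((48, 48))
        assert fsim(img, img).fsim == pytest.approx(1.0, abs=1e-12)

    def test_decreases_with_noise_level(self, rng):
        ref = np.zeros((64, 64))
        ref[16:48, 16:48] = 1.0
        ref[28:36, :] = 0.5
        scores = []
        for sigma in (0.05, 0.15, 0.4):
            per_seed = [fsim(ref + np.random.default_rng(s).normal(0, sigma, ref.shape),
                             ref).fsim for s in range(5)]
            scores.append(np.mean(per_seed))
        assert scores[0] > scores[1] > scores[2]

    def test_invariant_to_joint_affine_rescaling(self, rng):
        ref = rng.random((40, 40))
        test = ref + rng.normal(0, 0.1, ref.shape)
        base = fsim(test, ref).fsim
        assert fsim(3.0 * test + 7.0, 3.0 * ref + 7.0).fsim == pytest.approx(base)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            fsim(rng.random((8, 8)), rng.random((9, 8)))

    def test_parameters_recorded(self, rng):
        img = rng.random((32, 32))
        res = fsim(img, img + 0.01 * rng.random((32, 32)))
        assert res.parameters["nscale"] == 4
        assert res.parameters["norient"] == 4


class TestReference:
    def test_constant_sequence(self):
        seq = FrameSequence(np.full((7, 5, 5), 0.3))
        np.testing.assert_array_equal(reference_from_time_average(seq),
                                      np.full((5, 5), 0.3))

    def test_two_frame_average(self):
        seq = FrameSequence(np.stack([np.zeros((3, 3)), np.ones((3, 3))]))
        np.testing.assert_allclose(reference_from_time_average(seq), 0.5)

    def test_residual_variance_shrinks_with_frames(self, fluoro_noise, rng):
        clean = np.full((400, 20, 20), 0.5)
        noisy = clean + rng.normal(0, 0.05, clean.shape)
        short = FrameSequence(noisy[:100])
        long = FrameSequence(noisy)
        v_short = (reference_from_time_average(short) - 0.5).var()
        v_long = (reference_from_time_average(long) - 0.5).var()
        assert v_long == pytest.approx(v_short / 4, rel=0.4)
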