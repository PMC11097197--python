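"""PIV correlation engine: pairing, rate arithmetic, displacement
recovery, multipass behavior and postprocessing."""

import numpy as np
import pytest

from hemoveloc import (
    make_triphasic_waveform,
    multipass_piv,
    ncc_pass,
    pair_frames,
    poiseuille_profile,
    postprocess_fields,
    preprocess_optical,
    profile_to_field,
    render_particle_images,
)
from hemoveloc.piv import (
    EPIV_CONTROL_SCHEDULE,
    OPIV_SCHEDULE,
    PivSchedule,
    fields_per_second,
)
from hemoveloc.types import ParticleImageSequence

from conftest import render_uniform, uniform_field


class TestPairingAndRates:
    def test_non_overlapping_pairs(self):
        pairs = pair_frames(8, 8000.0, "non_overlapping")
        assert pairs[:3] == [(0, 1), (2, 3), (4, 5)]
        assert len(pairs) == 4

    def test_sliding_pairs(self):
        pairs = pair_frames(3000, 3000.0, "sliding")
        assert len(pairs) == 2999
        assert pairs[0] == (0, 1) and pairs[-1] == (2998, 2999)

    def test_two_frames_single_pair(self):
        assert pair_frames(2, 100.0, "non_overlapping") == [(0, 1)]
        assert pair_frames(2, 100.0, "sliding") == [(0, 1)]

    def test_epiv_rate_300_fields_per_second(self):
        """9000 fps, 3-angle compounding, correlation averaging of 10."""
        assert fields_per_second(9000, 3, "sliding", 10) == pytest.approx(300.0)

    def test_opiv_rate_400_fields_per_second(self):
        """8000 fps camera, non-overlapping pairs, 10-ensemble average."""
        assert fields_per_second(8000, 1, "non_overlapping", 10) == pytest.approx(400.0)

    def test_unity_pipeline_rate(self):
        assert fields_per_second(1000, 1, "sliding", 1) == pytest.approx(1000.0)


class TestPreprocessOptical:
    def test_constant_background_removed(self):
        """A uniform offset under moving particles is removed exactly:
        preprocessing the offset stack equals preprocessing the clean one."""
        seq, _ = render_uniform(40.0, n_frames=12, noise_sd=0.0, seed=2)
        raised = ParticleImageSequence(frames=seq.frames + 30.0,
                                       pixel_size=seq.pixel_size,
                                       frame_rate=seq.frame_rate)
        out_raised = preprocess_optical(raised, background_window=8,
                                        clahe_clip=None)
        out_clean = preprocess_optical(seq, background_window=8,
                                       clahe_clip=None)
        np.testing.assert_allclose(out_raised.frames, out_clean.frames,
                                   atol=1.0)
        # the offset itself is gone: somewhere the moving minimum reaches it
        assert out_raised.frames.min() == 0.0

    def test_all_zero_frames_stay_zero(self):
        zeros = ParticleImageSequence(frames=np.zeros((6, 32, 32)),
                                      pixel_size=0.05, frame_rate=100.0)
        out = preprocess_optical(zeros, background_window=4)
        assert np.all(out.frames == 0.0)

    def test_static_particle_treated_as_background(self):
        """A particle static over the whole window enters the moving
        minimum and is removed by the subtraction."""
        frames = np.zeros((10, 32, 32))
        frames[:, 16, 16] = 200.0  # static
        frames[4, 8, 8] = 150.0  # transient
        seq = ParticleImageSequence(frames=frames, pixel_size=0.05,
                                    frame_rate=100.0)
        out = preprocess_optical(seq, background_window=6, clahe_clip=None)
        assert out.frames[:, 16, 16].max() == 0.0
        assert out.frames[4, 8, 8] == 150.0

    def test_window_longer_than_sequence_warns(self):
        seq, _ = render_uniform(10.0, n_frames=4)
        with pytest.warns(UserWarning, match="background window"):
            preprocess_optical(seq, background_window=500, clahe_clip=None)


class TestDisplacementRecovery:
    def test_integer_shift_recovered_with_predictor(self):
        """3.0 px uniform shift: a predictor-seeded pass nails every
        interior node to within 0.05 px."""
        seq, (dpx, _) = render_uniform(30.0, noise_sd=0.0, seed=3)
        g1 = ncc_pass(seq, [(0, 1)], 32, 0.5)[0]
        g = ncc_pass(seq, [(0, 1)], 32, 0.5, predictor=g1)[0]
        inner = np.zeros_like(g.valid)
        inner[1:-1, 1:-1] = True
        sel = g.valid & inner
        assert dpx == pytest.approx(3.0)
        np.testing.assert_allclose(g.dcol[sel], dpx, atol=0.05)
        np.testing.assert_allclose(g.drow[sel], 0.0, atol=0.05)

    def test_subpixel_shift_recovered(self):
        """0.25 px shift exercises the 3-point Gaussian subpixel fit."""
        seq, (dpx, _) = render_uniform(2.5, noise_sd=0.0, seed=3)
        g = ncc_pass(seq, [(0, 1)], 32, 0.5)[0]
        sel = g.valid
        assert dpx == pytest.approx(0.25)
        assert g.dcol[sel].mean() == pytest.approx(0.25, abs=0.05)

    def test_identical_frames_zero_displacement(self):
        seq, _ = render_uniform(0.0, noise_sd=0.0, seed=3)
        g = ncc_pass(seq, [(0, 1)], 32, 0.5)[0]
        np.testing.assert_allclose(g.dcol[g.valid], 0.0, atol=1e-9)
        np.testing.assert_allclose(g.drow[g.valid], 0.0, atol=1e-9)

    def test_flat_window_flagged_invalid(self):
        frames = np.zeros((2, 64, 128))
        frames[:, 10:20, 80:120] = 100.0  # texture only on the right
        frames[:, 14, 90] = 180.0
        seq = ParticleImageSequence(frames=frames, pixel_size=0.05,
                                    frame_rate=100.0)
        g = ncc_pass(seq, [(0, 1)], 32, 0.5)[0]
        assert not g.valid[0, 0]  # flat corner window

    @pytest.mark.parametrize("disp_px", [0.5, 2.0, 6.0])
    def test_uniform_translation_mean_within_tenth_pixel(self, disp_px):
        """Mean recovered displacement within 0.1 px across the range of
        usable displacements (standard synthetic-PIV acceptance)."""
        c_cm = disp_px * 0.05 * 2000.0 / 10.0
        seq, (dpx, _) = render_uniform(c_cm, noise_sd=0.5, seed=9)
        g1 = ncc_pass(seq, [(0, 1)], 32, 0.5)[0]
        g = ncc_pass(seq, [(0, 1)], 32, 0.5, predictor=g1)[0]
        assert g.dcol[g.valid].mean() == pytest.approx(dpx, abs=0.1)

    def test_galilean_shift_invariance(self):
        """Adding a constant displacement d shifts every recovered vector
        by d (within 0.1 px on the mean)."""
        base, (d0, _) = render_uniform(20.0, noise_sd=0.0, seed=13)
        shifted, (d1, _) = render_uniform(40.0, noise_sd=0.0, seed=13)
        def measure(seq):
            g1 = ncc_pass(seq, [(0, 1)], 32, 0.5)[0]
            g = ncc_pass(seq, [(0, 1)], 32, 0.5, predictor=g1)[0]
            return g.dcol[g.valid].mean()
        assert measure(shifted) - measure(base) == pytest.approx(d1 - d0, abs=0.1)

    def test_correlation_averaging_reduces_noise(self):
        """On a sparse noisy sequence, averaging 10 correlation planes
        does not degrade (and typically improves) the RMS error."""
        field = uniform_field(25.0)
        seq = render_particle_images(field, seeding_density=0.01 / 0.05**2,
                                     pixel_size=0.05, frame_rate=2000.0,
                                     n_frames=11, noise_sd=12.0, seed=21)
        pairs = pair_frames(seq.n_frames, seq.frame_rate, "sliding")
        true = 25.0 * 10.0 / 2000.0 / 0.05
        g1 = ncc_pass(seq, pairs[:1], 16, 0.5)[0]
        g10 = ncc_pass(seq, pairs, 16, 0.5, correlation_averaging_n=10)[0]
        rms1 = np.sqrt(np.mean((g1.dcol[g1.valid] - true) ** 2))
        rms10 = np.sqrt(np.mean((g10.dcol[g10.valid] - true) ** 2))
        assert rms10 <= rms1


class TestMultipass:
    def test_final_grid_spacing_law_opiv(self):
        """64/32/16 px at 50% overlap on 0.0525 mm pixels -> 0.42 mm."""
        field = uniform_field(20.0, extent=(13.44, 6.72), spacing=0.105)
        seq = render_particle_images(field, pixel_size=0.0525,
                                     frame_rate=2000.0, n_frames=2,
                                     noise_sd=0.0, seed=1)
        out = multipass_piv(seq, OPIV_SCHEDULE)
        assert out.attrs["vector_spacing_mm"] == pytest.approx(0.42)
        assert out.spacing == pytest.approx(0.42, rel=1e-6)

    def test_poiseuille_profile_recovered(self):
        """Multipass PIV on a rendered parabolic flow recovers the profile
        to < 5% of u_max away from the walls."""
        R = 3.0
        u_max = 40.0  # cm/s
        q = (u_max / 100) * np.pi * (R * 1e-3) ** 2 / 2 * 1e6
        prof = poiseuille_profile(q, R, n_radial=201)
        field = profile_to_field(prof, length=12.0, grid_spacing=0.1)
        seq = render_particle_images(field, pixel_size=0.05, frame_rate=2000.0,
                                     n_frames=2, noise_sd=0.5, seed=4)
        out = multipass_piv(seq, PivSchedule((32, 16), overlap=0.5,
                                             pairing_mode="sliding"))
        # PIV grid is anchored in the field's physical frame (tube axis y=0)
        truth = u_max * (1 - (out.y / R) ** 2)
        core = np.abs(out.y) < 0.7 * R
        err = out.vx[0][core].mean(axis=1) - truth[core]
        assert np.abs(err).max() < 0.05 * u_max

    def test_zero_flow_noise_floor(self):
        seq, _ = render_uniform(0.0, n_frames=2, noise_sd=0.3, seed=6)
        out = multipass_piv(seq, PivSchedule((32, 16), overlap=0.5,
                                             pairing_mode="sliding"))
        speed = np.hypot(out.vx, out.vy)[0][out.mask]
        # < 0.01 px equivalent velocity
        assert speed.max() < 0.01 * 0.05 * 2000.0 / 10.0

    def test_window_larger_than_image_rejected(self):
        seq, _ = render_uniform(10.0)
        big = PivSchedule((256,), overlap=0.5)
        with pytest.raises(ValueError):
            multipass_piv(seq, big)


class TestPostprocess:
    def test_block_ensemble_reduces_rate_by_factor(self):
        field = uniform_field(10.0)
        nt = 20
        vx = np.repeat(field.vx, nt, axis=0)
        vx += np.arange(nt)[:, None, None]  # make frames distinct
        from hemoveloc.types import VelocityField2D

        f = VelocityField2D(x=field.x, y=field.y, t=np.arange(nt) / 4000.0,
                            vx=vx, vy=np.zeros_like(vx), mask=field.mask)
        out = postprocess_fields(f, spatial_gaussian=False, temporal_window=10,
                                 temporal_mode="block_ensemble")
        assert out.t.size == 2
        assert out.frame_rate == pytest.approx(f.frame_rate / 10.0)

    def test_identity_when_disabled(self):
        field = uniform_field(10.0)
        out = postprocess_fields(field, spatial_gaussian=False, temporal_window=1)
        np.testing.assert_array_equal(out.vx, field.vx)

    def test_constant_field_invariant_under_both_filters(self):
        field = uniform_field(7.0)
        nt3 = np.repeat(field.vx, 6, axis=0)
        from hemoveloc.types import VelocityField2D

        f = VelocityField2D(x=field.x, y=field.y, t=np.arange(6) / 100.0,
                            vx=nt3, vy=np.zeros_like(nt3), mask=field.mask)
        out = postprocess_fields(f, spatial_gaussian=True, temporal_window=3,
                                 temporal_mode="moving_average")
        np.testing.assert_allclose(out.vx, 7.0, atol=1e-9)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            PivSchedule((16, 32), overlap=0.5)  # increasing
        with pytest.raises(ValueError):
            PivSchedule((16, 4), overlap=0.5)  # too small
        with pytest.raises(ValueError):
            PivSchedule((32,), overlap=1.2)
        assert EPIV_CONTROL_SCHEDULE.correlation_averaging_n == 10
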