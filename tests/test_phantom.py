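import numpy as np
import pytest

from petmoco.correct import integrate
from petmoco.frames import FrameTiming
from petmoco.geometry import InvalidInputError
from petmoco.metrics import probe_displacements
from petmoco.phantom import (
    ROI_NAMES,
    TrajectorySpec,
    make_phantom,
    make_trajectory,
    simulate_frames,
    simulate_static_pair,
)


class TestMakePhantom:
    def test_deterministic_for_fixed_seed(self):
        a = make_phantom((32, 32, 32), 4.0, seed=3)
        b = make_phantom((32, 32, 32), 4.0, seed=3)
        assert np.array_equal(a.activity.values, b.activity.values)
        assert np.array_equal(a.labels.values, b.labels.values)

    def test_too_small_shape_rejected(self):
        with pytest.raises(InvalidInputError):
            make_phantom((31, 32, 32), 4.0)

    def test_all_rois_present_and_populated(self, phantom40):
        assert set(phantom40.roi_definitions) == set(ROI_NAMES)
        for roi in ROI_NAMES:
            assert phantom40.roi_mask(roi).sum() >= 50, roi

    def test_wb_is_union_of_all_labels(self, phantom40):
        labeled = phantom40.labels.values.astype(int) > 0
        assert np.array_equal(phantom40.roi_mask("WB"), labeled)

    def test_gm_wm_contrast_in_fdg_range(self, phantom40):
        act = phantom40.activity.values
        gm = act[phantom40.roi_mask("GM")].mean()
        wm = act[phantom40.roi_mask("WM")].mean()
        assert 2.0 <= gm / wm <= 4.0

    def test_met_like_same_geometry_lower_uptake(self, phantom40, phantom_met40):
        assert np.array_equal(phantom40.labels.values, phantom_met40.labels.values)
        assert phantom_met40.activity.values.mean() <= 0.5 * phantom40.activity.values.mean() + 1e-12
        act = phantom_met40.activity.values
        gm = act[phantom_met40.roi_mask("GM")].mean()
        wm = act[phantom_met40.roi_mask("WM")].mean()
        assert gm > wm  # tissue ordering preserved, contrast compressed

    def test_ventricle_like_voids_present(self, phantom40):
        # unlabeled low-activity voxels strictly inside the brain
        lab = phantom40.labels.values.astype(int)
        inside = phantom40.roi_mask("WB")
        from scipy.ndimage import binary_erosion, binary_fill_holes
        deep = binary_erosion(binary_fill_holes(inside), iterations=2)
        voids = deep & (lab == 0)
        assert voids.sum() > 20
        assert phantom40.activity.values[voids].mean() < 0.2


class TestMakeTrajectory:
    def test_static_gives_zero_displacement(self, phantom32, timing6):
        traj = make_trajectory(TrajectorySpec("static"), timing6, 0, phantom32.brain_center)
        d = probe_displacements(traj, phantom32.brain_center)
        assert np.all(d.anterior_mm == 0) and np.all(d.posterior_mm == 0)

    def test_step_displacement_before_and_after(self, phantom32, timing6):
        spec = TrajectorySpec("step", translation_mm=(0, 2.5, 0), event_time_s=90.0)
        traj = make_trajectory(spec, timing6, 0, phantom32.brain_center)
        d = probe_displacements(traj, phantom32.brain_center)
        before = timing6.mid_s < 90.0
        assert np.all(d.anterior_mm[before] == 0)
        assert np.allclose(d.anterior_mm[~before], 2.5, atol=1e-12)

    def test_drift_displacement_linear_in_time(self, phantom32):
        timing = FrameTiming.uniform(10, 30.0)
        spec = TrajectorySpec("drift", translation_mm=(0, 5, 0))
        traj = make_trajectory(spec, timing, 0, phantom32.brain_center)
        d = probe_displacements(traj, phantom32.brain_center)
        frac = (timing.mid_s - timing.mid_s[0]) / (timing.mid_s[-1] - timing.mid_s[0])
        assert np.allclose(d.anterior_mm, 5 * frac, atol=1e-9)

    def test_reference_transform_is_identity_even_with_jitter(self, phantom32, timing6):
        spec = TrajectorySpec("jitter", noise_translation_sd_mm=0.5,
                              noise_rotation_sd_deg=0.3, seed=4)
        traj = make_trajectory(spec, timing6, 3, phantom32.brain_center)
        assert traj.transforms[3].is_identity()

    def test_event_outside_scan_rejected(self, phantom32, timing6):
        spec = TrajectorySpec("step", translation_mm=(1, 0, 0), event_time_s=1e4)
        with pytest.raises(InvalidInputError):
            make_trajectory(spec, timing6, 0, phantom32.brain_center)


class TestSimulateFrames:
    def test_frame_totals_near_constant_counts(self, phantom32, timing6):
        traj = make_trajectory(TrajectorySpec("static"), timing6, 0, phantom32.brain_center)
        s = simulate_frames(phantom32, traj, counts_per_frame=5e5, seed=1)
        totals = s.frames.sum(axis=(1, 2, 3))
        assert np.all(np.abs(totals - 5e5) < 5 * np.sqrt(5e5))

    def test_zero_noise_static_frames_identical(self, phantom32, timing6):
        traj = make_trajectory(TrajectorySpec("static"), timing6, 0, phantom32.brain_center)
        s = simulate_frames(phantom32, traj, noise=False)
        for f in range(1, s.n_frames):
            assert np.array_equal(s.frames[f], s.frames[0])

    def test_expectation_totals_conserved(self, phantom32, timing6):
        traj = make_trajectory(TrajectorySpec("static"), timing6, 0, phantom32.brain_center)
        s = simulate_frames(phantom32, traj, counts_per_frame=5e5, noise=False)
        totals = s.frames.sum(axis=(1, 2, 3))
        assert np.allclose(totals, 5e5, rtol=1e-6)

    def test_nonpositive_counts_rejected(self, phantom32, timing6):
        traj = make_trajectory(TrajectorySpec("static"), timing6, 0, phantom32.brain_center)
        with pytest.raises(InvalidInputError):
            simulate_frames(phantom32, traj, counts_per_frame=0)

    def test_two_seeds_same_expectation_different_noise(self, phantom32):
        timing = FrameTiming.uniform(50, 30.0)
        traj = make_trajectory(TrajectorySpec("static"), timing, 0, phantom32.brain_center)
        a = simulate_frames(phantom32, traj, seed=1)
        b = simulate_frames(phantom32, traj, seed=2)
        assert not np.array_equal(a.frames, b.frames)
        expect = simulate_frames(phantom32, traj, noise=False).frames[0]
        gm = phantom32.roi_mask("GM")
        for s in (a, b):
            mean_gm = s.frames.mean(axis=0)[gm].mean()
            sem = np.sqrt(expect[gm].mean() / (50 * gm.sum()))
            assert abs(mean_gm - expect[gm].mean()) < 3 * sem

    def test_met_like_has_lower_gm_snr_at_equal_counts(self, phantom40, phantom_met40):
        # SNR proxy: voxelwise mean/sd over replicate frames, averaged in GM
        timing = FrameTiming.uniform(20, 30.0)
        snr = {}
        for ph in (phantom40, phantom_met40):
            traj = make_trajectory(TrajectorySpec("static"), timing, 0, ph.brain_center)
            s = simulate_frames(ph, traj, counts_per_frame=5e5, seed=11)
            gm = ph.roi_mask("GM")
            mu = s.frames.mean(axis=0)[gm]
            sd = s.frames.std(axis=0, ddof=1)[gm]
            ok = sd > 0
            snr[ph.contrast] = float((mu[ok] / sd[ok]).mean())
        assert snr["met_like"] < snr["fdg_like"]


class TestSimulateStaticPair:
    def test_static_trajectory_gives_identical_pair(self, phantom32, timing6):
        traj = make_trajectory(TrajectorySpec("static"), timing6, 0, phantom32.brain_center)
        nomc, ddmc = simulate_static_pair(phantom32, traj, seed=2)
        assert np.array_equal(nomc.values, ddmc.values)

    def test_step_zero_noise_oracle(self, phantom40, timing6):
        # lattice-commensurate 7 mm step (2 voxels) so resampling is exact
        spec = TrajectorySpec("step", translation_mm=(0, 7, 0), event_time_s=90.0)
        traj = make_trajectory(spec, timing6, 0, phantom40.brain_center)
        nomc, ddmc = simulate_static_pair(phantom40, traj, noise=False)
        static = make_trajectory(TrajectorySpec("static"), timing6, 0, phantom40.brain_center)
        expect = integrate(simulate_frames(phantom40, static, noise=False))
        # ground-truth correction restores the motion-free expectation
        # (two trilinear passes: ~5% of peak resampling tolerance)
        interior = (slice(3, -3),) * 3
        rel = np.abs(ddmc.values - expect.values)[interior].max() / expect.values.max()
        assert rel < 0.05
        # the uncorrected integral is blurred: strictly lower peak
        assert nomc.values.max() < ddmc.values.max()

    def test_cortical_relative_difference_positive_for_step(self, phantom40, timing6):
        spec = TrajectorySpec("step", translation_mm=(0, 3, 0), event_time_s=90.0)
        traj = make_trajectory(spec, timing6, 0, phantom40.brain_center)
        nomc, ddmc = simulate_static_pair(phantom40, traj, noise=False)
        shell = phantom40.roi_mask("GM")
        rel = (ddmc.values[shell].mean() - nomc.values[shell].mean()) / ddmc.values[shell].mean()
        assert rel > 0
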