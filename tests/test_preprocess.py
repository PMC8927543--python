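"""Scrubbing chain: FD/DVARS/SD, censoring, nuisance regression, filtering, QC."""

import numpy as np
import pytest

from hubdisrupt.preprocess import (
    apply_scrubbing,
    build_censor_mask,
    clean_bold,
    compute_dvars,
    compute_fd,
    compute_sd_series,
    discard_initial,
    downsample_grid,
    downsample_volume,
    interpolate_censored,
    qc_check,
    regress_nuisance,
    temporal_filter,
)
from hubdisrupt.synthetic import generate_motion
from hubdisrupt.types import BoldSeries, NuisanceSet


def _bold(v=5, t=230, tr=2.5, rng=None):
    rng = rng or np.random.default_rng(0)
    coords = np.column_stack([np.arange(v), np.zeros(v, int), np.zeros(v, int)])
    return BoldSeries(rng.standard_normal((v, t)) + 100, coords, 6.0, tr)


class TestDiscard:
    def test_default_discard_of_four(self):
        out = discard_initial(_bold(t=230))
        assert out.n_volumes == 226

    def test_boundary_single_volume_left(self):
        out = discard_initial(_bold(t=5), n=4)
        assert out.n_volumes == 1

    def test_rejects_discarding_everything(self):
        with pytest.raises(ValueError):
            discard_initial(_bold(t=4), n=4)

    def test_retained_columns_unchanged(self):
        b = _bold(t=30)
        out = discard_initial(b, n=4)
        np.testing.assert_array_equal(out.data, b.data[:, 4:])


class TestFramewiseDisplacement:
    def test_constant_trace_is_zero(self):
        assert compute_fd(np.ones((20, 6))).max() == 0.0

    def test_stated_arithmetic(self):
        motion = np.zeros((2, 6))
        motion[1, :3] = [0.1, 0.2, 0.1]
        motion[1, 3:] = [0.002, 0.0, 0.001]
        fd = compute_fd(motion)
        assert fd[0] == 0.0
        assert fd[1] == pytest.approx(0.4 + 50 * 0.003)

    def test_matches_elementwise_oracle(self, rng):
        motion = np.cumsum(rng.normal(0, 0.05, (50, 6)), axis=0)
        fd = compute_fd(motion)
        for t in range(1, 50):
            d = np.abs(motion[t] - motion[t - 1])
            assert fd[t] == pytest.approx(d[:3].sum() + 50 * d[3:].sum())

    def test_rejects_nonfinite(self):
        bad = np.zeros((10, 6))
        bad[3, 0] = np.nan
        with pytest.raises(ValueError):
            compute_fd(bad)


class TestDvarsAndSd:
    def test_constant_in_time_gives_zero_dvars(self):
        data = np.outer(np.arange(5.0), np.ones(10))
        assert compute_dvars(data, normalize=False).max() == 0.0

    def test_single_voxel_raw_values(self):
        raw = compute_dvars(np.array([[0.0, 3.0, 3.0]]), normalize=False)
        np.testing.assert_allclose(raw, [0.0, 3.0, 0.0])

    def test_raw_dvars_matches_bruteforce(self, rng):
        data = rng.standard_normal((30, 40))
        mask = rng.random(30) < 0.5
        raw = compute_dvars(data, mask, normalize=False)
        for t in range(1, 40):
            expect = np.sqrt(np.mean((data[mask, t] - data[mask, t - 1]) ** 2))
            assert raw[t] == pytest.approx(expect)

    def test_constant_series_warns_and_zeros(self):
        with pytest.warns(RuntimeWarning):
            z = compute_dvars(np.zeros((3, 10)))
        assert np.all(z == 0)

    def test_identical_volumes_give_zero_sd_z(self):
        data = np.tile(np.arange(6.0)[:, None], (1, 12))
        with pytest.warns(RuntimeWarning):
            z = compute_sd_series(data)
        assert np.all(z == 0)

    def test_doubled_spread_volume_is_max(self, rng):
        data = rng.standard_normal((40, 20))
        data[:, 7] *= 2.0
        z = compute_sd_series(data)
        assert np.argmax(z) == 7

    def test_sd_matches_two_pass_oracle(self, rng):
        data = rng.standard_normal((25, 15)) * 3 + 5
        raw = compute_sd_series(data, normalize=False)
        np.testing.assert_allclose(raw, data.std(axis=0), atol=1e-12)


class TestCensorMask:
    def test_single_exceedance_expands_two_each_side(self):
        fd = np.zeros(10)
        fd[4] = 0.7
        censored = build_censor_mask(fd, np.zeros(10), np.zeros(10))
        assert set(np.flatnonzero(censored)) == {2, 3, 4, 5, 6}

    def test_boundary_clipping_at_start(self):
        dvars = np.zeros(10)
        dvars[0] = 3.0
        censored = build_censor_mask(np.zeros(10), dvars, np.zeros(10))
        assert set(np.flatnonzero(censored)) == {0, 1, 2}

    def test_no_exceedance_no_censoring(self):
        censored = build_censor_mask(np.full(20, 0.4), np.zeros(20), np.zeros(20))
        assert not censored.any()

    def test_threshold_is_strict(self):
        fd = np.full(10, 0.5)  # exactly at threshold: not "larger than"
        assert not build_censor_mask(fd, np.zeros(10), np.zeros(10)).any()

    def test_idempotent_on_clean_retained_volumes(self, rng):
        fd = np.abs(rng.normal(0.1, 0.05, 50))
        fd[20] = 1.0
        censored = build_censor_mask(fd, np.zeros(50), np.zeros(50))
        fd_kept = fd[~censored]
        again = build_censor_mask(fd_kept, np.zeros(len(fd_kept)), np.zeros(len(fd_kept)))
        assert not again.any()


class TestNuisanceRegression:
    def _nuisance(self, rng, t):
        return NuisanceSet(
            motion=rng.standard_normal((t, 6)),
            csf=rng.standard_normal(t),
            wm=rng.standard_normal(t),
            global_signal=rng.standard_normal(t),
        )

    def test_regressor_itself_yields_zero_residual(self, rng):
        nuis = self._nuisance(rng, 50)
        data = np.vstack([nuis.csf, nuis.global_signal])
        resid = regress_nuisance(data, nuis)
        np.testing.assert_allclose(resid, 0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        nuis = self._nuisance(rng, 60)
        data = rng.standard_normal((20, 60))
        resid = regress_nuisance(data, nuis)
        design = np.column_stack([np.ones(60), nuis.design()])
        dots = np.abs(resid @ design)
        norms = np.linalg.norm(resid, axis=1)[:, None] * np.linalg.norm(design, axis=0)
        assert np.all(dots < 1e-8 * np.maximum(norms, 1e-30))

    def test_invariant_to_regressor_rescaling(self, rng):
        nuis = self._nuisance(rng, 40)
        data = rng.standard_normal((10, 40))
        r1 = regress_nuisance(data, nuis)
        scaled = NuisanceSet(nuis.motion * 7.5, nuis.csf - 3.0, nuis.wm, nuis.global_signal)
        r2 = regress_nuisance(data, scaled)
        np.testing.assert_allclose(r1, r2, atol=1e-9)

    def test_collinear_design_warns(self, rng):
        t = 40
        nuis = NuisanceSet(
            motion=rng.standard_normal((t, 6)),
            csf=np.ones(t),  # collinear with the intercept
            wm=rng.standard_normal(t),
            global_signal=rng.standard_normal(t),
        )
        with pytest.warns(RuntimeWarning):
            regress_nuisance(rng.standard_normal((5, t)), nuis)


class TestTemporalFilter:
    TR = 2.5

    def _amplitude_ratio(self, freq):
        t = np.arange(800) * self.TR
        x = np.sin(2 * np.pi * freq * t)[None, :]
        y = temporal_filter(x, self.TR)
        mid = slice(150, 650)  # avoid edge transients
        return np.abs(y[0, mid]).max() / np.abs(x[0, mid]).max()

    def test_passband_tone_retained(self):
        assert self._amplitude_ratio(0.05) >= 0.90

    def test_stopband_tone_attenuated(self):
        # 0.25 Hz aliases to 0.15 Hz at fs = 0.4 Hz, outside the 0.1 Hz edge
        assert self._amplitude_ratio(0.25) <= 0.05

    def test_constant_series_removed(self):
        out = temporal_filter(np.full((3, 300), 7.0), self.TR)
        assert np.abs(out).max() < 1e-6

    def test_highpass_mode_keeps_fast_oscillation(self):
        t = np.arange(500) * self.TR
        x = np.sin(2 * np.pi * 0.15 * t)[None, :]
        y = temporal_filter(x, self.TR, high=None)
        assert np.abs(y[0, 100:400]).max() > 0.9

    @pytest.mark.parametrize("low,high", [(0.0, 0.1), (0.008, 0.3), (0.1, 0.05)])
    def test_rejects_bad_band_edges(self, low, high):
        with pytest.raises(ValueError):
            temporal_filter(np.zeros((2, 100)), self.TR, low=low, high=high)


class TestScrubbingAndQc:
    def test_column_deletion_count(self, rng):
        data = rng.standard_normal((4, 226))
        censored = np.zeros(226, bool)
        censored[[3, 4, 5, 6, 7]] = True
        assert apply_scrubbing(data, censored).shape[1] == 221

    def test_empty_censor_is_identity(self, rng):
        data = rng.standard_normal((4, 30))
        np.testing.assert_array_equal(apply_scrubbing(data, np.zeros(30, bool)), data)

    def test_retained_values_bit_identical(self, rng):
        data = rng.standard_normal((3, 20))
        censored = np.zeros(20, bool)
        censored[5] = True
        out = apply_scrubbing(data, censored)
        np.testing.assert_array_equal(out[:, 5:], data[:, 6:])

    def test_interpolation_bridges_censored_volumes(self):
        data = np.arange(10.0)[None, :]
        censored = np.zeros(10, bool)
        censored[[4, 5]] = True
        out = interpolate_censored(data, censored)
        np.testing.assert_allclose(out, np.arange(10.0)[None, :])  # linear fill

    @pytest.mark.parametrize("n,passes", [(119, False), (120, True), (226, True)])
    def test_qc_retention_rule(self, n, passes):
        assert qc_check(n) is passes


class TestDownsampling:
    def test_constant_image_unchanged(self):
        out = downsample_volume(np.full((6, 6, 6, 3), 2.5), factor=3)
        np.testing.assert_allclose(out, 2.5)

    def test_factor_one_identity(self, rng):
        data = rng.standard_normal((4, 4, 4, 2))
        np.testing.assert_array_equal(downsample_volume(data, 1), data)

    def test_block_mean_hand_computed(self, rng):
        block = rng.standard_normal((3, 3, 3, 1))
        out = downsample_volume(block, factor=3)
        assert out.shape == (1, 1, 1, 1)
        assert out[0, 0, 0, 0] == pytest.approx(block.mean())

    def test_boldseries_coordinate_bookkeeping(self, rng):
        coords = np.argwhere(np.ones((6, 3, 3), bool))
        b = BoldSeries(rng.standard_normal((len(coords), 10)), coords, 2.0, 2.5)
        out = downsample_grid(b, factor=3)
        assert out.voxel_size == 6.0
        assert out.n_voxels == 2  # two 3x3x3 blocks along x
        block0 = coords[:, 0] < 3
        np.testing.assert_allclose(out.data[0], b.data[block0].mean(axis=0))


class TestCleanBold:
    def test_end_to_end_censors_planted_spike(self):
        rng = np.random.default_rng(0)
        coords = np.argwhere(np.ones((4, 4, 4), bool))[:30]
        bold = BoldSeries(rng.standard_normal((30, 160)) + 100, coords, 6.0, 2.5)
        motion = generate_motion(160, [80], spike_mm=0.9, seed=1)
        result = clean_bold(bold, motion)
        # volume 80 pre-discard = 76 post-discard; halo of 2 on each side
        assert set(np.flatnonzero(result.censor.censored)) >= {74, 75, 76, 77, 78}
        assert result.bold.n_volumes == result.censor.n_retained
        assert result.qc_pass
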