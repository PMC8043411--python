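"""Modulation power spectrum: construction, band powers, permutation maps."""

import numpy as np
import pytest

from screamcalls import mps, stats, synth
from screamcalls.audio_prep import AudioClip
from screamcalls.mps import MPSGrid


def _tone(freq=1000.0, dur=0.8, rate=16000):
    t = np.arange(int(dur * rate)) / rate
    return AudioClip(samples=0.5 * np.sin(2 * np.pi * freq * t), rate_hz=rate)


class TestSpectrogram:
    def test_tone_peak_at_nearest_bin(self):
        spec = mps.spectrogram_log(_tone(1000.0))
        target_bin = int(np.argmin(np.abs(spec.freq_axis - 1000.0)))
        # skip edge frames where the window pads with zeros
        interior = spec.values[20:-20]
        peaks = interior.argmax(axis=1)
        assert np.all(np.abs(peaks - target_bin) <= 1)

    def test_time_step_equals_hop(self):
        spec = mps.spectrogram_log(_tone(), hop_s=0.002)
        assert spec.time_step_s == pytest.approx(0.002)

    def test_silence_is_flat_at_floor(self):
        clip = AudioClip(samples=np.zeros(8000), rate_hz=16000)
        spec = mps.spectrogram_log(clip, floor_db=80.0)
        assert np.ptp(spec.values) == 0.0
        assert spec.values[0, 0] == -80.0

    def test_parameter_validation(self):
        clip = _tone()
        with pytest.raises(ValueError, match="fmin"):
            mps.spectrogram_log(clip, fmin_hz=9000.0, fmax_hz=8000.0)
        with pytest.raises(ValueError, match="hop"):
            mps.spectrogram_log(clip, hop_s=-1.0)


class TestComputeMps:
    def test_constant_spectrogram_concentrates_at_origin(self):
        # a constant log-spectrogram has zero power everywhere after mean
        # removal; adding a pure DC offset keeps all power out of every bin
        spec = mps.Spectrogram(
            values=np.full((50, 16), 3.7),
            time_axis=np.arange(50) * 0.002,
            freq_axis=np.geomspace(100, 8000, 16),
        )
        grid = mps.compute_mps(spec)
        assert grid.power.max() <= 1e-20

    def test_hermitian_symmetry_of_full_plane(self):
        clip = synth.make_scream_clip(synth.ScreamSpec("fear", am_band=(50., 70.),
                                                       am_depth=0.8), 3)
        spec = mps.spectrogram_log(clip)
        power, wt, ws = mps._mps_full(spec)
        # P(wt, ws) == P(-wt, -ws): flipping both axes (about the fftshift
        # center) maps the grid onto itself once the unpaired negative
        # Nyquist row/column of even-length axes is dropped
        trimmed = power[1:, :] if len(ws) % 2 == 0 else power
        trimmed = trimmed[:, 1:] if len(wt) % 2 == 0 else trimmed
        np.testing.assert_allclose(trimmed, trimmed[::-1, ::-1], rtol=1e-9, atol=1e-12)

    def test_parseval_energy_bookkeeping(self):
        clip = synth.make_scream_clip(synth.ScreamSpec("pain", am_band=(55., 65.),
                                                       am_depth=0.7), 5)
        spec = mps.spectrogram_log(clip)
        power, _, _ = mps._mps_full(spec)
        x = spec.values - spec.values.mean()
        assert power.sum() == pytest.approx((x**2).sum(), rel=1e-6)

    def test_truncation_bounds(self):
        spec = mps.spectrogram_log(_tone())
        grid = mps.compute_mps(spec)
        assert np.abs(grid.wt_axis).max() <= 200.0
        assert grid.ws_axis.max() <= 12.0
        assert grid.ws_axis.min() >= 0.0

    def test_planted_60hz_am_peaks_in_band(self):
        clip = synth.make_scream_clip(synth.ScreamSpec("fear", am_band=(55., 65.),
                                                       am_depth=0.9, noise_level=0.0), 11)
        grid = mps.compute_mps(mps.spectrogram_log(clip))
        marginal = grid.power.sum(axis=0)
        # exclude the DC neighborhood, then the peak must fall within 50-70 Hz
        mask = np.abs(grid.wt_axis) > 20
        peak_wt = np.abs(grid.wt_axis[mask][np.argmax(marginal[mask])])
        assert 50.0 <= peak_wt <= 70.0

    def test_degenerate_spectrogram_errors(self):
        spec = mps.spectrogram_log(_tone())
        single = mps.Spectrogram(values=spec.values[:1], time_axis=spec.time_axis[:1],
                                 freq_axis=spec.freq_axis)
        with pytest.raises(ValueError, match="frames"):
            mps.compute_mps(single)


class TestBandPower:
    def test_uniform_grid_gives_one(self):
        wt = np.linspace(-200, 200, 81)
        ws = np.linspace(0, 12, 13)
        grid = MPSGrid(power=np.ones((13, 81)), wt_axis=wt, ws_axis=ws)
        for lo, hi in [(50, 70), (140, 180), (0, 200)]:
            assert mps.band_power(grid, lo, hi) == 1.0

    def test_band_outside_grid_errors(self):
        grid = MPSGrid(power=np.ones((3, 5)), wt_axis=np.linspace(-100, 100, 5),
                       ws_axis=np.linspace(0, 5, 3))
        with pytest.raises(ValueError, match="outside"):
            mps.band_power(grid, 140, 180)

    def test_time_reversal_invariance(self):
        """Reversing time flips the sign of the temporal modulation axis;
        band power is defined over |wt| and therefore unchanged."""
        clip = synth.make_scream_clip(synth.ScreamSpec("anger", am_band=(140., 180.),
                                                       am_depth=0.8), 17)
        spec = mps.spectrogram_log(clip)
        reversed_spec = mps.Spectrogram(values=spec.values[::-1].copy(),
                                        time_axis=spec.time_axis,
                                        freq_axis=spec.freq_axis)
        g1 = mps.compute_mps(spec)
        g2 = mps.compute_mps(reversed_spec)
        for band in [(50, 70), (140, 180)]:
            assert mps.band_power(g1, *band) == pytest.approx(
                mps.band_power(g2, *band), rel=1e-6
            )


def _random_grids(rng, n, shape=(6, 9), loc=0.0):
    wt = np.linspace(-180, 180, shape[1])
    ws = np.linspace(0, 10, shape[0])
    return [
        MPSGrid(power=np.abs(loc + 1.0 + 0.3 * rng.standard_normal(shape)),
                wt_axis=wt, ws_axis=ws)
        for _ in range(n)
    ]


class TestGroupDifference:
    def test_identical_groups_zero(self, rng):
        g = _random_grids(rng, 4)
        np.testing.assert_allclose(mps.mps_group_difference(g, g), 0.0, atol=1e-15)

    def test_constant_offset_and_antisymmetry(self, rng):
        a = _random_grids(rng, 5)
        c = 0.37
        b = [MPSGrid(power=g.power + c, wt_axis=g.wt_axis, ws_axis=g.ws_axis) for g in a]
        np.testing.assert_allclose(mps.mps_group_difference(b, a), c, atol=1e-12)
        np.testing.assert_allclose(
            mps.mps_group_difference(a, b), -mps.mps_group_difference(b, a), atol=1e-12
        )

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="congruent"):
            mps.mps_group_difference(_random_grids(rng, 2), _random_grids(rng, 2, (4, 7)))


class TestPermutationMap:
    def test_fixed_seed_identical_map(self, rng):
        a, b = _random_grids(rng, 6), _random_grids(rng, 6)
        m1 = mps.mps_permutation_pmap(a, b, n_perm=99, seed=5)
        m2 = mps.mps_permutation_pmap(a, b, n_perm=99, seed=5)
        np.testing.assert_array_equal(m1.p_values, m2.p_values)
        assert m1.p_values.min() >= 1 / 100
        assert m1.p_values.max() <= 1.0

    def test_planted_band_detected(self, rng):
        """3-SD band difference: most bins in the band come out significant."""
        a = _random_grids(rng, 12)
        b = _random_grids(rng, 12)
        band = slice(3, 6)  # columns of the planted effect
        for g in a:
            g.power[:, band] += 0.9  # 3 within-group SDs (SD = 0.3)
        pmap = mps.mps_permutation_pmap(a, b, n_perm=400, seed=0)
        in_band = pmap.p_values[:, band]
        assert (in_band < 0.05).mean() > 0.8

    def test_zero_perms_errors(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            mps.mps_permutation_pmap(_random_grids(rng, 3), _random_grids(rng, 3), n_perm=0)


class TestBandpowerRegression:
    def test_exact_linear_recovery(self, rng):
        import pandas as pd

        n = 40
        low = rng.uniform(1, 5, n)
        high = rng.uniform(0.5, 2, n)
        bands = pd.DataFrame({"low_band_power": low, "high_band_power": high},
                             index=[f"s{i}" for i in range(n)])
        ratings = pd.Series(0.1 + 0.12 * low + 0.05 * high, index=bands.index)
        res = mps.alarm_bandpower_regression(bands, ratings)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients[0] == pytest.approx(0.12, abs=1e-9)
        assert res.coefficients[1] == pytest.approx(0.05, abs=1e-9)
        assert res.coefficients[0] > 0 and res.coefficients[1] > 0

    def test_permuted_ratings_null(self, rng):
        import pandas as pd
        import scipy.stats as ss

        n = 40
        bands = pd.DataFrame({"low_band_power": rng.uniform(1, 5, n),
                              "high_band_power": rng.uniform(0.5, 2, n)},
                             index=[f"s{i}" for i in range(n)])
        pvals = []
        for _ in range(300):
            ratings = pd.Series(rng.uniform(size=n), index=bands.index)
            res = mps.alarm_bandpower_regression(bands, ratings)
            pvals.append(res.p_value)
            assert res.r_squared < 0.5
        assert ss.kstest(pvals, "uniform").pvalue > 0.01


def test_permutation_null_calibration(rng):
    """Null grids: rejection rate at alpha=.05 binomial-consistent, averaged
    over many seeds."""
    rejections, total = 0, 0
    for seed in range(50):
        r = np.random.default_rng(seed)
        a = _random_grids(r, 8, (4, 6))
        b = _random_grids(r, 8, (4, 6))
        pmap = mps.mps_permutation_pmap(a, b, n_perm=199, seed=seed)
        rejections += int((pmap.p_values < 0.05).sum())
        total += pmap.p_values.size
    # exact null level of the add-one estimator at 199 perms: 10/200 = 0.05
    rate = rejections / total
    assert abs(rate - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / total) + 0.005
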