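"""Number & brightness: moments, S-factor, cursors, cross-correlation."""

import numpy as np
import pytest

from scanfcs import nandb
from scanfcs.studies import complex_study, oligomer_study
from scanfcs.synthetic import RasterSeries, ScanConfig


@pytest.fixture(scope="module")
def poisson_series():
    rng = np.random.default_rng(0)
    counts = rng.poisson(3.0, size=(100, 48, 48)).astype(np.uint16)
    cfg = ScanConfig(image_size=48, frame_count=100)
    return RasterSeries(counts=counts, config=cfg)


class TestBrightnessMap:
    def test_poisson_reads_unit_brightness(self, poisson_series):
        bmap = nandb.brightness_map(poisson_series, s_factor=1.0)
        assert np.nanmedian(bmap.brightness) == pytest.approx(1.0, abs=0.02)
        assert np.nanmedian(bmap.number) == pytest.approx(3.0, rel=0.05)

    def test_zero_mean_pixels_masked(self):
        counts = np.zeros((40, 8, 8))
        counts[:, :4, :] = np.random.default_rng(1).poisson(2, (40, 4, 8))
        cfg = ScanConfig(image_size=8, frame_count=40)
        bmap = nandb.brightness_map(RasterSeries(counts=counts, config=cfg))
        assert np.isnan(bmap.brightness[6, 2])
        assert np.isfinite(bmap.brightness[1, 2])

    def test_few_frames_warns(self):
        counts = np.random.default_rng(2).poisson(2, (10, 8, 8))
        cfg = ScanConfig(image_size=8, frame_count=10)
        with pytest.warns(UserWarning, match="frames"):
            nandb.brightness_map(RasterSeries(counts=counts, config=cfg),
                                 detrend_window=4)

    def test_monomer_brightness_reads_epsilon(self, free_monomer_series):
        bmap = nandb.brightness_map(free_monomer_series, s_factor=1.0)
        assert np.nanmean(bmap.brightness) - 1 == pytest.approx(0.28,
                                                                rel=0.10)

    def test_dimer_brightness_doubles(self, free_monomer_series,
                                      free_dimer_series):
        b_m = np.nanmean(nandb.brightness_map(
            free_monomer_series, s_factor=1.0).brightness) - 1
        b_d = np.nanmean(nandb.brightness_map(
            free_dimer_series, s_factor=1.0).brightness) - 1
        assert b_d / b_m == pytest.approx(2.0, rel=0.10)

    def test_concentration_moves_number_not_brightness(self, psf):
        """Doubling concentration doubles N and leaves B unchanged."""
        from scanfcs.synthetic import SpeciesSpec, simulate_raster
        cfg = ScanConfig(pixel_size=0.1, image_size=48, frame_count=80)
        maps = {}
        for count in (1000, 2000):
            sp = [SpeciesSpec(label="m", diffusion_coefficient=2.45,
                              brightness_per_unit=0.5, count=count)]
            series = simulate_raster(sp, psf, cfg, seed=31)
            maps[count] = nandb.brightness_map(series, s_factor=1.0)
        b1 = np.nanmean(maps[1000].brightness)
        b2 = np.nanmean(maps[2000].brightness)
        n1 = np.nanmedian(maps[1000].number)
        n2 = np.nanmedian(maps[2000].number)
        assert b2 == pytest.approx(b1, rel=0.05)
        assert n2 / n1 == pytest.approx(2.0, rel=0.2)


class TestSFactor:
    def test_ideal_poisson_background(self, poisson_series):
        s = nandb.calibrate_sfactor(poisson_series)
        assert s == pytest.approx(1.0, abs=0.03)

    def test_doubled_variance_halves_sfactor(self, poisson_series):
        doubled = RasterSeries(
            counts=(poisson_series.counts.astype(int) * 2),
            config=poisson_series.config)
        s = nandb.calibrate_sfactor(doubled)
        assert s == pytest.approx(0.5, abs=0.02)

    def test_small_background_region_rejected(self, poisson_series):
        mask = np.zeros((48, 48), bool)
        mask[:4, :4] = True
        with pytest.raises(ValueError, match="too small"):
            nandb.calibrate_sfactor(poisson_series, background_mask=mask)

    def test_calibration_centres_background_at_one(self, background_series):
        s = nandb.calibrate_sfactor(background_series)
        bmap = nandb.brightness_map(background_series, s_factor=s)
        assert np.nanmedian(bmap.brightness) == pytest.approx(1.0, abs=1e-9)


class TestMonomerCursor:
    def test_recovers_tabulated_gfp_brightness(self, free_monomer_series):
        cur = nandb.measure_monomer(free_monomer_series, s_factor=1.0)
        assert 0.25 <= cur.monomer_brightness <= 0.31

    def test_brightness_linear_in_power(self, psf):
        from scanfcs.synthetic import SpeciesSpec, simulate_raster
        cfg = ScanConfig(pixel_size=0.1, image_size=64, frame_count=100)
        eps_hat = {}
        for eps in (0.28, 0.14):
            sp = [SpeciesSpec(label="m", diffusion_coefficient=2.45,
                              brightness_per_unit=eps, count=3000)]
            series = simulate_raster(sp, psf, cfg, seed=33)
            eps_hat[eps] = nandb.measure_monomer(
                series, s_factor=1.0).monomer_brightness
        assert eps_hat[0.14] / eps_hat[0.28] == pytest.approx(0.5, rel=0.15)

    def test_empty_image_rejected(self):
        counts = np.zeros((40, 16, 16))
        cfg = ScanConfig(image_size=16, frame_count=40)
        with pytest.raises(ValueError):
            nandb.measure_monomer(RasterSeries(counts=counts, config=cfg),
                                  s_factor=1.0)

    def test_bimodal_sample_rejected(self, free_monomer_series,
                                     free_dimer_series):
        mixed = RasterSeries(
            counts=np.concatenate([free_monomer_series.counts,
                                   free_dimer_series.counts], axis=2),
            config=free_monomer_series.config)
        with pytest.raises(ValueError, match="not monomeric"):
            nandb.measure_monomer(mixed, s_factor=1.0)


class TestOligomerClassification:
    def test_overlapping_cursors_rejected(self):
        cur = nandb.CursorSpec(s_factor=1.0, monomer_brightness=0.1,
                               cursor_size=0.3)
        bmap = nandb.BrightnessMap(mean=np.ones((4, 4)),
                                   variance=np.ones((4, 4)),
                                   brightness=np.ones((4, 4)),
                                   number=np.ones((4, 4)),
                                   s_factor=1.0, n_frames=50)
        with pytest.raises(ValueError, match="overlap"):
            nandb.classify_oligomers(bmap, cur)

    def test_all_monomer_pixels(self):
        cur = nandb.CursorSpec(s_factor=1.0, monomer_brightness=1.0,
                               cursor_size=0.5)
        b = np.full((20, 20), 2.0)
        bmap = nandb.BrightnessMap(mean=b, variance=b, brightness=b,
                                   number=b, s_factor=1.0, n_frames=50)
        out = nandb.classify_oligomers(bmap, cur, smooth=1)
        assert out["pct_monomer"] == 100.0 and out["pct_dimer"] == 0.0

    def test_dimer_fraction_recovery(self, oligomer_cursor):
        """92.5/7.5 monomer/homodimer mixture of confined entities."""
        vals = [nandb.classify_oligomers(
            nandb.brightness_map(oligomer_study(0.075, seed), s_factor=1.0),
            oligomer_cursor)["pct_dimer"] for seed in range(10)]
        assert 5.5 <= np.mean(vals) <= 9.5

    def test_pure_monomer_false_dimer_rate(self, oligomer_cursor):
        vals = [nandb.classify_oligomers(
            nandb.brightness_map(oligomer_study(0.0, seed), s_factor=1.0),
            oligomer_cursor)["pct_dimer"] for seed in range(3)]
        assert np.mean(vals) <= 3.0

    def test_recovery_monotone_in_truth(self, oligomer_cursor):
        means = []
        for frac in (0.0, 0.05, 0.10, 0.20):
            vals = [nandb.classify_oligomers(
                nandb.brightness_map(oligomer_study(frac, seed + 40),
                                     s_factor=1.0),
                oligomer_cursor)["pct_dimer"] for seed in range(3)]
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)


class TestCrossBrightness:
    def test_independent_channels_uncorrelated(self, free_monomer_series,
                                               free_dimer_series):
        cross = nandb.cross_brightness(free_monomer_series,
                                       free_dimer_series)
        assert abs(np.nanmedian(cross.b_cc)) < 0.05

    def test_anticorrelated_channels_negative(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(10, size=(80, 16, 16)).astype(float)
        cfg = ScanConfig(image_size=16, frame_count=80)
        green = RasterSeries(counts=base, config=cfg)
        red = RasterSeries(counts=base.max() - base, config=cfg)
        cross = nandb.cross_brightness(green, red, detrend_window=None)
        assert np.nanmedian(cross.b_cc) < 0.0

    def test_shape_mismatch_rejected(self, free_monomer_series):
        cfg = ScanConfig(image_size=16, frame_count=10)
        other = RasterSeries(counts=np.ones((10, 16, 16)), config=cfg)
        with pytest.raises(ValueError):
            nandb.cross_brightness(free_monomer_series, other)

    def test_comoving_complexes_cross_correlate(self):
        series = complex_study(0.0, seed=60)
        green, red = series.channel(0), series.channel(1)
        cross = nandb.cross_brightness(green, red)
        sig = cross.b_cc[np.isfinite(cross.b_cc) & (cross.mean_g > 0.2)]
        assert np.median(sig) > 0.05

    def test_temporal_shuffle_collapses_cross_brightness(self):
        """The null oracle for complex detection: shuffling one channel in
        time kills the cross-brightness at the pixels that carried it."""
        series = complex_study(0.15, seed=61)
        green, red = series.channel(0), series.channel(1)
        bright = (green.counts.mean(axis=0) > 0.2) & \
                 (red.counts.mean(axis=0) > 0.2)
        paired = np.nanmedian(
            nandb.cross_brightness(green, red).b_cc[bright])
        rng = np.random.default_rng(0)
        perm = rng.permutation(red.counts.shape[0])
        shuffled = RasterSeries(counts=red.counts[perm], config=red.config)
        collapsed = np.nanmedian(
            nandb.cross_brightness(green, shuffled).b_cc[bright])
        assert paired > 0.05
        assert abs(collapsed) < 0.2 * paired


@pytest.fixture(scope="module")
def cursors():
    from scanfcs.studies import monomer_calibration_study
    green = nandb.measure_monomer(monomer_calibration_study(200),
                                  s_factor=1.0)
    red_series = monomer_calibration_study(201, channel="red")
    red = nandb.measure_monomer(red_series.channel(1), s_factor=1.0)
    return green, red


class TestStoichiometry:
    def test_pure_11_mixture(self, cursors):
        green_cur, red_cur = cursors
        vals = []
        for seed in (70, 71, 72):
            series = complex_study(0.0, seed)
            cross = nandb.cross_brightness(series.channel(0),
                                           series.channel(1),
                                           green_cur, red_cur)
            st = nandb.complex_stoichiometry(cross, green_cur, red_cur,
                                             seed=seed)
            vals.append(st.fraction_11)
        assert np.mean(vals) >= 95.0

    def test_85_15_mixture_recovery(self, cursors):
        green_cur, red_cur = cursors
        vals = []
        for seed in range(10):
            series = complex_study(0.15, seed)
            cross = nandb.cross_brightness(series.channel(0),
                                           series.channel(1),
                                           green_cur, red_cur)
            st = nandb.complex_stoichiometry(cross, green_cur, red_cur,
                                             seed=seed)
            vals.append(st.fraction_21)
        assert 10.0 <= np.nanmean(vals) <= 20.0

    def test_no_cross_correlation_warns_not_raises(self, cursors,
                                                   free_monomer_series,
                                                   free_dimer_series):
        green_cur, red_cur = cursors
        cross = nandb.cross_brightness(free_monomer_series,
                                       free_dimer_series)
        st = nandb.complex_stoichiometry(cross, green_cur, red_cur, seed=0)
        if st.n_significant == 0:
            assert st.warning is not None
        else:                      # a few pixels may clear the null by chance
            assert st.n_significant < 100
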