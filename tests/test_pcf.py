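"""pCF carpets, arch detection and the Movement Index."""

import numpy as np
import pytest

from scanfcs import pcf
from scanfcs.studies import PCF_WALL_COLUMN, pcf_config, pcf_study
from scanfcs.synthetic import (LineScanSeries, PSFModel, ReferenceImage,
                               ScanConfig, SpeciesSpec, simulate_line_scan)


def _noise_lines(seed, n_lines=50_000, rate=1.0):
    rng = np.random.default_rng(seed)
    cfg = pcf_config(n_lines)
    return LineScanSeries(counts=rng.poisson(rate, (n_lines, 32)), config=cfg)


class TestPrepareCarpet:
    def test_display_period_blocks(self):
        lines = _noise_lines(0, n_lines=20_000)
        prepared = pcf.prepare_carpet(lines, period=800)
        assert prepared.display.shape == (25, 32)

    def test_constant_series_no_bleach_no_trim(self):
        lines = _noise_lines(1)
        prepared = pcf.prepare_carpet(lines)
        assert not prepared.bleach_flag and prepared.n_trimmed == 0

    def test_exponential_decay_flags_bleach(self):
        lines = _noise_lines(2, n_lines=40_000, rate=4.0)
        decay = np.exp(-0.5 * np.arange(40_000) / 40_000)   # ~40% decay
        bleached = LineScanSeries(
            counts=np.random.default_rng(3).poisson(
                4.0 * decay[:, None] * np.ones((1, 32))),
            config=lines.config)
        assert pcf.prepare_carpet(bleached).bleach_flag

    def test_overtrim_rejected(self):
        lines = _noise_lines(4, n_lines=20_000)
        with pytest.raises(ValueError, match="10\\^4"):
            pcf.prepare_carpet(lines, bleach_trim=0.9)


class TestColumnAutocorrelation:
    def test_white_noise_has_no_delay_correlation(self):
        lines = _noise_lines(5, n_lines=20_000, rate=3.0)
        carpet = pcf.column_autocorrelation(lines)
        assert np.nanmax(np.abs(carpet.values[carpet.delays > 1])) < 0.02

    def test_immobile_bright_column_detrended_away(self):
        lines = _noise_lines(6, n_lines=20_000, rate=1.0)
        counts = lines.counts.copy().astype(float)
        counts[:, 10] += 20.0                     # constant bright structure
        carpet = pcf.column_autocorrelation(
            LineScanSeries(counts=counts, config=lines.config))
        assert np.nanmax(np.abs(carpet.values[carpet.delays > 1, 10])) < 0.02

    def test_half_decay_shrinks_with_faster_diffusion(self):
        half = {}
        for d in (2.0, 8.0):
            lines = pcf_study(1.0, 1.0, seed=8, n_lines=50_000, D=d)
            carpet = pcf.column_autocorrelation(lines)
            col = np.nanmean(carpet.values[:, 4:12], axis=1)
            half[d] = carpet.delays[np.argmax(col < col[0] / 2)]
        assert half[8.0] < half[2.0]

    def test_window_validation(self):
        with pytest.raises(ValueError):
            pcf.column_autocorrelation(_noise_lines(7, n_lines=100),
                                       window=200)


class TestLocateWall:
    def test_marker_maximum(self):
        ref = ReferenceImage(fluor=np.ones((4, 32)),
                             marker=np.r_[np.ones(16), 30.0, np.ones(15)])
        assert pcf.locate_wall(ref) == 16

    def test_flat_reference_rejected(self):
        ref = ReferenceImage(fluor=np.ones((4, 32)), marker=np.ones(32))
        with pytest.raises(ValueError, match="not localizable"):
            pcf.locate_wall(ref)

    def test_synthetic_ground_truth_wall(self):
        lines = pcf_study(1.0, 1.0, seed=9, n_lines=20_000)
        assert pcf.locate_wall(lines.reference_before) == PCF_WALL_COLUMN


class TestPairCorrelation:
    def test_independent_noise_uncorrelated(self):
        lines = _noise_lines(10, n_lines=30_000, rate=2.0)
        carpet = pcf.pair_correlation(lines, 5, "forward")
        assert np.nanmax(np.abs(carpet.values)) < 0.05

    def test_zero_separation_is_column_autocorrelation(self):
        lines = _noise_lines(11, n_lines=20_000, rate=2.0)
        carpet = pcf.pair_correlation(lines, 0, "forward")
        col = lines.counts[:, 7].astype(float)
        direct = pcf._column_xcorr(col, col, carpet.delays)
        assert np.allclose(carpet.values[:, 7], direct, atol=1e-12)

    def test_columns_without_partner_are_missing(self):
        lines = _noise_lines(12, n_lines=20_000)
        carpet = pcf.pair_correlation(lines, 5, "forward")
        assert np.isnan(carpet.values[:, -3]).all()
        assert np.isfinite(carpet.values[:, 0]).all()

    def test_time_reversal_maps_forward_to_reverse(self):
        """On stationary data, the forward carpet of the time-reversed
        series equals the reverse carpet at the partner column."""
        lines = pcf_study(1.0, 1.0, seed=13, n_lines=50_000)
        dr = 5
        fwd_rev_time = pcf.pair_correlation(
            LineScanSeries(counts=lines.counts[::-1], config=lines.config),
            dr, "forward")
        rev = pcf.pair_correlation(lines, dr, "reverse")
        c = 10
        a = fwd_rev_time.values[:, c]
        b = rev.values[:, c + dr]
        mask = fwd_rev_time.delays < 5000
        assert np.nanmax(np.abs(a[mask] - b[mask])) < 0.05


class TestArchDetection:
    def test_all_zero_carpet_is_no_arch(self):
        lines = _noise_lines(14, n_lines=50_000, rate=0.5)
        carpet = pcf.pair_correlation(lines, 5, "forward")
        assert pcf.detect_arch(carpet, 16, seed=0) == 0

    def test_open_wall_detected_in_most_seeds(self):
        """Molecules crossing a fully permeable wall produce the delayed
        correlation arch in the large majority of acquisitions (the
        per-distance detection power at these study conditions is ~70-80%;
        the Movement Index aggregates three distances and replicates)."""
        hits = []
        for seed in range(10):
            lines = pcf_study(1.0, 1.0, seed, n_lines=200_000)
            carpet = pcf.pair_correlation(lines, 5, "forward",
                                          columns=range(10, 22))
            hits.append(pcf.detect_arch(carpet, 16, seed=1000 + seed))
        assert sum(hits) >= 7

    def test_impermeable_wall_silent_in_at_least_9_of_10_seeds(self):
        hits = []
        for seed in range(10):
            lines = pcf_study(0.0, 0.0, seed, n_lines=200_000)
            carpet = pcf.pair_correlation(lines, 5, "forward",
                                          columns=range(10, 22))
            hits.append(pcf.detect_arch(carpet, 16, seed=1000 + seed))
        assert sum(hits) <= 1

    def test_false_positive_rate_on_pure_noise(self):
        hits = []
        for seed in range(10):
            carpet = pcf.pair_correlation(_noise_lines(seed + 30), 7,
                                          "forward")
            hits.append(pcf.detect_arch(carpet, 16, seed=seed))
        assert np.mean(hits) <= 0.10

    def test_missing_wall_pair_rejected(self):
        lines = _noise_lines(15, n_lines=20_000)
        carpet = pcf.pair_correlation(lines, 5, "forward")
        with pytest.raises(ValueError, match="spans the wall"):
            pcf.detect_arch(carpet, 30, seed=0)


class TestMovementIndex:
    def test_single_replicate_mean(self):
        res = pcf.movement_index([[1, 0, 1]])
        assert res.mi == pytest.approx(2 / 3, abs=1e-9)
        assert res.n == 1

    def test_all_positive_calls(self):
        res = pcf.movement_index([[1, 1, 1], [1, 1, 1]])
        assert res.mi == 1.0 and res.sem == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pcf.movement_index([])
        with pytest.raises(ValueError):
            pcf.movement_index([[]])

    def test_replicate_means_quantised_to_thirds(self):
        res = pcf.movement_index([[1, 0, 0], [1, 1, 0], [0, 0, 0]])
        allowed = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        assert all(np.isclose(allowed, m).any()
                   for m in res.replicate_means)

    def test_unidirectional_wall_separates_directions(self):
        """Sustained source-sink flux across a one-way wall: forward MI
        exceeds reverse MI by at least 0.4 over 10 replicates."""
        fwd, rev = [], []
        for rep in range(10):
            lines = pcf_study(1.0, 0.0, rep, n_lines=200_000,
                              seed_side="left")
            f, r = [], []
            for dr in pcf.STANDARD_DISTANCES:
                cols = range(16 - dr, 16 + dr + 1)
                cf = pcf.pair_correlation(lines, dr, "forward", columns=cols)
                f.append(pcf.detect_arch(cf, 16, seed=1000 + rep))
                cr = pcf.pair_correlation(lines, dr, "reverse", columns=cols)
                r.append(pcf.detect_arch(cr, 16, seed=1000 + rep))
            fwd.append(f)
            rev.append(r)
        mi_f = pcf.movement_index(fwd)
        mi_r = pcf.movement_index(rev)
        assert mi_f.mi - mi_r.mi >= 0.4


class TestDriftCheck:
    def test_no_drift_no_flag(self):
        lines = pcf_study(1.0, 1.0, seed=16, n_lines=20_000)
        shift, flag = pcf.check_drift(lines)
        assert not flag

    def test_injected_drift_flagged(self):
        lines = pcf_study(1.0, 1.0, seed=17, n_lines=20_000,
                          drift_shift=0.6)
        shift, flag = pcf.check_drift(lines)
        assert flag and abs(shift) >= 1
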