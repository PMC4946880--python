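"""Brownian-dynamics simulator: physics and rendering contracts."""

import numpy as np
import pytest

from scanfcs.synthetic import (GAMMA_3DG, Geometry, PSFModel, ScanConfig,
                               SpeciesSpec, Wall, make_mixture,
                               render_raster_series, simulate_line_scan,
                               simulate_particles, simulate_raster)


def test_scan_config_validation():
    with pytest.raises(ValueError):
        ScanConfig(pixel_size=-0.1)
    with pytest.raises(ValueError):
        ScanConfig(pixel_dwell=40.0, image_size=256, line_time=7.56)
    cfg = ScanConfig()
    assert cfg.frame_time_s == pytest.approx(cfg.line_time_s * cfg.image_size)


def test_psf_validation():
    with pytest.raises(ValueError):
        PSFModel(w0=0.5, wz=0.3)


def test_zero_diffusion_particles_static():
    geom = Geometry(bounds=((0, 10), (0, 10), (-2, 2)))
    sp = SpeciesSpec(label="fixed", diffusion_coefficient=0.0,
                     brightness_per_unit=1.0, count=20)
    traj = simulate_particles([sp], geom, total_time=0.01, dt=1e-3, seed=0)
    assert np.allclose(traj.positions, traj.positions[0], atol=1e-12)


def test_impermeable_wall_keeps_right_side_empty():
    geom = Geometry(bounds=((0, 10), (0, 2), (-1, 1)),
                    walls=(Wall(5.0, 0.0, 0.0),))
    sp = SpeciesSpec(label="m", diffusion_coefficient=5.0,
                     brightness_per_unit=1.0, count=100,
                     initial_bounds=((0, 5.0), (0, 2), (-1, 1)))
    traj = simulate_particles([sp], geom, total_time=1.0, dt=1e-3, seed=1)
    assert (traj.positions[:, :, 0] < 5.0).all()


def test_one_way_wall_drains_left_side():
    geom = Geometry(bounds=((0, 10), (0, 2), (-1, 1)),
                    walls=(Wall(5.0, 1.0, 0.0),))
    sp = SpeciesSpec(label="m", diffusion_coefficient=5.0,
                     brightness_per_unit=1.0, count=200,
                     initial_bounds=((0, 5.0), (0, 2), (-1, 1)))
    traj = simulate_particles([sp], geom, total_time=5.0, dt=1e-3, seed=2)
    right = (traj.positions[:, :, 0] > 5.0).mean(axis=1)
    assert right[0] == 0.0
    assert right[-1] > 0.9
    # coarse-grained occupancy is nondecreasing until the left reservoir drains
    coarse = right[:4000].reshape(40, 100).mean(axis=1)
    assert np.all(np.diff(coarse) > -0.02)


def test_msd_matches_einstein_relation():
    """Mean squared displacement per axis = 2 D t (free diffusion)."""
    geom = Geometry(bounds=((0, 200), (0, 200), (-100, 100)))
    sp = SpeciesSpec(label="egfp", diffusion_coefficient=78.0,
                     brightness_per_unit=0.28, count=1000)
    traj = simulate_particles([sp], geom, total_time=0.02, dt=1e-6, seed=3)
    disp = traj.positions[-1].astype(float) - traj.positions[0]
    msd = (disp ** 2).mean()
    assert msd == pytest.approx(2 * 78.0 * traj.duration, rel=0.05)


def test_dt_too_coarse_rejected_with_species_name():
    geom = Geometry(bounds=((0, 4), (0, 2), (-1, 1)), walls=(Wall(2.0),))
    sp = SpeciesSpec(label="speedy", diffusion_coefficient=100.0,
                     brightness_per_unit=1.0, count=1)
    with pytest.raises(ValueError, match="speedy"):
        simulate_particles([sp], geom, total_time=0.1, dt=1e-2, seed=0)


def test_background_counts_are_poisson(background_series):
    counts = background_series.counts.astype(float)
    assert counts.mean() == pytest.approx(2.0, rel=0.02)
    # variance/mean ratio of shot noise is 1
    assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.02)


def test_immobile_particle_renders_psf_profile(psf):
    cfg = ScanConfig(pixel_size=0.05, image_size=32, frame_count=20,
                     line_time=7.56)
    center = 16.5 * 0.05
    sp = SpeciesSpec(label="bead", diffusion_coefficient=0.0,
                     brightness_per_unit=20.0, count=1,
                     initial_bounds=((center, center), (center, center),
                                     (0.0, 0.0)))
    series = simulate_raster([sp], psf, cfg, seed=4, background_rate=0.0)
    img = series.counts.mean(axis=0)
    peak = img.max()
    r, c = np.unravel_index(img.argmax(), img.shape)
    # intensity at lateral distance w0 should be ~ e^-2 of the peak
    off = int(round(psf.w0 / 0.05))
    ring = img[r, c + off]
    assert ring / peak == pytest.approx(np.exp(-2.0), rel=0.35)


def test_dimer_variance_exceeds_monomer(free_monomer_series,
                                        free_dimer_series):
    """Matched mean intensity, doubled per-particle brightness -> more
    photon-count variance (doubly stochastic Poisson)."""
    mono = free_monomer_series.counts.astype(float)
    dim = free_dimer_series.counts.astype(float)
    assert dim.mean() == pytest.approx(mono.mean(), rel=0.05)
    assert dim.var() > 1.1 * mono.var()


def test_rendering_reproducible_bit_for_bit(psf):
    cfg = ScanConfig(pixel_size=0.1, image_size=32, frame_count=10)
    sp = SpeciesSpec(label="m", diffusion_coefficient=2.0,
                     brightness_per_unit=1.0, count=200)
    a = simulate_raster([sp], psf, cfg, seed=42)
    b = simulate_raster([sp], psf, cfg, seed=42)
    assert np.array_equal(a.counts, b.counts)


def test_line_series_shape_and_wall_validation(psf):
    cfg = ScanConfig(pixel_size=0.25, line_time=1.0, line_length=32,
                     image_size=32, n_lines=5000)
    sp = SpeciesSpec(label="m", diffusion_coefficient=2.0,
                     brightness_per_unit=1.0, count=50)
    lines = simulate_line_scan([sp], psf, cfg, seed=5, wall_column=16)
    assert lines.counts.shape == (5000, 32)
    assert lines.reference_before is not None
    with pytest.raises(ValueError, match="wall"):
        simulate_line_scan([sp], psf, cfg, seed=5, wall_column=1)


def test_default_line_scan_protocol():
    cfg = ScanConfig()
    assert cfg.n_lines == 200_000 and cfg.line_length == 32


class TestMakeMixture:
    def test_pure_monomer(self):
        species = make_mixture(1.0, 0.0, 0.0, 0.0, totals=100)
        assert len(species) == 1
        assert species[0].n_fluorophores_green == 1
        assert species[0].n_fluorophores_red == 0

    def test_unit_bookkeeping_and_conservation(self):
        species = make_mixture(0.0, 0.0, 0.848, 0.152, totals=1000)
        assert sum(sp.count for sp in species) == 1000
        units_g = sum(sp.count * sp.n_fluorophores_green for sp in species)
        units_r = sum(sp.count * sp.n_fluorophores_red for sp in species)
        assert units_g / units_r == pytest.approx(1.152, abs=0.001)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_mixture(-0.1, 1.1, 0.0, 0.0, totals=10)

    @pytest.mark.parametrize("fractions", [(0.5, 0.5, 0.0, 0.0),
                                           (0.25, 0.25, 0.25, 0.25)])
    def test_total_conserved(self, fractions):
        species = make_mixture(*fractions, totals=123)
        assert sum(sp.count for sp in species) == 123


def test_pixel_rate_matches_analytic_mean(psf):
    """Ensemble pixel mean equals concentration x PSF volume x peak rate."""
    cfg = ScanConfig(pixel_size=0.1, image_size=32, frame_count=30)
    geom = Geometry(bounds=((-1, 4.2), (-1, 4.2), (-2.25, 2.25)))
    sp = SpeciesSpec(label="m", diffusion_coefficient=3.0,
                     brightness_per_unit=0.5, count=1000)
    series = simulate_raster([sp], psf, cfg, seed=6, geometry=geom)
    vol = 5.2 * 5.2 * 4.5
    v1 = (np.pi / 2) * psf.w0 ** 2 * np.sqrt(np.pi / 2) * psf.wz
    expected = 1000 / vol * v1 * 0.5 / GAMMA_3DG
    assert series.counts.mean() == pytest.approx(expected, rel=0.05)


class TestMixtureProperties:
    """Property tests: entity conservation and unit bookkeeping hold for
    arbitrary mixture compositions."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(raw=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4)
           .filter(lambda v: sum(v) > 1e-6),
           totals=st.integers(1, 5000))
    def test_counts_conserved_and_units_consistent(self, raw, totals):
        fr = np.array(raw) / sum(raw)
        species = make_mixture(*fr, totals=totals)
        assert sum(sp.count for sp in species) == totals
        for sp in species:
            if sp.n_fluorophores_green == 2 and sp.n_fluorophores_red == 0:
                assert sp.label == "dimer"
            assert sp.n_fluorophores_green + sp.n_fluorophores_red >= 1
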