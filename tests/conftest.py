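"""Shared fixtures: expensive synthetic acquisitions built once per session."""

import numpy as np
import pytest

from scanfcs import nandb
from scanfcs.studies import (monomer_calibration_study, nandb_config,
                             oligomer_study, rics_study)
from scanfcs.synthetic import PSFModel, ScanConfig, SpeciesSpec, simulate_raster


@pytest.fixture(scope="session")
def psf():
    return PSFModel(w0=0.25, wz=0.75)


@pytest.fixture(scope="session")
def calibrated_model():
    """Wild-type model after calibrating d2, K2D, L to the measured
    compositions (the parameter set all model-stage analyses use)."""
    from scanfcs import calibrate as cal
    from scanfcs import model as mdl
    return cal.estimate_parameters(mdl.default_params())


@pytest.fixture(scope="session")
def free_monomer_series(psf):
    """Freely diffusing monomers at the tabulated GFP brightness (0.28)."""
    cfg = ScanConfig(pixel_size=0.1, image_size=64, frame_count=100)
    species = [SpeciesSpec(label="monomer", diffusion_coefficient=2.45,
                           brightness_per_unit=0.28, count=3000)]
    return simulate_raster(species, psf, cfg, seed=11, background_rate=0.0)


@pytest.fixture(scope="session")
def free_dimer_series(psf):
    """Homodimers of the same fluorophore at matched mean intensity."""
    cfg = ScanConfig(pixel_size=0.1, image_size=64, frame_count=100)
    species = [SpeciesSpec(label="dimer", diffusion_coefficient=2.45,
                           brightness_per_unit=0.28, count=1500,
                           n_fluorophores_green=2)]
    return simulate_raster(species, psf, cfg, seed=12, background_rate=0.0)


@pytest.fixture(scope="session")
def background_series(psf):
    cfg = ScanConfig(pixel_size=0.1, image_size=64, frame_count=100)
    empty = [SpeciesSpec(label="none", diffusion_coefficient=0.0,
                         brightness_per_unit=0.0, count=0)]
    return simulate_raster(empty, psf, cfg, seed=13, background_rate=2.0)


@pytest.fixture(scope="session")
def oligomer_cursor():
    """Monomer cursor calibrated on a confined monomer-only study."""
    cal = monomer_calibration_study(seed=100)
    return nandb.measure_monomer(cal, s_factor=1.0)


@pytest.fixture(scope="session")
def rics_series_d2(psf):
    return rics_study(D=2.0, seed=0)
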