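"""Frozen synthetic study designs.

Each builder returns ready-to-analyse synthetic acquisitions under the
conditions the validation studies use throughout the package (tests,
analysis drivers, acceptance checks).  The conditions are part of the study
design — they are fixed here once and shared everywhere:

* RICS: freely diffusing monomers at cytosolic density under the
  recommended raster settings (0.1 um pixels, 12.61 us dwell, 7.56 ms
  lines), image scaled to 64 px for desk-scale runtimes.
* N&B oligomers: monomers and homodimers as locally confined entities
  (chromatin-associated; 0.25 um confinement, ~1 entity per PSF-sized
  spot) so that pixel-cursor counting is meaningful.
* Cross-N&B: 1:1 and 2:1 complexes, both confined, two synchronous
  channels.
* pCF: a thin channel along the scanned line with a cell-wall barrier of
  configurable directional permeability; sparse bright molecules scanned
  at 0.5 ms per 32-pixel line.

See docs/methods.md for the rationale behind each choice and what the
designs do and do not emulate.
"""

from __future__ import annotations

import numpy as np

from .synthetic import (Geometry, LineScanSeries, PSFModel, RasterSeries,
                        ScanConfig, SpeciesSpec, Wall, simulate_line_scan,
                        simulate_raster)

__all__ = [
    "DEFAULT_PSF",
    "rics_config",
    "rics_study",
    "background_study",
    "nandb_config",
    "oligomer_study",
    "complex_study",
    "pcf_config",
    "pcf_study",
    "PCF_WALL_COLUMN",
]

DEFAULT_PSF = PSFModel(w0=0.25, wz=0.75)

# ---------------------------------------------------------------------------
# RICS


def rics_config(image_size: int = 64, frame_count: int = 40) -> ScanConfig:
    """Recommended raster timings at a desk-scale image size."""
    return ScanConfig(pixel_size=0.1, pixel_dwell=12.61, line_time=7.56,
                      image_size=image_size, frame_count=frame_count)


def rics_study(D: float, seed: int, config: ScanConfig | None = None,
               brightness: float = 0.5, count: int = 2000,
               background: float = 0.05,
               psf: PSFModel = DEFAULT_PSF) -> RasterSeries:
    """Raster series of freely diffusing monomers at cytosolic density."""
    config = config or rics_config()
    species = [SpeciesSpec(label="monomer", diffusion_coefficient=D,
                           brightness_per_unit=brightness, count=count)]
    return simulate_raster(species, psf, config, seed=seed,
                           background_rate=background)


def background_study(seed: int, rate: float = 2.0,
                     config: ScanConfig | None = None,
                     psf: PSFModel = DEFAULT_PSF) -> RasterSeries:
    """Background-only frames: pure Poisson detector noise at ``rate``."""
    config = config or ScanConfig(pixel_size=0.1, image_size=256,
                                  frame_count=100)
    empty = [SpeciesSpec(label="none", diffusion_coefficient=0.0,
                         brightness_per_unit=0.0, count=0)]
    return simulate_raster(empty, psf, config, seed=seed,
                           background_rate=rate)


def solution_scan_study(seed: int, D: float = 78.0, w0: float = 0.25,
                        count: int = 300, brightness: float = 1.0,
                        frame_count: int = 12,
                        image_size: int = 64) -> RasterSeries:
    """Raster scan of a homogeneous dye solution (PSF calibration input).

    Free EGFP diffuses fast enough that motion within a scan line matters,
    so the trajectory is sampled at the pixel dwell and rendered at pixel
    time resolution.
    """
    from .synthetic import render_raster_series, simulate_particles

    psf = PSFModel(w0=w0, wz=3.0 * w0)
    config = ScanConfig(pixel_size=0.05, pixel_dwell=12.61, line_time=1.0,
                        image_size=image_size, frame_count=frame_count)
    geometry = Geometry.for_scan(config, psf, "raster")
    rng = np.random.default_rng(seed)
    species = [SpeciesSpec(label="dye", diffusion_coefficient=D,
                           brightness_per_unit=brightness, count=count)]
    traj = simulate_particles(species, geometry, config.raster_duration_s,
                              config.pixel_dwell_s, rng)
    traj.seed = seed
    return render_raster_series(traj, psf, config, background_rate=0.02,
                                seed=rng, time_resolution="pixel")


# ---------------------------------------------------------------------------
# N&B


def nandb_config(image_size: int = 64, frame_count: int = 100) -> ScanConfig:
    return ScanConfig(pixel_size=0.1, pixel_dwell=12.61, line_time=7.56,
                      image_size=image_size, frame_count=frame_count)


NANDB_BRIGHTNESS = 2.0        # counts/dwell/fluorophore unit
NANDB_CONFINEMENT = 0.25      # um, half-width of the local excursion box
NANDB_LOCAL_D = 1.0           # um^2/s inside the confinement
NANDB_ENTITIES = 150          # ~1 entity per PSF-sized spot at 64 px
NANDB_BACKGROUND = 0.05
NANDB_FOCAL_HALFWIDTH = 0.4   # um, entities seeded near the focal plane


def _confined_species(label: str, n_green: int, n_red: int, count: int,
                      geometry: Geometry) -> SpeciesSpec:
    (xlo, xhi), (ylo, yhi), _ = geometry.bounds
    zb = (-NANDB_FOCAL_HALFWIDTH, NANDB_FOCAL_HALFWIDTH)
    return SpeciesSpec(
        label=label, diffusion_coefficient=NANDB_LOCAL_D,
        brightness_per_unit=NANDB_BRIGHTNESS, count=count,
        n_fluorophores_green=n_green, n_fluorophores_red=n_red,
        brightness_per_unit_red=NANDB_BRIGHTNESS,
        confinement_radius=NANDB_CONFINEMENT,
        initial_bounds=((xlo, xhi), (ylo, yhi), zb))


def oligomer_study(dimer_fraction: float, seed: int,
                   config: ScanConfig | None = None,
                   psf: PSFModel = DEFAULT_PSF) -> RasterSeries:
    """Monomer/homodimer mixture of confined nuclear entities."""
    config = config or nandb_config()
    geometry = Geometry.for_scan(config, psf, "raster")
    n_dim = int(round(dimer_fraction * NANDB_ENTITIES))
    species = [_confined_species("monomer", 1, 0, NANDB_ENTITIES - n_dim,
                                 geometry)]
    if n_dim:
        species.append(_confined_species("homodimer", 2, 0, n_dim, geometry))
    return simulate_raster(species, psf, config, seed=seed,
                           background_rate=NANDB_BACKGROUND,
                           geometry=geometry)


def complex_study(fraction_21: float, seed: int,
                  config: ScanConfig | None = None,
                  psf: PSFModel = DEFAULT_PSF) -> RasterSeries:
    """Two-colour 1:1 / 2:1 SHR-SCR-like complex mixture (both confined)."""
    config = config or nandb_config()
    geometry = Geometry.for_scan(config, psf, "raster")
    n21 = int(round(fraction_21 * NANDB_ENTITIES))
    species = [_confined_species("complex_1_1", 1, 1,
                                 NANDB_ENTITIES - n21, geometry)]
    if n21:
        species.append(_confined_species("complex_2_1", 2, 1, n21, geometry))
    return simulate_raster(species, psf, config, seed=seed,
                           background_rate=NANDB_BACKGROUND,
                           geometry=geometry, channels=("green", "red"))


def monomer_calibration_study(seed: int, channel: str = "green",
                              config: ScanConfig | None = None,
                              psf: PSFModel = DEFAULT_PSF) -> RasterSeries:
    """Confined monomer-only sample for cursor calibration."""
    config = config or nandb_config()
    geometry = Geometry.for_scan(config, psf, "raster")
    ng, nr = (1, 0) if channel == "green" else (0, 1)
    species = [_confined_species("monomer", ng, nr, NANDB_ENTITIES, geometry)]
    channels = ("green",) if channel == "green" else ("green", "red")
    return simulate_raster(species, psf, config, seed=seed,
                           background_rate=NANDB_BACKGROUND,
                           geometry=geometry, channels=channels)


# ---------------------------------------------------------------------------
# pCF


PCF_WALL_COLUMN = 16
PCF_PIXEL_SIZE = 0.25         # um
PCF_LINE_TIME = 0.5           # ms
PCF_CHANNEL_HALFWIDTH = 0.4   # um (y and z)
PCF_COUNT = 24
PCF_BRIGHTNESS = 8.0          # counts/dwell/molecule: sparse bright regime
PCF_D = 6.0                   # um^2/s, free-GFP-like
PCF_BACKGROUND = 0.02
PCF_DOMAIN_X = (-0.5, 8.5)    # um; wall at 4.0 um = column 16


def pcf_config(n_lines: int = 100_000) -> ScanConfig:
    return ScanConfig(pixel_size=PCF_PIXEL_SIZE, pixel_dwell=12.61,
                      line_time=PCF_LINE_TIME, line_length=32, image_size=32,
                      n_lines=n_lines)


def pcf_study(p_forward: float, p_reverse: float, seed: int,
              n_lines: int = 100_000, seed_side: str = "both",
              D: float = PCF_D, count: int = PCF_COUNT,
              psf: PSFModel = DEFAULT_PSF,
              drift_shift: float = 0.0) -> LineScanSeries:
    """Line scan across a cell-wall barrier of given directional permeability.

    ``seed_side='left'`` sets up a sustained source-sink flux: molecules
    start in the upstream (left) compartment and any molecule leaving the
    domain downstream is reinjected upstream, emulating continuous
    production on the producing side — the condition under which
    unidirectional movement is probed.
    """
    config = pcf_config(n_lines)
    # wall runs through the centre of its column
    wall_x = (PCF_WALL_COLUMN + 0.5) * PCF_PIXEL_SIZE
    hw = PCF_CHANNEL_HALFWIDTH
    ib = None
    recycle = None
    if seed_side == "left":
        ib = ((PCF_DOMAIN_X[0], wall_x), (-hw, hw), (-hw, hw))
        recycle = ib
    geom = Geometry(bounds=(PCF_DOMAIN_X, (-hw, hw), (-hw, hw)),
                    walls=(Wall(wall_x, p_forward, p_reverse),),
                    recycle=recycle)
    species = [SpeciesSpec(label="tracer", diffusion_coefficient=D,
                           brightness_per_unit=PCF_BRIGHTNESS, count=count,
                           initial_bounds=ib)]
    return simulate_line_scan(species, psf, config, seed=seed,
                              background_rate=PCF_BACKGROUND, geometry=geom,
                              wall_column=PCF_WALL_COLUMN,
                              drift_shift=drift_shift)
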