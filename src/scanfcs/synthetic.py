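"""Brownian-dynamics raster/line-scan simulator with known ground truth.

Generates confocal photon-count data for freely diffusing and confined
fluorescent species observed through a 3D Gaussian point spread function
(PSF) with Poisson detector statistics.  Cell-wall barriers with optional
directional permeability emulate intercellular movement restriction.

Conventions
-----------
* Lengths in micrometres, times in seconds unless a field says otherwise
  (``ScanConfig`` mirrors instrument panels: dwell in us, line time in ms).
* ``SpeciesSpec.brightness_per_unit`` is the *apparent* molecular brightness
  per fluorophore unit, in counts/dwell/molecule, i.e. the quantity N&B
  measures as B-1.  The renderer converts it to a peak detection rate by the
  3D-Gaussian gamma factor (eps_peak = eps * 2^{3/2}), so that a simulated
  monomer of brightness eps reads back B-1 ~= eps.
* Particles advance one Brownian step per scan line; within a line the
  sample is frozen.  For the diffusion coefficients and dwell times of
  interest, intra-line motion is negligible against the PSF width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMA_3DG",
    "ScanConfig",
    "PSFModel",
    "SpeciesSpec",
    "Wall",
    "Geometry",
    "ParticleTrajectories",
    "ReferenceImage",
    "RasterSeries",
    "LineScanSeries",
    "simulate_particles",
    "render_raster_series",
    "render_line_series",
    "make_mixture",
    "simulate_raster",
    "simulate_line_scan",
]

#: shape factor of the 3D Gaussian observation volume, integral q^2 / integral q
GAMMA_3DG = 2.0 ** -1.5


# ---------------------------------------------------------------------------
# configuration / domain types


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition settings of a raster or line scan.

    Defaults follow the recommended confocal imaging conditions for RICS and
    N&B on Arabidopsis roots (pixel 0.05-0.1 um, dwell 12.61 or 25.21 us,
    line time 7.56 or 15.13 ms, 50-100 frames of 256x256).

    The retrace-time invariant (pixel_dwell * image_size <= line_time) is
    checked against ``image_size``; a configuration used purely for line
    scans should set ``image_size = line_length``.
    """

    pixel_size: float = 0.1        # um
    pixel_dwell: float = 12.61     # us
    line_time: float = 7.56        # ms
    frame_count: int = 50
    image_size: int = 256
    line_length: int = 32          # pixels (line mode)
    n_lines: int = 200_000         # line mode repetitions

    def __post_init__(self) -> None:
        for name in ("pixel_size", "pixel_dwell", "line_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("frame_count", "image_size", "line_length", "n_lines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pixel_dwell * self.image_size > self.line_time * 1e3:
            raise ValueError(
                "pixel_dwell * image_size exceeds the line time: "
                "retrace time would be negative"
            )

    # -- derived times, in seconds
    @property
    def pixel_dwell_s(self) -> float:
        return self.pixel_dwell * 1e-6

    @property
    def line_time_s(self) -> float:
        return self.line_time * 1e-3

    @property
    def frame_time_s(self) -> float:
        return self.line_time_s * self.image_size

    @property
    def raster_duration_s(self) -> float:
        return self.frame_time_s * self.frame_count

    @property
    def line_scan_duration_s(self) -> float:
        return self.line_time_s * self.n_lines

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "pixel_dwell": self.pixel_dwell,
            "line_time": self.line_time,
            "frame_count": self.frame_count,
            "image_size": self.image_size,
            "line_length": self.line_length,
            "n_lines": self.n_lines,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


@dataclass(frozen=True)
class PSFModel:
    """3D Gaussian PSF with lateral waist ``w0`` and axial waist ``wz`` (um)."""

    w0: float = 0.25
    wz: float = 0.75

    def __post_init__(self) -> None:
        if not (self.wz >= self.w0 > 0):
            raise ValueError("PSF requires wz >= w0 > 0")

    @property
    def axial_ratio(self) -> float:
        return self.wz / self.w0


@dataclass(frozen=True)
class SpeciesSpec:
    """One simulated molecular species.

    ``n_fluorophores_green``/``_red`` count fluorophore units per entity
    (a homodimer of a GFP-tagged monomer carries 2 green units).
    ``diffusion_coefficient`` of 0 marks an immobile fraction.
    ``confinement_radius`` (um), when set, tethers each particle to its seed
    position inside a reflecting cube of that half-width — used to emulate
    chromatin-associated complexes which fluctuate locally but do not roam.
    """

    label: str
    diffusion_coefficient: float          # um^2/s
    brightness_per_unit: float            # counts/dwell/molecule (apparent), green
    count: int
    n_fluorophores_green: int = 1
    n_fluorophores_red: int = 0
    brightness_per_unit_red: float | None = None   # defaults to the green value
    confinement_radius: float | None = None
    initial_bounds: tuple | None = None   # ((xlo,xhi),(ylo,yhi),(zlo,zhi))

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if self.brightness_per_unit < 0:
            raise ValueError("brightness_per_unit must be >= 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "diffusion_coefficient": self.diffusion_coefficient,
            "brightness_per_unit": self.brightness_per_unit,
            "count": self.count,
            "n_fluorophores_green": self.n_fluorophores_green,
            "n_fluorophores_red": self.n_fluorophores_red,
        }
        if self.brightness_per_unit_red is not None:
            d["brightness_per_unit_red"] = self.brightness_per_unit_red
        if self.confinement_radius is not None:
            d["confinement_radius"] = self.confinement_radius
        return d


@dataclass(frozen=True)
class Wall:
    """Barrier perpendicular to the scan (x) axis.

    ``p_forward`` is the probability that a particle crossing left->right is
    let through; ``p_reverse`` for right->left.  Rejected crossings reflect.
    """

    position: float
    p_forward: float = 1.0
    p_reverse: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_forward <= 1.0 and 0.0 <= self.p_reverse <= 1.0):
            raise ValueError("wall permeabilities must lie in [0, 1]")


@dataclass(frozen=True)
class Geometry:
    """Simulation domain: reflecting box plus optional walls along x.

    ``recycle`` (optional bounds triple) turns the high-x face into a sink:
    particles leaving through it are reinjected uniformly into the recycle
    region.  This sustains a nonequilibrium flux, emulating continuous
    production upstream and turnover downstream of the scanned cells.
    """

    bounds: tuple = (((0.0, 12.8), (0.0, 12.8), (-2.25, 2.25)))
    walls: tuple = ()
    recycle: tuple | None = None

    def __post_init__(self) -> None:
        for (lo, hi) in self.bounds:
            if hi <= lo:
                raise ValueError("geometry bounds must have hi > lo")
        xlo, xhi = self.bounds[0]
        for w in self.walls:
            if not (xlo < w.position < xhi):
                raise ValueError("wall positions must lie strictly inside the domain")

    @classmethod
    def for_scan(cls, config: ScanConfig, psf: PSFModel,
                 mode: str = "raster", walls: Sequence[Wall] = (),
                 axial_halfwidth: float | None = None,
                 lateral_margin: float = 1.0) -> "Geometry":
        """Domain just covering the scanned region plus a margin.

        The axial extent defaults to a slab of thickness 6*wz centred on the
        focal plane.
        """
        if axial_halfwidth is None:
            axial_halfwidth = 3.0 * psf.wz
        npx = config.image_size if mode == "raster" else config.line_length
        ext = npx * config.pixel_size
        x = (-lateral_margin, ext + lateral_margin)
        if mode == "raster":
            y = (-lateral_margin, ext + lateral_margin)
        else:
            y = (-lateral_margin, lateral_margin)
        return cls(bounds=(x, y, (-axial_halfwidth, axial_halfwidth)),
                   walls=tuple(walls))


@dataclass
class ParticleTrajectories:
    """Positions of all particles sampled on a regular time grid."""

    times: np.ndarray                  # (n_steps,) seconds
    positions: np.ndarray              # (n_steps, n_particles, 3) um
    species_index: np.ndarray          # (n_particles,) -> index into species
    species: tuple                     # tuple[SpeciesSpec]
    geometry: Geometry
    seed: int

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def position_at(self, t: float | np.ndarray) -> np.ndarray:
        """Positions at the trajectory sample nearest to time ``t``."""
        idx = np.rint(np.asarray(t) / self.dt).astype(int) if self.dt else 0
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.positions[idx]


@dataclass
class ReferenceImage:
    """Small raster taken before/after a line series for drift checking."""

    fluor: np.ndarray                  # (rows, line_length) counts
    marker: np.ndarray                 # (line_length,) wall-marker profile


@dataclass
class RasterSeries:
    """Time-ordered photon-count frames plus acquisition metadata.

    ``counts`` is (frames, rows, cols) for the first (green) channel;
    ``counts2`` holds the red channel of a two-colour acquisition.
    Acquisition time of a pixel is
    ``frame*frame_time + row*line_time + col*pixel_dwell``.
    """

    counts: np.ndarray
    config: ScanConfig
    counts2: np.ndarray | None = None
    ground_truth: dict | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be (frames, rows, cols)")
        if np.issubdtype(c.dtype, np.integer) and c.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def channels(self) -> int:
        return 1 if self.counts2 is None else 2

    @property
    def frame_count(self) -> int:
        return self.counts.shape[0]

    def channel(self, i: int) -> "RasterSeries":
        if i == 0:
            return replace(self, counts2=None)
        if i == 1 and self.counts2 is not None:
            return replace(self, counts=self.counts2, counts2=None)
        raise IndexError(f"series has {self.channels} channel(s)")


@dataclass
class LineScanSeries:
    """Repeated 32-pixel line scans: (n_lines, line_length) counts."""

    counts: np.ndarray
    config: ScanConfig
    reference_before: ReferenceImage | None = None
    reference_after: ReferenceImage | None = None
    ground_truth: dict | None = None
    seed: int | None = None

    @property
    def n_lines(self) -> int:
        return self.counts.shape[0]

    @property
    def line_length(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# particle dynamics


def _seed_positions(spec: SpeciesSpec, geometry: Geometry,
                    rng: np.random.Generator) -> np.ndarray:
    bounds = spec.initial_bounds if spec.initial_bounds is not None else geometry.bounds
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return rng.uniform(lo, hi, size=(spec.count, 3))


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by specular reflection."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def _min_wall_gap(geometry: Geometry) -> float:
    xlo, xhi = geometry.bounds[0]
    xs = sorted([xlo] + [w.position for w in geometry.walls] + [xhi])
    return min(b - a for a, b in zip(xs, xs[1:]))


def simulate_particles(species: Sequence[SpeciesSpec], geometry: Geometry,
                       total_time: float, dt: float,
                       seed: int | np.random.Generator = 0) -> ParticleTrajectories:
    """Brownian dynamics of all species over ``total_time`` at step ``dt``.

    Per-axis step variance is 2*D*dt.  Wall crossings (x axis) are accepted
    with the wall's directional permeability, otherwise reflected; domain
    faces reflect.  Confined species reflect inside a cube around their seed
    position.  Raises if ``dt`` is too coarse to resolve the wall spacing for
    the fastest species.
    """
    if dt <= 0 or total_time <= 0:
        raise ValueError("dt and total_time must be > 0")
    species = tuple(species)
    if geometry.walls:
        gap = _min_wall_gap(geometry)
        for sp in species:
            if np.sqrt(2.0 * sp.diffusion_coefficient * dt) >= gap / 4.0:
                raise ValueError(
                    f"dt={dt:g}s too coarse for species '{sp.label}': RMS step "
                    f"{np.sqrt(2 * sp.diffusion_coefficient * dt):.3g} um exceeds a "
                    f"quarter of the minimum wall spacing {gap:.3g} um"
                )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1

    n_steps = int(np.ceil(total_time / dt)) + 1
    times = np.arange(n_steps) * dt

    counts = [sp.count for sp in species]
    n_total = int(sum(counts))
    species_index = np.repeat(np.arange(len(species)), counts)
    sigma = np.sqrt(2.0 * np.array([sp.diffusion_coefficient for sp in species]) * dt)
    sigma_per_particle = sigma[species_index][:, None] if n_total else np.zeros((0, 1))

    x0 = (np.vstack([_seed_positions(sp, geometry, rng) for sp in species])
          if n_total else np.zeros((0, 3)))

    confined = np.array([sp.confinement_radius is not None for sp in species])
    has_confined = bool(confined.any()) and n_total > 0
    if has_confined:
        conf_mask = confined[species_index]
        conf_r = np.array([sp.confinement_radius or 0.0 for sp in species])[species_index]
        homes = x0.copy()

    mobile = sigma_per_particle[:, 0] > 0 if n_total else np.zeros(0, bool)
    free_only = (not geometry.walls and not has_confined
                 and geometry.recycle is None)

    positions = np.empty((n_steps, n_total, 3))
    positions[0] = x0
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = geometry.bounds

    if free_only:
        # single-precision in-place path: step noise ~1e-2 um against
        # cumulative rounding ~1e-4 um, far below the PSF scale
        raw = np.empty((n_steps, n_total, 3), dtype=np.float32)
        raw[0] = 0.0
        if n_total:
            rng.standard_normal(size=(n_steps - 1, n_total, 3),
                                dtype=np.float32, out=raw[1:])
            raw[1:] *= sigma_per_particle.astype(np.float32)[None, :, :]
        np.cumsum(raw, axis=0, out=raw)
        raw += x0.astype(np.float32)[None, :, :]
        raw[:, :, 0] = _reflect(raw[:, :, 0], xlo, xhi)
        raw[:, :, 1] = _reflect(raw[:, :, 1], ylo, yhi)
        raw[:, :, 2] = _reflect(raw[:, :, 2], zlo, zhi)
        return ParticleTrajectories(times, raw, species_index, species,
                                    geometry, seed_val)

    wall_pos = np.array([w.position for w in geometry.walls])
    p_fwd = np.array([w.p_forward for w in geometry.walls])
    p_rev = np.array([w.p_reverse for w in geometry.walls])

    x = x0.copy()
    for step in range(1, n_steps):
        dx = rng.normal(0.0, 1.0, size=(n_total, 3)) * sigma_per_particle
        new = x + dx
        # walls act on the x axis only; dt constraint ensures <=1 wall crossed
        for wi in range(len(wall_pos)):
            wp = wall_pos[wi]
            crossed = (x[:, 0] - wp) * (new[:, 0] - wp) < 0
            if not crossed.any():
                continue
            fwd = crossed & (x[:, 0] < wp)
            rev = crossed & ~fwd
            u = rng.uniform(size=n_total)
            blocked = crossed & (
                (fwd & (u >= p_fwd[wi])) | (rev & (u >= p_rev[wi]))
            )
            new[blocked, 0] = 2.0 * wp - new[blocked, 0]
        if geometry.recycle is not None:
            exiting = new[:, 0] > xhi
            if exiting.any():
                rlo = np.array([b[0] for b in geometry.recycle])
                rhi = np.array([b[1] for b in geometry.recycle])
                new[exiting] = rng.uniform(rlo, rhi,
                                           size=(int(exiting.sum()), 3))
        new[:, 0] = _reflect(new[:, 0], xlo, xhi)
        new[:, 1] = _reflect(new[:, 1], ylo, yhi)
        new[:, 2] = _reflect(new[:, 2], zlo, zhi)
        if has_confined:
            for ax in range(3):
                new[conf_mask, ax] = _reflect(
                    new[conf_mask, ax],
                    homes[conf_mask, ax] - conf_r[conf_mask],
                    homes[conf_mask, ax] + conf_r[conf_mask],
                )
        positions[step] = new
        x = new

    return ParticleTrajectories(times, positions, species_index, species,
                                geometry, seed_val)


# ---------------------------------------------------------------------------
# photon rendering


def _channel_amplitudes(traj: ParticleTrajectories, channel: str) -> np.ndarray:
    """Peak detection rate (counts/dwell) of every particle in one channel."""
    per_species = []
    for sp in traj.species:
        if channel == "green":
            eps, units = sp.brightness_per_unit, sp.n_fluorophores_green
        else:
            eps = (sp.brightness_per_unit_red
                   if sp.brightness_per_unit_red is not None
                   else sp.brightness_per_unit)
            units = sp.n_fluorophores_red
        per_species.append(units * eps / GAMMA_3DG)
    return np.asarray(per_species)[traj.species_index]


def _render_lines(traj: ParticleTrajectories, psf: PSFModel, amps: np.ndarray,
                  line_times: np.ndarray, line_rows_y: np.ndarray,
                  px_x: np.ndarray, background: float,
                  pixel_dwell_s: float | None = None) -> np.ndarray:
    """Expected count rate for a batch of scan lines.

    With ``pixel_dwell_s`` None the sample is frozen within each line
    (adequate whenever the RMS motion during the active line is small
    against the PSF waist); otherwise each pixel samples the trajectory at
    its own acquisition time, which matters for solution scans of fast dyes.
    """
    n_lines = len(line_times)
    n_px = len(px_x)
    rates = np.full((n_lines, n_px), float(background))
    if traj.positions.shape[1] == 0 or not np.any(amps):
        return rates
    dt = traj.dt
    inv_w02 = 2.0 / psf.w0 ** 2
    inv_wz2 = 2.0 / psf.wz ** 2
    # margin covers motion of the fastest species during the active line
    d_max = max(sp.diffusion_coefficient for sp in traj.species)
    wander = (np.sqrt(2.0 * d_max * pixel_dwell_s * n_px)
              if pixel_dwell_s else 0.0)
    cut_y = 3.5 * psf.w0 + wander
    cut_z = 3.0 * psf.wz + wander
    idx0 = np.clip(np.rint(line_times / dt).astype(int), 0, len(traj.times) - 1)
    if pixel_dwell_s:
        px_steps = np.clip(np.rint((np.arange(n_px) * pixel_dwell_s) / dt)
                           .astype(int), 0, None)
    for li in range(n_lines):
        pos0 = traj.positions[idx0[li]]
        dy = pos0[:, 1] - line_rows_y[li]
        keep = (np.abs(dy) < cut_y) & (np.abs(pos0[:, 2]) < cut_z) & (amps > 0)
        if not keep.any():
            continue
        if pixel_dwell_s:
            steps = np.clip(idx0[li] + px_steps, 0, len(traj.times) - 1)
            p = traj.positions[steps][:, keep, :]        # (n_px, kept, 3)
            w = np.exp(-inv_w02 * ((p[:, :, 0] - px_x[:, None]) ** 2
                                   + (p[:, :, 1] - line_rows_y[li]) ** 2)
                       - inv_wz2 * p[:, :, 2] ** 2)
            rates[li] += w @ amps[keep]
        else:
            p = pos0[keep]
            a = amps[keep] * np.exp(
                -inv_w02 * (p[:, 1] - line_rows_y[li]) ** 2
                - inv_wz2 * p[:, 2] ** 2)
            dx2 = (p[:, 0][:, None] - px_x[None, :]) ** 2
            rates[li] += a @ np.exp(-inv_w02 * dx2)
    return rates


def render_raster_series(traj: ParticleTrajectories, psf: PSFModel,
                         config: ScanConfig, background_rate: float = 0.0,
                         seed: int | np.random.Generator = 0,
                         channels: Sequence[str] = ("green",),
                         time_resolution: str = "line") -> RasterSeries:
    """Render a raster time series from particle trajectories.

    Pixel counts are Poisson with mean
    ``background + sum_m eps_peak * exp(-2 dr_lat^2/w0^2 - 2 dz^2/wz^2)``
    evaluated at the pixel's acquisition line.  Channels are rendered
    independently from each species' green/red fluorophore units.
    """
    if traj.duration + 1e-12 < config.raster_duration_s:
        raise ValueError("trajectory is shorter than the scan duration")
    if psf.w0 < config.pixel_size / 10.0:
        warnings.warn("PSF waist is below a tenth of the pixel size: "
                      "the PSF is undersampled", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    n = config.image_size
    px = (np.arange(n) + 0.5) * config.pixel_size
    frames = np.arange(config.frame_count)
    rows = np.arange(n)
    ftime = config.frame_time_s
    ltime = config.line_time_s
    line_times = (frames[:, None] * ftime + rows[None, :] * ltime).ravel()
    line_rows_y = np.tile(px, config.frame_count)

    dwell = config.pixel_dwell_s if time_resolution == "pixel" else None
    out: dict[str, np.ndarray] = {}
    for ch in channels:
        amps = _channel_amplitudes(traj, ch)
        rates = _render_lines(traj, psf, amps, line_times, line_rows_y,
                              px, background_rate, pixel_dwell_s=dwell)
        counts = rng.poisson(rates).astype(np.uint16)
        out[ch] = counts.reshape(config.frame_count, n, n)

    gt = {
        "species": [sp.to_dict() for sp in traj.species],
        "walls": [(w.position, w.p_forward, w.p_reverse) for w in traj.geometry.walls],
        "seed": traj.seed,
        "psf": {"w0": psf.w0, "wz": psf.wz},
        "background_rate": background_rate,
    }
    return RasterSeries(counts=out[channels[0]], config=config,
                        counts2=out.get(channels[1]) if len(channels) > 1 else None,
                        ground_truth=gt, seed=seed_val)


def _render_reference(traj: ParticleTrajectories, psf: PSFModel,
                      config: ScanConfig, t0: float, background: float,
                      rng: np.random.Generator, n_rows: int = 8,
                      shift: float = 0.0) -> ReferenceImage:
    """Small raster around the scan line plus a wall-marker profile."""
    px = (np.arange(config.line_length) + 0.5) * config.pixel_size + shift
    rows_y = (np.arange(n_rows) - n_rows / 2 + 0.5) * config.pixel_size
    line_times = np.full(n_rows, t0)
    amps = _channel_amplitudes(traj, "green")
    rates = _render_lines(traj, psf, amps, line_times, rows_y, px, background)
    fluor = rng.poisson(rates).astype(np.uint16)
    marker = np.full(config.line_length, max(background, 0.05))
    for w in traj.geometry.walls:
        marker += 20.0 * np.exp(-0.5 * ((px - w.position) / config.pixel_size) ** 2)
    marker = rng.poisson(marker * 50).astype(float) / 50.0
    return ReferenceImage(fluor=fluor, marker=marker)


def render_line_series(traj: ParticleTrajectories, psf: PSFModel,
                       config: ScanConfig, wall_column: int | None = None,
                       seed: int | np.random.Generator = 0,
                       background_rate: float = 0.0,
                       drift_shift: float = 0.0) -> LineScanSeries:
    """Render a repeated line scan (pCF acquisition).

    ``wall_column`` is only validated here (the geometry carries the wall);
    reference images are rendered before and after the series, the latter
    optionally shifted by ``drift_shift`` um to emulate sample drift.
    """
    if wall_column is not None and not (2 < wall_column < config.line_length - 2):
        raise ValueError("line must span the wall interior "
                         "(wall_column strictly between 2 and line_length-2)")
    if traj.duration + 1e-12 < config.line_scan_duration_s:
        raise ValueError("trajectory is shorter than the line-scan duration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    px = (np.arange(config.line_length) + 0.5) * config.pixel_size
    line_times = np.arange(config.n_lines) * config.line_time_s
    line_rows_y = np.zeros(config.n_lines)
    amps = _channel_amplitudes(traj, "green")

    ref_before = _render_reference(traj, psf, config, 0.0, background_rate, rng)
    rates = _render_lines(traj, psf, amps, line_times, line_rows_y,
                          px, background_rate)
    counts = rng.poisson(rates).astype(np.uint16)
    ref_after = _render_reference(traj, psf, config, line_times[-1],
                                  background_rate, rng, shift=drift_shift)

    gt = {
        "species": [sp.to_dict() for sp in traj.species],
        "walls": [(w.position, w.p_forward, w.p_reverse) for w in traj.geometry.walls],
        "seed": traj.seed,
        "psf": {"w0": psf.w0, "wz": psf.wz},
        "background_rate": background_rate,
        "wall_column": wall_column,
    }
    return LineScanSeries(counts=counts, config=config,
                          reference_before=ref_before, reference_after=ref_after,
                          ground_truth=gt, seed=seed_val)


# ---------------------------------------------------------------------------
# species mixtures


def make_mixture(monomer_fraction: float, dimer_fraction: float,
                 complex_11_fraction: float, complex_21_fraction: float,
                 totals: int, brightness: tuple[float, float] = (0.28, 0.34),
                 diffusion: float = 2.45,
                 complex_confinement: float | None = None,
                 complex_diffusion: float | None = None) -> list[SpeciesSpec]:
    """Species list for a monomer/dimer/complex mixture.

    Fractions refer to entities and must sum to 1.  A homodimer carries two
    green units; a 1:1 complex one green + one red; a 2:1 complex two green +
    one red.  Total entity count is conserved across the returned list.
    """
    fr = np.array([monomer_fraction, dimer_fraction,
                   complex_11_fraction, complex_21_fraction], float)
    if (fr < 0).any():
        raise ValueError("fractions must be >= 0")
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    eps_g, eps_r = brightness
    counts = np.rint(fr * totals).astype(int)
    counts[np.argmax(counts)] += totals - counts.sum()   # conserve totals

    cdiff = complex_diffusion if complex_diffusion is not None else diffusion
    proto = [
        ("monomer", 1, 0, diffusion, None),
        ("dimer", 2, 0, cdiff, complex_confinement),
        ("complex_1_1", 1, 1, cdiff, complex_confinement),
        ("complex_2_1", 2, 1, cdiff, complex_confinement),
    ]
    out = []
    for (label, ng, nr, D, conf), c in zip(proto, counts):
        if c == 0:
            continue
        out.append(SpeciesSpec(
            label=label, diffusion_coefficient=D, brightness_per_unit=eps_g,
            count=int(c), n_fluorophores_green=ng, n_fluorophores_red=nr,
            brightness_per_unit_red=eps_r, confinement_radius=conf,
        ))
    return out


# ---------------------------------------------------------------------------
# convenience wrappers (simulate + render in one call)


def simulate_raster(species: Sequence[SpeciesSpec], psf: PSFModel,
                    config: ScanConfig, seed: int = 0,
                    background_rate: float = 0.0,
                    geometry: Geometry | None = None,
                    channels: Sequence[str] = ("green",)) -> RasterSeries:
    """Simulate particles for one raster acquisition and render it."""
    rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = Geometry.for_scan(config, psf, "raster")
    traj = simulate_particles(species, geometry, config.raster_duration_s,
                              config.line_time_s, rng)
    traj.seed = seed
    return render_raster_series(traj, psf, config, background_rate, rng,
                                channels=channels)


def simulate_line_scan(species: Sequence[SpeciesSpec], psf: PSFModel,
                       config: ScanConfig, seed: int = 0,
                       background_rate: float = 0.0,
                       geometry: Geometry | None = None,
                       wall_column: int | None = None,
                       drift_shift: float = 0.0) -> LineScanSeries:
    """Simulate particles for one line-scan acquisition and render it."""
    rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = Geometry.for_scan(config, psf, "line")
    traj = simulate_particles(species, geometry, config.line_scan_duration_s,
                              config.line_time_s, rng)
    traj.seed = seed
    return render_line_series(traj, psf, config, wall_column, rng,
                              background_rate, drift_shift)
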