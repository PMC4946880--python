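"""Raster image correlation spectroscopy (RICS).

Spatial autocorrelation of raster-scanned fluorescence images and its fit to
the one-component 3D Gaussian diffusion model.  Because pixels along a line
are acquired microseconds apart while successive lines are milliseconds
apart, the spatial lags (xi, psi) of the autocorrelation double as time lags
``tau = tau_pixel*|xi| + tau_line*|psi|``, which is what lets a purely
spatial correlation surface encode a diffusion coefficient.

The fitted model is ``G_S(xi, psi) = S(xi, psi) * G(xi, psi)`` with

    G = G0 * (1 + 4 D tau / w0^2)^-1 * (1 + 4 D tau / wz^2)^-1/2
    S = exp(-((xi dx)^2 + (psi dx)^2) / (w0^2 (1 + 4 D tau / w0^2)))

where dx is the pixel size and (w0, wz) the PSF waists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .synthetic import PSFModel, RasterSeries, ScanConfig

__all__ = [
    "ACFSurface",
    "DiffusionFit",
    "subtract_moving_average",
    "compute_acf",
    "rics_model",
    "fit_diffusion",
    "calibrate_psf",
    "pool_diffusion",
    "mw_fold_change_for_dc_ratio",
    "implied_molecular_weight",
]

#: default frame window of the immobile-fraction moving average
MOVING_AVERAGE_WINDOW = 10

#: QC rule: the ACF peak must exceed the largest fit residual by this factor
QC_RESIDUAL_FACTOR = 3.0


@dataclass
class ACFSurface:
    """Spatial autocorrelation surface G_S(xi, psi).

    ``values[i, j]`` is the correlation at row lag ``psi[i]`` and column lag
    ``xi[j]``; lags run symmetrically about 0 and the surface satisfies
    G_S(xi, psi) = G_S(-xi, -psi).
    """

    xi: np.ndarray
    psi: np.ndarray
    values: np.ndarray
    mean_intensity: float
    n_frames: int

    @property
    def g0(self) -> float:
        """Amplitude at zero lag (contains the shot-noise spike)."""
        i = int(np.where(self.psi == 0)[0][0])
        j = int(np.where(self.xi == 0)[0][0])
        return float(self.values[i, j])


@dataclass
class DiffusionFit:
    """Result of fitting the RICS diffusion model to an ACF surface."""

    D: float                   # um^2/s
    G0: float
    residuals: np.ndarray
    qc_pass: bool
    n_frames_used: int
    converged: bool = True
    w0: float | None = None    # set by PSF calibration fits


def subtract_moving_average(series: RasterSeries,
                            window: int = MOVING_AVERAGE_WINDOW) -> RasterSeries:
    """Remove the immobile/slow fraction with a moving frame average.

    For each retained frame i the mean of frames i-w/2 .. i+w/2 (inclusive,
    window+1 frames) is subtracted pixelwise and the series grand mean is
    re-added so the correlation normalisation stays defined.  The first and
    last window/2 frames are dropped — there the full window is unavailable.
    """
    if window < 2 or window % 2:
        raise ValueError("window must be an even integer >= 2")
    counts = np.asarray(series.counts, dtype=float)
    n = counts.shape[0]
    if window >= n:
        raise ValueError(f"window ({window}) must be smaller than the "
                         f"frame count ({n})")
    half = window // 2
    cum = np.concatenate([np.zeros((1,) + counts.shape[1:]),
                          np.cumsum(counts, axis=0)])
    # inclusive mean over [i-half, i+half] for interior frames
    idx = np.arange(half, n - half)
    local_mean = (cum[idx + half + 1] - cum[idx - half]) / (window + 1)
    grand_mean = counts.mean()
    filtered = counts[idx] - local_mean + grand_mean
    return replace(series, counts=filtered, counts2=None)


def compute_acf(series: RasterSeries, roi: tuple | None = None) -> ACFSurface:
    """Spatial ACF ``<dI(x,y) dI(x+xi,y+psi)> / <I>^2`` averaged over frames.

    ``roi`` is ((row0, col0), size).  The ACF is computed by FFT with
    zero-padding (no wraparound); lags are reported to +-size/4.
    """
    counts = np.asarray(series.counts, dtype=float)
    if roi is not None:
        (r0, c0), size = roi
        if r0 < 0 or c0 < 0 or r0 + size > counts.shape[1] or \
                c0 + size > counts.shape[2]:
            raise ValueError("ROI falls outside the image")
        counts = counts[:, r0:r0 + size, c0:c0 + size]
    n_frames, h, w = counts.shape
    mean = counts.mean()
    if mean == 0:
        raise ValueError("series mean intensity is zero")
    delta = counts - mean

    ph, pw = 2 * h, 2 * w
    f = np.fft.rfft2(delta, s=(ph, pw))
    num = np.fft.irfft2((f * np.conj(f)).mean(axis=0), s=(ph, pw))
    num = np.fft.fftshift(num)

    ones = np.fft.rfft2(np.ones((h, w)), s=(ph, pw))
    overlap = np.fft.fftshift(np.fft.irfft2(ones * np.conj(ones), s=(ph, pw)))
    overlap = np.maximum(np.rint(overlap), 1.0)

    g = num / overlap / mean ** 2

    max_lag = min(h, w) // 4
    cy, cx = ph // 2, pw // 2
    sl_y = slice(cy - max_lag, cy + max_lag + 1)
    sl_x = slice(cx - max_lag, cx + max_lag + 1)
    lags = np.arange(-max_lag, max_lag + 1)
    return ACFSurface(xi=lags, psi=lags.copy(), values=g[sl_y, sl_x],
                      mean_intensity=mean, n_frames=n_frames)


def rics_model(xi: np.ndarray, psi: np.ndarray, D: float, G0: float,
               psf: PSFModel, config: ScanConfig) -> np.ndarray:
    """One-component scanning+diffusion model evaluated on a lag grid."""
    tau = config.pixel_dwell_s * np.abs(xi) + config.line_time_s * np.abs(psi)
    denom_lat = 1.0 + 4.0 * D * tau / psf.w0 ** 2
    denom_ax = 1.0 + 4.0 * D * tau / psf.wz ** 2
    g_diff = G0 / (denom_lat * np.sqrt(denom_ax))
    r2 = (xi * config.pixel_size) ** 2 + (psi * config.pixel_size) ** 2
    s_scan = np.exp(-r2 / (psf.w0 ** 2 * denom_lat))
    return g_diff * s_scan


def _fit_mask(acf: ACFSurface) -> np.ndarray:
    xi, psi = np.meshgrid(acf.xi, acf.psi)
    return ~((xi == 0) & (psi == 0))


def fit_diffusion(acf: ACFSurface, psf: PSFModel, config: ScanConfig,
                  init: tuple[float, float | None] = (1.0, None)) -> DiffusionFit:
    """Bounded least-squares fit of (D, G0) to an ACF surface.

    The zero-lag point is excluded (shot-noise spike).  Multi-start over
    D0 x {0.1, 1, 10}; ties broken by lowest sum of squares.  The fit passes
    QC when max(ACF) >= 3 * max|residual| over the fitted lags.
    """
    if not np.all(np.isfinite(acf.values)):
        raise ValueError("ACF surface contains non-finite values")
    d0, g0_init = init
    mask = _fit_mask(acf)
    xi, psi = np.meshgrid(acf.xi, acf.psi)
    xi_f, psi_f, y = xi[mask], psi[mask], acf.values[mask]
    if g0_init is None:
        g0_init = max(float(y.max()), 1e-6)

    def resid(p):
        return rics_model(xi_f, psi_f, p[0], p[1], psf, config) - y

    best = None
    for factor in (0.1, 1.0, 10.0):
        try:
            sol = least_squares(resid, x0=[d0 * factor, g0_init],
                                bounds=([1e-3, -np.inf], [1e3, np.inf]),
                                method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        flat = np.zeros_like(acf.values)
        return DiffusionFit(D=np.nan, G0=np.nan, residuals=flat,
                            qc_pass=False, n_frames_used=acf.n_frames,
                            converged=False)

    d_fit, g0_fit = best.x
    res_surface = np.zeros_like(acf.values)
    res_surface[mask] = resid(best.x)
    qc = float(np.max(y)) >= QC_RESIDUAL_FACTOR * float(np.max(np.abs(res_surface)))
    return DiffusionFit(D=float(d_fit), G0=float(g0_fit),
                        residuals=res_surface, qc_pass=bool(qc),
                        n_frames_used=acf.n_frames)


def calibrate_psf(solution_series: RasterSeries, fixed_D: float = 78.0,
                  axial_ratio: float = 3.0,
                  window: int | None = None) -> PSFModel:
    """Fit the lateral beam waist on a homogeneous dye-solution scan.

    The diffusion coefficient is clamped to the known value (free EGFP,
    78 um^2/s) and w0 solved for, with wz tied at ``axial_ratio * w0``.
    A solution scan has no immobile fraction, so the moving-average
    subtraction is skipped unless a window is given.
    """
    if fixed_D <= 0:
        raise ValueError("fixed_D must be > 0")
    filtered = (subtract_moving_average(solution_series, window)
                if window else solution_series)
    acf = compute_acf(filtered)
    config = solution_series.config
    mask = _fit_mask(acf)
    xi, psi = np.meshgrid(acf.xi, acf.psi)
    xi_f, psi_f, y = xi[mask], psi[mask], acf.values[mask]
    g0_init = max(float(y.max()), 1e-6)
    w_lo, w_hi = 0.05, 1.5

    def resid(p):
        w0, g0 = p
        psf = PSFModel(w0=w0, wz=axial_ratio * w0)
        return rics_model(xi_f, psi_f, fixed_D, g0, psf, config) - y

    best = None
    for w0_init in (0.15, 0.25, 0.4):
        sol = least_squares(resid, x0=[w0_init, g0_init],
                            bounds=([w_lo, -np.inf], [w_hi, np.inf]),
                            method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    w0_fit = float(best.x[0])
    if w0_fit <= w_lo * 1.01 or w0_fit >= w_hi * 0.99:
        raise RuntimeError("PSF unidentifiable at these settings "
                           "(fitted waist ran to a bound)")
    return PSFModel(w0=w0_fit, wz=axial_ratio * w0_fit)


def pool_diffusion(fits: list[DiffusionFit], qc_only: bool = True) -> float:
    """Population diffusion coefficient: mean of per-image fitted D."""
    ds = [f.D for f in fits if (f.qc_pass or not qc_only) and np.isfinite(f.D)]
    if not ds:
        raise ValueError("no fits passed QC")
    return float(np.mean(ds))


def mw_fold_change_for_dc_ratio(dc_ratio: float) -> float:
    """Molecular-weight fold change implied by a diffusion-coefficient ratio.

    For Stokes-Einstein-like scaling D ~ MW^(-1/3), a k-fold drop in D
    implies a k^3-fold higher molecular weight.
    """
    if dc_ratio <= 0:
        raise ValueError("dc_ratio must be > 0")
    return float(dc_ratio) ** 3


def implied_molecular_weight(dc_ratio: float, reference_mw_kda: float = 27.0) -> float:
    """MW (kDa) a protein would need for its DC to drop ``dc_ratio``-fold
    relative to a reference of ``reference_mw_kda`` (GFP ~ 27 kDa)."""
    return mw_fold_change_for_dc_ratio(dc_ratio) * reference_mw_kda
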