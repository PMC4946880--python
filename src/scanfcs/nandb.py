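"""Number & Brightness (N&B) and two-colour cross-N&B analysis.

Per-pixel moment analysis of a raster time series: the apparent particle
number ``N = <k>^2 / sigma^2`` and apparent brightness ``B = sigma^2 / <k>``
(population variance, divisor K).  For pure shot noise B = 1; a mobile
species of molecular brightness eps raises it to ``B = 1 + eps``, and a
homodimer of that species to ``B = 1 + 2 eps`` — the basis of the cursor
classification of oligomeric states.

The S-factor is a detector scaling applied to B so that the immobile /
background population sits exactly at B = 1.

Cross-N&B uses the per-pixel cross-variance between two channels,
``B_cc = sigma_cc^2 / (<G><R>)``; co-moving (complexed) species give
``B_cc > 0`` and the (green B, red B) cursor pair at those pixels gives the
complex stoichiometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.stats import gaussian_kde

from .synthetic import RasterSeries

__all__ = [
    "BrightnessMap",
    "CursorSpec",
    "CrossMap",
    "StoichiometryResult",
    "brightness_map",
    "calibrate_sfactor",
    "measure_monomer",
    "classify_oligomers",
    "cross_brightness",
    "complex_stoichiometry",
]

DETREND_WINDOW = 10          # frames, immobile-fraction moving average
MIN_FRAMES = 30
MIN_BACKGROUND_PIXELS = 500


@dataclass
class BrightnessMap:
    """Per-pixel apparent number/brightness of one channel."""

    mean: np.ndarray           # <k> per pixel
    variance: np.ndarray       # sigma^2 per pixel (detrended, bias-corrected)
    brightness: np.ndarray     # B, S-factor scaled; NaN where <k> == 0
    number: np.ndarray         # N, NaN where variance == 0
    s_factor: float
    n_frames: int
    channel: int = 0


@dataclass
class CursorSpec:
    """Brightness-axis cursor calibration for one channel.

    ``monomer_brightness`` (eps) is the apparent molecular brightness of the
    monomeric fluorophore in counts/dwell/molecule; ``cursor_size`` the full
    B-axis span of the cursor window.  Instrument reference values for the
    LSM 780 green channel: S-factor 1.34, eps 0.28.
    """

    s_factor: float
    monomer_brightness: float
    cursor_size: float
    channel: int = 0

    def __post_init__(self) -> None:
        if self.monomer_brightness <= 0:
            raise ValueError("monomer_brightness must be > 0")
        if self.cursor_size <= 0:
            raise ValueError("cursor_size must be > 0")

    def monomer_window(self) -> tuple[float, float]:
        c = 1.0 + self.monomer_brightness
        return (c - self.cursor_size / 2, c + self.cursor_size / 2)

    def dimer_window(self) -> tuple[float, float]:
        # brightness above background doubles; the shot-noise unit does not
        c = 1.0 + 2.0 * self.monomer_brightness
        return (c - self.cursor_size / 2, c + self.cursor_size / 2)


@dataclass
class CrossMap:
    """Per-pixel cross-variance statistics of a two-colour acquisition."""

    sigma_cc: np.ndarray
    b_cc: np.ndarray           # NaN where either channel mean is 0
    n_cc: np.ndarray
    mean_g: np.ndarray
    mean_r: np.ndarray
    b_g: np.ndarray            # calibrated per-channel brightness maps
    b_r: np.ndarray
    n_frames: int
    green: RasterSeries | None = None
    red: RasterSeries | None = None


@dataclass
class StoichiometryResult:
    """Composition of cross-correlated (complexed) pixels."""

    fraction_11: float         # percent of complexed pixels
    fraction_21: float
    n_pixels_11: int
    n_pixels_21: int
    n_significant: int
    histogram: dict | None = None
    warning: str | None = None


# ---------------------------------------------------------------------------


def _detrended_moments(counts: np.ndarray, window: int | None):
    """Per-pixel mean and fluctuation variance.

    With a detrend window w, each frame's local (w+1)-frame inclusive mean is
    subtracted before the variance is taken, removing immobile/slow signal;
    the residual variance is divided by (1 - 1/(w+1)) which makes the
    estimator exact for frame-independent noise (Poisson input stays B = 1).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if window:
        if window >= n:
            raise ValueError("detrend window must be smaller than frame count")
        half = window // 2
        cum = np.concatenate([np.zeros((1,) + counts.shape[1:]),
                              np.cumsum(counts, axis=0)])
        idx = np.arange(half, n - half)
        local_mean = (cum[idx + half + 1] - cum[idx - half]) / (window + 1)
        resid = counts[idx] - local_mean
        var = resid.var(axis=0) / (1.0 - 1.0 / (window + 1))
        mean = counts[idx].mean(axis=0)
        k_used = len(idx)
    else:
        mean = counts.mean(axis=0)
        var = counts.var(axis=0)
        k_used = n
    return mean, var, k_used


def brightness_map(series: RasterSeries, s_factor: float = 1.0,
                   detrend_window: int | None = DETREND_WINDOW,
                   channel: int = 0) -> BrightnessMap:
    """Apparent number and brightness per pixel.

    Fewer than 30 frames triggers an unstable-variance warning; pixels with
    zero mean are masked (NaN), never reported as 0/0.
    """
    counts = series.counts if channel == 0 else series.counts2
    if counts is None:
        raise ValueError("requested channel not present")
    if counts.shape[0] < MIN_FRAMES:
        import warnings
        warnings.warn(f"only {counts.shape[0]} frames: variance estimates "
                      "are unstable below 30", stacklevel=2)
    if np.issubdtype(np.asarray(counts).dtype, np.signedinteger) and counts.min() < 0:
        raise ValueError("counts must be nonnegative")
    mean, var, k_used = _detrended_moments(counts, detrend_window)

    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(mean > 0, s_factor * var / mean, np.nan)
        n = np.where(var > 0, mean ** 2 / var, np.nan)
    return BrightnessMap(mean=mean, variance=var, brightness=b, number=n,
                         s_factor=s_factor, n_frames=k_used, channel=channel)


def calibrate_sfactor(background_series: RasterSeries,
                      background_mask: np.ndarray | None = None,
                      detrend_window: int | None = DETREND_WINDOW) -> float:
    """S-factor that centres the background population at B = 1.

    ``s = 1 / median(raw B over background pixels)``.
    """
    raw = brightness_map(background_series, s_factor=1.0,
                         detrend_window=detrend_window)
    b = raw.brightness
    if background_mask is not None:
        b = b[background_mask]
    b = b[np.isfinite(b)]
    if b.size < MIN_BACKGROUND_PIXELS:
        raise ValueError(f"background region too small: {b.size} usable pixels "
                         f"(need >= {MIN_BACKGROUND_PIXELS})")
    med = float(np.median(b))
    if med <= 0:
        raise ValueError("background brightness is non-positive")
    return 1.0 / med


def _kde_peaks(values: np.ndarray, rel_prominence: float = 0.1):
    """Locations of prominent modes of a 1D sample (KDE + peak scan).

    A narrow bandwidth (0.1 x sample sd) keeps a broad secondary mode —
    e.g. a dimer population whose brightness noise scales with B — from
    being smoothed into the primary peak.
    """
    from scipy.signal import find_peaks
    kde = gaussian_kde(values, bw_method=0.1)
    lo, hi = np.percentile(values, [0.5, 99.5])
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=rel_prominence * dens.max())
    return grid[peaks], dens[peaks], (grid, dens)


def measure_monomer(series: RasterSeries, s_factor: float,
                    detrend_window: int | None = DETREND_WINDOW,
                    min_separation: float = 0.1,
                    smooth: int = 3) -> CursorSpec:
    """Calibrate the monomer cursor on a monomer-only acquisition.

    eps is the mode of (B - 1) over fluorescent pixels (B > 1); the cursor
    size spans the central 95% of the monomer B distribution.  A clearly
    bimodal B distribution raises: the sample is not monomeric.  The map is
    boxcar-smoothed first: per-pixel variance estimates are right-skewed at
    moderate frame counts, and neighbouring pixels sample the same
    molecules, so local averaging tightens the distribution around the true
    brightness without mixing species that are spatially separated.
    """
    bmap = brightness_map(series, s_factor=s_factor,
                          detrend_window=detrend_window)
    smoothed = _smooth(bmap.brightness, smooth)
    # fluorescent pixels: B above shot noise AND carrying real signal — in a
    # spatially structured sample the dim pixels between molecules would
    # otherwise contribute a spurious low-brightness mode
    mean_sm = _smooth(bmap.mean, smooth)
    floor = 0.25 * np.nanpercentile(mean_sm, 99)
    keep = np.isfinite(smoothed) & (smoothed > 1.0) & (mean_sm > floor)
    fluor = smoothed[keep]
    if fluor.size < 100:
        raise ValueError("too few fluorescent pixels to calibrate a monomer")
    locs, heights, _ = _kde_peaks(fluor - 1.0)
    if len(locs) > 1 and (locs.max() - locs.min()) > min_separation:
        raise ValueError("sample not monomeric: brightness distribution "
                         f"has modes at {np.round(locs, 3).tolist()}")
    eps = float(locs[np.argmax(heights)]) if len(locs) else float(np.median(fluor) - 1)
    if eps <= 0:
        raise ValueError("monomer brightness came out non-positive")
    lo, hi = np.percentile(fluor, [2.5, 97.5])
    # clip so that monomer and dimer windows can never overlap — the manual
    # equivalent is shrinking the cursor until the rectangles separate
    size = min(float(hi - lo), 0.9 * eps)
    return CursorSpec(s_factor=s_factor, monomer_brightness=eps,
                      cursor_size=size)


def _smooth(img: np.ndarray, size: int) -> np.ndarray:
    """NaN-aware boxcar smoothing of a brightness map."""
    if size <= 1:
        return img
    filled = np.where(np.isfinite(img), img, 0.0)
    weight = np.isfinite(img).astype(float)
    num = uniform_filter(filled, size=size, mode="nearest")
    den = uniform_filter(weight, size=size, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out[~np.isfinite(img) & (den == 0)] = np.nan
    return out


def classify_oligomers(bmap: BrightnessMap, cursor: CursorSpec,
                       smooth: int = 3) -> dict:
    """Percent monomer / homodimer by pixel-cursor counting.

    Pixels are classified on the brightness axis alone: the monomer cursor
    is centred at 1 + eps, the homodimer cursor at 1 + 2 eps (same size).
    Percentages are over monomer+dimer pixels only.  Neighbouring pixels
    sample the same molecules, so a small boxcar smooth (default 3x3) is
    applied before classification to suppress estimator noise.
    """
    if cursor.cursor_size > cursor.monomer_brightness:
        raise ValueError(
            "monomer and dimer cursors overlap: cursor size "
            f"{cursor.cursor_size:.3g} exceeds eps {cursor.monomer_brightness:.3g}; "
            f"need eps >= {cursor.cursor_size:.3g}"
        )
    b = _smooth(bmap.brightness, smooth)
    m_lo, m_hi = cursor.monomer_window()
    d_lo, d_hi = cursor.dimer_window()
    mono = np.nansum((b >= m_lo) & (b < m_hi))
    dim = np.nansum((b >= d_lo) & (b < d_hi))
    total = mono + dim
    if total == 0:
        return {"pct_monomer": np.nan, "pct_dimer": np.nan,
                "n_monomer": 0, "n_dimer": 0}
    return {"pct_monomer": 100.0 * mono / total,
            "pct_dimer": 100.0 * dim / total,
            "n_monomer": int(mono), "n_dimer": int(dim)}


# ---------------------------------------------------------------------------
# cross-N&B


def cross_brightness(green: RasterSeries, red: RasterSeries,
                     cursor_green: CursorSpec | None = None,
                     cursor_red: CursorSpec | None = None,
                     detrend_window: int | None = DETREND_WINDOW) -> CrossMap:
    """Per-pixel cross-variance, cross-brightness and cross-number.

    ``sigma_cc^2 = sum_i (G_i - <G>)(R_i - <R>) / K`` on detrended
    fluctuations; ``B_cc = sigma_cc^2 / (<G><R>)`` is defined only where both
    channel means are positive.  Channels must be pixel-registered and
    frame-synchronous.
    """
    g = np.asarray(green.counts, float)
    r = np.asarray(red.counts, float)
    if g.shape != r.shape:
        raise ValueError(f"channel shapes differ: {g.shape} vs {r.shape}")
    n = g.shape[0]
    window = detrend_window
    if window:
        if window >= n:
            raise ValueError("detrend window must be smaller than frame count")
        half = window // 2

        def resid_and_mean(c):
            cum = np.concatenate([np.zeros((1,) + c.shape[1:]),
                                  np.cumsum(c, axis=0)])
            idx = np.arange(half, n - half)
            local = (cum[idx + half + 1] - cum[idx - half]) / (window + 1)
            res = c[idx] - local
            return res - res.mean(axis=0), c[idx].mean(axis=0)

        dg, mg = resid_and_mean(g)
        dr, mr = resid_and_mean(r)
        corr = 1.0 - 1.0 / (window + 1)
        sigma_cc = (dg * dr).mean(axis=0) / corr
        k_used = dg.shape[0]
    else:
        mg, mr = g.mean(axis=0), r.mean(axis=0)
        sigma_cc = ((g - mg) * (r - mr)).mean(axis=0)
        k_used = n

    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (mg > 0) & (mr > 0)
        b_cc = np.where(ok, sigma_cc / (mg * mr), np.nan)
        n_cc = np.where(sigma_cc != 0, mg * mr / sigma_cc, np.nan)

    sg = cursor_green.s_factor if cursor_green else 1.0
    sr = cursor_red.s_factor if cursor_red else 1.0
    b_g = brightness_map(green, s_factor=sg, detrend_window=window).brightness
    b_r = brightness_map(red, s_factor=sr, detrend_window=window).brightness
    return CrossMap(sigma_cc=sigma_cc, b_cc=b_cc, n_cc=n_cc, mean_g=mg,
                    mean_r=mr, b_g=b_g, b_r=b_r, n_frames=k_used,
                    green=green, red=red)


def _bcc_shuffle_null(cross: CrossMap, n_shuffles: int, seed: int,
                      detrend_window: int | None) -> np.ndarray:
    """Pooled B_cc values under temporal shuffling of the red channel."""
    rng = np.random.default_rng(seed)
    vals = []
    red = cross.red
    for _ in range(n_shuffles):
        perm = rng.permutation(red.counts.shape[0])
        shuf = RasterSeries(counts=red.counts[perm], config=red.config)
        null = cross_brightness(cross.green, shuf,
                                detrend_window=detrend_window)
        v = null.b_cc[np.isfinite(null.b_cc)]
        vals.append(v)
    return np.concatenate(vals) if vals else np.array([])


def complex_stoichiometry(cross: CrossMap, cursor_green: CursorSpec,
                          cursor_red: CursorSpec, smooth: int = 3,
                          n_shuffles: int = 10, seed: int = 0,
                          null_quantile: float = 95.0,
                          detrend_window: int | None = DETREND_WINDOW) -> StoichiometryResult:
    """Stoichiometry of cross-correlated complexes by cursor-pair counting.

    Pixels whose B_cc exceeds the ``null_quantile`` percentile of a
    temporal-shuffle null are taken as complexed; among those with red
    brightness in the red monomer cursor, green brightness in the monomer
    cursor marks a 1:1 complex and in the dimer cursor a 2:1 complex.
    Percentages are over classified complexed pixels.
    """
    if cross.green is None or cross.red is None:
        raise ValueError("CrossMap must retain its source series")
    null = _bcc_shuffle_null(cross, n_shuffles, seed, detrend_window)
    thr = np.percentile(null, null_quantile) if null.size else np.inf
    b_cc = _smooth(cross.b_cc, smooth)
    sig = np.isfinite(b_cc) & (b_cc > max(thr, 0.0))
    n_sig = int(sig.sum())
    if n_sig == 0:
        return StoichiometryResult(fraction_11=np.nan, fraction_21=np.nan,
                                   n_pixels_11=0, n_pixels_21=0,
                                   n_significant=0,
                                   warning="no cross-correlated pixels")
    b_g = _smooth(cross.b_g, smooth)
    b_r = _smooth(cross.b_r, smooth)
    rm_lo, rm_hi = cursor_red.monomer_window()
    red_mono = sig & (b_r >= rm_lo) & (b_r < rm_hi)
    gm_lo, gm_hi = cursor_green.monomer_window()
    gd_lo, gd_hi = cursor_green.dimer_window()
    is11 = red_mono & (b_g >= gm_lo) & (b_g < gm_hi)
    is21 = red_mono & (b_g >= gd_lo) & (b_g < gd_hi)
    n11, n21 = int(is11.sum()), int(is21.sum())
    total = n11 + n21
    counts, edges = np.histogram(b_g[sig & np.isfinite(b_g)], bins=32)
    hist = {"green_b_counts": counts.tolist(),
            "green_b_edges": np.round(edges, 4).tolist(),
            "n_unclassified": n_sig - total}
    if total == 0:
        return StoichiometryResult(fraction_11=np.nan, fraction_21=np.nan,
                                   n_pixels_11=0, n_pixels_21=0,
                                   n_significant=n_sig, histogram=hist,
                                   warning="no pixels inside the cursors")
    return StoichiometryResult(
        fraction_11=100.0 * n11 / total, fraction_21=100.0 * n21 / total,
        n_pixels_11=n11, n_pixels_21=n21, n_significant=n_sig,
        histogram=hist)
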