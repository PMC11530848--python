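"""Per-pixel power spectral densities and the A f^-m + B model fit.

Each pixel's decorrelated time series is turned into a one-sided
periodogram over [1/duration, 1/(2 dt)] (0.01-10 Hz at the default
100 s / 20 fps acquisition), normalized so that the integral of the PSD
over frequency equals the temporal variance (Parseval).  The mean PSD over
background pixels defines the *floor*; cell pixels are retained for
fitting only when their PSD clears the floor by a configurable margin at
enough frequencies.  The floor-subtracted (differential) PSD is then
fitted to

    S(f) = A f^-m + B

in the log domain.  m > 0 is the logarithmic slope — near 1 + beta for
passive (thermal) dynamics and approaching 2 (1 + beta) inside active
regions.  The reported amplitude is the power-law component evaluated at
the lowest resolved frequency, ``A * 0.01**-m`` by default.  B is a
constant correction mimicking the flattening toward thermal fluctuations
at high frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .core_io import AnalysisConfig, OPDMovie, RegionMask

__all__ = [
    "PixelPSD",
    "PSDFloor",
    "PSDFit",
    "pixel_psd",
    "movie_psds",
    "psd_floor",
    "filter_pixels",
    "fit_psd",
    "slope_amplitude_maps",
]


@dataclass
class PixelPSD:
    """One-sided PSD of a single pixel, DC excluded.

    Satisfies Parseval: sum(values) * df == temporal variance of the
    (mean-removed) series, to float precision.
    """

    frequencies: np.ndarray  # Hz
    values: np.ndarray  # nm^2/Hz
    constant_input: bool = False  # zero-variance series flag


@dataclass
class PSDFloor:
    """Frequency-wise mean PSD over background pixels."""

    frequencies: np.ndarray
    values: np.ndarray
    degenerate: bool = False  # all-zero background flag


@dataclass
class PSDFit:
    """Result of the S(f) = A f^-m + B fit for one pixel."""

    A: float
    m: float
    B: float
    amp_eval: float  # power-law component at the evaluation frequency
    eval_freq: float
    success: bool
    fallback: bool  # True when the nonlinear fit failed and the log-log line was used
    residual: float  # RMS log-residual of the accepted fit
    n_excluded: int  # non-positive differential-PSD bins left out of the fit


def pixel_psd(series: np.ndarray, dt: float) -> PixelPSD:
    """One-sided periodogram of a single time series.

    Boxcar window, constant detrend (mean removal), density scaling — the
    combination for which the discrete Parseval identity is exact.  The DC
    bin is dropped.  A constant series yields a zero PSD with
    ``constant_input`` set.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 16:
        raise ValueError("series must be 1-D with at least 16 samples")
    freqs, pxx = signal.periodogram(
        series, fs=1.0 / dt, window="boxcar", detrend="constant", scaling="density"
    )
    constant = bool(np.allclose(series, series[0]))
    return PixelPSD(frequencies=freqs[1:], values=pxx[1:], constant_input=constant)


def movie_psds(
    movie: OPDMovie, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Periodograms of every masked pixel at once: (freqs, (npix, nf) array)."""
    mask = np.asarray(mask, bool)
    series = movie.data[:, mask].T  # (npix, T)
    freqs, pxx = signal.periodogram(
        series, fs=movie.meta.frame_rate, window="boxcar", detrend="constant",
        scaling="density", axis=-1,
    )
    return freqs[1:], pxx[:, 1:]


def psd_floor(residual: OPDMovie, mask: RegionMask) -> PSDFloor:
    """Average PSD over all background pixels of the decorrelated movie."""
    bg = mask.background_mask()
    if not bg.any():
        raise ValueError("mask defines no background pixels")
    freqs, pxx = movie_psds(residual, bg)
    mean = pxx.mean(axis=0)
    return PSDFloor(frequencies=freqs, values=mean, degenerate=bool(np.all(mean == 0)))


def filter_pixels(
    psd_values: np.ndarray,
    floor: PSDFloor,
    ratio: float = 1.25,
    min_frac: float = 0.70,
) -> np.ndarray | bool:
    """Pixel-retention rule for spectral fitting.

    Keep a pixel iff its PSD exceeds ``ratio`` x floor at a fraction of
    frequency bins >= ``min_frac`` (boundary inclusive).  Accepts a single
    PSD (1-D) or a stack (npix, nf); returns a bool or bool array.
    """
    v = np.atleast_2d(np.asarray(psd_values, dtype=float))
    if v.shape[-1] != floor.values.shape[0]:
        raise ValueError("PSD and floor frequency grids do not match")
    frac = (v > ratio * floor.values).mean(axis=-1)
    keep = frac >= min_frac - 1e-12
    return bool(keep[0]) if np.asarray(psd_values).ndim == 1 else keep


def _loglog_line(f: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    """Log-log linear regression; returns (A, m, rms residual)."""
    res = linregress(np.log(f), np.log(p))
    m = -res.slope
    A = float(np.exp(res.intercept))
    pred = res.intercept + res.slope * np.log(f)
    rms = float(np.sqrt(np.mean((np.log(p) - pred) ** 2)))
    return A, float(m), rms


def fit_psd(
    frequencies: np.ndarray,
    diff_psd: np.ndarray,
    band: tuple[float, float] | None = None,
    eval_freq: float = 0.01,
    amp_includes_offset: bool = False,
    min_bins: int = 8,
) -> PSDFit:
    """Fit S(f) = A f^-m + B to a floor-subtracted PSD in the log domain.

    Non-positive differential bins are excluded (not clipped) to avoid
    log-domain bias; their count is reported.  The nonlinear fit is
    initialized from the log-log linear regression, with B started at the
    median of the top frequency decade.  If it fails to converge, the pure
    log-log line (B = 0) is returned with ``fallback`` set.

    ``band`` restricts the fit to [fmin, fmax]; ``amp_eval`` is
    A * eval_freq**-m, or the full model value including B when
    ``amp_includes_offset`` is true.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(diff_psd, dtype=float)
    sel = np.isfinite(p)
    if band is not None:
        sel &= (f >= band[0]) & (f <= band[1])
    n_excluded = int((sel & (p <= 0)).sum())
    sel &= p > 0
    f_fit, p_fit = f[sel], p[sel]
    if f_fit.size < min_bins:
        return PSDFit(np.nan, np.nan, np.nan, np.nan, eval_freq,
                      success=False, fallback=False, residual=np.nan,
                      n_excluded=n_excluded)

    A0, m0, rms0 = _loglog_line(f_fit, p_fit)
    top_decade = f_fit >= f_fit.max() / 10.0
    B0 = max(float(np.median(p_fit[top_decade])), 1e-300)

    def log_model(logf, logA, m, logB):
        return np.logaddexp(logA - m * logf, logB)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                log_model,
                np.log(f_fit),
                np.log(p_fit),
                p0=[np.log(max(A0, 1e-300)), m0, np.log(B0)],
                bounds=([-700.0, -2.0, -700.0], [700.0, 8.0, 700.0]),
                maxfev=2000,
            )
        A, m, B = float(np.exp(popt[0])), float(popt[1]), float(np.exp(popt[2]))
        pred = log_model(np.log(f_fit), *popt)
        rms = float(np.sqrt(np.mean((np.log(p_fit) - pred) ** 2)))
        fallback = False
    except (RuntimeError, ValueError):
        A, m, B, rms, fallback = A0, m0, 0.0, rms0, True

    amp = A * eval_freq ** (-m) + (B if amp_includes_offset else 0.0)
    return PSDFit(A=A, m=m, B=B, amp_eval=amp, eval_freq=eval_freq,
                  success=True, fallback=fallback, residual=rms,
                  n_excluded=n_excluded)


def slope_amplitude_maps(
    residual: OPDMovie,
    cell_mask: np.ndarray,
    floor: PSDFloor,
    config: AnalysisConfig | None = None,
    band: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel PSD -> filter -> fit over a cell: (m map, amplitude map, fitted mask).

    Unfit pixels (filtered out, or fit failure) are NaN in both maps.
    Cell-level summaries should average over the fitted mask only.
    """
    config = config or AnalysisConfig()
    cell_mask = np.asarray(cell_mask, bool)
    if not cell_mask.any():
        nan_map = np.full(residual.frame_shape, np.nan)
        return nan_map, nan_map.copy(), np.zeros(residual.frame_shape, bool)
    freqs, pxx = movie_psds(residual, cell_mask)
    keep = filter_pixels(pxx, floor, config.psd_floor_ratio, config.psd_min_frac)
    m_map = np.full(residual.frame_shape, np.nan)
    a_map = np.full(residual.frame_shape, np.nan)
    fitted = np.zeros(residual.frame_shape, bool)
    rows, cols = np.nonzero(cell_mask)
    for i in np.flatnonzero(keep):
        fit = fit_psd(
            freqs,
            pxx[i] - floor.values,
            band=band,
            eval_freq=config.amplitude_eval_freq,
            amp_includes_offset=config.amp_includes_offset,
        )
        if fit.success:
            r, c = rows[i], cols[i]
            m_map[r, c] = fit.m
            a_map[r, c] = fit.amp_eval
            fitted[r, c] = True
    return m_map, a_map, fitted
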